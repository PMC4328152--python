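"""MK models of discrete sociality and stochastic character mapping.

Sociality is modelled as a continuous-time Markov chain (the MK model) on the
phylogeny, with the root state fixed (solitary is the accepted ancestral
condition in Hymenoptera, so the likelihood conditions on it rather than
averaging over root states).  Transition rates are estimated by maximum
likelihood with the Felsenstein pruning algorithm; character histories are
then drawn conditional on the observed tip states by sampling node states
pre-order from their joint conditional distribution and filling in each
branch with an endpoint-conditioned path via uniformization.

States are integer codes.  The two-state coding is 0 = solitary,
1 = eusocial; the four-state coding is 0 = solitary, 1 = cooperative breeder,
2 = facultatively eusocial, 3 = obligately eusocial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from karyosocial.phylo_core import Phylogeny

__all__ = [
    "MKFit",
    "StochasticMap",
    "build_rate_matrix",
    "transition_probability",
    "mk_loglik",
    "fit_mk",
    "sample_histories",
    "sample_branch_path",
    "state_occupancy",
    "simmap_to_annotated_newick",
]

LOG_RATE_BOUNDS = (-12.0, 5.0)  # optimization box on log(rate) per unit time


@dataclass
class MKFit:
    """A fitted MK model: rate matrix, fixed root state, and its log-likelihood."""

    n_states: int
    Q: np.ndarray
    root_state: int
    loglik: float
    parameterization: str = "ARD"
    tip_states: np.ndarray | None = None  # canonical tip order of the fitted tree

    def __post_init__(self):
        self.Q = np.asarray(self.Q, dtype=float)
        _validate_q(self.Q)


@dataclass
class StochasticMap:
    """One sampled character history on a tree.

    ``segments[i]`` lists ``(state, duration)`` pairs along the branch
    subtending node ``i``, ordered from the parent towards the node; the root
    (node 0) has no branch and an empty list.  ``node_states[i]`` is the state
    at node ``i``.
    """

    tree: Phylogeny
    node_states: np.ndarray
    segments: list[list[tuple[int, float]]]
    root_state: int
    seed_key: tuple[int, ...] = field(default=())

    def branch_duration(self, i: int) -> float:
        return sum(d for _, d in self.segments[i])


def _validate_q(Q: np.ndarray) -> None:
    Q = np.asarray(Q, dtype=float)
    if Q.ndim != 2 or Q.shape[0] != Q.shape[1]:
        raise ValueError("Q must be square")
    off = Q[~np.eye(Q.shape[0], dtype=bool)]
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal rates must be non-negative")
    if np.any(np.abs(Q.sum(axis=1)) > 1e-10 * max(1.0, np.abs(Q).max())):
        raise ValueError("rows of Q must sum to zero")


def build_rate_matrix(rates: Sequence[float], n_states: int,
                      parameterization: str = "ARD") -> np.ndarray:
    """Assemble Q from free rates.

    ``ARD`` takes ``k*(k-1)`` rates filling off-diagonals row-major;
    ``ER`` takes a single shared rate.
    """
    k = n_states
    Q = np.zeros((k, k))
    if parameterization == "ARD":
        if len(rates) != k * (k - 1):
            raise ValueError(f"ARD needs {k*(k-1)} rates")
        it = iter(rates)
        for i in range(k):
            for j in range(k):
                if i != j:
                    Q[i, j] = next(it)
    elif parameterization == "ER":
        if len(rates) != 1:
            raise ValueError("ER needs exactly 1 rate")
        Q[:] = rates[0]
        np.fill_diagonal(Q, 0.0)
    else:
        raise ValueError(f"unknown parameterization {parameterization!r}")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix P(t) = exp(Qt)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    _validate_q(np.asarray(Q, dtype=float))
    P = expm(np.asarray(Q, dtype=float) * t)
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _tip_state_array(tree: Phylogeny, tip_states: Mapping[str, int] | Sequence[int]
                     ) -> np.ndarray:
    if isinstance(tip_states, Mapping):
        missing = [lb for lb in tree.tip_labels if lb not in tip_states]
        if missing:
            raise ValueError(f"tips without a state: {missing[:5]}")
        arr = np.array([tip_states[lb] for lb in tree.tip_labels], dtype=np.int64)
    else:
        arr = np.asarray(tip_states, dtype=np.int64)
        if len(arr) != tree.n_tips:
            raise ValueError("tip state vector length must equal tip count")
    return arr


def _pruning(tree: Phylogeny, states: np.ndarray, Q: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Post-order partial likelihoods with per-subtree log rescaling.

    Returns (partials L, per-node accumulated log scalers, per-edge P matrices).
    """
    k = Q.shape[0]
    n = tree.n_nodes
    P = np.empty((n, k, k))
    P[0] = np.eye(k)
    for i in range(1, n):
        P[i] = transition_probability(Q, float(tree.edge_length[i]))
    L = np.zeros((n, k))
    logsc = np.zeros(n)
    state_of = {int(t): int(s) for t, s in zip(tree.tip_indices, states)}
    for i in tree.postorder:
        ch = tree.children[i]
        if not ch:
            if not 0 <= state_of[int(i)] < k:
                raise ValueError(f"tip state {state_of[int(i)]} outside 0..{k-1}")
            L[i, state_of[int(i)]] = 1.0
        else:
            v = np.ones(k)
            s = 0.0
            for c in ch:
                v = v * (P[c] @ L[c])
                s += logsc[c]
            m = v.max()
            if m <= 0.0:
                L[i] = 0.0
                logsc[i] = -np.inf
            else:
                L[i] = v / m
                logsc[i] = s + np.log(m)
    return L, logsc, P


def mk_loglik(tree: Phylogeny, tip_states, Q: np.ndarray, root_state: int) -> float:
    """Log-likelihood of tip states under the MK model, conditioning on a
    fixed root state (no averaging over root states)."""
    states = _tip_state_array(tree, tip_states)
    Q = np.asarray(Q, dtype=float)
    _validate_q(Q)
    L, logsc, _ = _pruning(tree, states, Q)
    val = L[0, root_state]
    if val <= 0.0 or not np.isfinite(logsc[0]):
        return -np.inf
    return float(np.log(val) + logsc[0])


def fit_mk(tree: Phylogeny, tip_states, root_state: int,
           parameterization: str = "ARD", n_restarts: int = 8,
           seed: int | None = 0) -> MKFit:
    """Maximum-likelihood MK fit with the root state fixed.

    Optimization is on the log-rate scale inside a box, from several random
    starts (Nelder–Mead exploration followed by an L-BFGS-B polish); ties are
    broken by log-likelihood then by smaller rate-vector norm.
    """
    states = _tip_state_array(tree, tip_states)
    observed = np.unique(states)
    k = max(int(max(observed.max(), root_state)) + 1, 2)
    if tree.n_tips < 2:
        raise ValueError("need at least 2 tips")
    n_par = k * (k - 1) if parameterization == "ARD" else 1
    lo, hi = LOG_RATE_BOUNDS

    def neg_ll(logr):
        Q = build_rate_matrix(np.exp(np.clip(logr, lo, hi)), k, parameterization)
        return -mk_loglik(tree, states, Q, root_state)

    rng = np.random.default_rng(seed)
    depth = max(tree.tip_depths().max(), 1e-12)
    best = None
    for r in range(max(1, n_restarts)):
        if r == 0:
            x0 = np.full(n_par, np.log(1.0 / depth))
        else:
            x0 = rng.uniform(np.log(0.1 / depth), np.log(10.0 / depth), size=n_par)
        res = minimize(neg_ll, x0, method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8})
        res = minimize(neg_ll, np.clip(res.x, lo, hi), method="L-BFGS-B",
                       bounds=[(lo, hi)] * n_par)
        if not np.isfinite(res.fun):
            continue
        cand = (res.fun, float(np.linalg.norm(np.exp(res.x))), res.x)
        if best is None or cand[0] < best[0] - 1e-8 or (
                abs(cand[0] - best[0]) <= 1e-8 and cand[1] < best[1]):
            best = cand
    if best is None:
        raise RuntimeError("MK likelihood non-finite at every start")
    Q = build_rate_matrix(np.exp(np.clip(best[2], lo, hi)), k, parameterization)
    return MKFit(n_states=k, Q=Q, root_state=int(root_state),
                 loglik=-best[0], parameterization=parameterization,
                 tip_states=states)


# ----------------------------------------------------------------- sampling


def sample_branch_path(Q: np.ndarray, t: float, a: int, b: int,
                       rng: np.random.Generator,
                       p_ab: float | None = None) -> list[tuple[int, float]]:
    """Endpoint-conditioned CTMC path on one branch, by uniformization.

    Returns ``(state, duration)`` segments from the parent end (state ``a``)
    to the child end (state ``b``); durations sum to ``t``.
    """
    Q = np.asarray(Q, dtype=float)
    k = Q.shape[0]
    if t <= 0.0:
        if a != b:
            raise ValueError("zero-length branch cannot change state")
        return [(int(a), float(t))]
    lam = float(np.max(-np.diag(Q)))
    if lam <= 0.0:
        if a != b:
            raise ValueError("zero rate matrix cannot change state")
        return [(int(a), float(t))]
    if p_ab is None:
        p_ab = transition_probability(Q, t)[a, b]
    if p_ab <= 0.0:
        raise ValueError(f"endpoint pair ({a} -> {b}) has zero probability")
    R = np.eye(k) + Q / lam
    # number of uniformized jumps N: p(n) ∝ Poisson(lam*t; n) * R^n[a, b]
    u = rng.uniform()
    pois = np.exp(-lam * t)
    Rpow = [np.eye(k)]
    cum = pois * Rpow[0][a, b] / p_ab
    N = 0
    while cum < u:
        N += 1
        pois *= lam * t / N
        Rpow.append(Rpow[-1] @ R)
        cum += pois * Rpow[N][a, b] / p_ab
        if N > 100000:  # pragma: no cover - numerical safety net
            raise RuntimeError("uniformization failed to converge")
    if N == 0:
        return [(int(a), float(t))]
    times = np.sort(rng.uniform(0.0, t, size=N))
    seq = [int(a)]
    for j in range(1, N + 1):
        w = R[seq[-1], :] * Rpow[N - j][:, b]
        tot = w.sum()
        if tot <= 0.0:
            raise ValueError(f"endpoint pair ({a} -> {b}) has zero probability")
        seq.append(int(rng.choice(k, p=w / tot)))
    # collapse virtual (self) jumps into segments
    segments: list[tuple[int, float]] = []
    cur_state = int(a)
    cur_start = 0.0
    for j in range(1, N + 1):
        if seq[j] != cur_state:
            segments.append((cur_state, float(times[j - 1] - cur_start)))
            cur_state = int(seq[j])
            cur_start = float(times[j - 1])
    segments.append((cur_state, float(t - cur_start)))
    return segments


def sample_histories(tree: Phylogeny, fit: MKFit, n_maps: int,
                     seed: int = 0) -> list[StochasticMap]:
    """Draw stochastic character maps conditioned on tip states and the fixed
    root state.

    Node states are sampled pre-order from their joint conditional
    distribution (using the pruning partials), then each branch history is
    filled in conditional on both endpoints.  Each map uses its own named
    random stream ``(seed, map_index)`` so individual maps are reproducible.
    """
    if n_maps < 1:
        raise ValueError("n_maps must be >= 1")
    if fit.tip_states is None:
        raise ValueError("MKFit carries no tip states; use "
                         "sample_histories_for_data to supply them")
    return sample_histories_for_data(tree, fit.tip_states, fit.Q,
                                     fit.root_state, n_maps, seed)


def sample_histories_for_data(tree: Phylogeny, tip_states, Q: np.ndarray,
                              root_state: int, n_maps: int,
                              seed: int = 0) -> list[StochasticMap]:
    """As :func:`sample_histories`, with tip states passed explicitly."""
    states = _tip_state_array(tree, tip_states)
    Q = np.asarray(Q, dtype=float)
    L, logsc, P = _pruning(tree, states, Q)
    if L[0, root_state] <= 0.0 or not np.isfinite(logsc[0]):
        raise ValueError("tip data have zero probability under this model")
    maps = []
    n = tree.n_nodes
    for m in range(n_maps):
        rng = np.random.default_rng([seed, m])
        node_states = np.empty(n, dtype=np.int64)
        node_states[0] = root_state
        for i in range(1, n):  # preorder
            w = P[i][node_states[tree.parent[i]], :] * L[i]
            tot = w.sum()
            if tot <= 0.0:
                raise ValueError(f"no feasible state for node {i}")
            node_states[i] = rng.choice(Q.shape[0], p=w / tot)
        segments: list[list[tuple[int, float]]] = [[]]
        for i in range(1, n):
            a = int(node_states[tree.parent[i]])
            b = int(node_states[i])
            try:
                segs = sample_branch_path(Q, float(tree.edge_length[i]), a, b,
                                          rng, p_ab=float(P[i][a, b]))
            except ValueError as exc:
                raise ValueError(f"branch above node {i}: {exc}") from exc
            segments.append(segs)
        maps.append(StochasticMap(tree=tree, node_states=node_states,
                                  segments=segments, root_state=int(root_state),
                                  seed_key=(seed, m)))
    return maps


def state_occupancy(smap: StochasticMap) -> dict[int, float]:
    """Total time spent in each state across all branches of a map."""
    occ: dict[int, float] = {}
    for segs in smap.segments:
        for s, d in segs:
            occ[s] = occ.get(s, 0.0) + d
    return occ


def simmap_to_annotated_newick(smap: StochasticMap) -> str:
    """Serialize a map as Newick with per-branch ``[&map=state,dur;...]``
    comment annotations (parent-to-child order)."""
    tree = smap.tree

    def render(i: int) -> str:
        if tree.children[i]:
            inner = ",".join(render(c) for c in tree.children[i])
            base = f"({inner})"
        else:
            base = tree.labels[i]
        if i == 0:
            return base
        ann = ";".join(f"{s},{d:.10g}" for s, d in smap.segments[i])
        return f"{base}:{tree.edge_length[i]:.10g}[&map={ann}]"

    return render(0) + ";\n"
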