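"""Independent brute-force oracles used only by the test suite.

Each oracle computes the same quantity as a package operation through a
different route (full enumeration, per-pair path walking, rejection
sampling), so agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.linalg import expm

from karyosocial.mk_simmap import StochasticMap
from karyosocial.phylo_core import Phylogeny


def mk_loglik_enumeration(tree: Phylogeny, tip_states: np.ndarray,
                          Q: np.ndarray, root_state: int) -> float:
    """Likelihood by explicit summation over all internal-node state
    assignments (exponential cost; only for tiny trees)."""
    k = Q.shape[0]
    P = {i: expm(Q * float(tree.edge_length[i]))
         for i in range(1, tree.n_nodes)}
    internal = [i for i in range(tree.n_nodes) if tree.children[i]]
    state_of = {int(t): int(s) for t, s in zip(tree.tip_indices, tip_states)}
    total = 0.0
    for assign in itertools.product(range(k), repeat=len(internal)):
        amap = dict(zip(internal, assign))
        if amap[0] != root_state:
            continue
        p = 1.0
        for i in range(1, tree.n_nodes):
            sp = amap[tree.parent[i]]
            si = amap[i] if i in amap else state_of[i]
            p *= P[i][sp, si]
        total += p
    return float(np.log(total)) if total > 0 else -np.inf


def painted_covariance_pathwalk(tree: Phylogeny, smap: StochasticMap,
                                rates) -> np.ndarray:
    """Painted-tree BM covariance by walking each tip pair's root paths and
    accumulating rate-weighted durations on the shared edges."""
    ancestors = []
    for t in tree.tip_indices:
        chain = []
        i = int(t)
        while i != 0:
            chain.append(i)
            i = int(tree.parent[i])
        ancestors.append(set(chain))
    n = tree.n_tips
    C = np.zeros((n, n))
    for a in range(n):
        for b in range(a, n):
            shared = ancestors[a] & ancestors[b]
            v = 0.0
            for e in shared:
                for s, d in smap.segments[e]:
                    r = rates[s] if not np.isscalar(rates) else float(rates)
                    v += r * d
            C[a, b] = C[b, a] = v
    return C


def rejection_sample_paths(Q: np.ndarray, t: float, a: int, b: int,
                           n_paths: int, rng: np.random.Generator
                           ) -> np.ndarray:
    """Numbers of true state changes on endpoint-conditioned paths, sampled
    by forward simulation with rejection on the end state."""
    k = Q.shape[0]
    counts = np.empty(n_paths, dtype=np.int64)
    got = 0
    while got < n_paths:
        s = a
        pos = 0.0
        changes = 0
        while True:
            rate = -Q[s, s]
            if rate <= 0:
                break
            wait = rng.exponential(1.0 / rate)
            if pos + wait >= t:
                break
            pos += wait
            probs = np.clip(Q[s], 0.0, None)
            probs[s] = 0.0
            s = int(rng.choice(k, p=probs / probs.sum()))
            changes += 1
        if s == b:
            counts[got] = changes
            got += 1
    return counts
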