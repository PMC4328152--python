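"""Sister-group contrasts and Siegel's matched-pair randomization test.

Each contrast pairs a eusocial clade with its solitary sister group and
records the difference in mean haploid chromosome number,
``d = eusocial mean - solitary mean``.  Under the null hypothesis that
eusociality does not shift chromosome number, the sign of each ``d`` is
exchangeable, so the test enumerates all ``2^n`` sign assignments of the
observed differences and computes the two-tailed probability that the sum
statistic ``T = sum(d_i)`` is at least as extreme as observed.

The pair in which eusociality was secondarily *lost* (the derived clade is
solitary) tests the reverse prediction, so it is excluded from the matched
contrast set when losses are filtered out; it is still counted and reported
alongside the origins.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence
import warnings

import numpy as np
import pandas as pd

__all__ = [
    "SisterContrast",
    "RandomizationResult",
    "read_pairs_table",
    "load_packaged_pairs",
    "build_contrasts",
    "count_positive",
    "randomization_test",
]


@dataclass(frozen=True)
class SisterContrast:
    contrast_id: str
    eusocial_clade: str
    eusocial_mean: float
    eusocial_n: int
    solitary_clade: str
    solitary_mean: float
    solitary_n: int
    is_loss: bool = False

    @property
    def difference(self) -> float:
        """Eusocial mean minus solitary mean."""
        return self.eusocial_mean - self.solitary_mean


@dataclass
class RandomizationResult:
    statistic: float
    n_pairs: int
    n_assignments: int
    p_value: float
    exact: bool


def read_pairs_table(path) -> pd.DataFrame:
    """Read a sister-pair TSV: columns ``contrast``, ``clade``, ``eusocial``
    (0/1), ``mean_n`` (NA allowed), ``n_species``, ``origin`` (origin/loss)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"contrast", "clade", "eusocial", "mean_n", "n_species"}
    if not needed <= set(df.columns):
        raise ValueError(f"pairs table must have columns {sorted(needed)}")
    return df


def load_packaged_pairs() -> pd.DataFrame:
    """The packaged sister-group comparison table for Hymenoptera (clade mean
    haploid counts and species numbers compiled from the published karyotype
    literature)."""
    ref = resources.files("karyosocial").joinpath("data/sister_groups.tsv")
    with resources.as_file(ref) as path:
        return read_pairs_table(path)


def build_contrasts(pairs: pd.DataFrame, min_species: int = 1,
                    include_losses: bool = True) -> list[SisterContrast]:
    """Pair up rows per contrast id and apply the data filters.

    Data-deficient pairs (either clade mean missing) are dropped; pairs where
    either clade has fewer than ``min_species`` species are dropped;
    ``include_losses=False`` additionally drops pairs flagged as a loss of
    eusociality (those test the reverse prediction).
    """
    out = []
    for cid, grp in pairs.groupby("contrast", sort=True):
        eu = grp[grp["eusocial"] == 1]
        so = grp[grp["eusocial"] == 0]
        if len(eu) != 1 or len(so) != 1:
            raise ValueError(f"contrast {cid!r} must have one eusocial and "
                             "one solitary clade")
        eu, so = eu.iloc[0], so.iloc[0]
        if pd.isna(eu["mean_n"]) or pd.isna(so["mean_n"]):
            continue
        if "origin" in grp.columns:
            is_loss = str(grp["origin"].iloc[0]).strip().lower() == "loss"
        else:
            is_loss = False
        if int(eu["n_species"]) < min_species or int(so["n_species"]) < min_species:
            continue
        if is_loss and not include_losses:
            continue
        out.append(SisterContrast(
            contrast_id=str(cid),
            eusocial_clade=str(eu["clade"]), eusocial_mean=float(eu["mean_n"]),
            eusocial_n=int(eu["n_species"]),
            solitary_clade=str(so["clade"]), solitary_mean=float(so["mean_n"]),
            solitary_n=int(so["n_species"]), is_loss=is_loss))
    return out


def count_positive(contrasts: Sequence[SisterContrast]) -> tuple[int, int]:
    """(number of contrasts with a higher eusocial mean, number of ties)."""
    if len(contrasts) == 0:
        raise ValueError("no contrasts to count")
    pos = sum(1 for c in contrasts if c.difference > 0)
    ties = sum(1 for c in contrasts if c.difference == 0)
    return pos, ties


def randomization_test(differences: Sequence[float], tails: int = 2,
                       max_exact: int = 20, n_mc: int = 100_000,
                       seed: int | None = 0,
                       statistic: str = "sum") -> RandomizationResult:
    """Siegel's randomization test for matched pairs.

    Enumerates all ``2^n`` sign assignments exactly when ``n <= max_exact``,
    otherwise uses ``n_mc`` Monte-Carlo assignments.  ``statistic`` is the
    sum of signed differences (classical) or the sum of signs.  Zero
    differences are dropped with a warning.
    """
    if tails != 2:
        raise ValueError("only the two-tailed test is defined (the sign-flip "
                         "null is symmetric)")
    d = np.asarray(list(differences), dtype=float)
    if np.any(d == 0):
        warnings.warn("dropping zero differences before enumeration",
                      stacklevel=2)
        d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("no nonzero differences")
    if statistic == "signs":
        d = np.sign(d)
    elif statistic != "sum":
        raise ValueError("statistic must be 'sum' or 'signs'")
    t_obs = float(d.sum())
    if n <= max_exact:
        # all 2^n sign vectors, in blocks to bound memory
        total = 0
        n_assign = 2 ** n
        block = 1 << 16
        codes = np.arange(n_assign, dtype=np.int64)
        for start in range(0, n_assign, block):
            c = codes[start:start + block]
            signs = ((c[:, None] >> np.arange(n)) & 1) * 2 - 1
            t = signs @ d
            total += int(np.sum(np.abs(t) >= abs(t_obs) - 1e-12))
        p = total / n_assign
        return RandomizationResult(statistic=t_obs, n_pairs=n,
                                   n_assignments=n_assign, p_value=p,
                                   exact=True)
    rng = np.random.default_rng(seed)
    signs = rng.integers(0, 2, size=(n_mc, n)) * 2 - 1
    t = signs @ d
    p = float(np.mean(np.abs(t) >= abs(t_obs) - 1e-12))
    return RandomizationResult(statistic=t_obs, n_pairs=n, n_assignments=n_mc,
                               p_value=p, exact=False)
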