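"""Trees, trait tables, and karyotype data-coding rules.

The central object is :class:`Phylogeny`, an immutable array-backed rooted
tree with branch lengths in time units.  Newick reading and writing is
delegated to :mod:`dendropy`; the array form (parent pointers plus traversal
orders) is what the likelihood machinery in the rest of the package consumes.

Data-coding conventions for karyotype compilations:

* multiple published haploid counts for one species are averaged, a count
  reported as a range contributes the midpoint of the inclusive range;
* polygyny or polyandry (or both) codes a species as ``"low"`` relatedness,
  a singly mated monogynous species as ``"high"``;
* species names are matched exactly after whitespace/underscore
  normalization and case-folding.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Phylogeny",
    "KaryotypeRecord",
    "NewickParseError",
    "parse_karyotype_field",
    "aggregate_karyotype",
    "code_relatedness",
    "normalize_species",
    "match_tree_and_traits",
    "read_trait_table",
    "write_trait_table",
    "read_occurrences",
    "validate_taxonomy",
    "TAXONOMIC_LEVELS",
]

TAXONOMIC_LEVELS = ("superfamily", "family", "subfamily", "genus")


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class Phylogeny:
    """Rooted tree with branch lengths, backed by flat numpy arrays.

    Nodes are indexed ``0 .. n_nodes-1`` in preorder (root first).  Tips are
    the nodes without children; their order of appearance in preorder defines
    the canonical tip order used by every tip-indexed vector or matrix in the
    package.

    Parameters
    ----------
    parent:
        Parent index per node; ``-1`` for the root (exactly one).
    edge_length:
        Length of the branch subtending each node (0.0 for the root).
    labels:
        Taxon label per node; ``None`` for unlabelled internal nodes.
    """

    __slots__ = ("parent", "edge_length", "labels", "children",
                 "_tip_indices", "_postorder")

    def __init__(self, parent: Sequence[int], edge_length: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.edge_length = np.asarray(edge_length, dtype=np.float64)
        self.labels = list(labels)
        n = len(self.parent)
        if not (len(self.edge_length) == len(self.labels) == n):
            raise ValueError("parent, edge_length and labels must align")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"tree must have exactly one root, found {len(roots)}")
        if roots[0] != 0:
            raise ValueError("root must be node 0 (preorder layout)")
        if np.any(self.edge_length[1:] < 0):
            raise ValueError("branch lengths must be non-negative")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise ValueError("nodes must be in preorder (parent before child)")
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(1, n):
            self.children[self.parent[i]].append(i)
        self._tip_indices = np.array(
            [i for i in range(n) if not self.children[i]], dtype=np.int64)
        tip_labels = [self.labels[i] for i in self._tip_indices]
        if any(lb is None for lb in tip_labels):
            raise ValueError("every tip must be labelled")
        if len(set(tip_labels)) != len(tip_labels):
            raise ValueError("tip labels must be unique")
        # children come after parents, so reversed preorder is a postorder
        self._postorder = np.arange(n - 1, -1, -1)

    # ------------------------------------------------------------------ I/O

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree) -> "Phylogeny":
        nodes = list(dtree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = [-1 if nd.parent_node is None else index[id(nd.parent_node)]
                  for nd in nodes]
        edge_length = [0.0 if nd.parent_node is None
                       else float(nd.edge.length or 0.0) for nd in nodes]
        labels = [nd.taxon.label if nd.taxon is not None else nd.label
                  for nd in nodes]
        return cls(parent, edge_length, labels)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse a Newick string (branch lengths required on non-root nodes)."""
        try:
            dtree = dendropy.Tree.get(
                data=text, schema="newick", preserve_underscores=True,
                suppress_internal_node_taxa=True)
        except Exception as exc:  # dendropy raises several error types
            raise NewickParseError(f"malformed Newick: {exc}") from exc
        return cls.from_dendropy(dtree)

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [dendropy.Node() for _ in range(self.n_nodes)]
        tipset = set(self._tip_indices.tolist())
        for i in range(self.n_nodes):
            dnodes[i].edge.length = float(self.edge_length[i])
            if i in tipset:
                dnodes[i].taxon = taxa.new_taxon(self.labels[i])
            elif self.labels[i] is not None:
                dnodes[i].label = self.labels[i]
        for i in range(1, self.n_nodes):
            dnodes[self.parent[i]].add_child(dnodes[i])
        dtree.seed_node = dnodes[0]
        return dtree

    def to_newick(self) -> str:
        out = self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True,
            real_value_format_specifier=".10g")
        return out.strip() + ("\n" if not out.endswith("\n") else "")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    # ----------------------------------------------------------- structure

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return 0

    @property
    def tip_indices(self) -> np.ndarray:
        return self._tip_indices

    @property
    def n_tips(self) -> int:
        return len(self._tip_indices)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self._tip_indices]

    @property
    def postorder(self) -> np.ndarray:
        """Node indices, children before parents."""
        return self._postorder

    def node_depths(self) -> np.ndarray:
        """Distance from the root to every node."""
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.edge_length[i]
        return depth

    def tip_depths(self) -> np.ndarray:
        return self.node_depths()[self._tip_indices]

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        d = self.tip_depths()
        return bool(np.ptp(d) <= rtol * max(d.max(), 1e-300))

    @property
    def total_branch_length(self) -> float:
        return float(self.edge_length[1:].sum())

    def descendant_tip_sets(self) -> list[np.ndarray]:
        """Per node, positions (in canonical tip order) of descendant tips."""
        tip_pos = {int(t): k for k, t in enumerate(self._tip_indices)}
        sets: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i in self._postorder:
            if not self.children[i]:
                sets[i] = [tip_pos[int(i)]]
            else:
                for c in self.children[i]:
                    sets[i].extend(sets[c])
        return [np.array(sorted(s), dtype=np.int64) for s in sets]

    def vcv(self) -> np.ndarray:
        """Shared root-to-MRCA path-length matrix over tips (BM covariance
        under a unit rate)."""
        n = self.n_tips
        C = np.zeros((n, n))
        desc = self.descendant_tip_sets()
        for i in range(1, self.n_nodes):
            idx = desc[i]
            C[np.ix_(idx, idx)] += self.edge_length[i]
        return C

    def prune_to(self, keep_labels: Iterable[str]) -> "Phylogeny":
        """Restrict the tree to ``keep_labels``; unifurcations are collapsed
        with their branch lengths summed, so root-to-tip path lengths of
        retained tips are preserved."""
        keep = set(keep_labels)
        present = [lb for lb in self.tip_labels if lb in keep]
        if not present:
            raise ValueError("no requested tip labels are present in the tree")
        if set(self.tip_labels) <= keep:
            return self
        dtree = self.to_dendropy()
        dtree.retain_taxa_with_labels(present)
        # dendropy may leave a unifurcate root carrying a stub edge
        dtree.suppress_unifurcations()
        seed = dtree.seed_node
        while len(seed.child_nodes()) == 1:
            child = seed.child_nodes()[0]
            child.parent_node = None
            dtree.seed_node = child
            seed = child
        dtree.seed_node.edge.length = None
        return Phylogeny.from_dendropy(dtree)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


# ---------------------------------------------------------------- karyotypes


@dataclass(frozen=True)
class KaryotypeRecord:
    """One published haploid chromosome count: a point value (``low == high``)
    or an inclusive range."""

    low: float
    high: float

    def __post_init__(self):
        if self.low <= 0 or self.high <= 0:
            raise ValueError("haploid counts must be positive")
        if self.low > self.high:
            raise ValueError("range low must not exceed high")

    @classmethod
    def point(cls, value: float) -> "KaryotypeRecord":
        return cls(float(value), float(value))

    @property
    def value(self) -> float:
        """Point value, or the midpoint of a range record."""
        return 0.5 * (self.low + self.high)


_RANGE_RE = re.compile(r"^\s*(\d+(?:\.\d+)?)\s*[-–]\s*(\d+(?:\.\d+)?)\s*$")


def parse_karyotype_field(field: str) -> list[KaryotypeRecord]:
    """Parse a semicolon-separated chromosome-count field, e.g. ``"16;53-60"``."""
    records = []
    for tok in str(field).split(";"):
        tok = tok.strip()
        if not tok:
            continue
        m = _RANGE_RE.match(tok)
        if m:
            records.append(KaryotypeRecord(float(m.group(1)), float(m.group(2))))
        else:
            records.append(KaryotypeRecord.point(float(tok)))
    return records


def aggregate_karyotype(records: Sequence[KaryotypeRecord | float]) -> float:
    """Aggregate multiple records for one species as the arithmetic mean;
    a range record contributes its midpoint."""
    if len(records) == 0:
        raise ValueError("cannot aggregate an empty record list")
    vals = [r.value if isinstance(r, KaryotypeRecord) else float(r)
            for r in records]
    if any(v <= 0 for v in vals):
        raise ValueError("haploid counts must be positive")
    return float(np.mean(vals))


def code_relatedness(polygynous: bool | None, polyandrous: bool | None) -> str | None:
    """Binary relatedness coding: any of polygyny/polyandry gives ``"low"``;
    a singly mated monogynous species gives ``"high"``.  A missing flag gives
    ``None`` (species excluded from relatedness analyses)."""
    if polygynous is None or polyandrous is None:
        return None
    return "low" if (polygynous or polyandrous) else "high"


# --------------------------------------------------------------- name match


def normalize_species(name: str) -> str:
    """Canonical species-name key: whitespace and underscores collapsed to a
    single underscore, case-folded.  Matching is exact on the key."""
    return re.sub(r"[\s_]+", "_", str(name).strip()).casefold()


def match_tree_and_traits(tree: Phylogeny, table: pd.DataFrame
                          ) -> tuple[Phylogeny, pd.DataFrame]:
    """Intersect a tree and a trait table on species name.

    Returns the tree pruned to the shared species and the table subset,
    reordered to the pruned tree's canonical tip order.  The table must have
    a ``species`` column.
    """
    key_to_row = {}
    for idx, sp in table["species"].items():
        key_to_row.setdefault(normalize_species(sp), idx)
    keep = [lb for lb in tree.tip_labels if normalize_species(lb) in key_to_row]
    if not keep:
        raise ValueError("tree and trait table share no species")
    pruned = tree.prune_to(keep)
    rows = [key_to_row[normalize_species(lb)] for lb in pruned.tip_labels]
    aligned = table.loc[rows].reset_index(drop=True)
    aligned["species"] = pruned.tip_labels
    return pruned, aligned


# ------------------------------------------------------------------- tables

_TRAIT_COLUMNS = ["species", "chromosome_n", "sociality", "colony_size",
                  "queens", "matings", "castes", "parasite",
                  "superfamily", "family", "subfamily", "genus"]


def read_trait_table(path) -> pd.DataFrame:
    """Read a tab-separated species trait table and apply the coding rules.

    Adds derived columns: ``n`` (aggregated haploid count), ``log_n``
    (natural log), ``eusocial`` (sociality >= 2) and ``relatedness``
    (from queen and mate numbers; NaN where either is missing).
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    if "species" not in df.columns:
        raise ValueError("trait table must have a 'species' column")
    if df["species"].duplicated().any():
        dups = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValueError(f"duplicate species rows: {dups[:5]}")
    if "chromosome_n" in df.columns:
        df["n"] = [
            aggregate_karyotype(parse_karyotype_field(v)) if pd.notna(v) else np.nan
            for v in df["chromosome_n"]
        ]
        df["log_n"] = np.log(df["n"])
    if "sociality" in df.columns:
        df["sociality"] = df["sociality"].astype("Int64")
        df["eusocial"] = (df["sociality"] >= 2).astype("Int64")
        df.loc[df["sociality"].isna(), "eusocial"] = pd.NA
    if {"queens", "matings"} <= set(df.columns):
        rel = []
        for q, m in zip(df["queens"], df["matings"]):
            if pd.isna(q) or pd.isna(m):
                rel.append(None)
            else:
                rel.append(code_relatedness(q > 1, m > 1))
        df["relatedness"] = rel
    return df


def write_trait_table(df: pd.DataFrame, path) -> None:
    cols = [c for c in _TRAIT_COLUMNS if c in df.columns]
    df.to_csv(path, sep="\t", index=False, columns=cols)


def read_occurrences(path) -> pd.DataFrame:
    """Read a tab-separated occurrence file (species, latitude, longitude).

    Malformed or out-of-range rows are dropped with a warning, mirroring how
    raw specimen databases are cleaned before range scoring.
    """
    df = pd.read_csv(path, sep="\t", dtype={"species": str})
    needed = {"species", "latitude", "longitude"}
    if not needed <= set(df.columns):
        raise ValueError(f"occurrence file must have columns {sorted(needed)}")
    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    ok = (lat.between(-90, 90) & lon.ge(-180) & lon.lt(180)
          & df["species"].notna())
    if (~ok).any():
        warnings.warn(f"dropping {int((~ok).sum())} invalid occurrence rows",
                      stacklevel=2)
    out = df.loc[ok, ["species"]].copy()
    out["latitude"] = lat[ok]
    out["longitude"] = lon[ok]
    return out.reset_index(drop=True)


def validate_taxonomy(df: pd.DataFrame) -> None:
    """Check that the nested taxonomy is consistent: each genus maps to one
    subfamily, each subfamily to one family, each family to one superfamily."""
    pairs = [("genus", "subfamily"), ("subfamily", "family"),
             ("family", "superfamily")]
    for child, parent in pairs:
        if child not in df.columns or parent not in df.columns:
            continue
        sub = df[[child, parent]].dropna().drop_duplicates()
        counts = sub.groupby(child)[parent].nunique()
        bad = counts[counts > 1]
        if len(bad):
            raise ValueError(
                f"inconsistent taxonomy: {child} {bad.index[0]!r} maps to "
                f"{bad.iloc[0]} different {parent} values")
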