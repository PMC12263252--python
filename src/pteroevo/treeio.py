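"""Phylogeny, trait-table and occupancy-table containers with readers and validators.

Trees are held in a flat array representation (parent pointers + branch
lengths in Myr) that the likelihood machinery consumes directly; Newick
parsing and writing go through :mod:`dendropy` so BEAST/IQ-TREE style files
(quoted labels, square-bracket comments, support values) interoperate.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "TreeError",
    "DataError",
    "canonical_name",
    "Phylogeny",
    "TraitTable",
    "OccupancyTable",
    "read_newick",
    "write_newick",
    "bm_covariance",
    "check_ultrametric",
    "align_data",
    "AlignedData",
    "read_trait_table",
    "write_trait_table",
    "read_occupancy",
    "write_occupancy",
]

AREA_KINDS = ("island", "archipelago", "continent")


class TreeError(ValueError):
    """Raised for malformed or inconsistent phylogenies."""


class DataError(ValueError):
    """Raised for malformed trait or occupancy tables."""


def canonical_name(name: object) -> str:
    """Trim and collapse internal whitespace; the only normalization applied.

    Exact matching after this normalization is deliberate: a silent fuzzy
    mis-join between e.g. two *Pteropus* subspecies would corrupt every
    downstream likelihood.
    """
    return re.sub(r"\s+", " ", str(name).strip())


class Phylogeny:
    """A rooted phylogeny with branch lengths, in flat array form.

    Nodes are integers ``0..n_nodes-1``; ``parent[i]`` is ``-1`` for the
    root; ``length[i]`` is the length of the branch *above* node ``i``
    (0 for the root). ``labels[i]`` is the taxon name for tips, ``None``
    for internal nodes. Multifurcations are permitted.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=float)
        self.labels = list(labels)
        self._validate()
        self._cache: dict = {}

    # -- construction / validation -------------------------------------
    def _validate(self) -> None:
        n = self.parent.size
        if n < 3:
            raise TreeError("tree must have at least 3 nodes")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        if np.any(self.length < 0):
            raise TreeError("negative branch length")
        if np.any((self.parent >= n)):
            raise TreeError("parent index out of range")
        has_child = np.zeros(n, dtype=bool)
        for i, p in enumerate(self.parent):
            if p >= 0:
                has_child[p] = True
        tips = np.flatnonzero(~has_child)
        labs = [self.labels[i] for i in tips]
        if any(l is None or l == "" for l in labs):
            raise TreeError("every tip must carry a non-empty label")
        if len(set(labs)) != len(labs):
            dup = sorted({l for l in labs if labs.count(l) > 1})
            raise TreeError(f"duplicate tip labels: {dup}")
        # acyclicity / connectivity: walk up from every node
        for i in range(n):
            seen = set()
            j = i
            while j >= 0:
                if j in seen:
                    raise TreeError("cycle in parent links")
                seen.add(j)
                j = int(self.parent[j])

    # -- basic structure -----------------------------------------------
    @property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @property
    def root(self) -> int:
        return int(np.flatnonzero(self.parent < 0)[0])

    @property
    def children(self) -> list[list[int]]:
        if "children" not in self._cache:
            ch: list[list[int]] = [[] for _ in range(self.n_nodes)]
            for i, p in enumerate(self.parent):
                if p >= 0:
                    ch[p].append(i)
            self._cache["children"] = ch
        return self._cache["children"]

    @property
    def tip_indices(self) -> np.ndarray:
        if "tips" not in self._cache:
            ch = self.children
            self._cache["tips"] = np.array(
                [i for i in range(self.n_nodes) if not ch[i]], dtype=np.int64)
        return self._cache["tips"]

    @property
    def internal_indices(self) -> np.ndarray:
        ch = self.children
        return np.array([i for i in range(self.n_nodes) if ch[i]], dtype=np.int64)

    @property
    def n_tips(self) -> int:
        return int(self.tip_indices.size)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def preorder(self) -> np.ndarray:
        if "preorder" not in self._cache:
            order = []
            stack = [self.root]
            ch = self.children
            while stack:
                v = stack.pop()
                order.append(v)
                stack.extend(reversed(ch[v]))
            self._cache["preorder"] = np.array(order, dtype=np.int64)
        return self._cache["preorder"]

    @property
    def postorder(self) -> np.ndarray:
        if "postorder" not in self._cache:
            self._cache["postorder"] = self.preorder[::-1].copy()
        return self._cache["postorder"]

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (Myr)."""
        if "depths" not in self._cache:
            d = np.zeros(self.n_nodes)
            for v in self.preorder:
                p = self.parent[v]
                if p >= 0:
                    d[v] = d[p] + self.length[v]
            self._cache["depths"] = d
        return self._cache["depths"]

    def root_path(self, node: int) -> list[int]:
        """Nodes from the root's child down to ``node`` inclusive."""
        path = []
        j = int(node)
        while j >= 0:
            path.append(j)
            j = int(self.parent[j])
        path.reverse()
        return path[1:]  # drop the root itself; entries are branch-bearing

    @property
    def tip_paths(self) -> list[list[int]]:
        if "tip_paths" not in self._cache:
            self._cache["tip_paths"] = [self.root_path(int(t)) for t in self.tip_indices]
        return self._cache["tip_paths"]

    @property
    def tip_mrca(self) -> np.ndarray:
        """(n_tips, n_tips) matrix of MRCA node indices."""
        if "tip_mrca" not in self._cache:
            paths = [[self.root] + p for p in self.tip_paths]
            n = self.n_tips
            M = np.empty((n, n), dtype=np.int64)
            for i in range(n):
                pi = paths[i]
                M[i, i] = pi[-1]
                for j in range(i + 1, n):
                    pj = paths[j]
                    m = self.root
                    for a, b in zip(pi, pj):
                        if a != b:
                            break
                        m = a
                    M[i, j] = M[j, i] = m
            self._cache["tip_mrca"] = M
        return self._cache["tip_mrca"]

    def mrca(self, a: int, b: int) -> int:
        pa = [self.root] + self.root_path(int(a))
        pb = [self.root] + self.root_path(int(b))
        m = self.root
        for x, y in zip(pa, pb):
            if x != y:
                break
            m = x
        return m

    def tip_index_of(self, label: str) -> int:
        lab = canonical_name(label)
        for i in self.tip_indices:
            if self.labels[i] == lab:
                return int(i)
        raise TreeError(f"no tip named {lab!r}")

    # -- surgery ---------------------------------------------------------
    def resolve_polytomies(self) -> "Phylogeny":
        """Replace multifurcations by bifurcations joined by zero-length
        branches, combining children left-to-right in input order."""
        parent = list(self.parent)
        length = list(self.length)
        labels = list(self.labels)
        changed = False
        for v in list(range(self.n_nodes)):
            kids = [i for i, p in enumerate(parent) if p == v]
            while len(kids) > 2:
                changed = True
                new = len(parent)
                parent.append(v)
                length.append(0.0)
                labels.append(None)
                parent[kids[0]] = new
                parent[kids[1]] = new
                kids = [new] + kids[2:]
        if not changed:
            return self
        return Phylogeny(parent, length, labels)

    def prune_to(self, keep: Iterable[str]) -> "Phylogeny":
        """Subtree restricted to the given tip labels, suppressing the
        resulting unifurcations (their branch lengths are summed)."""
        keep_set = {canonical_name(k) for k in keep}
        tips = [int(i) for i in self.tip_indices if self.labels[i] in keep_set]
        if not tips:
            raise TreeError("pruning would remove every tip")
        keep_nodes = set()
        for t in tips:
            j = t
            while j >= 0 and j not in keep_nodes:
                keep_nodes.add(j)
                j = int(self.parent[j])
        # effective child lists within the kept node set
        kids = {v: [] for v in keep_nodes}
        for v in keep_nodes:
            p = int(self.parent[v])
            if p >= 0:
                kids[p].append(v)
        parent_new: list[int] = []
        length_new: list[float] = []
        labels_new: list[str | None] = []

        # the original root is always retained so that root-to-node depths
        # (hence the BM covariance of the kept tips) are preserved; other
        # unifurcations are collapsed with their branch lengths summed
        def add(node: int, parent_idx: int, extra: float) -> None:
            ks = kids.get(node, [])
            if len(ks) == 1 and parent_idx >= 0:
                add(ks[0], parent_idx, extra + float(self.length[ks[0]]))
                return
            idx = len(parent_new)
            parent_new.append(parent_idx)
            length_new.append(extra)
            labels_new.append(self.labels[node])
            for k in ks:
                add(k, idx, float(self.length[k]))

        add(self.root, -1, 0.0)
        if len(labels_new) < 3:
            raise TreeError("pruned tree has fewer than 2 tips")
        return Phylogeny(parent_new, length_new, labels_new)

    # -- IO ---------------------------------------------------------------
    def to_newick(self) -> str:
        ch = self.children

        def fmt(v: int) -> str:
            if ch[v]:
                inner = ",".join(fmt(c) for c in ch[v])
                s = f"({inner})"
            else:
                lab = self.labels[v]
                s = f"'{lab}'" if re.search(r"[\s(),:;\[\]']", lab) else lab
            if self.parent[v] >= 0:
                s += f":{self.length[v]:.10g}"
            return s

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


# ---------------------------------------------------------------------------
# Newick IO

def read_newick(text: str, resolve_polytomies: bool = False,
                default_length: float | None = None) -> Phylogeny:
    """Parse a Newick string into a :class:`Phylogeny`.

    Quoted labels and square-bracket comments are accepted and stripped;
    internal-node labels (support values) are ignored. Branches without a
    length raise unless ``default_length`` is given.
    """
    try:
        dt = dendropy.Tree.get(data=text, schema="newick",
                               preserve_underscores=True,
                               suppress_internal_node_taxa=True)
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc
    nodes = list(dt.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    parent, length, labels = [], [], []
    for nd in nodes:
        if nd.parent_node is None:
            parent.append(-1)
            length.append(0.0)
        else:
            parent.append(index[id(nd.parent_node)])
            bl = nd.edge.length
            if bl is None:
                if default_length is None:
                    raise TreeError("branch without a length "
                                    "(set default_length to accept)")
                bl = default_length
            if bl < 0:
                raise TreeError(f"negative branch length {bl}")
            length.append(float(bl))
        if nd.is_leaf():
            lab = nd.taxon.label if nd.taxon is not None else None
            if lab is None or lab == "":
                raise TreeError("tip without a label")
            labels.append(canonical_name(lab))
        else:
            labels.append(None)
    tree = Phylogeny(parent, length, labels)
    if resolve_polytomies:
        tree = tree.resolve_polytomies()
    return tree


def write_newick(tree: Phylogeny) -> str:
    return tree.to_newick()


# ---------------------------------------------------------------------------
# Covariance structure

def bm_covariance(tree: Phylogeny) -> np.ndarray:
    """Brownian-motion covariance structure: entry (i, j) is the shared
    root-to-MRCA path length of tips i and j (Myr); tip order follows
    ``tree.tip_labels``."""
    d = tree.depths()
    return d[tree.tip_mrca]


def check_ultrametric(tree: Phylogeny, rel_tol: float = 1e-6) -> tuple[bool, float]:
    """True iff all root-to-tip depths agree within ``rel_tol`` of the
    maximum depth; returns (flag, absolute depth spread)."""
    d = tree.depths()[tree.tip_indices]
    spread = float(d.max() - d.min())
    if d.max() <= 0:
        raise TreeError("tree has zero depth")
    return spread <= rel_tol * d.max(), spread


# ---------------------------------------------------------------------------
# Trait and occupancy tables

@dataclass
class TraitTable:
    """Per-taxon mean condylobasal length (CBL, mm) with optional
    per-specimen records.

    ``summary`` columns: taxon, mean_cbl_mm, n, sd_mm (sd may be NaN).
    ``specimens`` columns: taxon, cbl_mm, island.
    """

    summary: pd.DataFrame
    specimens: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        req = {"taxon", "mean_cbl_mm", "n"}
        if not req.issubset(self.summary.columns):
            raise DataError(f"trait summary must have columns {sorted(req)}")
        df = self.summary.copy()
        df["taxon"] = df["taxon"].map(canonical_name)
        if "sd_mm" not in df.columns:
            df["sd_mm"] = np.nan
        if df["taxon"].duplicated().any():
            dup = sorted(df.loc[df["taxon"].duplicated(), "taxon"])
            raise DataError(f"duplicate taxa in trait table: {dup}")
        if (df["mean_cbl_mm"] <= 0).any():
            raise DataError("trait means must be positive")
        if (df["n"] < 1).any():
            raise DataError("specimen counts must be >= 1")
        self.summary = df.reset_index(drop=True)
        if self.specimens is not None:
            sp = self.specimens.copy()
            if not {"taxon", "cbl_mm"}.issubset(sp.columns):
                raise DataError("specimen table needs columns taxon, cbl_mm")
            sp["taxon"] = sp["taxon"].map(canonical_name)
            if "island" not in sp.columns:
                sp["island"] = ""
            self.specimens = sp.reset_index(drop=True)
            means = sp.groupby("taxon")["cbl_mm"].mean()
            for t, m in means.items():
                stored = self.mean_of(t)
                if abs(stored - m) > 1e-9:
                    raise DataError(
                        f"stored mean for {t!r} ({stored}) differs from "
                        f"specimen mean ({m})")

    @property
    def taxa(self) -> list[str]:
        return list(self.summary["taxon"])

    def mean_of(self, taxon: str) -> float:
        t = canonical_name(taxon)
        row = self.summary.loc[self.summary["taxon"] == t, "mean_cbl_mm"]
        if row.empty:
            raise DataError(f"no trait data for {t!r}")
        return float(row.iloc[0])

    def as_series(self) -> pd.Series:
        return self.summary.set_index("taxon")["mean_cbl_mm"]

    def subset(self, taxa: Iterable[str]) -> "TraitTable":
        keep = {canonical_name(t) for t in taxa}
        summ = self.summary[self.summary["taxon"].isin(keep)]
        spec = None
        if self.specimens is not None:
            spec = self.specimens[self.specimens["taxon"].isin(keep)]
        return TraitTable(summ.reset_index(drop=True),
                          None if spec is None else spec.reset_index(drop=True))

    @classmethod
    def from_means(cls, means: Mapping[str, float]) -> "TraitTable":
        df = pd.DataFrame({"taxon": list(means), "mean_cbl_mm": list(means.values()),
                           "n": 1, "sd_mm": np.nan})
        return cls(df)


@dataclass
class OccupancyTable:
    """Long-format taxa-by-area occupancy: columns area, area_kind, taxon."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        req = {"area", "area_kind", "taxon"}
        if not req.issubset(self.table.columns):
            raise DataError(f"occupancy table must have columns {sorted(req)}")
        df = self.table.copy()
        df["area"] = df["area"].map(canonical_name)
        df["taxon"] = df["taxon"].map(canonical_name)
        bad = set(df["area_kind"]) - set(AREA_KINDS)
        if bad:
            raise DataError(f"unknown area kinds {sorted(bad)}; "
                            f"expected one of {AREA_KINDS}")
        if df.empty:
            raise DataError("occupancy table is empty")
        self.table = df.drop_duplicates().reset_index(drop=True)

    @property
    def areas(self) -> list[str]:
        return sorted(self.table["area"].unique())

    @property
    def taxa(self) -> list[str]:
        return sorted(self.table["taxon"].unique())

    def taxa_in(self, area: str) -> list[str]:
        a = canonical_name(area)
        return sorted(self.table.loc[self.table["area"] == a, "taxon"])

    def areas_of(self, taxon: str) -> list[str]:
        t = canonical_name(taxon)
        return sorted(self.table.loc[self.table["taxon"] == t, "area"])

    def subset_taxa(self, taxa: Iterable[str]) -> "OccupancyTable":
        keep = {canonical_name(t) for t in taxa}
        return OccupancyTable(
            self.table[self.table["taxon"].isin(keep)].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Alignment of the three inputs

@dataclass
class AlignedData:
    tree: Phylogeny
    traits: TraitTable
    occupancy: OccupancyTable | None
    report: dict = field(default_factory=dict)


def align_data(tree: Phylogeny, traits: TraitTable,
               occupancy: OccupancyTable | None = None) -> AlignedData:
    """Prune the tree to taxa with trait data and flag taxa that have traits
    or occupancy records but no tip (recently extinct / unsequenced species).

    Context-only taxa stay in the occupancy table: they inform size-category
    assignment even though they never enter a likelihood.
    """
    tip_set = set(tree.tip_labels)
    trait_set = set(traits.taxa)
    shared = tip_set & trait_set
    if not shared:
        raise DataError("no taxon is shared between the tree and the trait table")
    dropped_tips = sorted(tip_set - trait_set)
    context_only = sorted(trait_set - tip_set)
    pruned = tree if not dropped_tips else tree.prune_to(shared)
    report = {
        "dropped_tips": dropped_tips,
        "context_only": context_only,
        "n_analysis_taxa": len(shared),
    }
    if occupancy is not None:
        no_area = sorted(trait_set - set(occupancy.taxa))
        report["taxa_without_area"] = no_area
    return AlignedData(pruned, traits, occupancy, report)


# ---------------------------------------------------------------------------
# CSV IO

def read_trait_table(summary_path, specimens_path=None) -> TraitTable:
    summ = pd.read_csv(summary_path)
    spec = pd.read_csv(specimens_path) if specimens_path is not None else None
    return TraitTable(summ, spec)


def write_trait_table(traits: TraitTable, summary_path, specimens_path=None) -> None:
    traits.summary.to_csv(summary_path, index=False)
    if specimens_path is not None and traits.specimens is not None:
        traits.specimens.to_csv(specimens_path, index=False)


def read_occupancy(path) -> OccupancyTable:
    return OccupancyTable(pd.read_csv(path))


def write_occupancy(occ: OccupancyTable, path) -> None:
    occ.table.to_csv(path, index=False)
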