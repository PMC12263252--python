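"""Sympatry-based selective-regime assignment for the Hansen model.

Each taxon is placed in a size category — small (S), medium (M), large (L),
or isolated (I) — from its relative size among the species it co-occurs
with on islands, archipelagos or continental areas. The resulting scheme
paints every branch of the tree (branch regime = category of its child
node; internal nodes carry a single painted category) and feeds the
multi-optimum Ornstein-Uhlenbeck likelihood. A permutation/uniform
randomizer provides the random-regime null.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .treeio import (DataError, OccupancyTable, Phylogeny, TraitTable,
                     canonical_name)

__all__ = [
    "RegimeScheme",
    "assign_categories",
    "paint_internal_nodes",
    "randomize_regimes",
    "scheme_to_files",
    "scheme_from_files",
    "THREE_CAT",
    "FOUR_CAT",
]

THREE_CAT = ("S", "M", "L")
FOUR_CAT = ("S", "M", "L", "I")
_BAND_ORDER = {"S": 0, "M": 1, "L": 2}


@dataclass(frozen=True)
class RegimeScheme:
    """Mapping of taxa (and internal nodes) to size categories.

    ``tip_categories`` may cover more taxa than any particular tree has
    tips (context-only taxa participate in category assignment without
    entering the likelihood); consumers restrict to the working tree.
    ``internal_category`` is the single category painted on every internal
    node (None until :func:`paint_internal_nodes` is applied; model code
    defaults to 'M').
    """

    scheme_id: str
    tip_categories: dict[str, str]
    internal_category: str | None = None
    provenance: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        allowed = set(self.allowed_categories)
        bad = set(self.tip_categories.values()) - allowed
        if bad:
            raise DataError(f"categories {sorted(bad)} not allowed under "
                            f"scheme {self.scheme_id!r}")
        if self.internal_category is not None and self.internal_category not in allowed:
            raise DataError(
                f"internal category {self.internal_category!r} not allowed "
                f"under scheme {self.scheme_id!r}")

    @property
    def allowed_categories(self) -> tuple[str, ...]:
        return FOUR_CAT if self.scheme_id == "four_cat" else THREE_CAT

    @property
    def categories_present(self) -> tuple[str, ...]:
        present = set(self.tip_categories.values())
        if self.internal_category is not None:
            present.add(self.internal_category)
        return tuple(c for c in FOUR_CAT if c in present)

    def category_of(self, taxon: str) -> str:
        t = canonical_name(taxon)
        if t not in self.tip_categories:
            raise DataError(f"taxon {t!r} has no regime assignment")
        return self.tip_categories[t]

    def node_categories(self, tree: Phylogeny) -> dict[int, str]:
        """Category for every node of ``tree``: tips from the mapping,
        internal nodes from the painting (default M)."""
        internal = self.internal_category or "M"
        out: dict[int, str] = {}
        tipset = set(tree.tip_indices.tolist())
        for v in range(tree.n_nodes):
            if v in tipset:
                out[v] = self.category_of(tree.labels[v])
            else:
                out[v] = internal
        return out


# ---------------------------------------------------------------------------

def _band_edges(values: np.ndarray) -> tuple[float, float, float, float]:
    lo, hi = float(values.min()), float(values.max())
    r = hi - lo
    return lo, lo + r / 3.0, lo + 2.0 * r / 3.0, hi


def _band_of(v: float, edges) -> str:
    lo, b1, b2, hi = edges
    if v < b1:
        return "S"
    if v < b2:
        return "M"
    return "L"


def _split_adjacent(band: str) -> tuple[str, str]:
    # two same-band sympatric species resolved into adjacent bands:
    # smaller steps down, except from S where the larger steps up
    if band == "S":
        return "S", "M"
    if band == "M":
        return "S", "M"
    return "M", "L"


def assign_categories(occupancy: OccupancyTable, traits: TraitTable,
                      scheme: str = "three_cat",
                      min_gap: float | None = None,
                      tie_break: str = "error") -> RegimeScheme:
    """Assign every taxon a global size category from per-area relative sizes.

    Per-area rules: three sympatric species are ranked S/M/L; two species
    are labelled by membership in global size-tercile bands, with same-band
    pairs split into adjacent bands when their size gap reaches ``min_gap``
    (default 5% of the global sympatric size range); four or more species
    are labelled by band membership (rank terciles if all share one band).
    Widespread taxa take their modal per-area label; taxa alone in all
    their areas go to M (three_cat) or I (four_cat).
    """
    if scheme not in ("three_cat", "four_cat"):
        raise DataError(f"unknown scheme {scheme!r}")
    if tie_break not in ("error", "prefer_middle"):
        raise DataError(f"unknown tie_break {tie_break!r}")
    means = traits.as_series()
    occ_taxa = set(occupancy.taxa)
    no_area = sorted(set(means.index) - occ_taxa)
    if no_area:
        raise DataError(f"taxa with trait data but no area: {no_area}")
    no_size = sorted(occ_taxa - set(means.index))
    if no_size:
        raise DataError(f"taxa in occupancy without a mean size: {no_size}")

    area_members = {a: sorted(occupancy.taxa_in(a)) for a in occupancy.areas}
    sympatric = sorted({t for mem in area_members.values() if len(mem) >= 2
                        for t in mem})
    provisional: dict[str, list[str]] = {t: [] for t in occupancy.taxa}
    provenance: dict[str, list[str]] = {t: [] for t in occupancy.taxa}

    if sympatric:
        pool = means.loc[sympatric].to_numpy(dtype=float)
        edges = _band_edges(pool)
        gap = (0.05 * (edges[3] - edges[0])) if min_gap is None else float(min_gap)
    else:
        edges = gap = None

    for area in sorted(area_members):
        members = sorted(area_members[area],
                         key=lambda t: (means[t], t))
        k = len(members)
        if k == 1:
            provenance[members[0]].append(f"{area}: alone")
            continue
        if k == 2:
            a, b = members
            ba, bb = _band_of(means[a], edges), _band_of(means[b], edges)
            if ba == bb:
                if means[b] - means[a] >= gap:
                    ba, bb = _split_adjacent(ba)
                    rule = "same band, gap split"
                else:
                    rule = "same band, overlapping"
            else:
                rule = "band membership"
            labels = [ba, bb]
        elif k == 3:
            labels = ["S", "M", "L"]
            rule = "rank order"
        else:
            labels = [_band_of(means[t], edges) for t in members]
            if len(set(labels)) == 1:
                groups = np.array_split(np.arange(k), 3)
                labels = [None] * k
                for cat, idx in zip(("S", "M", "L"), groups):
                    for i in idx:
                        labels[int(i)] = cat
                rule = "rank terciles (single band)"
            else:
                rule = "band membership"
        for t, lab in zip(members, labels):
            provisional[t].append(lab)
            provenance[t].append(f"{area}: {lab} ({rule})")

    tip_categories: dict[str, str] = {}
    for t in sorted(provisional):
        labs = provisional[t]
        if not labs:
            tip_categories[t] = "I" if scheme == "four_cat" else "M"
            provenance[t].append("isolated in all areas")
            continue
        counts = pd.Series(labs).value_counts()
        top = counts[counts == counts.max()].index.tolist()
        if len(top) == 1:
            tip_categories[t] = top[0]
        elif tie_break == "prefer_middle":
            if "M" in top:
                tip_categories[t] = "M"
            else:
                tip_categories[t] = sorted(top, key=_BAND_ORDER.get)[len(top) // 2]
            provenance[t].append(f"modal tie {sorted(top)} -> "
                                 f"{tip_categories[t]} (prefer_middle)")
        else:
            raise DataError(
                f"modal-category tie for {t!r}: {sorted(top)}; "
                "pass tie_break='prefer_middle' to resolve")
    return RegimeScheme(
        scheme_id=scheme,
        tip_categories=tip_categories,
        provenance={t: "; ".join(v) for t, v in provenance.items()},
    )


def paint_internal_nodes(tree: Phylogeny, scheme: RegimeScheme,
                         category: str = "M") -> RegimeScheme:
    """Paint every internal node of the working tree the given category.

    The Butler-King construction needs a category on every branch; the
    empirical default is M (model fits were insensitive to the choice, so
    the fit is typically swept over S, M and L paintings).
    """
    if category not in scheme.allowed_categories:
        raise DataError(f"category {category!r} invalid for scheme "
                        f"{scheme.scheme_id!r}")
    missing = [lab for lab in tree.tip_labels
               if lab not in scheme.tip_categories]
    if missing:
        raise DataError(f"tree tips without a category: {missing}")
    return replace(scheme, internal_category=category)


def randomize_regimes(scheme: RegimeScheme, mode: str = "permute",
                      seed: int = 0) -> RegimeScheme:
    """Random reassignment of tip categories for the OU3r-style null.

    ``permute`` shuffles the observed labels (category counts preserved,
    the stricter null); ``uniform`` draws each tip independently from
    {S, M, L}. Internal painting is untouched.
    """
    if scheme.scheme_id == "four_cat" or "I" in scheme.tip_categories.values():
        raise DataError("randomization is defined for three-category schemes "
                        "only (I is never randomized)")
    if mode not in ("permute", "uniform"):
        raise DataError(f"unknown randomization mode {mode!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(11,)))
    taxa = sorted(scheme.tip_categories)
    if mode == "permute":
        labs = [scheme.tip_categories[t] for t in taxa]
        rng.shuffle(labs)
    else:
        labs = [THREE_CAT[i] for i in rng.integers(0, 3, size=len(taxa))]
    return RegimeScheme(
        scheme_id="random",
        tip_categories=dict(zip(taxa, labs)),
        internal_category=scheme.internal_category,
        provenance={t: f"randomized ({mode})" for t in taxa},
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# serialization: CSV of tip categories + JSON sidecar

def scheme_to_files(scheme: RegimeScheme, csv_path, json_path) -> None:
    df = pd.DataFrame({
        "taxon": sorted(scheme.tip_categories),
        "category": [scheme.tip_categories[t]
                     for t in sorted(scheme.tip_categories)],
        "provenance": [scheme.provenance.get(t, "")
                       for t in sorted(scheme.tip_categories)],
    })
    df.to_csv(csv_path, index=False)
    with open(json_path, "w") as fh:
        json.dump({"scheme_id": scheme.scheme_id,
                   "internal_category": scheme.internal_category,
                   "seed": scheme.seed}, fh, sort_keys=True)


def scheme_from_files(csv_path, json_path=None) -> RegimeScheme:
    df = pd.read_csv(csv_path)
    meta = {"scheme_id": None, "internal_category": None, "seed": None}
    if json_path is not None:
        with open(json_path) as fh:
            meta.update(json.load(fh))
    cats = dict(zip(df["taxon"].map(canonical_name), df["category"]))
    scheme_id = meta["scheme_id"] or (
        "four_cat" if "I" in cats.values() else "three_cat")
    prov = {}
    if "provenance" in df.columns:
        prov = dict(zip(df["taxon"].map(canonical_name),
                        df["provenance"].fillna("")))
    return RegimeScheme(scheme_id=scheme_id, tip_categories=cats,
                        internal_category=meta["internal_category"],
                        provenance=prov, seed=meta["seed"])
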