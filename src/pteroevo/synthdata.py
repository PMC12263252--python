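"""Synthetic trees, traits and island communities.

The generators emulate the statistical structure of the empirical study
system: Yule trees of ~56 tips with a crown age of ~8.7 Myr, condylobasal
lengths (mm) evolved under BM / EB / OU with regime-dependent optima on the
scale of the fitted Hansen model (theta roughly 47-93 mm, alpha ~0.6 /Myr,
sigma^2 ~52 mm^2/Myr), and island communities of 1-5 co-occurring species
with planted size separation. Every generator is bit-reproducible given
(seed, config): random streams are per-operation, derived from the master
seed as ``SeedSequence(seed, spawn_key=(STREAM,))`` so adding one simulation
never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .regimes import RegimeScheme
from .treeio import DataError, OccupancyTable, Phylogeny, TraitTable

__all__ = [
    "SimulationConfig",
    "simulate_yule",
    "simulate_yule_duration",
    "simulate_trait",
    "TraitSimulation",
    "simulate_island_communities",
    "CommunitySimulation",
    "simulate_specimens",
]

# stream ids for per-operation random streams
_STREAM_YULE = 1
_STREAM_TRAIT = 2
_STREAM_COMM = 3
_STREAM_SPEC = 4

# defaults mirror the fitted four-optimum model for the genus:
# alpha 0.60 /Myr, sigma^2 52.0 mm^2/Myr, optima (L, M, S, I) in mm
DEFAULT_THETA = {"L": 93.4, "M": 65.1, "S": 47.5, "I": 54.4}


@dataclass
class SimulationConfig:
    """Parameters of a trait simulation (units: Myr, mm)."""

    seed: int = 0
    n_tips: int = 56
    crown_age: float | None = 8.7
    birth_rate: float | None = None
    model: str = "OU"                 # BM | EB | OU
    sigma2: float | dict[str, float] = 52.0
    alpha: float | dict[str, float] = 0.60
    theta: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_THETA))
    eb_rate: float = -0.2
    z0: float | None = None           # None: OU uses the root-regime optimum,
                                      # BM/EB use the ancestral size 55.6 mm
    regime_source: str | None = None  # path of a scheme CSV, if painted from file

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise DataError("n_tips must be >= 3")
        sig = (self.sigma2.values() if isinstance(self.sigma2, Mapping)
               else [self.sigma2])
        if any(s <= 0 for s in sig):
            raise DataError("sigma2 must be > 0")
        al = (self.alpha.values() if isinstance(self.alpha, Mapping)
              else [self.alpha])
        if any(a < 0 for a in al):
            raise DataError("alpha must be >= 0")
        if self.eb_rate > 0:
            raise DataError("EB decay rate must be <= 0")
        if self.model not in ("BM", "EB", "OU"):
            raise DataError(f"unknown simulation model {self.model!r}")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stream,)))


# ---------------------------------------------------------------------------
# trees

def simulate_yule(n_tips: int, birth_rate: float | None = None,
                  crown_age: float | None = None, seed: int = 0) -> Phylogeny:
    """Pure-birth (Yule) tree conditioned on ``n_tips``.

    Inter-event waits are Exp(k*b) while k lineages are extant, with a final
    Exp(n*b) segment beyond the last split. When ``crown_age`` is given the
    tree is rescaled so every root-to-tip depth equals it exactly.
    """
    if n_tips < 3:
        raise DataError("n_tips must be >= 3")
    if birth_rate is None and crown_age is None:
        raise DataError("give birth_rate or crown_age")
    b = 1.0 if birth_rate is None else float(birth_rate)
    if b <= 0:
        raise DataError("birth rate must be > 0")
    rng = _rng(seed, _STREAM_YULE)

    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]          # time each node came into being
    active = [1, 2]
    t = 0.0
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / (k * b))
        i = int(rng.integers(k))
        node = active.pop(i)
        birth[node] = t
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([node, node])
        birth.extend([t, t])
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / (n_tips * b))

    scale = 1.0 if crown_age is None else crown_age / t_end
    depth = (crown_age if crown_age is not None else t_end)
    birth_arr = np.asarray(birth) * scale
    n_nodes = len(parent)
    length = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes
    children = [False] * n_nodes
    for v in range(n_nodes):
        if parent[v] >= 0:
            children[parent[v]] = True
    end_time = np.array([birth_arr[v] for v in range(n_nodes)])
    tip_no = 0
    for v in range(n_nodes):
        if not children[v]:
            end_time[v] = depth          # tips extend to the present, exactly
            tip_no += 1
            labels[v] = f"sp{tip_no:02d}"
    for v in range(n_nodes):
        if parent[v] >= 0:
            length[v] = end_time[v] - birth_arr[parent[v]]
    return Phylogeny(parent, length, labels)


def simulate_yule_duration(birth_rate: float, duration: float,
                           seed: int = 0) -> Phylogeny | None:
    """Crown-conditioned Yule tree grown for a fixed time span.

    Starts from the crown split (2 lineages) and runs for ``duration``; the
    tip count is random with expectation 2*exp(b*duration). Returns None in
    the (impossible for a pure-birth process) degenerate case of < 2 tips.
    """
    if birth_rate <= 0 or duration <= 0:
        raise DataError("birth rate and duration must be > 0")
    rng = _rng(seed, _STREAM_YULE)
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    active = [1, 2]
    t = 0.0
    while True:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        if t + wait >= duration:
            break
        t += wait
        i = int(rng.integers(k))
        node = active.pop(i)
        birth[node] = t
        c1, c2 = len(parent), len(parent) + 1
        parent.extend([node, node])
        birth.extend([t, t])
        active.extend([c1, c2])
    n_nodes = len(parent)
    length = np.zeros(n_nodes)
    labels: list[str | None] = [None] * n_nodes
    has_child = [False] * n_nodes
    for v in range(n_nodes):
        if parent[v] >= 0:
            has_child[parent[v]] = True
    tip_no = 0
    for v in range(n_nodes):
        if not has_child[v]:
            tip_no += 1
            labels[v] = f"sp{tip_no:02d}"
    for v in range(n_nodes):
        if parent[v] >= 0:
            end = duration if not has_child[v] else birth[v]
            length[v] = end - birth[parent[v]]
    return Phylogeny(parent, length, labels)


# ---------------------------------------------------------------------------
# traits

@dataclass
class TraitSimulation:
    traits: TraitTable
    tip_values: dict[str, float]
    node_states: dict[int, float]     # true value at every node (tree indices)
    regimes: RegimeScheme | None


def simulate_trait(tree: Phylogeny, config: SimulationConfig,
                   regimes: RegimeScheme | None = None,
                   seed: int | None = None) -> TraitSimulation:
    """Evolve a trait along the tree by exact per-branch Gaussian transitions.

    BM: child ~ N(parent, sigma2*t). EB: variance is the integral of
    sigma2*exp(r*s) over the branch (s = time since root). OU: child ~
    N(parent*e^{-a t} + theta*(1 - e^{-a t}), sigma2*(1 - e^{-2 a t})/(2a)),
    with the a -> 0 limit handled analytically. The regime of a branch is
    the regime of its child node.
    """
    seed = config.seed if seed is None else seed
    rng = _rng(seed, _STREAM_TRAIT)
    if config.model == "OU" and regimes is None and len(config.theta) > 1:
        raise DataError("multi-optimum OU simulation needs a regime scheme")
    node_cat: Mapping[int, str]
    if regimes is not None:
        node_cat = regimes.node_categories(tree)
    else:
        node_cat = {v: "0" for v in range(tree.n_nodes)}

    def get(value, cat, name):
        if isinstance(value, Mapping):
            if cat not in value:
                raise DataError(f"{name} not specified for regime {cat!r}")
            return float(value[cat])
        return float(value)

    if config.z0 is not None:
        z0 = float(config.z0)
    elif config.model == "OU":
        # stationary-root convention: start at the root regime's optimum
        if regimes is not None:
            z0 = get(config.theta, node_cat[tree.root], "theta")
        else:
            z0 = float(next(iter(config.theta.values())))
    else:
        z0 = 55.6  # ancestral condylobasal length, mm

    depths = tree.depths()
    states = np.empty(tree.n_nodes)
    states[tree.root] = z0
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        dt = float(tree.length[v])
        cat = node_cat[int(v)]
        s2 = get(config.sigma2, cat, "sigma2")
        if config.model == "BM":
            mu, var = states[p], s2 * dt
        elif config.model == "EB":
            r = config.eb_rate
            if r == 0.0:
                var = s2 * dt
            else:
                var = s2 * (math.exp(r * depths[v]) - math.exp(r * depths[p])) / r
            mu = states[p]
        else:  # OU
            a = get(config.alpha, cat, "alpha")
            if a == 0.0:
                mu, var = states[p], s2 * dt
            else:
                th = get(config.theta, cat if regimes is not None else
                         next(iter(config.theta)), "theta")
                decay = math.exp(-a * dt)
                mu = states[p] * decay + th * (1.0 - decay)
                var = s2 * (-math.expm1(-2.0 * a * dt)) / (2.0 * a)
        states[v] = mu + math.sqrt(var) * rng.standard_normal()

    tip_values = {tree.labels[i]: float(states[i]) for i in tree.tip_indices}
    traits = TraitTable.from_means(tip_values)
    return TraitSimulation(traits=traits, tip_values=tip_values,
                           node_states={v: float(states[v])
                                        for v in range(tree.n_nodes)},
                           regimes=regimes)


def simulate_specimens(tip_values: Mapping[str, float], n_per_taxon: int,
                       sd: float, islands: Mapping[str, str] | None = None,
                       seed: int = 0) -> TraitTable:
    """Per-specimen Gaussian noise around each species value; the summary
    means are recomputed from the specimens."""
    if n_per_taxon < 1 or sd < 0:
        raise DataError("need n_per_taxon >= 1 and sd >= 0")
    rng = _rng(seed, _STREAM_SPEC)
    rows = []
    for taxon in sorted(tip_values):
        vals = tip_values[taxon] + sd * rng.standard_normal(n_per_taxon)
        isl = islands.get(taxon, "") if islands else ""
        for v in vals:
            rows.append({"taxon": taxon, "cbl_mm": float(v), "island": isl})
    spec = pd.DataFrame(rows)
    summ = (spec.groupby("taxon")["cbl_mm"]
            .agg(mean_cbl_mm="mean", n="count", sd_mm="std")
            .reset_index())
    return TraitTable(summ, spec)


# ---------------------------------------------------------------------------
# island communities

@dataclass
class CommunitySimulation:
    occupancy: OccupancyTable
    planted_tiers: dict[str, str]     # rank categories for 3-species areas
    structure: str
    seed: int


def simulate_island_communities(sizes: Mapping[str, float], n_areas: int,
                                species_per_area: int | Sequence[int] = 3,
                                structure: str = "displaced",
                                min_gap: float = 8.0,
                                seed: int = 0) -> CommunitySimulation:
    """Assemble island communities of 1-5 co-occurring species.

    ``displaced`` partitions taxa among areas (each taxon in exactly one
    area) such that co-occurring sizes are pairwise separated by at least
    ``min_gap`` mm — the planted character-displacement structure; single
    -species areas leave their taxon isolated. ``random`` draws each area's
    occupants from the full pool without regard to size (taxa may recur
    across areas).
    """
    if structure not in ("displaced", "random"):
        raise DataError(f"unknown structure {structure!r}")
    if isinstance(species_per_area, int):
        per_area = [species_per_area] * n_areas
    else:
        per_area = list(species_per_area)
        if len(per_area) != n_areas:
            raise DataError("species_per_area length must equal n_areas")
    if any(k < 1 or k > 5 for k in per_area):
        raise DataError("species_per_area must be within 1..5")
    taxa = sorted(sizes)
    rng = _rng(seed, _STREAM_COMM)
    rows = []
    planted: dict[str, str] = {}
    rank_cats = {2: ["S", "L"], 3: ["S", "M", "L"]}

    if structure == "random":
        for a, k in enumerate(per_area):
            if k > len(taxa):
                raise DataError("not enough taxa to fill an area")
            chosen = list(rng.choice(taxa, size=k, replace=False))
            for t in chosen:
                rows.append({"area": f"area{a + 1:02d}",
                             "area_kind": "island", "taxon": t})
    else:
        if sum(per_area) > len(taxa):
            raise DataError("not enough taxa to fill all areas without reuse")
        remaining = list(taxa)
        for a, k in enumerate(per_area):
            chosen: list[str] = []
            order = list(rng.permutation(remaining))
            for t in order:
                if all(abs(sizes[t] - sizes[c]) >= min_gap for c in chosen):
                    chosen.append(t)
                    if len(chosen) == k:
                        break
            if len(chosen) < k:
                raise DataError(
                    f"cannot assemble a {k}-species area with min gap "
                    f"{min_gap} mm from the available size pool")
            for t in chosen:
                remaining.remove(t)
                rows.append({"area": f"area{a + 1:02d}",
                             "area_kind": "island", "taxon": t})
            if k in rank_cats:
                for t, cat in zip(sorted(chosen, key=lambda x: sizes[x]),
                                  rank_cats[k]):
                    planted[t] = cat
            elif k == 1:
                planted[chosen[0]] = "I"
    occ = OccupancyTable(pd.DataFrame(rows))
    return CommunitySimulation(occupancy=occ, planted_tiers=planted,
                               structure=structure, seed=int(seed))
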