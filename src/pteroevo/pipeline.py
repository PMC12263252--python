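"""Configuration-driven end-to-end analysis runs.

A run executes: align inputs -> assign (or load) regimes -> phylogenetic
signal -> model fits (with the internal-node painting sweep) -> AICc
comparison -> random-regime null -> ancestral states + per-category change
accounting -> disparity through time -> per-population CV -> per-island
size report. Every stage writes CSV/JSON under the output directory; JSON
output is deterministic for a fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .ancestral import ancestral_bm, category_change_summary, annotated_newick
from .disparity import dtt, population_cv
from .models import (FitOptions, ModelFit, compare, fit, format_comparison,
                     random_regime_null)
from .regimes import (RegimeScheme, assign_categories, paint_internal_nodes,
                      scheme_from_files, scheme_to_files)
from .signal import blomberg_k, pagel_delta, pagel_lambda
from .synthdata import (SimulationConfig, simulate_island_communities,
                        simulate_trait, simulate_yule)
from .treeio import (DataError, align_data, read_newick, read_occupancy,
                     read_trait_table, write_newick)

__all__ = ["AnalysisConfig", "run", "StageError"]

log = logging.getLogger("pteroevo")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class AnalysisConfig:
    """Inputs and knobs of a full analysis run."""

    seed: int
    out_dir: str
    tree_path: str | None = None
    traits_path: str | None = None
    specimens_path: str | None = None
    occupancy_path: str | None = None
    scheme_path: str | None = None          # hand-curated scheme CSV bypassing
                                            # automatic assignment
    synthetic: dict | None = None           # SimulationConfig fields
    scope: str = "genus_only"               # genus_only | frugivores
    scope_column: str | None = None         # trait-table column with scope flags
    schemes: tuple[str, ...] = ("three_cat", "four_cat")
    paintings: tuple[str, ...] = ("M",)
    models: tuple[str, ...] = ("BM", "BMS", "EB", "OU1", "OUM")
    log_transform: bool = False
    tie_break: str = "error"
    n_perm: int = 999
    n_sim: int = 1000
    n_reps: int = 100
    resume: bool = False

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("schemes", "paintings", "models"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        for attr in ("tree_path", "traits_path", "occupancy_path",
                     "scheme_path", "specimens_path"):
            p = getattr(cfg, attr)
            if p is not None and not Path(p).exists():
                raise DataError(f"{attr} does not exist: {p}")
        return cfg

    def content_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


def _json_dump(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=_coerce)
                    + "\n")


def _coerce(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (pd.DataFrame,)):
        return o.to_dict(orient="records")
    if hasattr(o, "to_dict"):
        return o.to_dict()
    return str(o)


def _load_inputs(cfg: AnalysisConfig, out: Path):
    if cfg.synthetic is not None:
        sim_fields = dict(cfg.synthetic)
        sim_fields.setdefault("seed", cfg.seed)
        scfg = SimulationConfig(**sim_fields)
        tree = simulate_yule(scfg.n_tips, birth_rate=scfg.birth_rate,
                             crown_age=scfg.crown_age, seed=scfg.seed)
        sizes0 = {lab: 1.0 for lab in tree.tip_labels}
        # provisional sizes are only used to place taxa; communities are
        # assembled from simulated trait values below
        comm = simulate_island_communities(
            {t: i for i, t in enumerate(sorted(sizes0))},
            n_areas=max(1, tree.n_tips // 3), species_per_area=3,
            structure="random", min_gap=0.0, seed=scfg.seed)
        scheme_true = None
        if scfg.model == "OU" and len(scfg.theta) > 1:
            # paint tips with planted categories so the simulation has the
            # multi-optimum structure the analysis is meant to recover
            rng = np.random.default_rng(
                np.random.SeedSequence(scfg.seed, spawn_key=(51,)))
            cats = sorted(scfg.theta)
            labels = [cats[i] for i in rng.integers(0, len(cats),
                                                    size=tree.n_tips)]
            scheme_id = "four_cat" if "I" in cats else "three_cat"
            scheme_true = RegimeScheme(scheme_id=scheme_id,
                                       tip_categories=dict(zip(
                                           tree.tip_labels, labels)),
                                       internal_category="M")
        sim = simulate_trait(tree, scfg, regimes=scheme_true, seed=scfg.seed)
        traits = sim.traits
        occupancy = comm.occupancy
        (out / "inputs").mkdir(exist_ok=True)
        (out / "inputs" / "tree.nwk").write_text(write_newick(tree) + "\n")
        traits.summary.to_csv(out / "inputs" / "traits.csv", index=False)
        occupancy.table.to_csv(out / "inputs" / "occupancy.csv", index=False)
        return tree, traits, occupancy, scheme_true
    if cfg.tree_path is None or cfg.traits_path is None:
        raise DataError("either synthetic: or tree_path+traits_path required")
    tree = read_newick(Path(cfg.tree_path).read_text(),
                       resolve_polytomies=True)
    traits = read_trait_table(cfg.traits_path, cfg.specimens_path)
    occupancy = (read_occupancy(cfg.occupancy_path)
                 if cfg.occupancy_path else None)
    return tree, traits, occupancy, None


def _apply_scope(cfg: AnalysisConfig, traits):
    if cfg.scope_column is None:
        return traits
    if cfg.scope_column not in traits.summary.columns:
        raise DataError(f"scope column {cfg.scope_column!r} missing "
                        "from trait table")
    keep = traits.summary.loc[
        traits.summary[cfg.scope_column].astype(str) == cfg.scope, "taxon"]
    return traits.subset(keep)


def run(cfg: AnalysisConfig) -> dict:
    """Execute the full analysis; returns a summary dict of stage outputs.

    Raises :class:`StageError` on the first failing stage (downstream
    stages are skipped); all completed outputs remain on disk.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = cfg.content_hash()
    done: dict = {}
    if cfg.resume and manifest_path.exists():
        prev = json.loads(manifest_path.read_text())
        if prev.get("config_hash") == chash:
            done = prev.get("stages", {})
    summary: dict = {"config_hash": chash, "version": __version__,
                     "seed": cfg.seed, "stages": {}}
    logging.basicConfig(level=logging.INFO)

    def stage(name):
        def deco(fn):
            if cfg.resume and done.get(name) == "ok" and _outputs_exist(out, name):
                log.info("stage %s: cached, skipping", name)
                summary["stages"][name] = "ok"
                return None
            log.info("stage %s: running", name)
            try:
                fn()
            except Exception as exc:
                summary["stages"][name] = f"failed: {exc}"
                _json_dump(summary, manifest_path)
                raise StageError(name, exc) from exc
            summary["stages"][name] = "ok"
            return None
        return deco

    tree, traits, occupancy, scheme_true = _load_inputs(cfg, out)
    traits = _apply_scope(cfg, traits)
    aligned = align_data(tree, traits, occupancy)
    tree, traits = aligned.tree, aligned.traits
    _json_dump(aligned.report, out / "align_report.json")

    schemes: dict[str, RegimeScheme] = {}

    @stage("regimes")
    def _regimes():
        if scheme_true is not None:
            for sid in cfg.schemes:
                if sid == scheme_true.scheme_id:
                    schemes[sid] = scheme_true
                elif sid == "three_cat":
                    # collapse I into M for the three-category view
                    cats = {t: ("M" if c == "I" else c)
                            for t, c in scheme_true.tip_categories.items()}
                    schemes[sid] = RegimeScheme("three_cat", cats,
                                                internal_category="M")
        elif cfg.scheme_path is not None:
            s = scheme_from_files(cfg.scheme_path)
            schemes[s.scheme_id] = s
        else:
            if occupancy is None:
                raise DataError("regime assignment needs an occupancy table")
            for sid in cfg.schemes:
                schemes[sid] = assign_categories(
                    occupancy.subset_taxa(traits.taxa), traits, scheme=sid,
                    tie_break=cfg.tie_break)
        for sid, s in schemes.items():
            scheme_to_files(s, out / f"scheme_{sid}.csv",
                            out / f"scheme_{sid}.json")

    @stage("signal")
    def _signal():
        res = pagel_lambda(tree, traits).to_dict()
        res.update(blomberg_k(tree, traits, n_perm=cfg.n_perm,
                              seed=cfg.seed).to_dict())
        res.update(pagel_delta(tree, traits).to_dict())
        _json_dump(res, out / "signal.json")

    fits_by_scheme: dict[str, list[ModelFit]] = {}

    @stage("models")
    def _models():
        opts = FitOptions(log_transform=cfg.log_transform, seed=cfg.seed)
        for sid, scheme in sorted(schemes.items()):
            fits: list[ModelFit] = []
            for model in cfg.models:
                if model in ("BM", "EB", "OU1"):
                    fits.append(fit(model, tree, traits, None, opts))
                else:
                    for painting in cfg.paintings:
                        painted = paint_internal_nodes(tree, scheme, painting)
                        f = fit(model, tree, traits, painted, opts)
                        f.model = f"{model}[{sid},{painting}]"
                        fits.append(f)
            fits_by_scheme[sid] = fits
            table = compare(fits)
            table.to_csv(out / f"comparison_{sid}.csv", index=False)
            (out / f"comparison_{sid}.txt").write_text(
                format_comparison(fits) + "\n")
            _json_dump([f.to_dict() for f in fits], out / f"fits_{sid}.json")

    @stage("null")
    def _null():
        if "three_cat" not in schemes or cfg.n_reps <= 0:
            _json_dump({"skipped": "no three_cat scheme or n_reps=0"},
                       out / "null.json")
            return
        painted = paint_internal_nodes(tree, schemes["three_cat"],
                                       cfg.paintings[0])
        res = random_regime_null(tree, traits, painted, n_reps=cfg.n_reps,
                                 seed=cfg.seed,
                                 options=FitOptions(
                                     log_transform=cfg.log_transform,
                                     seed=cfg.seed))
        _json_dump({"observed_aicc": res.observed.aicc,
                    "exceedance": res.exceedance, "n_reps": res.n_reps,
                    "p_value": res.p_value,
                    "aicc_range": [float(res.aiccs.min()),
                                   float(res.aiccs.max())]
                    if res.aiccs.size else None},
                   out / "null.json")

    @stage("ancestral")
    def _ancestral():
        anc = ancestral_bm(tree, traits, method="REML")
        anc.table.to_csv(out / "ancestral.csv", index=False)
        (out / "ancestral_annotated.nwk").write_text(
            annotated_newick(tree, anc) + "\n")
        sid = ("four_cat" if "four_cat" in schemes
               else next(iter(sorted(schemes)), None))
        if sid:
            ch = category_change_summary(tree, traits, schemes[sid], anc)
            ch.per_tip.to_csv(out / "change_per_tip.csv", index=False)
            ch.per_category.to_csv(out / "change_per_category.csv",
                                   index=False)
        _json_dump({"root_estimate": anc.root_estimate, "rate": anc.rate,
                    "method": anc.method}, out / "ancestral_summary.json")

    @stage("dtt")
    def _dtt():
        res = dtt(tree, traits, n_sim=cfg.n_sim, seed=cfg.seed)
        res.as_frame().to_csv(out / "dtt.csv", index=False)
        _json_dump({"mdi": res.mdi, "p_ge": res.p_ge, "p_le": res.p_le,
                    "n_sim": res.n_sim, "degenerate": res.degenerate},
                   out / "dtt_summary.json")

    @stage("cv")
    def _cv():
        if traits.specimens is not None and len(traits.specimens):
            population_cv(traits.specimens).to_csv(out / "population_cv.csv",
                                                   index=False)
        else:
            (out / "population_cv.csv").write_text(
                "taxon,island,n,mean,cv\n")

    @stage("island_report")
    def _island():
        if occupancy is None:
            (out / "island_report.csv").write_text(
                "area,area_kind,taxon,mean_cbl_mm\n")
            return
        means = traits.as_series()
        df = occupancy.table.copy()
        df = df[df["taxon"].isin(means.index)]
        df["mean_cbl_mm"] = df["taxon"].map(means)
        df = df.sort_values(["area", "mean_cbl_mm"]).reset_index(drop=True)
        df.to_csv(out / "island_report.csv", index=False)

    _json_dump(summary, manifest_path)
    log.info("run complete: %s", out)
    return summary


_STAGE_OUTPUTS = {
    "regimes": ["scheme_three_cat.csv"],
    "signal": ["signal.json"],
    "models": [],
    "null": ["null.json"],
    "ancestral": ["ancestral.csv"],
    "dtt": ["dtt.csv"],
    "cv": ["population_cv.csv"],
    "island_report": ["island_report.csv"],
}


def _outputs_exist(out: Path, stage: str) -> bool:
    return all((out / f).exists() for f in _STAGE_OUTPUTS.get(stage, []))
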