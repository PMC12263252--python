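"""Ancestral state reconstruction under Brownian motion, and per-category
accounting of size change relative to each tip's reconstructed parent.

Estimates are the GLS (equivalently, conditional-Gaussian) predictions of
internal-node states given the tip values; REML and ML differ only in the
rate convention used for the intervals (contrast-based divisor n-1 versus
the ML divisor n) — the point estimates are identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .regimes import RegimeScheme
from .treeio import DataError, Phylogeny, bm_covariance
from .models import _trait_vector

__all__ = ["AncestralResult", "ancestral_bm", "category_change_summary",
           "ChangeSummary", "annotated_newick"]

Z95 = 1.959963984540054


@dataclass
class AncestralResult:
    """Node estimates (mm) with 95% intervals; tips carry their observed
    values with zero-width intervals."""

    table: pd.DataFrame          # node, estimate, lo, hi, is_tip, label
    method: str                  # REML | ML
    rate: float                  # sigma^2 under the chosen convention
    root_estimate: float
    degenerate: bool = False

    def estimate_of(self, node: int) -> float:
        return float(self.table.set_index("node").loc[node, "estimate"])


def _node_tip_cov(tree: Phylogeny, node: int) -> np.ndarray:
    """Covariance structure between an internal node (as a point at its
    depth) and every tip: depth of their MRCA."""
    d = tree.depths()
    out = np.empty(tree.n_tips)
    for i, t in enumerate(tree.tip_indices):
        out[i] = d[tree.mrca(node, int(t))]
    return out


def ancestral_bm(tree: Phylogeny, traits, method: str = "REML") -> AncestralResult:
    """GLS/REML ancestral states for every internal node.

    The interval at node a uses the conditional Gaussian variance
    rate * (C_aa - c'C^-1 c + (1 - c'C^-1 1)^2 / (1'C^-1 1)), the last term
    propagating root (GLS mean) uncertainty.
    """
    if method not in ("REML", "ML"):
        raise DataError(f"unknown method {method!r}")
    y = _trait_vector(tree, traits)
    n = y.size
    if n < 3:
        raise DataError("ancestral reconstruction needs >= 3 tips")
    C = bm_covariance(tree)
    c = cho_factor(C, lower=True)
    one = np.ones(n)
    Vi1 = cho_solve(c, one)
    denom = float(one @ Vi1)
    mu = float(one @ cho_solve(c, y)) / denom
    r = y - mu
    Vir = cho_solve(c, r)
    quad = float(r @ Vir)
    degenerate = np.ptp(y) < 1e-12
    rate = quad / (n - 1) if method == "REML" else quad / n
    d = tree.depths()

    rows = []
    tipset = set(tree.tip_indices.tolist())
    for v in range(tree.n_nodes):
        if v in tipset:
            val = float(y[list(tree.tip_indices).index(v)])
            rows.append({"node": v, "estimate": val, "lo": val, "hi": val,
                         "is_tip": True, "label": tree.labels[v]})
            continue
        cov = _node_tip_cov(tree, v)
        Vic = cho_solve(c, cov)
        est = mu + float(cov @ Vir)
        var_struct = (float(d[v]) - float(cov @ Vic)
                      + (1.0 - float(cov @ Vi1)) ** 2 / denom)
        sd = math.sqrt(max(rate * var_struct, 0.0))
        rows.append({"node": v, "estimate": est, "lo": est - Z95 * sd,
                     "hi": est + Z95 * sd, "is_tip": False, "label": None})
    table = pd.DataFrame(rows)
    root_est = float(table.set_index("node").loc[tree.root, "estimate"])
    return AncestralResult(table=table, method=method, rate=float(rate),
                           root_estimate=root_est, degenerate=bool(degenerate))


# ---------------------------------------------------------------------------
# per-category change accounting

@dataclass
class ChangeSummary:
    per_tip: pd.DataFrame        # taxon, category, tip_value, parent_estimate,
                                 # change_pct
    per_category: pd.DataFrame   # category, n, mean_change_pct,
                                 # n_decreasing, n_gt_threshold
    threshold_pct: float


def category_change_summary(tree: Phylogeny, traits, scheme: RegimeScheme,
                            ancestral: AncestralResult,
                            threshold_pct: float = 5.0) -> ChangeSummary:
    """Percent size change of every tip versus its direct parent's
    reconstructed state, aggregated per size category.

    'Most recent ancestor' of a tip is its direct parent node in the
    working tree; the reporting threshold (default 5%) counts taxa whose
    absolute change exceeds it.
    """
    y = _trait_vector(tree, traits)
    est = ancestral.table.set_index("node")["estimate"]
    rows = []
    for i, t in enumerate(tree.tip_indices):
        parent = int(tree.parent[t])
        pe = float(est.loc[parent])
        tip_val = float(y[i])
        change = (tip_val - pe) / pe * 100.0
        rows.append({"taxon": tree.labels[t],
                     "category": scheme.category_of(tree.labels[t]),
                     "tip_value": tip_val, "parent_estimate": pe,
                     "change_pct": change})
    per_tip = pd.DataFrame(rows)
    agg = (per_tip.groupby("category")["change_pct"]
           .agg(n="count", mean_change_pct="mean",
                n_decreasing=lambda s: int((s < 0).sum()),
                n_gt_threshold=lambda s: int((s.abs() > threshold_pct).sum()))
           .reset_index())
    return ChangeSummary(per_tip=per_tip, per_category=agg,
                         threshold_pct=threshold_pct)


# ---------------------------------------------------------------------------

def annotated_newick(tree: Phylogeny, ancestral: AncestralResult) -> str:
    """Newick with node comments carrying the reconstructed values."""
    est = ancestral.table.set_index("node")["estimate"]
    ch = tree.children

    def fmt(v: int) -> str:
        if ch[v]:
            inner = ",".join(fmt(k) for k in ch[v])
            s = f"({inner})[&cbl={est.loc[v]:.4f}]"
        else:
            s = tree.labels[v]
        if tree.parent[v] >= 0:
            s += f":{tree.length[v]:.10g}"
        return s

    return fmt(tree.root) + ";"
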