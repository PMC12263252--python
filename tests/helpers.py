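"""Independent oracles used by the tests.

The dense multivariate-normal oracle builds the joint Gaussian law over
*all* tree nodes by propagating the full node-by-node covariance matrix
through the per-branch linear-Gaussian transitions (child = phi*parent +
shift + noise), then marginalizes to the tips and evaluates the density
with scipy. This is a deliberately different route from the package's
pairwise shared-path construction, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import multivariate_normal


def dense_mvn_loglik(tree, y, model, node_cat, params,
                     root_mode="stationary"):
    """Log-likelihood of tip values ``y`` (in tree tip order) by full joint
    covariance propagation. ``node_cat``: dict node -> regime name;
    ``params``: sigma2 / alpha / theta (scalars or per-regime dicts),
    z0, eb_rate as the model requires."""
    n = tree.n_nodes
    S = np.zeros((n, n))
    m = np.zeros(n)
    depths = tree.depths()
    root = tree.root

    def per(cat, value):
        return value[cat] if isinstance(value, dict) else value

    bm_family = model in ("BM", "BMS", "EB")
    if bm_family or root_mode == "estimated":
        m[root] = params["z0"]
    else:
        m[root] = per(node_cat[root], params["theta"])

    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        dt = float(tree.length[v])
        cat = node_cat[int(v)]
        s2 = per(cat, params["sigma2"])
        if bm_family:
            phi, shift = 1.0, 0.0
            if model == "EB" and params.get("eb_rate", 0.0) != 0.0:
                r = params["eb_rate"]
                q = s2 * (math.exp(r * depths[v])
                          - math.exp(r * depths[p])) / r
            else:
                q = s2 * dt
        else:
            a = per(cat, params["alpha"])
            th = per(cat, params["theta"])
            phi = math.exp(-a * dt)
            shift = th * (1.0 - phi)
            q = s2 * (1.0 - math.exp(-2.0 * a * dt)) / (2.0 * a)
        m[v] = phi * m[p] + shift
        row = phi * S[p, :].copy()
        S[v, :] = row
        S[:, v] = row
        S[v, v] = phi * phi * S[p, p] + q

    tips = tree.tip_indices
    return float(multivariate_normal.logpdf(
        y, mean=m[tips], cov=S[np.ix_(tips, tips)]))


def random_model_params(rng, categories):
    """Random but well-conditioned parameters for every model family."""
    theta = {c: float(rng.uniform(40.0, 95.0)) for c in categories}
    alpha = {c: float(rng.uniform(0.2, 2.0)) for c in categories}
    sigma2 = {c: float(rng.uniform(2.0, 60.0)) for c in categories}
    scalar_a = float(rng.uniform(0.2, 2.0))
    scalar_s = float(rng.uniform(2.0, 60.0))
    z0 = float(rng.uniform(40.0, 90.0))
    return {
        "BM": {"sigma2": scalar_s, "z0": z0},
        "BMS": {"sigma2": sigma2, "z0": z0},
        "EB": {"sigma2": scalar_s, "eb_rate": float(rng.uniform(-0.8, -0.05)),
               "z0": z0},
        "OU1": {"sigma2": scalar_s, "alpha": scalar_a,
                "theta": float(rng.uniform(40.0, 95.0))},
        "OUM": {"sigma2": scalar_s, "alpha": scalar_a, "theta": theta},
        "OUMV": {"sigma2": sigma2, "alpha": scalar_a, "theta": theta},
        "OUMA": {"sigma2": scalar_s, "alpha": alpha, "theta": theta},
        "OUMVA": {"sigma2": sigma2, "alpha": alpha, "theta": theta},
    }
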