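"""Likelihoods and ML fitting for continuous-trait evolution on a phylogeny.

Models: BM (single-rate Brownian motion), BMS (per-regime Brownian rates),
EB (early burst, exponentially decaying rate), OU1 (single-optimum
Ornstein-Uhlenbeck) and the multi-optimum Hansen models OUM / OUMV / OUMA /
OUMVA in which the optimum theta (and optionally sigma^2 and/or alpha) vary
among selective regimes painted on the branches.

All models are exact Gaussian: the tip vector is multivariate normal with a
mean from the Hansen weight construction (each tip's expectation is a convex
combination of the root state and the regime optima, weighted by
exponentially discounted residence times along its root path) and a
covariance accumulated branch-by-branch. For tips i, j with MRCA m the
covariance is the variance accumulated along the shared root-to-m path,
discounted by exp(-(A_i - A_m) - (A_j - A_m)) where A is the cumulative
integral of alpha along each lineage; with a single alpha on an ultrametric
tree this reduces to the familiar
sigma^2/(2 alpha) * exp(-alpha d_ij) * (1 - exp(-2 alpha s_ij)).
The root state is fixed (no stationary root variance); under the default
``root_mode='stationary'`` it equals the optimum of the root regime and is
not a free parameter.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import qmc

from .regimes import RegimeScheme, randomize_regimes
from .treeio import (DataError, Phylogeny, TraitTable, TreeError,
                     check_ultrametric)

__all__ = [
    "ModelFit",
    "FitOptions",
    "MODELS",
    "loglik",
    "fit",
    "compare",
    "aicc",
    "akaike_weights",
    "random_regime_null",
    "NullResult",
    "format_comparison",
]

BM_FAMILY = ("BM", "BMS", "EB")
OU_FAMILY = ("OU1", "OUM", "OUMV", "OUMA", "OUMVA")
MODELS = BM_FAMILY + OU_FAMILY
_NEEDS_SCHEME = ("BMS", "OUM", "OUMV", "OUMA", "OUMVA")
_CAT_ORDER = ("S", "M", "L", "I")


# ---------------------------------------------------------------------------
# results

@dataclass
class ModelFit:
    """A fitted (or externally supplied) evolutionary model."""

    model: str
    loglik: float
    k: int
    n: int
    sigma2: float | dict[str, float] | None = None
    alpha: float | dict[str, float] | None = None
    theta: dict[str, float] | None = None
    theta_se: dict[str, float] | None = None
    z0: float | None = None
    eb_rate: float | None = None
    aicc: float = float("nan")
    weight: float | None = None
    converged: bool = True
    restarts: int = 0
    boundary: list[str] = field(default_factory=list)
    degenerate: bool = False
    data_fingerprint: str = ""

    def __post_init__(self) -> None:
        if math.isnan(self.aicc):
            self.aicc = aicc(self.loglik, self.k, self.n)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items()}
        return d


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample Akaike information criterion:
    AICc = -2 logL + 2k + 2k(k+1)/(n-k-1)."""
    if n - k - 1 <= 0:
        return float("inf")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aiccs: Sequence[float]) -> np.ndarray:
    a = np.asarray(aiccs, dtype=float)
    delta = a - a.min()
    w = np.exp(-0.5 * delta)
    return w / w.sum()


# ---------------------------------------------------------------------------
# Gaussian moments on the tree

def _as_regime_map(value, regimes: Sequence[str], name: str) -> dict[str, float]:
    if isinstance(value, Mapping):
        missing = [r for r in regimes if r not in value]
        if missing:
            raise DataError(f"{name} missing for regimes {missing}")
        return {r: float(value[r]) for r in regimes}
    return {r: float(value) for r in regimes}


def _moments(tree: Phylogeny, node_cat: Mapping[int, str],
             alpha: Mapping[str, float] | None,
             sigma2: Mapping[str, float],
             eb_rate: float = 0.0,
             theta_cols: Sequence[str] | None = None,
             root_mode: str = "stationary"):
    """Mean design matrix W (tips x columns) and covariance V (tips x tips).

    ``alpha=None`` selects the BM family (single ``z0`` mean column);
    otherwise columns are the theta regimes, with the root weight folded
    into the root regime's column under ``root_mode='stationary'`` or kept
    as a separate ``z0`` column under ``'estimated'``.
    """
    n_nodes = tree.n_nodes
    parent = tree.parent
    length = tree.length
    depths = tree.depths()
    A = np.zeros(n_nodes)     # cumulative integral of alpha from the root
    H = np.zeros(n_nodes)     # discounted accumulated variance e^{-2A(v)} G(v)
    for v in tree.preorder:
        p = parent[v]
        if p < 0:
            continue
        dt = float(length[v])
        cat = node_cat[int(v)]
        a = 0.0 if alpha is None else alpha[cat]
        s2 = sigma2[cat]
        A[v] = A[p] + a * dt
        if a > 0.0:
            decay = math.exp(-2.0 * a * dt)
            H[v] = decay * H[p] + s2 * (-math.expm1(-2.0 * a * dt)) / (2.0 * a)
        elif eb_rate != 0.0:
            H[v] = H[p] + s2 * (math.exp(eb_rate * depths[v])
                                - math.exp(eb_rate * depths[p])) / eb_rate
        else:
            H[v] = H[p] + s2 * dt

    tips = tree.tip_indices
    Ai = A[tips]
    M = tree.tip_mrca
    expo = 2.0 * A[M] - Ai[:, None] - Ai[None, :]
    V = H[M] * np.exp(expo)

    if alpha is None:
        W = np.ones((tips.size, 1))
        cols = ["z0"]
        return W, V, cols

    cols = list(theta_cols)
    root_cat = node_cat[tree.root]
    if root_mode == "stationary":
        col_index = {c: i for i, c in enumerate(cols)}
        W = np.zeros((tips.size, len(cols)))
    elif root_mode == "estimated":
        col_index = {c: i for i, c in enumerate(cols)}
        W = np.zeros((tips.size, len(cols) + 1))
        cols = cols + ["z0"]
    else:
        raise DataError(f"unknown root_mode {root_mode!r}")
    for i, path in enumerate(tree.tip_paths):
        ai = Ai[i]
        for v in path:
            p = parent[v]
            w = math.exp(A[v] - ai) - math.exp(A[p] - ai)
            W[i, col_index[node_cat[int(v)]]] += w
        root_w = math.exp(-ai)
        if root_mode == "stationary":
            W[i, col_index[root_cat]] += root_w
        else:
            W[i, -1] += root_w
    return W, V, cols


def _regimes_of(tree: Phylogeny, scheme: RegimeScheme) -> tuple[dict[int, str], list[str]]:
    node_cat = scheme.node_categories(tree)
    present = sorted(set(node_cat.values()), key=_CAT_ORDER.index)
    return node_cat, present


def _mvn_loglik(y: np.ndarray, mean: np.ndarray, V: np.ndarray) -> float:
    n = y.size
    try:
        c = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:
        raise DataError("singular trait covariance (coincident tips?)") from exc
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    r = y - mean
    quad = float(r @ cho_solve(c, r))
    return -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)


def _gls(y: np.ndarray, W: np.ndarray, V: np.ndarray):
    """GLS estimate of the mean coefficients and residual quadratic form."""
    c = cho_factor(V, lower=True)
    Vi_W = cho_solve(c, W)
    Vi_y = cho_solve(c, y)
    XtVX = W.T @ Vi_W
    beta = np.linalg.solve(XtVX, W.T @ Vi_y)
    r = y - W @ beta
    quad = float(r @ cho_solve(c, r))
    logdet = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    return beta, quad, logdet, XtVX


def _profiled_ll(y: np.ndarray, W: np.ndarray, V0: np.ndarray):
    """ML log-likelihood with the overall rate profiled out of V = s2*V0
    (GLS mean, sigma2_hat = quad/n)."""
    n = y.size
    beta, quad, logdet0, XtVX = _gls(y, W, V0)
    s2 = max(quad / n, 1e-300)
    ll = -0.5 * (n * math.log(2.0 * math.pi * s2) + logdet0 + n)
    return ll, beta, s2, XtVX


# ---------------------------------------------------------------------------
# public likelihood

def _check_model(model: str, scheme, tree: Phylogeny) -> None:
    if model not in MODELS:
        raise DataError(f"unknown model {model!r}; expected one of {MODELS}")
    if model in _NEEDS_SCHEME and scheme is None:
        raise DataError(f"model {model} requires a regime scheme")
    if model in OU_FAMILY:
        ok, spread = check_ultrametric(tree, rel_tol=1e-3)
        if not ok:
            raise TreeError(
                f"OU-family models need an ultrametric tree "
                f"(depth spread {spread:.4g} Myr)")


def _trait_vector(tree: Phylogeny, traits: TraitTable | Mapping[str, float],
                  log_transform: bool = False) -> np.ndarray:
    series = traits.as_series() if isinstance(traits, TraitTable) else pd.Series(traits)
    try:
        y = series.loc[tree.tip_labels].to_numpy(dtype=float)
    except KeyError as exc:
        raise DataError(f"trait value missing for tree tip: {exc}") from exc
    if log_transform:
        y = np.log(y)
    return y


def _fingerprint(tree: Phylogeny, y: np.ndarray, log_transform: bool) -> str:
    payload = repr((tree.tip_labels, np.round(y, 12).tolist(), log_transform))
    return hashlib.sha1(payload.encode()).hexdigest()[:16]


def loglik(model: str, tree: Phylogeny, traits, scheme: RegimeScheme | None,
           params: Mapping, log_transform: bool = False,
           root_mode: str = "stationary") -> float:
    """Exact Gaussian log-likelihood of ``model`` at explicit parameters.

    ``params`` keys by model: BM (sigma2, z0); BMS (sigma2 per regime, z0);
    EB (sigma2, eb_rate, z0); OU1 (alpha, sigma2, theta); OUM/OUMV/OUMA/
    OUMVA (alpha, sigma2, theta, scalars or per-regime dicts as the model
    requires; z0 additionally under root_mode='estimated').
    """
    _check_model(model, scheme, tree)
    y = _trait_vector(tree, traits, log_transform)
    for key in ("sigma2", "alpha", "eb_rate", "z0", "theta"):
        val = params.get(key)
        vals = list(val.values()) if isinstance(val, Mapping) else [val]
        if any(v is not None and not np.isfinite(v) for v in vals):
            raise DataError(f"non-finite parameter {key}")

    if model in BM_FAMILY:
        if scheme is not None and model == "BMS":
            node_cat, present = _regimes_of(tree, scheme)
        else:
            node_cat = {v: "0" for v in range(tree.n_nodes)}
            present = ["0"]
        sigma2 = _as_regime_map(params["sigma2"], present, "sigma2")
        eb_rate = float(params.get("eb_rate", 0.0)) if model == "EB" else 0.0
        if eb_rate > 0:
            raise DataError("EB decay rate must be <= 0")
        W, V, _ = _moments(tree, node_cat, None, sigma2, eb_rate)
        mean = W @ np.array([float(params["z0"])])
        return _mvn_loglik(y, mean, V)

    # OU family
    if model == "OU1":
        node_cat = {v: "0" for v in range(tree.n_nodes)}
        present = ["0"]
    else:
        node_cat, present = _regimes_of(tree, scheme)
    alpha = _as_regime_map(params["alpha"], present, "alpha")
    if any(a <= 0 for a in alpha.values()):
        raise DataError("alpha must be > 0 for OU models (use BM for alpha=0)")
    sigma2 = _as_regime_map(params["sigma2"], present, "sigma2")
    theta = _as_regime_map(params["theta"], present, "theta")
    W, V, cols = _moments(tree, node_cat, alpha, sigma2,
                          theta_cols=present, root_mode=root_mode)
    beta = [theta[c] for c in present]
    if root_mode == "estimated":
        beta = beta + [float(params["z0"])]
    mean = W @ np.asarray(beta, dtype=float)
    return _mvn_loglik(y, mean, V)


# ---------------------------------------------------------------------------
# fitting

@dataclass
class FitOptions:
    log_transform: bool = False
    n_restarts: int = 10
    seed: int = 0
    alpha_bounds: tuple[float, float] = (1e-6, 100.0)
    sigma2_bounds: tuple[float, float] = (1e-8, 1e6)
    eb_rate_bounds: tuple[float, float] = (-10.0, 0.0)
    root_mode: str = "stationary"
    grid_size: int = 40


def _param_count(model: str, n_regimes: int, root_mode: str) -> int:
    R = n_regimes
    k = {"BM": 2, "EB": 3, "OU1": 3, "BMS": R + 1, "OUM": 2 + R,
         "OUMV": 1 + 2 * R, "OUMA": 1 + 2 * R, "OUMVA": 3 * R}[model]
    if model in OU_FAMILY and root_mode == "estimated":
        k += 1
    return k


def _theta_se(XtVX: np.ndarray, s2: float) -> np.ndarray:
    cov = s2 * np.linalg.inv(XtVX)
    return np.sqrt(np.clip(np.diag(cov), 0.0, None))


def fit(model: str, tree: Phylogeny, traits, scheme: RegimeScheme | None = None,
        options: FitOptions | None = None) -> ModelFit:
    """Maximum-likelihood fit by bounded multi-start optimization.

    Single-hyperparameter models (EB, OU1, OUM) use a deterministic
    grid-plus-Brent profile over the non-linear parameter with sigma^2 and
    the mean coefficients (z0 / theta) solved in closed form; multi-rate
    models use L-BFGS-B from Latin-hypercube starts. Optimum standard
    errors for theta come from the conditional GLS covariance at
    (alpha_hat, sigma2_hat).
    """
    opts = options or FitOptions()
    _check_model(model, scheme, tree)
    y = _trait_vector(tree, traits, opts.log_transform)
    n = y.size
    fp = _fingerprint(tree, y, opts.log_transform)

    if np.ptp(y) < 1e-12:
        # constant trait: the ML rate runs to the lower bound and the
        # likelihood diverges; report the capped boundary fit and flag it
        s2_lo = opts.sigma2_bounds[0]
        ll = loglik("BM", tree, dict(zip(tree.tip_labels, y)), None,
                    {"sigma2": s2_lo, "z0": float(y[0])})
        return ModelFit(model=model, loglik=ll, k=2, n=n, sigma2=s2_lo,
                        z0=float(y[0]), converged=False, degenerate=True,
                        boundary=["sigma2"], data_fingerprint=fp)

    if model in BM_FAMILY:
        result = _fit_bm_family(model, tree, y, scheme, opts)
    else:
        result = _fit_ou_family(model, tree, y, scheme, opts)
    result.n = n
    result.aicc = aicc(result.loglik, result.k, n)
    result.data_fingerprint = fp
    return result


def _fit_bm_family(model, tree, y, scheme, opts) -> ModelFit:
    n = y.size
    node_cat0 = {v: "0" for v in range(tree.n_nodes)}

    if model == "BM":
        _, V0, _ = _moments(tree, node_cat0, None, {"0": 1.0})
        ll, beta, s2, _ = _profiled_ll(y, np.ones((n, 1)), V0)
        return ModelFit(model="BM", loglik=ll, k=2, n=n, sigma2=float(s2),
                        z0=float(beta[0]))

    if model == "EB":
        lo, hi = opts.eb_rate_bounds

        def nll(r):
            _, V0, _ = _moments(tree, node_cat0, None, {"0": 1.0}, eb_rate=r)
            try:
                return -_profiled_ll(y, np.ones((n, 1)), V0)[0]
            except np.linalg.LinAlgError:
                return 1e10

        r_hat = _grid_brent(nll, lo, hi, opts.grid_size)
        _, V0, _ = _moments(tree, node_cat0, None, {"0": 1.0}, eb_rate=r_hat)
        ll, beta, s2, _ = _profiled_ll(y, np.ones((n, 1)), V0)
        boundary = ["eb_rate"] if (r_hat - lo < 1e-8 or hi - r_hat < 1e-10) else []
        return ModelFit(model="EB", loglik=ll, k=3, n=n, sigma2=float(s2),
                        eb_rate=float(r_hat), z0=float(beta[0]),
                        boundary=boundary)

    # BMS: per-regime Brownian rates, z0 via GLS
    node_cat, present = _regimes_of(tree, scheme)
    R = len(present)
    lo, hi = np.log(opts.sigma2_bounds)
    ones = np.ones((n, 1))

    def nll(x):
        sig = dict(zip(present, np.exp(x)))
        _, V, _ = _moments(tree, node_cat, None, sig)
        try:
            beta, quad, logdet, _ = _gls(y, ones, V)
        except np.linalg.LinAlgError:
            return 1e10
        return 0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)

    # start from the single-rate BM solution plus Latin-hypercube restarts
    bm = _fit_bm_family("BM", tree, y, None, opts)
    starts = [np.full(R, math.log(max(bm.sigma2, 1e-6)))]
    sampler = qmc.LatinHypercube(d=R, seed=opts.seed)
    for row in sampler.random(opts.n_restarts):
        starts.append(lo + row * (hi - lo))
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B",
                                bounds=[(lo, hi)] * R)
        if best is None or res.fun < best.fun:
            best = res
    sig_hat = dict(zip(present, np.exp(best.x)))
    _, V, _ = _moments(tree, node_cat, None, sig_hat)
    beta, quad, logdet, _ = _gls(y, np.ones((n, 1)), V)
    ll = -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
    boundary = []
    reported = {}
    for r in present:
        if sig_hat[r] <= opts.sigma2_bounds[0] * (1 + 1e-6):
            boundary.append(f"sigma2[{r}]")
            reported[r] = 0.0
        else:
            reported[r] = float(sig_hat[r])
    return ModelFit(model="BMS", loglik=ll, k=R + 1, n=n, sigma2=reported,
                    z0=float(beta[0]), boundary=boundary,
                    converged=bool(best.success), restarts=len(starts))


def _grid_brent(nll, lo, hi, grid_size):
    xs = np.linspace(lo, hi, grid_size)
    vals = [nll(x) for x in xs]
    i = int(np.argmin(vals))
    a = xs[max(i - 1, 0)]
    b = xs[min(i + 1, len(xs) - 1)]
    if a == b:
        return xs[i]
    res = optimize.minimize_scalar(nll, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-10})
    return float(res.x) if res.fun <= vals[i] else float(xs[i])


def _fit_ou_family(model, tree, y, scheme, opts) -> ModelFit:
    n = y.size
    if model == "OU1":
        node_cat = {v: "0" for v in range(tree.n_nodes)}
        present = ["0"]
    else:
        node_cat, present = _regimes_of(tree, scheme)
    R = len(present)
    la_lo, la_hi = np.log(opts.alpha_bounds)
    ls_lo, ls_hi = np.log(opts.sigma2_bounds)
    root_mode = opts.root_mode

    def moments(alpha_map, sigma2_map):
        return _moments(tree, node_cat, alpha_map, sigma2_map,
                        theta_cols=present, root_mode=root_mode)

    if model in ("OU1", "OUM"):
        def nll(la):
            a = math.exp(la)
            W, V0, _ = moments({r: a for r in present}, {r: 1.0 for r in present})
            try:
                return -_profiled_ll(y, W, V0)[0]
            except np.linalg.LinAlgError:
                return 1e10

        la_hat = _grid_brent(nll, la_lo, la_hi, opts.grid_size)
        a_hat = math.exp(la_hat)
        W, V0, cols = moments({r: a_hat for r in present}, {r: 1.0 for r in present})
        ll, beta, s2, XtVX = _profiled_ll(y, W, V0)
        se = _theta_se(XtVX, s2)
        boundary = []
        if la_hat - la_lo < 1e-6:
            boundary.append("alpha(lower)")
        if la_hi - la_hat < 1e-6:
            boundary.append("alpha(upper)")
        theta = {c: float(b) for c, b in zip(cols, beta) if c != "z0"}
        theta_se = {c: float(s) for c, s in zip(cols, se) if c != "z0"}
        z0 = float(beta[-1]) if root_mode == "estimated" else None
        if model == "OU1":
            theta = {"theta": theta["0"]}
            theta_se = {"theta": theta_se["0"]}
        k = _param_count(model, R, root_mode)
        return ModelFit(model=model, loglik=ll, k=k, n=n, sigma2=float(s2),
                        alpha=float(a_hat), theta=theta, theta_se=theta_se,
                        z0=z0, boundary=boundary)

    # OUMA: per-regime alpha, scalar sigma2 profiled
    # OUMV: scalar alpha, per-regime sigma2
    # OUMVA: both per-regime
    if model == "OUMA":
        dim, profiled = R, True
    elif model == "OUMV":
        dim, profiled = 1 + R, False
    else:
        dim, profiled = 2 * R, False

    def unpack(x):
        if model == "OUMA":
            return dict(zip(present, np.exp(x))), {r: 1.0 for r in present}
        if model == "OUMV":
            a = math.exp(x[0])
            return ({r: a for r in present},
                    dict(zip(present, np.exp(x[1:]))))
        return (dict(zip(present, np.exp(x[:R]))),
                dict(zip(present, np.exp(x[R:]))))

    def nll(x):
        alpha_map, sigma2_map = unpack(x)
        try:
            W, V, _ = moments(alpha_map, sigma2_map)
            if profiled:
                return -_profiled_ll(y, W, V)[0]
            beta, quad, logdet, _ = _gls(y, W, V)
            return 0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
        except (np.linalg.LinAlgError, DataError):
            return 1e10

    # seed starts from the nested OUM solution
    oum = _fit_ou_family("OUM" if model != "OU1" else "OU1", tree, y, scheme, opts)
    la0 = math.log(oum.alpha)
    ls0 = math.log(max(oum.sigma2, 1e-7))
    if model == "OUMA":
        starts = [np.full(R, la0)]
        bounds = [(la_lo, la_hi)] * R
    elif model == "OUMV":
        starts = [np.array([la0] + [ls0] * R)]
        bounds = [(la_lo, la_hi)] + [(ls_lo, ls_hi)] * R
    else:
        starts = [np.array([la0] * R + [ls0] * R)]
        bounds = [(la_lo, la_hi)] * R + [(ls_lo, ls_hi)] * R
    sampler = qmc.LatinHypercube(d=dim, seed=opts.seed)
    lows = np.array([b[0] for b in bounds])
    highs = np.array([b[1] for b in bounds])
    for row in sampler.random(opts.n_restarts):
        starts.append(lows + row * (highs - lows))
    best = None
    for x0 in starts:
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    alpha_map, sigma2_map = unpack(best.x)
    W, V, cols = moments(alpha_map, sigma2_map)
    if profiled:
        ll, beta, s2, XtVX = _profiled_ll(y, W, V)
        sigma2_out: float | dict = float(s2)
        se = _theta_se(XtVX, s2)
    else:
        beta, quad, logdet, XtVX = _gls(y, W, V)
        ll = -0.5 * (n * math.log(2.0 * math.pi) + logdet + quad)
        sigma2_out = {r: float(v) for r, v in sigma2_map.items()}
        se = _theta_se(XtVX, 1.0)
    theta = {c: float(b) for c, b in zip(cols, beta) if c != "z0"}
    theta_se = {c: float(s) for c, s in zip(cols, se) if c != "z0"}
    alpha_out = ({r: float(v) for r, v in alpha_map.items()}
                 if model in ("OUMA", "OUMVA") else float(next(iter(alpha_map.values()))))
    k = _param_count(model, R, root_mode)
    return ModelFit(model=model, loglik=ll, k=k, n=n, sigma2=sigma2_out,
                    alpha=alpha_out, theta=theta, theta_se=theta_se,
                    z0=float(beta[-1]) if root_mode == "estimated" else None,
                    converged=bool(best.success), restarts=len(starts))


# ---------------------------------------------------------------------------
# model comparison

def compare(fits: Sequence[ModelFit], n: int | None = None) -> pd.DataFrame:
    """AICc comparison table with delta-AICc and Akaike weights.

    All fits must be on identical data (checked via the stored fingerprint
    when present); weights are written back onto the fits.
    """
    if not fits:
        raise DataError("no fits to compare")
    fps = {f.data_fingerprint for f in fits if f.data_fingerprint}
    if len(fps) > 1:
        raise DataError("fits were made on different data (fingerprint mismatch)")
    if n is None:
        ns = {f.n for f in fits}
        if len(ns) != 1:
            raise DataError("fits disagree on n; pass n explicitly")
        n = ns.pop()
    rows = []
    aiccs = [aicc(f.loglik, f.k, n) for f in fits]
    weights = akaike_weights(aiccs)
    best = min(aiccs)
    for f, a, w in zip(fits, aiccs, weights):
        f.aicc = a
        f.weight = float(w)
        rows.append({"model": f.model, "logLik": f.loglik, "k": f.k,
                     "AICc": a, "dAICc": a - best, "weight": float(w)})
    return pd.DataFrame(rows).sort_values("AICc").reset_index(drop=True)


def format_comparison(fits: Sequence[ModelFit]) -> str:
    """Text block with one column per model: log_L, AICc, sigma^2, alpha and
    per-category optima (point estimate with its standard error)."""
    def fmt_multi(value, order=_CAT_ORDER):
        if value is None:
            return ""
        if isinstance(value, dict):
            return ", ".join(f"{value[c]:.1f}" for c in order if c in value)
        return f"{value:.2f}"

    names = [f.model for f in fits]
    lines = [["model"] + names,
             ["log_L"] + [f"{f.loglik:.2f}" for f in fits],
             ["AICc"] + [f"{f.aicc:.2f}" for f in fits],
             ["sigma2"] + [fmt_multi(f.sigma2) for f in fits],
             ["alpha"] + [fmt_multi(f.alpha) for f in fits]]
    cats = sorted({c for f in fits if f.theta for c in f.theta},
                  key=lambda c: (_CAT_ORDER.index(c) if c in _CAT_ORDER else 9))
    for c in cats:
        row = [f"theta_{c} (s.e.)"]
        for f in fits:
            if f.theta and c in f.theta:
                se = f.theta_se.get(c) if f.theta_se else None
                row.append(f"{f.theta[c]:.1f} ({se:.1f})" if se is not None
                           else f"{f.theta[c]:.1f}")
            else:
                row.append("")
        lines.append(row)
    lines.append(["z0"] + [f"{f.z0:.1f}" if f.z0 is not None else "" for f in fits])
    widths = [max(len(row[i]) for row in lines) for i in range(len(names) + 1)]
    return "\n".join("  ".join(cell.ljust(w) for cell, w in zip(row, widths))
                     for row in lines)


# ---------------------------------------------------------------------------
# random-regime null

@dataclass
class NullResult:
    observed: ModelFit
    aiccs: np.ndarray
    exceedance: int          # replicates with AICc <= observed
    n_reps: int
    failures: list[str]
    seed: int
    mode: str

    @property
    def p_value(self) -> float:
        """Add-one proportion of random regimes fitting at least as well."""
        return (1 + self.exceedance) / (1 + self.n_reps)


def random_regime_null(tree: Phylogeny, traits, scheme: RegimeScheme,
                       n_reps: int = 1000, seed: int = 0,
                       mode: str = "permute",
                       options: FitOptions | None = None) -> NullResult:
    """Fit the multi-optimum OU model under randomized regime paintings.

    The observed scheme's AICc is compared with the AICc distribution over
    ``n_reps`` random reassignments of tip categories; a small exceedance
    count is the analog of the empirical finding that randomized schemes fit
    worse in every simulation.
    """
    observed = fit("OUM", tree, traits, scheme, options)
    seeds = np.random.SeedSequence(seed, spawn_key=(21,)).generate_state(
        max(n_reps, 1)) & 0x7FFFFFFF
    aiccs = []
    failures = []
    for rep in range(n_reps):
        rscheme = randomize_regimes(scheme, mode=mode, seed=int(seeds[rep]))
        try:
            f = fit("OUM", tree, traits, rscheme, options)
            aiccs.append(f.aicc)
        except (DataError, TreeError, np.linalg.LinAlgError) as exc:
            failures.append(f"rep {rep}: {exc}")
    arr = np.asarray(aiccs, dtype=float)
    exceed = int(np.sum(arr <= observed.aicc)) if arr.size else 0
    return NullResult(observed=observed, aiccs=arr, exceedance=exceed,
                      n_reps=len(aiccs), failures=failures, seed=seed,
                      mode=mode)
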