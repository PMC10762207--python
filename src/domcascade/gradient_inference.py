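"""Gradient trend estimation and environmental/spatial variance partitioning.

Two inferential layers sit on top of the cascade statistics:

* :func:`fit_trend` — generalised linear models of per-sample responses
  (universal-compound proportions, weighted masses, ...) against ordered
  depth / hillslope factors, with catchment and sample-type nuisance terms,
  estimated marginal means back-transformed to the response scale, and
  Tukey-adjusted pairwise contrasts against a baseline level.  Over-dispersed
  proportion-of-count responses use quasi-binomial dispersion scaling.

* a redundancy-analysis (RDA) toolkit — Pearson-correlation collinearity
  pruning, permutation-tested stepwise selection, principal coordinates of
  neighbour matrices (PCNM) for spatial structure, adjusted-R² variance
  partitioning over 2–3 predictor matrices with full inclusion–exclusion
  Venn algebra, and hierarchical partitioning (Shapley-style averaging of a
  predictor's incremental adjusted R² over all subsets).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform
import statsmodels.api as sm

__all__ = [
    "GradientDesign",
    "TrendResult",
    "VarPartResult",
    "fit_trend",
    "reduce_collinear",
    "forward_select",
    "pcnm",
    "rda_adj_r2",
    "variance_partition",
    "hierarchical_partition",
]

FAMILIES = ("binomial", "gaussian", "gaussian-logit", "gaussian-log")


# ---------------------------------------------------------------------------
# Trend models
# ---------------------------------------------------------------------------

@dataclass
class GradientDesign:
    """One trend-model specification.

    ``response`` names the response column (for the binomial family it holds
    successes and ``trials`` the trial counts).  ``focal`` is the gradient
    factor whose marginal means and contrasts are wanted; ``covariates`` are
    additive nuisance factors (catchment, the other gradient, sample type).
    ``interaction_with`` optionally names a covariate whose interaction with
    the focal factor is fitted first and dropped when a likelihood-ratio test
    gives p > 0.05.  Factor levels follow pandas Categorical ordering when
    present, otherwise order of appearance.
    """

    data: pd.DataFrame
    response: str
    focal: str
    covariates: tuple[str, ...] = ()
    family: str = "gaussian"
    trials: str | None = None
    baseline: str | None = None
    interaction_with: str | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "binomial" and self.trials is None:
            raise ValueError("binomial designs need a trials column")
        if self.interaction_with is not None and self.interaction_with not in self.covariates:
            raise ValueError("interaction_with must be one of the covariates")


@dataclass
class TrendResult:
    """Marginal means, Tukey-adjusted contrasts, and model diagnostics."""

    emmeans: pd.DataFrame       # level, emmean, ci_low, ci_high (response scale)
    contrasts: pd.DataFrame     # level, estimate (link scale), t, p_unadj, p_adj
    df_resid: float
    dispersion: float
    family: str
    interaction_dropped: bool | None = None
    adjustment: str = "tukey"


def _levels(series: pd.Series) -> list:
    if isinstance(series.dtype, pd.CategoricalDtype):
        return [l for l in series.cat.categories if l in set(series.dropna())]
    seen: dict = {}
    for v in series.dropna():
        seen.setdefault(v, None)
    return list(seen)


def _dummies(values: pd.Series, levels: list, prefix: str) -> pd.DataFrame:
    """Treatment coding against the first level."""
    out = {}
    for lev in levels[1:]:
        out[f"{prefix}[{lev}]"] = (values == lev).astype(float).to_numpy()
    return pd.DataFrame(out, index=values.index)


def _check_full_rank(X: pd.DataFrame) -> None:
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # name the aliased columns via pivoted QR
        _, _, piv = scipy.linalg.qr(X.to_numpy(), pivoting=True, mode="economic")
        aliased = [X.columns[i] for i in piv[rank:]]
        raise ValueError(f"singular design matrix; aliased term(s): {aliased}")


def _fit_glm(endog, X: pd.DataFrame, family: str):
    """Fit the working model; returns (results, dispersion, df_resid, deviance).

    Binomial responses use a GLM with quasi-likelihood (Pearson) dispersion;
    the (possibly transformed) gaussian families use OLS, which handles
    zero-variance responses gracefully.
    """
    with warnings.catch_warnings():
        # saturated toy designs (df_resid = 0) are legal here; dispersion is
        # handled explicitly below
        warnings.simplefilter("ignore")
        if family == "binomial":
            res = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial()).fit()
            deviance = float(res.deviance)
            df_resid = float(res.df_resid)
            dispersion = float(res.pearson_chi2 / df_resid) if df_resid > 0 else 1.0
        else:
            res = sm.OLS(endog, X.to_numpy()).fit()
            deviance = float(res.ssr)
            df_resid = float(res.df_resid)
            dispersion = float(res.ssr / df_resid) if df_resid > 0 else 0.0
    return res, dispersion, df_resid, deviance


def fit_trend(design: GradientDesign) -> TrendResult:
    """Fit the additive gradient GLM and summarise the focal factor.

    Marginal means are equal-weight averages of link-scale predictions over
    all combinations of observed covariate levels, back-transformed to the
    response scale with delta-method confidence intervals.  Pairwise
    contrasts of every focal level against the baseline are adjusted with the
    multivariate-t (Tukey-style) reference distribution of the contrast set;
    when the contrast covariance is singular the adjustment falls back to
    Holm (recorded in ``adjustment``).
    """
    used = [design.response, design.focal, *design.covariates]
    if design.trials:
        used.append(design.trials)
    data = design.data.dropna(subset=used).copy()
    if not len(data):
        raise ValueError("no complete rows for the requested design")

    focal_levels = _levels(data[design.focal])
    if len(focal_levels) < 2:
        raise ValueError(f"focal factor {design.focal!r} needs >= 2 observed levels")
    baseline = design.baseline if design.baseline is not None else focal_levels[0]
    if baseline not in focal_levels:
        raise ValueError(f"baseline {baseline!r} not among focal levels {focal_levels}")
    focal_levels = [baseline] + [l for l in focal_levels if l != baseline]

    cov_levels = {c: _levels(data[c]) for c in design.covariates}
    cov_levels = {c: ls for c, ls in cov_levels.items() if len(ls) >= 1}

    def build_X(frame: pd.DataFrame, with_interaction: bool) -> pd.DataFrame:
        parts = [pd.DataFrame({"Intercept": np.ones(len(frame))}, index=frame.index)]
        parts.append(_dummies(frame[design.focal], focal_levels, design.focal))
        for c, ls in cov_levels.items():
            if len(ls) > 1:
                parts.append(_dummies(frame[c], ls, c))
        if with_interaction and design.interaction_with is not None:
            f = _dummies(frame[design.focal], focal_levels, design.focal)
            g = _dummies(frame[design.interaction_with],
                         cov_levels[design.interaction_with], design.interaction_with)
            inter = {}
            for fc in f.columns:
                for gc in g.columns:
                    inter[f"{fc}:{gc}"] = f[fc].to_numpy() * g[gc].to_numpy()
            parts.append(pd.DataFrame(inter, index=frame.index))
        return pd.concat(parts, axis=1)

    # response / transform
    if design.family == "binomial":
        succ = data[design.response].to_numpy(dtype=float)
        trials = data[design.trials].to_numpy(dtype=float)
        endog = np.column_stack([succ, trials - succ])
    else:
        y = data[design.response].to_numpy(dtype=float)
        if design.family == "gaussian-logit":
            if np.any((y <= 0) | (y >= 1)):
                raise ValueError("gaussian-logit needs responses strictly inside (0, 1)")
            endog = np.log(y / (1 - y))
        elif design.family == "gaussian-log":
            if np.any(y <= 0):
                raise ValueError("gaussian-log needs strictly positive responses")
            endog = np.log(y)
        else:
            endog = y

    if design.family in ("binomial", "gaussian-logit"):
        def back(x):
            return 1.0 / (1.0 + np.exp(-np.asarray(x)))
    elif design.family == "gaussian-log":
        back = np.exp
    else:
        def back(x):
            return np.asarray(x)

    interaction_dropped: bool | None = None
    X_add = build_X(data, with_interaction=False)
    _check_full_rank(X_add)
    if design.interaction_with is not None:
        X_int = build_X(data, with_interaction=True)
        try:
            _check_full_rank(X_int)
            res_int, disp_int, df_int, dev_int = _fit_glm(endog, X_int, design.family)
            _, _, _, dev_add = _fit_glm(endog, X_add, design.family)
            q = X_int.shape[1] - X_add.shape[1]
            scale = max(disp_int, 1e-12) if design.family == "binomial" else max(
                dev_int / df_int if df_int > 0 else 1.0, 1e-12
            )
            lr = (dev_add - dev_int) / scale
            p_lr = scipy.stats.chi2.sf(max(lr, 0.0), q)
            interaction_dropped = bool(p_lr > 0.05)
        except ValueError:
            interaction_dropped = True  # aliased interaction cells: keep additive
        X = X_add if interaction_dropped else X_int
    else:
        X = X_add
    res, dispersion, df_resid, _dev = _fit_glm(endog, X, design.family)

    if design.family == "binomial":
        cov_params = np.asarray(res.cov_params()) * dispersion
    elif df_resid > 0:
        cov_params = np.asarray(res.cov_params())
    else:
        Xa = X.to_numpy()  # saturated gaussian fit: unit-scale covariance
        cov_params = np.linalg.pinv(Xa.T @ Xa)
    params = np.asarray(res.params)

    # reference grid: focal levels x product of covariate level combos
    combos = list(itertools.product(*[cov_levels[c] for c in cov_levels])) or [()]
    L_rows = {}
    for lev in focal_levels:
        grid = pd.DataFrame(
            [
                {design.focal: lev, **dict(zip(cov_levels, combo))}
                for combo in combos
            ]
        )
        Xg = build_X(grid, with_interaction=(X.shape[1] != X_add.shape[1]))
        Xg = Xg.reindex(columns=X.columns, fill_value=0.0)
        L_rows[lev] = Xg.to_numpy().mean(axis=0)

    use_t = np.isfinite(df_resid) and df_resid > 0
    tdist = scipy.stats.t(df_resid) if use_t else scipy.stats.norm()

    em_rows = []
    for lev in focal_levels:
        L = L_rows[lev]
        eta = float(L @ params)
        se = float(np.sqrt(L @ cov_params @ L))
        crit = tdist.ppf(0.975)
        em_rows.append(
            dict(level=lev, emmean=float(back(eta)),
                 ci_low=float(back(eta - crit * se)), ci_high=float(back(eta + crit * se)))
        )
    emmeans = pd.DataFrame(em_rows)

    # contrasts vs baseline on the link scale
    others = focal_levels[1:]
    Lc = np.array([L_rows[lev] - L_rows[baseline] for lev in others])
    est = Lc @ params
    C = Lc @ cov_params @ Lc.T
    se = np.sqrt(np.clip(np.diag(C), 0, None))
    tstat = np.zeros_like(est)
    nonzero = se > 1e-12
    tstat[nonzero] = est[nonzero] / se[nonzero]
    tstat[~nonzero & (np.abs(est) > 1e-12)] = np.inf * np.sign(est[~nonzero & (np.abs(est) > 1e-12)])
    if use_t:
        p_unadj = 2 * scipy.stats.t.sf(np.abs(tstat), df_resid)
    else:
        p_unadj = 2 * scipy.stats.norm.sf(np.abs(tstat))
    p_unadj = np.where(np.isfinite(tstat), p_unadj, 0.0)
    p_unadj = np.where((np.abs(est) < 1e-12) & ~nonzero, 1.0, p_unadj)

    p_adj, adjustment = _tukey_adjust(tstat, C, df_resid if use_t else np.inf, p_unadj)
    contrasts = pd.DataFrame(
        dict(level=others, baseline=baseline, estimate=est, t=tstat,
             p_unadj=p_unadj, p_adj=np.maximum(p_adj, p_unadj))
    )
    return TrendResult(
        emmeans=emmeans, contrasts=contrasts, df_resid=df_resid,
        dispersion=dispersion, family=design.family,
        interaction_dropped=interaction_dropped, adjustment=adjustment,
    )


def _tukey_adjust(tstat: np.ndarray, C: np.ndarray, df: float, p_unadj: np.ndarray):
    """Multivariate-t rectangle probabilities for max-|T| adjustment.

    Falls back to Holm when the contrast covariance is (near-)singular.
    """
    k = len(tstat)
    if k <= 1:
        return p_unadj.copy(), "none"
    d = np.sqrt(np.clip(np.diag(C), 1e-300, None))
    R = C / np.outer(d, d)
    R = (R + R.T) / 2
    eig = np.linalg.eigvalsh(R)
    if eig.min() < 1e-10 or not np.all(np.isfinite(tstat)):
        order = np.argsort(p_unadj)
        p_holm = np.empty(k)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (k - rank) * p_unadj[idx])
            p_holm[idx] = min(1.0, running)
        return p_holm, "holm"
    p_adj = np.empty(k)
    for j in range(k):
        c = abs(tstat[j])
        if np.isfinite(df):
            mvt = scipy.stats.multivariate_t(shape=R, df=df, seed=12345)
            inside = mvt.cdf(np.full(k, c), lower_limit=np.full(k, -c))
        else:
            mvn = scipy.stats.multivariate_normal(cov=R, seed=12345)
            inside = mvn.cdf(np.full(k, c), lower_limit=np.full(k, -c))
        p_adj[j] = min(1.0, max(0.0, 1.0 - float(inside)))
    return p_adj, "tukey"


# ---------------------------------------------------------------------------
# Predictor preparation
# ---------------------------------------------------------------------------

def reduce_collinear(env: pd.DataFrame, r_threshold: float = 0.80) -> list[str]:
    """Iteratively drop the most globally correlated member of offending pairs.

    While any pair of predictors has Pearson \\|r\\| > ``r_threshold``, the
    variable involved in an offending pair with the largest mean \\|r\\|
    against all other remaining variables is removed.  Exact ties keep the
    earlier-listed variable.  Constant predictors are dropped up front with a
    warning.  Returns the kept column names in input order.
    """
    if env.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    kept = list(env.columns)
    for col in list(kept):
        if env[col].nunique() <= 1 or env[col].std() == 0:
            warnings.warn(f"dropping constant predictor {col!r}", stacklevel=2)
            kept.remove(col)
    while len(kept) >= 2:
        corr = env[kept].corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        if corr.max() <= r_threshold:
            break
        offenders = sorted(set(np.nonzero(corr > r_threshold)[0]))
        mean_r = corr.sum(axis=1) / (len(kept) - 1)
        # among offenders, largest mean |r|; ties -> remove the later-listed
        worst = max(offenders, key=lambda i: (mean_r[i], i))
        kept.pop(worst)
    return kept


def _standardize(X: pd.DataFrame | np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant predictor column cannot be standardised")
    return (X - mu) / sd


def _as_matrix(Y) -> np.ndarray:
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    return Y


def _rss(Yc: np.ndarray, Xc: np.ndarray | None) -> tuple[float, np.ndarray]:
    """Total residual sum of squares of centred Y on centred X (or the mean)."""
    if Xc is None or Xc.shape[1] == 0:
        return float((Yc ** 2).sum()), Yc.copy()
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ beta
    return float((resid ** 2).sum()), resid


def forward_select(
    Y,
    X: pd.DataFrame,
    alpha: float = 0.10,
    n_perm: int = 199,
    seed: int = 0,
) -> list[str]:
    """Permutation-tested stepwise predictor selection for multivariate Y.

    Forward: among candidates whose partial pseudo-F has permutation
    p <= ``alpha`` (Freedman–Lane residual permutation under the reduced
    model), add the one with the best F.  Backward: after each addition,
    drop any included predictor whose marginal permutation p > ``alpha``.
    Stops when neither step changes the model.  Fully seeded.
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    Yc = _as_matrix(Y)
    Yc = Yc - Yc.mean(axis=0)
    Xs = pd.DataFrame(_standardize(X), columns=list(X.columns))
    n = len(Yc)
    if len(Xs) != n:
        raise ValueError("Y and X row counts differ")
    rng = np.random.default_rng(seed)

    def partial_test(candidate: str, included: list[str]) -> tuple[float, float]:
        X0 = Xs[included].to_numpy() if included else None
        X1 = Xs[included + [candidate]].to_numpy()
        rss0, resid0 = _rss(Yc, X0)
        rss1, _ = _rss(Yc, X1)
        df2 = n - len(included) - 2  # intercept (centring) + predictors + candidate
        if df2 <= 0 or rss1 <= 0:
            return np.inf, 0.0
        F = (rss0 - rss1) / (rss1 / df2)
        fitted0 = Yc - resid0
        count = 1
        for _ in range(n_perm):
            perm = rng.permutation(n)
            Yp = fitted0 + resid0[perm]
            Yp = Yp - Yp.mean(axis=0)
            r0, _ = _rss(Yp, X0)
            r1, _ = _rss(Yp, X1)
            Fp = (r0 - r1) / (r1 / df2) if r1 > 0 else np.inf
            if Fp >= F:
                count += 1
        return F, count / (n_perm + 1)

    included: list[str] = []
    changed = True
    while changed:
        changed = False
        # forward
        best: tuple[float, str] | None = None
        for cand in Xs.columns:
            if cand in included:
                continue
            F, p = partial_test(cand, included)
            if p <= alpha and (best is None or F > best[0]):
                best = (F, cand)
        if best is not None:
            included.append(best[1])
            changed = True
        # backward
        dropped = True
        while dropped and included:
            dropped = False
            worst: tuple[float, str] | None = None
            for var in included:
                rest = [v for v in included if v != var]
                _, p = partial_test(var, rest)
                if p > alpha and (worst is None or p > worst[0]):
                    worst = (p, var)
            if worst is not None:
                included.remove(worst[1])
                changed = True
                dropped = True
    return included


# ---------------------------------------------------------------------------
# Spatial eigenvectors (PCNM)
# ---------------------------------------------------------------------------

def pcnm(coords, truncation: float | str = "auto") -> tuple[pd.DataFrame, np.ndarray]:
    """Principal coordinates of neighbour matrices from sample coordinates.

    Distances beyond the truncation threshold (default: the longest edge of
    the minimum spanning tree, which keeps all sites connected) are replaced
    by 4x the threshold; the truncated distance matrix is Gower-centred
    (-0.5 d², double-centred) and eigendecomposed.  Eigenvectors with
    eigenvalue > 1e-10 are returned as unit-norm columns PCNM1, PCNM2, ...
    ordered by decreasing eigenvalue, with the sign convention that the first
    nonzero loading is positive.
    """
    pts = np.asarray(coords, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = len(pts)
    if n < 2:
        raise ValueError("need at least 2 points")
    d = squareform(pdist(pts))
    if not d.any():
        raise ValueError("all points are identical; no spatial structure to model")
    if truncation == "auto":
        mst = minimum_spanning_tree(d).toarray()
        truncation = float(mst.max())
    t = float(truncation)
    if t <= 0:
        raise ValueError("truncation must be positive")
    dt = np.where(d > t, 4.0 * t, d)
    A = -0.5 * dt ** 2
    J = np.eye(n) - np.ones((n, n)) / n
    G = J @ A @ J
    G = (G + G.T) / 2
    eigval, eigvec = np.linalg.eigh(G)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-10
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    for j in range(eigvec.shape[1]):
        col = eigvec[:, j]
        nz = np.nonzero(np.abs(col) > 1e-12)[0]
        if len(nz) and col[nz[0]] < 0:
            eigvec[:, j] = -col
    table = pd.DataFrame(
        eigvec, columns=[f"PCNM{j + 1}" for j in range(eigvec.shape[1])]
    )
    return table, eigval


# ---------------------------------------------------------------------------
# RDA variance partitioning
# ---------------------------------------------------------------------------

def rda_adj_r2(Y, X) -> tuple[float, float]:
    """Redundancy-analysis R² and Ezekiel-adjusted R² of Y on X.

    Y and X are column-centred; R² is the share of Y's total variance
    captured by the multivariate least-squares fit; the adjustment is
    1 - (1 - R²)(n - 1)/(n - p - 1).  Negative adjusted values are legal and
    reported raw.  Rank-deficient X raises an error naming aliased columns.
    """
    Ym = _as_matrix(Y)
    Xm = _as_matrix(X)
    n, p = Xm.shape
    if len(Ym) != n:
        raise ValueError("Y and X row counts differ")
    if n <= p + 1:
        raise ValueError(f"adjustment needs n > p + 1 (n={n}, p={p})")
    Yc = Ym - Ym.mean(axis=0)
    Xc = Xm - Xm.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        cols = list(X.columns) if isinstance(X, pd.DataFrame) else list(range(p))
        _, _, piv = scipy.linalg.qr(Xc, pivoting=True, mode="economic")
        aliased = [cols[i] for i in piv[rank:]]
        raise ValueError(f"rank-deficient predictor matrix; aliased column(s): {aliased}")
    ss_tot = float((Yc ** 2).sum())
    if ss_tot == 0:
        raise ValueError("response has zero variance")
    rss, _ = _rss(Yc, Xc)
    r2 = 1.0 - rss / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    return float(r2), float(adj)


def _adj_r2_rank_safe(Yc: np.ndarray, Xblocks: Sequence[np.ndarray]) -> float:
    """Adjusted R² of Y on the union of blocks, dropping aliased columns.

    Unions of predictor matrices are routinely rank-deficient (duplicated or
    nested matrices), so the effective p is the rank of the independent
    column subset, as in standard variance-partitioning practice.
    """
    if not Xblocks:
        return 0.0
    Xc = np.hstack(Xblocks)
    Xc = Xc - Xc.mean(axis=0)
    n, p = Xc.shape
    rank = np.linalg.matrix_rank(Xc)
    if rank < p:
        _, _, piv = scipy.linalg.qr(Xc, pivoting=True, mode="economic")
        Xc = Xc[:, np.sort(piv[:rank])]
        p = rank
    if n <= p + 1:
        raise ValueError(f"adjustment needs n > p + 1 (n={n}, effective p={p})")
    ss_tot = float((Yc ** 2).sum())
    rss, _ = _rss(Yc, Xc)
    r2 = 1.0 - rss / ss_tot
    return float(1.0 - (1.0 - r2) * (n - 1) / (n - p - 1))


@dataclass
class VarPartResult:
    """Unique/shared adjusted-R² fractions for 2-3 predictor matrices.

    ``components`` maps each nonempty frozenset of matrix names to the Venn
    fraction shared by exactly those matrices (raw, may be negative);
    ``adj_r2`` maps each tested union to its adjusted R²; ``fractions`` is a
    tidy frame with raw and non-negative-truncated views.
    """

    names: tuple[str, ...]
    components: dict[frozenset, float]
    adj_r2: dict[frozenset, float]
    total_adj_r2: float
    fractions: pd.DataFrame = field(repr=False)


def variance_partition(Y, *X: pd.DataFrame | np.ndarray, names: Sequence[str] | None = None) -> VarPartResult:
    """Partition Y's adjusted R² over 2-3 predictor matrices.

    Every nonempty union of matrices is fitted; unique and shared Venn
    fractions come from Möbius inversion of the union adjusted R² values, so
    the raw fractions sum exactly to the full-model adjusted R².
    """
    if not 2 <= len(X) <= 3:
        raise ValueError("variance_partition takes 2 or 3 predictor matrices")
    names = tuple(names) if names is not None else tuple(f"X{i + 1}" for i in range(len(X)))
    if len(names) != len(X):
        raise ValueError("names length must match the number of matrices")
    Ym = _as_matrix(Y)
    Yc = Ym - Ym.mean(axis=0)
    blocks = {nm: _standardize(x) for nm, x in zip(names, X)}

    universe = frozenset(names)
    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            key = frozenset(combo)
            adj[key] = _adj_r2_rank_safe(Yc, [blocks[nm] for nm in combo])

    def B(S: frozenset) -> float:
        return adj[universe] - adj[universe - S]

    components: dict[frozenset, float] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            T = frozenset(combo)
            v = 0.0
            for k in range(len(T) + 1):
                for sub in itertools.combinations(sorted(T), k):
                    v += (-1) ** (len(T) - k) * B(frozenset(sub))
            components[T] = v

    rows = []
    for T, v in sorted(components.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))):
        rows.append(
            dict(component=" & ".join(sorted(T)),
                 kind="unique" if len(T) == 1 else "shared",
                 raw=v, truncated=max(v, 0.0))
        )
    fractions = pd.DataFrame(rows)
    return VarPartResult(
        names=names,
        components=components,
        adj_r2={k: v for k, v in adj.items() if k},
        total_adj_r2=adj[universe],
        fractions=fractions,
    )


def hierarchical_partition(
    Y, predictors: pd.DataFrame | Mapping[str, np.ndarray], max_p: int = 15
) -> pd.Series:
    """Average incremental adjusted R² of each predictor over all subsets.

    The Shapley-style hierarchical partitioning of Chevan & Sutherland,
    generalised to predictor matrices: a predictor's contribution is the
    average, over all subsets of the other predictors weighted by subset
    size, of the adjusted-R² gain from adding it.  Contributions sum to the
    full-model adjusted R².  Exact enumeration, hence the ``max_p`` cap.
    """
    if isinstance(predictors, pd.DataFrame):
        blocks = {str(c): _standardize(predictors[[c]]) for c in predictors.columns}
    else:
        blocks = {str(k): _standardize(v) for k, v in predictors.items()}
    names = list(blocks)
    p = len(names)
    if p == 0:
        raise ValueError("need at least one predictor")
    if p > max_p:
        raise ValueError(
            f"{p} predictors exceed max_p={max_p}; group variables before partitioning"
        )
    Ym = _as_matrix(Y)
    Yc = Ym - Ym.mean(axis=0)

    cache: dict[frozenset, float] = {frozenset(): 0.0}

    def adj(S: frozenset) -> float:
        if S not in cache:
            cache[S] = _adj_r2_rank_safe(Yc, [blocks[nm] for nm in sorted(S)])
        return cache[S]

    import math

    contrib = {nm: 0.0 for nm in names}
    for nm in names:
        others = [o for o in names if o != nm]
        for k in range(p):
            w = math.factorial(k) * math.factorial(p - 1 - k) / math.factorial(p)
            for sub in itertools.combinations(others, k):
                S = frozenset(sub)
                contrib[nm] += w * (adj(S | {nm}) - adj(S))
    return pd.Series(contrib, name="contribution")
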