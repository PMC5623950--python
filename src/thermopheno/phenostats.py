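"""Population statistics for canopy-temperature phenotyping trials.

Covers the analysis battery of a two-treatment clonal field trial:
Box-Cox transformation profiled on the additive genotype + treatment
model, Bartlett's homogeneity test, additive block adjustment within
plots, sequential two-way ANOVA, REML variance components for the
mixed model (treatment fixed; genotype and genotype-by-treatment
random), broad-sense heritability within and across treatments,
distribution shape statistics, cross-method agreement tests, and the
stomatal-conductance validation regression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

__all__ = [
    "StatResult", "RegressionFit", "TransformSpec", "VarianceComponents",
    "ShapeStats", "boxcox_fit", "bartlett_test", "block_adjust",
    "anova_two_way", "reml_components", "average_replicates",
    "h2_within", "h2_combined", "shape_stats", "spearman_rho", "paired_t",
    "gs_regression",
]


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    n: int
    name: str = ""

    def __post_init__(self):
        if np.isfinite(self.p_value) and not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    p_value: float            # two-sided test of zero slope
    p_value_one_sided: float  # directional test (slope of the fitted sign)
    n: int

    def __post_init__(self):
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("R^2 outside [0, 1]")


@dataclass(frozen=True)
class TransformSpec:
    """Fitted Box-Cox transform: y -> (y^lambda - 1)/lambda (log y at 0)."""

    lambda_: float
    shift: float = 0.0
    fitted_on_model_residuals: bool = True

    def apply(self, y) -> np.ndarray:
        y = np.asarray(y, dtype=float) + self.shift
        if np.any(y <= 0):
            raise ValueError("Box-Cox requires positive data after shift")
        if self.lambda_ == 0:
            return np.log(y)
        return (y**self.lambda_ - 1.0) / self.lambda_


@dataclass
class ShapeStats:
    mean: float
    median: float
    skewness: float
    kurtosis: float  # excess kurtosis (normal -> 0)
    n: int


# ---------------------------------------------------------------------------
# transformation and homogeneity


def boxcox_fit(y, genotype=None, treatment=None, shift: float = 0.0,
               lambda_grid=None):
    """Profile-likelihood Box-Cox on the additive model.

    The transformation parameter maximizes the restricted profile
    log-likelihood of the additive (genotype + treatment) fixed-effects
    model over a deterministic grid (default [-2, 2] in steps of 0.01).
    Without covariates the model is intercept-only.  Returns
    ``(TransformSpec, transformed_y)``.
    """
    y = np.asarray(y, dtype=float)
    ys = y + shift
    if np.any(ys <= 0):
        raise ValueError("Box-Cox requires positive data (apply a shift)")
    if lambda_grid is None:
        lambda_grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 10)
    if np.ptp(ys) == 0:
        warnings.warn("constant response: Box-Cox likelihood is flat, "
                      "defaulting to lambda = 1")
        spec = TransformSpec(1.0, shift, genotype is not None)
        return spec, spec.apply(y)

    columns = [np.ones_like(ys)]
    for cov in (genotype, treatment):
        if cov is not None:
            codes, _ = pd.factorize(np.asarray(cov))
            dummies = np.eye(codes.max() + 1)[codes][:, 1:]
            columns.append(dummies)
    X = np.column_stack(columns)
    Q, _ = np.linalg.qr(X)
    log_y_sum = float(np.sum(np.log(ys)))
    n = ys.size

    best_ll, best_lam = -np.inf, 1.0
    for lam in lambda_grid:
        z = np.log(ys) if lam == 0 else (ys**lam - 1.0) / lam
        resid = z - Q @ (Q.T @ z)
        rss = float(resid @ resid)
        if rss <= 0:
            continue
        ll = -0.5 * n * np.log(rss / n) + (lam - 1.0) * log_y_sum
        if ll > best_ll:
            best_ll, best_lam = ll, float(lam)
    spec = TransformSpec(best_lam, shift, genotype is not None)
    return spec, spec.apply(y)


def bartlett_test(*groups) -> StatResult:
    """Bartlett's chi-squared test of variance homogeneity across groups."""
    if len(groups) == 1 and not np.isscalar(groups[0][0]):
        try:
            if not np.isscalar(groups[0][0][0]):
                groups = tuple(groups[0])
        except (TypeError, IndexError):
            pass
    if len(groups) < 2:
        raise ValueError("Bartlett's test needs at least two groups")
    for g in groups:
        if len(g) < 2:
            raise ValueError("each group needs at least two observations")
    variances = [np.var(g, ddof=1) for g in groups]
    if all(v == variances[0] for v in variances):
        n = sum(len(g) for g in groups)
        return StatResult(0.0, 1.0, n, "bartlett")
    statistic, p = stats.bartlett(*groups)
    return StatResult(float(statistic), float(p), sum(len(g) for g in groups),
                      "bartlett")


def block_adjust(values, blocks, plots=None) -> np.ndarray:
    """Additive block adjustment within each plot.

    Each observation is shifted by -(block mean - plot grand mean), so all
    block means within a plot coincide with the plot grand mean afterwards
    (the plot grand mean is preserved up to block-size weighting).
    """
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    plots = np.zeros(values.size) if plots is None else np.asarray(plots)
    out = values.copy()
    df = pd.DataFrame({"y": values, "b": blocks, "p": plots})
    for _, plot_df in df.groupby("p"):
        grand = plot_df["y"].mean()
        for _, block_df in plot_df.groupby("b"):
            if block_df.empty:
                raise ValueError("empty block")
            out[block_df.index] -= block_df["y"].mean() - grand
    return out


# ---------------------------------------------------------------------------
# ANOVA


def anova_two_way(genotype, treatment, y, ss_type: int = 1) -> pd.DataFrame:
    """Two-way ANOVA with interaction, sequential (Type I) SS by default.

    Terms enter in the order Genotype, Treatment, G × T; the returned
    table has rows Genotype, Treatment, G × T, Error, Total with columns
    df, sum_sq, mean_sq, F, p.
    """
    genotype = np.asarray(genotype)
    treatment = np.asarray(treatment)
    y = np.asarray(y, dtype=float)
    if len(set(genotype)) < 2 or len(set(treatment)) < 2:
        raise ValueError("both factors need at least two levels")
    data = pd.DataFrame({"g": genotype, "t": treatment, "y": y})
    model = smf.ols("y ~ C(g) + C(t) + C(g):C(t)", data=data).fit()
    table = anova_lm(model, typ=ss_type)
    rename = {"C(g)": "Genotype", "C(t)": "Treatment",
              "C(g):C(t)": "G x T", "Residual": "Error"}
    table = table.rename(index=rename)
    out = pd.DataFrame({
        "df": table["df"].astype(float),
        "sum_sq": table["sum_sq"].astype(float),
    }, index=table.index)
    out = out.reindex(["Genotype", "Treatment", "G x T", "Error"])
    out.loc["Total"] = [out["df"].sum(), out["sum_sq"].sum()]
    out["mean_sq"] = out["sum_sq"] / out["df"]
    out.loc["Total", "mean_sq"] = np.nan
    ms_error = out.loc["Error", "mean_sq"]
    f = out["mean_sq"] / ms_error
    f.loc[["Error", "Total"]] = np.nan
    out["F"] = f
    out["p"] = [
        stats.f.sf(fv, dfn, out.loc["Error", "df"]) if np.isfinite(fv) else np.nan
        for fv, dfn in zip(out["F"], out["df"])
    ]
    return out


# ---------------------------------------------------------------------------
# REML variance components


@dataclass
class VarianceComponents:
    """REML estimates for the mixed model with treatment fixed.

    sigma2_G, sigma2_GT and sigma2_eps are the genotype,
    genotype-by-treatment and residual variance components (°C²,
    clipped at zero); ``r_within`` and ``r_experiment`` are average
    replicate counts per genotype within a treatment and over the whole
    experiment; ``n_treatments`` is the number of treatments.
    """

    sigma2_G: float
    sigma2_GT: float
    sigma2_eps: float
    r_within: float
    r_experiment: float
    n_treatments: int
    se: dict = field(default_factory=dict)
    converged: bool = True
    loglik: float = float("nan")

    def __post_init__(self):
        if min(self.sigma2_G, self.sigma2_GT, self.sigma2_eps) < 0:
            raise ValueError("variance components must be non-negative")

    def h2_within(self) -> float:
        return h2_within(self.sigma2_G, self.sigma2_eps, self.r_within)

    def h2_combined(self) -> float:
        return h2_combined(self.sigma2_G, self.sigma2_GT, self.sigma2_eps,
                           self.n_treatments, self.r_experiment)


def _reml_blocks(genotype, treatment, y):
    """Group observations by genotype, sorted by treatment within genotype.

    Returns a dict mapping each distinct replicate structure (tuple of
    per-treatment counts) to (Y rows, treatment level counts, X design).
    """
    df = pd.DataFrame({"g": genotype, "t": treatment, "y": y})
    t_levels = sorted(df["t"].unique())
    df = df.sort_values(["g", "t"], kind="mergesort")
    structures = {}
    for _, block in df.groupby("g", sort=False):
        counts = tuple(int((block["t"] == lev).sum()) for lev in t_levels)
        structures.setdefault(counts, []).append(block["y"].to_numpy())
    out = {}
    for counts, ys in structures.items():
        Y = np.vstack(ys)
        # fixed-effect design: intercept + treatment dummies, per observation
        X = [np.ones(sum(counts))]
        offset = np.repeat(np.arange(len(counts)), counts)
        for j in range(1, len(counts)):
            X.append((offset == j).astype(float))
        out[counts] = (Y, np.array(counts), np.column_stack(X))
    return out, len(t_levels)


def _reml_neg2ll(theta, blocks, p_fixed, with_grad: bool = False):
    """-2 × restricted log-likelihood (and its gradient wrt the three
    variance components), exploiting block-diagonality over genotypes and
    sharing per-replicate-structure factorizations."""
    s2g, s2gt, s2e = theta
    if s2e <= 0:
        return (np.inf, np.full(3, np.nan)) if with_grad else np.inf
    logdet_sum = 0.0
    yVy = 0.0
    W = np.zeros((p_fixed, p_fixed))
    b = np.zeros(p_fixed)
    cache = {}
    for counts, (Y, cvec, X) in blocks.items():
        ni = int(cvec.sum())
        cell = np.repeat(np.arange(len(cvec)), cvec)
        V = np.full((ni, ni), s2g) + s2gt * (cell[:, None] == cell[None, :]) \
            + s2e * np.eye(ni)
        sign, logdet = np.linalg.slogdet(V)
        if sign <= 0:
            return (np.inf, np.full(3, np.nan)) if with_grad else np.inf
        Vinv = np.linalg.inv(V)
        m = Y.shape[0]
        logdet_sum += m * logdet
        yVy += float(np.einsum("ij,jk,ik->", Y, Vinv, Y))
        A = Vinv @ X
        W += m * (X.T @ A)
        b += A.T @ Y.sum(axis=0)
        cache[counts] = (Vinv, A, cell)
    sign, logdet_W = np.linalg.slogdet(W)
    if sign <= 0:
        return (np.inf, np.full(3, np.nan)) if with_grad else np.inf
    beta = np.linalg.solve(W, b)
    quad = yVy - float(b @ beta)
    neg2ll = logdet_sum + logdet_W + quad
    if not with_grad:
        return neg2ll

    # d(-2ll)/dσ²_k = tr(P V_k) - y'P V_k P y with P = V⁻¹ - V⁻¹X W⁻¹ X'V⁻¹
    Winv = np.linalg.inv(W)
    tr = np.zeros(3)
    ypvy = np.zeros(3)
    for counts, (Y, cvec, X) in blocks.items():
        Vinv, A, cell = cache[counts]
        m = Y.shape[0]
        C = (cell[:, None] == np.arange(len(cvec))[None, :]).astype(float)
        ones = np.ones(len(cell))
        a1 = A.T @ ones
        tr[0] += m * (float(ones @ Vinv @ ones) - float(a1 @ Winv @ a1))
        q2 = np.einsum("ic,ij,jc->c", C, Vinv, C)
        A2 = A.T @ C
        tr[1] += m * (float(q2.sum()) - float(np.einsum(
            "pc,pq,qc->", A2, Winv, A2)))
        tr[2] += m * (float(np.trace(Vinv)) - float(np.trace(Winv @ (A.T @ A))))
        E = Y - (X @ beta)[None, :]
        Pm = E @ Vinv.T
        ypvy[0] += float((Pm.sum(axis=1) ** 2).sum())
        ypvy[1] += float(((Pm @ C) ** 2).sum())
        ypvy[2] += float((Pm**2).sum())
    return neg2ll, tr - ypvy


def reml_components(genotype, treatment, y, tol: float = 1e-10,
                    max_iter: int = 10_000,
                    r_method: str = "arithmetic") -> VarianceComponents:
    """REML variance components for T_c with treatment fixed.

    Genotype and genotype-by-treatment effects are independent random
    draws; the restricted log-likelihood is maximized numerically
    (L-BFGS-B followed by a Nelder-Mead polish) over the non-negative
    orthant, exploiting the block-diagonal structure over genotypes.
    Estimates are clipped at zero.  Raises on non-convergence.
    """
    genotype = np.asarray(genotype)
    treatment = np.asarray(treatment)
    y = np.asarray(y, dtype=float)
    blocks, n_treat = _reml_blocks(genotype, treatment, y)
    p_fixed = n_treat

    var_y = float(np.var(y, ddof=1))
    start = np.array([var_y / 3, var_y / 3, var_y / 3])
    floor = var_y * 1e-12
    bounds = [(0.0, None), (0.0, None), (floor, None)]
    obj = lambda th: _reml_neg2ll(th, blocks, p_fixed)
    objg = lambda th: _reml_neg2ll(th, blocks, p_fixed, with_grad=True)
    res = optimize.minimize(objg, start, jac=True, method="L-BFGS-B",
                            bounds=bounds,
                            options={"maxiter": max_iter, "ftol": 1e-14,
                                     "gtol": 1e-10})
    theta = np.maximum(res.x, [0.0, 0.0, floor])
    # Newton polish on the analytic gradient (free coordinates only): the
    # curvature is estimated by differencing the gradient, giving machine
    # precision in the stationarity condition away from the boundary
    for _ in range(50):
        _, g = objg(theta)
        free = [i for i in range(3)
                if theta[i] > 0 or g[i] < 0]
        if not free or np.max(np.abs(g[free])) < tol * max(1.0, 1.0 / var_y):
            break
        h = np.maximum(np.abs(theta), var_y * 1e-6) * 1e-7
        H = np.zeros((len(free), len(free)))
        for a, i in enumerate(free):
            step = np.zeros(3)
            step[i] = h[i]
            _, gp = objg(theta + step)
            H[:, a] = (gp[free] - g[free]) / h[i]
        H = 0.5 * (H + H.T)
        try:
            delta = np.linalg.solve(H, -g[free])
        except np.linalg.LinAlgError:
            break
        new = theta.copy()
        for a, i in enumerate(free):
            new[i] = theta[i] + delta[a]
        new = np.maximum(new, [0.0, 0.0, floor])
        f_new = obj(new)
        if not np.isfinite(f_new):
            break
        theta = new
        if np.max(np.abs(delta)) < var_y * 1e-13:
            break
    best_fun = obj(theta)
    if not np.isfinite(best_fun):
        raise RuntimeError(f"REML did not converge; last iterate {theta}")
    best = optimize.OptimizeResult(x=theta, fun=best_fun)
    theta = np.maximum(theta, 0.0)

    # asymptotic SEs from the numerical Hessian of the -2 log-likelihood / 2
    se = {}
    try:
        h = np.maximum(np.abs(theta), var_y * 1e-3) * 1e-4
        H = np.zeros((3, 3))
        f0 = best.fun
        for i in range(3):
            for j in range(i, 3):
                ei = np.eye(3)[i] * h[i]
                ej = np.eye(3)[j] * h[j]
                fpp = obj(theta + ei + ej)
                fpm = obj(theta + ei - ej) if theta[j] - h[j] >= 0 else np.nan
                fmp = obj(theta - ei + ej) if theta[i] - h[i] >= 0 else np.nan
                fmm = (obj(theta - ei - ej)
                       if min(theta[i] - h[i], theta[j] - h[j]) >= 0 else np.nan)
                if np.all(np.isfinite([fpp, fpm, fmp, fmm])):
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
                else:  # forward difference at the boundary
                    fi = obj(theta + ei)
                    fj = obj(theta + ej)
                    H[i, j] = H[j, i] = (fpp - fi - fj + f0) / (h[i] * h[j])
        cov = np.linalg.inv(H / 2.0)
        names = ["sigma2_G", "sigma2_GT", "sigma2_eps"]
        for i, name in enumerate(names):
            se[name] = float(np.sqrt(cov[i, i])) if cov[i, i] > 0 else float("nan")
    except np.linalg.LinAlgError:
        pass

    r_within, r_experiment = average_replicates(genotype, treatment,
                                                method=r_method)
    return VarianceComponents(
        sigma2_G=float(theta[0]), sigma2_GT=float(theta[1]),
        sigma2_eps=float(theta[2]), r_within=r_within,
        r_experiment=r_experiment, n_treatments=n_treat, se=se,
        converged=True, loglik=-0.5 * float(best.fun))


def average_replicates(genotype, treatment, method: str = "arithmetic"):
    """Average replicates per genotype (within treatment, and overall)."""
    df = pd.DataFrame({"g": genotype, "t": treatment})
    per_cell = df.groupby(["g", "t"]).size().to_numpy(dtype=float)
    per_geno = df.groupby("g").size().to_numpy(dtype=float)
    if method == "arithmetic":
        return float(per_cell.mean()), float(per_geno.mean())
    if method == "harmonic":
        return (float(stats.hmean(per_cell)), float(stats.hmean(per_geno)))
    raise ValueError("method must be 'arithmetic' or 'harmonic'")


# ---------------------------------------------------------------------------
# heritability


def h2_within(sigma2_G: float, sigma2_eps: float, r: float) -> float:
    """Broad-sense heritability within a treatment:
    H² = σ²_G / [σ²_G + σ²_ε / r]."""
    if sigma2_G < 0 or sigma2_eps < 0:
        raise ValueError("variance components must be non-negative")
    if r <= 0:
        raise ValueError("r must be positive")
    denom = sigma2_G + sigma2_eps / r
    if denom == 0:
        raise ValueError("heritability undefined: all components zero")
    return sigma2_G / denom


def h2_combined(sigma2_G: float, sigma2_GT: float, sigma2_eps: float,
                n: float, r: float) -> float:
    """Broad-sense heritability over combined treatments:
    H² = σ²_G / [σ²_G + σ²_G×T / n + σ²_ε / (n r)]."""
    if min(sigma2_G, sigma2_GT, sigma2_eps) < 0:
        raise ValueError("variance components must be non-negative")
    if n <= 0 or r <= 0:
        raise ValueError("n and r must be positive")
    denom = sigma2_G + sigma2_GT / n + sigma2_eps / (n * r)
    if denom == 0:
        raise ValueError("heritability undefined: all components zero")
    return sigma2_G / denom


# ---------------------------------------------------------------------------
# descriptive and agreement statistics


def shape_stats(x) -> ShapeStats:
    """Mean, median, sample skewness and excess kurtosis.

    Moment estimators without small-sample bias correction; the normal
    distribution has skewness 0 and (excess) kurtosis 0.  Requires
    non-constant data and n >= 4.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("shape statistics require at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("shape statistics undefined for constant data")
    return ShapeStats(
        mean=float(np.mean(x)), median=float(np.median(x)),
        skewness=float(stats.skew(x, bias=True)),
        kurtosis=float(stats.kurtosis(x, fisher=True, bias=True)),
        n=int(x.size))


def spearman_rho(x, y) -> StatResult:
    """Spearman rank correlation with average ranks on ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    rho, p = stats.spearmanr(x, y)
    return StatResult(float(rho), float(p), int(x.size), "spearman")


def paired_t(x, y, paired: bool = True) -> StatResult:
    """Student's t-test between two T_c datasets (paired on genotype by
    default; unpaired via ``paired=False``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if paired and x.size != y.size:
        raise ValueError("length mismatch for paired test")
    if paired:
        diff = x - y
        if np.allclose(diff, 0):
            return StatResult(0.0, 1.0, int(x.size), "paired-t")
        t, p = stats.ttest_rel(x, y)
    else:
        t, p = stats.ttest_ind(x, y)
    return StatResult(float(t), float(p), int(x.size), "t")


def gs_regression(gs, tc_minus_ta) -> RegressionFit:
    """OLS of stomatal conductance on (T_c − T_a).

    Reports slope (mmol m⁻² s⁻¹ per °C), intercept, R², the two-sided
    p-value and the one-sided p-value for the directional hypothesis
    matching the fitted slope's sign.
    """
    gs = np.asarray(gs, dtype=float)
    x = np.asarray(tc_minus_ta, dtype=float)
    if gs.size != x.size:
        raise ValueError("length mismatch")
    if gs.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in predictor")
    fit = stats.linregress(x, gs)
    return RegressionFit(
        slope=float(fit.slope), intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2), p_value=float(fit.pvalue),
        p_value_one_sided=float(fit.pvalue / 2.0), n=int(gs.size))
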