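"""Inferential layer: correlations, threshold fits, ANOVA, PCA, regressions.

Five analyses mirror how laboratory flammability studies are usually
reported:

* Pearson product-moment correlation with a t test on n-2 df (e.g.
  phylogenetic distance vs. mixture effect size; fuelbed traits vs.
  flammability parameters);
* a descending logistic threshold curve of proportion burned against
  packing ratio, fit by quasi-binomial deviance minimisation on species
  means, reporting the midpoint and the 0.9/0.1 transition interval;
* a Gaussian (normal-PDF-shaped) response of maximum temperature against
  packing ratio;
* a two-way ANOVA (type-II sums of squares, main effects only) of absolute
  effect sizes against weighting method and focal-clade membership;
* PCA of the correlation matrix, and per-litter-type OLS regressions of
  packing ratio on log10 particle size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

LOG9 = float(np.log(9.0))


# ---------------------------------------------------------------------------
# Pearson correlation

@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int  # n - 2
    p: float  # two-sided

    def stars(self) -> str:
        if self.p < 0.001:
            return "***"
        if self.p < 0.01:
            return "**"
        if self.p < 0.05:
            return "*"
        return ""


def pearson_test(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Pearson r with a two-sided t test on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), df=len(x) - 2, p=float(res.pvalue))


# ---------------------------------------------------------------------------
# Logistic threshold curve

@dataclass
class LogisticFit:
    """Descending logistic p(x) = 1 / (1 + exp(slope * (x - midpoint))).

    ``midpoint`` is the packing ratio (%) at which the expected proportion
    burned is 0.5; ``transition_interval`` brackets the sharp part of the
    curve, (x at p=0.9, x at p=0.1). ``p_slope`` is the likelihood-ratio
    p-value of the slope against an intercept-only model. ``separated``
    flags (quasi-)complete separation, where the slope is only bounded
    below by the data.
    """

    slope: float  # per packing-% point, > 0 for a descending curve
    midpoint: float  # packing-%
    transition_interval: tuple  # (x at p=0.9, x at p=0.1)
    deviance: float
    p_slope: float
    separated: bool = False
    midpoint_in_hull: bool = True

    def predict(self, x):
        return expit(-self.slope * (np.asarray(x, dtype=float) - self.midpoint))


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / p), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - p)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


_MAX_SLOPE = 200.0  # per packing-% point; the separation bound


def fit_logistic_threshold(packing_ratio_pct: Sequence[float],
                           prop_burned: Sequence[float]) -> LogisticFit:
    """Fit the flammability threshold curve to proportion-burned data.

    ``packing_ratio_pct`` in %, ``prop_burned`` fractions in [0, 1]
    (typically species means over replicate burns). Proportions are treated
    as quasi-binomial and fit by deviance minimisation over Nelder-Mead
    restarts on a (slope, midpoint) grid. Complete separation is reported
    via the ``separated`` flag rather than as a failure.
    """
    x = np.asarray(packing_ratio_pct, dtype=float)
    y = np.asarray(prop_burned, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 6:
        raise ValueError("need at least 6 observations")
    if ((y < 0) | (y > 1)).any():
        raise ValueError("proportions must lie in [0, 1]")

    def objective(params):
        b, x50 = params
        if not (0 < b <= _MAX_SLOPE):
            return np.inf
        return _binomial_deviance(y, expit(-b * (x - x50)))

    starts = [
        (b0, x0)
        for b0 in (0.1, 0.3, 1.0, 3.0, 10.0)
        for x0 in np.quantile(x, (0.25, 0.5, 0.75))
    ]
    best = None
    for s in starts:
        res = optimize.minimize(objective, s, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    b, x50 = best.x
    dev = float(best.fun)

    # intercept-only null for the likelihood-ratio slope test
    ybar = float(np.clip(y.mean(), 1e-12, 1 - 1e-12))
    dev0 = _binomial_deviance(y, np.full_like(y, ybar))
    p_slope = float(stats.chi2.sf(max(dev0 - dev, 0.0), df=1))

    binaryish = np.all((y <= 0.05) | (y >= 0.95))
    one_sided = np.all(y >= 0.5) or np.all(y <= 0.5)
    separated = bool(one_sided or (binaryish and dev < 1e-6) or b > 0.5 * _MAX_SLOPE)

    interval = (x50 - LOG9 / b, x50 + LOG9 / b)
    in_hull = bool(x.min() <= x50 <= x.max())
    if not in_hull:
        warnings.warn(f"logistic midpoint {x50:.2f} lies outside the data hull", stacklevel=2)
    return LogisticFit(slope=float(b), midpoint=float(x50), transition_interval=interval,
                       deviance=dev, p_slope=p_slope, separated=separated,
                       midpoint_in_hull=in_hull)


# ---------------------------------------------------------------------------
# Gaussian response

@dataclass
class GaussianFit:
    """T(x) = amplitude * exp(-(x - mean)^2 / (2 sd^2)) + baseline."""

    amplitude: float  # °C
    mean: float  # packing-%
    sd: float  # packing-%
    baseline: float  # °C
    rss: float

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.amplitude * np.exp(-((x - self.mean) ** 2) / (2 * self.sd ** 2)) + self.baseline


def fit_gaussian_response(packing_ratio_pct: Sequence[float],
                          max_temp: Sequence[float]) -> GaussianFit:
    """Least-squares Gaussian response of maximum temperature to packing ratio.

    Multi-start over data-quantile initialisations of the mean and spread.
    Raises on degenerate (constant) responses and on non-convergence of all
    starts.
    """
    x = np.asarray(packing_ratio_pct, dtype=float)
    y = np.asarray(max_temp, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length 1-D vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(y) == 0:
        raise ValueError("constant response: Gaussian spread is unidentifiable")

    def model(x, a, mu, sigma, c):
        return a * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)) + c

    span = np.ptp(x) or 1.0
    a0, c0 = float(np.ptp(y)), float(y.min())
    best = None
    errors = []
    for mu0 in np.quantile(x, (0.25, 0.5, 0.75)):
        for s0 in (span / 8, span / 4, span / 2):
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, _ = optimize.curve_fit(model, x, y, p0=(a0, mu0, s0, c0), maxfev=20000)
            except (RuntimeError, optimize.OptimizeWarning) as exc:
                errors.append(str(exc))
                continue
            rss = float(np.sum((y - model(x, *popt)) ** 2))
            if best is None or rss < best[1]:
                best = (popt, rss)
    if best is None:
        raise RuntimeError(f"Gaussian fit failed from all starts: {errors[-1] if errors else 'no starts'}")
    (a, mu, sigma, c), rss = best
    return GaussianFit(amplitude=float(a), mean=float(mu), sd=float(abs(sigma)),
                       baseline=float(c), rss=rss)


# ---------------------------------------------------------------------------
# Two-way ANOVA (main effects only, type-II SS)

@dataclass
class AnovaFactor:
    name: str
    ss: float
    df: int
    F: float
    p: float


@dataclass
class AnovaTable:
    factors: list  # of AnovaFactor
    residual_ss: float
    residual_df: int

    def __getitem__(self, name: str) -> AnovaFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)


def two_way_anova(abs_effect_size: Sequence[float],
                  weighting: Sequence[str],
                  clade_group: Sequence[str],
                  interaction: bool = False) -> AnovaTable:
    """Two-way ANOVA of |effect size| on weighting method and clade group.

    Main effects only by default (type-II sums of squares); pass
    ``interaction=True`` to add the interaction term. A zero residual sum
    of squares yields infinite F for factors with nonzero SS.
    """
    df = pd.DataFrame({
        "aes": np.asarray(abs_effect_size, dtype=float),
        "weighting": list(weighting),
        "clade_group": list(clade_group),
    })
    for col in ("weighting", "clade_group"):
        levels = df[col].unique()
        if len(levels) != 2:
            raise ValueError(f"factor {col} must have exactly 2 levels, has {len(levels)}")
    cells = df.groupby(["weighting", "clade_group"]).size()
    if len(cells) < 4:
        raise ValueError("empty cell in the 2x2 design")

    formula = "aes ~ C(weighting) + C(clade_group)"
    if interaction:
        formula += " + C(weighting):C(clade_group)"
    model = smf.ols(formula, data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-residual division handled below
        table = anova_lm(model, typ=2)

    resid_ss = float(table.loc["Residual", "sum_sq"])
    resid_df = int(table.loc["Residual", "df"])
    factors = []
    name_map = {"C(weighting)": "weighting", "C(clade_group)": "clade_group",
                "C(weighting):C(clade_group)": "interaction"}
    for row_name, name in name_map.items():
        if row_name not in table.index:
            continue
        ss = float(table.loc[row_name, "sum_sq"])
        fdf = int(table.loc[row_name, "df"])
        if resid_ss <= 1e-12 * max(ss, 1.0):
            F = np.inf if ss > 1e-12 else 0.0
            p = 0.0 if ss > 1e-12 else 1.0
        else:
            F = float(table.loc[row_name, "F"])
            p = float(table.loc[row_name, "PR(>F)"])
        factors.append(AnovaFactor(name=name, ss=ss, df=fdf, F=F, p=p))
    return AnovaTable(factors=factors, residual_ss=resid_ss, residual_df=resid_df)


# ---------------------------------------------------------------------------
# PCA on the correlation matrix

@dataclass
class PcaResult:
    loadings: pd.DataFrame  # variables x axes (PC1, PC2, ...)
    variance_explained: np.ndarray  # % per axis, sums to 100
    eigenvalues: np.ndarray


def pca_correlation(data: pd.DataFrame, log_columns: Sequence[str] = ()) -> PcaResult:
    """PCA of the correlation matrix of ``data`` (complete cases).

    Columns named in ``log_columns`` (e.g. particle size in cm³) are
    log10-transformed first; all columns are then z-standardised and the
    correlation matrix eigendecomposed. Per axis, the sign is fixed so the
    variable with the largest |loading| has a positive loading.
    """
    df = data.dropna().astype(float).copy()
    if df.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    if df.shape[0] <= df.shape[1]:
        raise ValueError("need more complete rows than columns")
    for col in log_columns:
        if (df[col] <= 0).any():
            raise ValueError(f"column {col!r} must be positive for log10 transform")
        df[col] = np.log10(df[col])
    if (df.std(ddof=1) == 0).any():
        bad = df.columns[df.std(ddof=1) == 0].tolist()
        raise ValueError(f"constant column(s): {bad}")
    z = (df - df.mean()) / df.std(ddof=1)
    corr = np.corrcoef(z.values, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    eigval = np.clip(eigval, 0, None)
    for k in range(eigvec.shape[1]):
        i_max = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[i_max, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    axes = [f"PC{i + 1}" for i in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=df.columns, columns=axes)
    return PcaResult(loadings=loadings,
                     variance_explained=100.0 * eigval / eigval.sum(),
                     eigenvalues=eigval)


# ---------------------------------------------------------------------------
# Per-litter-type OLS

@dataclass
class GroupFit:
    group: str
    n: int
    slope: float
    intercept: float
    r: float
    p: float
    significant: bool  # p < .01


def linear_fit_by_group(x: Sequence[float], y: Sequence[float],
                        group: Sequence[str],
                        alpha: float = 0.01) -> dict:
    """OLS of y on x within each group; groups with <3 points are skipped.

    Typical use: packing ratio (%) against log10 particle size (cm³) per
    litter type. Returns {group: GroupFit}.
    """
    df = pd.DataFrame({"x": np.asarray(x, dtype=float),
                       "y": np.asarray(y, dtype=float),
                       "g": list(group)}).dropna()
    fits = {}
    for g, sub in df.groupby("g"):
        if len(sub) < 3:
            warnings.warn(f"group {g!r}: only {len(sub)} points, skipped", stacklevel=2)
            continue
        res = stats.linregress(sub["x"], sub["y"])
        fits[g] = GroupFit(group=str(g), n=len(sub), slope=float(res.slope),
                           intercept=float(res.intercept), r=float(res.rvalue),
                           p=float(res.pvalue), significant=bool(res.pvalue < alpha))
    return fits
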