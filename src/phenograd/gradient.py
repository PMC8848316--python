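"""Gradient effect-size regression: the study's core statistic.

For each phenotypic descriptor, species and imaging day, the descriptor is
regressed on the log-transformed red:blue ratio measured at each pot
position (ordinary least squares). The fitted line predicts the descriptor
at the minimal and maximal observed ratios; the difference between the two
predictions, expressed as a percentage of the prediction at the minimal
ratio, is the *effect size* of the gradient. Pearson R, R², and the
two-sided p-value of the slope accompany each fit, and the fit is repeated
at every imaging day to give the effect-size time course.

The module follows the model/results idiom: :class:`GradientRegression`
holds the data, its :meth:`~GradientRegression.fit` returns a
:class:`GradientFit` with estimates, covariance, ``effect_size`` and
``summary``. All internal logs are natural; the effect size and p-value are
invariant to the log base.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GradientRegression",
    "GradientFit",
    "EffectSize",
    "GradientEffect",
    "classify_significance",
    "effect_time_course",
    "fit_descriptor_gradient",
]

#: strict thresholds, most significant first
DEFAULT_THRESHOLDS: tuple[tuple[float, str], ...] = (
    (0.01, "p<0.01"), (0.05, "p<0.05"))


def classify_significance(
    p_value: float,
    thresholds: tuple[tuple[float, str], ...] = DEFAULT_THRESHOLDS,
) -> str:
    """Ordered significance category for a p-value (strict inequalities)."""
    if not 0.0 <= p_value <= 1.0:
        if math.isnan(p_value):
            return "NS"
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    for cut, label in sorted(thresholds):
        if p_value < cut:
            return label
    return "NS"


@dataclass(frozen=True)
class EffectSize:
    """Signed percentage difference across the gradient, with 95% CI."""

    percent: float
    ci_low: float
    ci_high: float
    y_at_min: float
    y_at_max: float
    min_ratio: float
    max_ratio: float
    baseline: str = "min"

    @property
    def defined(self) -> bool:
        return not math.isnan(self.percent)


@dataclass(frozen=True)
class GradientEffect:
    """One row of the effects table: species x descriptor x day."""

    species: str
    descriptor: str
    day: int
    n: int
    slope: float
    intercept: float
    pearson_r: float
    r_squared: float
    p_value: float
    y_at_min: float
    y_at_max: float
    effect_size_percent: float
    significance: str
    post_treatment: bool = False


class GradientRegression:
    """OLS of one descriptor on ln(red:blue ratio) over pots.

    Parameters
    ----------
    values : array-like
        Descriptor values, one per pot.
    ratios : array-like
        Red:blue ratio measured at each pot (must be > 0).

    Non-finite pairs are dropped. At least 3 finite pairs and at least two
    distinct ratios are required.
    """

    def __init__(self, values, ratios, *, descriptor: str = "",
                 species: str = "", day: int = 0):
        values = np.asarray(values, dtype=float)
        ratios = np.asarray(ratios, dtype=float)
        if values.shape != ratios.shape:
            raise ValueError("values and ratios differ in length")
        if (ratios[np.isfinite(ratios)] <= 0).any():
            raise ValueError("ratios must be positive")
        keep = np.isfinite(values) & np.isfinite(ratios)
        self.values = values[keep]
        self.ratios = ratios[keep]
        self.log_ratios = np.log(self.ratios)
        self.descriptor = descriptor
        self.species = species
        self.day = day
        if len(self.values) < 3:
            raise ValueError(
                f"need >= 3 finite (value, ratio) pairs, got {len(self.values)}")
        if np.ptp(self.log_ratios) == 0:
            raise ValueError("all ratios identical: gradient regression undefined")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, descriptor: str,
                       ratio_col: str = "ratio", **meta) -> "GradientRegression":
        return cls(df[descriptor].to_numpy(), df[ratio_col].to_numpy(),
                   descriptor=descriptor, **meta)

    def fit(self) -> "GradientFit":
        x, y = self.log_ratios, self.values
        if np.ptp(y) == 0:
            # constant response: flat line, no evidence of an effect
            return GradientFit(self, slope=0.0, intercept=float(y[0]),
                               pearson_r=0.0, p_value=1.0,
                               slope_se=0.0,
                               cov_params=np.zeros((2, 2)))
        X = sm.add_constant(x)
        res = sm.OLS(y, X).fit()
        slope = float(res.params[1])
        r = float(np.corrcoef(x, y)[0, 1])
        return GradientFit(
            self,
            slope=slope,
            intercept=float(res.params[0]),
            pearson_r=r,
            p_value=float(res.pvalues[1]),
            slope_se=float(res.bse[1]),
            cov_params=np.asarray(res.cov_params()),
        )


class GradientFit:
    """Fitted gradient regression: estimates, uncertainty, effect size."""

    def __init__(self, model: GradientRegression, *, slope: float,
                 intercept: float, pearson_r: float, p_value: float,
                 slope_se: float, cov_params: np.ndarray):
        self.model = model
        self.slope = slope
        self.intercept = intercept
        self.pearson_r = pearson_r
        self.r_squared = pearson_r ** 2
        self.p_value = p_value
        self.slope_se = slope_se
        self.cov_params = cov_params
        self.n = len(model.values)
        self.df_resid = self.n - 2

    def predict(self, ratio) -> np.ndarray:
        """Predicted descriptor value at the given red:blue ratio(s)."""
        lr = np.log(np.asarray(ratio, dtype=float))
        return self.intercept + self.slope * lr

    @property
    def significance(self) -> str:
        return classify_significance(self.p_value)

    def effect_size(
        self,
        min_ratio: float | None = None,
        max_ratio: float | None = None,
        baseline: str = "min",
        alpha: float = 0.05,
    ) -> EffectSize:
        """Percentage difference of predictions across the gradient.

        ``baseline`` selects the denominator: the prediction at the minimal
        ratio (default), maximal ratio, or the midpoint of the two
        predictions. The CI comes from the delta method on (intercept,
        slope) with a t(n−2) quantile. A non-positive baseline prediction
        makes the percentage undefined (NaN) — percent change from a
        non-positive level has no meaning for positive-valued descriptors.
        """
        rmin = float(min_ratio) if min_ratio is not None else float(self.model.ratios.min())
        rmax = float(max_ratio) if max_ratio is not None else float(self.model.ratios.max())
        if rmin >= rmax:
            raise ValueError("min_ratio must be < max_ratio")
        x0, x1 = math.log(rmin), math.log(rmax)
        y0 = self.intercept + self.slope * x0
        y1 = self.intercept + self.slope * x1
        if baseline == "min":
            ref = y0
        elif baseline == "max":
            ref = y1
        elif baseline == "mid":
            ref = 0.5 * (y0 + y1)
        else:
            raise ValueError(f"unknown baseline {baseline!r}")
        if ref <= 0:
            return EffectSize(math.nan, math.nan, math.nan, y0, y1,
                              rmin, rmax, baseline)
        percent = 100.0 * (y1 - y0) / ref
        # delta method: effect = 100 d b / (a + b x*), d = x1 - x0
        d = x1 - x0
        if baseline == "min":
            xs = x0
        elif baseline == "max":
            xs = x1
        else:
            xs = 0.5 * (x0 + x1)
        g = np.array([
            -100.0 * self.slope * d / ref ** 2,
            100.0 * d * (ref - self.slope * xs) / ref ** 2,
        ])
        var = float(g @ self.cov_params @ g)
        if var > 0 and self.df_resid > 0:
            half = stats.t.ppf(1 - alpha / 2, self.df_resid) * math.sqrt(var)
        else:
            half = 0.0
        return EffectSize(percent, percent - half, percent + half,
                          y0, y1, rmin, rmax, baseline)

    def to_effect(self, *, min_ratio=None, max_ratio=None, baseline="min",
                  post_treatment: bool = False) -> GradientEffect:
        es = self.effect_size(min_ratio, max_ratio, baseline)
        return GradientEffect(
            species=self.model.species, descriptor=self.model.descriptor,
            day=self.model.day, n=self.n, slope=self.slope,
            intercept=self.intercept, pearson_r=self.pearson_r,
            r_squared=self.r_squared, p_value=self.p_value,
            y_at_min=es.y_at_min, y_at_max=es.y_at_max,
            effect_size_percent=es.percent, significance=self.significance,
            post_treatment=post_treatment,
        )

    def summary(self) -> str:
        es = self.effect_size()
        lines = [
            "Gradient effect-size regression (OLS on ln red:blue ratio)",
            "-" * 60,
            f"descriptor: {self.model.descriptor or '<unnamed>'}"
            + (f"   species: {self.model.species}" if self.model.species else "")
            + f"   day: {self.model.day}",
            f"n pots: {self.n}",
            f"slope: {self.slope:.5g} per ln unit (SE {self.slope_se:.3g})",
            f"intercept: {self.intercept:.5g}",
            f"Pearson R: {self.pearson_r:.4f}   R^2: {self.r_squared:.4f}",
            f"p-value (slope, two-sided): {self.p_value:.4g}"
            f"   [{self.significance}]",
            f"prediction at ratio {es.min_ratio:.3g}: {es.y_at_min:.5g}",
            f"prediction at ratio {es.max_ratio:.3g}: {es.y_at_max:.5g}",
            f"effect size: {es.percent:.2f}% "
            f"(95% CI {es.ci_low:.2f} .. {es.ci_high:.2f})",
        ]
        return "\n".join(lines)


def fit_descriptor_gradient(values, ratios, **meta) -> GradientFit:
    """One-call OLS of descriptor values on ln(red:blue ratio)."""
    return GradientRegression(values, ratios, **meta).fit()


def effect_time_course(
    table: pd.DataFrame,
    descriptors: list[str],
    *,
    ratio_col: str = "ratio",
    species_col: str = "species",
    day_col: str = "day",
    baseline: str = "min",
    treatment_end: float | None = None,
    min_n: int = 3,
    fdr: bool = False,
    species_ratio_range: bool = True,
) -> pd.DataFrame:
    """Effects table: one gradient fit per species × descriptor × day.

    Ratio extremes default to the per-species observed range (species occupy
    different rows of the gradient room). Days after ``treatment_end`` are
    flagged ``post_treatment``. Cells with fewer than ``min_n`` finite pairs
    are omitted. ``fdr=True`` adds Benjamini–Hochberg adjusted p-values and
    categories (no correction by default).
    """
    rows = []
    for (species, day), grp in table.groupby([species_col, day_col]):
        ratios = grp[ratio_col].to_numpy(dtype=float)
        if species_ratio_range:
            rmin, rmax = float(np.nanmin(ratios)), float(np.nanmax(ratios))
        else:
            rmin = float(np.nanmin(table[ratio_col]))
            rmax = float(np.nanmax(table[ratio_col]))
        for name in descriptors:
            vals = grp[name].to_numpy(dtype=float)
            ok = np.isfinite(vals) & np.isfinite(ratios)
            if ok.sum() < min_n or np.ptp(np.log(ratios[ok])) == 0:
                continue
            fit = GradientRegression(
                vals, ratios, descriptor=name, species=str(species),
                day=int(day),
            ).fit()
            post = treatment_end is not None and day > treatment_end
            rows.append(fit.to_effect(
                min_ratio=rmin, max_ratio=rmax, baseline=baseline,
                post_treatment=post,
            ))
    out = pd.DataFrame([r.__dict__ for r in rows])
    if fdr and len(out):
        from statsmodels.stats.multitest import multipletests

        ok = np.isfinite(out["p_value"].to_numpy())
        adj = np.full(len(out), np.nan)
        if ok.any():
            adj[ok] = multipletests(out.loc[ok, "p_value"], method="fdr_bh")[1]
        out["p_adjusted"] = adj
        out["significance_adjusted"] = [
            classify_significance(p) if np.isfinite(p) else "NS" for p in adj
        ]
    return out
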