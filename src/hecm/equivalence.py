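"""External-standard quantification and hepatotoxic-equivalence testing.

Marker contents are quantified against ordinary-least-squares calibration
curves (LOD = 3.3 sigma/S, LOQ = 10 sigma/S from the residual standard
deviation sigma and slope S).  Hepatotoxic equivalence between a candidate
marker mixture (B) and the whole extract (H) follows the two-one-sided-test
construction on log-transformed enzyme activities: the 90% confidence
interval

    exp( (YB - YH) -/+ t(0.95, n1+n2-2) * sigma_w * sqrt(1/2 (1/n1 + 1/n2)) )

must fall strictly inside (0.70, 1.43).  Note the 1/2 inside the square
root: the source construction halves the variance relative to the textbook
two-sample standard error; ``textbook_se=True`` computes the standard form
for comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CalibrationCurve",
    "Quantification",
    "ToxicityGroup",
    "EquivalenceResult",
    "fit_calibration",
    "quantify",
    "hecm_dose",
    "equivalence_ci",
    "equivalence_decision",
    "pooled_log_sigma",
]

DEFAULT_LIMITS = (0.70, 1.43)


@dataclass
class CalibrationCurve:
    """OLS calibration Y = slope * X + intercept over a concentration range."""

    slope: float
    intercept: float
    range: tuple[float, float]  # (low, high) ug/mL
    r2: float
    lod: float  # ug/mL
    loq: float  # ug/mL

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope must be nonzero")
        if self.range[0] >= self.range[1]:
            raise ValueError("range low must be < high")

    def predict(self, conc: float) -> float:
        return self.slope * conc + self.intercept


def fit_calibration(
    concs: Sequence[float], responses: Sequence[float]
) -> CalibrationCurve:
    """Least-squares line through (concentration, response) standards."""
    x = np.asarray(concs, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3 or np.unique(x).size < 3:
        raise ValueError("need at least 3 distinct concentrations")
    res = stats.linregress(x, y)
    resid = y - (res.slope * x + res.intercept)
    sigma = math.sqrt(float((resid**2).sum()) / (x.size - 2))
    return CalibrationCurve(
        slope=float(res.slope),
        intercept=float(res.intercept),
        range=(float(x.min()), float(x.max())),
        r2=float(res.rvalue**2),
        lod=3.3 * sigma / abs(res.slope),
        loq=10.0 * sigma / abs(res.slope),
    )


@dataclass
class Quantification:
    conc: float  # ug/mL
    below_lod: bool
    below_loq: bool
    outside_range: bool


def quantify(response: float, c: CalibrationCurve) -> Quantification:
    """Invert the calibration line and flag out-of-range results."""
    conc = (response - c.intercept) / c.slope
    return Quantification(
        conc=conc,
        below_lod=conc < c.lod,
        below_loq=conc < c.loq,
        outside_range=not (c.range[0] <= conc <= c.range[1]),
    )


def hecm_dose(content_fraction: float, extract_dose: float) -> float:
    """Marker dose equivalent to its content in a given extract dose.

    ``content_fraction`` is dimensionless (e.g. 0.066 for a 6.6% w/w
    content) and ``extract_dose`` is in mg/kg; the product is the marker
    dose in mg/kg.
    """
    if not 0 <= content_fraction <= 1:
        raise ValueError("content_fraction must be in [0, 1]")
    if extract_dose <= 0:
        raise ValueError("extract_dose must be positive")
    return content_fraction * extract_dose


@dataclass
class ToxicityGroup:
    """Per-animal enzyme activities (U/L) for one treatment group."""

    label: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-D array")
        if np.any(self.values <= 0):
            raise ValueError("enzyme activities must be > 0 (log transform)")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class EquivalenceResult:
    ratio_ci: tuple[float, float]
    alpha: float
    sigma_w: float
    df: int
    t_quantile: float
    limits: tuple[float, float]
    equivalent: bool
    ratio: float  # geometric-mean ratio candidate/original


def pooled_log_sigma(groups: Sequence[ToxicityGroup]) -> tuple[float, int]:
    """Within-group SD of log values pooled across groups (ANOVA root-MSE)."""
    ss = 0.0
    df = 0
    for g in groups:
        logs = np.log(g.values)
        ss += float(((logs - logs.mean()) ** 2).sum())
        df += g.n - 1
    if df < 1:
        raise ValueError("no residual degrees of freedom for sigma_w")
    return math.sqrt(ss / df), df


def equivalence_ci(
    candidate: ToxicityGroup,
    original: ToxicityGroup,
    alpha: float = 0.10,
    limits: tuple[float, float] = DEFAULT_LIMITS,
    extra_groups: "Sequence[ToxicityGroup] | None" = None,
    textbook_se: bool = False,
) -> EquivalenceResult:
    """90% (1 - alpha) CI of the candidate/original toxicity ratio.

    Means are taken on the natural-log scale; sigma_w is the pooled
    within-group SD of log values (one-way ANOVA root mean square when
    ``extra_groups`` supplies additional experiment groups).  The default
    standard error carries the verbatim 1/2 inside the square root;
    ``textbook_se=True`` drops it, giving the conventional two-sample form.
    """
    if candidate.n < 2 or original.n < 2:
        raise ValueError("both groups need n >= 2")
    yb = float(np.log(candidate.values).mean())
    yh = float(np.log(original.values).mean())
    pool = [candidate, original] + (list(extra_groups) if extra_groups else [])
    sigma_w, _ = pooled_log_sigma(pool)
    df = candidate.n + original.n - 2
    if df < 1:
        raise ValueError("need n1 + n2 - 2 >= 1")
    tq = float(stats.t.ppf(1.0 - alpha / 2.0, df))
    half_factor = 0.5 if not textbook_se else 1.0
    se = sigma_w * math.sqrt(half_factor * (1.0 / candidate.n + 1.0 / original.n))
    delta = yb - yh
    ci = (math.exp(delta - tq * se), math.exp(delta + tq * se))
    return EquivalenceResult(
        ratio_ci=ci,
        alpha=alpha,
        sigma_w=sigma_w,
        df=df,
        t_quantile=tq,
        limits=limits,
        equivalent=limits[0] < ci[0] and ci[1] < limits[1],
        ratio=math.exp(delta),
    )


def equivalence_decision(r: EquivalenceResult) -> tuple[bool, str]:
    """Strict-containment decision with a percentage-style report string."""
    lo, hi = r.ratio_ci
    ok = r.limits[0] < lo and hi < r.limits[1]
    report = (
        f"90% CI {lo * 100:.1f}-{hi * 100:.1f}% "
        f"{'within' if ok else 'outside'} "
        f"({r.limits[0] * 100:.0f}%, {r.limits[1] * 100:.0f}%): "
        f"{'equivalent' if ok else 'not equivalent'}"
    )
    return ok, report
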