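"""Decay-model fitting and age-dependent half-life arithmetic.

The degradation of a biomolecule pool in accumulating sediment is described
by a power function of sediment age,

    Y(t) = a * t**b,      b <= 0,

where Y is content (or gene copies) per g dry sediment and t is sediment
age in years.  The slope b of the log-log regression is the apparent
first-order decay rate; k = -b is called the decay constant.  Because
apparent reactivity declines with age, the halving time of the pool is not
constant: under Y = a*t**(-k) the time D(t) for the pool at age t to fall
to half its level satisfies (t + D)/t = 2**(1/k), i.e.

    D(t) = t * (2**(1/k) - 1),

linear in t.  An instantaneous-rate variant D(t) = ln(2) * t / k (from the
local decay rate k/t) is also provided; both are linear in age and
coincide as k grows large.

Exponential (semi-log) and linear (raw-space) alternatives are fitted the
same way so their coefficients of determination can be compared with the
power model's; each R-squared is reported in the space the model was
fitted in.

Fits are ordinary least squares.  Power fits use log-transformed age and
value, which presumes multiplicative (lognormal) measurement error — the
natural noise model for contents spanning orders of magnitude.  Zero or
negative values (non-detects) and surface ages t <= 0 are excluded from
log-space fits; an optional pseudo-value (half the smallest positive value
of the series) can be imputed instead, and a raw-space nonlinear fit is
available behind ``method="nls"`` for sensitivity analysis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .series import AnalyteSeries

#: Sediment ages (years) of the standard half-life schedule.
TABLE_AGES = (1.0, 20.0, 50.0, 100.0, 200.0, 500.0, 1000.0)

#: Reliability-flag thresholds: a fit is flagged when the slope is
#: nonsignificant (p > 0.05) and/or the coefficient of determination is
#: low (R^2 < 0.2).
FLAG_P_MAX = 0.05
FLAG_R2_MIN = 0.2


class InsufficientDataError(ValueError):
    """Fewer usable points than the model's minimum (3)."""


def flag_fit(p_slope: float, r_squared: float) -> bool:
    """Reliability flag: True iff p > 0.05 or R^2 < 0.2 (strict)."""
    return bool(p_slope > FLAG_P_MAX or r_squared < FLAG_R2_MIN)


# ---------------------------------------------------------------------------
# half-life arithmetic


def half_life(k: float, age: float, formula: str = "exact_halving") -> float:
    """Age-dependent half-life (years) under power-law decay.

    Parameters
    ----------
    k : decay constant (-slope of the log-log fit); k <= 0 means no net
        decay and returns ``inf`` with a warning.
    age : sediment age t > 0 at which the halving time is evaluated.
    formula : ``"exact_halving"`` (default) is the exact halving time
        t*(2**(1/k) - 1) of Y = a*t**(-k); ``"instantaneous_rate"`` is
        ln(2)*t/k from the local rate.  Both are linear in age.
    """
    if age <= 0:
        raise ValueError("age must be > 0")
    if k <= 0:
        warnings.warn(f"decay constant k={k} <= 0: no decay, half-life infinite")
        return math.inf
    if formula == "exact_halving":
        return age * (2.0 ** (1.0 / k) - 1.0)
    if formula == "instantaneous_rate":
        return math.log(2.0) * age / k
    raise ValueError(f"unknown half-life formula {formula!r}")


def calibrate_k_from_h1(h1: float, formula: str = "exact_halving") -> float:
    """Invert the half-life formula at age 1 y: the k whose half-life at
    sediment age 1 year equals ``h1``.

    For ``exact_halving``, h1 = 2**(1/k) - 1 gives k = ln 2 / ln(1 + h1);
    for ``instantaneous_rate``, k = ln 2 / h1.
    """
    if h1 <= 0:
        raise ValueError("h1 must be > 0")
    if formula == "exact_halving":
        return math.log(2.0) / math.log1p(h1)
    if formula == "instantaneous_rate":
        return math.log(2.0) / h1
    raise ValueError(f"unknown half-life formula {formula!r}")


@dataclass
class HalfLifeSchedule:
    """Half-lives of one decay constant over a ladder of sediment ages.

    Because both formulas are linear in age, ``half_lives[i]/ages[i]`` is
    constant across the schedule and half-lives grow strictly with age
    whenever k > 0.
    """

    decay_constant: float
    ages: tuple[float, ...]
    half_lives: tuple[float, ...]
    formula: str = "exact_halving"

    def as_row(self) -> dict:
        row = {"decay_constant": self.decay_constant, "formula": self.formula}
        row.update({f"hl_age_{g:g}": h for g, h in zip(self.ages, self.half_lives)})
        return row


def half_life_schedule(k: float, ages=TABLE_AGES,
                       formula: str = "exact_halving") -> HalfLifeSchedule:
    """Evaluate :func:`half_life` over a ladder of ages (default 1–1,000 y)."""
    ages = tuple(float(a) for a in ages)
    return HalfLifeSchedule(
        decay_constant=k,
        ages=ages,
        half_lives=tuple(half_life(k, a, formula) for a in ages),
        formula=formula,
    )


# ---------------------------------------------------------------------------
# model/results objects


@dataclass
class DecayFit:
    """Results of one decay-model fit.

    ``amplitude`` is the content at age 1 y for the power model and the
    intercept (at t=0) otherwise.  ``exponent`` is the fitted slope in the
    model's own space: dimensionless for power, per-year for exponential,
    content/year for linear.  ``decay_constant`` (= -exponent) is defined
    for power fits only.  ``r_squared`` is the fraction of variance
    explained in the fitted space and ``p_slope`` the two-sided p-value of
    the slope.  ``flagged`` marks unreliable fits (p > 0.05 or R^2 < 0.2).
    """

    model: str
    amplitude: float
    exponent: float
    r_squared: float
    p_slope: float
    n_points: int
    decay_constant: float | None = None
    flagged: bool = False
    stderr_slope: float = math.nan
    n_excluded: int = 0
    analyte_id: str = ""
    organism_group: str = ""
    compound_class: str = ""
    station_id: str = ""
    lake_id: str = ""

    def predict(self, ages) -> np.ndarray:
        t = np.asarray(ages, dtype=float)
        if self.model == "power":
            return self.amplitude * t ** self.exponent
        if self.model == "exponential":
            return self.amplitude * np.exp(self.exponent * t)
        return self.amplitude + self.exponent * t

    def half_life(self, age: float, formula: str = "exact_halving") -> float:
        if self.model != "power":
            raise ValueError("age-dependent half-life is defined for power fits")
        return half_life(self.decay_constant, age, formula)

    def half_life_schedule(self, ages=TABLE_AGES,
                           formula: str = "exact_halving") -> HalfLifeSchedule:
        if self.model != "power":
            raise ValueError("age-dependent half-life is defined for power fits")
        return half_life_schedule(self.decay_constant, ages, formula)

    def summary(self) -> str:
        lines = [
            f"{self.model} decay fit" + (f": {self.analyte_id}" if self.analyte_id else ""),
            f"  amplitude a      {self.amplitude:.6g}",
            f"  slope b          {self.exponent:.6g}  (SE {self.stderr_slope:.3g})",
        ]
        if self.decay_constant is not None:
            lines.append(f"  decay constant k {self.decay_constant:.6g}")
        lines += [
            f"  R-squared        {self.r_squared:.4f}",
            f"  p(slope)         {self.p_slope:.4g}",
            f"  n (excluded)     {self.n_points} ({self.n_excluded})",
            f"  flagged          {self.flagged}",
        ]
        return "\n".join(lines)


def _slope_ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """OLS of y on x: (intercept, slope, r_squared, p_slope, stderr_slope).

    Degenerate y (zero variance) is reported as slope 0, R^2 = 0, p = 1,
    so that a constant profile reads as "no decay" rather than an error.
    """
    if np.ptp(y) == 0:
        return float(y[0]), 0.0, 0.0, 1.0, 0.0
    res = stats.linregress(x, y)
    return (float(res.intercept), float(res.slope), float(res.rvalue) ** 2,
            float(res.pvalue), float(res.stderr))


class _DecayModelBase:
    """statsmodels-flavoured model object: holds the data, ``fit()`` returns
    a :class:`DecayFit` results object."""

    model_name = ""
    #: include points with age == 0 (power fits require t > 0)
    allow_zero_age = True

    def __init__(self, series: AnalyteSeries, zero_policy: str = "exclude"):
        if zero_policy not in ("exclude", "pseudo"):
            raise ValueError("zero_policy must be 'exclude' or 'pseudo'")
        self.series = series
        self.zero_policy = zero_policy
        self.ages, self.values, self.n_excluded = self._usable_points()
        if self.ages.size < 3:
            raise InsufficientDataError(
                f"insufficient data: {self.ages.size} usable points in "
                f"{series.label!r} (need >= 3)"
            )

    def _usable_points(self) -> tuple[np.ndarray, np.ndarray, int]:
        ages, values = self.series.ages, self.series.values
        if self.zero_policy == "pseudo":
            pos = values[values > 0]
            if pos.size:
                values = np.where(values > 0, values, pos.min() / 2.0)
        mask = values > 0
        if not self.allow_zero_age:
            mask &= ages > 0
        return ages[mask], values[mask], int((~mask).sum())

    def _transform(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def _finish(self, intercept, slope, r2, p, se) -> DecayFit:
        raise NotImplementedError

    def fit(self) -> DecayFit:
        x, y = self._transform()
        out = self._finish(*_slope_ols(x, y))
        out.n_points = int(x.size)
        out.n_excluded = self.n_excluded
        out.flagged = flag_fit(out.p_slope, out.r_squared)
        s = self.series
        out.analyte_id, out.organism_group = s.analyte_id, s.organism_group
        out.compound_class, out.station_id, out.lake_id = (
            s.compound_class, s.station_id, s.lake_id)
        return out


class PowerDecayModel(_DecayModelBase):
    """Y = a * t**b fitted by OLS on (ln t, ln Y); t > 0, Y > 0 required."""

    model_name = "power"
    allow_zero_age = False

    def __init__(self, series, zero_policy: str = "exclude", method: str = "ols"):
        if method not in ("ols", "nls"):
            raise ValueError("method must be 'ols' or 'nls'")
        self.method = method
        super().__init__(series, zero_policy)

    def _transform(self):
        return np.log(self.ages), np.log(self.values)

    def _finish(self, intercept, slope, r2, p, se) -> DecayFit:
        if self.method == "nls":
            a0, b0 = math.exp(intercept), slope
            popt, _ = optimize.curve_fit(
                lambda t, a, b: a * t ** b, self.ages, self.values,
                p0=(a0, b0), maxfev=10000)
            a, b = float(popt[0]), float(popt[1])
            resid = self.values - a * self.ages ** b
            ss_tot = float(np.sum((self.values - self.values.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else 0.0
            return DecayFit("power", a, b, max(0.0, min(1.0, r2)), p,
                            self.ages.size, decay_constant=-b, stderr_slope=se)
        return DecayFit("power", math.exp(intercept), slope, r2, p,
                        self.ages.size, decay_constant=-slope, stderr_slope=se)


class ExponentialDecayModel(_DecayModelBase):
    """Y = a * exp(b t) fitted by OLS on (t, ln Y); R^2 in semi-log space."""

    model_name = "exponential"

    def _transform(self):
        return self.ages, np.log(self.values)

    def _finish(self, intercept, slope, r2, p, se) -> DecayFit:
        return DecayFit("exponential", math.exp(intercept), slope, r2, p,
                        self.ages.size, stderr_slope=se)


class LinearDecayModel(_DecayModelBase):
    """Y = a + b t fitted by OLS in raw space."""

    model_name = "linear"

    def _usable_points(self):
        # raw-space fit keeps zero values; only requires >= 3 points
        return self.series.ages, self.series.values, 0

    def _transform(self):
        return self.ages, self.values

    def _finish(self, intercept, slope, r2, p, se) -> DecayFit:
        return DecayFit("linear", intercept, slope, r2, p,
                        self.ages.size, stderr_slope=se)


def fit_power(series: AnalyteSeries, zero_policy: str = "exclude",
              method: str = "ols") -> DecayFit:
    """Fit the power decay model (see :class:`PowerDecayModel`)."""
    return PowerDecayModel(series, zero_policy, method).fit()


def fit_exponential(series: AnalyteSeries, zero_policy: str = "exclude") -> DecayFit:
    return ExponentialDecayModel(series, zero_policy).fit()


def fit_linear(series: AnalyteSeries) -> DecayFit:
    return LinearDecayModel(series).fit()


_MODEL_ORDER = {"power": 0, "exponential": 1, "linear": 2}
_MODEL_CLASSES = {
    "power": PowerDecayModel,
    "exponential": ExponentialDecayModel,
    "linear": LinearDecayModel,
}


@dataclass
class ModelComparison:
    fits: dict[str, DecayFit]
    best: str

    @property
    def ranking(self) -> list[str]:
        return sorted(self.fits,
                      key=lambda m: (-self.fits[m].r_squared, _MODEL_ORDER[m]))


def compare_models(series: AnalyteSeries, zero_policy: str = "exclude") -> ModelComparison:
    """Fit power, exponential and linear models and rank them by R-squared.

    Each model's R-squared is computed in its own fitted space (log-log,
    semi-log, raw).  Ties are broken by preferring power, then exponential:
    the power law is the mechanistically motivated default and the tie
    order makes the ranking deterministic.  Models with too few usable
    points are skipped; if none can be fitted an error is raised.
    """
    fits: dict[str, DecayFit] = {}
    for name, cls in _MODEL_CLASSES.items():
        try:
            fits[name] = cls(series, zero_policy).fit() if name != "linear" \
                else cls(series).fit()
        except InsufficientDataError:
            continue
    if not fits:
        raise InsufficientDataError(f"no model fittable for {series.label!r}")
    best = min(fits, key=lambda m: (-fits[m].r_squared, _MODEL_ORDER[m]))
    return ModelComparison(fits=fits, best=best)


# ---------------------------------------------------------------------------
# group summaries


@dataclass
class GroupDecaySummary:
    """Mean and sample SD of decay constants over the power fits in a group
    (stations within a lake, or lakes within a study)."""

    label: str
    mean_k: float
    sd_k: float
    n_fits: int
    member_fits: list[DecayFit] = field(default_factory=list)
    applicable: bool = True

    @property
    def k_values(self) -> list[float]:
        return [f.decay_constant for f in self.member_fits]


def summarize_decay(fits, grouping) -> list[GroupDecaySummary]:
    """Average decay constants of power fits per group.

    ``grouping`` is either a callable mapping a :class:`DecayFit` to a
    label or the name of a DecayFit attribute (e.g. ``"organism_group"``,
    ``"analyte_id"``).  Non-power fits are ignored.  A group in which no
    constant is positive — the content did not decrease over time — is
    returned with ``applicable=False`` ('na').  SD uses ddof=1; a
    single-fit group reports SD 0.
    """
    key = grouping if callable(grouping) else (lambda f: getattr(f, grouping))
    groups: dict[str, list[DecayFit]] = {}
    for f in fits:
        if f.model != "power":
            continue
        groups.setdefault(key(f), []).append(f)
    out = []
    for label in groups:
        members = groups[label]
        ks = np.array([f.decay_constant for f in members])
        if ks.size == 0:
            warnings.warn(f"group {label!r} empty after filtering; omitted")
            continue
        out.append(GroupDecaySummary(
            label=label,
            mean_k=float(ks.mean()),
            sd_k=float(ks.std(ddof=1)) if ks.size > 1 else 0.0,
            n_fits=int(ks.size),
            member_fits=members,
            applicable=bool(np.any(ks > 0)),
        ))
    return out
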