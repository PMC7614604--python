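"""Ecological epidemiology of EGFR-mutant lung cancer incidence and PM2.5.

Region-level analyses relate ambient fine particulate matter (PM2.5,
ug m^-3) to the incidence of EGFR-mutant lung cancer.  The building
blocks implemented here:

- direct age standardization of incidence,
  ``ASR = (sum_i w_i x_i / d_i) / (sum_i w_i) * 100,000``, with ``w_i``
  a standard-population weight (ESP 2013 or WHO 2000, both packaged),
  ``x_i`` the case count and ``d_i`` the population of stratum ``i``;
- Dobson confidence intervals for the ASR, anchoring the normal-theory
  variance of the weighted rate to the exact Poisson limits of the total
  case count;
- the EGFR mutation rate (abnormal tests over all informative tests) and
  the EGFR-mutant incidence (incidence times mutation rate);
- backward-looking PM2.5 exposure windows with an optional washout;
- weighted Pearson correlation (weights = tested cases per region);
- quantile-based low/intermediate/high exposure groups.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MissingYearError

__all__ = [
    "Stratum",
    "RegionRecord",
    "ExposureWindowSpec",
    "GroupThresholds",
    "load_standard_population",
    "age_standardized_rate",
    "dobson_ci",
    "egfr_mutation_rate",
    "egfrm_incidence",
    "pm25_exposure_window",
    "weighted_pearson",
    "exposure_groups",
]


@dataclass(frozen=True)
class Stratum:
    """One age(-sex) stratum: cases ``x``, population ``d``, weight ``w``."""

    age_group: str
    cases: float
    population: float
    std_weight: float
    sex: str = ""

    def __post_init__(self) -> None:
        if self.population <= 0:
            raise ValueError("stratum population must be positive")
        if self.cases < 0:
            raise ValueError("stratum cases must be non-negative")
        if self.std_weight <= 0:
            raise ValueError("stratum weight must be positive")


@dataclass
class RegionRecord:
    """A region's PM2.5 series, test counts and (optional) incidence."""

    region_id: str
    pm25_by_year: Mapping[int, float]
    diagnosis_year: int
    egfr_abnormal: int = 0
    egfr_normal: int = 0
    incidence: float | None = None

    @property
    def n_tested(self) -> int:
        return self.egfr_abnormal + self.egfr_normal


@dataclass(frozen=True)
class ExposureWindowSpec:
    """Averaging window (years) and washout (years) before diagnosis."""

    window_years: int = 10
    washout_years: int = 0

    def __post_init__(self) -> None:
        if self.window_years < 1:
            raise ValueError("window_years must be >= 1")
        if self.washout_years < 0:
            raise ValueError("washout_years must be >= 0")


@dataclass(frozen=True)
class GroupThresholds:
    """Exposure cutoffs at the low and high quantiles."""

    low_cut: float
    high_cut: float

    def __post_init__(self) -> None:
        if self.low_cut > self.high_cut:
            raise ValueError("low_cut must not exceed high_cut")


def load_standard_population(name: str = "esp2013") -> pd.DataFrame:
    """Load a packaged standard-population weight table.

    ``"esp2013"`` — 2013 European Standard Population (5-year bands,
    weights summing to 100,000); ``"who2000"`` — WHO 2000 world standard.
    """
    name = name.lower()
    if name not in {"esp2013", "who2000"}:
        raise ValueError("standard population must be 'esp2013' or 'who2000'")
    ref = resources.files("clonoprev.data").joinpath(f"{name}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def _strata_arrays(strata) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(strata, pd.DataFrame):
        for col in ("cases", "population", "std_weight"):
            if col not in strata.columns:
                raise ValueError(f"strata table missing column {col!r}")
        x = strata["cases"].to_numpy(dtype=float)
        d = strata["population"].to_numpy(dtype=float)
        w = strata["std_weight"].to_numpy(dtype=float)
    else:
        strata = list(strata)
        x = np.array([s.cases for s in strata], dtype=float)
        d = np.array([s.population for s in strata], dtype=float)
        w = np.array([s.std_weight for s in strata], dtype=float)
    if x.size == 0:
        raise ValueError("at least one stratum is required")
    if np.any(d <= 0):
        raise ValueError("stratum populations must be positive")
    if np.any(w <= 0):
        raise ValueError("stratum weights must be positive")
    if np.any(x < 0):
        raise ValueError("stratum cases must be non-negative")
    return x, d, w


def age_standardized_rate(
    strata: Sequence[Stratum] | pd.DataFrame, per: float = 100_000.0
) -> float:
    """Directly standardized rate per ``per`` population."""
    x, d, w = _strata_arrays(strata)
    return float(np.sum(w * x / d) / np.sum(w) * per)


def _poisson_exact_limits(x: float, level: float) -> tuple[float, float]:
    """Exact Poisson limits for an observed count via the chi-square identity."""
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else stats.chi2.ppf(alpha / 2, 2 * x) / 2.0
    upper = stats.chi2.ppf(1 - alpha / 2, 2 * x + 2) / 2.0
    return float(lower), float(upper)


def dobson_ci(
    strata: Sequence[Stratum] | pd.DataFrame,
    level: float = 0.95,
    per: float = 100_000.0,
) -> tuple[float, float]:
    """Dobson confidence interval for the age-standardized rate.

    With ``R`` the standardized rate, ``X`` the total case count,
    ``v = Var(R)`` under independent Poisson strata and ``(X_L, X_U)`` the
    exact Poisson limits of ``X``:

        CI = ( R + (X_L - X) * sqrt(v / X),  R + (X_U - X) * sqrt(v / X) )

    floored at zero.  With ``X = 0`` the rate and variance are zero; the
    lower bound is 0 and the upper bound uses the most conservative
    single-case scale ``max_i(w_i / d_i) / sum(w)`` in place of
    ``sqrt(v / X)`` (degenerate-input convention, see the methods note).
    """
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    x, d, w = _strata_arrays(strata)
    R = age_standardized_rate(strata, per=per)
    X = float(np.sum(x))
    wsum = np.sum(w)
    x_lo, x_hi = _poisson_exact_limits(X, level)
    if X == 0:
        scale = float(np.max(w / d) / wsum * per)
        return 0.0, x_hi * scale
    v = float(np.sum(w**2 * x / d**2) / wsum**2 * per**2)
    scale = np.sqrt(v / X)
    lower = max(0.0, R + (x_lo - X) * scale)
    upper = R + (x_hi - X) * scale
    return lower, upper


def egfr_mutation_rate(abnormal: int, normal: int) -> float:
    """EGFR mutation rate: abnormal tests / (abnormal + normal)."""
    if abnormal < 0 or normal < 0:
        raise ValueError("test counts must be non-negative")
    total = abnormal + normal
    if total == 0:
        raise ValueError("no informative EGFR tests")
    return abnormal / total


def egfrm_incidence(incidence: float, mutation_rate: float) -> float:
    """EGFR-mutant lung cancer incidence: incidence times mutation rate."""
    if incidence < 0:
        raise ValueError("incidence must be non-negative")
    if not 0 <= mutation_rate <= 1:
        raise ValueError("mutation rate must lie in [0, 1]")
    return incidence * mutation_rate


def pm25_exposure_window(
    record: RegionRecord | Mapping[int, float],
    spec: ExposureWindowSpec = ExposureWindowSpec(),
    diagnosis_year: int | None = None,
    min_year: int | None = None,
) -> float:
    """Mean PM2.5 over the exposure window preceding diagnosis.

    The washout counts calendar years back from and including the
    diagnosis year, with a minimum of 1 (the diagnosis year itself is
    never part of the window); the window spans up to ``window_years``
    ending at ``diagnosis_year - max(washout_years, 1)``.  Examples: a
    2018 diagnosis with no washout and a 10-year window averages
    2008-2017; a 2017 diagnosis with a 2-year washout averages years up
    to 2015 (2006-2015 when data start in 2006, via ``min_year``).

    Missing years inside the window raise :class:`MissingYearError`; no
    silent imputation.
    """
    if isinstance(record, RegionRecord):
        series = record.pm25_by_year
        diagnosis_year = record.diagnosis_year
    else:
        series = record
        if diagnosis_year is None:
            raise ValueError("diagnosis_year is required with a bare PM2.5 series")
    end = diagnosis_year - max(spec.washout_years, 1)
    start = end - spec.window_years + 1
    if min_year is not None:
        start = max(start, min_year)
    if start > end:
        raise ValueError("exposure window is empty")
    years = range(start, end + 1)
    missing = [y for y in years if y not in series]
    if missing:
        raise MissingYearError(f"PM2.5 missing for years {missing}")
    return float(np.mean([series[y] for y in years]))


def weighted_pearson(x, y, w) -> float:
    """Weighted Pearson correlation with weighted means throughout.

    ``r_w = sum w (x - mx)(y - my) / sqrt(sum w (x - mx)^2 sum w (y - my)^2)``
    with ``mx``, ``my`` the weighted means.  Equal weights reduce exactly
    to the ordinary Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape) or x.ndim != 1:
        raise ValueError("x, y and w must be 1-d arrays of equal length")
    if x.size < 3:
        raise ValueError("at least 3 observations are required")
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    wsum = w.sum()
    mx = np.sum(w * x) / wsum
    my = np.sum(w * y) / wsum
    cov = np.sum(w * (x - mx) * (y - my))
    vx = np.sum(w * (x - mx) ** 2)
    vy = np.sum(w * (y - my) ** 2)
    if vx == 0 or vy == 0:
        raise ValueError("correlation undefined: zero weighted variance")
    r = cov / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def exposure_groups(
    values, low_q: float = 0.2, high_q: float = 0.8
) -> tuple[list[str], GroupThresholds]:
    """Label exposures low / intermediate / high by distribution quantiles.

    Thresholds are the ``low_q`` and ``high_q`` quantiles (linear
    interpolation, numpy's default type-7 convention).  A value is
    ``"low"`` when strictly below the low cutoff, ``"high"`` when strictly
    above the high cutoff, otherwise ``"intermediate"`` (values equal to a
    cutoff are intermediate).
    """
    vals = np.asarray(values, dtype=float)
    if vals.ndim != 1 or vals.size < 5:
        raise ValueError("at least 5 exposure values are required")
    if not 0 <= low_q <= high_q <= 1:
        raise ValueError("quantiles must satisfy 0 <= low_q <= high_q <= 1")
    low_cut, high_cut = np.quantile(vals, [low_q, high_q])
    thresholds = GroupThresholds(float(low_cut), float(high_cut))
    labels = [
        "low" if v < thresholds.low_cut else "high" if v > thresholds.high_cut else "intermediate"
        for v in vals
    ]
    return labels, thresholds
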