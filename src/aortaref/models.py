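"""Domain types and deterministic chart arithmetic.

The central object is a :class:`ReferenceChart`: a pair of polynomials in a
single fetal biometric predictor (gestational age in weeks, biparietal
diameter or femur length in mm), one giving the conditional mean of a
response — ascending-aorta systolic diameter Dmax, diastolic diameter Dmin,
or diameter distensibility DD = (Dmax − Dmin)/Dmin — and one giving its
conditional standard deviation.  A measurement is scored as

    z = (observed − mean(x)) / sd(x)

and |z| > 1.65 flags the outer 10% of the reference population.

Distensibility is held internally as a dimensionless fraction; percent is
presentation only (see :func:`distensibility_percent`).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    ChartDomainError,
    EmptyInputError,
    ExtrapolationWarning,
    InconsistentFramesError,
    IncompleteRecordError,
    InvalidMeasurementError,
    InvalidSDError,
    MalformedModelError,
    UnknownChartError,
)

Response = Literal["Dmax", "Dmin", "DD"]
Predictor = Literal["GA", "BPD", "FL"]

RESPONSES: tuple[Response, ...] = ("Dmax", "Dmin", "DD")
PREDICTORS: tuple[Predictor, ...] = ("GA", "BPD", "FL")

#: classification threshold for the 90% reference band, as printed in
#: clinical usage (distinct from the exact quantile 1.6449 used for curves)
BAND_THRESHOLD = 1.65

#: exact standard-normal 95th-percentile quantile used in percentile math
Z_90 = 1.6449


def distensibility(dmax: float, dmin: float) -> float:
    """Relative systolic–diastolic diameter expansion, (Dmax − Dmin)/Dmin.

    Dimensionless fraction; ``dmin`` must be positive and not exceed
    ``dmax`` (the vessel cannot be narrower at end-systole).
    """
    if dmin <= 0:
        raise InvalidMeasurementError(f"dmin must be > 0 mm, got {dmin}")
    if dmax < dmin:
        raise InconsistentFramesError(
            f"dmax ({dmax}) < dmin ({dmin}): end-systolic diameter "
            "must not be smaller than end-diastolic"
        )
    return (dmax - dmin) / dmin


def distensibility_percent(dmax: float, dmin: float) -> float:
    """Distensibility rendered as a percentage (fraction × 100)."""
    return 100.0 * distensibility(dmax, dmin)


@dataclass(frozen=True)
class FitStats:
    """Goodness-of-fit summary: multiple correlation R and overall-F p."""

    r: float
    p: float


@dataclass(frozen=True)
class PolyModel:
    """A polynomial in one predictor, stored as explicit (power, coefficient) terms.

    ``provenance`` distinguishes coefficients transcribed from the published
    tables (``published_as_printed``), typographic corrections of corrupt
    printed entries (``published_sanitized``), and models fitted from data
    (``fitted``, the only provenance carrying ``fit_stats``).
    ``printed_form`` optionally retains the verbatim published formula.
    """

    predictor: Predictor
    terms: tuple[tuple[int, float], ...]
    provenance: Literal[
        "published_as_printed", "published_sanitized", "fitted"
    ] = "fitted"
    fit_stats: FitStats | None = None
    printed_form: str | None = None

    def __post_init__(self) -> None:
        if not self.terms:
            raise MalformedModelError("polynomial has no terms")
        powers = [p for p, _ in self.terms]
        if len(set(powers)) != len(powers):
            raise MalformedModelError(f"duplicate powers in term list: {powers}")
        if any(p < 0 or p != int(p) for p in powers):
            raise MalformedModelError(f"powers must be non-negative integers: {powers}")
        if (self.fit_stats is not None) != (self.provenance == "fitted"):
            raise MalformedModelError(
                "fit_stats must be present iff provenance is 'fitted'"
            )

    @property
    def powers(self) -> tuple[int, ...]:
        return tuple(p for p, _ in self.terms)

    @property
    def degree(self) -> int:
        return max(self.powers)

    def __call__(self, x):
        """Evaluate by exact term summation; accepts scalars or arrays."""
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x)
        for power, coef in self.terms:
            out = out + coef * x**power
        return float(out) if out.ndim == 0 else out

    def derivative(self) -> "PolyModel | None":
        terms = tuple(
            (p - 1, p * c) for p, c in self.terms if p >= 1 and p * c != 0.0
        )
        if not terms:
            return None
        return PolyModel(self.predictor, terms, provenance=self.provenance)


def evaluate_poly(model: PolyModel, x) -> float:
    """Evaluate ``model`` at predictor value(s) ``x``."""
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError(f"predictor value must be finite, got {x}")
    return model(x)


@dataclass(frozen=True)
class BiometryRecord:
    """One fetus: predictors (GA weeks, BPD mm, FL mm) and responses (mm).

    ``dd`` (diameter distensibility) is always derived from the diameters,
    never supplied.  BPD and FL may be absent (None) when only GA-based
    charts are used.
    """

    ga: float
    dmax: float
    dmin: float
    bpd: float | None = None
    fl: float | None = None

    def __post_init__(self) -> None:
        if self.dmax <= 0:
            raise InvalidMeasurementError(f"dmax must be > 0 mm, got {self.dmax}")
        if self.dmin <= 0:
            raise InvalidMeasurementError(f"dmin must be > 0 mm, got {self.dmin}")
        if self.dmax < self.dmin:
            raise InconsistentFramesError(
                f"dmax ({self.dmax}) < dmin ({self.dmin})"
            )

    @property
    def dd(self) -> float:
        """Diameter distensibility as a dimensionless fraction."""
        return distensibility(self.dmax, self.dmin)

    def predictor_value(self, predictor: Predictor) -> float:
        value = {"GA": self.ga, "BPD": self.bpd, "FL": self.fl}[predictor]
        if value is None:
            raise IncompleteRecordError(f"record has no {predictor} value")
        return float(value)

    def response_value(self, response: Response) -> float:
        return float({"Dmax": self.dmax, "Dmin": self.dmin, "DD": self.dd}[response])


@dataclass(frozen=True)
class ZScoreResult:
    """A scored measurement with its chart context and 90%-band flag."""

    observed: float
    predicted_mean: float
    predicted_sd: float
    z: float
    band_flag: Literal["within_90", "outside_90"]
    extrapolated: bool = False

    @property
    def outside_band(self) -> bool:
        return self.band_flag == "outside_90"


def zscore(
    observed: float,
    predicted_mean: float,
    predicted_sd: float,
    *,
    extrapolated: bool = False,
) -> ZScoreResult:
    """Score an observation against a predicted mean and SD.

    The band flag uses strict inequality: |z| exactly at the 1.65 threshold
    is classified within the 90% band.
    """
    if predicted_sd <= 0:
        raise InvalidSDError(f"predicted SD must be > 0, got {predicted_sd}")
    z = (observed - predicted_mean) / predicted_sd
    flag = "outside_90" if abs(z) > BAND_THRESHOLD else "within_90"
    return ZScoreResult(
        observed=observed,
        predicted_mean=predicted_mean,
        predicted_sd=predicted_sd,
        z=z,
        band_flag=flag,
        extrapolated=extrapolated,
    )


@dataclass(frozen=True)
class ReferenceChart:
    """Paired mean and SD polynomials for one (response, predictor).

    On construction the SD model is checked to be strictly positive on a
    dense grid over ``predictor_range`` (``validate=False`` skips the check
    so corrupt as-printed published models remain inspectable; their
    ``predict_sd`` still raises pointwise).
    """

    response: Response
    mean_model: PolyModel
    sd_model: PolyModel
    predictor_range: tuple[float, float]
    validate: bool = field(default=True, compare=False)

    def __post_init__(self) -> None:
        if self.mean_model.predictor != self.sd_model.predictor:
            raise MalformedModelError(
                "mean and SD models must share a predictor, got "
                f"{self.mean_model.predictor} vs {self.sd_model.predictor}"
            )
        lo, hi = self.predictor_range
        if not lo < hi:
            raise MalformedModelError(f"invalid predictor range ({lo}, {hi})")
        if self.validate:
            grid = np.linspace(lo, hi, 513)
            sd = self.sd_model(grid)
            if np.any(sd <= 0):
                bad = float(grid[np.argmin(sd)])
                raise ChartDomainError(
                    f"SD model non-positive within range, e.g. at "
                    f"{self.predictor} = {bad:g}"
                )

    @property
    def predictor(self) -> Predictor:
        return self.mean_model.predictor

    def _check_range(self, x: float) -> bool:
        lo, hi = self.predictor_range
        if x < lo or x > hi:
            warnings.warn(
                f"{self.predictor} = {x:g} outside validated range "
                f"[{lo:g}, {hi:g}]; extrapolating",
                ExtrapolationWarning,
                stacklevel=3,
            )
            return True
        return False

    def predict_mean(self, x: float) -> float:
        self._check_range(float(x))
        return evaluate_poly(self.mean_model, x)

    def predict_sd(self, x: float) -> float:
        self._check_range(float(x))
        sd = evaluate_poly(self.sd_model, x)
        if sd <= 0:
            raise ChartDomainError(
                f"predicted SD {sd:g} <= 0 at {self.predictor} = {x:g}; "
                "value is outside the chart's valid domain or the "
                "coefficient set is corrupt"
            )
        return sd

    def score(self, observed: float, x: float) -> ZScoreResult:
        extrapolated = self._check_range(float(x))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ExtrapolationWarning)
            mean = self.predict_mean(x)
            sd = self.predict_sd(x)
        return zscore(observed, mean, sd, extrapolated=extrapolated)

    # --- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "response": self.response,
            "predictor": self.predictor,
            "terms": [[p, c] for p, c in self.mean_model.terms],
            "sd_terms": [[p, c] for p, c in self.sd_model.terms],
            "range": list(self.predictor_range),
            "provenance": {
                "mean": self.mean_model.provenance,
                "sd": self.sd_model.provenance,
            },
        }
        if self.mean_model.fit_stats is not None:
            d["mean_fit_stats"] = {
                "R": self.mean_model.fit_stats.r,
                "p": self.mean_model.fit_stats.p,
            }
        if self.sd_model.fit_stats is not None:
            d["sd_fit_stats"] = {
                "R": self.sd_model.fit_stats.r,
                "p": self.sd_model.fit_stats.p,
            }
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: Mapping) -> "ReferenceChart":
        prov = d.get("provenance", {"mean": "fitted", "sd": "fitted"})

        def _stats(key):
            s = d.get(key)
            return None if s is None else FitStats(r=s["R"], p=s["p"])

        mean = PolyModel(
            predictor=d["predictor"],
            terms=tuple((int(p), float(c)) for p, c in d["terms"]),
            provenance=prov["mean"],
            fit_stats=_stats("mean_fit_stats"),
        )
        sd = PolyModel(
            predictor=d["predictor"],
            terms=tuple((int(p), float(c)) for p, c in d["sd_terms"]),
            provenance=prov["sd"],
            fit_stats=_stats("sd_fit_stats"),
        )
        return cls(
            response=d["response"],
            mean_model=mean,
            sd_model=sd,
            predictor_range=(float(d["range"][0]), float(d["range"][1])),
        )

    @classmethod
    def from_json(cls, text_or_path) -> "ReferenceChart":
        try:
            d = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path, encoding="utf-8") as fh:
                d = json.load(fh)
        return cls.from_dict(d)


@dataclass(frozen=True)
class PercentileCurve:
    """One reference percentile line: mean(x) + Φ⁻¹(p/100)·sd(x) on a grid."""

    percentile: float
    grid: tuple[float, ...]
    values: tuple[float, ...]


def percentile_curves(
    chart: ReferenceChart,
    grid: Sequence[float],
    percentiles: Iterable[float] = (5.0, 50.0, 95.0),
) -> list[PercentileCurve]:
    """Reference percentile lines over a predictor grid.

    The p = 50 curve is exactly the mean model; p and 100 − p curves are
    symmetric about it.
    """
    grid_arr = np.asarray(list(grid), dtype=float)
    if grid_arr.size == 0:
        raise EmptyInputError("empty predictor grid")
    mean = chart.mean_model(grid_arr)
    sd = chart.sd_model(grid_arr)
    if np.any(sd <= 0):
        raise ChartDomainError("SD model non-positive on the requested grid")
    curves = []
    for p in percentiles:
        if not 0 < p < 100:
            raise ValueError(f"percentile must be in (0, 100), got {p}")
        zp = 0.0 if p == 50 else float(stats.norm.ppf(p / 100.0))
        curves.append(
            PercentileCurve(
                percentile=float(p),
                grid=tuple(grid_arr.tolist()),
                values=tuple((mean + zp * sd).tolist()),
            )
        )
    return curves


def score_record(
    record: BiometryRecord,
    response: Response,
    predictor: Predictor,
    registry: Mapping[tuple[Response, Predictor], ReferenceChart],
) -> ZScoreResult:
    """Score one record's response against the registry chart for (response, predictor)."""
    key = (response, predictor)
    if key not in registry:
        raise UnknownChartError(f"no chart registered for {response}~{predictor}")
    chart = registry[key]
    x = record.predictor_value(predictor)
    observed = record.response_value(response)
    return chart.score(observed, x)
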