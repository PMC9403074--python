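"""Three-step reference-chart construction.

Step 1 fits candidate polynomial mean models of the response on the
predictor by ordinary least squares and selects the best by adjusted R²
(or AIC).  Step 2 models the heteroscedastic residual SD as a linear
function of the predictor, either from per-bin sample SDs (weighted by bin
count, the default) or from absolute residuals with the half-normal
correction √(π/2).  Step 3 standardises every observation with the two
fitted curves, yielding the training-cohort z-scores used by the
calibration diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import statsmodels.api as sm

from .errors import (
    InsufficientBinsError,
    InsufficientDataError,
    NonPositiveSDError,
    NoModelError,
    SingularFitError,
)
from .models import (
    BiometryRecord,
    FitStats,
    PolyModel,
    Predictor,
    ReferenceChart,
    Response,
    ZScoreResult,
    zscore,
)

#: default candidate power sets: every non-empty-or-empty subset of
#: {1, 2, 3}; the intercept (power 0) is always included
DEFAULT_TERM_SETS: tuple[tuple[int, ...], ...] = (
    (),
    (1,),
    (2,),
    (3,),
    (1, 2),
    (1, 3),
    (2, 3),
    (1, 2, 3),
)

#: half-normal correction: E|e| = sd·√(2/π) for centred Gaussian residuals
HALF_NORMAL_FACTOR = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class FitConfig:
    """Configuration for chart construction.

    ``bin_width`` is the predictor bin size for the grouped-SD method:
    1 week for gestational age, 5 mm for the biometry predictors (set
    automatically by :func:`build_reference_chart` unless overridden).
    """

    candidate_term_sets: tuple[tuple[int, ...], ...] = DEFAULT_TERM_SETS
    selection_criterion: Literal["adjusted_R2", "AIC"] = "adjusted_R2"
    sd_method: Literal["binned_by_week", "absolute_residual"] = "binned_by_week"
    min_bin_count: int = 5
    bin_width: float | None = None

    def __post_init__(self) -> None:
        if self.min_bin_count < 2:
            raise ValueError("min_bin_count must be >= 2")
        for ts in self.candidate_term_sets:
            if 0 in ts:
                raise ValueError(
                    "candidate term sets list non-intercept powers only; "
                    "the intercept is always included"
                )

    def bin_width_for(self, predictor: Predictor) -> float:
        if self.bin_width is not None:
            return self.bin_width
        return 1.0 if predictor == "GA" else 5.0


def _design(x: np.ndarray, powers: Sequence[int]) -> np.ndarray:
    return np.column_stack([x**p for p in powers])


def fit_mean_model(
    x: Sequence[float],
    y: Sequence[float],
    term_set: Iterable[int] = (1,),
    predictor: Predictor = "GA",
) -> PolyModel:
    """OLS fit of y on the given powers of x (intercept always included).

    ``fit_stats`` carries the multiple correlation R = √R² and the overall-F
    p-value, mirroring the columns conventionally reported next to
    published reference equations.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    powers = (0,) + tuple(sorted(set(int(p) for p in term_set) - {0}))
    n_terms = len(powers)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if len(x) < n_terms + 2:
        raise InsufficientDataError(
            f"need at least {n_terms + 2} observations for {n_terms} terms, "
            f"got {len(x)}"
        )
    if len(np.unique(x)) < 2:
        raise SingularFitError("predictor has fewer than 2 distinct values")
    design = _design(x, powers)
    if np.linalg.matrix_rank(design) < n_terms:
        raise SingularFitError(f"rank-deficient design for powers {powers}")
    res = sm.OLS(y, design).fit()
    r = math.sqrt(max(res.rsquared, 0.0))
    p = float(res.f_pvalue) if n_terms > 1 and np.isfinite(res.f_pvalue) else 1.0
    return PolyModel(
        predictor=predictor,
        terms=tuple(zip(powers, (float(c) for c in res.params))),
        provenance="fitted",
        fit_stats=FitStats(r=r, p=p),
    )


def _criterion_value(res, criterion: str) -> float:
    """Higher is better for both criteria (AIC is negated)."""
    if criterion == "adjusted_R2":
        return float(res.rsquared_adj)
    if criterion == "AIC":
        return -float(res.aic)
    raise ValueError(f"unknown selection criterion {criterion!r}")


def select_best_model(
    x: Sequence[float],
    y: Sequence[float],
    config: FitConfig = FitConfig(),
    predictor: Predictor = "GA",
) -> PolyModel:
    """Fit every candidate term set and return the winner.

    Ranking is by the configured criterion; candidates whose criterion
    values agree to 1e−9 are tied and broken toward fewer terms, then
    lower maximum power.  Candidates too large for the sample, or with
    singular designs, are silently excluded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scored: list[tuple[float, int, int, PolyModel]] = []
    for term_set in config.candidate_term_sets:
        powers = (0,) + tuple(sorted(set(term_set)))
        if len(x) < len(powers) + 2:
            continue
        design = _design(x, powers)
        if np.linalg.matrix_rank(design) < len(powers):
            continue
        res = sm.OLS(y, design).fit()
        crit = _criterion_value(res, config.selection_criterion)
        model = PolyModel(
            predictor=predictor,
            terms=tuple(zip(powers, (float(c) for c in res.params))),
            provenance="fitted",
            fit_stats=FitStats(
                r=math.sqrt(max(res.rsquared, 0.0)),
                p=float(res.f_pvalue)
                if len(powers) > 1 and np.isfinite(res.f_pvalue)
                else 1.0,
            ),
        )
        scored.append((crit, len(powers), max(powers), model))
    if not scored:
        raise NoModelError("no candidate term set could be fitted")
    best_crit = max(s[0] for s in scored)
    tied = [s for s in scored if best_crit - s[0] <= 1e-9]
    tied.sort(key=lambda s: (s[1], s[2]))
    return tied[0][3]


@dataclass(frozen=True)
class SDFitDetail:
    """Diagnostics from an SD-model fit (bin table or residual regression)."""

    method: str
    bin_centers: tuple[float, ...] = ()
    bin_sds: tuple[float, ...] = ()
    bin_counts: tuple[int, ...] = ()
    standard_errors: tuple[float, ...] = ()  # (intercept SE, slope SE)


def fit_sd_model(
    x: Sequence[float],
    residuals: Sequence[float],
    config: FitConfig = FitConfig(),
    predictor: Predictor = "GA",
    *,
    return_detail: bool = False,
):
    """Fit a linear SD-on-predictor model from mean-model residuals.

    ``binned_by_week``: group observations into predictor bins (1 week for
    GA, 5 mm for BPD/FL), compute each bin's sample SD, and regress bin SD
    on bin center weighted by bin count.  ``absolute_residual``: regress
    |residual| on x and scale the fitted line by √(π/2), the half-normal
    factor that converts a mean absolute deviation into a Gaussian SD.
    """
    x = np.asarray(x, dtype=float)
    residuals = np.asarray(residuals, dtype=float)
    if x.shape != residuals.shape or x.ndim != 1:
        raise ValueError("x and residuals must be 1-D arrays of equal length")

    if config.sd_method == "binned_by_week":
        width = config.bin_width_for(predictor)
        idx = np.floor(x / width + 0.5)  # bin center at multiples of width
        centers, sds, counts = [], [], []
        for b in np.unique(idx):
            mask = idx == b
            m = int(mask.sum())
            if m < config.min_bin_count:
                continue
            s = float(np.std(residuals[mask], ddof=1))
            centers.append(float(b) * width)
            sds.append(s)
            counts.append(m)
        if len(centers) < 2:
            raise InsufficientBinsError(
                f"only {len(centers)} bins meet min_bin_count="
                f"{config.min_bin_count}"
            )
        centers_a = np.asarray(centers)
        sds_a = np.asarray(sds)
        counts_a = np.asarray(counts, dtype=float)
        design = sm.add_constant(centers_a)
        res = sm.WLS(sds_a, design, weights=counts_a).fit()
        intercept, slope = (float(c) for c in res.params)
        ses = tuple(float(s) for s in res.bse)
        detail = SDFitDetail(
            method="binned_by_week",
            bin_centers=tuple(centers),
            bin_sds=tuple(sds),
            bin_counts=tuple(int(c) for c in counts),
            standard_errors=ses,
        )
    elif config.sd_method == "absolute_residual":
        design = sm.add_constant(x)
        res = sm.OLS(np.abs(residuals), design).fit()
        intercept, slope = (
            float(c) * HALF_NORMAL_FACTOR for c in res.params
        )
        detail = SDFitDetail(
            method="absolute_residual",
            standard_errors=tuple(
                float(s) * HALF_NORMAL_FACTOR for s in res.bse
            ),
        )
    else:
        raise ValueError(f"unknown sd_method {config.sd_method!r}")

    model = PolyModel(
        predictor=predictor,
        terms=((0, intercept), (1, slope)),
        provenance="fitted",
        fit_stats=FitStats(
            r=math.sqrt(max(res.rsquared, 0.0)),
            p=float(res.f_pvalue) if np.isfinite(res.f_pvalue) else 1.0,
        ),
    )
    # the fitted SD must be usable as a z-score divisor over the data range
    lo, hi = float(x.min()), float(x.max())
    grid = np.linspace(lo, hi, 257) if hi > lo else np.array([lo])
    if np.any(model(grid) <= 0):
        raise NonPositiveSDError(
            "fitted SD model is non-positive within the data range "
            f"[{lo:g}, {hi:g}]"
        )
    return (model, detail) if return_detail else model


@dataclass(frozen=True)
class ChartFitResult:
    """A fitted chart plus its training-cohort z-scores for diagnostics."""

    chart: ReferenceChart
    z_results: tuple[ZScoreResult, ...]
    sd_detail: SDFitDetail
    predictor_values: tuple[float, ...]

    @property
    def z(self) -> np.ndarray:
        return np.array([r.z for r in self.z_results])


def build_reference_chart(
    records: Sequence[BiometryRecord],
    response: Response,
    predictor: Predictor,
    config: FitConfig = FitConfig(),
    *,
    min_records: int = 50,
    min_distinct: int = 10,
) -> ChartFitResult:
    """Run the full three-step construction on a cohort.

    Selects the mean model over the candidate set, fits the SD model to
    the residuals, and standardises every record, returning the chart
    together with the training z-scores.
    """
    if len(records) < min_records:
        raise InsufficientDataError(
            f"need at least {min_records} records, got {len(records)}"
        )
    x = np.array([r.predictor_value(predictor) for r in records])
    y = np.array([r.response_value(response) for r in records])
    if len(np.unique(x)) < min_distinct:
        raise InsufficientDataError(
            f"need at least {min_distinct} distinct {predictor} values"
        )
    mean_model = select_best_model(x, y, config, predictor=predictor)
    residuals = y - mean_model(x)
    sd_model, detail = fit_sd_model(
        x, residuals, config, predictor=predictor, return_detail=True
    )
    chart = ReferenceChart(
        response=response,
        mean_model=mean_model,
        sd_model=sd_model,
        predictor_range=(float(x.min()), float(x.max())),
    )
    mean_pred = mean_model(x)
    sd_pred = sd_model(x)
    z_results = tuple(
        zscore(float(yi), float(mi), float(si))
        for yi, mi, si in zip(y, mean_pred, sd_pred)
    )
    return ChartFitResult(
        chart=chart,
        z_results=z_results,
        sd_detail=detail,
        predictor_values=tuple(x.tolist()),
    )
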