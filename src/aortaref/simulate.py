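"""Synthetic cohorts and rating tables with the structure the pipeline assumes.

A simulated fetus gets a gestational age on 18–40 weeks, biometry (BPD, FL)
from linear growth maps anchored at standard values, a diameter
distensibility drawn from the truth chart's Gaussian law at its GA, and a
systolic diameter Dmax likewise; the diastolic diameter is then *derived*
as Dmin = Dmax/(1 + DD) so the three responses are exactly consistent with
the distensibility definition.  The induced Dmin marginal SD is therefore
a consequence, not a dial.

Defaults emulate the reference study's design: 490 fetuses, GA 18–40 weeks,
the sanitized published truth models, Gaussian residuals with SD varying
linearly in GA.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from .errors import ConfigError
from .models import BiometryRecord, Predictor, ReferenceChart, Response
from .registry import published_registry
from .repeatability import RepeatabilityTable

#: linear biometry growth maps (mm per week, intercept mm) hitting standard
#: anchors: BPD ≈ 47 mm at 20 w and 95 mm at 40 w; FL ≈ 33 mm at 20 w and
#: 76 mm at 40 w
BPD_SLOPE, BPD_INTERCEPT = 2.4, -1.0
FL_SLOPE, FL_INTERCEPT = 2.15, -10.0

#: physical floors for truncated Gaussian draws
DD_FLOOR = 0.01
DMAX_FLOOR_MM = 0.5


@dataclass(frozen=True)
class GeneratorConfig:
    """Study-condition parameters for cohort simulation.

    ``ga_distribution="empirical_skewed"`` thins the cohort below 20 and
    above 38 weeks (under 20 cases in each tail for n = 490), mimicking the
    reference study's stated sparsity; ``uniform`` is the default for clean
    recovery tests.
    """

    n: int = 490
    ga_range: tuple[float, float] = (18.0, 40.0)
    ga_distribution: Literal["uniform", "empirical_skewed"] = "uniform"
    truth_models: Mapping[tuple[Response, Predictor], ReferenceChart] | None = None
    biometry_noise_sd: float = 2.0
    measurement_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError(f"n must be >= 1, got {self.n}")
        lo, hi = self.ga_range
        if not (10.0 < lo < hi < 45.0):
            raise ConfigError(f"ga_range must lie within (10, 45), got {self.ga_range}")
        if self.biometry_noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ConfigError("noise SDs must be >= 0")

    def truth(self) -> Mapping[tuple[Response, Predictor], ReferenceChart]:
        return self.truth_models if self.truth_models is not None else published_registry("sanitized")


@dataclass(frozen=True)
class CohortResult:
    """Simulated records plus bookkeeping on truncation events."""

    records: tuple[BiometryRecord, ...]
    truncation_fraction: float


def _draw_ga(rng: np.random.Generator, config: GeneratorConfig) -> np.ndarray:
    lo, hi = config.ga_range
    if config.ga_distribution == "uniform":
        return rng.uniform(lo, hi, size=config.n)
    if config.ga_distribution == "empirical_skewed":
        # piecewise-uniform with thinned tails: <20 w and >38 w down-weighted
        # so each tail carries ~3% of the cohort (≈15 of 490 fetuses)
        edges = np.array([lo, 20.0, 38.0, hi])
        probs = np.array([0.03, 0.94, 0.03])
        seg = rng.choice(3, size=config.n, p=probs)
        return rng.uniform(edges[seg], edges[seg + 1])
    raise ConfigError(f"unknown ga_distribution {config.ga_distribution!r}")


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    floor: float,
    max_redraws: int = 100,
) -> tuple[np.ndarray, int]:
    """Gaussian draws resampled above a physical floor; counts truncations."""
    out = rng.normal(mean, sd)
    n_trunc = 0
    for _ in range(max_redraws):
        bad = out <= floor
        if not np.any(bad):
            break
        n_trunc += int(bad.sum())
        out[bad] = rng.normal(mean[bad], sd[bad])
    np.clip(out, floor, None, out=out)
    return out, n_trunc


def simulate_cohort(config: GeneratorConfig = GeneratorConfig()) -> CohortResult:
    """Draw one cohort of internally consistent biometry records.

    Reproducible: the same config (including seed) yields a bit-identical
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    truth = config.truth()
    dd_chart = truth[("DD", "GA")]
    dmax_chart = truth[("Dmax", "GA")]

    ga = _draw_ga(rng, config)
    lo, hi = config.ga_range
    grid = np.linspace(lo, hi, 257)
    for chart in (dd_chart, dmax_chart):
        if np.any(chart.sd_model(grid) <= 0):
            raise ConfigError(
                f"truth SD model for {chart.response} non-positive in ga_range"
            )

    bpd = BPD_SLOPE * ga + BPD_INTERCEPT + rng.normal(0, config.biometry_noise_sd, config.n)
    fl = FL_SLOPE * ga + FL_INTERCEPT + rng.normal(0, config.biometry_noise_sd, config.n)

    dd, t1 = _truncated_normal(
        rng, dd_chart.mean_model(ga), dd_chart.sd_model(ga), DD_FLOOR
    )
    dmax, t2 = _truncated_normal(
        rng, dmax_chart.mean_model(ga), dmax_chart.sd_model(ga), DMAX_FLOOR_MM
    )
    dmin = dmax / (1.0 + dd)

    records = tuple(
        BiometryRecord(
            ga=float(g), dmax=float(dx), dmin=float(dn), bpd=float(b), fl=float(f)
        )
        for g, dx, dn, b, f in zip(ga, dmax, dmin, bpd, fl)
    )
    return CohortResult(
        records=records, truncation_fraction=(t1 + t2) / (2.0 * config.n)
    )


def simulate_repeatability(
    config: GeneratorConfig,
    n_subjects: int = 20,
    k: int = 2,
    target_design: Literal["intraobserver", "interobserver"] = "intraobserver",
    parameter: Response = "Dmax",
    rater_offset: float = 0.0,
) -> RepeatabilityTable:
    """A subjects × measurements table from the cohort model plus rater noise.

    Subject true values are the truth-chart mean at a random GA plus the
    chart's between-subject Gaussian spread; each of the ``k`` measurements
    adds independent N(0, measurement_noise_sd) error.  For the
    interobserver design a constant ``rater_offset`` may be added to the
    second rater's column to emulate a systematic bias.
    """
    if n_subjects < 5:
        raise ConfigError(f"need >= 5 subjects, got {n_subjects}")
    if k < 2:
        raise ConfigError(f"need >= 2 measurements, got {k}")
    rng = np.random.default_rng(config.seed)
    chart = config.truth()[(parameter, "GA")]
    lo, hi = config.ga_range
    ga = rng.uniform(lo, hi, size=n_subjects)
    true_values = rng.normal(chart.mean_model(ga), chart.sd_model(ga))
    matrix = true_values[:, None] + rng.normal(
        0, config.measurement_noise_sd, size=(n_subjects, k)
    )
    if target_design == "interobserver" and rater_offset != 0.0:
        matrix[:, 1:] += rater_offset
    return RepeatabilityTable(matrix=matrix, design=target_design)
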