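"""Intra- and inter-observer agreement via intraclass correlation.

Measurement repeatability is assessed on a subjects × measurements table.
Two single-measure ICC forms are provided, computed from the ANOVA mean
squares:

* **ICC(1,1)** — one-way random effects; appropriate when replicate
  measurements by the same observer are exchangeable (intraobserver
  design).  ICC(1,1) = (MS_B − MS_W)/(MS_B + (k − 1)·MS_W).
* **ICC(2,1)** — two-way random effects, absolute agreement; appropriate
  when columns are distinct raters and systematic rater offsets should
  count against agreement (interobserver design).
  ICC(2,1) = (MS_R − MS_E)/(MS_R + (k − 1)·MS_E + (k/n)·(MS_C − MS_E)).

Confidence intervals use the exact F-distribution bounds of McGraw & Wong.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, EmptyInputError

ICCForm = Literal["ICC_2_1_agreement", "ICC_1_1", "ICC_3_1_consistency"]


@dataclass(frozen=True)
class RepeatabilityTable:
    """Subjects (rows) × measurements (columns), no missing cells."""

    matrix: np.ndarray
    design: Literal["intraobserver", "interobserver"] = "intraobserver"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2:
            raise ValueError("matrix must be 2-D (subjects × measurements)")
        n, k = m.shape
        if k < 2:
            raise EmptyInputError(f"need >= 2 measurement columns, got {k}")
        if n < 5:
            raise EmptyInputError(f"need >= 5 subjects, got {n}")
        if not np.all(np.isfinite(m)):
            raise ValueError("matrix contains missing or non-finite cells")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_measurements(self) -> int:
        return self.matrix.shape[1]

    @property
    def default_form(self) -> ICCForm:
        return "ICC_1_1" if self.design == "intraobserver" else "ICC_2_1_agreement"


@dataclass(frozen=True)
class AnovaMeanSquares:
    """Two-way crossed ANOVA decomposition of a complete table."""

    ms_rows: float  # between-subjects
    ms_cols: float  # between-measurements/raters
    ms_error: float  # residual (interaction + error)
    ms_within: float  # one-way within-subjects (cols + error pooled)


def anova_mean_squares(matrix: np.ndarray) -> AnovaMeanSquares:
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * float(np.sum((row_means - grand) ** 2))
    ss_cols = n * float(np.sum((col_means - grand) ** 2))
    resid = m - row_means[:, None] - col_means[None, :] + grand
    ss_error = float(np.sum(resid**2))
    ss_within = float(np.sum((m - row_means[:, None]) ** 2))
    return AnovaMeanSquares(
        ms_rows=ss_rows / (n - 1),
        ms_cols=ss_cols / (k - 1),
        ms_error=ss_error / ((n - 1) * (k - 1)),
        ms_within=ss_within / (n * (k - 1)),
    )


@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_lower: float
    ci_upper: float
    form: ICCForm
    n_subjects: int
    n_measurements: int


def icc(
    table: RepeatabilityTable,
    form: ICCForm = "ICC_2_1_agreement",
    confidence: float = 0.95,
) -> ICCResult:
    """Single-measure intraclass correlation with an exact-F confidence interval.

    Rows with exactly zero within-subject spread across the whole table
    yield ICC = 1 by definition (perfect agreement), short-circuiting the
    ANOVA ratio.
    """
    m = table.matrix
    n, k = m.shape
    if np.ptp(m) == 0:
        raise DegenerateTableError("table has zero total variance")
    if float(np.max(np.ptp(m, axis=1))) == 0.0:
        # every subject measured identically: perfect agreement
        return ICCResult(1.0, 1.0, 1.0, form, n, k)
    ms = anova_mean_squares(m)
    alpha = 1.0 - confidence

    if form == "ICC_1_1":
        est = (ms.ms_rows - ms.ms_within) / (
            ms.ms_rows + (k - 1) * ms.ms_within
        )
        if ms.ms_within == 0:
            return ICCResult(1.0, 1.0, 1.0, form, n, k)
        f_obs = ms.ms_rows / ms.ms_within
        df1, df2 = n - 1, n * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (f_l - 1) / (f_l + k - 1)
        upper = (f_u - 1) / (f_u + k - 1)
    elif form == "ICC_2_1_agreement":
        denom = ms.ms_rows + (k - 1) * ms.ms_error + (k / n) * (
            ms.ms_cols - ms.ms_error
        )
        if denom == 0:
            raise DegenerateTableError("zero ANOVA denominator")
        est = (ms.ms_rows - ms.ms_error) / denom
        lower, upper = _icc_a1_ci(ms, n, k, est, alpha)
    elif form == "ICC_3_1_consistency":
        # two-way mixed, consistency: rater offsets do not count against it
        if ms.ms_error == 0:
            return ICCResult(1.0, 1.0, 1.0, form, n, k)
        est = (ms.ms_rows - ms.ms_error) / (ms.ms_rows + (k - 1) * ms.ms_error)
        f_obs = ms.ms_rows / ms.ms_error
        df1, df2 = n - 1, (n - 1) * (k - 1)
        f_l = f_obs / stats.f.ppf(1 - alpha / 2, df1, df2)
        f_u = f_obs * stats.f.ppf(1 - alpha / 2, df2, df1)
        lower = (f_l - 1) / (f_l + k - 1)
        upper = (f_u - 1) / (f_u + k - 1)
    else:
        raise ValueError(f"unknown ICC form {form!r}")

    lower = float(np.clip(lower, -1.0 / (k - 1), 1.0))
    upper = float(np.clip(upper, -1.0 / (k - 1), 1.0))
    return ICCResult(float(est), lower, upper, form, n, k)


def _icc_a1_ci(
    ms: AnovaMeanSquares, n: int, k: int, est: float, alpha: float
) -> tuple[float, float]:
    """McGraw & Wong Satterthwaite-type bounds for ICC(A,1)."""
    r = est
    if r >= 1.0:
        return 1.0, 1.0
    a = (k * r) / (n * (1 - r))
    b = 1 + (k * r * (n - 1)) / (n * (1 - r))
    num = (a * ms.ms_cols + b * ms.ms_error) ** 2
    den = (a * ms.ms_cols) ** 2 / (k - 1) + (b * ms.ms_error) ** 2 / (
        (n - 1) * (k - 1)
    )
    nu = num / den if den > 0 else (n - 1) * (k - 1)
    f_star = stats.f.ppf(1 - alpha / 2, n - 1, nu)
    f_star2 = stats.f.ppf(1 - alpha / 2, nu, n - 1)
    common = k * ms.ms_cols + (k * n - k - n) * ms.ms_error
    lower = n * (ms.ms_rows - f_star * ms.ms_error) / (
        f_star * common + n * ms.ms_rows
    )
    upper = n * (f_star2 * ms.ms_rows - ms.ms_error) / (
        common + n * f_star2 * ms.ms_rows
    )
    return lower, upper


@dataclass(frozen=True)
class ReportCell:
    parameter: str
    design: str
    result: ICCResult | None
    error: str | None = None


def repeatability_report(
    tables: Mapping[tuple[str, str], RepeatabilityTable],
    form_by_design: Mapping[str, ICCForm] | None = None,
) -> list[ReportCell]:
    """ICC estimates for a grid of (design, parameter) tables.

    Mirrors the conventional repeatability-table layout: intraobserver and
    interobserver consistency for each measured parameter.  A failing cell
    carries its error message without aborting the rest.
    """
    forms = {
        "intraobserver": "ICC_1_1",
        "interobserver": "ICC_2_1_agreement",
    }
    if form_by_design:
        forms.update(form_by_design)
    cells: list[ReportCell] = []
    for (design, parameter), table in tables.items():
        try:
            if not isinstance(table, RepeatabilityTable):
                kind = design if design in ("intraobserver", "interobserver") else "intraobserver"
                table = RepeatabilityTable(np.atleast_2d(np.asarray(table, dtype=float)), design=kind)
            res = icc(table, form=forms.get(design, "ICC_2_1_agreement"))
            cells.append(ReportCell(parameter, design, res))
        except Exception as exc:  # partial-failure contract
            cells.append(ReportCell(parameter, design, None, error=str(exc)))
    return cells
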