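"""Calibration fitting, bioanalytical validation verdicts, and comparison statistics.

A graded series of a reference reductant (e.g. sodium thiosulfate or
ascorbic acid, 0.01-0.1 M, 5-6 replicate spots per level) is fitted by
ordinary least squares of integrated density on nominal concentration.
Validation follows the structure of bioanalytical method-validation
guidance:

* **accuracy**: per-level back-calculated mean concentration as a percent
  of nominal, accepted within +/-15% (+/-20% at the lowest level, the LLOQ);
* **precision**: per-level coefficient of variation (n-1 sample SD / mean),
  accepted at <= 15% (<= 20% at the lowest level);
* **linearity**: calibration R^2 at or above a configurable cutoff
  (default 0.98).

The module also provides the two comparison statistics used to benchmark
the assay: OLS R^2 with a slope p-value for method-vs-method agreement
(e.g. against a redox microelectrode), and the two-sided Wilcoxon rank-sum
(Mann-Whitney) test for two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DataError, DegenerateModelError, InsufficientDataError

__all__ = [
    "CalibrationSeries",
    "CalibrationModel",
    "ValidationThresholds",
    "ValidationReport",
    "fit_calibration",
    "back_calculate",
    "validate_method",
    "cv_percent",
    "compare_methods",
    "compare_groups",
]


@dataclass(frozen=True)
class CalibrationSeries:
    """Graded-concentration replicates: [(nominal mol/L, [densities...]), ...].

    Nominal concentrations must be positive and strictly increasing. At
    least 3 distinct levels are needed for a linearity assessment and at
    least 2 replicates per level for a CV.
    """

    levels: tuple[tuple[float, tuple[float, ...]], ...]
    analyte: str = ""

    def __post_init__(self) -> None:
        lv = tuple((float(c), tuple(float(x) for x in reps)) for c, reps in self.levels)
        concs = [c for c, _ in lv]
        if any(c <= 0 for c in concs):
            raise DataError("nominal concentrations must be > 0")
        if any(b <= a for a, b in zip(concs, concs[1:])):
            raise DataError("nominal concentrations must be strictly increasing")
        if any(len(reps) == 0 for _, reps in lv):
            raise DataError("every level needs at least one replicate")
        object.__setattr__(self, "levels", lv)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([c for c, _ in self.levels])

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """All (concentration, density) pairs, replicates expanded."""
        x, y = [], []
        for c, reps in self.levels:
            x.extend([c] * len(reps))
            y.extend(reps)
        return np.asarray(x), np.asarray(y)


@dataclass(frozen=True)
class CalibrationModel:
    """OLS calibration line: density = slope * concentration + intercept."""

    slope: float
    intercept: float
    r_squared: float
    residual_sd: float
    n_obs: int

    def predict(self, concentration):
        return self.slope * np.asarray(concentration) + self.intercept


@dataclass(frozen=True)
class ValidationThresholds:
    """Acceptance cutoffs for the validation verdicts (all overridable)."""

    accuracy_tol: float = 0.15        # +/-15% of nominal
    accuracy_tol_lloq: float = 0.20   # +/-20% at the lowest level
    cv_max: float = 15.0              # percent
    cv_max_lloq: float = 20.0
    r_squared_min: float = 0.98


@dataclass(frozen=True)
class ValidationReport:
    """Per-level accuracy/CV with pass/fail verdicts against the thresholds."""

    nominal: tuple[float, ...]
    accuracy_percent: tuple[float, ...]
    cv_percent: tuple[float | None, ...]
    r_squared: float
    pass_accuracy: bool
    pass_precision: bool
    pass_linearity: bool
    thresholds: ValidationThresholds
    failed_accuracy_levels: tuple[float, ...] = ()
    failed_precision_levels: tuple[float, ...] = ()
    flags: tuple[str, ...] = ()

    def summary(self) -> str:
        """Human-readable validation table."""
        lines = [
            f"{'nominal':>10}  {'accuracy%':>10}  {'CV%':>8}",
        ]
        for c, acc, cv in zip(self.nominal, self.accuracy_percent, self.cv_percent):
            cv_s = f"{cv:8.2f}" if cv is not None else "     n/a"
            lines.append(f"{c:10.4g}  {acc:10.2f}  {cv_s}")
        lines.append(f"R^2 = {self.r_squared:.5f}")
        lines.append(f"accuracy: {'PASS' if self.pass_accuracy else 'FAIL'}  "
                     f"precision: {'PASS' if self.pass_precision else 'FAIL'}  "
                     f"linearity: {'PASS' if self.pass_linearity else 'FAIL'}")
        return "\n".join(lines)


def fit_calibration(series: CalibrationSeries) -> CalibrationModel:
    """Unweighted OLS of integrated density on nominal concentration.

    All replicates enter individually. Requires >= 3 distinct levels.
    """
    if len(series.levels) < 3:
        raise InsufficientDataError("calibration needs >= 3 distinct concentration levels")
    x, y = series.flat()
    res = stats.linregress(x, y)
    pred = res.slope * x + res.intercept
    resid = y - pred
    dof = max(len(x) - 2, 1)
    residual_sd = float(np.sqrt((resid**2).sum() / dof))
    ss_tot = float(((y - y.mean()) ** 2).sum())
    # constant response: nothing to explain, R^2 reported as 0
    r2 = 0.0 if ss_tot == 0 else float(res.rvalue**2)
    return CalibrationModel(slope=float(res.slope), intercept=float(res.intercept),
                            r_squared=r2, residual_sd=residual_sd, n_obs=len(x))


def back_calculate(model: CalibrationModel, density) -> float | np.ndarray:
    """Invert the calibration line: concentration = (density - intercept) / slope."""
    if model.slope == 0:
        raise DegenerateModelError("cannot back-calculate with zero slope")
    out = (np.asarray(density, dtype=np.float64) - model.intercept) / model.slope
    return float(out) if out.ndim == 0 else out


def cv_percent(replicates) -> float:
    """Coefficient of variation in percent: 100 * sample SD (n-1) / mean."""
    reps = np.asarray(replicates, dtype=np.float64)
    if reps.size < 2:
        raise InsufficientDataError("CV needs at least 2 replicates")
    mean = reps.mean()
    if mean == 0:
        raise DegenerateModelError("CV undefined for zero mean")
    return float(100.0 * reps.std(ddof=1) / mean)


def validate_method(
    series: CalibrationSeries,
    thresholds: ValidationThresholds | None = None,
) -> ValidationReport:
    """Full validation verdict: per-level accuracy and CV plus linearity.

    Accuracy at each level is the back-calculated mean density expressed as
    a percent of the nominal concentration. The lowest level plays the LLOQ
    role and receives the wider tolerance. Levels with a single replicate
    get no CV; their precision verdict is withheld (flagged) rather than
    failed.
    """
    thr = thresholds or ValidationThresholds()
    model = fit_calibration(series)

    nominal, acc, cvs = [], [], []
    flags: list[str] = []
    failed_acc, failed_prec = [], []
    for i, (c, reps) in enumerate(series.levels):
        reps_arr = np.asarray(reps, dtype=np.float64)
        back = back_calculate(model, reps_arr.mean())
        a = 100.0 * back / c
        tol = thr.accuracy_tol_lloq if i == 0 else thr.accuracy_tol
        if abs(a - 100.0) > 100.0 * tol:
            failed_acc.append(c)
        if len(reps) >= 2:
            cv = cv_percent(reps_arr)
            cv_max = thr.cv_max_lloq if i == 0 else thr.cv_max
            if cv > cv_max:
                failed_prec.append(c)
        else:
            cv = None
            flags.append(f"single_replicate_level:{c:g}")
        nominal.append(c)
        acc.append(float(a))
        cvs.append(cv)

    return ValidationReport(
        nominal=tuple(nominal),
        accuracy_percent=tuple(acc),
        cv_percent=tuple(cvs),
        r_squared=model.r_squared,
        pass_accuracy=not failed_acc,
        pass_precision=not failed_prec,
        pass_linearity=model.r_squared >= thr.r_squared_min,
        thresholds=thr,
        failed_accuracy_levels=tuple(failed_acc),
        failed_precision_levels=tuple(failed_prec),
        flags=tuple(flags),
    )


def compare_methods(x, y) -> tuple[float, float]:
    """Method-vs-method agreement: OLS of y on x.

    Returns (R^2, two-sided p-value for zero slope). Used to benchmark the
    membrane readout against an independent measurement of the same samples
    (e.g. a platinum redox microelectrode).
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 3:
        raise InsufficientDataError("compare_methods needs equal-length vectors, n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("inputs must be finite")
    if np.ptp(x) == 0:
        raise DegenerateModelError("x has zero variance")
    res = stats.linregress(x, y)
    return float(res.rvalue**2), float(res.pvalue)


def compare_groups(a, b) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when the combined sample is small (n <= 20) and
    the tie-corrected normal approximation otherwise. Returns
    (U statistic of the first group, two-sided p, method used).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    method = "exact" if a.size + b.size <= 20 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue), method
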