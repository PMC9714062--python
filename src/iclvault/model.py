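"""Vault prediction formula, ICL size selection and outcome classification.

The EVO implantable collamer lens (ICL) is manufactured in four overall
lengths (12.1, 12.6, 13.2 and 13.7 mm).  Postoperative *vault* — the
clearance in μm between the back surface of the implant and the front
surface of the crystalline lens — is the safety-critical outcome of size
selection: too little vault risks anterior subcapsular cataract and lens
rotation, too much risks angle closure and pigment dispersion.

This module implements a published linear predictor of central vault from
ultrasound-biomicroscopy (UBM) biometry,

    vault (μm) = -1369.05 + 657.121·size - 287.408·STS_h
                 - 432.497·LT - 137.33·STS_v

where ``size`` is the ICL length (mm), ``STS_h``/``STS_v`` the horizontal
and vertical sulcus-to-sulcus diameters (mm) and ``LT`` the crystalline
lens thickness (mm), together with the clinical decision rule built on it:
choose the size whose predicted vault falls in a target window (default
300–700 μm), classify achieved vaults as low/normal/high, and flag eyes
whose prediction missed by more than 300 μm in either direction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "UBM_FEATURES",
    "ICL_SIZES",
    "ModelCoefficients",
    "DEFAULT_COEFFICIENTS",
    "TargetWindow",
    "BiometryRecord",
    "SizingResult",
    "ValidationRecord",
    "predict_vault",
    "vault_step",
    "select_icl_size",
    "classify_vault",
    "assign_error_group",
    "round_half_away",
]

#: UBM features recorded as booleans; geometry of their definition is out of
#: scope here (they arrive as flags from the reading clinician).
UBM_FEATURES = (
    "wide_ica",
    "iris_concavity",
    "anterior_ciliary_body",
    "ciliary_body_cyst",
)

#: The four manufactured ICL lengths, mm, ascending.
ICL_SIZES = (12.1, 12.6, 13.2, 13.7)

# Plausibility ranges for biometry; violations raise, never clamp.
_STS_RANGE = (8.0, 16.0)
_LT_RANGE = (2.5, 6.0)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting convention)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


@dataclass(frozen=True)
class ModelCoefficients:
    """Coefficients of the linear vault predictor (μm, μm/mm).

    Defaults are the published values; override only through explicit
    construction (e.g. for sensitivity studies or refit comparisons).
    """

    intercept: float = -1369.05
    coef_size: float = 657.121
    coef_sts_h: float = -287.408
    coef_lt: float = -432.497
    coef_sts_v: float = -137.33

    def as_tuple(self) -> tuple[float, float, float, float, float]:
        return (
            self.intercept,
            self.coef_size,
            self.coef_sts_h,
            self.coef_lt,
            self.coef_sts_v,
        )


DEFAULT_COEFFICIENTS = ModelCoefficients()


@dataclass(frozen=True)
class TargetWindow:
    """Acceptable predicted-vault interval [low, high] with a preference center.

    The study targeted 300–700 μm.  When several sizes land in the window
    the one predicting nearest ``center`` is preferred (ties broken toward
    the smaller size, since excess vault drives the severest complications).
    """

    low: float = 300.0
    high: float = 700.0
    center: float = 500.0

    def __post_init__(self) -> None:
        if not self.low < self.center < self.high:
            raise ValueError(
                f"require low < center < high, got ({self.low}, {self.center}, {self.high})"
            )

    def contains(self, vault: float) -> bool:
        return self.low <= vault <= self.high

    def distance(self, vault: float) -> float:
        """Distance from ``vault`` to the window (0 inside)."""
        return max(self.low - vault, vault - self.high, 0.0)


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo < value < hi:
        raise ValueError(f"{name}={value!r} outside plausible range ({lo}, {hi}) mm")


@dataclass(frozen=True)
class BiometryRecord:
    """One eye's preoperative measurements.

    ``sts_horizontal``/``sts_vertical``: sulcus-to-sulcus diameters, mm.
    ``lens_thickness``: crystalline lens thickness, mm.  ``acd`` (anterior
    chamber depth) and ``wtw`` (white-to-white) are informational and do not
    enter the formula.  ``ubm_features`` is a (possibly empty) subset of
    :data:`UBM_FEATURES`.
    """

    sts_horizontal: float
    sts_vertical: float
    lens_thickness: float
    acd: float | None = None
    wtw: float | None = None
    ubm_features: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        _check_range("sts_horizontal", self.sts_horizontal, *_STS_RANGE)
        _check_range("sts_vertical", self.sts_vertical, *_STS_RANGE)
        _check_range("lens_thickness", self.lens_thickness, *_LT_RANGE)
        object.__setattr__(self, "ubm_features", frozenset(self.ubm_features))
        unknown = self.ubm_features - set(UBM_FEATURES)
        if unknown:
            raise ValueError(f"unknown UBM features: {sorted(unknown)}")


def _validate_size(size: float) -> float:
    for s in ICL_SIZES:
        if math.isclose(size, s, abs_tol=1e-9):
            return s
    raise ValueError(f"ICL size must be one of {ICL_SIZES}, got {size!r}")


def predict_vault(
    record: BiometryRecord,
    size: float,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> float:
    """Predicted central vault in μm for ``record`` at ICL length ``size`` (mm).

    Pure linear evaluation; the result is unrounded and may be negative
    (no clamping at this layer).
    """
    size = _validate_size(size)
    return (
        coeffs.intercept
        + coeffs.coef_size * size
        + coeffs.coef_sts_h * record.sts_horizontal
        + coeffs.coef_lt * record.lens_thickness
        + coeffs.coef_sts_v * record.sts_vertical
    )


def vault_step(
    size_from: float,
    size_to: float,
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
) -> int:
    """Change in predicted vault (integer μm) when switching ICL length.

    Depends only on the size coefficient: 12.1→12.6 gives +329 μm and
    12.6→13.2 gives +394 μm under the default coefficients.  Antisymmetric.
    """
    size_from = _validate_size(size_from)
    size_to = _validate_size(size_to)
    return round_half_away(coeffs.coef_size * (size_to - size_from))


@dataclass(frozen=True)
class SizingResult:
    """Outcome of size selection for one eye.

    ``predictions`` maps every manufactured size to its (unrounded)
    predicted vault; ``selected`` is the chosen size, ``in_window`` whether
    its prediction lies in the target window, and ``adjusted_for_feature``
    whether the anterior-ciliary-body downsizing preference changed the
    default choice.
    """

    predictions: Mapping[float, float]
    selected: float
    selected_prediction: float
    in_window: bool
    adjusted_for_feature: bool = False


def select_icl_size(
    record: BiometryRecord,
    window: TargetWindow = TargetWindow(),
    coeffs: ModelCoefficients = DEFAULT_COEFFICIENTS,
    apply_feature_adjustment: bool = False,
) -> SizingResult:
    """Choose an ICL length for ``record`` against ``window``.

    Evaluates the predictor at all four sizes.  Among sizes predicting
    inside the window, the one nearest ``window.center`` wins (tie → the
    smaller size).  If no size is feasible the boundary-nearest size is
    returned with ``in_window=False`` — infeasibility is a flagged result,
    not an error, so cohort pipelines can count exclusions.

    With ``apply_feature_adjustment`` and an anteriorly positioned ciliary
    body (a feature associated with higher-than-predicted vaults), the
    smallest feasible size is preferred over the default choice.
    """
    predictions = {s: predict_vault(record, s, coeffs) for s in ICL_SIZES}
    feasible = [s for s in ICL_SIZES if window.contains(predictions[s])]

    adjusted = False
    if feasible:
        selected = min(feasible, key=lambda s: (abs(predictions[s] - window.center), s))
        if (
            apply_feature_adjustment
            and "anterior_ciliary_body" in record.ubm_features
            and min(feasible) < selected
        ):
            selected = min(feasible)
            adjusted = True
        in_window = True
    else:
        selected = min(ICL_SIZES, key=lambda s: (window.distance(predictions[s]), s))
        in_window = False

    return SizingResult(
        predictions=predictions,
        selected=selected,
        selected_prediction=predictions[selected],
        in_window=in_window,
        adjusted_for_feature=adjusted,
    )


def classify_vault(actual_vault: float) -> str:
    """Classify an achieved vault (μm) as ``low`` (<200), ``normal``
    (200–800) or ``high`` (>800).

    Real-valued generalisation of the clinical integer bands 0–199 /
    200–800 / ≥801 μm.
    """
    if not math.isfinite(actual_vault) or actual_vault < 0:
        raise ValueError(f"actual vault must be finite and >= 0, got {actual_vault!r}")
    if actual_vault < 200:
        return "low"
    if actual_vault <= 800:
        return "normal"
    return "high"


def assign_error_group(error: float) -> str:
    """Bucket a prediction error (actual − predicted, μm) at the ±300 μm
    threshold: ``overestimated`` (< −300), ``underestimated`` (> +300),
    else ``within``.  Both inequalities are strict.
    """
    if not math.isfinite(error):
        raise ValueError(f"error must be finite, got {error!r}")
    if error < -300:
        return "overestimated"
    if error > 300:
        return "underestimated"
    return "within"


@dataclass(frozen=True)
class ValidationRecord:
    """Predicted vs achieved vault for one eye in a validation run."""

    predicted_vault: float
    actual_vault: float
    stratum: object = None
    category: str = field(init=False)
    error: float = field(init=False)
    error_group: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "category", classify_vault(self.actual_vault))
        object.__setattr__(self, "error", self.actual_vault - self.predicted_vault)
        object.__setattr__(self, "error_group", assign_error_group(self.error))
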