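"""End-to-end validation pipeline: load/generate → size → validate → report.

Mirrors the clinical validation workflow: each eye's vault is predicted at
its implanted (or rule-selected) ICL size, the achieved vault is classified
against the 200–800 μm normal band, the prediction error is bucketed at
±300 μm, and four report tables are produced — per-season vault summaries,
the category distribution, Bland–Altman agreement, and the UBM-feature
comparison between large-error groups.

Eyes-within-subject clustering is ignored in all statistics (eyes are the
analysis unit, as in the validation study); this is recorded in the report
metadata as a known limitation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import bland_altman, bland_altman_plot, distribution_table, summarize_vaults
from .cohort import BIOMETRY_COLUMNS, CohortSpec, generate_cohort
from .contingency import compare_features
from .model import (
    DEFAULT_COEFFICIENTS,
    ICL_SIZES,
    UBM_FEATURES,
    BiometryRecord,
    ModelCoefficients,
    TargetWindow,
    assign_error_group,
    classify_vault,
    predict_vault,
    select_icl_size,
)

__all__ = [
    "RunConfig",
    "ValidationReport",
    "read_biometry",
    "size_cohort",
    "run_validation",
    "season_of",
]

log = logging.getLogger("iclvault")

_STUDY_SPAN = (pd.Timestamp("2020-07-01"), pd.Timestamp("2021-06-30"))
# month → season stratum; the study year ran Jul→Jun.
_MONTH_SEASON = {7: 1, 8: 1, 9: 1, 10: 2, 11: 2, 12: 2, 1: 3, 2: 3, 3: 3, 4: 4, 5: 4, 6: 4}

_REQUIRED_COLUMNS = ("sts_horizontal_mm", "sts_vertical_mm", "lens_thickness_mm")


def season_of(date) -> int:
    """Map a date to its three-month season stratum (1–4).

    The study year ran July 2020 – June 2021 in four consecutive seasons;
    dates outside that span fall back to the same month→season mapping
    (Jul–Sep → 1, …, Apr–Jun → 4) with a warning.
    """
    try:
        ts = pd.Timestamp(date)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable date {date!r}") from exc
    if pd.isna(ts):
        raise ValueError(f"unparseable date {date!r}")
    if not _STUDY_SPAN[0] <= ts <= _STUDY_SPAN[1]:
        warnings.warn(
            f"date {ts.date()} outside the study span; using quarter-of-year mapping",
            stacklevel=2,
        )
    return _MONTH_SEASON[ts.month]


@dataclass
class RunConfig:
    """One validation run: exactly one of ``input_path`` / ``cohort_spec``."""

    input_path: str | Path | None = None
    cohort_spec: CohortSpec | None = None
    window: TargetWindow = field(default_factory=TargetWindow)
    coefficients: ModelCoefficients = DEFAULT_COEFFICIENTS
    stratify_by: str = "season"
    out_dir: str | Path | None = None
    seed: int = 0
    apply_feature_adjustment: bool = False
    make_plots: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.cohort_spec is None):
            raise ValueError("provide exactly one of input_path or cohort_spec")

    def digest(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        blob = repr(dataclasses.asdict(self)).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def read_biometry(path: str | Path) -> pd.DataFrame:
    """Read a cohort file (CSV, header row, units fixed by column name).

    Checks required columns and per-row biometry ranges; bad rows are
    dropped with a logged diagnostic naming the row number.  Raises if no
    row survives.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    bad: list[int] = []
    for i, row in df.iterrows():
        try:
            BiometryRecord(
                sts_horizontal=float(row["sts_horizontal_mm"]),
                sts_vertical=float(row["sts_vertical_mm"]),
                lens_thickness=float(row["lens_thickness_mm"]),
            )
        except (ValueError, TypeError) as exc:
            log.warning("row %d dropped: %s", i, exc)
            bad.append(i)
    if bad:
        df = df.drop(index=bad).reset_index(drop=True)
    if df.empty:
        raise ValueError(f"{path}: no valid rows")
    log.info("read %d valid rows (%d dropped) from %s", len(df), len(bad), path)
    return df


def _record_from_row(row: pd.Series) -> BiometryRecord:
    feats = frozenset(f for f in UBM_FEATURES if f in row.index and bool(row[f]))
    return BiometryRecord(
        sts_horizontal=float(row["sts_horizontal_mm"]),
        sts_vertical=float(row["sts_vertical_mm"]),
        lens_thickness=float(row["lens_thickness_mm"]),
        acd=float(row["acd_mm"]) if "acd_mm" in row.index and pd.notna(row["acd_mm"]) else None,
        wtw=float(row["wtw_mm"]) if "wtw_mm" in row.index and pd.notna(row["wtw_mm"]) else None,
        ubm_features=feats,
    )


def size_cohort(
    df: pd.DataFrame,
    window: TargetWindow = TargetWindow(),
    coefficients: ModelCoefficients = DEFAULT_COEFFICIENTS,
    apply_feature_adjustment: bool = False,
) -> pd.DataFrame:
    """Append per-size predictions and the selected size to a cohort frame.

    Adds ``pred_vault_12_1`` … ``pred_vault_13_7``, ``selected_size_mm``,
    ``selected_pred_um``, ``in_window`` and ``adjusted_for_feature``.  When
    an ``icl_size_mm`` column records the implanted size, ``predicted_vault``
    is evaluated at that size; otherwise at the selected one.
    """
    out = df.copy()
    cols: dict[str, list] = {f"pred_vault_{str(s).replace('.', '_')}": [] for s in ICL_SIZES}
    sel, sel_pred, in_win, adj, pred_at_implant = [], [], [], [], []
    n_negative = 0
    for _, row in out.iterrows():
        rec = _record_from_row(row)
        res = select_icl_size(rec, window, coefficients, apply_feature_adjustment)
        for s in ICL_SIZES:
            cols[f"pred_vault_{str(s).replace('.', '_')}"].append(res.predictions[s])
        sel.append(res.selected)
        sel_pred.append(res.selected_prediction)
        in_win.append(res.in_window)
        adj.append(res.adjusted_for_feature)
        if any(p < 0 for p in res.predictions.values()):
            n_negative += 1
        if "icl_size_mm" in row.index and pd.notna(row["icl_size_mm"]):
            pred_at_implant.append(predict_vault(rec, float(row["icl_size_mm"]), coefficients))
        else:
            pred_at_implant.append(res.selected_prediction)
    for name, vals in cols.items():
        out[name] = vals
    out["selected_size_mm"] = sel
    out["selected_pred_um"] = sel_pred
    out["in_window"] = in_win
    out["adjusted_for_feature"] = adj
    out["predicted_vault"] = pred_at_implant
    if n_negative:
        log.warning("%d eyes had a negative predicted vault at some size", n_negative)
    n_out = int((~np.asarray(in_win)).sum())
    if n_out:
        log.warning("%d eyes infeasible for the %s–%s μm window", n_out, window.low, window.high)
    return out


@dataclass
class ValidationReport:
    """All report tables plus run provenance.

    ``agreement``/``features`` are None when the input carries no achieved
    vaults (sizing-only degraded mode) or, for ``features``, when a
    large-error group is empty.
    """

    sizing: pd.DataFrame
    summary: pd.DataFrame | None
    distribution: pd.DataFrame | None
    agreement: pd.DataFrame | None
    features: pd.DataFrame | None
    metadata: dict

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.sizing.to_csv(out / "sizing.csv", index=False)
        for name in ("summary", "distribution", "agreement", "features"):
            tbl = getattr(self, name)
            if tbl is not None:
                tbl.to_csv(out / f"{name}.csv", index=False)
        (out / "metadata.json").write_text(json.dumps(self.metadata, indent=2, sort_keys=True))


def _agreement_table(df: pd.DataFrame, stratum_key: str) -> pd.DataFrame:
    rows = []
    groups = [(label, g) for label, g in df.groupby(stratum_key, sort=True)]
    groups.append(("overall", df))
    for label, g in groups:
        if len(g) < 2:
            log.warning("stratum %r has %d eye(s); agreement row skipped", label, len(g))
            continue
        s = bland_altman(g["actual_vault_um"], g["predicted_vault"])
        rows.append(
            {
                "stratum": label,
                "n": s.n,
                "mean_diff": s.mean_diff,
                "sd_diff": s.sd_diff,
                "min_diff": s.diff_range[0],
                "max_diff": s.diff_range[1],
                "q25": s.quartiles[0],
                "q75": s.quartiles[1],
                "ci95_low": s.ci95[0],
                "ci95_high": s.ci95[1],
                "loa95_low": s.loa95[0],
                "loa95_high": s.loa95[1],
            }
        )
    return pd.DataFrame(rows)


def run_validation(config: RunConfig) -> ValidationReport:
    """Execute a full validation run and return its report.

    Deterministic given the configuration: the input file or the cohort
    spec (with its seed) fully determines every reported number.
    """
    if config.cohort_spec is not None:
        spec = dataclasses.replace(config.cohort_spec, seed=config.seed)
        df = generate_cohort(spec)
        source = f"synthetic(n={spec.n_eyes}, seed={spec.seed})"
    else:
        df = read_biometry(config.input_path)
        source = str(config.input_path)

    sized = size_cohort(
        df, config.window, config.coefficients, config.apply_feature_adjustment
    )
    stratum_key = config.stratify_by
    if stratum_key not in sized.columns:
        sized[stratum_key] = 1

    has_actual = "actual_vault_um" in sized.columns and sized["actual_vault_um"].notna().all()
    summary = distribution = agreement = features = None
    if has_actual:
        sized["category"] = sized["actual_vault_um"].map(classify_vault)
        sized["error"] = sized["actual_vault_um"] - sized["predicted_vault"]
        sized["error_group"] = sized["error"].map(assign_error_group)

        frame = sized.rename(columns={"actual_vault_um": "actual_vault"})
        summary = summarize_vaults(frame, stratum_key)
        distribution = distribution_table(frame, stratum_key)
        agreement = _agreement_table(sized, stratum_key)
        have_features = all(f in sized.columns for f in UBM_FEATURES)
        groups = sized["error_group"].value_counts()
        if have_features and groups.get("overestimated", 0) and groups.get("underestimated", 0):
            features = compare_features(sized)
        else:
            log.info("feature comparison skipped: missing features or an empty error group")
        if config.make_plots and config.out_dir is not None:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            for label, g in sized.groupby(stratum_key, sort=True):
                bland_altman_plot(
                    g["actual_vault_um"],
                    g["predicted_vault"],
                    out / f"bland_altman_{label}.png",
                    title=f"{stratum_key}={label}",
                )
            bland_altman_plot(
                sized["actual_vault_um"], sized["predicted_vault"],
                out / "bland_altman_overall.png", title="overall",
            )
    else:
        log.info("no complete actual_vault_um column: sizing-only report")

    metadata = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.digest(),
        "source": source,
        "n_eyes": int(len(sized)),
        "stratify_by": stratum_key,
        "sections_absent": [
            name
            for name, tbl in (
                ("summary", summary),
                ("distribution", distribution),
                ("agreement", agreement),
                ("features", features),
            )
            if tbl is None
        ],
        "limitations": [
            "eyes-within-subject clustering is ignored; eyes are treated as independent"
        ],
    }
    report = ValidationReport(
        sizing=sized,
        summary=summary,
        distribution=distribution,
        agreement=agreement,
        features=features,
        metadata=metadata,
    )
    if config.out_dir is not None:
        report.write(config.out_dir)
    return report
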