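"""Bland–Altman agreement statistics and stratified vault summary tables.

Agreement between predicted and achieved vault is assessed the standard
way for two measurements of the same quantity: the per-eye difference
d = actual − predicted is summarised by its mean, SD, 95% confidence
interval of the mean, and 95% limits of agreement mean ± 1.96·SD.  The
z multiplier (1.96) is used for both intervals, consistent with the LoA
definition; with strata of n ≈ 200+ the z/t distinction is below printed
precision anyway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "AgreementSummary",
    "bland_altman",
    "summarize_vaults",
    "distribution_table",
    "bland_altman_plot",
]

_Z95 = 1.96

CATEGORIES = ("low", "normal", "high")


@dataclass(frozen=True)
class AgreementSummary:
    """Agreement between two paired vault series (all fields in μm)."""

    n: int
    mean_diff: float
    sd_diff: float
    diff_range: tuple[float, float]
    quartiles: tuple[float, float]
    ci95: tuple[float, float]
    loa95: tuple[float, float]


def _as_series(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def bland_altman(actual, predicted) -> AgreementSummary:
    """Bland–Altman summary of ``actual - predicted`` (μm).

    SD uses the sample (n−1) denominator; quartiles use linear
    interpolation between order statistics; ci95 = mean ± 1.96·SD/√n and
    loa95 = mean ± 1.96·SD.

    Raises ``ValueError`` on length mismatch or n < 2.
    """
    a = _as_series(actual, "actual")
    p = _as_series(predicted, "predicted")
    if a.size != p.size:
        raise ValueError(f"length mismatch: {a.size} actual vs {p.size} predicted")
    if a.size < 2:
        raise ValueError(f"need at least 2 pairs, got {a.size}")

    d = a - p
    n = d.size
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    q25, q75 = np.percentile(d, [25, 75])  # linear interpolation
    half_loa = _Z95 * sd
    half_ci = _Z95 * sd / np.sqrt(n)
    return AgreementSummary(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        diff_range=(float(np.min(d)), float(np.max(d))),
        quartiles=(float(q25), float(q75)),
        ci95=(mean - half_ci, mean + half_ci),
        loa95=(mean - half_loa, mean + half_loa),
    )


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")


def summarize_vaults(records: pd.DataFrame, stratum_key: str = "season") -> pd.DataFrame:
    """Per-stratum and overall mean ± SD and range of predicted and actual vault.

    ``records`` needs columns ``predicted_vault``, ``actual_vault`` and
    ``stratum_key``.  The overall row pools all eyes (it is not an average
    of stratum rows).
    """
    _require_columns(records, ("predicted_vault", "actual_vault", stratum_key))
    if records.empty:
        raise ValueError("no records to summarize")

    def row(df: pd.DataFrame, label) -> dict:
        out: dict = {"stratum": label, "n": len(df)}
        for col, tag in (("predicted_vault", "predicted"), ("actual_vault", "actual")):
            v = df[col].to_numpy(float)
            out[f"{tag}_mean"] = float(np.mean(v))
            out[f"{tag}_sd"] = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
            out[f"{tag}_min"] = float(np.min(v))
            out[f"{tag}_max"] = float(np.max(v))
        return out

    rows = [row(g, label) for label, g in records.groupby(stratum_key, sort=True)]
    rows.append(row(records, "overall"))
    return pd.DataFrame(rows)


def distribution_table(records: pd.DataFrame, stratum_key: str = "season") -> pd.DataFrame:
    """Counts and percentages of low/normal/high vault per stratum and overall.

    Percentages are 100·count/stratum_n rounded to 2 decimals; the overall
    column sums the stratum counts.
    """
    _require_columns(records, ("category", stratum_key))

    def row(df: pd.DataFrame, label) -> dict:
        n = len(df)
        counts = df["category"].value_counts()
        out: dict = {"stratum": label, "n": n}
        for cat in CATEGORIES:
            c = int(counts.get(cat, 0))
            out[f"{cat}_count"] = c
            out[f"{cat}_pct"] = round(100.0 * c / n, 2) if n else float("nan")
        return out

    rows = [row(g, label) for label, g in records.groupby(stratum_key, sort=True)]
    rows.append(row(records, "overall"))
    return pd.DataFrame(rows)


def bland_altman_plot(actual, predicted, path, title: str | None = None) -> None:
    """Write a Bland–Altman scatter (difference vs pairwise mean) to ``path``.

    Dotted line at the mean difference, dashed lines at the 95% limits of
    agreement.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a = _as_series(actual, "actual")
    p = _as_series(predicted, "predicted")
    summ = bland_altman(a, p)

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + p) / 2, a - p, s=8, alpha=0.5, color="tab:blue")
    ax.axhline(summ.mean_diff, linestyle=":", color="k")
    for lim in summ.loa95:
        ax.axhline(lim, linestyle="--", color="k")
    ax.set_xlabel("mean of actual and predicted vault (μm)")
    ax.set_ylabel("actual − predicted vault (μm)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
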