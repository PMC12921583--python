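"""Per-particle feature table assembly and interquartile-range outlier removal.

One row per trapped particle, built from the Lorentzian fit reports: the
three peak fits (amplitude A, centre frequency, width), the detector
conversion factor, the per-peak radius estimates and the mass, plus the
class label. Silica nanoparticle batches have considerable size dispersion,
so rows whose value in ANY numeric column lies more than 1.5 interquartile
ranges from that column's median are screened out before embedding and
classification.
"""

from __future__ import annotations

import json
import logging
import warnings

import numpy as np
import pandas as pd

from .spectral import PEAK_LABELS, FitReport

__all__ = ["FEATURE_COLUMNS", "LABEL_COLUMN", "assemble", "remove_outliers",
           "save_feature_table"]

logger = logging.getLogger(__name__)

LABEL_COLUMN = "label"

#: Deterministic column order of the numeric features.
FEATURE_COLUMNS = (
    "f1_A", "f1_freq_hz", "f1_width_hz",
    "f2_A", "f2_freq_hz", "f2_width_hz",
    "f3_A", "f3_freq_hz", "f3_width_hz",
    "gamma_v_per_m",
    "radius_f1_m", "radius_f2_m", "radius_f3_m",
    "mass_kg",
)


def assemble(fit_reports: list[FitReport]) -> pd.DataFrame:
    """Build the feature table from fit reports, one row per particle.

    Reports without three converged peak fits (or without derived
    calibration quantities) are excluded; the exclusion count and reasons
    are logged.
    """
    rows = []
    excluded = 0
    for i, report in enumerate(fit_reports):
        if not report.converged:
            excluded += 1
            missing = [lb for lb in PEAK_LABELS if lb not in report.peaks]
            bad = [lb for lb, p in report.peaks.items() if not p.converged]
            logger.info(
                "report %d excluded: missing=%s unconverged=%s failure=%s",
                i, missing, bad, report.metadata.get("failure", ""),
            )
            continue
        row = {}
        for lb in PEAK_LABELS:
            pk = report.peaks[lb]
            row[f"{lb}_A"] = pk.A
            row[f"{lb}_freq_hz"] = pk.frequency_hz
            row[f"{lb}_width_hz"] = pk.width_hz
        drv = report.derived
        row["gamma_v_per_m"] = drv.conv_factor
        for lb in PEAK_LABELS:
            row[f"radius_{lb}_m"] = drv.radius_per_peak[lb]
        row["mass_kg"] = drv.mass
        row[LABEL_COLUMN] = report.metadata.get("class_label", "unknown")
        rows.append(row)
    if excluded:
        logger.info("assemble: excluded %d of %d reports", excluded, len(fit_reports))
    table = pd.DataFrame(rows, columns=list(FEATURE_COLUMNS) + [LABEL_COLUMN])
    if len(table) and table[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("assembled table contains missing values")
    return table


def remove_outliers(
    table: pd.DataFrame,
    factor: float = 1.5,
    per_class: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Screen out rows far from the column medians.

    A row is an outlier when ``|x - median(col)| > factor * IQR(col)`` for
    any numeric column. Medians and IQRs are computed once on the input
    table (single pass; the statistics are frozen before any row is
    dropped), with quartiles by linear interpolation between order
    statistics. The strict inequality means identical columns (IQR = 0)
    remove nothing.

    Returns ``(kept, removed)``. Tables with fewer than 4 rows have no
    defined quartiles and pass through unchanged with a warning. With
    ``per_class=True`` the rule is applied within each label group.
    """
    if per_class:
        kept_parts, removed_parts = [], []
        for _, group in table.groupby(LABEL_COLUMN, sort=False):
            k, r = remove_outliers(group, factor, per_class=False)
            kept_parts.append(k)
            removed_parts.append(r)
        return pd.concat(kept_parts), pd.concat(removed_parts)

    if len(table) < 4:
        warnings.warn(
            "fewer than 4 rows: quartiles undefined, no filtering applied",
            stacklevel=2,
        )
        return table.copy(), table.iloc[0:0].copy()

    numeric = table.select_dtypes(include=[np.number])
    median = numeric.median()
    q1 = numeric.quantile(0.25, interpolation="linear")
    q3 = numeric.quantile(0.75, interpolation="linear")
    iqr = q3 - q1
    outlying = (numeric.sub(median).abs()).gt(factor * iqr, axis=1).any(axis=1)
    kept = table.loc[~outlying].copy()
    removed = table.loc[outlying].copy()
    logger.info(
        "remove_outliers: %d of %d rows removed (factor=%.3g)",
        len(removed), len(table), factor,
    )
    return kept, removed


def save_feature_table(
    table: pd.DataFrame,
    path,
    sidecar: dict | None = None,
) -> None:
    """Write the table as CSV; optional JSON sidecar of filter settings."""
    table.to_csv(path, index=False)
    if sidecar is not None:
        with open(str(path) + ".json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
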