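"""Feature-level quality filtering, normalization and transformation.

The non-targeted processing chain is: CV-filter on raw QC intensities ->
sample-weight normalization -> drift correction -> replicate averaging ->
log2 transform.  Thresholds follow common pooled-QC practice: features with
QC CV strictly above 30% are discarded, and in targeted mode features with
mean QC intensity strictly below 2000 counts are discarded as well.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .tables import FeatureTable

REFERENCE_DRY_WEIGHT_MG = 500.0  # nominal sample aliquot


def qc_cv(table: FeatureTable, min_qc: int = 2) -> pd.Series:
    """Per-feature coefficient of variation over usable QC injections.

    CV = sample standard deviation (n-1) / mean; missing QC cells are
    excluded.  Features with fewer than ``min_qc`` observed QC values get
    NaN (flagged as insufficient downstream).
    """
    qc = table.intensities[table.usable_qc_ids]
    if qc.shape[1] == 0:
        raise ValueError("table has no usable QC injections")
    n = qc.notna().sum(axis=1)
    cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    cv[n < min_qc] = np.nan
    cv.name = "qc_cv"
    return cv


def filter_features(
    table: FeatureTable,
    cv_max: float = 0.30,
    min_mean_qc: float | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drop low-repeatability (and, optionally, low-intensity) features.

    Removes features whose QC CV is strictly greater than ``cv_max``; when
    ``min_mean_qc`` is set (targeted mode), also removes features whose
    mean QC intensity is strictly below it.  Features whose CV is
    undefined (fewer than two QC values) are removed with reason
    ``insufficient_QC``.  Returns the retained table and a removal log
    with reason codes {CV, intensity, insufficient_QC}.
    """
    cv = qc_cv(table)
    mean_qc = table.intensities[table.usable_qc_ids].mean(axis=1)
    reasons = {}
    for fid in table.intensities.index:
        if np.isnan(cv.loc[fid]):
            reasons[fid] = "insufficient_QC"
        elif cv.loc[fid] > cv_max:
            reasons[fid] = "CV"
        elif min_mean_qc is not None and mean_qc.loc[fid] < min_mean_qc:
            reasons[fid] = "intensity"
    log = pd.DataFrame(
        {
            "feature_id": list(reasons),
            "reason": list(reasons.values()),
            "qc_cv": [cv.loc[f] for f in reasons],
            "mean_qc": [mean_qc.loc[f] for f in reasons],
        }
    )
    keep = [f for f in table.intensities.index if f not in reasons]
    return table.subset_features(keep), log


def normalize_by_weight(
    table: FeatureTable, reference_weight: float = REFERENCE_DRY_WEIGHT_MG
) -> FeatureTable:
    """Scale biological injections to a common sample dry weight.

    intensity * (reference_weight / dry_weight); QC and blank injections
    are left unscaled.  A biological injection without a dry weight is an
    error.
    """
    out = table.copy()
    meta = out.injections
    bio = meta["sample_type"] == "biological"
    weights = meta.loc[bio, "dry_weight"]
    if weights.isna().any():
        missing = list(weights.index[weights.isna()])
        raise ValueError(f"biological injections without dry weight: {missing}")
    factors = reference_weight / weights.astype(float)
    out.intensities.loc[:, factors.index] = (
        out.intensities[factors.index] * factors
    )
    return out


def average_replicates(
    table: FeatureTable,
    level: str = "technical",
    keep_qc: bool = True,
) -> FeatureTable:
    """Average replicate injections of biological samples.

    ``level="technical"`` averages technical replicates within each
    (class, agronomic replicate); ``level="technical+agronomic"`` averages
    all replicates within each class (one column per cultivar).  Missing
    cells are excluded from the mean; QC injections are carried through
    unaveraged when ``keep_qc``.
    """
    if level not in ("technical", "technical+agronomic"):
        raise ValueError(f"unknown averaging level {level!r}")
    meta = table.injections
    bio = meta[meta["sample_type"] == "biological"]
    if level == "technical":
        keys = list(zip(bio["class_label"], bio["agronomic_rep"]))
        name = lambda k: f"{k[0]}_a{int(k[1])}"
    else:
        keys = list(bio["class_label"])
        name = lambda k: str(k)
    groups: dict = {}
    for inj, key in zip(bio.index, keys):
        groups.setdefault(key, []).append(inj)

    cols, meta_rows = {}, []
    for key, members in groups.items():
        cid = name(key)
        cols[cid] = table.intensities[members].mean(axis=1)
        first = meta.loc[members[0]]
        meta_rows.append(
            dict(
                injection_id=cid,
                batch_id=first["batch_id"],
                order=first["order"],
                sample_type="biological",
                class_label=first["class_label"],
                agronomic_rep=first["agronomic_rep"] if level == "technical" else np.nan,
                technical_rep=np.nan,
                extract_rep=np.nan,
                dry_weight=np.nan,
                ion_mode=first["ion_mode"],
                usable_for_drift=False,
            )
        )
    if keep_qc:
        for inj in table.qc_ids:
            cols[inj] = table.intensities[inj]
            row = meta.loc[inj].to_dict()
            row["injection_id"] = inj
            meta_rows.append(row)
    new_meta = pd.DataFrame(meta_rows).set_index("injection_id")
    values = pd.DataFrame(cols, index=table.intensities.index)
    return FeatureTable(values, table.features.copy(), new_meta)


def log2_transform(table: FeatureTable) -> FeatureTable:
    """Elementwise log2; missing propagates, non-positive values error."""
    vals = table.intensities
    if (vals <= 0).any().any():
        raise ValueError("log2 transform requires strictly positive intensities")
    out = table.copy()
    out.intensities = np.log2(vals)
    return out
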