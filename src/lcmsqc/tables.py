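"""Containers for multi-batch LC-MS feature data.

A :class:`FeatureTable` holds a features x injections intensity matrix
together with feature descriptors (m/z, retention time) and per-injection
metadata (batch, injection order, sample type, class label, replicate
indices, dry weight).  Missing intensities are NaN, never zero.  The
delimited on-disk form is two CSV files: ``matrix.csv`` (rows = features,
columns = injections, preceded by ``mz``/``rt`` descriptor columns) and
``injections.csv`` (one row per injection).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SAMPLE_TYPES = (
    "QC",
    "biological",
    "blank",
    "spike_A",
    "spike_B",
    "spike_C",
    "non_spiked_D",
)
ION_MODES = ("positive", "negative")

#: metadata columns written to injections.csv, in order
INJECTION_COLUMNS = (
    "batch_id",
    "order",
    "sample_type",
    "class_label",
    "agronomic_rep",
    "technical_rep",
    "extract_rep",
    "dry_weight",
    "ion_mode",
    "usable_for_drift",
)


@dataclass(frozen=True)
class InjectionRecord:
    """Metadata for a single injection.

    ``usable_for_drift`` is True for QC injections that enter drift-curve
    fitting (i.e. QCs past the equilibration block at the start of a batch).
    """

    injection_id: str
    batch_id: str
    order: int
    sample_type: str
    class_label: str | None = None
    agronomic_rep: int | None = None
    technical_rep: int | None = None
    extract_rep: int | None = None
    dry_weight: float | None = None
    ion_mode: str = "positive"
    usable_for_drift: bool = False

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError(f"injection order must be >= 1, got {self.order}")
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample_type {self.sample_type!r}")
        if self.ion_mode not in ION_MODES:
            raise ValueError(f"unknown ion_mode {self.ion_mode!r}")
        if self.sample_type == "QC" and self.class_label is not None:
            raise ValueError("QC injections carry no class label")
        if self.dry_weight is not None and not self.dry_weight > 0:
            raise ValueError("dry_weight must be positive when present")


def records_to_frame(records: Sequence[InjectionRecord]) -> pd.DataFrame:
    """Injection metadata records -> DataFrame indexed by injection_id."""
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows).set_index("injection_id")
    ids = df.index
    if ids.has_duplicates:
        raise ValueError("duplicate injection ids")
    for batch, sub in df.groupby("batch_id"):
        if sub["order"].duplicated().any():
            raise ValueError(f"duplicate injection order within batch {batch!r}")
    return df[list(INJECTION_COLUMNS)]


@dataclass
class FeatureTable:
    """Features x injections intensity matrix plus linked metadata.

    Attributes
    ----------
    intensities:
        DataFrame indexed by feature_id with one column per injection_id;
        NaN marks a missing value.
    features:
        DataFrame indexed by feature_id with at least ``mz`` and ``rt``
        columns (``ion_mode`` optional).
    injections:
        DataFrame indexed by injection_id with the columns of
        :data:`INJECTION_COLUMNS` (extra columns are preserved).
    provenance:
        Optional same-shape DataFrame of per-cell correction flags
        ({"curve", "median_fallback", "uncorrected"}) set by drift
        correction.
    """

    intensities: pd.DataFrame
    features: pd.DataFrame
    injections: pd.DataFrame
    provenance: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if set(self.intensities.columns) != set(self.injections.index):
            raise ValueError("intensity columns do not match injection metadata")
        if not self.intensities.index.equals(self.features.index):
            raise ValueError("intensity rows do not match feature descriptors")
        # keep column order aligned with metadata order
        self.intensities = self.intensities[self.injections.index]
        if "mz" in self.features and (self.features["mz"] <= 0).any():
            raise ValueError("m/z values must be positive")
        if "rt" in self.features and (self.features["rt"] < 0).any():
            raise ValueError("retention times must be non-negative")

    # -- convenience selectors -------------------------------------------------
    @property
    def qc_ids(self) -> pd.Index:
        return self.injections.index[self.injections["sample_type"] == "QC"]

    @property
    def usable_qc_ids(self) -> pd.Index:
        meta = self.injections
        mask = (meta["sample_type"] == "QC") & meta["usable_for_drift"].astype(bool)
        return meta.index[mask]

    @property
    def biological_ids(self) -> pd.Index:
        return self.injections.index[self.injections["sample_type"] == "biological"]

    def copy(self) -> "FeatureTable":
        return FeatureTable(
            self.intensities.copy(),
            self.features.copy(),
            self.injections.copy(),
            None if self.provenance is None else self.provenance.copy(),
        )

    def subset_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        idx = pd.Index(feature_ids)
        return FeatureTable(
            self.intensities.loc[idx],
            self.features.loc[idx],
            self.injections.copy(),
            None if self.provenance is None else self.provenance.loc[idx],
        )

    def to_long(self) -> pd.DataFrame:
        """Long form: one row per (feature, injection) with metadata joined."""
        long = (
            self.intensities.rename_axis("feature_id")
            .reset_index()
            .melt(id_vars="feature_id", var_name="injection_id", value_name="intensity")
        )
        return long.join(self.injections, on="injection_id")

    # -- delimited round-trip --------------------------------------------------
    def write(self, directory: str | Path) -> None:
        """Write matrix.csv / injections.csv (UTF-8, comma separated)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        matrix = self.features.join(self.intensities)
        matrix.rename_axis("feature_id").to_csv(directory / "matrix.csv")
        self.injections.rename_axis("injection_id").to_csv(directory / "injections.csv")

    @classmethod
    def read(cls, directory: str | Path) -> "FeatureTable":
        directory = Path(directory)
        matrix = pd.read_csv(directory / "matrix.csv", index_col="feature_id")
        meta = pd.read_csv(directory / "injections.csv", index_col="injection_id")
        meta.index = meta.index.astype(str)
        feat_cols = [c for c in matrix.columns if c not in meta.index]
        return cls(
            matrix[[c for c in matrix.columns if c in meta.index]].astype(float),
            matrix[feat_cols],
            meta,
        )

    @classmethod
    def from_records(
        cls,
        intensities: pd.DataFrame,
        records: Sequence[InjectionRecord],
        features: pd.DataFrame | None = None,
    ) -> "FeatureTable":
        meta = records_to_frame(records)
        if features is None:
            n = len(intensities)
            features = pd.DataFrame(
                {"mz": np.full(n, 100.0), "rt": np.full(n, 1.0)},
                index=intensities.index,
            )
        return cls(intensities, features, meta)
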