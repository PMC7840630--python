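"""Quantifier-ion EIC construction and peak integration.

Targeted relative quantification works on extracted-ion chromatograms:
for each target the centroid intensities within a ppm window around the
quantifier m/z are summed per spectrum, and the chromatographic peak is
integrated over a retention-time window after subtracting a linear
baseline anchored at the window edges.
"""
from __future__ import annotations

import base64
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

DEFAULT_TOL_PPM = 20.0
DEFAULT_RT_HALF_WINDOW_MIN = 0.1


@dataclass
class EICTrace:
    """Extracted-ion chromatogram on a strictly increasing time grid."""

    times: np.ndarray  # minutes
    intensities: np.ndarray  # counts
    target_mz: float | None = None
    tol_ppm: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.intensities):
            raise ValueError("times and intensities must be 1-D and aligned")
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("time grid must be strictly increasing")


@dataclass(frozen=True)
class TargetDefinition:
    """A quantifier ion: compound id, m/z, expected RT and window."""

    compound_id: str
    mz: float
    rt: float
    rt_half_window: float = DEFAULT_RT_HALF_WINDOW_MIN
    ion_mode: str = "positive"

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("quantifier m/z must be positive")
        if self.rt_half_window <= 0:
            raise ValueError("RT window must be positive")


def read_target_list(path: str | Path) -> list[TargetDefinition]:
    """Read a delimited target list (compound_id, mz, rt[, rt_half_window, ion_mode])."""
    df = pd.read_csv(path)
    targets = []
    for _, row in df.iterrows():
        targets.append(
            TargetDefinition(
                compound_id=str(row["compound_id"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                rt_half_window=float(row.get("rt_half_window", DEFAULT_RT_HALF_WINDOW_MIN)),
                ion_mode=str(row.get("ion_mode", "positive")),
            )
        )
    return targets


def extract_eic(
    spectra: Iterable[tuple[float, np.ndarray, np.ndarray]],
    target_mz: float,
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> EICTrace:
    """Sum centroid intensities within target_mz +- tol_ppm per spectrum.

    ``spectra`` is a time-ordered iterable of (time, m/z array,
    intensity array) centroided scans; scans lacking matching centroids
    contribute zero.
    """
    half = target_mz * tol_ppm / 1e6
    times, intens = [], []
    for t, mz, inten in spectra:
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        sel = np.abs(mz - target_mz) <= half
        times.append(float(t))
        intens.append(float(inten[sel].sum()) if len(mz) else 0.0)
    times = np.asarray(times)
    if len(times) >= 2 and np.any(np.diff(times) <= 0):
        raise ValueError("spectra must be strictly time-ordered")
    return EICTrace(times, np.asarray(intens), target_mz=target_mz, tol_ppm=tol_ppm)


def integrate_peak(
    trace: EICTrace,
    rt_center: float,
    window: float,
    edge_points: int = 3,
) -> float:
    """Baseline-subtracted trapezoidal peak area within rt_center +- window.

    The baseline is the line between the median intensities of the first
    and last ``edge_points`` grid points inside the window; the integrand
    is floored at zero so noise dips do not subtract area.
    """
    t, y = trace.times, trace.intensities
    lo, hi = rt_center - window, rt_center + window
    if lo < t[0] or hi > t[-1]:
        raise ValueError("integration window extends beyond the time grid")
    sel = (t >= lo) & (t <= hi)
    ts, ys = t[sel], y[sel]
    if len(ts) < 2:
        raise ValueError("fewer than two grid points inside the window")
    k = min(edge_points, len(ts))
    left = float(np.median(ys[:k]))
    right = float(np.median(ys[-k:]))
    baseline = left + (right - left) * (ts - ts[0]) / (ts[-1] - ts[0])
    return float(np.trapezoid(np.maximum(ys - baseline, 0.0), ts))


def quantify_targets(
    spectra_by_injection: dict[str, Sequence[tuple[float, np.ndarray, np.ndarray]]],
    targets: Sequence[TargetDefinition],
    tol_ppm: float = DEFAULT_TOL_PPM,
) -> pd.DataFrame:
    """Per-compound x injection peak-area table (feeds drift correction)."""
    rows = {}
    for target in targets:
        areas = {}
        for inj, spectra in spectra_by_injection.items():
            trace = extract_eic(spectra, target.mz, tol_ppm)
            areas[inj] = integrate_peak(trace, target.rt, target.rt_half_window)
        rows[target.compound_id] = areas
    return pd.DataFrame(rows).T.rename_axis("feature_id")


# ---------------------------------------------------------------------------
# mzML input/output (centroided spectra)
# ---------------------------------------------------------------------------

def read_mzml(path: str | Path) -> list[tuple[float, np.ndarray, np.ndarray]]:
    """Centroided MS1 spectra from an mzML file as (time_min, mz, intensity).

    Reads uncompressed or zlib-compressed 32/64-bit float arrays; scan
    start times declared in seconds are converted to minutes.
    """
    import zlib

    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    spectra = []
    for _, spec in etree.iterparse(str(path), tag=f"{ns}spectrum"):
        minutes = None
        for cv in spec.iter(f"{ns}cvParam"):
            if cv.get("accession") == "MS:1000016":  # scan start time
                minutes = float(cv.get("value"))
                if cv.get("unitName", "minute") in ("second", "seconds"):
                    minutes /= 60.0
        arrays: dict[str, np.ndarray] = {}
        for bda in spec.iter(f"{ns}binaryDataArray"):
            dtype, compressed, kind = np.float64, False, None
            for cv in bda.iter(f"{ns}cvParam"):
                acc = cv.get("accession")
                if acc == "MS:1000521":
                    dtype = np.float32
                elif acc == "MS:1000574":
                    compressed = True
                elif acc == "MS:1000514":
                    kind = "mz"
                elif acc == "MS:1000515":
                    kind = "intensity"
            node = bda.find(f"{ns}binary")
            raw = base64.b64decode(node.text or "")
            if compressed:
                raw = zlib.decompress(raw)
            if kind is not None:
                arrays[kind] = np.frombuffer(raw, dtype=dtype).astype(float)
        if minutes is not None and "mz" in arrays and "intensity" in arrays:
            spectra.append((minutes, arrays["mz"], arrays["intensity"]))
        spec.clear()
    spectra.sort(key=lambda s: s[0])
    return spectra


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack("<" + "d" * len(values), *map(float, values))
    return base64.b64encode(raw).decode("ascii")


def write_mzml(
    path: str | Path,
    spectra: Sequence[tuple[float, np.ndarray, np.ndarray]],
) -> None:
    """Minimal mzML writer for centroided spectra (synthetic fixtures).

    Emits uncompressed 64-bit float m/z and intensity arrays with the
    controlled-vocabulary terms pyteomics needs to read them back; times
    are written in minutes.  Not a general-purpose mzML exporter.
    """
    chunks = []
    for i, (t, mz, inten) in enumerate(spectra):
        mz = np.asarray(mz, dtype=float)
        inten = np.asarray(inten, dtype=float)
        n = len(mz)
        chunks.append(f"""
      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{n}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{t:.6f}" unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{_b64_doubles(mz)}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="0">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{_b64_doubles(inten)}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>""")
    body = "".join(chunks)
    doc = f"""<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="2">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
    <cv id="UO" fullName="Unit Ontology" URI="http://obo.cvs.sourceforge.net/obo/obo/ontology/phenotype/unit.obo"/>
  </cvList>
  <run id="run1">
    <spectrumList count="{len(spectra)}" defaultDataProcessingRef="dp1">{body}
    </spectrumList>
  </run>
</mzML>
"""
    Path(path).write_text(doc)
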