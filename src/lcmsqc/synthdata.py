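"""Synthetic multi-batch LC-MS data with known ground truth.

Emulates the data-generating process of a pooled-QC bracketed batch design:
monotone within-batch sensitivity drift, nested technical variance
(batch / extraction / injection), cultivar (class) effects, matrix-effect
suppression, spike-in validation groups, dilution series with detector
saturation, spiked accuracy series and Gaussian extracted-ion
chromatograms.  Every generator is deterministic given its seed.

Noise model: multiplicative log-normal.  A coefficient of variation ``cv``
maps to the log-scale standard deviation via ``sigma = sqrt(log(1 + cv**2))``
so that the generated intensities have exactly the requested CV.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .tables import FeatureTable, InjectionRecord, records_to_frame

DRIFT_SHAPES = ("linear", "exponential", "spline_knots")

#: default raw technical CVs (batch, extraction, injection) of the emulated
#: platform: inter-batch 31.2%, extraction 0.6%, injection 8.6%.
DEFAULT_CV_BATCH = 0.312
DEFAULT_CV_EXTRACTION = 0.006
DEFAULT_CV_INJECTION = 0.086

#: illustrative drift amplitudes; negative ion mode drifts more strongly
DEFAULT_DRIFT_AMPLITUDE = {"positive": 0.15, "negative": 0.25}


def cv_to_sigma(cv: float) -> float:
    """Log-scale sigma of a log-normal with the given coefficient of variation."""
    return math.sqrt(math.log1p(cv * cv))


def sigma_to_cv(sigma: float) -> float:
    return math.sqrt(math.expm1(sigma * sigma))


@dataclass
class SyntheticConfig:
    """Parameters of the feature-table generator.

    ``class_effects`` maps feature_id -> {class_label: log2 effect} relative
    to the feature's baseline mean; unlisted classes get effect 0.
    """

    n_features: int = 100
    n_batches: int = 1
    drift_amplitude: float = 0.15
    drift_shape: str = "linear"
    cv_injection: float = DEFAULT_CV_INJECTION
    cv_extraction: float = DEFAULT_CV_EXTRACTION
    cv_batch: float = DEFAULT_CV_BATCH
    class_effects: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    missing_rate: float = 0.0
    seed: int = 0
    mean_intensity_range: tuple[float, float] = (1e4, 1e6)
    detection_floor: float = 100.0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ValueError("n_features must be >= 1")
        for name in ("cv_injection", "cv_extraction", "cv_batch"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.drift_amplitude < 1:
            raise ValueError("drift_amplitude must be in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.drift_shape not in DRIFT_SHAPES:
            raise ValueError(f"unknown drift_shape {self.drift_shape!r}")
        lo, hi = self.mean_intensity_range
        if not 0 < lo <= hi:
            raise ValueError("mean_intensity_range must be positive and ordered")


@dataclass
class SyntheticTruth:
    """Ground truth backing a generated table.

    ``drift_curves[(feature_id, batch_id)]`` maps injection order to the
    relative detector sensitivity; by construction it equals 1.0 at the
    order of the first injection of the batch.
    """

    true_mean: pd.DataFrame  # features x (classes + "QC")
    drift_curves: dict[tuple[str, str], Callable[[np.ndarray], np.ndarray]]
    variance_components_true: dict[str, float]  # cv_batch / cv_extraction / cv_injection
    spike_truth: pd.DataFrame | None = None
    seed: int | None = None

    def write_json(self, path: str | Path) -> None:
        payload = {
            "true_mean": self.true_mean.to_dict(),
            "variance_components_true": self.variance_components_true,
            "spike_truth": None
            if self.spike_truth is None
            else self.spike_truth.to_dict(),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# batch design
# ---------------------------------------------------------------------------

def generate_batch_design(
    sample_ids: Sequence[str],
    max_injections_per_batch: int = 95,
    qc_lead: int = 7,
    qc_tail: int = 2,
    segment: int = 4,
    equilibration_qcs: int = 5,
    seed: int | None = None,
    shuffle: bool = True,
    ion_mode: str = "positive",
) -> list[InjectionRecord]:
    """Lay out injections in pooled-QC bracketed batches.

    Each batch opens with ``qc_lead`` QC injections (the first
    ``equilibration_qcs`` of which are platform-equilibration runs excluded
    from drift fitting), closes with ``qc_tail`` QCs, and interleaves a
    single QC between consecutive segments of at most ``segment`` randomly
    ordered samples.  New batches are opened whenever a batch would exceed
    ``max_injections_per_batch`` injections in total.
    """
    if len(sample_ids) == 0:
        raise ValueError("sample_ids must be non-empty")
    if segment < 1:
        raise ValueError("segment must be >= 1")
    for name, val in (
        ("max_injections_per_batch", max_injections_per_batch),
        ("qc_lead", qc_lead),
        ("qc_tail", qc_tail),
    ):
        if val < 1:
            raise ValueError(f"{name} must be >= 1")
    if equilibration_qcs < 0 or equilibration_qcs > qc_lead:
        raise ValueError("equilibration_qcs must be in [0, qc_lead]")

    ids = [str(s) for s in sample_ids]
    if len(set(ids)) != len(ids):
        raise ValueError("sample ids must be unique")
    if shuffle:
        rng = np.random.default_rng(seed)
        ids = [ids[i] for i in rng.permutation(len(ids))]

    def batch_size(n_samples: int) -> int:
        n_seg = math.ceil(n_samples / segment)
        return qc_lead + n_samples + (n_seg - 1) + qc_tail

    if batch_size(1) > max_injections_per_batch:
        raise ValueError("max_injections_per_batch too small for the QC layout")

    # greedy fill: as many samples per batch as the capacity allows
    capacity = 1
    while batch_size(capacity + 1) <= max_injections_per_batch:
        capacity += 1

    records: list[InjectionRecord] = []
    batch_no = 0
    pos = 0
    while pos < len(ids):
        batch_no += 1
        batch_id = f"B{batch_no:02d}"
        chunk = ids[pos : pos + capacity]
        pos += len(chunk)
        order = 0
        qc_no = 0

        def qc(usable: bool) -> InjectionRecord:
            nonlocal order, qc_no
            order += 1
            qc_no += 1
            return InjectionRecord(
                injection_id=f"{batch_id}_QC{qc_no:02d}",
                batch_id=batch_id,
                order=order,
                sample_type="QC",
                ion_mode=ion_mode,
                usable_for_drift=usable,
            )

        for k in range(qc_lead):
            records.append(qc(usable=k >= equilibration_qcs))
        for i, sid in enumerate(chunk):
            if i > 0 and i % segment == 0:
                records.append(qc(usable=True))
            order += 1
            records.append(
                InjectionRecord(
                    injection_id=sid,
                    batch_id=batch_id,
                    order=order,
                    sample_type="biological",
                    ion_mode=ion_mode,
                )
            )
        for _ in range(qc_tail):
            records.append(qc(usable=True))
    return records


def cultivar_design(
    n_classes: int = 8,
    n_agronomic: int = 4,
    n_technical: int = 2,
    dry_weight_mg: float = 500.0,
    dry_weight_jitter_mg: float = 10.0,
    seed: int | None = None,
    class_names: Sequence[str] | None = None,
    **layout_kwargs,
) -> list[InjectionRecord]:
    """Batch design for a cultivar profiling study.

    The default emulates an 8 cultivars x 4 agronomic replicates x
    2 technical replicates layout (64 biological injections) with sample
    dry weights of 500 +- 10 mg.  Layout keyword arguments are forwarded
    to :func:`generate_batch_design`.
    """
    import dataclasses as _dc

    if class_names is None:
        class_names = [f"class{i + 1:02d}" for i in range(n_classes)]
    info = {}
    sample_ids = []
    for cls in class_names:
        for a in range(1, n_agronomic + 1):
            for t in range(1, n_technical + 1):
                sid = f"{cls}_a{a}_t{t}"
                sample_ids.append(sid)
                info[sid] = (cls, a, t)
    records = generate_batch_design(sample_ids, seed=seed, **layout_kwargs)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    out = []
    for r in records:
        if r.sample_type != "biological":
            out.append(r)
            continue
        cls, a, t = info[r.injection_id]
        w = dry_weight_mg + (
            rng.uniform(-dry_weight_jitter_mg, dry_weight_jitter_mg)
            if dry_weight_jitter_mg > 0
            else 0.0
        )
        out.append(
            _dc.replace(
                r,
                class_label=cls,
                agronomic_rep=a,
                technical_rep=t,
                extract_rep=t,
                dry_weight=round(w, 1),
            )
        )
    return out


# ---------------------------------------------------------------------------
# drift curves
# ---------------------------------------------------------------------------

def _make_drift_curve(
    shape: str,
    amplitude: float,
    order_lo: int,
    order_hi: int,
    rng: np.random.Generator,
) -> Callable[[np.ndarray], np.ndarray]:
    """Relative-sensitivity curve: 1.0 at order_lo, (1 - amplitude) at order_hi."""
    span = max(order_hi - order_lo, 1)

    def rel(orders: np.ndarray) -> np.ndarray:
        return (np.asarray(orders, dtype=float) - order_lo) / span

    if amplitude == 0.0:
        return lambda orders: np.ones_like(np.asarray(orders, dtype=float))
    if shape == "linear":
        return lambda orders: 1.0 - amplitude * rel(orders)
    if shape == "exponential":
        return lambda orders: (1.0 - amplitude) ** rel(orders)
    # monotone spline through seeded interior knots
    n_knots = 4
    kx = np.concatenate([[0.0], np.sort(rng.uniform(0.1, 0.9, n_knots)), [1.0]])
    drops = rng.dirichlet(np.ones(n_knots + 1))
    ky = 1.0 - amplitude * np.concatenate([[0.0], np.cumsum(drops)])
    ky[-1] = 1.0 - amplitude
    interp = PchipInterpolator(kx, ky)
    return lambda orders: np.asarray(interp(np.clip(rel(orders), 0.0, 1.0)))


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def simulate_feature_table(
    config: SyntheticConfig,
    design: Sequence[InjectionRecord],
) -> tuple[FeatureTable, SyntheticTruth]:
    """Simulate a features x injections table over a batch design.

    intensity(f, i) = true_mean(f, class(i)) * drift(f, batch(i))(order(i))
    * exp(batch + extraction + injection noise), the three log-scale terms
    drawn per feature x batch, per feature x extract and per feature x
    injection with CVs from the config.  QC injections share one pooled
    composition (the mean of the class means) and, being re-injections of a
    single pooled extract, carry no extraction noise.  Intensities below the
    detection floor or hit by random dropout are recorded as missing (NaN).
    """
    if len(design) == 0:
        raise ValueError("design must be non-empty")
    meta = records_to_frame(design)
    n_design_batches = meta["batch_id"].nunique()
    if config.n_batches not in (0, n_design_batches):
        raise ValueError(
            f"config.n_batches={config.n_batches} but design has {n_design_batches}"
        )
    rng = np.random.default_rng(config.seed)
    n_f = config.n_features
    feature_ids = [f"F{i + 1:04d}" for i in range(n_f)]
    features = pd.DataFrame(
        {
            "mz": np.round(rng.uniform(100.0, 1000.0, n_f), 4),
            "rt": np.round(rng.uniform(0.5, 15.0, n_f), 3),
            "ion_mode": meta["ion_mode"].iloc[0],
        },
        index=pd.Index(feature_ids, name="feature_id"),
    )

    lo, hi = config.mean_intensity_range
    base = np.exp(rng.uniform(math.log(lo), math.log(hi), n_f))
    classes = sorted(
        {c for c in meta["class_label"].dropna().unique()}
    ) or ["pooled"]
    true_mean = pd.DataFrame(
        {c: base.copy() for c in classes}, index=features.index
    )
    for fid, effects in config.class_effects.items():
        for cls, log2_eff in effects.items():
            if fid in true_mean.index and cls in true_mean.columns:
                true_mean.loc[fid, cls] *= 2.0 ** log2_eff
    true_mean["QC"] = true_mean[classes].mean(axis=1)

    batches = list(meta["batch_id"].unique())
    sig_b = cv_to_sigma(config.cv_batch)
    sig_e = cv_to_sigma(config.cv_extraction)
    sig_i = cv_to_sigma(config.cv_injection)

    drift_curves: dict[tuple[str, str], Callable] = {}
    intens = np.empty((n_f, len(meta)))
    col_of = {inj: k for k, inj in enumerate(meta.index)}

    for b in batches:
        sub = meta[meta["batch_id"] == b]
        o_lo, o_hi = int(sub["order"].min()), int(sub["order"].max())
        curves = [
            _make_drift_curve(config.drift_shape, config.drift_amplitude, o_lo, o_hi, rng)
            for _ in range(n_f)
        ]
        for fid, cur in zip(feature_ids, curves):
            drift_curves[(fid, b)] = cur
        drift = np.vstack([cur(sub["order"].to_numpy()) for cur in curves])

        batch_eff = rng.normal(0.0, sig_b, n_f) if sig_b > 0 else np.zeros(n_f)

        # one extraction-noise draw per feature per extract; QCs are
        # re-injections of a single pooled extract -> no extraction term
        extract_keys = {}
        for inj, row in sub.iterrows():
            if row["sample_type"] == "QC":
                extract_keys[inj] = None
            else:
                key = (
                    row["class_label"],
                    row["agronomic_rep"],
                    row["technical_rep"],
                    row["extract_rep"],
                    b,
                )
                extract_keys[inj] = key
        uniq = sorted({k for k in extract_keys.values() if k is not None}, key=str)
        ext_eff = {
            k: (rng.normal(0.0, sig_e, n_f) if sig_e > 0 else np.zeros(n_f))
            for k in uniq
        }

        for j, (inj, row) in enumerate(sub.iterrows()):
            cls = "QC" if row["sample_type"] == "QC" else row["class_label"]
            if cls is None or cls not in true_mean.columns:
                cls = "QC"
            mean = true_mean[cls].to_numpy()
            noise = batch_eff.copy()
            key = extract_keys[inj]
            if key is not None:
                noise = noise + ext_eff[key]
            if sig_i > 0:
                noise = noise + rng.normal(0.0, sig_i, n_f)
            intens[:, col_of[inj]] = mean * drift[:, j] * np.exp(noise)

    values = pd.DataFrame(intens, index=features.index, columns=meta.index)
    if config.detection_floor > 0:
        values = values.mask(values < config.detection_floor)
    if config.missing_rate > 0:
        drop = rng.random(values.shape) < config.missing_rate
        values = values.mask(drop)

    table = FeatureTable(values, features, meta)
    truth = SyntheticTruth(
        true_mean=true_mean,
        drift_curves=drift_curves,
        variance_components_true={
            "cv_batch": config.cv_batch,
            "cv_extraction": config.cv_extraction,
            "cv_injection": config.cv_injection,
        },
        seed=config.seed,
    )
    return table, truth


# ---------------------------------------------------------------------------
# validation experiments
# ---------------------------------------------------------------------------

def simulate_validation_experiment(
    compounds: pd.DataFrame,
    n_per_group: int = 4,
    noise_cv: float = 0.0,
    seed: int | None = None,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Spike-recovery / matrix-effect experiment with configurable truth.

    ``compounds`` needs columns ``recovery``, ``matrix_effect``,
    ``solvent_response`` (pure-solvent peak area of the spike, group C) and
    ``background`` (endogenous level, group D); index = compound ids.
    Groups: A spiked before extraction, B spiked after extraction, C spiked
    solvent blank, D non-spiked matrix.  Noise-free group means are built so
    the standard estimators return the configured truth exactly:

        C = solvent_response
        B = background + matrix_effect * C
        A = background + recovery * matrix_effect * C
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    for col in ("recovery", "matrix_effect", "solvent_response", "background"):
        if col not in compounds:
            raise ValueError(f"compounds table lacks column {col!r}")
    bad = ~compounds[["recovery", "matrix_effect"]].apply(
        lambda s: (s > 0) & (s <= 1.5)
    )
    if bad.to_numpy().any():
        raise ValueError("recovery and matrix_effect fractions must be in (0, 1.5]")

    rng = np.random.default_rng(seed)
    C = compounds["solvent_response"].to_numpy(dtype=float)
    D = compounds["background"].to_numpy(dtype=float)
    B = D + compounds["matrix_effect"].to_numpy() * C
    A = D + compounds["recovery"].to_numpy() * compounds["matrix_effect"].to_numpy() * C
    group_means = {"spike_A": A, "spike_B": B, "spike_C": C, "non_spiked_D": D}

    records: list[InjectionRecord] = []
    cols: dict[str, np.ndarray] = {}
    sigma = cv_to_sigma(noise_cv) if noise_cv > 0 else 0.0
    order = 0
    for gtype in ("spike_A", "spike_B", "spike_C", "non_spiked_D"):
        for r in range(1, n_per_group + 1):
            order += 1
            inj = f"{gtype}_{r}"
            records.append(
                InjectionRecord(
                    injection_id=inj,
                    batch_id="V01",
                    order=order,
                    sample_type=gtype,
                    technical_rep=r,
                )
            )
            mean = group_means[gtype]
            if sigma > 0:
                cols[inj] = mean * np.exp(rng.normal(0.0, sigma, len(mean)))
            else:
                cols[inj] = mean.astype(float).copy()

    values = pd.DataFrame(cols, index=compounds.index)
    feats = pd.DataFrame(
        {
            "mz": compounds.get("mz", pd.Series(200.0, index=compounds.index)),
            "rt": compounds.get("rt", pd.Series(5.0, index=compounds.index)),
        },
        index=compounds.index,
    )
    table = FeatureTable(values, feats, records_to_frame(records))
    truth = compounds[["recovery", "matrix_effect", "solvent_response", "background"]].copy()
    return table, truth


def saturation_capacity(
    levels: np.ndarray,
    slope: float,
    n_flattened: int = 2,
    target_deviation: float = 0.13,
) -> float:
    """Capacity making exactly the top ``n_flattened`` levels deviate.

    The saturating response is ``y = a*x*C / (C + a*x)``; its relative
    deviation from the line ``a*x`` is ``a*x / (C + a*x)``, monotone in x.
    Pick C so the lowest flattened level sits at ``target_deviation``.
    """
    x = float(np.sort(np.asarray(levels, dtype=float))[-n_flattened])
    return slope * x * (1.0 - target_deviation) / target_deviation


def simulate_dilution_series(
    levels: Sequence[float] | None = None,
    slope: float = 1000.0,
    capacity: float | None = None,
    duplicates: int = 2,
    noise_cv: float = 0.0,
    seed: int | None = None,
    compound_id: str = "C01",
) -> FeatureTable:
    """Dilution series over 11 levels spanning 4-400 concentration units.

    Without ``capacity`` the response is a pure proportionality y = a*x;
    with it, detector saturation y = a*x*C/(C + a*x).  Each level is
    injected ``duplicates`` times.  The per-injection ``concentration`` is
    carried in the injection metadata.
    """
    if levels is None:
        levels = np.geomspace(4.0, 400.0, 11)
    levels = np.asarray(levels, dtype=float)
    if len(levels) < 2 or np.any(np.diff(levels) <= 0):
        raise ValueError("levels must be strictly increasing")
    if np.any(levels <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    sigma = cv_to_sigma(noise_cv) if noise_cv > 0 else 0.0

    records = []
    cols = {}
    order = 0
    for li, x in enumerate(levels, start=1):
        y = slope * x
        if capacity is not None:
            y = y * capacity / (capacity + slope * x)
        for r in range(1, duplicates + 1):
            order += 1
            inj = f"L{li:02d}_{r}"
            records.append(
                InjectionRecord(
                    injection_id=inj,
                    batch_id="D01",
                    order=order,
                    sample_type="biological",
                    class_label=f"level_{li:02d}",
                    technical_rep=r,
                )
            )
            cols[inj] = [y * math.exp(rng.normal(0.0, sigma)) if sigma > 0 else y]
    values = pd.DataFrame(cols, index=pd.Index([compound_id], name="feature_id"))
    feats = pd.DataFrame({"mz": [200.0], "rt": [5.0]}, index=values.index)
    meta = records_to_frame(records)
    meta["concentration"] = np.repeat(levels, duplicates)
    return FeatureTable(values, feats, meta)


def dilution_arrays(table: FeatureTable, feature_id: str | None = None):
    """(levels, responses) arrays from a dilution-series table.

    ``responses`` has shape (n_levels, n_duplicates).
    """
    fid = feature_id or table.intensities.index[0]
    meta = table.injections
    conc = meta["concentration"].astype(float)
    vals = table.intensities.loc[fid]
    levels = np.sort(conc.unique())
    resp = np.vstack([vals[conc == c].to_numpy() for c in levels])
    return levels, resp


DEFAULT_ACCURACY_LEVELS = (100, 105, 110, 115, 120, 125, 150, 200, 400, 800)


def simulate_accuracy_experiment(
    nominal_levels: Sequence[float] = DEFAULT_ACCURACY_LEVELS,
    cv: float = 0.03,
    n_batches: int = 3,
    duplicates: int = 2,
    base_area: float = 1e5,
    seed: int | None = None,
    compound_id: str = "C01",
) -> FeatureTable:
    """Spiked accuracy series: nominal levels in percent of the lowest.

    Per-injection peak areas are proportional to the nominal level with
    multiplicative log-normal noise of the given CV, analyzed in
    ``n_batches`` batches with ``duplicates`` injections per level each.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    nominal = np.asarray(nominal_levels, dtype=float)
    if np.any(nominal <= 0):
        raise ValueError("nominal levels must be positive")
    rng = np.random.default_rng(seed)
    sigma = cv_to_sigma(cv) if cv > 0 else 0.0
    records, cols = [], {}
    for b in range(1, n_batches + 1):
        order = 0
        for li, lev in enumerate(nominal, start=1):
            for r in range(1, duplicates + 1):
                order += 1
                inj = f"B{b:02d}_L{li:02d}_{r}"
                records.append(
                    InjectionRecord(
                        injection_id=inj,
                        batch_id=f"B{b:02d}",
                        order=order,
                        sample_type="biological",
                        class_label=f"{lev:g}",
                        technical_rep=r,
                    )
                )
                y = base_area * lev / nominal[0]
                cols[inj] = [y * math.exp(rng.normal(0.0, sigma)) if sigma > 0 else y]
    values = pd.DataFrame(cols, index=pd.Index([compound_id], name="feature_id"))
    feats = pd.DataFrame({"mz": [200.0], "rt": [5.0]}, index=values.index)
    meta = records_to_frame(records)
    meta["nominal_level"] = [float(records[k].class_label) for k in range(len(records))]
    return FeatureTable(values, feats, meta)


# ---------------------------------------------------------------------------
# chromatograms
# ---------------------------------------------------------------------------

def simulate_eic(
    peaks: Sequence[tuple[float, float, float]],
    time_grid: np.ndarray,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Sum of Gaussian peaks (apex_time, height, sigma) + baseline + noise."""
    from .quant import EICTrace  # local import to avoid cycle

    t = np.asarray(time_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    y = np.full_like(t, float(baseline))
    for apex, height, width in peaks:
        if width <= 0:
            raise ValueError("peak widths must be positive")
        y = y + height * np.exp(-0.5 * ((t - apex) / width) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, len(t))
    return EICTrace(times=t, intensities=y)
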