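"""Pooled-QC signal-drift correction and normalization.

Detector sensitivity in LC-MS decays systematically with injection order
within an analytical batch.  For every feature and batch, a correction
curve is built from the intensities of the pooled-QC injections versus
their injection order: a locally weighted linear regression (tricube
weights, LOWESS) smooths the QC points, a cubic spline interpolates the
smoothed points across all injection orders, and every injection is
normalized to the curve.  Corrected values are rescaled to the feature's
median QC intensity across all batches, which simultaneously removes
within-batch drift and between-batch sensitivity offsets.

The smoother is evaluated through explicit hat-matrix rows, so smoothing,
leave-one-out span selection and correction are all linear operators in
the QC intensities and vectorize across features that share a batch's QC
layout.  At the smallest admissible window (two points) the smoother
interpolates the QC points exactly, which is the appropriate setting for
noise-free validation data.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .tables import FeatureTable

DEFAULT_SPAN_GRID = (0.3, 0.45, 0.6, 0.75, 0.9, 1.0)
MIN_QC_POINTS = 4
_INTERPOLATE_SPAN = 1e-9  # window of 2 points -> exact interpolation


class InsufficientQCError(ValueError):
    """Fewer usable QC points than the minimum needed for curve fitting."""


def _smoother_row(x: np.ndarray, x0: float, k: int) -> np.ndarray:
    """Hat-matrix row of a tricube-weighted local linear fit at x0."""
    d = np.abs(x - x0)
    h = np.partition(d, k - 1)[k - 1] * 1.0001
    if h == 0:  # all selected points coincide with x0
        w = (d == 0).astype(float)
    else:
        u = np.clip(d / h, 0.0, 1.0)
        w = (1.0 - u**3) ** 3
    xc = x - x0
    sw = w.sum()
    swx = (w * xc).sum()
    swx2 = (w * xc * xc).sum()
    denom = sw * swx2 - swx * swx
    if denom <= 0 or not np.isfinite(denom):
        return w / sw  # degenerate: weighted mean
    return w * (swx2 - swx * xc) / denom


def smoother_matrix(
    x_train: np.ndarray, x_eval: np.ndarray, span: float
) -> np.ndarray:
    """Matrix S with ``smoothed = S @ y``; rows indexed by ``x_eval``."""
    x_train = np.asarray(x_train, dtype=float)
    x_eval = np.asarray(x_eval, dtype=float)
    n = len(x_train)
    if n < 2:
        raise ValueError("need at least two points to smooth")
    k = max(2, min(n, math.ceil(span * n)))
    return np.vstack([_smoother_row(x_train, x0, k) for x0 in x_eval])


def loo_matrix(x: np.ndarray, span: float) -> np.ndarray:
    """Rows predict x[i] from all points except i (zero diagonal)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least three points for leave-one-out")
    k = max(2, min(n - 1, math.ceil(span * (n - 1))))
    L = np.zeros((n, n))
    for i in range(n):
        keep = np.arange(n) != i
        L[i, keep] = _smoother_row(x[keep], x[i], k)
    return L


@dataclass
class DriftModel:
    """Fitted correction curve for one feature in one batch.

    ``curve`` maps injection order to the predicted QC-level intensity;
    outside the usable QC order range the nearest end value is held
    constant, and predictions are floored at a small fraction of the QC
    median so corrected intensities never flip sign.
    """

    feature_id: str
    batch_id: str
    qc_orders: np.ndarray
    qc_intensities: np.ndarray
    span: float
    reference_level: float
    smoothed: np.ndarray
    floor: float
    _spline: CubicSpline

    def curve(self, orders) -> np.ndarray:
        o = np.clip(
            np.asarray(orders, dtype=float), self.qc_orders[0], self.qc_orders[-1]
        )
        return np.maximum(self._spline(o), self.floor)

    def __call__(self, orders) -> np.ndarray:
        return self.curve(orders)


def fit_correction_curve(
    qc_orders: Sequence[float],
    qc_intensities: Sequence[float],
    span: float,
    feature_id: str = "",
    batch_id: str = "",
    min_points: int = MIN_QC_POINTS,
    floor_fraction: float = 0.01,
    reference_level: float | None = None,
) -> DriftModel:
    """LOWESS-smooth QC intensities over injection order, spline-interpolate.

    Raises :class:`InsufficientQCError` below ``min_points`` usable QCs
    (callers fall back to QC-median normalization) and ``ValueError`` for
    non-finite or non-positive intensities.
    """
    x = np.asarray(qc_orders, dtype=float)
    y = np.asarray(qc_intensities, dtype=float)
    if len(x) != len(y):
        raise ValueError("qc_orders and qc_intensities differ in length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite QC inputs")
    if np.any(y <= 0):
        raise ValueError("QC intensities must be positive")
    if len(x) < min_points:
        raise InsufficientQCError(
            f"{len(x)} usable QC points < minimum {min_points}"
        )
    sortkey = np.argsort(x)
    x, y = x[sortkey], y[sortkey]
    if np.any(np.diff(x) == 0):
        raise ValueError("duplicate QC injection orders")
    S = smoother_matrix(x, x, span)
    smoothed = S @ y
    med = float(np.median(y))
    floor = floor_fraction * med
    spline = CubicSpline(x, np.maximum(smoothed, floor))
    return DriftModel(
        feature_id=feature_id,
        batch_id=batch_id,
        qc_orders=x,
        qc_intensities=y,
        span=span,
        reference_level=med if reference_level is None else float(reference_level),
        smoothed=smoothed,
        floor=floor,
        _spline=spline,
    )


def optimize_span(
    qc_orders: Sequence[float],
    qc_intensities: Sequence[float],
    candidates: Sequence[float] = DEFAULT_SPAN_GRID,
) -> float:
    """Span minimizing leave-one-out RMSE; ties go to the largest span."""
    if len(candidates) == 0:
        raise ValueError("empty span candidate grid")
    x = np.asarray(qc_orders, dtype=float)
    y = np.asarray(qc_intensities, dtype=float)
    if len(x) < MIN_QC_POINTS + 1:
        raise ValueError("need at least minimum+1 QC points to cross-validate")
    sortkey = np.argsort(x)
    x, y = x[sortkey], y[sortkey]
    rmses = []
    for span in candidates:
        pred = loo_matrix(x, span) @ y
        rmses.append(float(np.sqrt(np.mean((pred - y) ** 2))))
    rmses = np.asarray(rmses)
    best = rmses.min()
    tol = best * 1e-9 + 1e-12
    eligible = [c for c, r in zip(candidates, rmses) if r <= best + tol]
    return float(max(eligible))


def _qc_cv(values: np.ndarray) -> float:
    """Intra-series CV (n-1 SD over mean) ignoring NaN; NaN if < 2 points."""
    v = values[np.isfinite(values)]
    if len(v) < 2 or v.mean() == 0:
        return float("nan")
    return float(v.std(ddof=1) / v.mean())


def apply_correction(
    table: FeatureTable,
    span_policy: float | str = "optimize",
    span_grid: Sequence[float] = DEFAULT_SPAN_GRID,
    min_qc_points: int = MIN_QC_POINTS,
    floor_fraction: float = 0.01,
) -> tuple[FeatureTable, pd.DataFrame]:
    """Drift-correct and normalize a feature table batch by batch.

    ``span_policy`` is a fixed span fraction, ``"optimize"`` (leave-one-out
    span selection per feature and batch over ``span_grid``), or
    ``"interpolate"`` (two-point window; the curve passes exactly through
    the usable QC points — intended for noise-free data).

    For each feature x batch with at least ``min_qc_points`` usable QCs:
    ``corrected = raw / curve(order) * reference_level`` with
    ``reference_level`` the feature's median usable-QC intensity across all
    batches.  Features with 1..3 usable QCs in a batch fall back to
    division by that batch's QC median (times the same reference); with
    none, the batch is left uncorrected and flagged.  Returns the corrected
    table (with per-cell provenance flags) and a per-feature x batch report
    with span, QC count, method and pre/post QC CV.
    """
    meta = table.injections
    raw = table.intensities
    usable_ids = table.usable_qc_ids
    if len(usable_ids) == 0:
        raise ValueError("table contains no usable QC injections")

    qc_vals = raw[usable_ids]
    mask_all = qc_vals.notna() & (qc_vals > 0)
    reference = qc_vals.where(mask_all).median(axis=1)  # per-feature global ref

    corrected = raw.copy().astype(float)
    provenance = pd.DataFrame("uncorrected", index=raw.index, columns=raw.columns)
    report_rows: list[dict] = []

    for batch_id, bmeta in meta.groupby("batch_id", sort=False):
        cols = bmeta.index
        orders = bmeta["order"].to_numpy(dtype=float)
        uq = bmeta.index[
            (bmeta["sample_type"] == "QC") & bmeta["usable_for_drift"].astype(bool)
        ]
        uq = uq[np.argsort(bmeta.loc[uq, "order"].to_numpy())]
        x = bmeta.loc[uq, "order"].to_numpy(dtype=float)
        Y = raw[uq]
        ok = Y.notna() & (Y > 0)
        n_ok = ok.sum(axis=1)

        pre_cv = Y.where(ok).apply(lambda r: _qc_cv(r.to_numpy()), axis=1)

        full = n_ok.index[(n_ok >= min_qc_points) & ok.all(axis=1)]
        partial = n_ok.index[(n_ok >= min_qc_points) & ~ok.all(axis=1)]
        fallback = n_ok.index[(n_ok >= 1) & (n_ok < min_qc_points)]
        none = n_ok.index[n_ok == 0]

        def choose_spans(Yblock: np.ndarray, xs: np.ndarray) -> np.ndarray:
            nf = Yblock.shape[0]
            if isinstance(span_policy, (int, float)):
                return np.full(nf, float(span_policy))
            if span_policy == "interpolate":
                return np.full(nf, _INTERPOLATE_SPAN)
            if span_policy != "optimize":
                raise ValueError(f"unknown span policy {span_policy!r}")
            if len(xs) < min_qc_points + 1:
                return np.full(nf, float(max(span_grid)))
            grid = sorted(span_grid)
            rm = np.empty((len(grid), nf))
            for gi, s in enumerate(grid):
                pred = Yblock @ loo_matrix(xs, s).T
                rm[gi] = np.sqrt(np.mean((pred - Yblock) ** 2, axis=1))
            best = rm.min(axis=0)
            tol = best * 1e-9 + 1e-12
            chosen = np.empty(nf)
            for gi, s in enumerate(grid):  # ascending: later (larger) spans win ties
                chosen[rm[gi] <= best + tol] = s
            return chosen

        # fully observed QC rows: vectorized smoothing + spline per span group
        if len(full) > 0 and len(x) >= 2:
            Yf = Y.loc[full].to_numpy(dtype=float)
            spans = choose_spans(Yf, x)
            for s in np.unique(spans):
                rows = full[spans == s]
                Yg = Y.loc[rows].to_numpy(dtype=float)
                S = smoother_matrix(x, x, s)
                smoothed = Yg @ S.T
                med = np.median(Yg, axis=1)
                floor = floor_fraction * med
                smoothed = np.maximum(smoothed, floor[:, None])
                spline = CubicSpline(x, smoothed, axis=1)
                curve = np.maximum(
                    spline(np.clip(orders, x[0], x[-1])), floor[:, None]
                )
                ref = reference.loc[rows].to_numpy()
                corrected.loc[rows, cols] = (
                    raw.loc[rows, cols].to_numpy() / curve * ref[:, None]
                )
                provenance.loc[rows, cols] = "curve"
                for fid, sp, nq in zip(rows, np.full(len(rows), s), n_ok.loc[rows]):
                    report_rows.append(
                        dict(feature_id=fid, batch_id=batch_id, span=sp,
                             n_qc=int(nq), method="curve")
                    )

        # rows with some missing/invalid QC cells: per-feature masks
        for fid in partial:
            okm = ok.loc[fid].to_numpy()
            xi = x[okm]
            yi = Y.loc[fid].to_numpy(dtype=float)[okm]
            if isinstance(span_policy, (int, float)):
                s = float(span_policy)
            elif span_policy == "interpolate":
                s = _INTERPOLATE_SPAN
            elif len(xi) >= min_qc_points + 1:
                s = optimize_span(xi, yi, span_grid)
            else:
                s = float(max(span_grid))
            model = fit_correction_curve(
                xi, yi, s, fid, batch_id,
                min_points=min_qc_points, floor_fraction=floor_fraction,
            )
            corrected.loc[fid, cols] = (
                raw.loc[fid, cols].to_numpy()
                / model.curve(orders)
                * reference.loc[fid]
            )
            provenance.loc[fid, cols] = "curve"
            report_rows.append(
                dict(feature_id=fid, batch_id=batch_id, span=s,
                     n_qc=int(n_ok.loc[fid]), method="curve")
            )

        for fid in fallback:
            med = float(Y.loc[fid].where(ok.loc[fid]).median())
            corrected.loc[fid, cols] = (
                raw.loc[fid, cols].to_numpy() / med * reference.loc[fid]
            )
            provenance.loc[fid, cols] = "median_fallback"
            report_rows.append(
                dict(feature_id=fid, batch_id=batch_id, span=float("nan"),
                     n_qc=int(n_ok.loc[fid]), method="median_fallback")
            )

        for fid in none:
            report_rows.append(
                dict(feature_id=fid, batch_id=batch_id, span=float("nan"),
                     n_qc=0, method="uncorrected")
            )

        post = corrected.loc[:, uq]
        post_cv = post.apply(lambda r: _qc_cv(r.to_numpy(dtype=float)), axis=1)
        for row in report_rows:
            if row["batch_id"] == batch_id and "pre_qc_cv" not in row:
                row["pre_qc_cv"] = float(pre_cv.loc[row["feature_id"]])
                row["post_qc_cv"] = float(post_cv.loc[row["feature_id"]])

    report = pd.DataFrame(
        report_rows,
        columns=["feature_id", "batch_id", "span", "n_qc", "method",
                 "pre_qc_cv", "post_qc_cv"],
    )
    out = FeatureTable(
        corrected, table.features.copy(), table.injections.copy(), provenance
    )
    return out, report
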