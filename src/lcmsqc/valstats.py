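"""Method-validation statistics for LC-MS metabolite profiling.

Four computations used to validate a profiling method:

* spike recovery and matrix effect from the four-group design
  (A spiked before extraction, B spiked after, C spiked solvent blank,
  D non-spiked matrix);
* nested variance-component estimation (batch / extraction / injection)
  from a balanced repeatability experiment via the expected-mean-squares
  method of moments;
* linear-range estimation of a dilution series under a through-origin
  calibration model y = a*x;
* fold-change accuracy of spiked concentration series with equal-variance
  two-tailed t-tests on per-batch means.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import FeatureTable


# ---------------------------------------------------------------------------
# recovery and matrix effect
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeGroups:
    """Mean drift-corrected areas of the four spike groups for one compound."""

    mean_a: float  # spiked before extraction
    mean_b: float  # spiked after extraction
    mean_c: float  # spiked solvent blank
    mean_d: float  # non-spiked matrix
    n: int = 4

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need n >= 2 replicates per group")
        if min(self.mean_a, self.mean_b, self.mean_c, self.mean_d) < 0:
            raise ValueError("group means must be non-negative")


def spike_groups_from_table(table: FeatureTable, feature_id: str) -> SpikeGroups:
    """Group means for one compound from a validation-experiment table."""
    meta = table.injections
    vals = table.intensities.loc[feature_id]
    means = {}
    ns = []
    for gtype, key in (
        ("spike_A", "mean_a"),
        ("spike_B", "mean_b"),
        ("spike_C", "mean_c"),
        ("non_spiked_D", "mean_d"),
    ):
        ids = meta.index[meta["sample_type"] == gtype]
        if len(ids) == 0:
            raise ValueError(f"no injections of group {gtype}")
        means[key] = float(vals[ids].mean())
        ns.append(len(ids))
    return SpikeGroups(n=min(ns), **means)


def recovery_rate(groups: SpikeGroups) -> float:
    """(A - D) / (B - D): fraction of a pre-extraction spike recovered.

    Undefined when the post-extraction spike is indistinguishable from the
    endogenous background (B <= D).
    """
    denom = groups.mean_b - groups.mean_d
    if denom <= 0:
        raise ValueError("spike indistinguishable from background (B <= D)")
    return (groups.mean_a - groups.mean_d) / denom


MATRIX_EFFECT_BANDS = ("none", "weak", "medium", "strong", "enhancement")


def matrix_effect(groups: SpikeGroups) -> tuple[float, str]:
    """(B - D) / C with an ion-suppression band.

    Suppression = 1 - ME.  Bands: weak suppression < 25%, medium 25-50%,
    strong > 50%; ME > 1 is ion enhancement.
    """
    if groups.mean_c <= 0:
        raise ValueError("solvent-blank mean C must be positive")
    me = (groups.mean_b - groups.mean_d) / groups.mean_c
    suppression = 1.0 - me
    if suppression <= 0:
        band = "enhancement" if me > 1 else "none"
    elif suppression < 0.25:
        band = "weak"
    elif suppression < 0.50:
        band = "medium"
    else:
        band = "strong"
    return me, band


# ---------------------------------------------------------------------------
# nested variance components
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    """Batch / extraction / injection variance decomposition.

    Variances are on the scale of the supplied data; CVs are the square
    roots divided by the grand mean.  Negative method-of-moments estimates
    are truncated to zero and flagged.
    """

    sigma2_batch: float
    sigma2_extract: float
    sigma2_injection: float
    cv_batch: float
    cv_extract: float
    cv_injection: float
    grand_mean: float
    truncated: tuple[str, ...] = ()


def variance_components(data: np.ndarray, scale: str = "intensity") -> VarianceComponents:
    """Balanced two-level nested ANOVA (batch -> extract -> injection).

    ``data`` has shape (n_batches, n_extracts, n_injections), fully
    observed.  Expected-mean-squares solution:

        sigma2_injection = MS_within
        sigma2_extract   = (MS_extract - MS_within) / n_r
        sigma2_batch     = (MS_batch - MS_extract) / (n_e * n_r)

    With ``scale="log"`` the decomposition runs on log intensities and CVs
    are mapped back via cv = sqrt(exp(sigma^2) - 1).
    """
    y = np.asarray(data, dtype=float)
    if y.ndim != 3:
        raise ValueError(
            "expect a balanced (n_batches, n_extracts, n_injections) array"
        )
    if np.isnan(y).any():
        raise ValueError("unbalanced or incomplete data are not supported")
    n_b, n_e, n_r = y.shape
    if n_b < 2 or n_e < 2 or n_r < 2:
        raise ValueError("need at least 2 levels of each nested factor")
    if scale not in ("intensity", "log"):
        raise ValueError(f"unknown scale {scale!r}")
    grand_mean_raw = float(y.mean())
    if scale == "log":
        if np.any(y <= 0):
            raise ValueError("log scale requires positive intensities")
        y = np.log(y)

    m_be = y.mean(axis=2)  # batch x extract means
    m_b = m_be.mean(axis=1)  # batch means
    m = y.mean()

    ms_within = ((y - m_be[:, :, None]) ** 2).sum() / (n_b * n_e * (n_r - 1))
    ms_extract = n_r * ((m_be - m_b[:, None]) ** 2).sum() / (n_b * (n_e - 1))
    ms_batch = n_e * n_r * ((m_b - m) ** 2).sum() / (n_b - 1)

    s2_inj = ms_within
    s2_ext = (ms_extract - ms_within) / n_r
    s2_bat = (ms_batch - ms_extract) / (n_e * n_r)

    truncated = []
    if s2_ext < 0:
        s2_ext = 0.0
        truncated.append("extract")
    if s2_bat < 0:
        s2_bat = 0.0
        truncated.append("batch")

    if scale == "log":
        cvs = [float(np.sqrt(np.expm1(s))) for s in (s2_bat, s2_ext, s2_inj)]
    else:
        cvs = [float(np.sqrt(s) / grand_mean_raw) for s in (s2_bat, s2_ext, s2_inj)]
    return VarianceComponents(
        sigma2_batch=float(s2_bat),
        sigma2_extract=float(s2_ext),
        sigma2_injection=float(s2_inj),
        cv_batch=cvs[0],
        cv_extract=cvs[1],
        cv_injection=cvs[2],
        grand_mean=grand_mean_raw,
        truncated=tuple(truncated),
    )


# ---------------------------------------------------------------------------
# linear range
# ---------------------------------------------------------------------------

class NoLinearRangeError(ValueError):
    """Fewer than three levels remain after excluding non-linear ones."""


@dataclass
class LinearRangeResult:
    slope: float
    r_squared: float
    retained_levels: np.ndarray  # contiguous from the lowest level
    excluded_levels: np.ndarray
    exclusion_reason: str = "relative deviation from through-origin fit"


def linear_range(
    levels: np.ndarray,
    responses: np.ndarray,
    tolerance: float = 0.10,
    anchor_levels: int = 3,
) -> LinearRangeResult:
    """Estimate the linear range of a dilution series under y = a*x.

    A provisional slope is anchored on the lowest ``anchor_levels`` levels
    (assumed within the linear regime) by through-origin least squares;
    the highest level is then dropped repeatedly while its mean response
    deviates from the anchored line by more than ``tolerance``
    (relative).  The final slope and the coefficient of determination are
    re-fit on the retained prefix of levels (r² on centered totals over
    all retained duplicate injections).
    """
    x = np.asarray(levels, dtype=float)
    Y = np.atleast_2d(np.asarray(responses, dtype=float))
    if Y.shape[0] != len(x):
        Y = Y.T
    if Y.shape[0] != len(x):
        raise ValueError("responses do not align with levels")
    if len(x) < 5:
        raise ValueError("need at least 5 concentration levels")
    if np.any(np.diff(x) <= 0):
        raise ValueError("levels must be strictly increasing")

    mean_resp = Y.mean(axis=1)
    xa = np.repeat(x[:anchor_levels], Y.shape[1])
    ya = Y[:anchor_levels].ravel()
    a0 = float((xa * ya).sum() / (xa * xa).sum())

    n_keep = len(x)
    while n_keep > 0:
        dev = abs(mean_resp[n_keep - 1] - a0 * x[n_keep - 1]) / (a0 * x[n_keep - 1])
        if dev <= tolerance:
            break
        n_keep -= 1
    if n_keep < 3:
        raise NoLinearRangeError(
            f"only {n_keep} levels within tolerance; no linear range"
        )

    xr = np.repeat(x[:n_keep], Y.shape[1])
    yr = Y[:n_keep].ravel()
    a = float((xr * yr).sum() / (xr * xr).sum())
    ss_res = float(((yr - a * xr) ** 2).sum())
    ss_tot = float(((yr - yr.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return LinearRangeResult(
        slope=a,
        r_squared=max(0.0, min(1.0, r2)),
        retained_levels=x[:n_keep].copy(),
        excluded_levels=x[n_keep:].copy(),
    )


# ---------------------------------------------------------------------------
# fold-change accuracy
# ---------------------------------------------------------------------------

@dataclass
class FoldChangeResult:
    nominal_fc: float
    experimental_fc: float
    p_value: float
    relative_error: float  # of the concentration difference (FC - 1)
    df: int


def fold_change_accuracy(
    table: FeatureTable,
    feature_id: str | None = None,
    baseline_level: float = 100.0,
) -> list[FoldChangeResult]:
    """Accuracy of relative quantification from a spiked accuracy series.

    Duplicate injections within each batch are averaged first; the
    fold-change of a level versus the baseline is the ratio of the means
    of the per-batch averages, the P value comes from a two-sample
    two-tailed equal-variance t-test on those averages (3 batches per
    level give df = 4), and the relative error is measured on the
    concentration difference: |(FC_exp - 1) - (FC_nom - 1)| / (FC_nom - 1).
    """
    fid = feature_id or table.intensities.index[0]
    meta = table.injections
    if "nominal_level" not in meta:
        raise ValueError("table lacks a nominal_level metadata column")
    vals = table.intensities.loc[fid]
    df_long = pd.DataFrame(
        {
            "level": meta["nominal_level"].astype(float),
            "batch": meta["batch_id"],
            "y": vals[meta.index].to_numpy(dtype=float),
        }
    )
    per_batch = df_long.groupby(["level", "batch"])["y"].mean().reset_index()
    n_batches = per_batch.groupby("level")["batch"].nunique()
    if (n_batches < 3).any():
        raise ValueError("need at least 3 batches per level")
    base = per_batch.loc[per_batch["level"] == baseline_level, "y"].to_numpy()
    if len(base) == 0:
        raise ValueError(f"baseline level {baseline_level} absent")
    if base.mean() == 0:
        raise ValueError("zero baseline mean")

    results = []
    for lev in sorted(per_batch["level"].unique()):
        if lev == baseline_level:
            continue
        y = per_batch.loc[per_batch["level"] == lev, "y"].to_numpy()
        fc = float(y.mean() / base.mean())
        t, p = stats.ttest_ind(y, base, equal_var=True)
        nominal_fc = lev / baseline_level
        rel_err = abs((fc - 1.0) - (nominal_fc - 1.0)) / (nominal_fc - 1.0)
        results.append(
            FoldChangeResult(
                nominal_fc=float(nominal_fc),
                experimental_fc=fc,
                p_value=float(p),
                relative_error=float(rel_err),
                df=len(y) + len(base) - 2,
            )
        )
    return results


def fold_change_power(
    nominal_fc: float,
    cv: float,
    n_batches: int = 3,
    duplicates: int = 2,
    alpha: float = 0.01,
) -> float:
    """Closed-form power of the two-sample t-test to detect a fold change.

    Per-batch averages of ``duplicates`` injections with per-injection CV
    ``cv`` are compared between a spiked level (mean FC) and the baseline
    (mean 1).  Two-tailed equal-variance t-test at ``alpha`` with
    df = 2*(n_batches - 1); power from the noncentral t distribution.
    """
    # multiplicative noise: absolute SD scales with the level mean, so the
    # pooled SD uses the average of the two group variances
    sd = cv * np.sqrt((1.0 + nominal_fc**2) / 2.0) / np.sqrt(duplicates)
    df = 2 * (n_batches - 1)
    ncp = (nominal_fc - 1.0) / (sd * np.sqrt(2.0 / n_batches))
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    upper = stats.nct.sf(tcrit, df, ncp)
    lower = stats.nct.cdf(-tcrit, df, ncp)  # negligible for ncp >> 0
    if not np.isfinite(lower):
        lower = 0.0
    return float(upper + lower)
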