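"""Sliding-window heterozygosity, SDV enrichment, and resampling tests.

Expected heterozygosity He = 2pq is summarized in 50 kb windows stepped by
10 kb along each chromosome arm, anchored at the arm's first observed
locus.  Windows are tested for SDV over-representation with an upper-tail
hypergeometric test against their arm's totals; significant windows are
tested for an uneven distribution across arms by resampling window sets.
Regimen-level comparisons (line-median t test, P_S<F, the
starting-frequency null, and the LD-decay profile) also live here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import DesignSpec
from .scan import qvalues

__all__ = [
    "locus_he",
    "build_windows",
    "window_mean_he",
    "window_enrichment",
    "arm_distribution_test",
    "TTestResult",
    "regimen_ttest",
    "p_s_less_f",
    "StartingFreqTest",
    "starting_freq_test",
    "LdDecayProfile",
    "ld_decay_profile",
    "ld_decay_by_arm",
    "windows_to_bed",
]


def locus_he(p):
    """Expected heterozygosity 2p(1-p); accepts scalars or arrays."""
    p = np.asarray(p, dtype=float)
    out = 2.0 * p * (1.0 - p)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# window construction and population
# ---------------------------------------------------------------------------

def build_windows(
    arm_extents: Mapping[str, tuple[int, int]],
    size: int = 50_000,
    step: int = 10_000,
) -> pd.DataFrame:
    """Tile each arm's observed extent with sliding windows.

    ``arm_extents`` maps arm -> (min_pos, max_pos) in 1-based inclusive
    coordinates (typically the first and last observed locus).  Output
    windows are 0-based half-open, anchored at min_pos; the last window
    starts at the largest anchor that still fits.  An arm shorter than
    ``size`` yields a single window covering its extent.
    """
    rows = []
    for chrom in sorted(arm_extents):
        min_pos, max_pos = arm_extents[chrom]
        if max_pos < min_pos:
            raise ValueError(f"{chrom}: max_pos < min_pos")
        start0, end0 = min_pos - 1, max_pos
        extent = end0 - start0
        if extent < size:
            rows.append((chrom, start0, end0))
            continue
        n_win = (extent - size) // step + 1
        for i in range(n_win):
            rows.append((chrom, start0 + i * step, start0 + i * step + size))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _window_ranges(
    windows: pd.DataFrame, chrom: np.ndarray, pos0: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-window [lo, hi) index ranges into the (sorted) locus arrays."""
    windows = windows.reset_index(drop=True)
    lo = np.empty(len(windows), dtype=int)
    hi = np.empty(len(windows), dtype=int)
    for arm, grp in windows.groupby("chrom", sort=False):
        in_arm = np.flatnonzero(chrom == arm)
        arm_pos = pos0[in_arm]
        base = in_arm[0] if in_arm.size else 0
        lo[grp.index] = base + np.searchsorted(arm_pos, grp["start"].to_numpy())
        hi[grp.index] = base + np.searchsorted(arm_pos, grp["end"].to_numpy())
    return lo, hi


def window_mean_he(
    windows: pd.DataFrame,
    loci: pd.DataFrame,
    he: np.ndarray,
    line_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-window, per-line arithmetic mean of locus He.

    ``loci`` must be sorted by (chrom, pos), 1-based positions.  Empty
    windows carry NaN means and are excluded from downstream medians.
    Adds an ``n`` column (locus count per window).
    """
    he = np.asarray(he, dtype=float)
    chrom = loci["chrom"].to_numpy()
    pos0 = loci["pos"].to_numpy() - 1
    lo, hi = _window_ranges(windows, chrom, pos0)

    csum = np.concatenate([np.zeros((1, he.shape[1])), np.cumsum(he, axis=0)])
    out = windows.copy()
    n = hi - lo
    out["n"] = n
    sums = csum[hi] - csum[lo]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = sums / n[:, None]
    for j, lid in enumerate(line_ids):
        out[f"he_{lid}"] = means[:, j]
    return out


def window_enrichment(
    windows: pd.DataFrame,
    loci: pd.DataFrame,
    sdv_mask: np.ndarray,
    fdr: float = 0.05,
    pi0_method: str = "smoother",
) -> pd.DataFrame:
    """Hypergeometric SDV-enrichment test per window.

    With N variants and K SDVs on a window's arm, the p-value is the
    upper tail P(X >= s) of drawing s SDVs among the window's n variants.
    q-values are computed genome-wide across all windows; a window is
    enriched when its q-value passes the FDR.
    """
    sdv_mask = np.asarray(sdv_mask, dtype=bool)
    if len(sdv_mask) != len(loci):
        raise ValueError("sdv flags must align with loci")
    chrom = loci["chrom"].to_numpy()
    pos0 = loci["pos"].to_numpy() - 1
    lo, hi = _window_ranges(windows, chrom, pos0)

    csum = np.concatenate([[0], np.cumsum(sdv_mask)])
    s = csum[hi] - csum[lo]
    n = (hi - lo) if "n" not in windows.columns else windows["n"].to_numpy()
    if not np.array_equal(n, hi - lo):
        raise ValueError("window n column inconsistent with locus assignment")

    arm_n = pd.Series(np.ones(len(loci), dtype=int)).groupby(chrom).sum()
    arm_k = pd.Series(sdv_mask.astype(int)).groupby(chrom).sum()
    big_n = windows["chrom"].map(arm_n).fillna(0).to_numpy(dtype=int)
    big_k = windows["chrom"].map(arm_k).fillna(0).to_numpy(dtype=int)
    if (s > big_k).any() or (n > big_n).any():
        raise ValueError("window contents exceed arm totals")

    p = stats.hypergeom.sf(s - 1, big_n, big_k, n)
    out = windows.copy()
    out["n"] = n
    out["s"] = s
    out["enrich_p"] = p
    out["enrich_q"] = qvalues(p, pi0_method=pi0_method)
    out["is_enriched"] = out["enrich_q"] <= fdr
    return out


def windows_to_bed(windows: pd.DataFrame, path) -> None:
    """Export windows as BED (0-based half-open), no header."""
    cols = ["chrom", "start", "end"]
    windows[cols].to_csv(path, sep="\t", index=False, header=False,
                         lineterminator="\n")


# ---------------------------------------------------------------------------
# resampling / comparison tests
# ---------------------------------------------------------------------------

def arm_distribution_test(
    significant_arms: Sequence[str],
    all_arms: Sequence[str],
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Are significant windows evenly distributed across arms?

    Resamples ``len(significant_arms)``-sized sets of windows without
    replacement from all windows and records per-arm counts; the observed
    count is flagged ``under``/``over`` when outside the 2.5-97.5
    percentile interval of the resampled counts.
    """
    rng = np.random.default_rng() if rng is None else rng
    sig = pd.Series(list(significant_arms), dtype=str)
    allw = pd.Series(list(all_arms), dtype=str)
    if len(sig) > len(allw):
        raise ValueError("more significant windows than windows")
    arms = allw.unique().tolist()
    counts_all = allw.value_counts().reindex(arms).to_numpy()
    counts_sig = sig.value_counts().reindex(arms).fillna(0).to_numpy(dtype=int)
    if not set(sig).issubset(arms):
        raise ValueError("significant windows on arms absent from all windows")

    # per-arm counts of a without-replacement window set are exactly
    # multivariate hypergeometric
    draws = rng.multivariate_hypergeometric(counts_all, len(sig), size=n_resamples)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    status = np.where(
        counts_sig < lo, "under", np.where(counts_sig > hi, "over", "ok")
    )
    return pd.DataFrame(
        {
            "arm": arms,
            "observed": counts_sig,
            "ci_low": lo,
            "ci_high": hi,
            "status": status,
        }
    )


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p_value: float
    degenerate: bool = False


def regimen_ttest(line_medians_success, line_medians_failure) -> TTestResult:
    """Pooled-variance two-sample t test of per-line median He.

    The statistic is (mean_failure - mean_success) / SE, so positive t
    means failure-selected lines are more heterozygous.  df = nS + nF - 2
    (6 for the 4+4 design).
    """
    s = np.asarray(line_medians_success, dtype=float)
    f = np.asarray(line_medians_failure, dtype=float)
    if s.size < 2 or f.size < 2:
        raise ValueError("need at least two line medians per regimen")
    df = s.size + f.size - 2
    sp2 = ((s.size - 1) * s.var(ddof=1) + (f.size - 1) * f.var(ddof=1)) / df
    diff = f.mean() - s.mean()
    if sp2 == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, df, 1.0)
        return TTestResult(float(np.sign(diff)) * np.inf, df, 0.0, degenerate=True)
    t = diff / np.sqrt(sp2 * (1.0 / s.size + 1.0 / f.size))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(float(t), df, float(p))


def p_s_less_f(
    he: np.ndarray,
    diffstat_mask: np.ndarray,
    line_ids: Sequence[str],
    design: DesignSpec,
) -> float:
    """Fraction of DiffStat loci with less variation in success lines.

    Regimen He at a locus is the mean of its four per-line He values; ties
    count as not-less.  Errors when no DiffStat loci exist.
    """
    he = np.asarray(he, dtype=float)
    mask = np.asarray(diffstat_mask, dtype=bool)
    if not mask.any():
        raise ValueError("P_S<F undefined: no DiffStat loci")
    index = {l: i for i, l in enumerate(line_ids)}
    s_cols = [index[l] for l in design.success_lines]
    f_cols = [index[l] for l in design.failure_lines]
    he_s = he[mask][:, s_cols].mean(axis=1)
    he_f = he[mask][:, f_cols].mean(axis=1)
    return float((he_s < he_f).mean())


@dataclass(frozen=True)
class StartingFreqTest:
    observed_median: float
    null_median: float
    ci_low: float
    ci_high: float
    is_low: bool
    n_resamples: int
    set_size: int


def starting_freq_test(
    start_freq: np.ndarray,
    sdv_mask: np.ndarray,
    set_size: int | None = None,
    n_resamples: int = 10_000,
    rng: np.random.Generator | None = None,
) -> StartingFreqTest:
    """Were the SDVs rare in the base population?

    Compares the median control-line (starting) frequency of the SDVs to a
    null built by resampling, with replacement, ``n_resamples`` sets of
    ``set_size`` starting frequencies from all loci and taking each set's
    median.  ``is_low`` flags an observed median below the null's 2.5th
    percentile.
    """
    rng = np.random.default_rng() if rng is None else rng
    sf = np.asarray(start_freq, dtype=float)
    mask = np.asarray(sdv_mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty SDV set")
    if set_size is None:
        set_size = int(mask.sum())
    observed = float(np.median(sf[mask]))

    medians = np.empty(n_resamples)
    chunk = max(1, 10_000_000 // max(set_size, 1))
    done = 0
    while done < n_resamples:
        b = min(chunk, n_resamples - done)
        draws = rng.choice(sf, size=(b, set_size), replace=True)
        medians[done : done + b] = np.median(draws, axis=1)
        done += b
    lo, hi = np.percentile(medians, [2.5, 97.5])
    return StartingFreqTest(
        observed_median=observed,
        null_median=float(np.median(medians)),
        ci_low=float(lo),
        ci_high=float(hi),
        is_low=bool(observed < lo),
        n_resamples=n_resamples,
        set_size=set_size,
    )


# ---------------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------------

@dataclass
class LdDecayProfile:
    """Mean p-value by distance-to-nearest-SDV in 50 bp bins."""

    bin_mid: np.ndarray
    mean_p: np.ndarray
    smoothed: np.ndarray
    n_per_bin: np.ndarray
    independence_distance: float
    no_decay: bool


def ld_decay_profile(
    p_values: np.ndarray,
    positions: np.ndarray,
    sdv_positions: np.ndarray,
    bin_width: int = 50,
    max_dist: int = 20_000,
    smooth_bins: int = 5,
    flat_range: float = 0.05,
) -> LdDecayProfile:
    """Profile GLM p-values against distance to the nearest SDV.

    Linkage is taken to have broken down where the smoothed profile
    peaks, i.e. first reaches its plateau: the independence distance is
    the midpoint of the first bin whose smoothed mean comes within 5% of
    the profile's full range below its maximum (a noise-robust reading of
    the first peak).  When the smoothed profile spans less than
    ``flat_range`` the profile is flagged ``no_decay`` and the distance is
    NaN (a flat profile has no stable peak).  SDVs themselves (distance 0)
    are excluded.
    """
    p = np.asarray(p_values, dtype=float)
    pos = np.asarray(positions, dtype=np.int64)
    sdv = np.unique(np.asarray(sdv_positions, dtype=np.int64))
    if sdv.size == 0:
        raise ValueError("no SDV positions given")
    dist = _distance_to_nearest_sdv(pos, sdv)
    return _profile_from_distances(
        p, dist, bin_width=bin_width, max_dist=max_dist,
        smooth_bins=smooth_bins, flat_range=flat_range,
    )


def _distance_to_nearest_sdv(pos: np.ndarray, sdv: np.ndarray) -> np.ndarray:
    """Distance to the nearest SDV, excluding the locus itself.

    A locus that sits exactly on an SDV position measures its distance to
    the nearest *other* SDV (infinite when there is none), so loci inside
    a fully significant linkage block still contribute at their true
    spacing instead of being discarded.
    """
    idx = np.searchsorted(sdv, pos)
    big = np.iinfo(np.int64).max // 4
    padded = np.concatenate([[-big], sdv, [big]])
    exact = (idx < sdv.size) & (sdv[np.clip(idx, 0, sdv.size - 1)] == pos)
    # padded[idx] is the SDV strictly below pos; the SDV at-or-above is
    # padded[idx + 1], and for an exact hit the next *other* SDV above is
    # padded[idx + 2]
    d_left = (pos - padded[idx]).astype(float)
    d_right = (padded[np.where(exact, idx + 2, idx + 1)] - pos).astype(float)
    dist = np.minimum(np.abs(d_left), np.abs(d_right))
    return np.where(dist > big / 2, np.inf, dist)


def _profile_from_distances(
    p: np.ndarray,
    dist: np.ndarray,
    bin_width: int,
    max_dist: int,
    smooth_bins: int,
    flat_range: float,
) -> LdDecayProfile:
    keep = (dist > 0) & (dist <= max_dist)
    n_bins = max_dist // bin_width
    bins = np.minimum((dist[keep] - 1) // bin_width, n_bins - 1).astype(int)
    sums = np.bincount(bins, weights=p[keep], minlength=n_bins)
    counts = np.bincount(bins, minlength=n_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_p = sums / counts
    mean_p[counts == 0] = np.nan

    # count-weighted moving average, so sparsely populated distance bins
    # cannot inject spurious maxima
    rsum = (
        pd.Series(sums).rolling(smooth_bins, center=True, min_periods=1)
        .sum().to_numpy()
    )
    rcount = (
        pd.Series(counts.astype(float))
        .rolling(smooth_bins, center=True, min_periods=1)
        .sum().to_numpy()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = rsum / rcount
    bin_mid = (np.arange(n_bins) + 0.5) * bin_width

    finite = np.flatnonzero(np.isfinite(smoothed))
    if finite.size == 0:
        return LdDecayProfile(bin_mid, mean_p, smoothed, counts, np.nan, True)
    span = smoothed[finite].max() - smoothed[finite].min()
    if span < flat_range:
        return LdDecayProfile(bin_mid, mean_p, smoothed, counts, np.nan, True)

    # first bin reaching the plateau, whose level is estimated robustly as
    # the median of the far half of the profile (a raw maximum would chase
    # noise in sparsely populated distant bins)
    lo = smoothed[finite].min()
    plateau = float(np.median(smoothed[finite[finite.size // 2:]]))
    thresh = lo + 0.95 * (plateau - lo)
    at_plateau = finite[smoothed[finite] >= thresh]
    peak = at_plateau[0] if at_plateau.size else finite[-1]
    return LdDecayProfile(
        bin_mid, mean_p, smoothed, counts, float(bin_mid[peak]), False
    )


def ld_decay_by_arm(
    p_values: np.ndarray,
    chrom: np.ndarray,
    positions: np.ndarray,
    sdv_mask: np.ndarray,
    **kwargs,
) -> dict[str, LdDecayProfile]:
    """Per-arm LD-decay profiles plus a pooled ``overall`` profile.

    Distances are always to the nearest SDV on the same arm; arms without
    SDVs are skipped.
    """
    p = np.asarray(p_values, dtype=float)
    chrom = np.asarray(chrom)
    pos = np.asarray(positions, dtype=np.int64)
    mask = np.asarray(sdv_mask, dtype=bool)
    if not mask.any():
        raise ValueError("no SDVs flagged")

    out: dict[str, LdDecayProfile] = {}
    pooled_p, pooled_d = [], []
    for arm in pd.unique(chrom):
        sel = chrom == arm
        if not mask[sel].any():
            continue
        prof = ld_decay_profile(p[sel], pos[sel], pos[sel & mask], **kwargs)
        out[str(arm)] = prof
        pooled_p.append(p[sel])
        pooled_d.append(
            _distance_to_nearest_sdv(pos[sel],
                                     np.unique(pos[sel & mask]))
        )
    defaults = dict(bin_width=50, max_dist=20_000, smooth_bins=5,
                    flat_range=0.05)
    defaults.update(kwargs)
    out["overall"] = _profile_from_distances(
        np.concatenate(pooled_p), np.concatenate(pooled_d), **defaults
    )
    return out
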