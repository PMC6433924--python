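"""Candidate-locus scan for bidirectional selection on replicate lines.

Two criteria identify candidates at each biallelic locus:

* **DiffStat** — the minimum allele-frequency difference between any
  success-line / failure-line pair; nonzero only when the two regimens'
  frequency ranges do not overlap.  A locus is a *significant DiffStat*
  locus when its DiffStat exceeds the drift statistic (the larger of the
  two within-regimen frequency ranges).
* **Quasibinomial GLM** — a logit-link binomial GLM of (minor, major) read
  counts on the regimen factor, with dispersion estimated from the
  full-model Pearson statistic and an analysis-of-deviance F test;
  p-values are converted to Storey q-values and thresholded at an FDR.

Significantly diverged variants (SDVs) satisfy both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from scipy.special import xlogy

from .data import AlleleCountTable, DesignSpec, allele_frequencies

__all__ = [
    "diffstat",
    "drift_stat",
    "diffstat_profile",
    "drift_stat_profile",
    "QuasibinomialFTest",
    "quasibinomial_ftest",
    "quasibinomial_ftest_profile",
    "estimate_pi0",
    "qvalues",
    "LocusScan",
    "scan_loci",
    "control_contrast",
]

_DEGENERATE_PHI = 1e-12


# ---------------------------------------------------------------------------
# DiffStat and the drift statistic
# ---------------------------------------------------------------------------

def diffstat_profile(success_p: np.ndarray, failure_p: np.ndarray) -> np.ndarray:
    """Vectorized DiffStat over loci.

    ``success_p`` and ``failure_p`` are (n_loci, n_lines) frequency arrays.
    Strict inequalities: any shared value across regimens gives zero.
    """
    s = np.atleast_2d(np.asarray(success_p, dtype=float))
    f = np.atleast_2d(np.asarray(failure_p, dtype=float))
    s_min, s_max = s.min(axis=1), s.max(axis=1)
    f_min, f_max = f.min(axis=1), f.max(axis=1)
    return np.where(
        s_min > f_max,
        s_min - f_max,
        np.where(s_max < f_min, f_min - s_max, 0.0),
    )


def drift_stat_profile(success_p: np.ndarray, failure_p: np.ndarray) -> np.ndarray:
    """Vectorized drift statistic: the larger within-regimen frequency range."""
    s = np.atleast_2d(np.asarray(success_p, dtype=float))
    f = np.atleast_2d(np.asarray(failure_p, dtype=float))
    return np.maximum(s.max(axis=1) - s.min(axis=1), f.max(axis=1) - f.min(axis=1))


def _check_arity(s: np.ndarray, f: np.ndarray) -> None:
    if s.shape != (4,) or f.shape != (4,):
        raise ValueError("expected exactly 4 frequencies per regimen")
    for arr in (s, f):
        if ((arr < 0) | (arr > 1)).any():
            raise ValueError("frequencies must lie in [0, 1]")


def diffstat(success_p, failure_p) -> float:
    """DiffStat for one locus given 4 success and 4 failure frequencies.

    Returns min(S) - max(F) when all success lines lie strictly above all
    failure lines, min(F) - max(S) in the mirror case, and 0 when the two
    ranges overlap or touch.  Symmetric in regimen order.
    """
    s = np.asarray(success_p, dtype=float)
    f = np.asarray(failure_p, dtype=float)
    _check_arity(s, f)
    return float(diffstat_profile(s[None, :], f[None, :])[0])


def drift_stat(success_p, failure_p) -> float:
    """Within-regimen divergence yardstick for one locus."""
    s = np.asarray(success_p, dtype=float)
    f = np.asarray(failure_p, dtype=float)
    _check_arity(s, f)
    return float(drift_stat_profile(s[None, :], f[None, :])[0])


# ---------------------------------------------------------------------------
# quasibinomial GLM F test
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QuasibinomialFTest:
    f_stat: float
    p_value: float
    df_num: int
    df_den: int
    dispersion: float
    degenerate_dispersion: bool


def _binomial_deviance(y, n, mu):
    """Deviance contributions, summed over lines (axis 1)."""
    return 2.0 * (
        xlogy(y, y) - xlogy(y, mu) + xlogy(n - y, n - y) - xlogy(n - y, n - mu)
    ).sum(axis=1)


def quasibinomial_ftest_profile(
    minor: np.ndarray, total: np.ndarray, group_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized quasibinomial analysis-of-deviance F test over loci.

    With a single two-level factor the IRLS fit collapses to pooled group
    proportions, so both model deviances have closed forms.  The dispersion
    phi is the full-model Pearson X^2 divided by its residual df
    (n_lines - 2); F = (D0 - D1) / phi on (1, n_lines - 2) df.

    Returns ``(f, p, phi, degenerate)`` arrays.  Loci with no deviance
    difference get F = 0, p = 1; loci with a deviance difference but
    vanishing dispersion get F = +inf, p = 0 and the degenerate flag.
    """
    y = np.atleast_2d(np.asarray(minor, dtype=float))
    n = np.atleast_2d(np.asarray(total, dtype=float))
    g = np.asarray(group_mask, dtype=bool)
    if y.shape != n.shape or y.shape[1] != g.size:
        raise ValueError("minor, total and group labels must align")
    if (n < 1).any():
        raise ValueError("every line needs at least one read")
    if g.all() or not g.any():
        raise ValueError("both factor levels must be present")
    k = y.shape[1]
    df_den = k - 2

    y1, n1 = y[:, g].sum(axis=1), n[:, g].sum(axis=1)
    y2, n2 = y[:, ~g].sum(axis=1), n[:, ~g].sum(axis=1)
    p1, p2 = y1 / n1, y2 / n2
    p0 = (y1 + y2) / (n1 + n2)

    phat = np.where(g[None, :], p1[:, None], p2[:, None])
    mu1 = n * phat
    d1 = _binomial_deviance(y, n, mu1)
    d0 = _binomial_deviance(y, n, n * p0[:, None])

    with np.errstate(invalid="ignore", divide="ignore"):
        pearson_terms = (y - mu1) ** 2 / (mu1 * (1.0 - phat))
    pearson_terms = np.where(np.isfinite(pearson_terms), pearson_terms, 0.0)
    phi = pearson_terms.sum(axis=1) / df_den

    delta = np.clip(d0 - d1, 0.0, None)
    no_signal = delta < 1e-12
    degenerate = (~no_signal) & (phi < _DEGENERATE_PHI)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(no_signal, 0.0, delta / np.where(phi > 0, phi, np.nan))
    f = np.where(degenerate, np.inf, f)
    p = np.where(
        no_signal, 1.0, np.where(degenerate, 0.0, stats.f.sf(f, 1, df_den))
    )
    return f, p, phi, degenerate


def quasibinomial_ftest(minor_counts, total_counts, regimen) -> QuasibinomialFTest:
    """Quasibinomial GLM F test at one locus.

    ``regimen`` is a length-k label vector with exactly two levels (e.g.
    8 labels in {success, failure} for the selection scan, 7 for a
    regimen-vs-control contrast).  Denominator df is k - 2.
    """
    labels = list(regimen)
    levels = sorted(set(labels))
    if len(levels) != 2:
        raise ValueError(f"expected exactly two regimen levels, got {levels}")
    mask = np.array([l == levels[0] for l in labels])
    f, p, phi, dg = quasibinomial_ftest_profile(
        np.asarray(minor_counts, dtype=float)[None, :],
        np.asarray(total_counts, dtype=float)[None, :],
        mask,
    )
    return QuasibinomialFTest(
        f_stat=float(f[0]),
        p_value=float(p[0]),
        df_num=1,
        df_den=len(labels) - 2,
        dispersion=float(phi[0]),
        degenerate_dispersion=bool(dg[0]),
    )


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def estimate_pi0(p: np.ndarray, method: str = "smoother") -> float:
    """Estimate the null proportion pi0 from a p-value vector.

    ``smoother``: Storey's recipe — pi0(lambda) = #{p > lambda}/(m(1-lambda))
    over lambda = 0.05, 0.10, ..., 0.95, smoothed by a natural cubic
    smoothing spline and evaluated at lambda = 0.95, clipped to (0, 1].
    ``fixed_1``: pi0 = 1 (Benjamini-Hochberg behaviour).
    """
    if method == "fixed_1":
        return 1.0
    if method != "smoother":
        raise ValueError(f"unknown pi0 method {method!r}")
    p = np.asarray(p, dtype=float)
    lams = np.arange(0.05, 0.96, 0.05)
    pi0_lam = np.array([(p > lam).mean() / (1.0 - lam) for lam in lams])
    try:
        spline = make_smoothing_spline(lams, pi0_lam)
        pi0 = float(spline(lams[-1]))
    except Exception:
        pi0 = float(pi0_lam[-1])
    return float(min(max(pi0, 1e-8), 1.0))


def qvalues(p, pi0_method: str = "smoother") -> np.ndarray:
    """Storey q-values for a vector of p-values.

    q_(i) = min_{j >= i} pi0 * m * p_(j) / j, capped at 1.  With
    ``pi0_method='fixed_1'`` this is exactly Benjamini-Hochberg.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    pi0 = estimate_pi0(p, pi0_method)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


# ---------------------------------------------------------------------------
# whole-table scan
# ---------------------------------------------------------------------------

@dataclass
class LocusScan:
    """Per-locus scan results.

    ``stats`` has one row per locus with coordinate, statistic, flag and
    per-line ``p_<line>`` / ``he_<line>`` columns.  ``freqs`` and ``he``
    are the matching (n_loci, n_lines) arrays.  ``glm_sig_threshold`` is
    the largest GLM p-value among q-significant loci (the data-dependent
    significance threshold; NaN when nothing is significant).
    """

    stats: pd.DataFrame
    freqs: np.ndarray
    he: np.ndarray
    line_ids: tuple[str, ...]
    design: DesignSpec
    fdr: float
    glm_sig_threshold: float

    @property
    def sdv_mask(self) -> np.ndarray:
        return self.stats["is_sdv"].to_numpy()

    def to_tsv(self, path) -> None:
        self.stats.to_csv(path, sep="\t", index=False, lineterminator="\n")


def scan_loci(
    table: AlleleCountTable,
    design: DesignSpec,
    fdr: float = 0.05,
    pi0_method: str = "smoother",
) -> LocusScan:
    """Run the full candidate-locus scan on a filtered, oriented table."""
    design.require_selection_lines()
    freqs = allele_frequencies(table)
    he = 2.0 * freqs * (1.0 - freqs)

    s_cols = table.line_columns(design.success_lines)
    f_cols = table.line_columns(design.failure_lines)
    c_cols = table.line_columns(design.control_lines)

    ds = diffstat_profile(freqs[:, s_cols], freqs[:, f_cols])
    dr = drift_stat_profile(freqs[:, s_cols], freqs[:, f_cols])

    sel_cols = np.concatenate([s_cols, f_cols])
    group = np.zeros(sel_cols.size, dtype=bool)
    group[: s_cols.size] = True
    depth = table.depth()
    _, glm_p, _, _ = quasibinomial_ftest_profile(
        table.minor[:, sel_cols], depth[:, sel_cols], group
    )
    glm_q = qvalues(glm_p, pi0_method=pi0_method)

    is_diffstat = ds > 0
    is_sig_diffstat = ds > dr
    is_glm_sig = glm_q <= fdr
    is_sdv = is_sig_diffstat & is_glm_sig
    threshold = float(glm_p[is_glm_sig].max()) if is_glm_sig.any() else float("nan")
    start_freq = (
        freqs[:, c_cols].mean(axis=1) if c_cols.size else np.full(len(freqs), np.nan)
    )

    stats_df = table.loci[["chrom", "pos"]].copy()
    stats_df["diffstat"] = ds
    stats_df["drift_stat"] = dr
    stats_df["glm_p"] = glm_p
    stats_df["glm_q"] = glm_q
    stats_df["is_diffstat"] = is_diffstat
    stats_df["is_sig_diffstat"] = is_sig_diffstat
    stats_df["is_glm_sig"] = is_glm_sig
    stats_df["is_sdv"] = is_sdv
    stats_df["start_freq"] = start_freq
    for j, lid in enumerate(table.line_ids):
        stats_df[f"p_{lid}"] = freqs[:, j]
    for j, lid in enumerate(table.line_ids):
        stats_df[f"he_{lid}"] = he[:, j]

    return LocusScan(
        stats=stats_df,
        freqs=freqs,
        he=he,
        line_ids=table.line_ids,
        design=design,
        fdr=fdr,
        glm_sig_threshold=threshold,
    )


def control_contrast(
    table: AlleleCountTable,
    design: DesignSpec,
    fdr: float = 0.05,
    pi0_method: str = "smoother",
) -> pd.DataFrame:
    """Loci diverged from the controls in opposite directions.

    Runs the quasibinomial F test independently for success-vs-control and
    failure-vs-control, q-adjusts each contrast across loci, and flags loci
    where both contrasts are significant and the regimen mean frequencies
    deviate from the control mean with opposite signs.
    """
    design.require_selection_lines()
    design.require_controls()
    freqs = allele_frequencies(table)
    depth = table.depth()

    def contrast(cols_a: np.ndarray, cols_c: np.ndarray):
        cols = np.concatenate([cols_a, cols_c])
        mask = np.zeros(cols.size, dtype=bool)
        mask[: cols_a.size] = True
        _, p, _, _ = quasibinomial_ftest_profile(
            table.minor[:, cols], depth[:, cols], mask
        )
        return p

    s_cols = table.line_columns(design.success_lines)
    f_cols = table.line_columns(design.failure_lines)
    c_cols = table.line_columns(design.control_lines)

    p_s = contrast(s_cols, c_cols)
    p_f = contrast(f_cols, c_cols)
    q_s = qvalues(p_s, pi0_method=pi0_method)
    q_f = qvalues(p_f, pi0_method=pi0_method)

    control_mean = freqs[:, c_cols].mean(axis=1)
    delta_s = freqs[:, s_cols].mean(axis=1) - control_mean
    delta_f = freqs[:, f_cols].mean(axis=1) - control_mean
    opposite = delta_s * delta_f < 0

    out = table.loci[["chrom", "pos"]].copy()
    out["q_success_vs_control"] = q_s
    out["q_failure_vs_control"] = q_f
    out["delta_success"] = delta_s
    out["delta_failure"] = delta_f
    out["is_divergent"] = (q_s <= fdr) & (q_f <= fdr) & opposite
    return out
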