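"""Pairwise F_ST between pool-seq lines, reads treated as sampled alleles.

The default estimator is the Weir & Cockerham (1984) two-population
multilocus estimator in its haploid (allele-count) form, combined across
loci as a ratio of averages; read depths stand in for sample sizes.  A
``hudson`` switch (Bhatia et al. 2013 ratio-of-averages form) is provided
because absolute F_ST levels are estimator-dependent — between-regimen
differences (DF_ST) are robust to the choice.

Loci that are monomorphic across both lines carry no information and
contribute zero to both the numerator and denominator sums.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AlleleCountTable, DesignSpec

__all__ = ["pairwise_fst", "fst_matrix", "FstResult", "regimen_fst",
           "regimen_fst_arrays"]

ESTIMATORS = ("wc84", "hudson")


def _wc84_terms(p1, n1, p2, n2):
    """Per-locus WC84 numerator/denominator (haploid, r = 2)."""
    ntot = n1 + n2
    pbar = (n1 * p1 + n2 * p2) / ntot
    msp = n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        msg = (n1 * p1 * (1 - p1) + n2 * p2 * (1 - p2)) / (ntot - 2)
    msg = np.where(ntot > 2, msg, 0.0)
    nc = ntot - (n1 * n1 + n2 * n2) / ntot
    a = msp - msg
    d = msp + (nc - 1.0) * msg
    informative = (pbar > 0) & (pbar < 1)
    return np.where(informative, a, 0.0), np.where(informative, d, 0.0)


def _hudson_terms(p1, n1, p2, n2):
    """Per-locus Hudson estimator terms (Bhatia et al. 2013)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        num = (
            (p1 - p2) ** 2
            - p1 * (1 - p1) / (n1 - 1)
            - p2 * (1 - p2) / (n2 - 1)
        )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = (n1 > 1) & (n2 > 1) & np.isfinite(num)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    informative = ok & (pbar > 0) & (pbar < 1)
    return np.where(informative, num, 0.0), np.where(informative, den, 0.0)


_TERM_FNS = {"wc84": _wc84_terms, "hudson": _hudson_terms}


def pairwise_fst(
    counts_i: tuple[np.ndarray, np.ndarray],
    counts_j: tuple[np.ndarray, np.ndarray],
    estimator: str = "wc84",
) -> float:
    """Multilocus F_ST between two lines from (minor, major) count vectors.

    Combines per-locus variance components as a ratio of averages:
    sum of numerators over sum of denominators.  Returns NaN (with a
    warning) when every locus is uninformative (monomorphic in both
    lines).  Symmetric in the two lines; can be slightly negative under
    no differentiation.
    """
    if estimator not in _TERM_FNS:
        raise ValueError(f"unknown estimator {estimator!r}; use one of {ESTIMATORS}")
    mi, ma = (np.asarray(a, dtype=float) for a in counts_i)
    mj, mb = (np.asarray(a, dtype=float) for a in counts_j)
    n1, n2 = mi + ma, mj + mb
    if (n1 == 0).any() or (n2 == 0).any():
        raise ValueError("zero read depth at some locus")
    p1, p2 = mi / n1, mj / n2
    a, d = _TERM_FNS[estimator](p1, n1, p2, n2)
    dsum = d.sum()
    if dsum == 0.0:
        warnings.warn("F_ST undefined: all loci monomorphic in both lines",
                      stacklevel=2)
        return float("nan")
    return float(a.sum() / dsum)


def fst_matrix(
    table: AlleleCountTable, estimator: str = "wc84"
) -> pd.DataFrame:
    """Symmetric line x line F_ST matrix (diagonal NaN)."""
    k = table.n_lines
    out = np.full((k, k), np.nan)
    for i, j in itertools.combinations(range(k), 2):
        est = pairwise_fst(
            (table.minor[:, i], table.major[:, i]),
            (table.minor[:, j], table.major[:, j]),
            estimator=estimator,
        )
        out[i, j] = out[j, i] = est
    return pd.DataFrame(out, index=table.line_ids, columns=table.line_ids)


@dataclass
class FstResult:
    """Pairwise F_ST matrix with within-regimen summaries."""

    matrix: pd.DataFrame
    fst_success: float   # mean over the 6 success-line pairs
    fst_failure: float   # mean over the 6 failure-line pairs
    dfst: float          # fst_success - fst_failure

    @property
    def estimator(self) -> str:
        return self.matrix.attrs.get("estimator", "wc84")


def regimen_fst_arrays(
    minor: np.ndarray,
    major: np.ndarray,
    s_cols: np.ndarray,
    f_cols: np.ndarray,
    estimator: str = "wc84",
) -> tuple[float, float]:
    """Within-regimen mean pairwise F_ST from raw count arrays.

    Returns (mean success F_ST, mean failure F_ST); used both on real
    tables and inside the drift simulator so both paths share one code
    path.
    """
    def mean_within(cols):
        vals = [
            pairwise_fst(
                (minor[:, i], major[:, i]),
                (minor[:, j], major[:, j]),
                estimator=estimator,
            )
            for i, j in itertools.combinations(cols, 2)
        ]
        return float(np.mean(vals))

    return mean_within(list(s_cols)), mean_within(list(f_cols))


def regimen_fst(
    table: AlleleCountTable, design: DesignSpec, estimator: str = "wc84"
) -> FstResult:
    """Per-regimen mean pairwise F_ST and their difference DF_ST."""
    design.require_selection_lines()
    matrix = fst_matrix(table, estimator=estimator)
    matrix.attrs["estimator"] = estimator
    s_cols = table.line_columns(design.success_lines)
    f_cols = table.line_columns(design.failure_lines)
    fs = float(
        np.mean([matrix.iat[i, j] for i, j in itertools.combinations(s_cols, 2)])
    )
    ff = float(
        np.mean([matrix.iat[i, j] for i, j in itertools.combinations(f_cols, 2)])
    )
    return FstResult(matrix=matrix, fst_success=fs, fst_failure=ff, dfst=fs - ff)
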