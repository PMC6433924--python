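"""Synthetic bidirectional-selection experiment with known ground truth.

Emulates the structure of the selection experiment — 4 success-selected,
4 failure-selected and 3 control lines of ~50 flies evolved for 14
generations, then pool-sequenced — with selection acting directly on
allele frequencies at planted causal loci through the genic recursion
p' = p(1+s) / (1+ps).  At causal loci the minor allele is favoured in
failure lines and disfavoured in success lines; controls drift neutrally.
The generator returns a valid :class:`~lekscan.data.AlleleCountTable`
plus an :class:`ExperimentTruth` for parameter-recovery evaluation.

Optional linkage blocks give groups of neighbouring loci one shared
latent trajectory (plus independent read noise), producing the spatial
p-value autocorrelation needed to exercise the LD-decay profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import AlleleCountTable, DesignSpec
from .drift import default_coverage_pool, default_start_freq_pool
from .scan import LocusScan

__all__ = [
    "ExperimentConfig",
    "ExperimentTruth",
    "RecoveryMetrics",
    "selection_update",
    "simulate_experiment",
    "evaluate_recovery",
]

ARMS = ("2L", "2R", "3L", "3R", "X")


def selection_update(p, s):
    """One generation of genic selection: p' = p(1+s) / (1+ps).

    Identity at s = 0; 0 and 1 are fixed points for any s.  Accepts
    scalars or arrays.
    """
    p = np.asarray(p, dtype=float)
    denom = 1.0 + p * s
    if (denom <= 0).any():
        raise ValueError("selection recursion undefined: 1 + p*s <= 0")
    out = p * (1.0 + s) / denom
    return float(out) if out.ndim == 0 else out


@dataclass
class ExperimentConfig:
    """Study conditions of the emulated experiment.

    Defaults mirror the real design: 4/4/3 lines of N = 50 for 14
    generations, depth ~30 reads, and a rare-allele base spectrum with
    mean ~0.12.  ``sel_coeff`` is the per-generation genic selection
    coefficient at causal loci (favouring the minor allele in failure
    lines, disfavouring it in success lines).
    """

    n_loci: int = 5_000
    fraction_causal: float = 0.0
    sel_coeff: float = 0.5
    n_population: int = 50
    generations: int = 14
    n_success_lines: int = 4
    n_failure_lines: int = 4
    n_control_lines: int = 3
    control_n_multiplier: float = 1.0
    coverage_pool: np.ndarray | None = None
    base_freq_alpha: float = 0.4
    base_freq_beta: float = 9.1
    base_freq_min: float = 0.05
    base_freq_max: float = 0.5
    locus_spacing_bp: int = 2_000
    linkage_block_bp: int | None = None
    causal_rare_quantile: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_causal <= 1.0:
            raise ValueError("fraction_causal must lie in [0, 1]")
        if self.causal_rare_quantile is not None and not (
            0.0 < self.causal_rare_quantile <= 1.0
        ):
            raise ValueError("causal_rare_quantile must lie in (0, 1]")
        if not abs(self.sel_coeff) < 1.0:
            raise ValueError("|sel_coeff| must be < 1")
        if self.n_population < 1 or self.generations < 0:
            raise ValueError("invalid population size or generation count")


@dataclass
class ExperimentTruth:
    """Ground truth of one simulated experiment."""

    loci: pd.DataFrame              # chrom, pos of every locus
    causal_indices: np.ndarray      # row indices into loci
    sel_coeff: np.ndarray           # per-locus s (0 at neutral loci)
    true_freqs: np.ndarray          # final true p, (n_loci, n_lines)
    line_ids: tuple[str, ...]

    def causal_keys(self) -> set[tuple[str, int]]:
        sub = self.loci.iloc[self.causal_indices]
        return set(zip(sub["chrom"], sub["pos"]))


def _layout_positions(config: ExperimentConfig) -> pd.DataFrame:
    chunks = np.array_split(np.arange(config.n_loci), len(ARMS))
    chroms, positions = [], []
    for arm, chunk in zip(ARMS, chunks):
        chroms.extend([arm] * len(chunk))
        positions.extend(1 + config.locus_spacing_bp * np.arange(len(chunk)))
    return pd.DataFrame({"chrom": chroms, "pos": positions,
                         "ref": "A", "alt": "T"})


def simulate_experiment(
    config: ExperimentConfig, rng: np.random.Generator
) -> tuple[AlleleCountTable, ExperimentTruth]:
    """Generate one synthetic experiment.

    Per generation and line: genic selection at causal loci (selection
    lines only, signs opposed between regimens), then binomial(2N) drift;
    after the final generation each locus x line cell is observed through
    pool-seq read sampling.  Deterministic given ``rng`` state.
    """
    loci = _layout_positions(config)
    n = config.n_loci

    # latent trajectories: one per linkage block, or one per locus
    if config.linkage_block_bp:
        block_key = pd.Series(
            loci["chrom"].astype(str)
            + ":"
            + ((loci["pos"] - 1) // config.linkage_block_bp).astype(str)
        )
        block_of = block_key.groupby(block_key, sort=False).ngroup().to_numpy()
    else:
        block_of = np.arange(n)
    n_blocks = block_of.max() + 1

    p0_pool = default_start_freq_pool(
        rng,
        alpha=config.base_freq_alpha,
        beta=config.base_freq_beta,
        low=config.base_freq_min,
        high=config.base_freq_max,
    )
    p0 = rng.choice(p0_pool, size=n_blocks, replace=True)

    # choose causal loci after the base frequencies are known, so they can
    # optionally be planted among the rarer starting alleles
    n_causal = int(round(config.fraction_causal * n))
    p0_locus = p0[block_of]
    if n_causal:
        if config.causal_rare_quantile is not None:
            cutoff = np.quantile(p0_locus, config.causal_rare_quantile)
            eligible = np.flatnonzero(p0_locus <= cutoff)
        else:
            eligible = np.arange(n)
        causal = np.sort(rng.choice(eligible, size=n_causal, replace=False))
    else:
        causal = np.array([], dtype=int)
    s_vec = np.zeros(n)
    s_vec[causal] = config.sel_coeff
    # a causal locus makes its whole linkage block's latent trajectory
    # selected (blocks model perfectly linked sites)
    s_block = np.zeros(n_blocks)
    s_block[block_of[causal]] = config.sel_coeff

    line_ids = (
        tuple(f"S{i+1}" for i in range(config.n_success_lines))
        + tuple(f"F{i+1}" for i in range(config.n_failure_lines))
        + tuple(f"C{i+1}" for i in range(config.n_control_lines))
    )
    regimens = (
        ["success"] * config.n_success_lines
        + ["failure"] * config.n_failure_lines
        + ["control"] * config.n_control_lines
    )
    design = DesignSpec(dict(zip(line_ids, regimens)))
    n_lines = len(line_ids)

    two_n = 2 * config.n_population
    two_n_ctrl = max(2, int(round(2 * config.n_population
                                  * config.control_n_multiplier)))
    p = np.repeat(p0[:, None], n_lines, axis=1)
    sel_sign = np.array(
        [{"success": -1.0, "failure": 1.0, "control": 0.0}[r] for r in regimens]
    )
    for _ in range(config.generations):
        s_eff = s_block[:, None] * sel_sign[None, :]
        p = selection_update(p, s_eff)
        for j, reg in enumerate(regimens):
            tn = two_n_ctrl if reg == "control" else two_n
            p[:, j] = rng.binomial(tn, p[:, j]) / tn

    true_p = p[block_of]
    cov = config.coverage_pool
    if cov is None:
        cov = default_coverage_pool(rng)
    k = rng.choice(np.asarray(cov, dtype=np.int64), size=true_p.shape,
                   replace=True)
    minor = rng.binomial(k, true_p)
    table = AlleleCountTable(loci, line_ids, minor, k - minor)
    truth = ExperimentTruth(
        loci=loci[["chrom", "pos"]].copy(),
        causal_indices=causal,
        sel_coeff=s_vec,
        true_freqs=true_p,
        line_ids=line_ids,
    )
    return table, truth


@dataclass(frozen=True)
class RecoveryMetrics:
    precision: float     # NaN (undefined) when no SDVs were called
    recall: float
    enrichment: float    # precision / base rate of causal loci; NaN if no SDVs
    n_sdv: int
    n_causal: int


def evaluate_recovery(scan: LocusScan, truth: ExperimentTruth) -> RecoveryMetrics:
    """Precision/recall of the SDV call set against planted causal loci.

    Loci are matched on (chrom, pos), so the scan may have been run on a
    filtered subset of the generated table.  The enrichment factor is the
    SDV precision divided by the genome-wide causal fraction.
    """
    causal = truth.causal_keys()
    sdv_rows = scan.stats.loc[scan.stats["is_sdv"], ["chrom", "pos"]]
    sdv = set(zip(sdv_rows["chrom"], sdv_rows["pos"]))
    n_causal = len(causal)
    hits = len(sdv & causal)
    if sdv:
        precision = hits / len(sdv)
        base = n_causal / len(truth.loci)
        enrichment = precision / base if base > 0 else float("nan")
    else:
        precision = float("nan")
        enrichment = float("nan")
    recall = hits / n_causal if n_causal else float("nan")
    return RecoveryMetrics(
        precision=precision,
        recall=recall,
        enrichment=enrichment,
        n_sdv=len(sdv),
        n_causal=n_causal,
    )
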