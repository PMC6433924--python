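"""Pool-seq allele-count tables: parsing, orientation, filtering, frequencies.

The universal input of the pipeline is a loci x lines matrix of
(minor_reads, major_reads) pairs with genomic coordinates, wrapped in
:class:`AlleleCountTable`.  Two dialects are read: a native TSV
(``chrom pos ref alt`` followed by ``<line>.minor <line>.major`` column
pairs) and the popoolation2 "sync" format (per-population ``A:T:C:G:N:del``
tallies).  Line-to-regimen assignment lives in :class:`DesignSpec`.

Coordinates are 1-based inclusive on input (VCF convention); window
arithmetic elsewhere converts to 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "REGIMENS",
    "CountTableParseError",
    "DesignSpec",
    "AlleleCountTable",
    "read_count_table",
    "write_count_table",
    "read_design",
    "orient_global_minor",
    "filter_loci",
    "allele_frequencies",
]

REGIMENS = ("success", "failure", "control")

#: fixed tally order of the sync dialect
SYNC_ALLELES = ("A", "T", "C", "G", "N", "del")

_LOCUS_KEY = ("chrom", "pos")
_LOCUS_COLS = ("chrom", "pos", "ref", "alt")


class CountTableParseError(ValueError):
    """A count-table file violates its dialect contract."""


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignSpec:
    """Maps line identifiers to selection regimens.

    The full pipeline requires 4 success-selected and 4 failure-selected
    lines plus at least one control line (the experiment used 4/4/3).
    """

    regimen: Mapping[str, str]

    def __post_init__(self) -> None:
        for line_id, reg in self.regimen.items():
            if reg not in REGIMENS:
                raise ValueError(
                    f"unknown regimen {reg!r} for line {line_id!r}; "
                    f"expected one of {REGIMENS}"
                )

    def lines(self, regimen: str) -> tuple[str, ...]:
        return tuple(l for l, r in self.regimen.items() if r == regimen)

    @property
    def success_lines(self) -> tuple[str, ...]:
        return self.lines("success")

    @property
    def failure_lines(self) -> tuple[str, ...]:
        return self.lines("failure")

    @property
    def control_lines(self) -> tuple[str, ...]:
        return self.lines("control")

    def require_selection_lines(self) -> None:
        """Check the 4+4 selection design needed by the locus scan."""
        ns, nf = len(self.success_lines), len(self.failure_lines)
        if ns != 4 or nf != 4:
            raise ValueError(
                f"scan requires 4 success and 4 failure lines, got {ns}+{nf}"
            )

    def require_controls(self) -> None:
        if not self.control_lines:
            raise ValueError("at least one control line is required")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DesignSpec":
        df = pd.read_csv(path, sep="\t", dtype=str)
        if not {"line_id", "regimen"}.issubset(df.columns):
            raise CountTableParseError(
                f"{path}: design file needs columns 'line_id' and 'regimen'"
            )
        return cls(dict(zip(df["line_id"], df["regimen"])))

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"line_id": list(self.regimen), "regimen": list(self.regimen.values())}
        ).to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> DesignSpec:
    return DesignSpec.from_tsv(path)


# ---------------------------------------------------------------------------
# count table container
# ---------------------------------------------------------------------------

@dataclass
class AlleleCountTable:
    """Loci x lines matrix of (minor, major) read counts.

    ``loci`` is a DataFrame with at least ``chrom`` and ``pos`` (1-based)
    columns, sorted by (chrom, pos) with no duplicates; extra columns such
    as ``ref``/``alt``/``variant_type`` are carried through untouched.
    ``minor`` and ``major`` are int arrays of shape (n_loci, n_lines),
    column order matching ``line_ids``.
    """

    loci: pd.DataFrame
    line_ids: tuple[str, ...]
    minor: np.ndarray
    major: np.ndarray

    def __post_init__(self) -> None:
        self.line_ids = tuple(self.line_ids)
        self.minor = np.asarray(self.minor, dtype=np.int64)
        self.major = np.asarray(self.major, dtype=np.int64)
        shape = (len(self.loci), len(self.line_ids))
        if self.minor.shape != shape or self.major.shape != shape:
            raise ValueError(
                f"count arrays must have shape {shape}, got "
                f"{self.minor.shape} / {self.major.shape}"
            )

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    def depth(self) -> np.ndarray:
        """Per-cell read depth (coverage) k."""
        return self.minor + self.major

    def pooled_minor_frequency(self) -> np.ndarray:
        """Global minor-allele frequency: counts pooled over all lines."""
        tot = self.depth().sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.minor.sum(axis=1) / tot

    def line_columns(self, line_ids: Iterable[str]) -> np.ndarray:
        index = {l: i for i, l in enumerate(self.line_ids)}
        return np.array([index[l] for l in line_ids], dtype=int)

    def validate(self) -> None:
        """Raise if container invariants are violated."""
        if (self.minor < 0).any() or (self.major < 0).any():
            raise ValueError("negative read counts")
        key = self.loci[list(_LOCUS_KEY)]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ValueError(f"duplicate locus {dup['chrom']}:{dup['pos']}")
        order = key.sort_values(list(_LOCUS_KEY), kind="mergesort").index
        if not np.array_equal(order.to_numpy(), np.arange(len(key))):
            raise ValueError("loci are not sorted by (chrom, pos)")

    def take(self, mask_or_index) -> "AlleleCountTable":
        """Subset loci by boolean mask or integer index, preserving order."""
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return AlleleCountTable(
            loci=self.loci.iloc[idx].reset_index(drop=True),
            line_ids=self.line_ids,
            minor=self.minor[idx],
            major=self.major[idx],
        )


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def read_count_table(
    path: str | Path,
    dialect: str = "native_tsv",
    line_ids: Sequence[str] | None = None,
    alleles: Mapping[tuple[str, int], tuple[str, str]] | None = None,
) -> AlleleCountTable:
    """Read an allele-count table.

    Parameters
    ----------
    dialect
        ``native_tsv`` (the package's own format) or ``sync``
        (popoolation2).
    line_ids
        Population names for the sync dialect (defaults to pop1..popN).
    alleles
        Optional per-locus ``(chrom, pos) -> (minor_base, major_base)``
        assignment for the sync dialect; when absent, the two most frequent
        pooled nucleotides are used (major = most frequent).
    """
    if dialect == "native_tsv":
        return _read_native(Path(path))
    if dialect == "sync":
        return _read_sync(Path(path), line_ids=line_ids, alleles=alleles)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_native(path: Path) -> AlleleCountTable:
    try:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise CountTableParseError(f"{path}: {exc}") from exc
    for col in ("chrom", "pos"):
        if col not in df.columns:
            raise CountTableParseError(f"{path}: missing required column {col!r}")
    ids = [c[: -len(".minor")] for c in df.columns if c.endswith(".minor")]
    if not ids:
        raise CountTableParseError(f"{path}: no '<line>.minor' count columns")
    for lid in ids:
        if f"{lid}.major" not in df.columns:
            raise CountTableParseError(f"{path}: missing column {lid!r}.major")

    count_cols = [f"{l}.{w}" for l in ids for w in ("minor", "major")]
    counts = df[count_cols]
    if counts.isna().any().any() or not all(
        np.issubdtype(d, np.integer) or np.issubdtype(d, np.floating)
        for d in counts.dtypes
    ):
        bad = counts.isna().any(axis=1)
        row = int(np.argmax(bad.to_numpy())) if bad.any() else 0
        raise CountTableParseError(f"{path}: non-numeric count at line {row + 2}")
    neg = (counts < 0).any(axis=1).to_numpy()
    if neg.any():
        raise CountTableParseError(
            f"{path}: negative count at line {int(np.argmax(neg)) + 2}"
        )
    dup = df[list(_LOCUS_KEY)].duplicated().to_numpy()
    if dup.any():
        row = int(np.argmax(dup))
        raise CountTableParseError(
            f"{path}: duplicate locus {df['chrom'][row]}:{df['pos'][row]} "
            f"at line {row + 2}"
        )

    df = df.sort_values(list(_LOCUS_KEY), kind="mergesort").reset_index(drop=True)
    locus_cols = [c for c in df.columns if c not in count_cols]
    minor = df[[f"{l}.minor" for l in ids]].to_numpy(dtype=np.int64)
    major = df[[f"{l}.major" for l in ids]].to_numpy(dtype=np.int64)
    return AlleleCountTable(df[locus_cols].copy(), tuple(ids), minor, major)


def write_count_table(table: AlleleCountTable, path: str | Path) -> None:
    """Write the native TSV dialect (lossless; read -> write round-trips)."""
    out = table.loci.copy()
    for j, lid in enumerate(table.line_ids):
        out[f"{lid}.minor"] = table.minor[:, j]
        out[f"{lid}.major"] = table.major[:, j]
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _read_sync(
    path: Path,
    line_ids: Sequence[str] | None = None,
    alleles: Mapping[tuple[str, int], tuple[str, str]] | None = None,
) -> AlleleCountTable:
    chroms: list[str] = []
    positions: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    minors: list[list[int]] = []
    majors: list[list[int]] = []
    seen: set[tuple[str, int]] = set()
    n_pops: int | None = None

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            raw = raw.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            parts = raw.split("\t")
            if len(parts) < 4:
                raise CountTableParseError(
                    f"{path}: line {lineno}: expected chrom, pos, ref and at "
                    f"least one population column"
                )
            chrom, pos_s, ref = parts[0], parts[1], parts[2]
            try:
                pos = int(pos_s)
            except ValueError:
                raise CountTableParseError(
                    f"{path}: line {lineno}: bad position {pos_s!r}"
                ) from None
            tallies = []
            for col in parts[3:]:
                vals = col.split(":")
                if len(vals) != 6:
                    raise CountTableParseError(
                        f"{path}: line {lineno}: malformed sync column {col!r}"
                    )
                tallies.append([int(v) for v in vals])
            if n_pops is None:
                n_pops = len(tallies)
            elif len(tallies) != n_pops:
                raise CountTableParseError(
                    f"{path}: line {lineno}: inconsistent population count"
                )
            pooled = np.sum(tallies, axis=0)
            if alleles is not None and (chrom, pos) in alleles:
                minor_base, major_base = alleles[(chrom, pos)]
                mi = SYNC_ALLELES.index(minor_base)
                ma = SYNC_ALLELES.index(major_base)
            else:
                # two most frequent pooled alleles; tie broken by tally order
                order = np.lexsort((np.arange(6), -pooled))
                ma, mi = int(order[0]), int(order[1])
            if (chrom, pos) in seen:
                raise CountTableParseError(
                    f"{path}: line {lineno}: duplicate locus {chrom}:{pos}"
                )
            seen.add((chrom, pos))
            chroms.append(chrom)
            positions.append(pos)
            refs.append(ref)
            alts.append(SYNC_ALLELES[mi])
            minors.append([t[mi] for t in tallies])
            majors.append([t[ma] for t in tallies])

    if n_pops is None:
        raise CountTableParseError(f"{path}: empty sync file")
    ids = tuple(line_ids) if line_ids else tuple(f"pop{i+1}" for i in range(n_pops))
    if len(ids) != n_pops:
        raise CountTableParseError(
            f"{path}: {len(ids)} line ids given for {n_pops} populations"
        )
    loci = pd.DataFrame(
        {"chrom": chroms, "pos": positions, "ref": refs, "alt": alts}
    )
    table = AlleleCountTable(loci, ids, np.array(minors), np.array(majors))
    order = loci.sort_values(list(_LOCUS_KEY), kind="mergesort").index.to_numpy()
    return table.take(order)


# ---------------------------------------------------------------------------
# transformations
# ---------------------------------------------------------------------------

def orient_global_minor(table: AlleleCountTable) -> AlleleCountTable:
    """Relabel counts so the minor allele is minor across all lines pooled.

    At each locus the allele with the smaller pooled read count over all
    lines becomes the minor allele; ties keep the input orientation.
    Idempotent.
    """
    pooled_minor = table.minor.sum(axis=1)
    pooled_major = table.major.sum(axis=1)
    flip = pooled_minor > pooled_major
    minor = np.where(flip[:, None], table.major, table.minor)
    major = np.where(flip[:, None], table.minor, table.major)
    return AlleleCountTable(table.loci.copy(), table.line_ids, minor, major)


def filter_loci(
    table: AlleleCountTable,
    min_cov: int = 5,
    max_cov: int = 250,
    min_global_maf: float = 0.05,
) -> AlleleCountTable:
    """Apply the locus screening filters.

    A locus is retained iff every line has min_cov <= depth <= max_cov
    (bounds inclusive) and the pooled minor-allele frequency across all
    lines is >= ``min_global_maf``.  Within-line frequencies may fall below
    the floor; only the pooled frequency counts.  Idempotent and
    order-preserving.  The table should already be oriented to the global
    minor allele.
    """
    depth = table.depth()
    cov_ok = ((depth >= min_cov) & (depth <= max_cov)).all(axis=1)
    maf_ok = table.pooled_minor_frequency() >= min_global_maf
    keep = cov_ok & maf_ok
    if not keep.any():
        warnings.warn("all loci removed by filtering", stacklevel=2)
    return table.take(keep)


def allele_frequencies(table: AlleleCountTable) -> np.ndarray:
    """Per-cell minor-allele frequency p = minor / (minor + major).

    Raises on any zero-depth cell (filtering guarantees depth >= min_cov).
    """
    depth = table.depth()
    if (depth == 0).any():
        i, j = np.argwhere(depth == 0)[0]
        raise ValueError(
            f"zero read depth at locus {table.loci['chrom'].iloc[i]}:"
            f"{table.loci['pos'].iloc[i]} line {table.line_ids[j]}"
        )
    return table.minor / depth
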