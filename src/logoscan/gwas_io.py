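"""Readers, writers and harmonization for GWAS summary data and panel metadata.

Conventions
-----------
Base-pair positions are 1-based in memory (PLINK ``.bim`` convention); all BED
input/output is 0-based half-open.  A SNP at 1-based position ``pos`` belongs
to block ``[start, end)`` iff ``start <= pos - 1 < end``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

SUMSTATS_COLUMNS = ("SNP", "A1", "A2", "Z", "N")


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class InputError(ValueError):
    """Inputs are structurally valid but unusable (empty, inconsistent...)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class SumStats:
    """Per-SNP association z-scores and metadata for one study.

    ``df`` has canonical lower-case columns: snp, a1, a2, z, n and optionally
    chrom, pos.
    """

    df: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp(self) -> np.ndarray:
        return self.df["snp"].to_numpy()

    @property
    def z(self) -> np.ndarray:
        return self.df["z"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.df["n"].to_numpy(dtype=float)


@dataclass
class HarmonizedPair:
    """Two studies aligned to each other and to a reference panel.

    ``df`` columns: snp, chrom, pos, a1, a2 (panel orientation), z1, z2.
    """

    df: pd.DataFrame
    n1: float
    n2: float

    def __len__(self) -> int:
        return len(self.df)

    @property
    def z1(self) -> np.ndarray:
        return self.df["z1"].to_numpy(dtype=float)

    @property
    def z2(self) -> np.ndarray:
        return self.df["z2"].to_numpy(dtype=float)

    @property
    def snp(self) -> np.ndarray:
        return self.df["snp"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.df["pos"].to_numpy(dtype=np.int64)

    @property
    def chrom(self) -> np.ndarray:
        return self.df["chrom"].to_numpy()


@dataclass(frozen=True)
class BlockSpec:
    """One approximately LD-independent genome block (BED convention)."""

    chrom: str
    start: int
    end: int
    block_id: int

    def __post_init__(self):
        if self.end <= self.start:
            raise InputError(
                f"block {self.block_id}: end ({self.end}) must exceed start ({self.start})"
            )


@dataclass
class RegionRecord:
    """One detected segment with its scan statistic and significance."""

    chrom: str
    start_bp: int  # 0-based half-open on output
    end_bp: int
    block_id: int
    n_snps: int
    q_stat: float
    p: float
    q_fdr: float = float("nan")


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map: dict | None = None) -> SumStats:
    """Read an LDSC-style tab-separated ``.sumstats`` file.

    Parameters
    ----------
    path : path-like
        Tab-separated file whose header contains SNP, A1, A2, Z, N (or the
        names given in ``column_map``).
    column_map : dict, optional
        Mapping from canonical name (e.g. ``"Z"``) to the column name used in
        the file.

    Rows with missing or non-finite z / n, non-ACGT alleles, or duplicated
    SNP ids (first kept) are dropped and counted in ``SumStats.n_dropped``.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{path}: empty summary statistics file") from None
    if raw.empty:
        raise InputError(f"{path}: summary statistics file has no rows")

    column_map = column_map or {}
    rename = {}
    for canon in SUMSTATS_COLUMNS:
        src = column_map.get(canon, canon)
        if src not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column '{src}' (for {canon})")
        rename[src] = canon.lower()
    df = raw.rename(columns=rename)[[c.lower() for c in SUMSTATS_COLUMNS]].copy()
    for extra in ("CHR", "BP", "POS"):
        if extra in raw.columns:
            df[{"CHR": "chrom", "BP": "pos", "POS": "pos"}[extra]] = raw[extra]

    n_in = len(df)
    df["z"] = pd.to_numeric(df["z"], errors="coerce")
    df["n"] = pd.to_numeric(df["n"], errors="coerce")
    df["a1"] = df["a1"].str.upper()
    df["a2"] = df["a2"].str.upper()
    ok = (
        np.isfinite(df["z"])
        & np.isfinite(df["n"])
        & (df["n"] > 0)
        & df["a1"].isin(VALID_ALLELES)
        & df["a2"].isin(VALID_ALLELES)
        & (df["a1"] != df["a2"])
    )
    df = df[ok]
    dup = df.duplicated(subset="snp", keep="first")
    if dup.any():
        log.warning("%s: dropping %d duplicated SNP id(s), keeping first", path, int(dup.sum()))
    df = df[~dup].reset_index(drop=True)
    n_dropped = n_in - len(df)
    if n_dropped:
        log.info("%s: dropped %d of %d rows during QC", path, n_dropped, n_in)
    if df.empty:
        raise InputError(f"{path}: no rows survive QC")
    return SumStats(df=df, n_dropped=n_dropped)


def is_strand_ambiguous(a1, a2) -> np.ndarray:
    """Elementwise test for palindromic (A/T, C/G) allele pairs."""
    a1 = np.asarray(a1, dtype=object)
    a2 = np.asarray(a2, dtype=object)
    return np.array([frozenset((x, y)) in _AMBIGUOUS for x, y in zip(a1, a2)])


def _orient(a1, a2, ref_a1, ref_a2, z):
    """Align one study to panel orientation.

    Returns (z_aligned, keep_mask).  Matching alleles keep z, swapped alleles
    flip the sign, anything else is dropped.
    """
    same = (a1 == ref_a1) & (a2 == ref_a2)
    swap = (a1 == ref_a2) & (a2 == ref_a1)
    z_out = np.where(swap, -z, z)
    return z_out, (same | swap)


def harmonize_pair(
    s1: SumStats,
    s2: SumStats,
    panel_meta: pd.DataFrame,
    maf_min: float | None = None,
) -> HarmonizedPair:
    """Intersect two studies with a reference panel and align allele coding.

    ``panel_meta`` needs columns snp, chrom, pos, a1, a2 and optionally maf
    (used when ``maf_min`` is given).  Strand-ambiguous SNPs are removed;
    studies whose alleles are swapped relative to the panel get their z-score
    sign flipped; SNPs whose alleles cannot be reconciled are dropped.
    Output is sorted by (chrom, pos).
    """
    p = panel_meta.rename(columns={"a1": "pa1", "pa2": "pa2"}).copy()
    p = p.rename(columns={"a2": "pa2"})
    if maf_min is not None and "maf" in p.columns:
        p = p[p["maf"].to_numpy(dtype=float) >= maf_min]
    d1 = s1.df.rename(columns={c: c + "_1" for c in ("a1", "a2", "z", "n")})
    d2 = s2.df.rename(columns={c: c + "_2" for c in ("a1", "a2", "z", "n")})
    cols1 = ["snp", "a1_1", "a2_1", "z_1", "n_1"]
    cols2 = ["snp", "a1_2", "a2_2", "z_2", "n_2"]
    merged = (
        p[[c for c in ("snp", "chrom", "pos", "pa1", "pa2", "maf") if c in p.columns]]
        .merge(d1[cols1], on="snp")
        .merge(d2[cols2], on="snp")
    )
    if merged.empty:
        raise InputError("empty intersection between the two studies and the panel")

    amb = (
        is_strand_ambiguous(merged["pa1"], merged["pa2"])
        | is_strand_ambiguous(merged["a1_1"], merged["a2_1"])
        | is_strand_ambiguous(merged["a1_2"], merged["a2_2"])
    )
    merged = merged[~amb]

    z1, keep1 = _orient(
        merged["a1_1"].to_numpy(), merged["a2_1"].to_numpy(),
        merged["pa1"].to_numpy(), merged["pa2"].to_numpy(),
        merged["z_1"].to_numpy(dtype=float),
    )
    z2, keep2 = _orient(
        merged["a1_2"].to_numpy(), merged["a2_2"].to_numpy(),
        merged["pa1"].to_numpy(), merged["pa2"].to_numpy(),
        merged["z_2"].to_numpy(dtype=float),
    )
    keep = keep1 & keep2
    merged = merged.assign(z1=z1, z2=z2)[keep]
    if merged.empty:
        raise InputError("no SNP survives allele harmonization")

    out = merged.rename(columns={"pa1": "a1", "pa2": "a2"})
    out = out[[c for c in ("snp", "chrom", "pos", "a1", "a2", "maf", "z1", "z2") if c in out.columns]]
    out["pos"] = out["pos"].astype(np.int64)
    out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    n1 = float(np.median(merged["n_1"].to_numpy(dtype=float)))
    n2 = float(np.median(merged["n_2"].to_numpy(dtype=float)))
    return HarmonizedPair(df=out, n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# blocks
# ---------------------------------------------------------------------------

def read_blocks(path) -> list[BlockSpec]:
    """Read LD-independent genome blocks from a 3+ column BED file."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: BED line has fewer than 3 columns: {line!r}")
            rows.append((parts[0], int(parts[1]), int(parts[2])))
    if not rows:
        raise InputError(f"{path}: no blocks found")
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    blocks = [BlockSpec(chrom=c, start=s, end=e, block_id=i) for i, (c, s, e) in enumerate(rows)]
    offenders = [
        (a, b)
        for a, b in zip(blocks, blocks[1:])
        if a.chrom == b.chrom and b.start < a.end
    ]
    if offenders:
        desc = "; ".join(
            f"{a.chrom}:{a.start}-{a.end} overlaps {b.chrom}:{b.start}-{b.end}"
            for a, b in offenders
        )
        raise InputError(f"{path}: overlapping blocks: {desc}")
    return blocks


def assign_blocks(chrom, pos, blocks: list[BlockSpec]) -> np.ndarray:
    """Map SNPs (1-based positions) to block ids; -1 when outside all blocks."""
    chrom = np.asarray(chrom)
    pos = np.asarray(pos, dtype=np.int64)
    out = np.full(len(pos), -1, dtype=np.int64)
    for b in blocks:
        mask = (chrom == b.chrom) & (b.start <= pos - 1) & (pos - 1 < b.end)
        out[mask] = b.block_id
    return out


def write_blocks(blocks: list[BlockSpec], path) -> None:
    with open(path, "w") as fh:
        for b in sorted(blocks, key=lambda b: (b.chrom, b.start)):
            fh.write(f"{b.chrom}\t{b.start}\t{b.end}\n")


# ---------------------------------------------------------------------------
# detected regions
# ---------------------------------------------------------------------------

_REGION_COLUMNS = ("chrom", "start", "end", "block_id", "n_snps", "q_stat", "p", "q_fdr")


def write_regions(regions: list[RegionRecord], path) -> None:
    """Write detected regions as a BED-compatible TSV, sorted by (chrom, start)."""
    recs = sorted(regions, key=lambda r: (r.chrom, r.start_bp))
    with open(path, "w") as fh:
        fh.write("\t".join(_REGION_COLUMNS) + "\n")
        for r in recs:
            fh.write(
                f"{r.chrom}\t{r.start_bp}\t{r.end_bp}\t{r.block_id}\t{r.n_snps}\t"
                f"{r.q_stat:.10g}\t{r.p:.10g}\t{r.q_fdr:.10g}\n"
            )


def read_regions(path) -> list[RegionRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        RegionRecord(
            chrom=str(row.chrom),
            start_bp=int(row.start),
            end_bp=int(row.end),
            block_id=int(row.block_id),
            n_snps=int(row.n_snps),
            q_stat=float(row.q_stat),
            p=float(row.p),
            q_fdr=float(row.q_fdr),
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# reference panels: PLINK bed/bim/fam and plain TSV dosage matrices
# ---------------------------------------------------------------------------

def read_bim(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp": str, "a1": str, "a2": str},
    )
    return df[["snp", "chrom", "pos", "a1", "a2"]]


def read_fam(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype=str,
    )


def read_bed(prefix) -> tuple[np.ndarray, pd.DataFrame]:
    """Read a SNP-major PLINK .bed/.bim/.fam trio.

    Returns (dosage matrix of A1 counts, n x m, NaN for missing; bim table).
    """
    prefix = str(prefix)
    bim = read_bim(prefix + ".bim")
    fam = read_fam(prefix + ".fam")
    n, m = len(fam), len(bim)
    data = np.fromfile(prefix + ".bed", dtype=np.uint8)
    if len(data) < 3 or data[0] != 0x6C or data[1] != 0x1B:
        raise FormatError(f"{prefix}.bed: not a PLINK bed file")
    if data[2] != 0x01:
        raise FormatError(f"{prefix}.bed: only SNP-major bed files are supported")
    bytes_per_snp = (n + 3) // 4
    body = data[3:].reshape(m, bytes_per_snp)
    # unpack 2-bit genotype codes, individual-fastest within byte
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, -1)[:, :n]
    # 00 -> 2 copies of A1, 10 -> 1, 11 -> 0, 01 -> missing
    lut = np.array([2.0, np.nan, 1.0, 0.0])
    return lut[codes].T.copy(), bim


_DOSAGE_META = ("snp", "chrom", "pos", "a1", "a2")


def write_dosage_tsv(dosages: np.ndarray, meta: pd.DataFrame, path) -> None:
    """Write an (n x m) dosage matrix as a plain-text SNP-per-row TSV."""
    n = dosages.shape[0]
    cols = {c: meta[c].to_numpy() for c in _DOSAGE_META}
    body = pd.DataFrame(cols)
    dos = pd.DataFrame(
        dosages.T, columns=[f"i{j}" for j in range(n)], index=body.index
    )
    out = pd.concat([body, dos], axis=1)
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path) -> tuple[np.ndarray, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", dtype={"snp": str, "chrom": str, "a1": str, "a2": str})
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: dosage TSV missing columns {missing}")
    meta = df[list(_DOSAGE_META)].copy()
    dos_cols = [c for c in df.columns if c not in _DOSAGE_META]
    dosages = df[dos_cols].to_numpy(dtype=float).T.copy()
    return dosages, meta


def load_panel_files(prefix_or_path):
    """Load raw dosages + metadata from a PLINK prefix or a dosage TSV path."""
    p = Path(str(prefix_or_path))
    if Path(str(p) + ".bed").exists():
        return read_bed(p)
    if p.suffix in {".tsv", ".txt"} and p.exists():
        return read_dosage_tsv(p)
    if p.exists() and not p.is_dir():
        return read_dosage_tsv(p)
    raise InputError(f"no panel found at {prefix_or_path} (tried PLINK prefix and TSV)")
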