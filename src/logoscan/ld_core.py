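"""Reference-panel LD: correlation matrices, LD scores, the bias-corrected
squared-LD estimator, and condition-number-capped pseudo-inverses."""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    pass


@dataclass
class GenotypePanel:
    """Standardized reference genotypes for LD estimation.

    ``X`` is an (n_ref x m) matrix whose columns have mean 0 and unit sample
    standard deviation (ddof=1).  ``meta`` holds snp, chrom, pos, a1, a2;
    ``maf`` the per-SNP minor-allele frequency.
    """

    X: np.ndarray
    meta: pd.DataFrame
    maf: np.ndarray
    n_ref: int

    @property
    def m(self) -> int:
        return self.X.shape[1]

    @property
    def pos(self) -> np.ndarray:
        return self.meta["pos"].to_numpy(dtype=np.int64)

    @property
    def chrom(self) -> np.ndarray:
        return self.meta["chrom"].to_numpy()

    def select(self, snp_ids) -> "GenotypePanel":
        """Subset to the given SNP ids, preserving their panel order."""
        wanted = set(snp_ids)
        mask = self.meta["snp"].isin(wanted).to_numpy()
        return GenotypePanel(
            X=self.X[:, mask],
            meta=self.meta[mask].reset_index(drop=True),
            maf=self.maf[mask],
            n_ref=self.n_ref,
        )

    def take(self, idx) -> "GenotypePanel":
        idx = np.asarray(idx)
        return GenotypePanel(
            X=self.X[:, idx],
            meta=self.meta.iloc[idx].reset_index(drop=True),
            maf=self.maf[idx],
            n_ref=self.n_ref,
        )


@dataclass
class LDMatrix:
    V: np.ndarray


@dataclass
class LDScores:
    l: np.ndarray
    window_bp: float = 1_000_000.0


@dataclass
class VtildeSq:
    matrix: np.ndarray
    n_ref: int
    m_used: int


def standardize_genotypes(
    raw: np.ndarray,
    meta: pd.DataFrame | None = None,
    maf_min: float = 0.0,
) -> GenotypePanel:
    """Mean-impute, filter and standardize raw dosages in {0, 1, 2}.

    Missing entries (NaN) are imputed to the column mean before centering;
    monomorphic columns and columns below the MAF threshold are dropped.
    Columns of the result have mean 0 and sample SD 1 (ddof=1).
    """
    raw = np.asarray(raw, dtype=float)
    n = raw.shape[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        col_mean = np.nanmean(raw, axis=0)
    all_missing = ~np.isfinite(col_mean)
    if all_missing.any():
        log.warning("dropping %d all-missing SNP column(s)", int(all_missing.sum()))
        col_mean = np.where(all_missing, 0.0, col_mean)
    X = np.where(np.isnan(raw), col_mean[None, :], raw)
    sd = X.std(axis=0, ddof=1)
    freq = col_mean / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    keep = (~all_missing) & (sd > 0) & (maf >= maf_min)
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("standardize_genotypes: dropped %d of %d SNPs", n_drop, raw.shape[1])
    X = (X[:, keep] - col_mean[keep][None, :]) / sd[keep][None, :]
    if meta is None:
        meta = pd.DataFrame({
            "snp": [f"snp{i}" for i in range(raw.shape[1])],
            "chrom": "1",
            "pos": np.arange(1, raw.shape[1] + 1),
            "a1": "A",
            "a2": "G",
        })
    meta = meta.reset_index(drop=True)[keep].reset_index(drop=True)
    return GenotypePanel(X=X, meta=meta, maf=maf[keep], n_ref=n)


def ld_matrix(panel: GenotypePanel, idx=None) -> LDMatrix:
    """Sample correlation matrix of the selected standardized columns."""
    if idx is None:
        X = panel.X
    else:
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ParameterError("ld_matrix: empty SNP index range")
        X = panel.X[:, idx]
    V = (X.T @ X) / (panel.n_ref - 1)
    np.fill_diagonal(V, 1.0)
    return LDMatrix(V=(V + V.T) / 2.0)


def ld_scores(panel: GenotypePanel, window_bp: float = 1_000_000.0, adjusted: bool = False) -> LDScores:
    """Per-SNP LD scores: sum of r^2 with SNPs within +-window_bp/2.

    The window is symmetric around the focal SNP (total span ``window_bp``)
    and restricted to the same chromosome.  ``adjusted`` applies the
    r^2 - (1 - r^2)/(n - 2) finite-sample correction.
    """
    m = panel.m
    pos = panel.pos
    chroms = panel.chrom
    half = window_bp / 2.0
    n = panel.n_ref
    l = np.empty(m)
    for c in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == c)
        cp = pos[cidx]
        order = np.argsort(cp, kind="mergesort")
        cidx, cp = cidx[order], cp[order]
        if not np.all(np.diff(cp) >= 0):  # pragma: no cover - sorted above
            raise ParameterError("positions must be sortable")
        Xc = panel.X[:, cidx]
        lo = np.searchsorted(cp, cp - half, side="left")
        hi = np.searchsorted(cp, cp + half, side="right")
        for k in range(len(cidx)):
            r = Xc[:, k] @ Xc[:, lo[k]:hi[k]] / (n - 1)
            r2 = r * r
            if adjusted:
                r2 = r2 - (1.0 - r2) / (n - 2)
            l[cidx[k]] = r2.sum()
    return LDScores(l=l, window_bp=window_bp)


def vtilde_sq(V: LDMatrix | np.ndarray, n_ref: int, m_used: int) -> VtildeSq:
    """Bias-corrected estimate of the squared population LD matrix:
    ((n_ref - 1) V^2 - m_used V) / (n_ref - 2)."""
    if n_ref <= 2:
        raise ParameterError(f"vtilde_sq requires n_ref > 2, got {n_ref}")
    Vm = V.V if isinstance(V, LDMatrix) else np.asarray(V, dtype=float)
    out = ((n_ref - 1) * (Vm @ Vm) - m_used * Vm) / (n_ref - 2)
    return VtildeSq(matrix=(out + out.T) / 2.0, n_ref=n_ref, m_used=m_used)


def tsvd_inverse(A: np.ndarray, cond_max: float = 1000.0) -> tuple[np.ndarray, int]:
    """Pseudo-inverse from the top-q singular triplets, with q the largest
    rank keeping the condition number strictly below ``cond_max``."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ParameterError("tsvd_inverse expects a square matrix")
    U, s, Vt = np.linalg.svd((A + A.T) / 2.0)
    if s.size == 0 or s[0] <= 0:
        log.warning("tsvd_inverse: zero matrix, returning zero inverse (q=0)")
        return np.zeros_like(A), 0
    keep = s > s[0] / cond_max  # strict: sigma_1 / sigma_q < cond_max
    q = int(keep.sum())
    inv = (Vt[:q].T / s[:q]) @ U[:, :q].T
    return inv, q
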