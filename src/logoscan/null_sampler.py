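"""Null covariance assembly for the stacked z-score pair and Monte-Carlo
pseudo z-score sampling via block-tridiagonal conditional Gaussians.

The null covariance of [z1; z2] is, per trait,
``(n h2 / M) Vtilde^2 + (1 - h2) V`` on the diagonal and
``(rho_e n_s / sqrt(n1 n2)) V`` across traits.  Sample overlap is handled by
splitting the covariance into a per-trait component and a shared component
realized by one common draw added to (or subtracted from) both traits, so
the two components always sum back to the full matrix.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .ld_core import GenotypePanel, ParameterError, ld_matrix, tsvd_inverse, vtilde_sq

log = logging.getLogger(__name__)

H2_RESIDUAL_FLOOR = 0.05  # floor on 1 - h2 (h2 capped at 0.95)


@dataclass
class NullEstimates:
    """Plug-in parameters the sampler needs (from covariance_regression)."""

    h2_1: float
    h2_2: float
    n1: float
    n2: float
    m_total: int
    rho_e_ns: float = 0.0  # rho_e * n_s, signed


@dataclass
class PseudoZPair:
    z1_star: np.ndarray
    z2_star: np.ndarray
    seed: int | None = None


@dataclass
class _ChunkGauss:
    """Sampling recipe for one chunk of one variance component."""

    factor: np.ndarray  # k x k; marginal or conditional covariance factor
    reg: np.ndarray | None  # k x k_prev regression on the previous chunk


@dataclass
class _BlockModel:
    sl: slice  # global SNP slice of this LD block
    V: np.ndarray
    Vt2: np.ndarray
    chunks: list[slice]  # relative to the block


@dataclass
class NullCovarianceModel:
    blocks: list[_BlockModel]
    components: dict  # name -> (coef_vt, coef_v, per-block list of _ChunkGauss)
    h2_1: float
    h2_2: float
    n1: float
    n2: float
    m_total: int
    a: float  # rho_e * n_s / sqrt(n1 n2)
    m: int


def _psd_factor(C: np.ndarray) -> np.ndarray:
    C = (C + C.T) / 2.0
    w, U = np.linalg.eigh(C)
    if w[0] < 0:
        # the plug-in Vtilde^2 and the tridiagonal conditional can push small
        # eigenvalues below zero; flooring at 0 is part of the contract
        level = logging.WARNING if w[0] < -0.25 * max(abs(w[-1]), 1.0) else logging.DEBUG
        log.log(level, "covariance eigenvalue %.3g floored at 0", w[0])
    w = np.clip(w, 0.0, None)
    return U * np.sqrt(w)


def _chunk_slices(pos: np.ndarray, chunk_bp: float) -> list[slice]:
    """Split sorted positions into genomic chunks aligned to a chunk_bp grid."""
    keys = ((pos - 1) // int(chunk_bp)).astype(np.int64)
    boundaries = np.flatnonzero(np.diff(keys)) + 1
    edges = np.concatenate([[0], boundaries, [len(pos)]])
    return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


def _component_chain(
    V: np.ndarray,
    Vt2: np.ndarray,
    chunks: list[slice],
    coef_vt: float,
    coef_v: float,
    cond_max: float,
) -> list[_ChunkGauss]:
    """Conditional Gaussian recipes for the tridiagonal chunk chain of
    Sigma = coef_vt * Vt2 + coef_v * V within one LD block."""
    out = []
    for i, sl in enumerate(chunks):
        Sii = coef_vt * Vt2[sl, sl] + coef_v * V[sl, sl]
        if i == 0:
            out.append(_ChunkGauss(factor=_psd_factor(Sii), reg=None))
            continue
        pr = chunks[i - 1]
        Sip = coef_vt * Vt2[sl, pr] + coef_v * V[sl, pr]
        Spp = coef_vt * Vt2[pr, pr] + coef_v * V[pr, pr]
        inv, _q = tsvd_inverse(Spp, cond_max=cond_max)
        reg = Sip @ inv
        cond = Sii - reg @ Sip.T
        out.append(_ChunkGauss(factor=_psd_factor(cond), reg=reg))
    return out


def build_null_model(
    panel: GenotypePanel,
    estimates: NullEstimates,
    block_ids: np.ndarray | None = None,
    chunk_bp: float = 1_000_000.0,
    cond_max: float = 1000.0,
) -> NullCovarianceModel:
    """Assemble the null model over the panel's SNPs.

    ``block_ids`` assigns each SNP to an LD block (SNPs must be sorted so
    each block is a contiguous run); chunks are <= ``chunk_bp`` segments
    within a block, and cross-chunk covariance is kept only for adjacent
    chunks of the same block (block-tridiagonal approximation).
    """
    m = panel.m
    if block_ids is None:
        block_ids = np.zeros(m, dtype=np.int64)
    block_ids = np.asarray(block_ids)

    h2_1 = float(np.clip(estimates.h2_1, 0.0, 1.0 - H2_RESIDUAL_FLOOR))
    h2_2 = float(np.clip(estimates.h2_2, 0.0, 1.0 - H2_RESIDUAL_FLOOR))
    a = estimates.rho_e_ns / np.sqrt(estimates.n1 * estimates.n2)
    for h2 in (h2_1, h2_2):
        if 1.0 - h2 - abs(a) <= 0:
            raise ParameterError(
                f"invalid variance split: 1 - h2 - |a| = {1 - h2 - abs(a):.4g} <= 0"
            )

    # contiguous runs of block ids
    change = np.flatnonzero(np.diff(block_ids)) + 1
    edges = np.concatenate([[0], change, [m]])
    if len(np.unique(block_ids)) != len(edges) - 1:
        raise ParameterError("block_ids must form contiguous runs (sort SNPs by position)")

    blocks = []
    pos = panel.pos
    for s, e in zip(edges[:-1], edges[1:]):
        sl = slice(int(s), int(e))
        idx = np.arange(sl.start, sl.stop)
        V = ld_matrix(panel, idx).V
        Vt2 = vtilde_sq(V, panel.n_ref, m_used=len(idx)).matrix
        blocks.append(
            _BlockModel(sl=sl, V=V, Vt2=Vt2, chunks=_chunk_slices(pos[sl], chunk_bp))
        )

    comps = {}
    specs = [
        ("t1", estimates.n1 * h2_1 / estimates.m_total, 1.0 - h2_1 - abs(a)),
        ("t2", estimates.n2 * h2_2 / estimates.m_total, 1.0 - h2_2 - abs(a)),
    ]
    if a != 0.0:
        specs.append(("shared", 0.0, abs(a)))
    for name, cvt, cv in specs:
        comps[name] = (
            cvt,
            cv,
            [_component_chain(b.V, b.Vt2, b.chunks, cvt, cv, cond_max) for b in blocks],
        )

    return NullCovarianceModel(
        blocks=blocks,
        components=comps,
        h2_1=h2_1,
        h2_2=h2_2,
        n1=estimates.n1,
        n2=estimates.n2,
        m_total=estimates.m_total,
        a=a,
        m=m,
    )


def _draw_component(model: NullCovarianceModel, name: str, n_draws: int, rng) -> np.ndarray:
    _, _, chains = model.components[name]
    out = np.empty((n_draws, model.m))
    for block, chain in zip(model.blocks, chains):
        prev = None
        for sl_rel, cg in zip(block.chunks, chain):
            k = sl_rel.stop - sl_rel.start
            eps = rng.standard_normal((n_draws, k))
            x = eps @ cg.factor.T
            if cg.reg is not None:
                x += prev @ cg.reg.T
            gsl = slice(block.sl.start + sl_rel.start, block.sl.start + sl_rel.stop)
            out[:, gsl] = x
            prev = x
    return out


def draw_batch(model: NullCovarianceModel, n_draws: int, rng) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n_draws`` pseudo z-score pairs; rows are draws."""
    z1 = _draw_component(model, "t1", n_draws, rng)
    z2 = _draw_component(model, "t2", n_draws, rng)
    if "shared" in model.components:
        w = _draw_component(model, "shared", n_draws, rng)
        z1 += w
        z2 += np.sign(model.a) * w
    return z1, z2


def draw_pseudo_pair(model: NullCovarianceModel, rng_seed: int) -> PseudoZPair:
    """One pseudo z-score pair; deterministic given the seed."""
    rng = np.random.default_rng(rng_seed)
    z1, z2 = draw_batch(model, 1, rng)
    return PseudoZPair(z1_star=z1[0], z2_star=z2[0], seed=rng_seed)


# ---------------------------------------------------------------------------
# standardization against the observed z-scores
# ---------------------------------------------------------------------------

def standardize_rows(Z: np.ndarray, target_mean: float, target_sd: float) -> np.ndarray:
    """Affinely rescale each row to the target mean and SD."""
    mu = Z.mean(axis=1, keepdims=True)
    sd = Z.std(axis=1, keepdims=True)
    if np.any(sd == 0):
        raise ParameterError("zero-variance pseudo z-score vector")
    return (Z - mu) / sd * target_sd + target_mean


def standardize_pseudo(pair: PseudoZPair, observed) -> PseudoZPair:
    """Rescale each pseudo vector to match the observed z vector's genome-wide
    mean and variance.  ``observed`` is a HarmonizedPair or a (z1, z2) tuple."""
    if hasattr(observed, "z1"):
        z1o, z2o = observed.z1, observed.z2
    else:
        z1o, z2o = observed
    z1 = standardize_rows(pair.z1_star[None, :], z1o.mean(), z1o.std())[0]
    z2 = standardize_rows(pair.z2_star[None, :], z2o.mean(), z2o.std())[0]
    return PseudoZPair(z1_star=z1, z2_star=z2, seed=pair.seed)


# ---------------------------------------------------------------------------
# dense assembly (verification/oracle support; desk scale only)
# ---------------------------------------------------------------------------

def _tridiag_dense(model: NullCovarianceModel, coef_vt: float, coef_v: float) -> np.ndarray:
    out = np.zeros((model.m, model.m))
    for b in model.blocks:
        off = b.sl.start
        for i, sl in enumerate(b.chunks):
            gi = slice(off + sl.start, off + sl.stop)
            out[gi, gi] = coef_vt * b.Vt2[sl, sl] + coef_v * b.V[sl, sl]
            if i > 0:
                pr = b.chunks[i - 1]
                gp = slice(off + pr.start, off + pr.stop)
                cross = coef_vt * b.Vt2[sl, pr] + coef_v * b.V[sl, pr]
                out[gi, gp] = cross
                out[gp, gi] = cross.T
    return out


def split_overlap_covariance(model: NullCovarianceModel) -> tuple[np.ndarray, np.ndarray]:
    """Dense (2m x 2m) additive split of the tridiagonal null covariance.

    Component A is block-diagonal across traits; component B carries the
    overlap term and equals the covariance induced by one shared draw
    w ~ N(0, |a| V) added as (+w, +w) for a > 0 or (+w, -w) for a < 0.
    The two components sum to the assembled null covariance exactly.
    """
    m = model.m
    cvt1, cv1, _ = model.components["t1"]
    cvt2, cv2, _ = model.components["t2"]
    comp_a = np.zeros((2 * m, 2 * m))
    comp_a[:m, :m] = _tridiag_dense(model, cvt1, cv1)
    comp_a[m:, m:] = _tridiag_dense(model, cvt2, cv2)
    comp_b = np.zeros((2 * m, 2 * m))
    if model.a != 0.0:
        S = _tridiag_dense(model, 0.0, abs(model.a))
        sgn = np.sign(model.a)
        comp_b[:m, :m] = S
        comp_b[m:, m:] = S
        comp_b[:m, m:] = sgn * S
        comp_b[m:, :m] = sgn * S
    return comp_a, comp_b


def assemble_covariance(model: NullCovarianceModel) -> np.ndarray:
    """The full (2m x 2m) tridiagonal-approximated null covariance."""
    comp_a, comp_b = split_overlap_covariance(model)
    return comp_a + comp_b
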