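"""Scan statistic, maximal-window search, peel-off scanning against the
Monte-Carlo null, region merging, BH FDR and adaptive theta selection.

The scan statistic over a SNP index set R is

    Q(R) = sum_{i in R} z1_i z2_i / (sum_{i in R} l_i)^theta

and significance of the per-block maximal |Q| is assessed against the
empirical null distribution from pseudo z-score draws.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import gwas_io
from .covariance_regression import (
    estimate_cross,
    estimate_h2,
    stratified_covariance,
)
from .gwas_io import BlockSpec, HarmonizedPair, RegionRecord, SumStats, assign_blocks, harmonize_pair
from .ld_core import GenotypePanel, ParameterError, ld_scores
from .null_sampler import (
    NullEstimates,
    build_null_model,
    draw_batch,
    standardize_rows,
)

log = logging.getLogger(__name__)

DEFAULT_THETA_GRID = (0.4, 0.45, 0.5, 0.55, 0.6, 0.65, 0.7)


class DataError(ValueError):
    pass


@dataclass
class ScanConfig:
    theta_grid: tuple = DEFAULT_THETA_GRID
    window_step: int = 10
    max_window: int | None = None  # None -> average SNPs per 1 Mb, up-rounded to 10
    n_mc: int = 5000
    alpha: float = 0.05
    merge_gap_bp: int = 100_000
    fdr_q: float = 0.05
    maf_min: float = 0.01
    chunk_bp: float = 1_000_000.0
    ld_window_bp: float = 1_000_000.0
    overlap: str | float = "auto"  # "auto" | "none" | explicit rho_e*n_s value
    seed: int = 0

    def __post_init__(self):
        for t in self.theta_grid:
            if not (0.0 <= t <= 1.0):
                raise ParameterError(f"theta {t} outside [0, 1]")
        if self.max_window is not None and self.max_window < self.window_step:
            raise ParameterError("max_window must be >= window_step")


@dataclass
class NullQmax:
    draws: np.ndarray  # B maximal-|Q| null draws for one block
    q95: float


@dataclass
class ThetaResult:
    thetas: tuple
    pis: np.ndarray
    regions_per_theta: list  # list of lists of RegionRecord (FDR-passing, merged)
    theta_hat: float


# ---------------------------------------------------------------------------
# the statistic and window machinery
# ---------------------------------------------------------------------------

def scan_statistic(z1, z2, l, index_set, theta: float) -> float:
    """Signed Q(R) over an explicit SNP index set."""
    idx = np.asarray(index_set)
    if idx.size == 0:
        raise DataError("scan_statistic: empty index set")
    lr = np.asarray(l, dtype=float)[idx]
    if np.any(lr <= 0):
        raise DataError("scan_statistic: non-positive LD score in region")
    num = float(np.asarray(z1, dtype=float)[idx] @ np.asarray(z2, dtype=float)[idx])
    return num / float(lr.sum()) ** theta


def window_lengths(block_snp_count: int, step: int = 10, cap: int | None = None) -> list[int]:
    hi = block_snp_count if cap is None else min(cap, block_snp_count)
    return list(range(step, hi + 1, step))


def enumerate_windows(block_snp_count: int, step: int = 10, cap: int | None = None) -> list[tuple[int, int]]:
    """All contiguous [start, end) windows with length a multiple of ``step``
    and at most min(cap, block size).  Blocks smaller than ``step`` yield the
    single full-block window."""
    if block_snp_count < 1:
        return []
    lengths = window_lengths(block_snp_count, step, cap)
    if not lengths:
        return [(0, block_snp_count)]
    return [(s, s + L) for L in lengths for s in range(block_snp_count - L + 1)]


def max_scan(z1, z2, l, theta: float, windows) -> tuple[float, tuple[int, int]]:
    """The window maximizing |Q|; ties go to the smallest start, then length.

    Returns (signed Q at the best window, best window).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l = np.asarray(l, dtype=float)
    cs = np.concatenate([[0.0], np.cumsum(z1 * z2)])
    ls = np.concatenate([[0.0], np.cumsum(l)])
    best_q, best_w, best_abs = 0.0, None, -np.inf
    for (s, e) in windows:
        q = (cs[e] - cs[s]) / (ls[e] - ls[s]) ** theta
        a = abs(q)
        if a > best_abs + 1e-15 or (
            best_w is not None
            and np.isclose(a, best_abs, rtol=0.0, atol=1e-12)
            and (s, e - s) < (best_w[0], best_w[1] - best_w[0])
        ):
            best_q, best_w, best_abs = q, (s, e), a
    if best_w is None:
        raise DataError("max_scan: no windows supplied")
    return best_q, best_w


def qmax_batch(prods: np.ndarray, l: np.ndarray, theta: float, step: int = 10, cap: int | None = None) -> np.ndarray:
    """Max |Q| over the standard window set for each row of ``prods``.

    ``prods`` is (B x m) of per-SNP z1*z2 products; vectorized over draws.
    """
    B, m = prods.shape
    cs = np.concatenate([np.zeros((B, 1)), np.cumsum(prods, axis=1)], axis=1)
    ls = np.concatenate([[0.0], np.cumsum(l)])
    out = np.zeros(B)
    lengths = window_lengths(m, step, cap)
    if not lengths:
        lengths = [m]
    for L in lengths:
        num = np.abs(cs[:, L:] - cs[:, :-L])
        den = (ls[L:] - ls[:-L]) ** theta
        np.maximum(out, (num / den[None, :]).max(axis=1), out=out)
    return out


def null_qmax_from_products(prods, l, theta, config: ScanConfig, cap: int) -> NullQmax:
    draws = qmax_batch(prods, l, theta, config.window_step, cap)
    if len(draws) < 100:
        log.warning("null_qmax: only %d draws, the 95%% quantile is unstable", len(draws))
    return NullQmax(draws=draws, q95=float(np.quantile(draws, 1.0 - config.alpha)))


def null_qmax(model, theta: float, config: ScanConfig, observed=None, rng=None, l=None) -> NullQmax:
    """Monte-Carlo null of the maximal |Q| for a single-block model."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    z1, z2 = draw_batch(model, config.n_mc, rng)
    if observed is not None:
        z1o, z2o = (observed.z1, observed.z2) if hasattr(observed, "z1") else observed
        z1 = standardize_rows(z1, z1o.mean(), z1o.std())
        z2 = standardize_rows(z2, z2o.mean(), z2o.std())
    cap = config.max_window if config.max_window is not None else z1.shape[1]
    l = np.ones(z1.shape[1]) if l is None else np.asarray(l, dtype=float)
    return null_qmax_from_products(z1 * z2, l, theta, config, cap)


# ---------------------------------------------------------------------------
# peel-off scan within one block
# ---------------------------------------------------------------------------

def _run_windows(active: np.ndarray, step: int, cap: int) -> list[tuple[int, int]]:
    """Enumerate windows over each contiguous run of surviving SNPs,
    returned in original block coordinates."""
    runs = []
    idx = np.flatnonzero(active)
    if idx.size == 0:
        return []
    splits = np.flatnonzero(np.diff(idx) > 1) + 1
    out = []
    for run in np.split(idx, splits):
        for (s, e) in enumerate_windows(len(run), step, cap):
            out.append((int(run[s]), int(run[e - 1]) + 1))
    return out


def peel_off_scan(z1, z2, l, null: NullQmax, theta: float, config: ScanConfig, cap: int | None = None) -> list[dict]:
    """Iterative maximal scan over one LD block.

    Repeatedly finds the max-|Q| window among remaining SNPs; windows at or
    above the null's 95% quantile are recorded (with an add-one Monte-Carlo
    p-value), their SNPs removed, and the scan repeats.  The null
    distribution is computed once per block and reused across iterations.
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l = np.asarray(l, dtype=float)
    m = len(z1)
    cap = cap if cap is not None else (config.max_window or m)
    active = np.ones(m, dtype=bool)
    B = len(null.draws)
    found = []
    while True:
        windows = _run_windows(active, config.window_step, cap)
        if not windows:
            break
        q, (s, e) = max_scan(z1, z2, l, theta, windows)
        if abs(q) < null.q95:
            break
        p = (1.0 + float((null.draws >= abs(q)).sum())) / (1.0 + B)
        found.append({"start": s, "end": e, "q": q, "p": p})
        active[s:e] = False
    return found


# ---------------------------------------------------------------------------
# FDR and merging
# ---------------------------------------------------------------------------

def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (q-values, rejection mask at level q)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    if n == 0:
        return np.array([]), np.array([], dtype=bool)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / np.arange(1, n + 1)
    qvals_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    qvals = np.empty(n)
    qvals[order] = np.minimum(qvals_sorted, 1.0)
    # step-up rejection: largest k with p_(k) <= k q / n, reject all smaller
    thresh = np.arange(1, n + 1) * q / n
    below = np.flatnonzero(p[order] <= thresh)
    reject = np.zeros(n, dtype=bool)
    if below.size:
        reject[order[: below[-1] + 1]] = True
    return qvals, reject


def merge_regions(regions: list[RegionRecord], gap_bp: int = 100_000) -> list[RegionRecord]:
    """Merge same-chromosome regions whose bp gap is <= ``gap_bp``.

    A merged region spans the union, inherits the smallest p and q_fdr of its
    members, the q_stat of largest magnitude, and the summed SNP count.
    """
    if not regions:
        return []
    recs = sorted(regions, key=lambda r: (r.chrom, r.start_bp, r.end_bp))
    out = [recs[0]]
    for r in recs[1:]:
        last = out[-1]
        if r.chrom == last.chrom and r.start_bp - last.end_bp <= gap_bp:
            out[-1] = RegionRecord(
                chrom=last.chrom,
                start_bp=last.start_bp,
                end_bp=max(last.end_bp, r.end_bp),
                block_id=last.block_id,
                n_snps=last.n_snps + r.n_snps,
                q_stat=r.q_stat if abs(r.q_stat) > abs(last.q_stat) else last.q_stat,
                p=min(last.p, r.p),
                q_fdr=min(last.q_fdr, r.q_fdr) if np.isfinite(last.q_fdr) else last.q_fdr,
            )
        else:
            out.append(r)
    return out


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _resolve_cap(config: ScanConfig, pos: np.ndarray) -> int:
    if config.max_window is not None:
        return config.max_window
    span = max(pos.max() - pos.min(), 1)
    per_mb = len(pos) / (span / 1e6)
    cap = int(np.ceil(per_mb / config.window_step) * config.window_step)
    return max(cap, config.window_step)


@dataclass
class _BlockData:
    block_id: int
    idx: np.ndarray  # global SNP indices (contiguous)
    chrom: str


def _split_blocks(block_ids: np.ndarray, chroms: np.ndarray) -> list[_BlockData]:
    change = np.flatnonzero(np.diff(block_ids)) + 1
    edges = np.concatenate([[0], change, [len(block_ids)]])
    out = []
    for s, e in zip(edges[:-1], edges[1:]):
        out.append(
            _BlockData(block_id=int(block_ids[s]), idx=np.arange(s, e), chrom=str(chroms[s]))
        )
    return out


def _scan_all_blocks(hp, l, blocks_data, null_prods, theta, config, cap):
    """Peel-off every block at one theta; returns candidate RegionRecords."""
    pos = hp.pos
    candidates = []
    for bd in blocks_data:
        sl = slice(bd.idx[0], bd.idx[-1] + 1)
        null = null_qmax_from_products(null_prods[:, sl], l[sl], theta, config, cap)
        hits = peel_off_scan(hp.z1[sl], hp.z2[sl], l[sl], null, theta, config, cap)
        for h in hits:
            gi = bd.idx[h["start"]:h["end"]]
            candidates.append(
                RegionRecord(
                    chrom=bd.chrom,
                    start_bp=int(pos[gi[0]]) - 1,  # BED half-open
                    end_bp=int(pos[gi[-1]]),
                    block_id=bd.block_id,
                    n_snps=len(gi),
                    q_stat=h["q"],
                    p=h["p"],
                )
            )
    return candidates


def select_theta(
    hp: HarmonizedPair,
    panel: GenotypePanel,
    l: np.ndarray,
    blocks_data,
    null_prods: np.ndarray,
    config: ScanConfig,
    n1: float,
    n2: float,
    cap: int,
) -> ThetaResult:
    """Run the scan on a theta grid (sharing the null draws), score each theta
    by the proportion pi(theta) of genetic covariance in its FDR-passing
    regions, and pick theta_hat = argmax |pi| (ties toward smaller theta)."""
    pos = hp.pos
    pis, per_theta = [], []
    for theta in config.theta_grid:
        cands = _scan_all_blocks(hp, l, blocks_data, null_prods, theta, config, cap)
        if cands:
            qvals, reject = bh_fdr([c.p for c in cands], config.fdr_q)
            passing = []
            for c, qv, rj in zip(cands, qvals, reject):
                c.q_fdr = float(qv)
                if rj:
                    passing.append(c)
        else:
            passing = []
        merged = merge_regions(passing, config.merge_gap_bp)
        if merged:
            mask = np.zeros(len(pos), dtype=bool)
            for r in merged:
                mask |= (hp.chrom == r.chrom) & (pos - 1 >= r.start_bp) & (pos - 1 < r.end_bp)
            strat = stratified_covariance(hp.z1, hp.z2, mask, panel, n1, n2, config.ld_window_bp)
            pis.append(0.0 if strat.unstable else strat.pi)
        else:
            pis.append(0.0)
        per_theta.append(merged)
    pis = np.asarray(pis)
    if np.all(pis == 0.0):
        grid = list(config.theta_grid)
        theta_hat = grid[len(grid) // 2]  # convention: grid midpoint
    else:
        best = int(np.argmax(np.abs(pis)))  # argmax takes the first (smallest theta) on ties
        theta_hat = config.theta_grid[best]
    return ThetaResult(
        thetas=tuple(config.theta_grid),
        pis=pis,
        regions_per_theta=per_theta,
        theta_hat=float(theta_hat),
    )


def run_logodetect(
    s1: SumStats,
    s2: SumStats,
    panel: GenotypePanel,
    blocks: list[BlockSpec],
    config: ScanConfig,
    estimates: NullEstimates | None = None,
) -> tuple[list[RegionRecord], ThetaResult, dict]:
    """End-to-end scan: harmonize, estimate, sample the null, select theta,
    peel off per block, pool, BH-correct and merge.

    Returns (final merged FDR-passing regions at theta_hat, the theta-grid
    result, and a diagnostics dict).  Fully reproducible given config.seed.
    """
    hp = harmonize_pair(s1, s2, panel.meta.assign(maf=panel.maf), maf_min=config.maf_min)
    sub = panel.select(hp.df["snp"])
    # align panel order to harmonized (chrom, pos) order
    order = hp.df.set_index("snp").index.get_indexer(sub.meta["snp"])
    inv = np.argsort(order)
    sub = sub.take(inv)
    if not np.array_equal(sub.meta["snp"].to_numpy(), hp.df["snp"].to_numpy()):
        raise DataError("panel/harmonized SNP alignment failed")

    lsc = ld_scores(sub, config.ld_window_bp)
    m = sub.m
    fit1 = estimates or estimate_h2(hp.z1, lsc.l, hp.n1, m)
    if estimates is None:
        fit2 = estimate_h2(hp.z2, lsc.l, hp.n2, m)
        cross = estimate_cross(hp.z1, hp.z2, lsc.l, hp.n1, hp.n2, m)
        if config.overlap == "none":
            rho_e_ns = 0.0
        elif config.overlap == "auto":
            rho_e_ns = cross.intercept_cross * np.sqrt(hp.n1 * hp.n2)
        else:
            rho_e_ns = float(config.overlap)
        estimates = NullEstimates(
            h2_1=fit1.h2, h2_2=fit2.h2, n1=hp.n1, n2=hp.n2, m_total=m, rho_e_ns=rho_e_ns
        )

    block_ids = assign_blocks(hp.chrom, hp.pos, blocks)
    keep = block_ids >= 0
    if not keep.all():
        log.info("dropping %d SNP(s) outside all LD blocks", int((~keep).sum()))
        hp = HarmonizedPair(df=hp.df[keep].reset_index(drop=True), n1=hp.n1, n2=hp.n2)
        sub = sub.take(np.flatnonzero(keep))
        lsc.l = lsc.l[keep]
        block_ids = block_ids[keep]

    model = build_null_model(sub, estimates, block_ids, chunk_bp=config.chunk_bp)
    rng = np.random.default_rng(config.seed)
    Z1, Z2 = draw_batch(model, config.n_mc, rng)
    Z1 = standardize_rows(Z1, hp.z1.mean(), hp.z1.std())
    Z2 = standardize_rows(Z2, hp.z2.mean(), hp.z2.std())
    null_prods = Z1 * Z2

    cap = _resolve_cap(config, hp.pos)
    blocks_data = _split_blocks(block_ids, hp.chrom)
    theta_result = select_theta(
        hp, sub, lsc.l, blocks_data, null_prods, config, hp.n1, hp.n2, cap
    )
    final = theta_result.regions_per_theta[
        list(config.theta_grid).index(theta_result.theta_hat)
    ]
    diagnostics = {
        "m_snps": m,
        "estimates": estimates,
        "cap": cap,
        "theta_hat": theta_result.theta_hat,
        "n_candidates_by_theta": [len(r) for r in theta_result.regions_per_theta],
    }
    return final, theta_result, diagnostics
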