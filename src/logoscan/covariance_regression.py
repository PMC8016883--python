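"""LD-score-regression estimators: heritability, cross-trait genetic
covariance with an overlap intercept, two-annotation stratified covariance,
and liability/observed scale conversion."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ld_core import GenotypePanel, LDScores, ParameterError

log = logging.getLogger(__name__)

MIN_SNPS = 50


@dataclass
class LdscFit:
    h2: float
    intercept: float
    h2_se: float
    intercept_se: float
    m_total: int


@dataclass
class CrossLdscFit:
    rho_g: float
    intercept_cross: float  # estimate of rho_e * n_s / sqrt(n1 * n2)
    rho_g_se: float
    intercept_se: float
    m_total: int


@dataclass
class StratifiedCovariance:
    rho_region: float
    rho_rest: float
    pi: float
    rho_region_se: float
    unstable: bool = False


@dataclass
class LiabilityScale:
    """Population (P) and sample (S) prevalences for a pair of binary traits."""

    p1: float
    s1: float
    p2: float | None = None
    s2: float | None = None

    def __post_init__(self):
        for v in (self.p1, self.s1, self.p2, self.s2):
            if v is not None and not (0.0 < v < 1.0):
                raise ParameterError(f"prevalence {v} outside (0, 1)")

    @property
    def tau1(self) -> float:
        return stats.norm.ppf(1.0 - self.s1)

    @property
    def tau2(self) -> float:
        return stats.norm.ppf(1.0 - self.s2)


# ---------------------------------------------------------------------------
# weighted regression with block jackknife
# ---------------------------------------------------------------------------

def _wls(y: np.ndarray, X: np.ndarray, w: np.ndarray) -> np.ndarray:
    Xw = X * w[:, None]
    return np.linalg.solve(X.T @ Xw, Xw.T @ y)


def _jackknife(y: np.ndarray, X: np.ndarray, w: np.ndarray, n_blocks: int):
    """Delete-one block jackknife over contiguous SNP blocks.

    Returns (coef, se) where coef is the full-sample WLS fit.
    """
    m = len(y)
    n_blocks = max(2, min(n_blocks, m // 2))
    edges = np.linspace(0, m, n_blocks + 1).astype(int)
    Xw = X * w[:, None]
    xtx = X.T @ Xw
    xty = Xw.T @ y
    coef = np.linalg.solve(xtx, xty)
    deleted = np.empty((n_blocks, X.shape[1]))
    for b in range(n_blocks):
        sl = slice(edges[b], edges[b + 1])
        xtx_b = X[sl].T @ Xw[sl]
        xty_b = Xw[sl].T @ y[sl]
        deleted[b] = np.linalg.solve(xtx - xtx_b, xty - xty_b)
    pseudo = n_blocks * coef[None, :] - (n_blocks - 1) * deleted
    se = pseudo.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return coef, se


def _check_inputs(z, l):
    z = np.asarray(z, dtype=float)
    lv = l.l if isinstance(l, LDScores) else np.asarray(l, dtype=float)
    if len(z) != len(lv):
        raise ParameterError("z and LD scores must be aligned")
    if len(z) < MIN_SNPS:
        raise ParameterError(f"need at least {MIN_SNPS} SNPs for a stable regression, got {len(z)}")
    return z, lv


def _weight_vector(l, n_eff, h2_guess, m_total, weights):
    lw = np.maximum(l, 1.0)
    if weights == "simple":
        return 1.0 / lw
    return 1.0 / (1.0 + (n_eff * max(h2_guess, 0.0) / m_total) * lw)


def estimate_h2(
    z,
    l,
    n: float,
    m_total: int,
    weights: str = "twostep",
    n_jackknife: int = 200,
) -> LdscFit:
    """Heritability via weighted regression of z^2 on LD scores.

    h2 = slope * m_total / n, with an unconstrained intercept.
    """
    z, lv = _check_inputs(z, l)
    y = z * z
    X = np.column_stack([lv, np.ones_like(lv)])
    w = _weight_vector(lv, n, 0.0, m_total, "simple")
    coef = _wls(y, X, w)
    if weights == "twostep":
        h2_1 = coef[0] * m_total / n
        w = _weight_vector(lv, n, h2_1, m_total, weights)
    coef, se = _jackknife(y, X, w, n_jackknife)
    scale = m_total / n
    return LdscFit(
        h2=coef[0] * scale,
        intercept=coef[1],
        h2_se=se[0] * scale,
        intercept_se=se[1],
        m_total=m_total,
    )


def estimate_cross(
    z1,
    z2,
    l,
    n1: float,
    n2: float,
    m_total: int,
    weights: str = "twostep",
    n_jackknife: int = 200,
) -> CrossLdscFit:
    """Global genetic covariance via weighted regression of z1*z2 on LD scores.

    rho_g = slope * m_total / sqrt(n1 n2); the intercept estimates
    rho_e * n_s / sqrt(n1 n2), the plug-in needed by the null sampler.
    """
    z1, lv = _check_inputs(z1, l)
    z2, _ = _check_inputs(z2, l)
    y = z1 * z2
    X = np.column_stack([lv, np.ones_like(lv)])
    n_eff = np.sqrt(n1 * n2)
    w = _weight_vector(lv, n_eff, 0.0, m_total, "simple")
    coef = _wls(y, X, w)
    if weights == "twostep":
        rho_1 = abs(coef[0]) * m_total / n_eff
        w = _weight_vector(lv, n_eff, rho_1, m_total, weights)
    coef, se = _jackknife(y, X, w, n_jackknife)
    scale = m_total / n_eff
    return CrossLdscFit(
        rho_g=coef[0] * scale,
        intercept_cross=coef[1],
        rho_g_se=se[0] * scale,
        intercept_se=se[1],
        m_total=m_total,
    )


def stratified_ld_scores(
    panel: GenotypePanel, mask: np.ndarray, window_bp: float = 1_000_000.0
) -> tuple[np.ndarray, np.ndarray]:
    """Windowed LD scores split by annotation: (score to masked SNPs,
    score to unmasked SNPs); their sum is the ordinary LD score."""
    mask = np.asarray(mask, dtype=bool)
    m = panel.m
    pos = panel.pos
    chroms = panel.chrom
    half = window_bp / 2.0
    n = panel.n_ref
    l_in = np.zeros(m)
    l_out = np.zeros(m)
    import pandas as pd

    for c in pd.unique(chroms):
        cidx = np.flatnonzero(chroms == c)
        cp = pos[cidx]
        order = np.argsort(cp, kind="mergesort")
        cidx, cp = cidx[order], cp[order]
        Xc = panel.X[:, cidx]
        cm = mask[cidx]
        lo = np.searchsorted(cp, cp - half, side="left")
        hi = np.searchsorted(cp, cp + half, side="right")
        for k in range(len(cidx)):
            r = Xc[:, k] @ Xc[:, lo[k]:hi[k]] / (n - 1)
            r2 = r * r
            win_mask = cm[lo[k]:hi[k]]
            l_in[cidx[k]] = r2[win_mask].sum()
            l_out[cidx[k]] = r2[~win_mask].sum()
    return l_in, l_out


def stratified_covariance(
    z1,
    z2,
    region_mask,
    panel: GenotypePanel,
    n1: float,
    n2: float,
    window_bp: float = 1_000_000.0,
    n_jackknife: int = 200,
) -> StratifiedCovariance:
    """Two-annotation stratified covariance: the masked region vs the rest.

    Joint weighted regression of z1*z2 on the two stratified LD-score
    columns; rho_region = slope_region * m_region / sqrt(n1 n2).  pi is the
    proportion of total genetic covariance in the region (0 for an empty
    region set, flagged unstable when the total is near zero).
    """
    region_mask = np.asarray(region_mask, dtype=bool)
    if region_mask.sum() == 0:
        return StratifiedCovariance(0.0, 0.0, 0.0, 0.0)
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    l_in, l_out = stratified_ld_scores(panel, region_mask, window_bp)
    l_tot = l_in + l_out
    y = z1 * z2
    n_eff = np.sqrt(n1 * n2)
    w = _weight_vector(l_tot, n_eff, 0.0, panel.m, "simple")
    m_in = int(region_mask.sum())
    m_out = panel.m - m_in
    if m_out == 0:
        # whole-genome annotation: the "rest" column is identically zero
        X = np.column_stack([l_in, np.ones_like(l_tot)])
        coef, se = _jackknife(y, X, w, n_jackknife)
        coef = np.array([coef[0], 0.0, coef[1]])
        se = np.array([se[0], 0.0, se[1]])
    else:
        X = np.column_stack([l_in, l_out, np.ones_like(l_tot)])
        coef, se = _jackknife(y, X, w, n_jackknife)
    rho_region = coef[0] * m_in / n_eff
    rho_rest = coef[1] * m_out / n_eff
    rho_g = rho_region + rho_rest
    unstable = abs(rho_g) < 1e-8
    pi = 0.0 if unstable else rho_region / rho_g
    if unstable:
        log.warning("stratified_covariance: |rho_g| near zero, pi is unstable")
    return StratifiedCovariance(
        rho_region=rho_region,
        rho_rest=rho_rest,
        pi=pi,
        rho_region_se=se[0] * m_in / n_eff,
        unstable=unstable,
    )


# ---------------------------------------------------------------------------
# liability <-> observed scale
# ---------------------------------------------------------------------------

def h2_observed(h2: float, P: float, S: float) -> float:
    """Observed-scale heritability from the liability-scale value."""
    if not (0.0 < P < 1.0 and 0.0 < S < 1.0):
        raise ParameterError("prevalences must lie in (0, 1)")
    tau = stats.norm.ppf(1.0 - S)
    phi2 = stats.norm.pdf(tau) ** 2
    return h2 * phi2 * S * (1.0 - S) / (P**2 * (1.0 - P) ** 2)


def rho_observed(rho_g: float, P1: float, S1: float, P2: float, S2: float) -> float:
    """Observed-scale genetic covariance from the liability-scale value."""
    for v in (P1, S1, P2, S2):
        if not (0.0 < v < 1.0):
            raise ParameterError("prevalences must lie in (0, 1)")
    t1 = stats.norm.ppf(1.0 - S1)
    t2 = stats.norm.ppf(1.0 - S2)
    num = np.sqrt(
        stats.norm.pdf(t1) ** 2 * stats.norm.pdf(t2) ** 2 * S1 * (1 - S1) * S2 * (1 - S2)
    )
    return rho_g * num / (P1 * (1 - P1) * P2 * (1 - P2))


def observed_scale(value: float, scales: LiabilityScale, mode: str = "h2") -> float:
    """Convert heritability (mode='h2', trait 1) or genetic covariance
    (mode='cov') from the liability scale to the observed scale."""
    if mode == "h2":
        return h2_observed(value, scales.p1, scales.s1)
    if mode == "cov":
        if scales.p2 is None or scales.s2 is None:
            raise ParameterError("mode='cov' needs prevalences for both traits")
        return rho_observed(value, scales.p1, scales.s1, scales.p2, scales.s2)
    raise ParameterError(f"unknown mode {mode!r}")
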