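"""Desk-scale generators for reference panels, bivariate genetic effects,
GWAS z-scores and complete on-disk input bundles.

Genotypes come from a haplotype copying-with-recombination mosaic over a
small founder pool, which produces positive short-range LD that decays with
genomic distance.  Effect sizes follow bivariate normal (or heavier-tailed)
models with configurable heritability, signal regions and effect
correlation; phenotypes are linear with optional shared individuals and
environmental correlation, or binary via a liability threshold.
"""
from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import gwas_io
from .ld_core import ParameterError

log = logging.getLogger(__name__)


@dataclass
class SimulationScenario:
    model: str = "infinitesimal"  # infinitesimal | heritability_enrichment |
    # signal_region | sparse | heavy_tailed | maf_ld_weighted
    h2_1: float = 0.2
    h2_2: float = 0.2
    rho: float = 0.0  # effect correlation inside signal regions
    n_regions: int = 0
    region_size: int = 0  # SNPs per signal region
    prop_h2: float = 0.3  # heritability share of signal / enriched SNPs
    enrichment_snps: int = 0  # enriched SNP count (heritability_enrichment)
    sparse_fraction: float = 0.01
    t_df: float = 4.0
    maf_exponent: float = 0.75
    n1: int = 2000
    n2: int = 2000
    n_shared: int = 0
    rho_e: float = 0.0
    binary: bool = False
    prevalence_pop: tuple = (0.5, 0.5)
    prevalence_sample: tuple = (0.5, 0.5)
    m_snps: int = 2000
    n_ref: int = 500
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.h2_1 < 1.0 and 0.0 <= self.h2_2 < 1.0):
            raise ParameterError("heritabilities must lie in [0, 1)")
        if abs(self.rho) > 1.0:
            raise ParameterError("|rho| must be <= 1")
        if self.n_regions * self.region_size > self.m_snps:
            raise ParameterError("signal regions exceed the SNP count")
        if self.n_shared > min(self.n1, self.n2):
            raise ParameterError("n_shared exceeds a cohort size")


@dataclass
class EffectDraw:
    beta: np.ndarray
    gamma: np.ndarray
    truth_regions: list  # list of (start, end) SNP-index intervals
    k_corr: int


@dataclass
class SimBundle:
    panel_path: Path
    sumstats1_path: Path
    sumstats2_path: Path
    blocks_path: Path
    truth_path: Path
    scenario_path: Path
    scenario: SimulationScenario


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

DEFAULT_LD_PROFILE = {
    "n_founders": 20,
    "switch_rate_per_bp": 5e-5,  # haplotype switch probability scale
    "founder_corr_rate_per_bp": 2e-5,  # founder-allele persistence decay
    "spacing_bp": (2000, 8000),
    "founder_freq_range": (0.15, 0.85),
}


def _founder_pool(freqs: np.ndarray, positions: np.ndarray, n_founders: int, corr_rate: float, rng) -> np.ndarray:
    """Founder haplotypes with serially correlated alleles, so copied mosaics
    carry LD beyond founder identity alone."""
    m = len(freqs)
    pool = np.empty((n_founders, m), dtype=np.int8)
    pool[:, 0] = rng.random(n_founders) < freqs[0]
    keep_prob = np.exp(-corr_rate * np.diff(positions))
    for j in range(1, m):
        keep = rng.random(n_founders) < keep_prob[j - 1]
        fresh = rng.random(n_founders) < freqs[j]
        pool[:, j] = np.where(keep, pool[:, j - 1], fresh)
    return pool


def _mosaic_haplotypes(founders: np.ndarray, positions: np.ndarray, n_hap: int, switch_prob: np.ndarray, rng) -> np.ndarray:
    """Copying process: each haplotype tracks a founder, switching between
    SNPs with the given per-interval probability."""
    f, m = founders.shape
    src = rng.integers(0, f, size=n_hap)
    out = np.empty((n_hap, m), dtype=np.int8)
    out[:, 0] = founders[src, 0]
    for j in range(1, m):
        flip = rng.random(n_hap) < switch_prob[j - 1]
        nsw = int(flip.sum())
        if nsw:
            src[flip] = rng.integers(0, f, size=nsw)
        out[:, j] = founders[src, j]
    return out


def simulate_panel(
    m_snps: int,
    n_ref: int,
    ld_profile: dict | None = None,
    seed: int = 0,
    maf_min: float = 0.05,
    chrom: str = "1",
    start_bp: int = 1,
):
    """Simulate diploid reference dosages with distance-decaying LD.

    Returns (raw dosages n_ref x m, meta DataFrame, founders, positions);
    SNPs failing the MAF filter in the panel are dropped from the meta/raw
    output.  The founder pool is returned so GWAS cohorts can be drawn from
    the same LD structure.
    """
    prof = {**DEFAULT_LD_PROFILE, **(ld_profile or {})}
    rng = np.random.default_rng(seed)
    lo, hi = prof["spacing_bp"]
    gaps = rng.integers(lo, hi, size=m_snps - 1) if m_snps > 1 else np.array([], dtype=int)
    positions = start_bp + np.concatenate([[0], np.cumsum(gaps)])
    flo, fhi = prof["founder_freq_range"]
    freqs = rng.uniform(flo, fhi, size=m_snps)
    founders = _founder_pool(
        freqs, positions, prof["n_founders"], prof["founder_corr_rate_per_bp"], rng
    )
    switch_prob = 1.0 - np.exp(-prof["switch_rate_per_bp"] * np.diff(positions))
    haps = _mosaic_haplotypes(founders, positions, 2 * n_ref, switch_prob, rng)
    raw = (haps[0::2] + haps[1::2]).astype(float)

    freq_hat = raw.mean(axis=0) / 2.0
    maf = np.minimum(freq_hat, 1.0 - freq_hat)
    keep = maf >= maf_min
    if keep.sum() < 2:
        raise ParameterError("MAF filter removed nearly all SNPs; relax the constraints")
    raw = raw[:, keep]
    positions = positions[keep]
    founders = founders[:, keep]
    meta = pd.DataFrame(
        {
            "snp": [f"rs{i}" for i in range(keep.sum())],
            "chrom": chrom,
            "pos": positions,
            "a1": "A",
            "a2": "G",
            "maf": maf[keep],
        }
    )
    return raw, meta, founders, positions


def cohort_genotypes(founders, positions, n_ind, ld_profile, rng) -> np.ndarray:
    """Draw diploid cohort dosages from the same founder mosaic process."""
    prof = {**DEFAULT_LD_PROFILE, **(ld_profile or {})}
    switch_prob = 1.0 - np.exp(-prof["switch_rate_per_bp"] * np.diff(positions))
    haps = _mosaic_haplotypes(founders, positions, 2 * n_ind, switch_prob, rng)
    return (haps[0::2] + haps[1::2]).astype(float)


# ---------------------------------------------------------------------------
# effect sizes
# ---------------------------------------------------------------------------

def _bivariate(rng, n, var1, var2, corr):
    cov = corr * np.sqrt(var1 * var2)
    L = np.linalg.cholesky(np.array([[var1, cov], [cov, var2]]))
    e = rng.standard_normal((n, 2)) @ L.T
    return e[:, 0], e[:, 1]


def simulate_effects(
    scenario: SimulationScenario,
    maf: np.ndarray | None = None,
    rng=None,
    truth_regions: list | None = None,
) -> EffectDraw:
    """Per-SNP effect vectors (beta, gamma) under the scenario's model.

    All models conserve the variance budget: E[sum beta^2] = h2_1 and
    E[sum gamma^2] = h2_2.  For the signal_region model, explicit
    ``truth_regions`` (disjoint (start, end) SNP intervals) override random
    placement.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed)
    M = scenario.m_snps
    h1, h2 = scenario.h2_1, scenario.h2_2
    model = scenario.model
    truth, k_corr = [], 0

    if model == "infinitesimal":
        beta = rng.normal(0.0, np.sqrt(h1 / M), M)
        gamma = rng.normal(0.0, np.sqrt(h2 / M), M)
    elif model == "heritability_enrichment":
        k = scenario.enrichment_snps or max(1, int(round(0.015 * M)))
        hot = rng.choice(M, size=k, replace=False)
        p = scenario.prop_h2
        beta = rng.normal(0.0, np.sqrt((1 - p) * h1 / (M - k)), M)
        gamma = rng.normal(0.0, np.sqrt((1 - p) * h2 / (M - k)), M)
        beta[hot] = rng.normal(0.0, np.sqrt(p * h1 / k), k)
        gamma[hot] = rng.normal(0.0, np.sqrt(p * h2 / k), k)
    elif model == "signal_region":
        N, L, p = scenario.n_regions, scenario.region_size, scenario.prop_h2
        if truth_regions is not None:
            truth = [(int(s), int(e)) for s, e in truth_regions]
        else:
            if N * L > M:
                raise ParameterError("signal regions exceed the SNP count")
            truth = _place_regions(M, N, L, rng)
        sig = np.zeros(M, dtype=bool)
        for s, e in truth:
            sig[s:e] = True
        k_corr = int(sig.sum())
        n_sig = k_corr
        beta = np.empty(M)
        gamma = np.empty(M)
        b_in, g_in = _bivariate(rng, n_sig, p * h1 / n_sig, p * h2 / n_sig, scenario.rho)
        beta[sig], gamma[sig] = b_in, g_in
        rest = M - n_sig
        if rest > 0:
            beta[~sig] = rng.normal(0.0, np.sqrt((1 - p) * h1 / rest), rest)
            gamma[~sig] = rng.normal(0.0, np.sqrt((1 - p) * h2 / rest), rest)
    elif model == "sparse":
        k = max(1, int(round(scenario.sparse_fraction * M)))
        beta = np.zeros(M)
        gamma = np.zeros(M)
        beta[rng.choice(M, k, replace=False)] = rng.normal(0.0, np.sqrt(h1 / k), k)
        gamma[rng.choice(M, k, replace=False)] = rng.normal(0.0, np.sqrt(h2 / k), k)
    elif model == "heavy_tailed":
        df = scenario.t_df
        scale = np.sqrt((df - 2) / df)  # unit-variance t
        beta = stats.t.rvs(df, size=M, random_state=rng) * scale * np.sqrt(h1 / M)
        gamma = stats.t.rvs(df, size=M, random_state=rng) * scale * np.sqrt(h2 / M)
    elif model == "maf_ld_weighted":
        if maf is None:
            raise ParameterError("maf_ld_weighted needs per-SNP MAF values")
        w = (maf * (1.0 - maf)) ** scenario.maf_exponent
        w = w / w.sum()
        beta = rng.normal(0.0, np.sqrt(h1 * w))
        gamma = rng.normal(0.0, np.sqrt(h2 * w))
    else:
        raise ParameterError(f"unknown effect model {model!r}")

    return EffectDraw(beta=beta, gamma=gamma, truth_regions=truth, k_corr=k_corr)


def _place_regions(M, N, L, rng) -> list[tuple[int, int]]:
    """Random disjoint (start, start+L) SNP-index intervals."""
    for _ in range(1000):
        starts = np.sort(rng.choice(M - L + 1, size=N, replace=False))
        if np.all(np.diff(starts) >= L) if N > 1 else True:
            return [(int(s), int(s + L)) for s in starts]
    raise ParameterError("could not place disjoint signal regions")


# ---------------------------------------------------------------------------
# GWAS z-scores
# ---------------------------------------------------------------------------

def _standardize_cols(G: np.ndarray) -> np.ndarray:
    mu = G.mean(axis=0)
    sd = G.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (G - mu[None, :]) / sd[None, :]


def _liability_to_binary(liab: np.ndarray, P: float, S: float, n_target: int, rng):
    """Case/control sampling at sample prevalence S from a liability vector."""
    thr = stats.norm.ppf(1.0 - P) * liab.std()
    cases = np.flatnonzero(liab > thr)
    controls = np.flatnonzero(liab <= thr)
    n_case = int(round(S * n_target))
    n_ctrl = n_target - n_case
    if len(cases) < n_case or len(controls) < n_ctrl:
        raise ParameterError(
            f"cannot reach sample prevalence {S}: have {len(cases)} cases / "
            f"{len(controls)} controls; simulate a larger cohort"
        )
    pick = np.concatenate([
        rng.choice(cases, n_case, replace=False),
        rng.choice(controls, n_ctrl, replace=False),
    ])
    y = np.zeros(len(pick))
    y[:n_case] = 1.0
    return pick, y


def simulate_gwas(
    genotypes: tuple[np.ndarray, np.ndarray],
    effects: EffectDraw,
    scenario: SimulationScenario,
    meta: pd.DataFrame | None = None,
    rng=None,
) -> tuple[gwas_io.SumStats, gwas_io.SumStats]:
    """GWAS z-scores for both cohorts: z = X_std^T y_std / sqrt(n).

    ``genotypes`` is (X cohort 1, Z cohort 2); when the scenario requests
    shared samples the first ``n_shared`` rows of each cohort must be the
    same individuals.  Residual variance is 1 - h2 per trait, with
    environmental correlation rho_e among shared individuals.  Binary mode
    thresholds the liability at the population prevalence and samples
    cases/controls to the sample prevalence.
    """
    rng = rng if rng is not None else np.random.default_rng(scenario.seed + 1)
    X, Z = genotypes
    ns = scenario.n_shared
    Xs = _standardize_cols(X)
    Zs = _standardize_cols(Z)

    g1 = Xs @ effects.beta
    g2 = Zs @ effects.gamma
    e1 = rng.normal(0.0, 1.0, X.shape[0]) * np.sqrt(max(1.0 - scenario.h2_1, 0.0))
    e2 = rng.normal(0.0, 1.0, Z.shape[0]) * np.sqrt(max(1.0 - scenario.h2_2, 0.0))
    if ns > 0 and scenario.rho_e != 0.0:
        # correlated residuals for the shared individuals
        shared = rng.multivariate_normal(
            [0.0, 0.0],
            [[1.0, scenario.rho_e], [scenario.rho_e, 1.0]],
            size=ns,
        )
        e1[:ns] = shared[:, 0] * np.sqrt(max(1.0 - scenario.h2_1, 0.0))
        e2[:ns] = shared[:, 1] * np.sqrt(max(1.0 - scenario.h2_2, 0.0))
    y1 = g1 + e1
    y2 = g2 + e2

    if scenario.binary:
        p1, p2 = scenario.prevalence_pop
        s1v, s2v = scenario.prevalence_sample
        pick1, y1b = _liability_to_binary(y1, p1, s1v, scenario.n1, rng)
        pick2, y2b = _liability_to_binary(y2, p2, s2v, scenario.n2, rng)
        Xs, y1 = Xs[pick1], y1b
        Zs, y2 = Zs[pick2], y2b
        Xs = _standardize_cols(Xs)
        Zs = _standardize_cols(Zs)

    y1 = (y1 - y1.mean()) / y1.std()
    y2 = (y2 - y2.mean()) / y2.std()
    n1, n2 = Xs.shape[0], Zs.shape[0]
    z1 = Xs.T @ y1 / np.sqrt(n1)
    z2 = Zs.T @ y2 / np.sqrt(n2)

    if meta is None:
        meta = pd.DataFrame(
            {
                "snp": [f"rs{i}" for i in range(len(z1))],
                "chrom": "1",
                "pos": np.arange(1, len(z1) + 1),
                "a1": "A",
                "a2": "G",
            }
        )

    def pack(z, n):
        df = meta[["snp", "chrom", "pos", "a1", "a2"]].copy()
        df["z"] = z
        df["n"] = float(n)
        return gwas_io.SumStats(df=df[["snp", "a1", "a2", "z", "n", "chrom", "pos"]])

    return pack(z1, n1), pack(z2, n2)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

SCENARIO_REGISTRY: dict[str, dict] = {
    "null_infinitesimal": dict(model="infinitesimal", h2_1=0.2, h2_2=0.2),
    "null_enriched": dict(
        model="heritability_enrichment", h2_1=0.2, h2_2=0.2, prop_h2=0.3, enrichment_snps=30
    ),
    "power_grid": dict(
        model="signal_region", h2_1=0.3, h2_2=0.3, rho=0.9, n_regions=5,
        region_size=100, prop_h2=0.3,
    ),
    "overlap_null": dict(model="infinitesimal", h2_1=0.2, h2_2=0.2, n_shared=1000, rho_e=0.4),
    "binary_null": dict(
        model="infinitesimal", h2_1=0.2, h2_2=0.2, binary=True,
        prevalence_pop=(0.3, 0.3), prevalence_sample=(0.5, 0.5), n1=1000, n2=1000,
    ),
    "signal_mixed": dict(
        model="signal_region", h2_1=0.4, h2_2=0.4, rho=0.9, n_regions=2,
        region_size=100, prop_h2=0.3, n_shared=500, rho_e=0.2,
    ),
}


def _write_sumstats(ss: gwas_io.SumStats, path: Path) -> None:
    out = ss.df.rename(
        columns={"snp": "SNP", "a1": "A1", "a2": "A2", "z": "Z", "n": "N"}
    )
    cols = ["SNP", "A1", "A2", "Z", "N"]
    out[cols].to_csv(path, sep="\t", index=False, float_format="%.8g")


def make_fixture(name: str, out_dir, seed: int | None = None, **overrides) -> SimBundle:
    """Write a complete, seeded, desk-scale input bundle for a registered
    scenario: panel TSV, two .sumstats files, LD-block BED, truth BED and a
    YAML scenario record."""
    if name not in SCENARIO_REGISTRY:
        raise ParameterError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIO_REGISTRY)}"
        )
    params = {**SCENARIO_REGISTRY[name], **overrides}
    if seed is not None:
        params["seed"] = seed
    scenario = SimulationScenario(**params)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    panel_seed, cohort_seed, effect_seed, pheno_seed = rng.integers(0, 2**31 - 1, 4)

    raw, meta, founders, positions = simulate_panel(
        scenario.m_snps, scenario.n_ref, seed=int(panel_seed)
    )
    scenario.m_snps = len(positions)  # post-MAF-filter SNP count
    crng = np.random.default_rng(int(cohort_seed))
    n_pool1 = scenario.n1 if not scenario.binary else int(scenario.n1 * 3)
    n_pool2 = scenario.n2 if not scenario.binary else int(scenario.n2 * 3)
    shared = cohort_genotypes(founders, positions, scenario.n_shared, None, crng) if scenario.n_shared else None
    X = cohort_genotypes(founders, positions, n_pool1 - scenario.n_shared, None, crng)
    Z = cohort_genotypes(founders, positions, n_pool2 - scenario.n_shared, None, crng)
    if shared is not None:
        X = np.vstack([shared, X])
        Z = np.vstack([shared, Z])

    maf = meta["maf"].to_numpy()
    effects = simulate_effects(scenario, maf=maf, rng=np.random.default_rng(int(effect_seed)))
    ss1, ss2 = simulate_gwas((X, Z), effects, scenario, meta=meta, rng=np.random.default_rng(int(pheno_seed)))

    panel_path = out_dir / "panel.tsv"
    gwas_io.write_dosage_tsv(raw, meta, panel_path)
    ss1_path = out_dir / "trait1.sumstats"
    ss2_path = out_dir / "trait2.sumstats"
    _write_sumstats(ss1, ss1_path)
    _write_sumstats(ss2, ss2_path)

    # LD blocks: tile the simulated span into ~10 equal blocks
    blocks_path = out_dir / "blocks.bed"
    span_start, span_end = int(positions.min()) - 1, int(positions.max())
    n_blocks = max(1, min(10, scenario.m_snps // 200))
    edges = np.linspace(span_start, span_end, n_blocks + 1).astype(int)
    blocks = [
        gwas_io.BlockSpec(chrom="1", start=int(a), end=int(b), block_id=i)
        for i, (a, b) in enumerate(zip(edges[:-1], edges[1:]))
        if b > a
    ]
    gwas_io.write_blocks(blocks, blocks_path)

    truth_path = out_dir / "truth.bed"
    with open(truth_path, "w") as fh:
        for s, e in effects.truth_regions:
            fh.write(f"1\t{int(positions[s]) - 1}\t{int(positions[e - 1])}\n")

    scenario_path = out_dir / "scenario.yaml"
    with open(scenario_path, "w") as fh:
        rec = dataclasses.asdict(scenario)
        rec["name"] = name
        rec["truth_regions_snp_idx"] = [list(t) for t in effects.truth_regions]
        yaml.safe_dump(rec, fh, sort_keys=True)

    return SimBundle(
        panel_path=panel_path,
        sumstats1_path=ss1_path,
        sumstats2_path=ss2_path,
        blocks_path=blocks_path,
        truth_path=truth_path,
        scenario_path=scenario_path,
        scenario=scenario,
    )
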