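"""Synthetic two-cohort experiment generator.

Genotypes are drawn from an AR(1)-latent-threshold model: within each LD
block a latent Gaussian with correlation rho^|i-j| is thresholded at the
allele-frequency quantile, twice per person, and the two haplotypes summed
to a dosage in {0, 1, 2}.  Phenotypes are additive on standardized
genotypes with the error variance set so the realized heritability matches
the configured h².  A discovery cohort yields marginal GWAS summary
statistics; an independent target cohort yields genotypes and phenotypes.
All randomness flows from one master seed through spawned child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import DosageMatrix
from .sumstats import DEFAULT_COLUMNS, SummaryStatRecord

# ordered non-ambiguous allele pairs (no A/T, no C/G)
_ALLELE_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_BLOCK_GAP_BP = 1_000_000  # between-block start spacing within a chromosome
_VARIANT_SPACING_BP = 5_000


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of the two-cohort experiment."""

    n_discovery: int = 2000
    n_target: int = 1000
    n_variants: int = 500
    block_size: int = 50
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    m_causal: int = 50
    h2: float = 0.098
    trait: str = "trait"
    trait_model: str = "continuous"  # "continuous" | "ordinal"
    thresholds: tuple[float, ...] = (0.25, 0.5, 0.75)  # cumulative probs, ordinal only
    info_range: tuple[float, float] = (0.85, 1.0)
    prob_ambiguous: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_discovery, self.n_target, self.n_variants, self.block_size) <= 0:
            raise SimulationError("all counts must be positive")
        if not 0 <= self.h2 < 1:
            raise SimulationError(f"h2 must be in [0, 1), got {self.h2}")
        if not 0 <= self.rho < 1:
            raise SimulationError(f"rho must be in [0, 1), got {self.rho}")
        if self.m_causal > self.n_variants:
            raise SimulationError("m_causal cannot exceed n_variants")
        if list(self.thresholds) != sorted(set(self.thresholds)):
            raise SimulationError("thresholds must be strictly increasing")


@dataclass
class SimTruth:
    """Ground truth retained for recovery tests."""

    causal_keys: list[tuple[str, int]]
    beta_std: np.ndarray  # effects on standardized genotypes
    beta_per_allele: np.ndarray
    genetic_values: np.ndarray
    realized_h2: float


def _variant_metadata(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Chromosome/position layout and allele/INFO draws for all variants."""
    n = config.n_variants
    block_ids = np.arange(n) // config.block_size
    n_blocks = int(block_ids.max()) + 1
    chrom_of_block = (np.arange(n_blocks) % 22) + 1
    block_rank = np.arange(n_blocks) // 22  # ordinal of the block on its chromosome

    chroms = chrom_of_block[block_ids].astype(str)
    within = np.arange(n) % config.block_size
    pos = 1 + block_rank[block_ids] * _BLOCK_GAP_BP + within * _VARIANT_SPACING_BP

    pair_idx = rng.integers(len(_ALLELE_PAIRS), size=n)
    counted = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    other = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    if config.prob_ambiguous > 0:
        amb = rng.random(n) < config.prob_ambiguous
        amb_idx = rng.integers(len(_AMBIGUOUS_PAIRS), size=n)
        for j in np.flatnonzero(amb):
            counted[j], other[j] = _AMBIGUOUS_PAIRS[amb_idx[j]]

    info = rng.uniform(*config.info_range, size=n)
    freq = rng.uniform(*config.maf_range, size=n)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos.astype(int),
            "counted_allele": counted,
            "other_allele": other,
            "info": info,
            "freq": freq,  # target frequency; replaced by realized freq later
        }
    )


def _draw_latent_block(
    rng: np.random.Generator, n: int, width: int, rho: float
) -> np.ndarray:
    """n x width latent Gaussians with AR(1) correlation rho^|i-j|."""
    z = np.empty((n, width))
    z[:, 0] = rng.standard_normal(n)
    if width > 1:
        innov = rng.standard_normal((n, width - 1)) * np.sqrt(1.0 - rho * rho)
        for j in range(1, width):
            z[:, j] = rho * z[:, j - 1] + innov[:, j - 1]
    return z


def simulate_genotypes(
    config: SimConfig,
    n_samples: int | None = None,
    rng: np.random.Generator | None = None,
    sample_prefix: str = "S",
    variants: pd.DataFrame | None = None,
) -> DosageMatrix:
    """Draw an LD-blocked dosage matrix.

    Shared variant metadata may be passed in so two cohorts segregate the
    same loci; otherwise it is drawn from the same stream first.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if n_samples is None:
        n_samples = config.n_target
    if variants is None:
        variants = _variant_metadata(config, rng)
    variants = variants.copy()

    n_var = len(variants)
    freqs = variants["freq"].to_numpy(dtype=float)
    cut = stats.norm.ppf(freqs)  # P(latent < cut) = freq

    dosages = np.empty((n_samples, n_var))
    block_ids = np.arange(n_var) // config.block_size
    for b in np.unique(block_ids):
        cols = np.flatnonzero(block_ids == b)
        width = len(cols)
        hap1 = _draw_latent_block(rng, n_samples, width, config.rho) < cut[cols]
        hap2 = _draw_latent_block(rng, n_samples, width, config.rho) < cut[cols]
        dosages[:, cols] = hap1.astype(float) + hap2.astype(float)

    variants["freq"] = dosages.mean(axis=0) / 2.0
    samples = [f"{sample_prefix}{i:06d}" for i in range(n_samples)]
    return DosageMatrix(samples=samples, variants=variants, dosages=dosages)


def draw_architecture(
    config: SimConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Causal variant indices and standardized effect sizes.

    Drawn once per experiment so the same architecture underlies every
    cohort; effects are N(0, 1/m_causal) on standardized genotypes.
    """
    causal = np.sort(rng.choice(config.n_variants, size=config.m_causal, replace=False))
    beta_std = rng.normal(0.0, np.sqrt(1.0 / config.m_causal), size=config.m_causal)
    return causal, beta_std


def simulate_phenotypes(
    geno: DosageMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    architecture: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, SimTruth]:
    """Additive phenotype at the configured heritability, plus ground truth.

    y = g + e with var(e) chosen so var(g)/var(y) = h2 in the simulated
    sample.  The causal architecture (variant indices and standardized
    effects) may be passed in so two cohorts share it; otherwise it is drawn
    from the phenotype stream.  Age and sex covariates are drawn
    independently of y.  For ``trait_model='ordinal'`` the continuous
    liability is additionally thresholded at the configured
    cumulative-probability quantiles into categories 1..k
    (k = len(thresholds) + 1).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    n = geno.n_samples
    p = geno.recompute_freq()
    sd = np.sqrt(2.0 * p * (1.0 - p))

    keys = geno.variant_keys()
    if config.h2 > 0:
        if architecture is None:
            architecture = draw_architecture(config, rng)
        causal, beta_std = architecture
        causal = np.asarray(causal, dtype=int)
        beta_std = np.asarray(beta_std, dtype=float)
        poly = (p[causal] > 0) & (p[causal] < 1)
        if not poly.all():
            # monomorphic in this cohort: contributes nothing
            causal, beta_std = causal[poly], beta_std[poly]
        z = (geno.dosages[:, causal] - 2.0 * p[causal]) / sd[causal]
        g = z @ beta_std
        var_g = g.var()
        var_e = var_g * (1.0 - config.h2) / config.h2 if var_g > 0 else 1.0
        e = rng.normal(0.0, np.sqrt(var_e), size=n)
        beta_pa = beta_std / sd[causal]
        causal_keys = [keys[j] for j in causal]
    else:
        g = np.zeros(n)
        e = rng.normal(0.0, 1.0, size=n)
        beta_std = np.empty(0)
        beta_pa = np.empty(0)
        causal_keys = []
    y = g + e
    realized_h2 = float(g.var() / y.var()) if y.var() > 0 else 0.0

    pheno = pd.DataFrame(
        {
            "sample": geno.samples,
            "age": rng.integers(25, 75, size=n).astype(float),
            "sex": rng.integers(0, 2, size=n).astype(float),
            config.trait: y,
        }
    )
    if config.trait_model == "ordinal":
        cuts = np.quantile(y, list(config.thresholds))
        pheno[f"{config.trait}_ordinal"] = (np.searchsorted(cuts, y, side="left") + 1).astype(float)

    truth = SimTruth(
        causal_keys=causal_keys,
        beta_std=beta_std,
        beta_per_allele=beta_pa,
        genetic_values=g,
        realized_h2=realized_h2,
    )
    return pheno, truth


def run_discovery_gwas(geno: DosageMatrix, y: np.ndarray) -> pd.DataFrame:
    """Per-variant marginal simple regression of y on dosage.

    Returns a canonical sumstats frame (chrom, pos, effect_allele,
    other_allele, beta, se, pvalue, eaf, info); the counted allele is the
    effect allele.  Monomorphic variants get NaN beta and are flagged in a
    ``flag`` column.
    """
    y = np.asarray(y, dtype=float)
    n = geno.n_samples
    if len(y) != n:
        raise SimulationError("phenotype length does not match sample count")

    x = geno.dosages
    nan = np.isnan(x)
    if nan.any():
        col_mean = np.nanmean(x, axis=0)
        x = np.where(nan, col_mean[None, :], x)

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc * xc).sum(axis=0)
    sxy = xc.T @ yc
    syy = float(yc @ yc)

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sxy / sxx
        rss = syy - beta * sxy
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    pval = np.clip(pval, 1e-300, 1.0)

    mono = sxx == 0
    beta[mono] = np.nan
    se[mono] = np.nan
    pval[mono] = np.nan

    out = pd.DataFrame(
        {
            "chrom": geno.variants["chrom"].astype(str),
            "pos": geno.variants["pos"].astype(int),
            "effect_allele": geno.variants["counted_allele"],
            "other_allele": geno.variants["other_allele"],
            "beta": beta,
            "se": se,
            "pvalue": pval,
            "eaf": x.mean(axis=0) / 2.0,
            "info": geno.variants["info"].astype(float),
            "flag": np.where(mono, "monomorphic", ""),
        }
    )
    return out


def sumstats_frame_to_records(df: pd.DataFrame) -> list[SummaryStatRecord]:
    """Convert a canonical sumstats frame to validated records, skipping NaN rows."""
    records = []
    for row in df.itertuples(index=False):
        if not np.isfinite(row.beta) or not np.isfinite(row.se) or row.se <= 0:
            continue
        if not (0 < row.eaf < 1):
            continue
        records.append(
            SummaryStatRecord(
                chrom=str(row.chrom),
                pos=int(row.pos),
                effect_allele=str(row.effect_allele),
                other_allele=str(row.other_allele),
                beta=float(row.beta),
                se=float(row.se),
                pvalue=float(min(max(row.pvalue, 1e-300), 1.0)),
                eaf=float(row.eaf),
                info=float(row.info),
            )
        )
    return records


@dataclass
class Experiment:
    """Outputs of :func:`make_portability_experiment`."""

    sumstats: pd.DataFrame
    discovery_truth: SimTruth
    target_geno: DosageMatrix
    target_pheno: pd.DataFrame
    target_truth: SimTruth
    config: SimConfig = field(repr=False)


def make_portability_experiment(config: SimConfig) -> Experiment:
    """Two independent cohorts from one generative process.

    The discovery cohort produces marginal summary statistics; the target
    cohort produces genotypes and phenotypes.  Both segregate the same
    variants (shared metadata) but are drawn from independent streams, so
    there is no sample overlap by construction.
    """
    ss = np.random.SeedSequence(config.seed)
    meta_rng, arch_rng, dg_rng, dp_rng, tg_rng, tp_rng = (
        np.random.default_rng(s) for s in ss.spawn(6)
    )
    variants = _variant_metadata(config, meta_rng)
    architecture = draw_architecture(config, arch_rng) if config.h2 > 0 else None

    disc_geno = simulate_genotypes(
        config, n_samples=config.n_discovery, rng=dg_rng,
        sample_prefix="D", variants=variants,
    )
    disc_pheno, disc_truth = simulate_phenotypes(
        disc_geno, config, rng=dp_rng, architecture=architecture
    )
    sumstats = run_discovery_gwas(disc_geno, disc_pheno[config.trait].to_numpy())

    target_geno = simulate_genotypes(
        config, n_samples=config.n_target, rng=tg_rng,
        sample_prefix="T", variants=variants,
    )
    target_pheno, target_truth = simulate_phenotypes(
        target_geno, config, rng=tp_rng, architecture=architecture
    )

    return Experiment(
        sumstats=sumstats,
        discovery_truth=disc_truth,
        target_geno=target_geno,
        target_pheno=target_pheno,
        target_truth=target_truth,
        config=config,
    )
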