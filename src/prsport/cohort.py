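"""Target-cohort genotype and sample QC.

Variant-level filtering (imputation INFO, autosomes), per-sample
heterozygosity F coefficients with outlier removal, the genomic relationship
matrix (GRM), and greedy relatedness pruning at a fixed cutoff.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

#: Required columns of the variant metadata frame.
VARIANT_COLUMNS = ("chrom", "pos", "counted_allele", "other_allele", "info", "freq")


class CohortError(ValueError):
    pass


@dataclass
class DosageMatrix:
    """Individuals x variants effect-allele dosages in [0, 2].

    Missing dosages are NaN.  ``variants`` is a DataFrame with columns
    ``chrom`` (string label), ``pos`` (1-based int), ``counted_allele``,
    ``other_allele``, ``info`` and ``freq`` (counted-allele frequency),
    one row per dosage column.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.variants)):
            raise CohortError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise CohortError(f"variant metadata missing columns {missing_cols}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise CohortError("dosages outside [0, 2]")
        keys = list(zip(self.variants["chrom"], self.variants["pos"]))
        if len(set(keys)) != len(keys):
            raise CohortError("duplicate variant keys")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_keys(self) -> list[tuple[str, int]]:
        return list(zip(self.variants["chrom"].astype(str), self.variants["pos"].astype(int)))

    def recompute_freq(self) -> np.ndarray:
        """Counted-allele frequency per variant from non-missing dosages."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.dosages, axis=0) / 2.0

    def subset_variants(self, mask_or_idx) -> "DosageMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return DosageMatrix(
            samples=list(self.samples),
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_samples(self, mask_or_idx) -> "DosageMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return DosageMatrix(
            samples=[self.samples[i] for i in idx],
            variants=self.variants.copy(),
            dosages=self.dosages[idx, :],
        )


@dataclass
class SampleQCReport:
    """Per-sample QC outcome; removal reasons are mutually exclusive."""

    samples: list[str]
    f_coeff: np.ndarray
    kept: np.ndarray  # bool
    reason: list[str]  # "" | "heterozygosity" | "relatedness"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "F": self.f_coeff,
                "kept": self.kept,
                "reason": self.reason,
            }
        )


def filter_variants_target(
    geno: DosageMatrix, info_min: float = 0.9, autosomes_only: bool = True
) -> DosageMatrix:
    """Keep variants with ``info >= info_min`` on autosomes 1-22.

    The boundary is retained (exclusion rule is INFO < info_min), unlike the
    strict discovery-side thresholds.
    """
    info = geno.variants["info"].to_numpy(dtype=float)
    keep = info >= info_min
    if autosomes_only:
        autosomes = {str(c) for c in range(1, 23)}
        chrom_ok = geno.variants["chrom"].astype(str).isin(autosomes).to_numpy()
        keep &= chrom_ok
    return geno.subset_variants(keep)


def heterozygosity_f(geno: DosageMatrix) -> np.ndarray:
    """Per-sample inbreeding/heterozygosity F coefficient.

    Dosages are rounded to hard calls.  For sample i over its M_i
    non-missing sites, F_i = (O_hom - E_hom) / (M_i - E_hom), with
    O_hom the observed count of genotypes in {0, 2} and
    E_hom = sum_j (1 - 2 p_j (1 - p_j)) using per-variant frequencies p_j
    estimated from the cohort.  Samples where M_i == E_hom (degenerate
    frequencies) get F = NaN.
    """
    hard = np.round(geno.dosages)
    missing = np.isnan(hard)
    p = geno.recompute_freq()

    obs_hom = ((hard == 0) | (hard == 2)) & ~missing
    o_hom = obs_hom.sum(axis=1).astype(float)
    per_var_ehom = 1.0 - 2.0 * p * (1.0 - p)
    e_hom = np.where(~missing, per_var_ehom[None, :], 0.0).sum(axis=1)
    m = (~missing).sum(axis=1).astype(float)

    denom = m - e_hom
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (o_hom - e_hom) / denom
    f[np.isclose(denom, 0.0)] = np.nan
    return f


def exclude_het_outliers(f: np.ndarray, sd_mult: float = 3.0) -> np.ndarray:
    """Boolean keep-mask: sample kept iff |F - mean(F)| <= sd_mult * sd(F).

    Mean and SD are computed once over all finite F values (no iteration).
    NaN F (undefined) is treated as an outlier.
    """
    f = np.asarray(f, dtype=float)
    if f.size < 2:
        raise CohortError("need at least 2 samples")
    finite = np.isfinite(f)
    mean = f[finite].mean()
    sd = f[finite].std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        keep = finite.copy()
        return keep
    if np.isinf(sd_mult):
        return finite.copy()
    keep = finite & (np.abs(f - mean) <= sd_mult * sd)
    return keep


def grm(geno: DosageMatrix) -> np.ndarray:
    """Genomic relationship matrix on mean-imputed, standardized dosages.

    A_ik = (1/M) sum_j (x_ij - 2 p_j)(x_kj - 2 p_j) / (2 p_j (1 - p_j)),
    with missing dosages imputed as 2 p_j (zero after centring) and
    monomorphic variants (p in {0, 1}) dropped from the sum with a warning.
    """
    p = geno.recompute_freq()
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic variant(s) from GRM",
            stacklevel=2,
        )
    if not poly.any():
        raise CohortError("no polymorphic variants for GRM")
    x = geno.dosages[:, poly]
    p = p[poly]
    centred = x - 2.0 * p[None, :]
    centred = np.where(np.isnan(centred), 0.0, centred)
    scale = np.sqrt(2.0 * p * (1.0 - p))
    z = centred / scale[None, :]
    m = z.shape[1]
    return (z @ z.T) / m


def rel_cutoff(a: np.ndarray, cutoff: float = 0.125) -> np.ndarray:
    """Greedy relatedness pruning: indices of samples to keep.

    While any off-diagonal entry among kept samples exceeds ``cutoff``,
    remove the sample with the most above-cutoff partners; ties broken by
    larger mean above-cutoff relatedness, then by input order.  The returned
    index set (ascending) has max pairwise relatedness <= cutoff.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise CohortError("relationship matrix must be square")
    over = a > cutoff
    np.fill_diagonal(over, False)

    alive = np.ones(n, dtype=bool)
    deg = over.sum(axis=1).astype(int)
    while True:
        max_deg = deg[alive].max(initial=0)
        if max_deg == 0:
            break
        cand = np.flatnonzero(alive & (deg == max_deg))
        if len(cand) > 1:
            # mean relatedness over above-cutoff partners, higher first
            means = np.array(
                [a[i, alive & over[i]].mean() for i in cand]
            )
            cand = cand[means == means.max()]
        victim = cand[0]
        alive[victim] = False
        partners = over[victim] & alive
        deg[partners] -= 1
        deg[victim] = 0
        over[victim, :] = False
        over[:, victim] = False
    return np.flatnonzero(alive)


def sample_qc(
    geno: DosageMatrix, sd_mult: float = 3.0, rel_cut: float = 0.125
) -> tuple[DosageMatrix, SampleQCReport]:
    """Heterozygosity outlier removal followed by relatedness pruning.

    Order is heterozygosity first (config-overridable upstream); the GRM for
    relatedness is computed on the heterozygosity-passing subset.
    """
    f = heterozygosity_f(geno)
    het_keep = exclude_het_outliers(f, sd_mult=sd_mult)

    reason = ["" if k else "heterozygosity" for k in het_keep]
    kept = het_keep.copy()

    surv_idx = np.flatnonzero(het_keep)
    if len(surv_idx) >= 2:
        sub = geno.subset_samples(surv_idx)
        a = grm(sub)
        rel_keep_local = rel_cutoff(a, cutoff=rel_cut)
        removed_local = set(range(len(surv_idx))) - set(rel_keep_local.tolist())
        for loc in removed_local:
            gi = surv_idx[loc]
            kept[gi] = False
            reason[gi] = "relatedness"

    report = SampleQCReport(
        samples=list(geno.samples), f_coeff=f, kept=kept, reason=reason
    )
    return geno.subset_samples(kept), report
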