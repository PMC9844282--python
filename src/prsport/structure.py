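"""Population structure: LD r², window-based LD pruning, and principal components."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import DosageMatrix


class StructureError(ValueError):
    pass


def ld_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed on the pairwise-complete (both non-missing) subset.  If either
    vector has zero variance on that subset the value is undefined; 0.0 is
    returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise StructureError("vectors must have the same length")
    ok = ~np.isnan(x) & ~np.isnan(y)
    x, y = x[ok], y[ok]
    if len(x) < 2:
        warnings.warn("fewer than 2 complete pairs; returning r2=0", stacklevel=2)
        return 0.0
    vx = x.var()
    vy = y.var()
    if vx == 0 or vy == 0:
        warnings.warn("zero-variance vector in ld_r2; returning 0", stacklevel=2)
        return 0.0
    cov = ((x - x.mean()) * (y - y.mean())).mean()
    return float(cov * cov / (vx * vy))


def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """All-pairs r² for a (samples x variants) block, NaN mean-imputed."""
    x = dos.copy()
    col_mean = np.nanmean(x, axis=0)
    nan_idx = np.isnan(x)
    if nan_idx.any():
        x[nan_idx] = np.take(col_mean, np.where(nan_idx)[1])
    x = x - x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic -> r2 0 with everything
    z = x / sd
    r = (z.T @ z) / z.shape[0]
    return r * r


def ld_prune(
    geno: DosageMatrix,
    window_kb: float = 250.0,
    step_variants: int = 1,
    r2_max: float = 0.1,
) -> np.ndarray:
    """Greedy position-ordered LD pruning; returns retained variant indices.

    Scanning variants within each chromosome in position order, a variant is
    retained only if its r² with every already-retained variant within
    ``window_kb`` is <= ``r2_max`` — i.e. of any conflicting pair the
    later-positioned member is dropped.  The exact scan guarantees that no
    retained pair within the window span exceeds the threshold, which is the
    post-condition windowed stepping approximates; ``step_variants`` is
    accepted for interface compatibility but does not change the result.
    """
    chroms = geno.variants["chrom"].astype(str).to_numpy()
    pos = geno.variants["pos"].to_numpy(dtype=float)
    window_bp = window_kb * 1000.0

    retained: list[int] = []
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        idx = idx[np.argsort(pos[idx], kind="stable")]
        kept_local: list[int] = []
        for j in idx:
            ok = True
            for k in reversed(kept_local):
                if pos[j] - pos[k] > window_bp:
                    break
                if ld_r2(geno.dosages[:, j], geno.dosages[:, k]) > r2_max:
                    ok = False
                    break
            if ok:
                kept_local.append(j)
        retained.extend(kept_local)
    return np.array(sorted(retained), dtype=int)


@dataclass
class PCScores:
    """Principal-component scores plus per-component variance fractions."""

    samples: list[str]
    scores: np.ndarray  # n_samples x k
    variance_fractions: np.ndarray  # length k, non-increasing

    def to_frame(self) -> pd.DataFrame:
        k = self.scores.shape[1]
        df = pd.DataFrame(self.scores, columns=[f"PC{i+1}" for i in range(k)])
        df.insert(0, "sample", self.samples)
        return df


def pca(geno: DosageMatrix, variant_idx: np.ndarray | None = None, k: int = 6) -> PCScores:
    """Top-k principal components of the standardized dosage matrix.

    Variants are standardized by subtracting 2p and dividing by
    sqrt(2 p (1-p)); missing entries are mean-imputed (zero after centring);
    monomorphic variants are dropped.  Signs are fixed by making the
    largest-magnitude loading of each component positive, so the result is
    deterministic.
    """
    sub = geno if variant_idx is None else geno.subset_variants(variant_idx)
    if sub.n_samples <= k:
        raise StructureError(f"need more than k={k} samples, got {sub.n_samples}")
    p = sub.recompute_freq()
    poly = (p > 0) & (p < 1) & np.isfinite(p)
    x = sub.dosages[:, poly]
    p = p[poly]
    z = (x - 2.0 * p[None, :]) / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    z = np.where(np.isnan(z), 0.0, z)

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(f"requested {k} components but rank is {rank}", stacklevel=2)

    # sign convention: largest-|loading| entry of each component positive
    signs = np.ones(k_eff)
    for c in range(k_eff):
        j = np.argmax(np.abs(vt[c]))
        if vt[c, j] < 0:
            signs[c] = -1.0
    scores = u[:, :k_eff] * s[:k_eff] * signs
    total_var = float((s * s).sum())
    var_frac = (s[:k_eff] ** 2) / total_var if total_var > 0 else np.zeros(k_eff)
    return PCScores(samples=list(sub.samples), scores=scores, variance_fractions=var_frac)
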