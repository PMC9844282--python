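"""Shared test fixtures and construction helpers."""

import numpy as np
import pandas as pd

from prsport.cohort import DosageMatrix

NON_AMBIGUOUS = [("A", "G"), ("A", "C"), ("T", "C"), ("T", "G"),
                 ("G", "A"), ("C", "A"), ("C", "T"), ("G", "T")]


def make_geno(
    dosages,
    chrom="1",
    pos=None,
    counted=None,
    other=None,
    info=None,
    samples=None,
    freq=None,
) -> DosageMatrix:
    """Build a DosageMatrix from a plain array with sensible metadata defaults."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if pos is None:
        pos = np.arange(1, m + 1) * 1000
    if np.isscalar(chrom):
        chrom = [str(chrom)] * m
    if counted is None:
        counted = [NON_AMBIGUOUS[j % len(NON_AMBIGUOUS)][0] for j in range(m)]
        other = [NON_AMBIGUOUS[j % len(NON_AMBIGUOUS)][1] for j in range(m)]
    if info is None:
        info = np.ones(m)
    if samples is None:
        samples = [f"S{i}" for i in range(n)]
    variants = pd.DataFrame(
        {
            "chrom": [str(c) for c in chrom],
            "pos": np.asarray(pos, dtype=int),
            "counted_allele": counted,
            "other_allele": other,
            "info": np.asarray(info, dtype=float),
            "freq": np.nanmean(d, axis=0) / 2.0 if freq is None else np.asarray(freq, float),
        }
    )
    return DosageMatrix(samples=list(samples), variants=variants, dosages=d)


def random_geno(rng, n=50, m=20, maf=(0.1, 0.5), chrom="1", spacing=10_000):
    f = rng.uniform(*maf, size=m)
    d = rng.binomial(2, f, size=(n, m)).astype(float)
    return make_geno(d, chrom=chrom, pos=np.arange(1, m + 1) * spacing)
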