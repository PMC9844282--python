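"""Greedy p-value-ordered LD clumping and per-individual score computation.

Clumping promotes the best remaining p-value to an index variant and assigns
every unassigned candidate within a window radius and in LD above a
threshold to it.  Scores are the weighted sum of counted-allele dosages over
the index variants, reported both as a raw sum and as a per-allele average
(sum / 2M), the latter being the conventional default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DosageMatrix
from .structure import ld_r2
from .sumstats import HarmonizedWeight, SummaryStatRecord


class ClumpError(ValueError):
    pass


@dataclass
class ClumpSet:
    """Index variants surviving clumping, with their clumped members.

    ``indices`` is ordered by ascending p (ties by chrom, pos); ``members``
    maps each index key to a list of (member key, r² with the index).
    """

    indices: list[tuple[tuple[str, int], float]]  # ((chrom, pos), pvalue)
    members: dict[tuple[str, int], list[tuple[tuple[str, int], float]]]
    n_missing_from_panel: int = 0

    def index_keys(self) -> list[tuple[str, int]]:
        return [key for key, _ in self.indices]

    def __len__(self) -> int:
        return len(self.indices)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (chrom, pos), p in self.indices:
            mem = self.members[(chrom, pos)]
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "pvalue": p,
                    "n_members": len(mem),
                    "members": ";".join(f"{c}:{q}:{r2:.4g}" for (c, q), r2 in mem),
                }
            )
        return pd.DataFrame(rows, columns=["chrom", "pos", "pvalue", "n_members", "members"])


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def clump(
    records: list[SummaryStatRecord],
    ld_panel: DosageMatrix,
    p_max: float = 5e-4,
    window_kb: float = 250.0,
    r2: float = 0.1,
) -> ClumpSet:
    """Greedy LD clumping of summary statistics against an LD panel.

    Candidates are records with ``pvalue < p_max`` that are present in the
    panel (absent candidates are dropped with a warning and counted).
    Iterating candidates by ascending p (ties by chrom then pos), each not
    yet assigned candidate becomes an index; all unassigned candidates on
    the same chromosome within +/- ``window_kb`` with r² >= ``r2`` to the
    index become its members.  Membership r² is inclusive (>= threshold).
    """
    panel_idx = {key: j for j, key in enumerate(ld_panel.variant_keys())}

    candidates = [r for r in records if r.pvalue < p_max]
    missing = [r for r in candidates if r.key not in panel_idx]
    if missing:
        warnings.warn(
            f"{len(missing)} candidate variant(s) absent from LD panel; dropped",
            stacklevel=2,
        )
    candidates = [r for r in candidates if r.key in panel_idx]
    order = sorted(
        range(len(candidates)),
        key=lambda i: (
            candidates[i].pvalue,
            _chrom_sort_key(candidates[i].chrom),
            candidates[i].pos,
        ),
    )

    window_bp = window_kb * 1000.0
    assigned = [False] * len(candidates)
    indices: list[tuple[tuple[str, int], float]] = []
    members: dict[tuple[str, int], list[tuple[tuple[str, int], float]]] = {}

    # pre-group candidate positions per chromosome for the window scan
    by_chrom: dict[str, list[int]] = {}
    for i, rec in enumerate(candidates):
        by_chrom.setdefault(rec.chrom, []).append(i)

    for i in order:
        if assigned[i]:
            continue
        rec = candidates[i]
        assigned[i] = True
        indices.append((rec.key, rec.pvalue))
        mem: list[tuple[tuple[str, int], float]] = []
        xi = ld_panel.dosages[:, panel_idx[rec.key]]
        for j in by_chrom[rec.chrom]:
            if assigned[j]:
                continue
            other = candidates[j]
            if abs(other.pos - rec.pos) > window_bp:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rsq = ld_r2(xi, ld_panel.dosages[:, panel_idx[other.key]])
            if rsq >= r2:
                assigned[j] = True
                mem.append((other.key, rsq))
        members[rec.key] = mem

    return ClumpSet(indices=indices, members=members, n_missing_from_panel=len(missing))


@dataclass
class ScoreTable:
    """Per-individual polygenic scores."""

    samples: list[str]
    score_avg: np.ndarray
    score_sum: np.ndarray
    n_variants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample": self.samples,
                "score_avg": self.score_avg,
                "score_sum": self.score_sum,
                "n_variants": self.n_variants,
            }
        )


def compute_prs(
    geno: DosageMatrix,
    weights: list[HarmonizedWeight],
    mode: str = "average",
    missing: str = "mean",
) -> ScoreTable:
    """Weighted allele score over the overlap of ``weights`` with ``geno``.

    raw_i = sum_j w_j * d_ij with missing dosages handled by frequency
    mean-imputation (``missing='mean'``, the referenced-tool default) or by
    omitting the site and rescaling the per-sample denominator
    (``missing='omit'``).  ``score_sum`` is the raw weighted sum and
    ``score_avg`` the per-allele average raw / (2 M).
    """
    if mode not in ("average", "sum"):
        raise ClumpError(f"mode must be 'average' or 'sum', got {mode!r}")
    if missing not in ("mean", "omit"):
        raise ClumpError(f"missing must be 'mean' or 'omit', got {missing!r}")

    panel_idx = {key: j for j, key in enumerate(geno.variant_keys())}
    cols: list[int] = []
    w: list[float] = []
    for hw in weights:
        j = panel_idx.get((hw.chrom, hw.pos))
        if j is None:
            continue
        cols.append(j)
        w.append(hw.weight)
    m = len(cols)
    if m == 0:
        raise ClumpError("no weight variants overlap the genotype matrix")

    d = geno.dosages[:, cols]
    wv = np.array(w, dtype=float)
    nan = np.isnan(d)
    if missing == "mean":
        freq = geno.variants["freq"].to_numpy(dtype=float)[cols]
        d = np.where(nan, 2.0 * freq[None, :], d)
        raw = d @ wv
        denom = np.full(geno.n_samples, 2.0 * m)
    else:
        d = np.where(nan, 0.0, d)
        raw = d @ wv
        denom = 2.0 * (m - nan.sum(axis=1)).astype(float)
        denom[denom == 0] = np.nan
    return ScoreTable(
        samples=list(geno.samples),
        score_avg=raw / denom,
        score_sum=raw,
        n_variants=m,
    )
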