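"""LD pruning and principal components for stratification adjustment."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

DEFAULT_R2_MAX = 0.2
DEFAULT_WINDOW_SNPS = 50
DEFAULT_STEP_SNPS = 5
DEFAULT_N_PCS = 10


@dataclass
class PCResult:
    scores: np.ndarray             # (n_samples, k)
    explained_variance_ratio: np.ndarray
    retained_snps: np.ndarray      # global SNP indices used


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between genotype columns, pairwise-complete."""
    df = pd.DataFrame(np.where(g == MISSING, np.nan, g.astype(float)))
    r = df.corr(min_periods=2).to_numpy()
    return np.nan_to_num(r, nan=0.0) ** 2


def ld_prune(gm: GenotypeMatrix, r2_max: float = DEFAULT_R2_MAX,
             window_snps: int = DEFAULT_WINDOW_SNPS,
             step_snps: int = DEFAULT_STEP_SNPS) -> np.ndarray:
    """Greedy windowed LD pruning on genotype codes; returns retained indices.

    Within each sliding block, while any retained pair exceeds r2_max the
    later-indexed SNP of the worst pair is removed. Blocks slide by
    step_snps within each chromosome.
    """
    keep = np.ones(gm.n_snps, dtype=bool)
    for c in gm.chromosomes():
        idx = np.flatnonzero(gm.chrom == c)
        start = 0
        while start < len(idx):
            block = idx[start:start + window_snps]
            live = [i for i in block if keep[i]]
            if len(live) >= 2:
                r2 = _pairwise_r2(gm.genotypes[:, live])
                np.fill_diagonal(r2, 0.0)
                while True:
                    i, j = np.unravel_index(np.argmax(r2), r2.shape)
                    if r2[i, j] <= r2_max:
                        break
                    drop = max(i, j)  # later-indexed SNP of the worst pair
                    keep[live[drop]] = False
                    r2[drop, :] = 0.0
                    r2[:, drop] = 0.0
            if start + window_snps >= len(idx):
                break
            start += step_snps
    return np.flatnonzero(keep)


def compute_pcs(gm: GenotypeMatrix, snp_indices: np.ndarray,
                k: int = DEFAULT_N_PCS) -> PCResult:
    """PCA on standardized genotype columns restricted to the pruned set.

    Columns are centered at twice the allele frequency and scaled by the
    binomial SD sqrt(2p(1-p)); missing entries become 0 after centering.
    Scores are the projections onto the top-k right singular vectors.
    """
    snp_indices = np.asarray(snp_indices)
    if snp_indices.size == 0:
        raise ValueError("pruned SNP set is empty")
    g = gm.genotypes[:, snp_indices].astype(float)
    g[g == MISSING] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    sd = np.sqrt(2.0 * p * (1.0 - p))
    informative = sd > 0
    z = (g - 2.0 * p) / np.where(informative, sd, 1.0)
    z[:, ~informative] = 0.0
    z = np.nan_to_num(z, nan=0.0)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(f"requested {k} PCs but rank is {rank}; returning {rank}")
        k = rank
    scores = u[:, :k] * s[:k]
    var = s ** 2
    evr = var[:k] / var.sum() if var.sum() > 0 else np.zeros(k)
    return PCResult(scores=scores, explained_variance_ratio=evr,
                    retained_snps=snp_indices)
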