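"""Homozygosity-intensity profiles via double-weight local polynomial smoothing.

For every SNP a nearest-neighbor sliding window (5% of the chromosome's SNPs
by default) is anchored at that SNP. Within a window, per-sample homozygosity
indicators are smoothed by weighted local polynomial regression where each
member SNP carries a tricube kernel weight in scaled distance from the anchor
times a minor-allele-frequency locus weight. The fitted value at the anchor,
clipped to [0,1], is the window's homozygosity intensity. Regions where the
intensity stays >= 0.9 over >= 5 Mb are reported as runs of homozygosity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

DEFAULT_WINDOW_FRACTION = 0.05
DEFAULT_MAF_THRESHOLD = 0.05
DEFAULT_MIN_INTENSITY = 0.9
DEFAULT_MIN_LENGTH_BP = 5_000_000


@dataclass
class WindowSet:
    """One window per anchor SNP; members are its k nearest neighbors."""

    anchor: np.ndarray             # (n_windows,) global SNP index of the anchor
    members: list[np.ndarray]      # per window, sorted global SNP indices
    chrom: np.ndarray              # (n_windows,) chromosome of the anchor
    anchor_pos: np.ndarray         # (n_windows,) int64
    k_per_chrom: dict              # chromosome -> k_j

    @property
    def n_windows(self) -> int:
        return len(self.anchor)


@dataclass
class IntensityProfile:
    """Individuals x windows homozygosity intensities in [0,1] (NaN = untestable)."""

    intensity: np.ndarray          # (n_samples, n_windows)
    windows: WindowSet
    samples: list[str]
    maf: np.ndarray                # per-SNP MAF used for locus weights


@dataclass
class HDRegion:
    sample: str
    chrom: object
    start: int                     # 1-based inclusive
    end: int
    mean_intensity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def window_size(n_snps: int, fraction: float = DEFAULT_WINDOW_FRACTION) -> int:
    """k_j = max(2, round(fraction * n_j)), capped at n_j."""
    return min(max(2, int(round(fraction * n_snps))), n_snps)


def build_windows(chrom: np.ndarray, pos: np.ndarray,
                  fraction: float = DEFAULT_WINDOW_FRACTION) -> WindowSet:
    """Anchor one window at every SNP; members = k nearest SNPs by |pos diff|.

    Ties in distance are broken toward the lower SNP index. Positions must be
    strictly increasing within each chromosome.
    """
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    anchors, members, wchrom, apos = [], [], [], []
    k_per_chrom: dict = {}
    seen: dict = {}
    for c in chrom:
        seen.setdefault(c, None)
    for c in seen:
        idx = np.flatnonzero(chrom == c)
        n_j = len(idx)
        if n_j < 2:
            raise ValueError(f"chromosome {c!r} has fewer than 2 SNPs")
        p = pos[idx]
        if np.any(np.diff(p) <= 0):
            raise ValueError(f"positions not sorted on chromosome {c!r}")
        k = window_size(n_j, fraction)
        k_per_chrom[c] = k
        for a in range(n_j):
            lo = hi = a  # inclusive bounds of the selected run
            for _ in range(k - 1):
                d_lo = p[a] - p[lo - 1] if lo > 0 else None
                d_hi = p[hi + 1] - p[a] if hi + 1 < n_j else None
                if d_hi is None or (d_lo is not None and d_lo <= d_hi):
                    lo -= 1  # tie goes to the lower index
                else:
                    hi += 1
            anchors.append(idx[a])
            members.append(idx[lo:hi + 1])
            wchrom.append(c)
            apos.append(p[a])
    return WindowSet(
        anchor=np.array(anchors, dtype=np.int64),
        members=members,
        chrom=np.array(wchrom, dtype=object),
        anchor_pos=np.array(apos, dtype=np.int64),
        k_per_chrom=k_per_chrom,
    )


def homozygosity_indicator(genotypes: np.ndarray) -> np.ndarray:
    """1 for homozygotes (codes 0/2), 0 for heterozygotes, NaN for missing."""
    g = np.asarray(genotypes)
    x = np.where(g == 1, 0.0, 1.0)
    x[g == MISSING] = np.nan
    return x


def locus_weights(maf: np.ndarray, threshold: float = DEFAULT_MAF_THRESHOLD) -> np.ndarray:
    """Capped linear ramp v = min(maf/threshold, 1); rare SNPs are down-weighted."""
    maf = np.asarray(maf, dtype=float)
    valid = ~np.isnan(maf)
    if np.any((maf[valid] < 0) | (maf[valid] > 0.5)):
        raise ValueError("MAF outside [0, 0.5]")
    v = np.minimum(maf / threshold, 1.0)
    return np.where(valid, v, 0.0)


def tricube(u: np.ndarray) -> np.ndarray:
    """Tricube kernel (1 - |u|^3)^3 on |u| <= 1, else 0."""
    au = np.abs(u)
    return np.where(au <= 1.0, (1.0 - au ** 3) ** 3, 0.0)


def estimate_intensity(indicators: np.ndarray, windows: WindowSet,
                       pos: np.ndarray, weights: np.ndarray,
                       degree: int = 1) -> np.ndarray:
    """Fit the double-weight local polynomial per sample and window.

    For window w with anchor position p0, scaled distances are
    u_i = (pos_i - p0)/h with bandwidth h = max |pos_i - p0| (>= 1), so
    every member has |u| <= 1. Combined weight = tricube(u) * locus weight;
    missing indicators get weight 0. The intensity is the weighted
    polynomial fit evaluated at u = 0, clipped to [0,1]; rank-deficient
    designs fall back to the weighted mean (degree 0). Returns an
    (n_samples, n_windows) array with NaN where no member is usable.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    x = np.asarray(indicators, dtype=float)
    n_samples = x.shape[0]
    out = np.full((n_samples, windows.n_windows), np.nan)
    for w in range(windows.n_windows):
        mem = windows.members[w]
        p0 = windows.anchor_pos[w]
        d = pos[mem].astype(float) - p0
        h = max(np.abs(d).max(), 1.0)
        u = d / h
        base_w = tricube(u) * weights[mem]
        xw = x[:, mem]                       # (S, m)
        ok = ~np.isnan(xw)
        W = np.where(ok, base_w[None, :], 0.0)
        sw = W.sum(axis=1)
        xf = np.where(ok, xw, 0.0)
        mean_num = (W * xf).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            wmean = mean_num / sw
        if degree == 0:
            est = wmean
        else:
            X = np.vander(u, degree + 1, increasing=True)  # (m, p)
            A = np.einsum("sm,mi,mj->sij", W, X, X)
            b = np.einsum("sm,mi->si", W * xf, X)
            est = np.array(wmean)
            # a design is usable at this degree only if it is well-conditioned
            detA = np.linalg.det(A)
            scale = np.einsum("sii->s", A) ** (degree + 1)
            solvable = (sw > 0) & (np.abs(detA) > 1e-12 * np.maximum(scale, 1e-300))
            if solvable.any():
                beta = np.linalg.solve(A[solvable], b[solvable][..., None])
                est[solvable] = beta[:, 0, 0]   # fitted value at u = 0
        est = np.clip(est, 0.0, 1.0)
        est[sw <= 0] = np.nan
        out[:, w] = est
    return out


def profile_genotypes(gm: GenotypeMatrix,
                      fraction: float = DEFAULT_WINDOW_FRACTION,
                      maf_threshold: float = DEFAULT_MAF_THRESHOLD,
                      degree: int = 1) -> IntensityProfile:
    """Full pipeline: windows -> indicators -> locus weights -> intensities."""
    windows = build_windows(gm.chrom, gm.pos, fraction)
    indicators = homozygosity_indicator(gm.genotypes)
    maf = gm.maf()
    v = locus_weights(maf, maf_threshold)
    H = estimate_intensity(indicators, windows, gm.pos, v, degree=degree)
    return IntensityProfile(intensity=H, windows=windows, samples=list(gm.samples), maf=maf)


def extract_hd_regions(profile: IntensityProfile,
                       min_intensity: float = DEFAULT_MIN_INTENSITY,
                       min_length_bp: int = DEFAULT_MIN_LENGTH_BP) -> list[HDRegion]:
    """Merge maximal runs of consecutive windows with H >= min_intensity.

    Region span = first to last anchor position of the run (1-based
    inclusive); runs shorter than min_length_bp are discarded. NaN intensity
    breaks a run.
    """
    regions: list[HDRegion] = []
    W = profile.windows
    order_chrom = list(W.k_per_chrom)
    for s, sample in enumerate(profile.samples):
        hrow = profile.intensity[s]
        for c in order_chrom:
            widx = np.flatnonzero(W.chrom == c)
            qual = hrow[widx] >= min_intensity  # NaN compares False
            start = None
            for i in range(len(widx) + 1):
                if i < len(widx) and qual[i]:
                    if start is None:
                        start = i
                elif start is not None:
                    run = widx[start:i]
                    lo = int(W.anchor_pos[run[0]])
                    hi = int(W.anchor_pos[run[-1]])
                    if hi - lo + 1 >= min_length_bp:
                        regions.append(HDRegion(
                            sample=sample, chrom=c, start=lo, end=hi,
                            mean_intensity=float(np.mean(hrow[run])),
                        ))
                    start = None
    return regions


def summarize_hd(regions: list[HDRegion]) -> pd.DataFrame:
    """Five-number summaries of region lengths and per-sample total lengths.

    Quartiles use linear interpolation between order statistics (numpy's
    default rule). Returns an empty frame for empty input.
    """
    cols = ["statistic", "region_length_bp", "total_length_bp"]
    if not regions:
        return pd.DataFrame(columns=cols)
    lengths = np.array([r.length for r in regions], dtype=float)
    totals = pd.Series([r.length for r in regions]).groupby(
        pd.Series([r.sample for r in regions])).sum().to_numpy(dtype=float)
    q = [0.0, 0.25, 0.5, 0.75, 1.0]
    names = ["min", "q1", "median", "q3", "max"]
    return pd.DataFrame({
        "statistic": names,
        "region_length_bp": np.quantile(lengths, q),
        "total_length_bp": np.quantile(totals, q),
    })
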