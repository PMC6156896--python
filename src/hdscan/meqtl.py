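"""cis/trans methylation-QTL scans: GEE of per-CpG methylation response on a
window's homozygosity intensity, sharing the association module's GEE core."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import DEFAULT_ALPHA, gee_window_test
from .io_formats import MethylationSet

DEFAULT_CIS_MARGIN_BP = 1_000_000


@dataclass
class MeqtlResult:
    table: pd.DataFrame            # per (window, CpG) rows with scope
    n_trans_tested: int
    alpha: float = DEFAULT_ALPHA

    @property
    def trans_threshold(self) -> float:
        return self.alpha / max(self.n_trans_tested, 1)

    @property
    def significant_trans(self) -> pd.DataFrame:
        t = self.table
        return t[(t["scope"] == "trans") & (t["pvalue"] < self.trans_threshold)]


def define_cis_set(meth: MethylationSet, region: tuple,
                   margin_bp: int = 0) -> np.ndarray:
    """Boolean cis mask: CpGs inside region (chrom, start, end) +/- margin."""
    if meth.n_cpg == 0:
        raise ValueError("empty CpG annotation")
    chrom, start, end = region
    return ((meth.chrom == chrom)
            & (meth.pos >= start - margin_bp)
            & (meth.pos <= end + margin_bp))


def meqtl_test(h_w: np.ndarray, m_response: np.ndarray,
               covariates: pd.DataFrame | None, clusters: np.ndarray):
    """Single-CpG GEE test; same contract as association.gee_window_test."""
    return gee_window_test(h_w, m_response, covariates, clusters)


def scan_window(h_w: np.ndarray, meth: MethylationSet, m_response: np.ndarray,
                covariates: pd.DataFrame | None, clusters: np.ndarray,
                region: tuple, margin_bp: int = DEFAULT_CIS_MARGIN_BP,
                alpha: float = DEFAULT_ALPHA,
                cpg_mask: np.ndarray | None = None,
                cis_mask: np.ndarray | None = None) -> MeqtlResult:
    """cis and trans scans of one window against every (masked) CpG.

    ``region`` is the window's cis territory; CpGs outside it are trans and
    receive a Bonferroni threshold alpha / (number of trans CpGs tested).
    A precomputed ``cis_mask`` (e.g. from gene spans in a BED file)
    overrides the region rule.
    """
    cis = cis_mask if cis_mask is not None else define_cis_set(meth, region, margin_bp)
    if cpg_mask is None:
        cpg_mask = np.ones(meth.n_cpg, dtype=bool)
    rows = []
    n_trans = 0
    for i in np.flatnonzero(cpg_mask):
        scope = "cis" if cis[i] else "trans"
        res = meqtl_test(h_w, m_response[i], covariates, clusters)
        if scope == "trans" and res.status == "ok":
            n_trans += 1
        rows.append({
            "cpg": meth.cpg_ids[i], "chrom": meth.chrom[i], "pos": int(meth.pos[i]),
            "scope": scope, "estimate": res.estimate, "se": res.se,
            "pvalue": res.pvalue, "n_used": res.n_used, "status": res.status,
        })
    return MeqtlResult(table=pd.DataFrame(rows), n_trans_tested=n_trans, alpha=alpha)
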