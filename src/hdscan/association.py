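"""Genome-wide GEE homozygosity association scan with eigenvalue-based
effective-number-of-tests correction.

Each window's homozygosity intensity is regressed on the triglyceride
response under a Gaussian GEE with exchangeable working correlation within
pedigree and a cluster-robust sandwich covariance. Multiplicity is handled
per chromosome: the effective number of independent tests is
n_e = n - sum_{lambda>1}(lambda - 1) over the eigenvalues of the correlation
matrix of window intensities, and the genome-wide threshold is
alpha / sum_j n_e,j.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.genmod.cov_struct import Exchangeable, Independence

from .homozygosity import IntensityProfile
from .io_formats import PhenotypeTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.05

#: covariates entering every model, beyond the metabolic index and PCs
BASE_COVARIATES = ("sex", "age", "smoking")


def tg_response(phenotypes: PhenotypeTable, policy: str = "available") -> pd.Series:
    """TG response = mean(post visits 3,4) - mean(pre visits 1,2), mg/dL.

    Under policy 'available' each side averages whatever visits are present
    and the response is missing only when a whole side is empty; under
    'complete' all four visits are required.
    """
    t = phenotypes.table
    pre = t[["tg1", "tg2"]].mean(axis=1, skipna=(policy == "available"))
    post = t[["tg3", "tg4"]].mean(axis=1, skipna=(policy == "available"))
    if policy not in ("available", "complete"):
        raise ValueError(f"unknown missing-visit policy {policy!r}")
    resp = post - pre
    resp.index = t["sample"].astype(str)
    return resp


@dataclass
class WindowTestResult:
    estimate: float
    se: float
    zvalue: float
    pvalue: float
    n_used: int
    status: str = "ok"             # ok | constant | failed


@dataclass
class ScanResult:
    table: pd.DataFrame            # per-window results
    per_chrom: pd.DataFrame        # chromosome, n_windows, n_used, n_effective
    eigenvalues: dict = field(default_factory=dict)  # chrom -> lambda array
    n_e_total: float = np.nan
    alpha: float = DEFAULT_ALPHA

    @property
    def threshold(self) -> float:
        return significance_threshold(self.alpha, self.n_e_total)

    @property
    def significant(self) -> pd.DataFrame:
        if not self.n_e_total >= 1:     # no usable multiplicity estimate
            return self.table.iloc[0:0]
        return self.table[self.table["pvalue"] < self.threshold]


def build_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Expand categorical covariates (field center) into dummy columns."""
    df = covariates.copy()
    if "center" in df.columns:
        dummies = pd.get_dummies(df.pop("center").astype(str), prefix="center",
                                 drop_first=True, dtype=float)
        df = pd.concat([df, dummies], axis=1)
    return df.astype(float)


def gee_window_test(h_w: np.ndarray, response: np.ndarray,
                    covariates: pd.DataFrame | None,
                    clusters: np.ndarray) -> WindowTestResult:
    """Gaussian GEE of the response on one window's intensity plus covariates.

    Exchangeable working correlation within cluster (independence when all
    clusters are singletons, where the two coincide), robust sandwich SEs,
    two-sided Wald p for the intensity coefficient. The Wald statistic is
    referred to a t distribution with (n_clusters - n_params) df, a standard
    small-sample guard that leaves estimates and SEs untouched and converges
    to the normal reference as clusters grow. Samples missing any model
    variable are dropped listwise.
    """
    h_w = np.asarray(h_w, dtype=float)
    response = np.asarray(response, dtype=float)
    n = len(h_w)
    X = pd.DataFrame({"const": np.ones(n), "intensity": h_w})
    if covariates is not None and covariates.shape[1] > 0:
        design = build_design(covariates.reset_index(drop=True))
        X = pd.concat([X, design], axis=1)
    ok = np.isfinite(response) & np.isfinite(X.to_numpy(float)).all(axis=1)
    Xc, yc, gc = X[ok], response[ok], np.asarray(clusters, dtype=object)[ok]
    n_used = int(ok.sum())
    if n_used < Xc.shape[1] + 1 or len(np.unique(gc)) < 2:
        return WindowTestResult(np.nan, np.nan, np.nan, np.nan, n_used, "failed")
    hv = Xc["intensity"].to_numpy()
    if np.ptp(hv) == 0:            # exactly constant among analyzed samples
        return WindowTestResult(np.nan, np.nan, np.nan, np.nan, n_used, "constant")
    sizes = pd.Series(range(len(gc))).groupby(pd.Series(gc)).size()
    cov_struct = Independence() if sizes.max() == 1 else Exchangeable()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.GEE(yc, Xc, groups=gc, family=sm.families.Gaussian(),
                           cov_struct=cov_struct)
            fit = model.fit()
            if not np.all(np.isfinite(fit.params)):
                # degenerate residuals (e.g. perfect fit) break the
                # exchangeable moment estimator; independence still works
                fit = sm.GEE(yc, Xc, groups=gc, family=sm.families.Gaussian(),
                             cov_struct=Independence()).fit()
        j = list(Xc.columns).index("intensity")
        z = float(fit.tvalues.iloc[j])
        df = max(len(np.unique(gc)) - Xc.shape[1], 1)
        pvalue = float(2.0 * stats.t.sf(abs(z), df))
        return WindowTestResult(
            estimate=float(fit.params.iloc[j]), se=float(fit.bse.iloc[j]),
            zvalue=z, pvalue=pvalue, n_used=n_used,
        )
    except (np.linalg.LinAlgError, ValueError) as exc:
        logger.warning("GEE failed: %s", exc)
        return WindowTestResult(np.nan, np.nan, np.nan, np.nan, n_used, "failed")


def effective_tests(intensity: np.ndarray) -> tuple[float, np.ndarray]:
    """Effective number of independent tests for one chromosome's windows.

    Eigenvalues come from the Pearson correlation matrix of window intensity
    columns over complete-case rows; zero-variance windows are excluded.
    n_e = n - sum_i I[lambda_i > 1] (lambda_i - 1); negative round-off
    eigenvalues are clipped at 0.
    """
    H = np.asarray(intensity, dtype=float)
    rows = np.isfinite(H).all(axis=1)
    Hc = H[rows]
    if Hc.shape[0] < 2:
        raise ValueError("fewer than 2 complete-case individuals")
    usable = np.ptp(Hc, axis=0) > 0
    n_excluded = int((~usable).sum())
    if n_excluded:
        logger.info("effective_tests: excluded %d zero-variance windows", n_excluded)
    Hc = Hc[:, usable]
    n = Hc.shape[1]
    if n < 2:
        raise ValueError("fewer than 2 usable windows")
    corr = np.corrcoef(Hc, rowvar=False)
    lam = np.clip(np.linalg.eigvalsh(corr), 0.0, None)
    n_e = float(n - np.sum((lam - 1.0)[lam > 1.0]))
    return n_e, lam


def significance_threshold(alpha: float, n_e_total: float) -> float:
    """Bonferroni threshold alpha / (total effective number of tests)."""
    if not n_e_total >= 1:
        raise ValueError("total effective number of tests must be >= 1")
    return alpha / n_e_total


def genome_scan(profile: IntensityProfile, response: np.ndarray,
                covariates: pd.DataFrame | None, clusters: np.ndarray,
                alpha: float = DEFAULT_ALPHA) -> ScanResult:
    """Run gee_window_test over every window and attach multiplicity quantities."""
    W = profile.windows
    rows = []
    for w in range(W.n_windows):
        res = gee_window_test(profile.intensity[:, w], response, covariates, clusters)
        rows.append({
            "window": w, "chrom": W.chrom[w], "anchor_pos": int(W.anchor_pos[w]),
            "anchor_snp": int(W.anchor[w]), "estimate": res.estimate,
            "se": res.se, "zvalue": res.zvalue, "pvalue": res.pvalue,
            "n_used": res.n_used, "status": res.status,
        })
    table = pd.DataFrame(rows)
    if (table["status"] != "ok").all():
        logger.warning("genome_scan: no testable windows")
    chrom_rows, eigs = [], {}
    for c in W.k_per_chrom:
        widx = np.flatnonzero(W.chrom == c)
        try:
            n_e, lam = effective_tests(profile.intensity[:, widx])
        except ValueError:
            n_e, lam = np.nan, np.array([])
        eigs[c] = lam
        chrom_rows.append({"chrom": c, "n_windows": len(widx),
                           "n_in_corr": len(lam), "n_effective": n_e})
    per_chrom = pd.DataFrame(chrom_rows)
    n_e_total = float(per_chrom["n_effective"].sum())
    return ScanResult(table=table, per_chrom=per_chrom, eigenvalues=eigs,
                      n_e_total=n_e_total, alpha=alpha)


def manhattan_table(scan: ScanResult) -> pd.DataFrame:
    """Plot-ready table sorted by (chromosome, anchor position)."""
    t = scan.table.copy()
    with np.errstate(divide="ignore"):
        t["neglog10p"] = -np.log10(t["pvalue"])
    return t.sort_values(["chrom", "anchor_pos"], kind="stable").reset_index(drop=True)


def manhattan_figure(scan: ScanResult, path: str) -> None:
    """Manhattan plot with the genome-wide threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = manhattan_table(scan)
    fig, ax = plt.subplots(figsize=(10, 4))
    offset, ticks = 0, {}
    for i, (c, sub) in enumerate(t.groupby("chrom", sort=False)):
        x = sub["anchor_pos"].to_numpy() + offset
        ax.scatter(x, sub["neglog10p"], s=6,
                   color="steelblue" if i % 2 == 0 else "darkorange")
        ticks[c] = x.mean()
        offset = x.max() + 1
    if np.isfinite(scan.n_e_total) and scan.n_e_total >= 1:
        ax.axhline(-np.log10(scan.threshold), color="red", ls="--", lw=1)
    ax.set_xticks(list(ticks.values()), [str(c) for c in ticks])
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
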