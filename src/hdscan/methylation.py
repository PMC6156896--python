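"""Probe-type normalization and M-value machinery for 450K-style beta values.

Type-II probes have a compressed dynamic range relative to type I. Per
sample, a 3-state beta mixture (unmethylated / hemimethylated / methylated)
is fitted to each probe type by EM with exact beta M-steps; type-II values
in the outer states are quantile-mapped onto the corresponding type-I
components, and the middle state is carried across by a monotone affine map
between the transformed boundaries. Type-I values pass through unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

from .io_formats import BETA_EPS, MethylationSet

logger = logging.getLogger(__name__)

EM_TOL = 1e-6
EM_MAX_ITER = 500
MIN_COMPONENT_WEIGHT = 1e-4
#: adjacent fitted components closer than this in mean are one real state
MIN_STATE_SEPARATION = 0.15


def beta_to_m(beta: np.ndarray) -> np.ndarray:
    """M = log2(beta / (1 - beta)); beta must be strictly inside (0,1)."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta values must lie strictly in (0,1); clamp first")
    return np.log2(beta / (1.0 - beta))


def m_to_beta(m: np.ndarray) -> np.ndarray:
    p = np.exp2(np.asarray(m, dtype=float))
    return p / (1.0 + p)


@dataclass
class BetaMixture:
    """Fitted beta mixture, components ordered by ascending mean."""

    shapes: np.ndarray             # (k, 2) (a, b) per component
    weights: np.ndarray            # (k,)
    loglik_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    refit_reduced: bool = False    # set when a degenerate/overlapping state forced a refit

    @property
    def n_states(self) -> int:
        return len(self.weights)

    def means(self) -> np.ndarray:
        return self.shapes[:, 0] / self.shapes.sum(axis=1)

    def responsibilities(self, x: np.ndarray) -> np.ndarray:
        logp = np.stack([
            np.log(w) + stats.beta.logpdf(x, a, b)
            for (a, b), w in zip(self.shapes, self.weights)
        ], axis=1)
        logp -= special.logsumexp(logp, axis=1, keepdims=True)
        return np.exp(logp)

    def loglik(self, x: np.ndarray) -> float:
        logp = np.stack([
            np.log(w) + stats.beta.logpdf(x, a, b)
            for (a, b), w in zip(self.shapes, self.weights)
        ], axis=1)
        return float(special.logsumexp(logp, axis=1).sum())


def _beta_mle(s_logx: float, s_log1mx: float, init: tuple[float, float]) -> tuple[float, float]:
    """Solve the beta MLE score equations given mean sufficient statistics."""

    def score(logab):
        a, b = np.exp(logab)
        dig = special.digamma(a + b)
        return [special.digamma(a) - dig - s_logx,
                special.digamma(b) - dig - s_log1mx]

    x0 = np.log(np.clip(init, 1e-3, 1e6))
    sol, info, ier, _ = optimize.fsolve(score, x0, full_output=True)
    if ier != 1 or not np.all(np.isfinite(sol)):
        return tuple(np.clip(init, 1e-3, 1e6))  # keep previous estimate
    a, b = np.exp(sol)
    return float(np.clip(a, 1e-3, 1e6)), float(np.clip(b, 1e-3, 1e6))


def _moment_shapes(x: np.ndarray, w: np.ndarray | None = None) -> tuple[float, float]:
    if w is None:
        w = np.ones_like(x)
    sw = w.sum()
    m = float((w * x).sum() / sw)
    v = float((w * (x - m) ** 2).sum() / sw)
    v = max(v, 1e-6)
    common = max(m * (1 - m) / v - 1.0, 1e-2)
    return max(m * common, 1e-3), max((1 - m) * common, 1e-3)


def _initial_blocks(x: np.ndarray, n_states: int) -> list[list[np.ndarray]]:
    """Two deterministic starting partitions: equal-count and value-range."""
    xs = np.sort(x)
    inits = [np.array_split(xs, n_states)]
    cuts = np.linspace(xs[0], xs[-1], n_states + 1)
    by_value = [xs[(xs >= cuts[k]) & (xs < cuts[k + 1])] for k in range(n_states)]
    by_value[-1] = xs[xs >= cuts[-2]]
    if all(len(b) >= 2 for b in by_value):
        inits.append(by_value)
    return inits


def _run_em(x: np.ndarray, blocks: list[np.ndarray],
            fixed_weights: np.ndarray | None = None) -> BetaMixture | None:
    """One EM run from a block partition; None when a component degenerates.

    With ``fixed_weights`` the mixing proportions are held constant and only
    the shape parameters are updated (still a monotone EM).
    """
    n_states = len(blocks)
    mix = BetaMixture(
        shapes=np.array([_moment_shapes(b) for b in blocks]),
        weights=(np.asarray(fixed_weights, dtype=float) if fixed_weights is not None
                 else np.array([len(b) for b in blocks], dtype=float) / len(x)),
    )
    logx, log1mx = np.log(x), np.log1p(-x)
    prev_ll = -np.inf
    for it in range(1, EM_MAX_ITER + 1):
        with np.errstate(divide="ignore"):
            r = mix.responsibilities(x)
        nk = r.sum(axis=0)
        if np.any(nk / len(x) < MIN_COMPONENT_WEIGHT):
            if n_states > 1 and fixed_weights is None:
                return None
            nk = np.maximum(nk, MIN_COMPONENT_WEIGHT * len(x))
        new_shapes = []
        for k in range(n_states):
            wk = r[:, k]
            s1 = float((wk * logx).sum() / nk[k])
            s2 = float((wk * log1mx).sum() / nk[k])
            new_shapes.append(_beta_mle(s1, s2, _moment_shapes(x, wk)))
        mix.shapes = np.array(new_shapes)
        if fixed_weights is None:
            mix.weights = nk / nk.sum()
        ll = mix.loglik(x)
        mix.loglik_trace.append(ll)
        mix.n_iter = it
        if ll - prev_ll < EM_TOL and it > 1:
            mix.converged = True
            break
        prev_ll = ll
    return mix


def fit_beta_mixture(x: np.ndarray, n_states: int = 3) -> BetaMixture:
    """EM fit of an n-state beta mixture, deterministic and label-ordered.

    Two deterministic initializations (equal-count blocks and value-range
    blocks) are run to convergence and the higher final log-likelihood wins;
    the M-step solves the exact weighted beta MLE so each run's
    log-likelihood is non-decreasing. Components are labeled by ascending
    mean. A degenerate (weight < 1e-4) or non-separated (adjacent means
    closer than 0.15) solution triggers a flagged refit with one state
    fewer; single-state data therefore collapses to one dominant component.
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    x = np.clip(x, BETA_EPS, 1 - BETA_EPS)
    if len(x) < 100:
        raise ValueError("need at least 100 beta values to fit a mixture")

    candidates = [m for m in (_run_em(x, blocks)
                              for blocks in _initial_blocks(x, n_states))
                  if m is not None]
    if not candidates:
        logger.warning("degenerate component; refitting with %d states",
                       n_states - 1)
        sub = fit_beta_mixture(x, n_states - 1)
        sub.refit_reduced = True
        return sub
    mix = max(candidates, key=lambda m: m.loglik_trace[-1])
    order = np.argsort(mix.means())
    mix.shapes = mix.shapes[order]
    mix.weights = mix.weights[order]
    means = mix.means()
    if mix.n_states > 1 and np.min(np.diff(means)) < MIN_STATE_SEPARATION:
        # overlapping components are one real state fitted twice
        logger.warning("components overlap (means %s); refitting with %d states",
                       np.round(means, 3), n_states - 1)
        sub = fit_beta_mixture(x, n_states - 1)
        sub.refit_reduced = True
        return sub
    return mix


def _state_boundaries(mix: BetaMixture, grid_size: int = 4001) -> np.ndarray:
    """Thresholds where the max-posterior state changes, scanned on a grid.

    Returns n_states - 1 cutpoints making the state assignment contiguous
    and the downstream normalization map monotone.
    """
    grid = np.linspace(BETA_EPS, 1 - BETA_EPS, grid_size)
    r = mix.responsibilities(grid)
    assign = np.argmax(r, axis=1)
    # enforce monotone state labels along the grid
    assign = np.maximum.accumulate(assign)
    cuts = []
    for k in range(mix.n_states - 1):
        above = np.flatnonzero(assign > k)
        cuts.append(grid[above[0]] if len(above) else 1.0 - BETA_EPS)
    return np.array(cuts)


def _component_map(x, shapes_from, shapes_to):
    """Probability integral transform through one fitted component pair."""
    q = stats.beta.cdf(x, *shapes_from)
    q = np.clip(q, 1e-12, 1 - 1e-12)
    return stats.beta.ppf(q, *shapes_to)


def _fit_anchored(x: np.ndarray, reference: BetaMixture) -> BetaMixture:
    """Fit a mixture with state proportions pinned to a reference fit.

    Both probe types interrogate the same genome, so their state proportions
    must agree; pinning the weights rules out the catch-all local optimum
    where one broad component swallows its neighbours.
    """
    x = np.clip(np.asarray(x, dtype=float), BETA_EPS, 1 - BETA_EPS)
    if len(x) < 100:
        raise ValueError("need at least 100 beta values to fit a mixture")
    xs = np.sort(x)
    cut_idx = (np.cumsum(reference.weights)[:-1] * len(xs)).astype(int)
    blocks = np.split(xs, cut_idx)
    if any(len(b) < 2 for b in blocks):
        raise ValueError("reference weights leave an empty block")
    mix = _run_em(x, blocks, fixed_weights=reference.weights)
    order = np.argsort(mix.means())
    mix.shapes = mix.shapes[order]
    mix.weights = mix.weights[order]
    return mix


def bmiq_normalize_sample(beta: np.ndarray, probe_type: np.ndarray,
                          n_states: int = 3) -> np.ndarray:
    """Map one sample's type-II betas onto its type-I mixture; type I unchanged."""
    beta = np.asarray(beta, dtype=float)
    out = beta.copy()
    is1, is2 = probe_type == "I", probe_type == "II"
    mix1 = fit_beta_mixture(beta[is1], n_states)
    mix2 = _fit_anchored(beta[is2], mix1)
    if mix1.n_states != mix2.n_states:
        raise RuntimeError("mixture fits returned different state counts")
    k = mix1.n_states
    cuts = _state_boundaries(mix2)
    x2 = beta[is2]
    y = np.empty_like(x2)
    lo_state, hi_state = 0, k - 1
    in_lo = x2 <= cuts[0]
    in_hi = x2 > cuts[-1]
    in_mid = ~(in_lo | in_hi)
    y[in_lo] = _component_map(x2[in_lo], mix2.shapes[lo_state], mix1.shapes[lo_state])
    y[in_hi] = _component_map(x2[in_hi], mix2.shapes[hi_state], mix1.shapes[hi_state])
    # middle state: monotone affine bridge between the transformed boundaries
    t1, t2 = cuts[0], cuts[-1]
    y1 = _component_map(np.array([t1]), mix2.shapes[lo_state], mix1.shapes[lo_state])[0]
    y2 = _component_map(np.array([t2]), mix2.shapes[hi_state], mix1.shapes[hi_state])[0]
    if y2 <= y1 or t2 <= t1:
        y[in_mid] = x2[in_mid]      # degenerate fit; pass through
    else:
        y[in_mid] = y1 + (x2[in_mid] - t1) * (y2 - y1) / (t2 - t1)
    out[is2] = np.clip(y, BETA_EPS, 1 - BETA_EPS)
    return out


def bmiq_normalize(meth: MethylationSet, n_states: int = 3) -> MethylationSet:
    """Per-sample, per-visit BMIQ-style normalization of type-II probes."""
    new_beta = {}
    for visit, mat in meth.beta.items():
        adj = mat.copy()
        for s in range(mat.shape[1]):
            try:
                adj[:, s] = bmiq_normalize_sample(mat[:, s], meth.probe_type, n_states)
            except (ValueError, RuntimeError) as exc:
                warnings.warn(f"BMIQ failed for sample {meth.samples[s]} "
                              f"visit {visit}: {exc}; passed through")
        new_beta[visit] = adj
    return MethylationSet(
        cpg_ids=meth.cpg_ids, chrom=meth.chrom, pos=meth.pos,
        probe_type=meth.probe_type, samples=list(meth.samples), beta=new_beta,
    )


def methylation_response(meth: MethylationSet, visits: tuple[int, int] = (2, 4)) -> np.ndarray:
    """M-value change: M(post visit) - M(pre visit), NaN where either missing."""
    pre, post = visits
    m_pre = beta_to_m(meth.beta[pre])
    m_post = beta_to_m(meth.beta[post])
    return m_post - m_pre
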