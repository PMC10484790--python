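"""Two-component Gaussian mixture decomposition of unlabeled variant
effect scores into likely-benign and likely-pathogenic fractions.

Two estimators are provided: a free two-Gaussian EM fit (used for
missense variants of uncertain significance) and a fixed-component
mixture where each class density is frozen from labeled scores and only
the mixing weight is estimated (used for indel VUS).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .errors import DegenerateFitError, ValidationError

_MIN_SCORES = 10
_SD_FLOOR_FRAC = 1e-4  # relative variance floor keeps EM numerically stable
_SEPARATION_FLOOR = 0.5  # components closer than this (in pooled s.d.) are degenerate


@dataclass(frozen=True)
class GaussianMixtureFit:
    """EM fit of a two-component 1-D Gaussian mixture.

    Components are ordered so ``means[0] > means[1]``: the higher-mean
    (less negative, benign-like) component comes first.
    """

    means: tuple
    sds: tuple
    weights: tuple
    log_likelihood: float
    n_iterations: int
    converged: bool
    degenerate: bool = False
    log_likelihood_trace: tuple = ()

    def __post_init__(self):
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        if any(w < 0 for w in self.weights):
            raise ValidationError("mixture weights must be non-negative")
        if any(s <= 0 for s in self.sds):
            raise ValidationError("component s.d. must be positive")
        if self.means[0] < self.means[1]:
            raise ValidationError("components must be ordered by decreasing mean")


@dataclass(frozen=True)
class ClassFractionEstimate:
    benign_fraction: float
    pathogenic_fraction: float

    def __post_init__(self):
        for f in (self.benign_fraction, self.pathogenic_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValidationError("fractions must lie in [0, 1]")
        if abs(self.benign_fraction + self.pathogenic_fraction - 1.0) > 1e-9:
            raise ValidationError("fractions must sum to 1")


def _em_run(x, mu, sd, w, tol, max_iter, sd_floor):
    """One EM run from a given start; returns params + ll trace."""
    n = x.size
    trace = []
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        log_comp = np.stack(
            [
                np.log(w[k]) + norm.logpdf(x, mu[k], sd[k])
                for k in range(2)
            ]
        )  # (2, n)
        log_norm = logsumexp(log_comp, axis=0)
        ll = float(log_norm.sum())
        trace.append(ll)
        resp = np.exp(log_comp - log_norm)  # (2, n)
        nk = resp.sum(axis=1)
        nk = np.maximum(nk, 1e-12)
        w = nk / n
        mu = (resp @ x) / nk
        var = np.array(
            [
                float(resp[k] @ (x - mu[k]) ** 2) / nk[k]
                for k in range(2)
            ]
        )
        sd = np.sqrt(np.maximum(var, sd_floor**2))
        if ll - ll_prev >= 0 and (ll - ll_prev) < tol * max(1.0, abs(ll)):
            converged = True
            break
        ll_prev = ll
    return mu, sd, w, trace[-1], it, converged, trace


def fit_two_component_gmm(
    scores,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
    n_restarts: int = 5,
) -> GaussianMixtureFit:
    """Fit a two-component Gaussian mixture by EM.

    Initialization splits the data at its median; additional seeded
    random restarts perturb the initial means, and the best-likelihood
    solution is kept. Deterministic for a given seed.
    """
    x = np.asarray(scores, dtype=np.float64)
    x = x[np.isfinite(x)]
    if x.size < _MIN_SCORES:
        raise ValidationError(
            f"need at least {_MIN_SCORES} finite scores, got {x.size}"
        )
    spread = float(x.std(ddof=0))
    if spread == 0.0:
        raise DegenerateFitError("scores are constant; mixture fit undefined")
    sd_floor = _SD_FLOOR_FRAC * spread

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # all mass at/below the median (heavy ties)
        lo, hi = x[x < med], x[x >= med]
    base_mu = np.array([lo.mean(), hi.mean()])
    base_sd = np.maximum(np.array([lo.std(ddof=0), hi.std(ddof=0)]), sd_floor)
    base_w = np.array([lo.size / x.size, hi.size / x.size])

    rng = np.random.default_rng(seed)
    starts = [(base_mu, base_sd, base_w)]
    for _ in range(n_restarts):
        jitter = rng.normal(0.0, 0.5 * spread, size=2)
        starts.append((base_mu + jitter, base_sd.copy(), np.array([0.5, 0.5])))

    best = None
    for mu0, sd0, w0 in starts:
        result = _em_run(x, mu0.copy(), sd0.copy(), w0.copy(), tol, max_iter, sd_floor)
        if best is None or result[3] > best[3]:
            best = result
    mu, sd, w, ll, it, converged, trace = best

    order = np.argsort(-mu)  # higher mean (benign-like) first
    mu, sd, w = mu[order], sd[order], w[order]
    pooled = float(np.sqrt((sd**2).mean()))
    degenerate = bool((mu[0] - mu[1]) < _SEPARATION_FLOOR * pooled)
    return GaussianMixtureFit(
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        weights=(float(w[0]), float(w[1])),
        log_likelihood=ll,
        n_iterations=it,
        converged=converged,
        degenerate=degenerate,
        log_likelihood_trace=tuple(trace),
    )


def estimate_class_fractions(fit: GaussianMixtureFit) -> ClassFractionEstimate:
    """Benign fraction = weight of the higher-mean component."""
    return ClassFractionEstimate(
        benign_fraction=fit.weights[0], pathogenic_fraction=fit.weights[1]
    )


def fit_fixed_class_mixture(
    unlabeled_scores,
    benign_scores,
    pathogenic_scores,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> ClassFractionEstimate:
    """Mixture of two frozen class densities with one free mixing weight.

    Each labeled class contributes a Gaussian with its empirical mean
    and population s.d.; the benign weight is then estimated by EM on
    the unlabeled scores. The likelihood is unimodal in the weight, so
    EM converges to the global optimum.
    """
    x = np.asarray(unlabeled_scores, dtype=np.float64)
    b = np.asarray(benign_scores, dtype=np.float64)
    p = np.asarray(pathogenic_scores, dtype=np.float64)
    if x.size == 0 or b.size == 0 or p.size == 0:
        raise ValidationError("all three score sets must be non-empty")
    if b.std(ddof=0) == 0.0 or p.std(ddof=0) == 0.0:
        raise DegenerateFitError("labeled class with zero spread")

    log_b = norm.logpdf(x, b.mean(), b.std(ddof=0))
    log_p = norm.logpdf(x, p.mean(), p.std(ddof=0))
    w = 0.5
    for _ in range(max_iter):
        log_wb = np.log(w) + log_b
        log_wp = np.log1p(-w) + log_p
        resp_b = np.exp(log_wb - np.logaddexp(log_wb, log_wp))
        w_new = float(resp_b.mean())
        if abs(w_new - w) < tol:
            w = w_new
            break
        w = w_new
    w = min(max(w, 0.0), 1.0)
    return ClassFractionEstimate(benign_fraction=w, pathogenic_fraction=1.0 - w)


def fixed_mixture_log_likelihood(w, unlabeled_scores, benign_scores, pathogenic_scores):
    """Unlabeled-data log-likelihood at benign weight ``w`` (for
    independent optimizer cross-checks)."""
    x = np.asarray(unlabeled_scores, dtype=np.float64)
    b = np.asarray(benign_scores, dtype=np.float64)
    p = np.asarray(pathogenic_scores, dtype=np.float64)
    log_b = norm.logpdf(x, b.mean(), b.std(ddof=0))
    log_p = norm.logpdf(x, p.mean(), p.std(ddof=0))
    return float(
        np.logaddexp(np.log(w) + log_b, np.log1p(-w) + log_p).sum()
    )
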