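"""Length-at-age assignment by a four-component Gaussian mixture.

Larval cohorts are separated by body length: lengths are fitted with a
K = 4 Gaussian mixture by EM and individuals are assigned to the
maximum-posterior component; components map to age classes 0, 1, 2, 3+
in ascending order of mean (longer larvae are older).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .synthetic import AgeMixtureModel

VARIANCE_FLOOR = 1e-4


@dataclass
class AgeMixtureFit:
    model: AgeMixtureModel
    labels: np.ndarray  # component index per individual (ascending mean)
    age_class: np.ndarray  # mapped age-class names
    posterior: np.ndarray
    loglik_trace: np.ndarray
    converged: bool
    degenerate: bool  # any variance pinned at the floor


def _quantile_init(x: np.ndarray, k: int):
    """Split the sorted sample into k equal-count blocks; means/sds per
    block. Deterministic and order-invariant."""
    xs = np.sort(x)
    blocks = np.array_split(xs, k)
    means = np.array([b.mean() for b in blocks])
    sds = np.array([max(b.std(), np.sqrt(VARIANCE_FLOOR)) for b in blocks])
    weights = np.full(k, 1.0 / k)
    return means, sds, weights


def assign_ages(
    lengths: np.ndarray,
    K: int = 4,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> AgeMixtureFit:
    """Fit the length mixture by EM and assign age classes.

    Initialization is quantile-based; iteration stops when the
    log-likelihood improves by less than ``tol`` (non-convergence after
    ``max_iter`` iterations raises, with the trace attached to the
    error). Variances are floored at 1e-4 mm^2; a fit that pins a
    variance at the floor is flagged degenerate rather than failed.
    """
    x = np.asarray(lengths, dtype=float)
    if len(x) < 5 * K:
        raise ValueError(f"need at least {5 * K} observations for {K} components")
    means, sds, weights = _quantile_init(x, K)
    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step
        logp = norm.logpdf(x[:, None], means[None, :], sds[None, :]) + np.log(weights)
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        ll = float(lse.sum())
        trace.append(ll)
        resp = np.exp(logp - lse[:, None])
        if ll - prev < tol and np.isfinite(prev):
            converged = True
            break
        prev = ll
        # M step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        weights = nk / nk.sum()
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means) ** 2).sum(axis=0) / nk
        var = np.maximum(var, VARIANCE_FLOOR)
        sds = np.sqrt(var)
    trace = np.asarray(trace)
    if not converged:
        err = RuntimeError(f"EM did not converge in {max_iter} iterations")
        err.trace = trace
        raise err
    degenerate = bool(np.any(sds**2 <= VARIANCE_FLOOR * (1 + 1e-12)))
    order = np.argsort(means)
    model = AgeMixtureModel(means[order], sds[order], weights[order] / weights[order].sum(), K=K)
    posterior = resp[:, order]
    labels = posterior.argmax(axis=1)
    classes = np.array(model.age_classes if K == 4 else [str(i) for i in range(K)], dtype=object)
    return AgeMixtureFit(
        model, labels, classes[labels], posterior, trace, converged, degenerate
    )
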