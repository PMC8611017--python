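"""Binomial-mixture clustering of multi-sample VAF vectors.

Variants restricted to copy-number-neutral diploid segments are clustered
jointly across a patient's samples with a K-component binomial mixture
fitted by EM; the component count is chosen by BIC with an upper bound of
20 clusters.  Sample purity is estimated from the VAF distribution of
copy-number-neutral variants (twice the median VAF of the highest-mean
1-D cluster), and cluster centres are converted to cellular fractions as
CF = 2 * theta / purity, truncated to [0, 1].

Observed VAFs of exactly zero are floored at 1e-10 (and mixture success
probabilities are clamped away from {0, 1}) so that the EM never evaluates
log(0) when many entries are exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .errors import InvalidInputError, NoDataError

K_MAX = 20
VAF_FLOOR = 1e-10
_THETA_MIN = 1e-10
_WEIGHT_PRUNE = 1e-3


@dataclass
class VafMatrix:
    """Variants x samples read-count matrix with a copy-number-neutral mask.

    ``neutral_mask`` marks variants lying in segments with
    cn_major == cn_minor == 1; only those take part in clustering, the rest
    are attached to the nearest cluster afterwards.
    """

    alt: np.ndarray             # variants x samples, int
    depth: np.ndarray           # variants x samples, int
    neutral_mask: np.ndarray    # variants, bool
    variant_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.alt = np.asarray(self.alt, dtype=int)
        self.depth = np.asarray(self.depth, dtype=int)
        self.neutral_mask = np.asarray(self.neutral_mask, dtype=bool)
        if self.alt.shape != self.depth.shape:
            raise InvalidInputError("alt and depth must have the same shape")
        if np.any(self.alt > self.depth):
            raise InvalidInputError("alt_count exceeds depth")
        if np.any(self.alt < 0) or np.any(self.depth < 0):
            raise InvalidInputError("negative read counts")
        if self.neutral_mask.shape[0] != self.alt.shape[0]:
            raise InvalidInputError("neutral_mask length mismatch")

    @property
    def vaf(self) -> np.ndarray:
        """Observed VAFs with zeros floored at 1e-10."""
        with np.errstate(divide="ignore", invalid="ignore"):
            v = np.where(self.depth > 0, self.alt / np.maximum(self.depth, 1), 0.0)
        return np.maximum(v, VAF_FLOOR)


@dataclass
class MixtureModel:
    """A fitted K-component binomial mixture over S samples."""

    weights: np.ndarray         # K
    theta: np.ndarray           # K x S success probabilities
    responsibilities: np.ndarray  # N x K
    log_likelihood: float
    bic: float
    converged: bool
    n_iter: int

    @property
    def k(self) -> int:
        return len(self.weights)

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.responsibilities, axis=1)

    def cellular_fraction(self, purity) -> np.ndarray:
        """Cluster centres in CCF space: clip(2 * theta / rho, 0, 1)."""
        rho = np.asarray(purity, dtype=float)
        return np.clip(2.0 * self.theta / rho[None, :], 0.0, 1.0)


def _log_binom_const(alt, depth):
    return gammaln(depth + 1) - gammaln(alt + 1) - gammaln(depth - alt + 1)


def _em_once(alt, depth, k, theta0, *, tol, max_iter):
    """One EM run from a given theta initialisation; returns the model pieces.

    The log-likelihood is guaranteed non-decreasing per EM theory; a tiny
    numerical tolerance is allowed when testing that property.
    """
    n = alt.shape[0]
    const = _log_binom_const(alt, depth).sum(axis=1)    # N
    weights = np.full(k, 1.0 / k)
    theta = np.clip(theta0, _THETA_MIN, 1.0 - _THETA_MIN)
    prev_ll = -np.inf
    ll_trace = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E step: log p(x_i | k) summed over samples
        log_comp = (alt[:, None, :] * np.log(theta)[None, :, :]
                    + (depth - alt)[:, None, :] * np.log1p(-theta)[None, :, :]
                    ).sum(axis=2) + const[:, None]
        log_r = np.log(weights)[None, :] + log_comp
        ll = float(logsumexp(log_r, axis=1).sum())
        ll_trace.append(ll)
        resp = np.exp(log_r - logsumexp(log_r, axis=1, keepdims=True))
        # M step
        weights = resp.mean(axis=0)
        num = resp.T @ alt          # K x S
        den = resp.T @ depth
        theta = np.clip(num / np.maximum(den, 1e-300),
                        _THETA_MIN, 1.0 - _THETA_MIN)
        if np.isfinite(prev_ll) and abs(ll - prev_ll) <= tol * max(abs(prev_ll), 1.0):
            converged = True
            break
        prev_ll = ll
    return weights, theta, resp, ll_trace, converged, it


def fit_binomial_mixture(alt, depth, k: int, *, seed=0, n_restarts: int = 10,
                         tol: float = 1e-6, max_iter: int = 500) -> MixtureModel:
    """Fit a K-component binomial mixture by EM with seeded restarts.

    Initialisation picks K observed VAF vectors as starting centres (with
    jitter); the best of ``n_restarts`` runs by log-likelihood is kept.
    Components whose weight falls below 1e-3 are pruned and the
    responsibilities recomputed.  A model that never meets the convergence
    tolerance is returned with ``converged=False``.
    """
    alt = np.asarray(alt, dtype=float)
    depth = np.asarray(depth, dtype=float)
    if alt.ndim == 1:
        alt = alt[:, None]
        depth = depth[:, None]
    if k < 1:
        raise InvalidInputError("K must be >= 1")
    n, s = alt.shape
    if n == 0:
        raise NoDataError("empty VAF matrix")
    with np.errstate(invalid="ignore"):
        vaf = np.where(depth > 0, alt / np.maximum(depth, 1.0), 0.0)
    rng = np.random.default_rng(seed)

    best = None
    for _ in range(max(1, n_restarts)):
        idx = rng.choice(n, size=k, replace=(n < k))
        theta0 = vaf[idx] + rng.normal(0.0, 0.02, size=(k, s))
        pieces = _em_once(alt, depth, k, theta0, tol=tol, max_iter=max_iter)
        if best is None or pieces[3][-1] > best[3][-1]:
            best = pieces
    weights, theta, resp, ll_trace, converged, n_iter = best

    keep = weights >= _WEIGHT_PRUNE
    if not np.all(keep) and keep.sum() >= 1:
        weights = weights[keep] / weights[keep].sum()
        theta = theta[keep]
        w2, t2, resp, ll2, conv2, _ = _em_once(
            alt, depth, len(weights), theta, tol=tol, max_iter=max_iter)
        weights, theta = w2, t2
        ll_trace = ll_trace + ll2
        converged = converged or conv2
    if not converged:
        warnings.warn("binomial-mixture EM did not converge; "
                      "returning best model", stacklevel=2)

    ll = ll_trace[-1]
    k_eff = len(weights)
    n_params = (k_eff - 1) + k_eff * s
    bic = -2.0 * ll + n_params * np.log(n)
    return MixtureModel(weights=weights, theta=theta, responsibilities=resp,
                        log_likelihood=ll, bic=bic, converged=converged,
                        n_iter=n_iter)


def select_model(alt, depth, *, k_max: int = K_MAX, seed=0,
                 n_restarts: int = 10, patience: int = 3) -> MixtureModel:
    """Fit K = 1..k_max and return the BIC-minimal mixture.

    The scan stops early once BIC has worsened for ``patience`` consecutive
    K (BIC is convex-ish in K in practice); the bound of 20 clusters is
    never exceeded.
    """
    if k_max < 1:
        raise InvalidInputError("k_max must be >= 1")
    rng = np.random.default_rng(seed)
    best = None
    worse = 0
    for k in range(1, k_max + 1):
        model = fit_binomial_mixture(alt, depth, k,
                                     seed=int(rng.integers(2**31)),
                                     n_restarts=n_restarts)
        if best is None or model.bic < best.bic:
            best = model
            worse = 0
        else:
            worse += 1
            if worse >= patience:
                break
    return best


def estimate_purity(alt_s, depth_s, *, seed=0, k_max: int = 6,
                    min_variants: int = 5, min_weight: float = 0.05,
                    fallback: float | None = None) -> float:
    """Estimate tumour purity of one sample from copy-number-neutral VAFs.

    A 1-D binomial-mixture pre-clustering is fitted to the sample's neutral
    variants; purity is twice the median VAF of the highest-mean cluster
    (components below ``min_weight`` are ignored as noise), clipped to
    (0, 1].  With fewer than ``min_variants`` usable variants the
    user-supplied ``fallback`` is returned with a warning.
    """
    alt_s = np.asarray(alt_s, dtype=float)
    depth_s = np.asarray(depth_s, dtype=float)
    usable = depth_s > 0
    alt_s, depth_s = alt_s[usable], depth_s[usable]
    if alt_s.size < min_variants:
        if fallback is None:
            raise NoDataError(
                f"fewer than {min_variants} copy-number-neutral variants "
                "and no fallback purity supplied")
        warnings.warn("too few neutral variants; using fallback purity",
                      stacklevel=2)
        return float(fallback)
    model = select_model(alt_s[:, None], depth_s[:, None],
                         k_max=k_max, seed=seed)
    centers = model.theta[:, 0]
    ok = model.weights >= min_weight
    if not ok.any():
        ok[:] = True
    top = int(np.flatnonzero(ok)[np.argmax(centers[ok])])
    members = model.labels == top
    if not members.any():
        members = np.ones(alt_s.size, dtype=bool)
    med = float(np.median(alt_s[members] / depth_s[members]))
    return float(np.clip(2.0 * med, 1e-6, 1.0))


def attach_non_neutral(model: MixtureModel, cf_neutral: np.ndarray,
                       cf_variant: np.ndarray) -> int:
    """Attach a variant outside diploid segments to the nearest cluster.

    ``cf_neutral`` are the cluster centres in CCF space; ``cf_variant`` the
    variant's per-sample CCF estimate.  Returns the cluster index with the
    smallest Euclidean distance (such variants are flagged 'attached'
    downstream, they never influence the fitted centres).
    """
    d = np.linalg.norm(cf_neutral - cf_variant[None, :], axis=1)
    return int(np.argmin(d))
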