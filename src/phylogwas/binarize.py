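"""Binarization of continuous phenotypes.

The contrasting-pairs machinery needs binary traits, so each numeric trait is
converted to presence/absence calls first.  Two methods:

* ``kmeans`` — exact two-cluster 1-D k-means (optimal contiguous split of the
  sorted values, found by enumeration); every isolate gets a label.
* ``gmm`` — two-component univariate Gaussian mixture fit by EM; isolates
  whose maximum posterior falls below a cutoff (default 0.85) are treated as
  ambiguous and excluded from further analysis for that trait.

Label 1 is always the component with the larger mean.  Binary input traits
bypass this module untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.mixture import GaussianMixture

__all__ = [
    "BinarizationResult",
    "BinarizationError",
    "binarize_kmeans",
    "binarize_gmm",
    "DEFAULT_POSTERIOR_CUTOFF",
]

DEFAULT_POSTERIOR_CUTOFF = 0.85

# label codes in BinarizationResult.labels
MISSING = -2  # missing in the input
EXCLUDED = -1  # ambiguous under the mixture posterior cutoff


class BinarizationError(ValueError):
    """Trait cannot be binarized (constant values, or mixture fit failed
    with the skip policy)."""


@dataclass
class BinarizationResult:
    trait_id: str
    method: str  # kmeans | gmm | gmm_kmeans_fallback
    labels: np.ndarray  # int8 per isolate: 0, 1, EXCLUDED, MISSING
    means: tuple  # (low, high) component / cluster means
    posterior: Optional[np.ndarray]  # P(high component) per isolate (gmm only)
    n_excluded: int
    outcome: str = "ok"
    raw_values: Optional[np.ndarray] = None  # original numeric values (for reports)

    def trait_vector(self) -> np.ndarray:
        """Float vector with NaN for missing/excluded — the association input."""
        out = np.where(self.labels >= 0, self.labels.astype(float), np.nan)
        return out


def _exact_two_means(obs: np.ndarray):
    """Globally optimal 2-means on a line: best contiguous split of sorted values.

    Returns (labels01 over obs, (mean_low, mean_high)).  SSE ties are broken
    toward the larger low cluster, i.e. an equidistant point joins the
    lower-mean cluster.
    """
    order = np.argsort(obs, kind="stable")
    x = obs[order]
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    best_k, best_sse = None, None
    for k in range(1, n):  # low cluster = x[:k]
        s1, q1 = csum[k - 1], csq[k - 1]
        s2, q2 = csum[-1] - s1, csq[-1] - q1
        sse = (q1 - s1 * s1 / k) + (q2 - s2 * s2 / (n - k))
        tol = 1e-12 * (1.0 + abs(sse))
        if best_k is None or sse < best_sse - tol or abs(sse - best_sse) <= tol:
            # ties prefer the larger low cluster (equidistant point goes low)
            best_sse, best_k = min(sse, best_sse) if best_k is not None else sse, k
    k = best_k
    mean_lo = csum[k - 1] / k
    mean_hi = (csum[-1] - csum[k - 1]) / (n - k)
    labels_sorted = np.zeros(n, dtype=np.int8)
    labels_sorted[k:] = 1
    labels = np.empty(n, dtype=np.int8)
    labels[order] = labels_sorted
    return labels, (float(mean_lo), float(mean_hi))


def binarize_kmeans(values, trait_id: str = "") -> BinarizationResult:
    """Exact two-cluster k-means labeling; no abstentions."""
    values = np.asarray(values, dtype=float)
    miss = np.isnan(values)
    obs = values[~miss]
    if len(obs) < 4:
        raise BinarizationError(f"trait {trait_id!r}: fewer than 4 non-missing values")
    if len(np.unique(obs)) < 2:
        raise BinarizationError(f"trait {trait_id!r}: all values identical")
    lab01, means = _exact_two_means(obs)
    labels = np.full(len(values), MISSING, dtype=np.int8)
    labels[~miss] = lab01
    return BinarizationResult(trait_id, "kmeans", labels, means, None, 0, raw_values=values.copy())


def binarize_gmm(
    values,
    posterior_cutoff: float = DEFAULT_POSTERIOR_CUTOFF,
    on_failure: str = "kmeans",
    seed: int = 0,
    trait_id: str = "",
) -> BinarizationResult:
    """Two-component Gaussian mixture labeling with posterior abstention.

    EM is initialized deterministically (component means at the 25th/75th
    percentiles, equal weights, pooled variance); ``seed`` only governs
    potential re-starts inside scikit-learn.  The fit counts as failed on
    non-convergence within 500 iterations, a component weight below 2/n, or
    variance collapse below 1e-10 x the data variance; then ``on_failure``
    decides between dropping the trait (``skip``) and the k-means backup.
    """
    if on_failure not in ("skip", "kmeans"):
        raise ValueError(f"unknown on_failure policy: {on_failure}")
    values = np.asarray(values, dtype=float)
    miss = np.isnan(values)
    obs = values[~miss]
    if len(obs) < 6:
        raise BinarizationError(f"trait {trait_id!r}: fewer than 6 non-missing values")
    if len(np.unique(obs)) < 2:
        raise BinarizationError(f"trait {trait_id!r}: all values identical")

    failure = None
    var = float(obs.var())
    if var == 0.0:
        failure = "zero variance"
    else:
        q25, q75 = np.percentile(obs, [25, 75])
        gm = GaussianMixture(
            n_components=2,
            means_init=[[q25], [q75]],
            weights_init=[0.5, 0.5],
            precisions_init=[[[1.0 / var]], [[1.0 / var]]],
            max_iter=500,
            random_state=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gm.fit(obs.reshape(-1, 1))
        if not gm.converged_:
            failure = "EM did not converge in 500 iterations"
        elif gm.weights_.min() < 2.0 / len(obs):
            failure = "degenerate component weight"
        elif gm.covariances_.min() < 1e-10 * var:
            failure = "variance collapse"
        else:
            mu_ = gm.means_.ravel()
            hi_ = int(np.argmax(mu_))
            ph_ = gm.predict_proba(obs.reshape(-1, 1))[:, hi_]
            conf_ = np.maximum(ph_, 1.0 - ph_) >= posterior_cutoff
            calls_ = ph_[conf_] >= 0.5
            if not conf_.any() or calls_.all() or not calls_.any():
                # confident labels carry no contrast: the fit is useless
                failure = "single-class labeling after posterior cutoff"

    if failure is not None:
        if on_failure == "skip":
            raise BinarizationError(f"trait {trait_id!r}: GMM fit failed ({failure})")
        res = binarize_kmeans(values, trait_id=trait_id)
        res.method = "gmm_kmeans_fallback"
        res.outcome = f"gmm failed ({failure}); kmeans fallback"
        return res

    mu = gm.means_.ravel()
    hi_comp = int(np.argmax(mu))
    post_hi = gm.predict_proba(obs.reshape(-1, 1))[:, hi_comp]
    post_max = np.maximum(post_hi, 1.0 - post_hi)
    confident = post_max >= posterior_cutoff

    labels = np.full(len(values), MISSING, dtype=np.int8)
    lab_obs = np.full(len(obs), EXCLUDED, dtype=np.int8)
    lab_obs[confident] = (post_hi[confident] >= 0.5).astype(np.int8)
    labels[~miss] = lab_obs
    posterior = np.full(len(values), np.nan)
    posterior[~miss] = post_hi
    n_excl = int(np.sum(lab_obs == EXCLUDED))
    return BinarizationResult(
        trait_id,
        "gmm",
        labels,
        (float(mu.min()), float(mu.max())),
        posterior,
        n_excl,
        raw_values=values.copy(),
    )
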