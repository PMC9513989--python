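"""Clonal-group inference: product-binomial mixture over multi-sample counts.

Mutations with similar VAF trajectories across samples are taken to mark
one clonal group.  Rather than clustering VAF point estimates, the model
works on read counts directly: variant i in component c has likelihood

    prod_s  Binomial(b_is | d_is, xi_cs)

which weighs deep and shallow sites appropriately at the 40-50x coverage
typical of whole-genome studies.  Entries with depth 0 are missing and
contribute no likelihood term.  Model selection is by BIC over a K range
with multiple seeded restarts.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.cluster import KMeans

from . import ccf as ccf_mod

__all__ = ["BinomialMixtureVAF", "CloneCluster", "select_k", "assign_clusters"]

_XI_MIN, _XI_MAX = 1e-4, 0.999


@dataclass
class CloneCluster:
    """A clonal group: member variants and their per-sample centers."""

    cluster_id: int
    members: list[str]
    centers: pd.Series  # expected VAF xi per sample
    prevalence: pd.Series  # phi-hat derived via the CCF model

    @property
    def size(self) -> int:
        return len(self.members)


def _as_matrices(alt_counts, total_depths) -> tuple[np.ndarray, np.ndarray, list]:
    alt = np.asarray(alt_counts, dtype=float)
    dep = np.asarray(total_depths, dtype=float)
    if alt.shape != dep.shape or alt.ndim != 2:
        raise ValueError(f"alt/depth shapes differ or not 2-D: {alt.shape} vs {dep.shape}")
    if np.any(alt < 0) or np.any(dep < 0) or np.any(alt > dep):
        raise ValueError("require 0 <= alt <= depth elementwise")
    index = list(alt_counts.index) if hasattr(alt_counts, "index") else list(range(alt.shape[0]))
    return alt, dep, index


class BinomialMixtureVAF(BaseEstimator):
    """K-component product-binomial mixture over variants x samples counts.

    Parameters
    ----------
    n_components : int
        Number of mixture components (clonal groups), >= 1.
    max_iter : int
        EM iteration cap.
    tol : float
        Stop when the log-likelihood improves by less than this.
    n_init : int
        Number of seeded restarts; the best log-likelihood wins.
    random_state : int or None
        Seed for k-means++-style initialization on VAF vectors.

    Attributes
    ----------
    centers_ : (K, S) per-component per-sample expected VAF, in [1e-4, 0.999].
    weights_ : (K,) mixing proportions, summing to 1.
    responsibilities_ : (N, K) posterior component memberships, rows sum to 1.
    labels_ : (N,) hard assignments by maximum responsibility (ties to lower id).
    log_likelihood_ : float, final observed-data log-likelihood.
    log_likelihood_path_ : per-iteration log-likelihood of the winning run
        (non-decreasing, an EM guarantee asserted in the tests).
    bic_ : float, -2 loglik + q ln N_obs with q = K S + (K - 1) and N_obs the
        number of (variant, sample) cells with depth > 0.
    n_components_ : effective K after dropping empty components.
    """

    def __init__(
        self,
        n_components: int = 1,
        max_iter: int = 500,
        tol: float = 1e-6,
        n_init: int = 10,
        random_state: int | None = None,
    ):
        self.n_components = n_components
        self.max_iter = max_iter
        self.tol = tol
        self.n_init = n_init
        self.random_state = random_state

    # -- likelihood machinery ------------------------------------------------
    @staticmethod
    def _log_binom_const(alt: np.ndarray, dep: np.ndarray, mask: np.ndarray) -> float:
        c = gammaln(dep + 1) - gammaln(alt + 1) - gammaln(dep - alt + 1)
        return float(c[mask].sum())

    @staticmethod
    def _component_loglik(alt, dep, mask, centers) -> np.ndarray:
        """(N, K) sum over observed samples of b log xi + (d-b) log(1-xi)."""
        lx = np.log(centers)  # (K, S)
        l1x = np.log1p(-centers)
        a = np.where(mask, alt, 0.0)
        d = np.where(mask, dep, 0.0)
        return a @ lx.T + (d - a) @ l1x.T

    def _init_centers(self, alt, dep, mask, K, rng) -> np.ndarray:
        vaf = np.divide(alt, dep, out=np.zeros_like(alt), where=mask)
        col_mean = np.array(
            [vaf[mask[:, s], s].mean() if mask[:, s].any() else 0.0 for s in range(vaf.shape[1])]
        )
        filled = np.where(mask, vaf, col_mean)
        if K == 1:
            labels = np.zeros(len(alt), dtype=int)
        else:
            km = KMeans(n_clusters=K, init="k-means++", n_init=1,
                        random_state=int(rng.integers(0, 2**31 - 1)))
            labels = km.fit_predict(filled)
        centers = np.empty((K, alt.shape[1]))
        for c in range(K):
            sel = labels == c
            if not sel.any():
                sel = np.ones(len(alt), dtype=bool)
            num = (alt[sel] * mask[sel]).sum(axis=0)
            den = (dep[sel] * mask[sel]).sum(axis=0)
            centers[c] = np.divide(num, den, out=np.full(alt.shape[1], 0.25), where=den > 0)
        return np.clip(centers, _XI_MIN, _XI_MAX)

    def _em(self, alt, dep, mask, centers, const):
        K = centers.shape[0]
        weights = np.full(K, 1.0 / K)
        path = []
        prev = -np.inf
        for _ in range(self.max_iter):
            comp = self._component_loglik(alt, dep, mask, centers)  # (N, K)
            joint = comp + np.log(weights)
            norm = logsumexp(joint, axis=1)
            loglik = float(norm.sum()) + const
            path.append(loglik)
            resp = np.exp(joint - norm[:, None])
            if loglik - prev < self.tol and len(path) > 1:
                prev = loglik
                break
            prev = loglik
            # M-step
            weights = resp.mean(axis=0)
            weights = np.clip(weights, 1e-12, None)
            weights /= weights.sum()
            num = resp.T @ (alt * mask)
            den = resp.T @ (dep * mask)
            centers = np.divide(num, den, out=np.full_like(num, 0.5), where=den > 0)
            centers = np.clip(centers, _XI_MIN, _XI_MAX)
        return centers, weights, resp, prev, path

    def fit(self, alt_counts, total_depths):
        """Fit the mixture to variants x samples (alt, depth) matrices."""
        alt, dep, index = _as_matrices(alt_counts, total_depths)
        K = int(self.n_components)
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if K > alt.shape[0]:
            raise ValueError(f"n_components={K} exceeds n_variants={alt.shape[0]}")
        mask = dep > 0
        if not mask.any():
            raise ValueError("all depths are zero; nothing to fit")
        const = self._log_binom_const(alt, dep, mask)
        rng = np.random.default_rng(self.random_state)

        best = None
        for _ in range(max(1, self.n_init)):
            centers0 = self._init_centers(alt, dep, mask, K, rng)
            out = self._em(alt, dep, mask, centers0, const)
            if best is None or out[3] > best[3]:
                best = out
        centers, weights, resp, loglik, path = best

        # drop components that captured no variants; renormalize
        hard = resp.argmax(axis=1)
        occupied = np.array([np.any(hard == c) for c in range(K)])
        if not occupied.all():
            centers = centers[occupied]
            weights = weights[occupied] / weights[occupied].sum()
            comp = self._component_loglik(alt, dep, mask, centers) + np.log(weights)
            norm = logsumexp(comp, axis=1)
            resp = np.exp(comp - norm[:, None])
            loglik = float(norm.sum()) + const
            hard = resp.argmax(axis=1)

        k_eff = centers.shape[0]
        n_obs = int(mask.sum())
        q = k_eff * alt.shape[1] + (k_eff - 1)
        self.centers_ = centers
        self.weights_ = weights
        self.responsibilities_ = resp
        self.labels_ = hard
        self.log_likelihood_ = loglik
        self.log_likelihood_path_ = path
        self.bic_ = -2.0 * loglik + q * np.log(n_obs)
        self.n_components_ = k_eff
        self.n_obs_ = n_obs
        self.index_ = index
        return self

    def predict(self, alt_counts, total_depths) -> np.ndarray:
        """Hard component assignment of new count rows (ties to the lower id)."""
        alt, dep, _ = _as_matrices(alt_counts, total_depths)
        mask = dep > 0
        comp = self._component_loglik(alt, dep, mask, self.centers_) + np.log(self.weights_)
        # argmax returns the first (lowest-id) maximizer, the documented tie rule
        return comp.argmax(axis=1)

    def fit_predict(self, alt_counts, total_depths) -> np.ndarray:
        return self.fit(alt_counts, total_depths).labels_


def select_k(
    alt_counts,
    total_depths,
    k_range=range(1, 9),
    seed: int | None = 0,
    restarts: int = 10,
    min_cluster_size: int = 3,
) -> BinomialMixtureVAF:
    """Fit the mixture for each K and return the BIC-minimizing fit.

    After selection, clusters smaller than ``min_cluster_size`` are merged
    into the nearest surviving center (Euclidean distance in expected-VAF
    space); the returned fit's ``labels_``/``n_components_`` reflect the
    merge.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    fits = []
    for i, k in enumerate(ks):
        est = BinomialMixtureVAF(
            n_components=k,
            n_init=restarts,
            random_state=None if seed is None else seed + 1000 * i,
        )
        est.fit(alt_counts, total_depths)
        fits.append(est)
    best = min(fits, key=lambda f: f.bic_)
    _merge_small_clusters(best, min_cluster_size)
    return best


def _merge_small_clusters(fit: BinomialMixtureVAF, min_cluster_size: int) -> None:
    while True:
        sizes = np.bincount(fit.labels_, minlength=fit.n_components_)
        small = [c for c in range(fit.n_components_) if 0 < sizes[c] < min_cluster_size]
        if not small or (sizes >= min_cluster_size).sum() == 0:
            break
        c = min(small, key=lambda c: sizes[c])
        keep = [j for j in range(fit.n_components_) if j != c and sizes[j] >= min_cluster_size]
        if not keep:
            break
        dists = [np.linalg.norm(fit.centers_[c] - fit.centers_[j]) for j in keep]
        target = keep[int(np.argmin(dists))]
        fit.labels_ = np.where(fit.labels_ == c, target, fit.labels_)
        # compact ids
        remap = {old: new for new, old in enumerate(sorted(set(fit.labels_)))}
        fit.labels_ = np.array([remap[v] for v in fit.labels_])
        order = sorted(remap, key=remap.get)
        fit.centers_ = fit.centers_[order]
        fit.weights_ = fit.weights_[order] / fit.weights_[order].sum()
        fit.responsibilities_ = fit.responsibilities_[:, order]
        fit.responsibilities_ /= fit.responsibilities_.sum(axis=1, keepdims=True)
        fit.n_components_ = len(order)


def assign_clusters(
    fit: BinomialMixtureVAF,
    sample_ids,
    purity=None,
    copy_number: int = 2,
    multiplicity: int = 1,
) -> list[CloneCluster]:
    """Materialize hard clusters with prevalence (phi-hat) per sample.

    phi-hat converts each center's expected VAF through the CCF model using
    the per-sample purity (default 1.0) and local copy number.
    """
    sample_ids = list(sample_ids)
    if purity is None:
        purity = {s: 1.0 for s in sample_ids}
    clusters = []
    for c in range(fit.n_components_):
        members = [fit.index_[i] for i in np.flatnonzero(fit.labels_ == c)]
        centers = pd.Series(fit.centers_[c], index=sample_ids)
        prev = pd.Series(
            [
                ccf_mod.ccf_from_vaf(
                    min(float(v), 1.0), purity[s], copy_number, multiplicity
                ).ccf
                for s, v in centers.items()
            ],
            index=sample_ids,
        )
        clusters.append(CloneCluster(cluster_id=c, members=members, centers=centers, prevalence=prev))
    return clusters
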