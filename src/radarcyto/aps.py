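"""APS-style principal-component projection and subclone counting.

The automatic population separator (APS) view projects a blast
population onto the first two principal components of all standardized
channels — scatter and fluorescence alike — so that a population that
looks single on bivariate plots can reveal subclones. Cluster number is
then chosen by Gaussian-mixture BIC with a parsimony margin: a larger k
wins only on strong evidence, which mirrors how a split must show up as
two distinct density maxima before an analyst accepts it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .fcs_io import EventMatrix

__all__ = ["APSProjection", "HomogeneityCall", "aps_project", "count_clusters"]


@dataclass
class APSProjection:
    """First two principal components of the standardized channels."""

    scores: np.ndarray            # (n_events, 2)
    explained_variance: np.ndarray  # fractions, non-increasing
    components: np.ndarray        # (2, n_channels) orthonormal loadings
    channels: list[str]
    eigenvalues: np.ndarray       # all eigenvalues of the standardized cov

    def __post_init__(self):
        ev = np.asarray(self.explained_variance, dtype=float)
        if ev.shape != (2,) or (ev < -1e-12).any() or (ev > 1 + 1e-12).any():
            raise ValueError("explained_variance must be two fractions")
        if ev[0] + 1e-12 < ev[1]:
            raise ValueError("explained_variance must be non-increasing")


@dataclass
class HomogeneityCall:
    n_clusters: int
    call: str  # "homogeneous" | "heterogeneous"
    criterion_values: dict[int, float]
    low_confidence: bool = False

    def __post_init__(self):
        if self.call != ("homogeneous" if self.n_clusters == 1
                         else "heterogeneous"):
            raise ValueError("call must mirror n_clusters")


def aps_project(m: EventMatrix, markers: list[str] | None = None
                ) -> APSProjection:
    """Standardized PCA of the blast events over all channels.

    Channels are standardized to zero mean and unit variance before the
    decomposition (so scatter's instrument units do not dominate); the
    sign convention makes each component's largest-magnitude loading
    positive. Channels with zero variance are dropped; if fewer than two
    informative channels remain the covariance is degenerate.
    """
    if markers is None:
        markers = [c.marker for c in m.channels]
    if m.n_events < 3:
        raise ValueError("aps_project needs at least 3 events")
    X = np.column_stack([m.get(mk) for mk in markers])
    sd = X.std(axis=0, ddof=1)  # ddof=1 so eigenvalues sum to n_channels
    keep = sd > 1e-12
    if keep.sum() < 2:
        raise ValueError("degenerate covariance")
    kept = [mk for mk, k in zip(markers, keep) if k]
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]

    pca = PCA(n_components=min(Z.shape)).fit(Z)
    comps = pca.components_[:2].copy()
    scores = pca.transform(Z)[:, :2].copy()
    for i in range(2):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] *= -1.0
            scores[:, i] *= -1.0
    return APSProjection(
        scores=scores,
        explained_variance=pca.explained_variance_ratio_[:2].copy(),
        components=comps,
        channels=kept,
        eigenvalues=pca.explained_variance_.copy(),
    )


def count_clusters(proj: APSProjection, k_max: int = 4, seed: int = 0,
                   min_events: int = 100, bic_margin: float = 10.0,
                   n_init: int = 5, max_events: int = 2000) -> HomogeneityCall:
    """Number of blast subclones in the 2-D APS scores.

    Gaussian mixtures with full covariances are fitted for k = 1..k_max
    (k-means++ initialization, ``n_init`` restarts, best likelihood kept)
    and k is selected by BIC with a parsimony margin: a larger k wins only
    if its BIC improves on the current best by at least ``bic_margin``
    (strong-evidence convention). Samples smaller than ``min_events`` are
    called homogeneous with a low-confidence flag. ``max_events`` caps the
    number of events fitted (seeded subsample) to keep runtime flat.
    """
    scores = np.asarray(proj.scores, dtype=float)
    if len(scores) < min_events:
        return HomogeneityCall(1, "homogeneous", {}, low_confidence=True)
    rng = np.random.default_rng(seed)
    if len(scores) > max_events:
        scores = scores[rng.choice(len(scores), max_events, replace=False)]
    bic: dict[int, float] = {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, covariance_type="full", n_init=n_init,
            init_params="k-means++", random_state=seed, reg_covar=1e-6,
        ).fit(scores)
        bic[k] = float(gm.bic(scores))
    best_k = 1
    for k in range(2, k_max + 1):
        if bic[k] <= bic[best_k] - bic_margin:
            best_k = k
    return HomogeneityCall(
        best_k,
        "homogeneous" if best_k == 1 else "heterogeneous",
        bic,
    )
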