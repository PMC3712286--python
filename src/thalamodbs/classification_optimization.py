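"""Clustering of stimulation regimes and brute-force excitability fitting.

Feature vectors of simulated (or real) LFP segments are clustered with a
k-means under the Mahalanobis metric induced by the pooled covariance of
all vectors — equivalently, Lloyd iterations in the whitened space.  The
cortical excitability triplet (A_C, B_C, G_C) is fitted by exhaustive
grid search minimizing the Euclidean distance between the average
feature vector of simulated segments and a target feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import feature_extraction as fx
from . import model_core as mc
from .stimulation import StimProtocol

__all__ = [
    "ClusterResult",
    "GridSpec",
    "OptimResult",
    "mahalanobis_kmeans",
    "condition_features",
    "regime_classification",
    "expected_grouping",
    "grouping_matches",
    "brute_force_optimize",
]


# ---------------------------------------------------------------------------
# Mahalanobis k-means
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    labels: np.ndarray
    centroids: np.ndarray            # in the original feature space
    inertia: float                   # total intra-cluster Mahalanobis dispersion
    inertia_history: list[float]     # per-Lloyd-iteration, best restart
    seed: int
    n_restarts: int
    covariance: np.ndarray


def _whitener(X: np.ndarray, ridge: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Symmetric inverse square root of the pooled covariance (ridged)."""
    cov = np.cov(X, rowvar=False)
    cov = np.atleast_2d(cov)
    evals = np.linalg.eigvalsh(cov)
    regularized = evals.min() < ridge * max(evals.max(), 1e-30)
    cov_r = cov + ridge * max(np.trace(cov) / cov.shape[0], 1e-30) * np.eye(cov.shape[0])
    evals, evecs = np.linalg.eigh(cov_r)
    w = evecs @ np.diag(evals ** -0.5) @ evecs.T
    return w, cov, regularized


def mahalanobis_kmeans(
    vectors: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 25,
    ridge: float = 1e-8,
    max_iter: int = 300,
    cov: np.ndarray | None = None,
) -> ClusterResult:
    """Lloyd k-means under the pooled-covariance Mahalanobis distance.

    The pooled covariance of all vectors defines the metric
    ``d(x, c) = sqrt((x-c)^T S^-1 (x-c))``; clustering runs as Euclidean
    Lloyd iterations on whitened data with ``n_restarts`` seeded random
    initializations, keeping the solution of least inertia.  A singular
    covariance (band fractions sum to one, so the pooled covariance is
    always rank-deficient by one) is ridge-regularized; a fixed metric can
    be supplied through ``cov``.
    """
    X = np.asarray(vectors, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < k:
        raise ValueError("need at least k vectors")
    n = X.shape[0]
    if cov is None:
        W, cov, _ = _whitener(X, ridge)
    else:
        cov = np.asarray(cov, dtype=np.float64)
        evals, evecs = np.linalg.eigh(cov)
        if evals.min() <= 0:
            raise ValueError("supplied covariance must be positive definite")
        W = evecs @ np.diag(evals ** -0.5) @ evecs.T
    Z = X @ W

    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=k, replace=False)
        C = Z[idx].copy()
        labels = np.full(n, -1)
        history: list[float] = []
        for _ in range(max_iter):
            d2 = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)
            new_labels = np.argmin(d2, axis=1)
            inertia = float(d2[np.arange(n), new_labels].sum())
            history.append(inertia)
            if np.array_equal(new_labels, labels):
                break
            labels = new_labels
            for j in range(k):
                members = Z[labels == j]
                if len(members):
                    C[j] = members.mean(axis=0)
                else:  # re-seed an empty cluster at the worst-fitted point
                    C[j] = Z[int(np.argmax(d2[np.arange(n), labels]))]
        if best is None or history[-1] < best[0]:
            best = (history[-1], labels.copy(), C.copy(), history)
    inertia, labels, C, history = best
    W_inv = np.linalg.inv(W)
    return ClusterResult(
        labels=labels,
        centroids=C @ W_inv,
        inertia=inertia,
        inertia_history=history,
        seed=seed,
        n_restarts=n_restarts,
        covariance=cov,
    )


# ---------------------------------------------------------------------------
# Stimulation-regime classification
# ---------------------------------------------------------------------------

#: Conditions of the regime-classification experiment: label -> f_s (Hz).
DEFAULT_CONDITIONS = {
    "NS": 0.0,
    "LFS2": 2.0,
    "IFS50": 50.0,
    "HFS70": 70.0,
    "HFS100": 100.0,
    "HFS150": 150.0,
}


def condition_features(
    params: mc.ModelParameters,
    conditions: dict[str, float] | None = None,
    n_segments: int = 5,
    seg_duration: float = 5.0,
    burn_in: float = 2.0,
    seed: int = 0,
    max_atoms: int = 60,
    min_residual_fraction: float = 0.05,
) -> dict[str, np.ndarray]:
    """Simulate each stimulation condition and extract per-segment features.

    Returns a mapping condition -> (n_segments, 9) array of band-energy
    vectors of the cortical LFP.
    """
    conditions = DEFAULT_CONDITIONS if conditions is None else conditions
    seeds = mc.spawn_seeds(seed, len(conditions))
    n_samples = int(round(seg_duration * mc.OUTPUT_RATE))
    dico = fx.build_dictionary(n_samples, mc.OUTPUT_RATE)
    out: dict[str, np.ndarray] = {}
    for (label, f_s), s in zip(conditions.items(), seeds):
        protocol = None if f_s == 0 else StimProtocol(f_s=f_s)
        segs, _ = mc.simulate_segments(
            params, protocol, n_segments, seg_duration, burn_in=burn_in, seed=s)
        feats = [
            fx.band_features(seg, mc.OUTPUT_RATE, dictionary=dico,
                             max_atoms=max_atoms,
                             min_residual_fraction=min_residual_fraction).e
            for seg in segs
        ]
        out[label] = np.vstack(feats)
    return out


def regime_classification(
    features_by_condition: dict[str, np.ndarray],
    k: int = 3,
    seed: int = 0,
    n_restarts: int = 25,
    use_3d: bool = False,
) -> tuple[ClusterResult, dict[str, int]]:
    """Cluster per-condition feature vectors and map conditions to clusters.

    Each condition is assigned the cluster holding the majority of its
    segments.  Clustering runs in the 9-D feature space by default (the
    3-D projection is primarily for display and available via
    ``use_3d``).
    """
    labels_order = list(features_by_condition)
    X = np.vstack([features_by_condition[c] for c in labels_order])
    if use_3d:
        X = np.vstack([fx.project_3d(x) for x in X])
    res = mahalanobis_kmeans(X, k, seed=seed, n_restarts=n_restarts)
    regime_map: dict[str, int] = {}
    i = 0
    for c in labels_order:
        m = len(features_by_condition[c])
        seg_labels = res.labels[i:i + m]
        regime_map[c] = int(np.bincount(seg_labels, minlength=k).argmax())
        i += m
    return res, regime_map


def expected_grouping() -> list[set[str]]:
    """Published grouping of the six conditions into three regimes."""
    return [{"LFS2"}, {"NS", "IFS50"}, {"HFS70", "HFS100", "HFS150"}]


def grouping_matches(regime_map: dict[str, int],
                     groups: list[set[str]] | None = None) -> bool:
    """True when the condition -> cluster map realizes the expected partition."""
    groups = expected_grouping() if groups is None else groups
    partition: dict[int, set[str]] = {}
    for cond, lab in regime_map.items():
        partition.setdefault(lab, set()).add(cond)
    got = sorted(map(sorted, partition.values()))
    want = sorted(map(sorted, groups))
    return got == want


# ---------------------------------------------------------------------------
# Brute-force excitability fitting
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Search grid over the cortical excitability triplet (A_C, B_C, G_C)."""

    a_c: np.ndarray = field(
        default_factory=lambda: np.arange(2.0, 8.0 + 1e-9, 0.5))
    b_c: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 50.0 + 1e-9, 3.0))
    g_c: np.ndarray = field(
        default_factory=lambda: np.arange(5.0, 25.0 + 1e-9, 1.5))

    def __post_init__(self):
        for name in ("a_c", "b_c", "g_c"):
            ax = np.asarray(getattr(self, name), dtype=float)
            if ax.size == 0 or not np.all(np.isfinite(ax)):
                raise ValueError(f"grid axis {name} must be finite and non-empty")
            setattr(self, name, ax)

    @property
    def shape(self) -> tuple[int, int, int]:
        return len(self.a_c), len(self.b_c), len(self.g_c)


@dataclass
class OptimResult:
    best: tuple[float, float, float]
    best_distance: float
    distance: np.ndarray        # shape (len(a_c), len(b_c), len(g_c))
    invalid: np.ndarray         # True where the simulation diverged
    grid: GridSpec
    target: np.ndarray
    seeds: list[int]
    n_segments: int
    seg_duration: float


def model_feature_vector(
    params: mc.ModelParameters,
    seeds: list[int],
    n_segments: int = 2,
    seg_duration: float = 5.0,
    burn_in: float = 2.0,
    dictionary: fx.MPDictionary | None = None,
    max_atoms: int = 60,
    min_residual_fraction: float = 0.05,
) -> np.ndarray:
    """Average band-energy vector of no-stimulation runs over fixed seeds."""
    if dictionary is None:
        n_samples = int(round(seg_duration * mc.OUTPUT_RATE))
        dictionary = fx.build_dictionary(n_samples, mc.OUTPUT_RATE)
    feats = []
    for s in seeds:
        segs, _ = mc.simulate_segments(
            params, None, n_segments, seg_duration, burn_in=burn_in, seed=s)
        feats.extend(
            fx.band_features(seg, mc.OUTPUT_RATE, dictionary=dictionary,
                             max_atoms=max_atoms,
                             min_residual_fraction=min_residual_fraction).e
            for seg in segs
        )
    return np.mean(feats, axis=0)


def brute_force_optimize(
    target: np.ndarray,
    grid: GridSpec | None = None,
    base_params: mc.ModelParameters | None = None,
    seeds: list[int] | None = None,
    n_segments: int = 2,
    seg_duration: float = 5.0,
    burn_in: float = 2.0,
    max_atoms: int = 60,
    min_residual_fraction: float = 0.05,
) -> OptimResult:
    """Exhaustive search of (A_C, B_C, G_C) minimizing feature distance.

    For every triplet of the grid the model is simulated without
    stimulation using the same fixed seed list, the per-segment feature
    vectors are averaged, and the Euclidean distance to ``target`` is
    recorded; the argmin triplet and the full distance surface are
    returned.  Grid points where the simulation diverges are marked
    invalid and excluded from the argmin.
    """
    target = np.asarray(target, dtype=np.float64)
    if target.shape != (9,):
        raise ValueError("target must be a 9-component feature vector")
    grid = grid or GridSpec()
    base = base_params or mc.default_parameters("pathological")
    seeds = [0, 1] if seeds is None else list(seeds)
    n_samples = int(round(seg_duration * mc.OUTPUT_RATE))
    dico = fx.build_dictionary(n_samples, mc.OUTPUT_RATE)

    dist = np.full(grid.shape, np.nan)
    invalid = np.zeros(grid.shape, dtype=bool)
    for i, a in enumerate(grid.a_c):
        for j, b in enumerate(grid.b_c):
            for l, g in enumerate(grid.g_c):
                p = base.copy(A_C=float(a), B_C=float(b), G_C=float(g))
                try:
                    v = model_feature_vector(
                        p, seeds, n_segments=n_segments,
                        seg_duration=seg_duration, burn_in=burn_in,
                        dictionary=dico, max_atoms=max_atoms,
                        min_residual_fraction=min_residual_fraction)
                except mc.SimulationDiverged:
                    invalid[i, j, l] = True
                    continue
                dist[i, j, l] = float(np.linalg.norm(v - target))
    if np.all(invalid):
        raise RuntimeError("every grid point diverged")
    masked = np.where(invalid, np.inf, dist)
    i, j, l = np.unravel_index(np.nanargmin(masked), grid.shape)
    return OptimResult(
        best=(float(grid.a_c[i]), float(grid.b_c[j]), float(grid.g_c[l])),
        best_distance=float(dist[i, j, l]),
        distance=dist,
        invalid=invalid,
        grid=grid,
        target=target,
        seeds=seeds,
        n_segments=n_segments,
        seg_duration=seg_duration,
    )
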