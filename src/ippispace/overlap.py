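"""Chemical-space overlap: joint PCA, per-component densities, Weitzman Δ.

The overlap between two compound collections is quantified in the principal
component space of the *whole* collection under study:

1.  All datasets are pooled and every descriptor is standardized to zero
    mean and unit variance before a full-rank PCA (all components kept, so
    the variance fractions V_i sum to 100%).
2.  On each component, a Gaussian kernel density estimate is computed for
    each dataset's scores, with the classical rule-of-thumb bandwidth
    0.9 * min(SD, IQR/1.34) * n^(-1/5) evaluated on a 512-point grid
    extended three bandwidths beyond the sample range.
3.  The one-component overlap is Weitzman's measure,
    delta = integral of min(f1, f2), evaluated on a shared 1,024-point grid
    spanning the union of both supports.
4.  The overlap score is the variance-weighted mean
    Delta = sum_i delta_i * V_i / sum_i V_i over all components, a number in
    [0, 1]: 1 for identical datasets, 0 for disjoint ones.

Because the PCA is fitted on the union of all datasets being compared, a
Delta value depends on the collection it was computed within, not only on
the two datasets of the pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

logger = logging.getLogger(__name__)

KDE_GRID_POINTS = 512
KDE_CUT_BANDWIDTHS = 3.0
COMMON_GRID_POINTS = 1024
MIN_DATASET_SIZE = 5


@dataclass
class PCAModel:
    """Standardization + loadings + scores of a joint scaled PCA."""

    loadings: pd.DataFrame  # descriptors x components
    scores: pd.DataFrame  # compounds x components
    variance_fractions: np.ndarray  # percent per component, sums to 100
    scaling_mean: pd.Series
    scaling_sd: pd.Series

    @property
    def n_components(self) -> int:
        return len(self.variance_fractions)

    def transform(self, frame: pd.DataFrame) -> pd.DataFrame:
        """Project new rows (same descriptors) onto the fitted components."""
        x = (frame[self.scaling_mean.index] - self.scaling_mean) / self.scaling_sd
        scores = x.to_numpy() @ self.loadings.to_numpy()
        return pd.DataFrame(scores, index=frame.index, columns=self.loadings.columns)


def fit_pca(matrix: pd.DataFrame, descriptors: list[str]) -> PCAModel:
    """Scaled full-rank PCA over all rows of ``matrix``.

    Each descriptor is standardized to zero mean / unit variance first; all
    components are retained so the variance fractions reach 100%.
    """
    if len(matrix) < 2:
        raise ValueError("need at least two compounds")
    missing = [d for d in descriptors if d not in matrix.columns]
    if missing:
        raise ValueError(f"descriptors not in table: {missing}")
    x = matrix[descriptors].to_numpy(dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("descriptor columns contain non-finite values")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    dead = [d for d, s in zip(descriptors, sd) if s == 0]
    if dead:
        raise ValueError(f"zero-variance descriptors: {dead}")
    z = (x - mean) / sd
    pca = PCA(n_components=len(descriptors), svd_solver="full")
    scores = pca.fit_transform(z)
    comp_names = [f"PC{i + 1}" for i in range(len(descriptors))]
    return PCAModel(
        loadings=pd.DataFrame(pca.components_.T, index=descriptors, columns=comp_names),
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        variance_fractions=100.0 * pca.explained_variance_ratio_,
        scaling_mean=pd.Series(mean, index=descriptors),
        scaling_sd=pd.Series(sd, index=descriptors),
    )


@dataclass
class DensityEstimate:
    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def rule_of_thumb_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 * min(SD, IQR/1.34) * n^(-1/5)."""
    sd = np.std(x, ddof=1)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    if spread == 0:
        raise ValueError("cannot estimate a density for a constant sample")
    return 0.9 * spread * len(x) ** (-0.2)


def kde_1d(
    x,
    bandwidth: float | None = None,
    n_grid: int = KDE_GRID_POINTS,
    cut: float = KDE_CUT_BANDWIDTHS,
) -> DensityEstimate:
    """Gaussian KDE on a regular grid extended ``cut`` bandwidths past the
    sample range."""
    x = np.asarray(x, dtype=float)
    if bandwidth is None:
        bandwidth = rule_of_thumb_bandwidth(x)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x.min() - cut * bandwidth, x.max() + cut * bandwidth, n_grid)
    # evaluate in chunks to bound the n x grid kernel matrix
    dens = np.zeros(n_grid)
    inv = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    for start in range(0, len(x), 4096):
        chunk = x[start : start + 4096, None]
        dens += np.exp(-0.5 * ((grid[None, :] - chunk) / bandwidth) ** 2).sum(axis=0)
    dens *= inv / len(x)
    return DensityEstimate(grid=grid, density=dens, bandwidth=float(bandwidth))


def weitzman_delta(f1: DensityEstimate, f2: DensityEstimate) -> float:
    """Weitzman's overlapping coefficient: integral of min(f1, f2).

    Both densities are linearly interpolated onto a shared grid spanning
    the union of their supports (density 0 outside each estimate's own
    grid) and the minimum is integrated trapezoidally.
    """
    for i, f in enumerate((f1, f2), start=1):
        err = abs(f.integral() - 1.0)
        if err > 1e-2:
            raise ValueError(f"density {i} is not normalized (integral off by {err:.3g})")
    lo = min(f1.grid[0], f2.grid[0])
    hi = max(f1.grid[-1], f2.grid[-1])
    grid = np.linspace(lo, hi, COMMON_GRID_POINTS)
    d1 = np.interp(grid, f1.grid, f1.density, left=0.0, right=0.0)
    d2 = np.interp(grid, f2.grid, f2.density, left=0.0, right=0.0)
    delta = float(np.trapezoid(np.minimum(d1, d2), grid))
    return min(delta, 1.0)


def weighted_mean_overlap(deltas, variance_fractions) -> float:
    """Delta = sum_i delta_i * V_i / sum_i V_i (arithmetic mean weighted by
    each component's variance fraction)."""
    deltas = np.asarray(deltas, dtype=float)
    v = np.asarray(variance_fractions, dtype=float)
    if deltas.shape != v.shape:
        raise ValueError("deltas and variance fractions differ in length")
    return float((deltas * v).sum() / v.sum())


def overlap_score(
    scores_a: pd.DataFrame | np.ndarray,
    scores_b: pd.DataFrame | np.ndarray,
    variance_fractions: np.ndarray,
) -> float:
    """Variance-weighted mean of per-component Weitzman overlaps.

    Both score sets must come from the same fitted PCA.  Components with a
    zero variance fraction carry zero weight and are skipped.
    """
    return component_overlaps(scores_a, scores_b, variance_fractions)[1]


def component_overlaps(
    scores_a, scores_b, variance_fractions
) -> tuple[np.ndarray, float]:
    """Per-component deltas plus the weighted score, for reporting."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    v = np.asarray(variance_fractions, dtype=float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1] or a.shape[1] != len(v):
        raise ValueError(
            f"component counts differ: {a.shape[1:]}, {b.shape[1:]}, {len(v)}"
        )
    deltas = np.zeros(len(v))
    for i, vi in enumerate(v):
        if vi <= 0:
            continue
        deltas[i] = weitzman_delta(kde_1d(a[:, i]), kde_1d(b[:, i]))
    return deltas, weighted_mean_overlap(deltas, v)


@dataclass
class OverlapMatrix:
    labels: list[str]
    values: pd.DataFrame  # symmetric, unit diagonal, entries in [0, 1]
    per_component: pd.DataFrame | None = None  # long-format pair table

    def validate(self) -> None:
        v = self.values.to_numpy()
        if not np.allclose(v, v.T):
            raise ValueError("overlap matrix must be symmetric")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("overlap scores must lie in [0, 1]")

    def write(self, path, pairs_path=None) -> None:
        self.values.to_csv(path, index=True, index_label="dataset")
        if pairs_path is not None and self.per_component is not None:
            self.per_component.to_csv(pairs_path, index=False)


def pairwise_overlap(
    collection: pd.DataFrame,
    descriptors: list[str],
    dataset_col: str = "dataset",
) -> OverlapMatrix:
    """Delta for every unordered pair of datasets in one joint PCA space.

    Datasets with fewer than :data:`MIN_DATASET_SIZE` rows are dropped with
    a log message.  The diagonal is set to 1 by definition.
    """
    sizes = collection[dataset_col].value_counts()
    labels = [l for l in collection[dataset_col].unique() if sizes[l] >= MIN_DATASET_SIZE]
    dropped = [l for l in sizes.index if sizes[l] < MIN_DATASET_SIZE]
    for l in dropped:
        logger.info("dataset %r dropped: only %d rows", l, sizes[l])
    if len(labels) < 2:
        raise ValueError("need at least two datasets with >= 5 members")
    subset = collection[collection[dataset_col].isin(labels)]
    model = fit_pca(subset, descriptors)
    scores = {
        l: model.scores[subset[dataset_col].to_numpy() == l].to_numpy() for l in labels
    }
    n = len(labels)
    mat = np.eye(n)
    rows = []
    for i in range(n):
        for j in range(i + 1, n):
            deltas, score = component_overlaps(
                scores[labels[i]], scores[labels[j]], model.variance_fractions
            )
            mat[i, j] = mat[j, i] = score
            rows.append(
                {
                    "dataset_a": labels[i],
                    "dataset_b": labels[j],
                    **{f"delta_PC{k + 1}": d for k, d in enumerate(deltas)},
                    "Delta": score,
                }
            )
    values = pd.DataFrame(mat, index=labels, columns=labels)
    result = OverlapMatrix(labels=labels, values=values, per_component=pd.DataFrame(rows))
    result.validate()
    return result
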