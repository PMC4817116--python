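"""Combination of sub-pocket cavity descriptors into whole-pocket vectors.

Cavity-detection software describes a binding pocket as a set of grid
points, each labelled with one of eight pharmacophoric features
(hydrophobic, aromatic, H-bond acceptor, negative ionizable, H-bond
acceptor/donor, H-bond donor, positive ionizable, dummy), reported as a
total point count, per-feature percentages, and per-feature percentages
binned by a projection distance.  When a pocket is detected as several
sub-cavities, their records are merged with a count-weighted rule:
percentages are converted back to point counts, the counts are summed, and
the sums are renormalised by the combined total.

The whole-pocket vector used for pocket-space clustering has 117 entries:
89 base descriptors (total count + 8 feature percentages + 8x10 binned
percentages), 10 per-distance sums over the eight features, and 18 shape
descriptors computed externally on the pocket's negative image (globularity,
normalized PMI ratios, radius of gyration, volume, surface area, ...).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

FEATURES = (
    "hydrophobic",
    "aromatic",
    "h_bond_acceptor",
    "negative_ionizable",
    "h_bond_acceptor_donor",
    "h_bond_donor",
    "positive_ionizable",
    "dummy",
)

#: Ten projection-distance bins; edges are configurable in principle but the
#: canonical layout spans 0-100 in steps of 10 (e.g. "between 40 and 50").
DISTANCE_BIN_EDGES = tuple(float(x) for x in range(0, 110, 10))
DISTANCE_BINS = tuple(
    f"{int(lo)}-{int(hi)}" for lo, hi in zip(DISTANCE_BIN_EDGES[:-1], DISTANCE_BIN_EDGES[1:])
)

SHAPE_DESCRIPTORS = (
    "glob",
    "npr1",
    "npr2",
    "pmi",
    "pmi1",
    "pmi2",
    "pmi3",
    "pmiX",
    "pmiY",
    "pmiZ",
    "rgyr",
    "std_dim1",
    "std_dim2",
    "std_dim3",
    "vol",
    "VSA",
    "Vsurf_G",
    "Vsurf_R",
)

_PCT_TOL = 1e-6


@dataclass
class SubPocketRecord:
    """One sub-cavity: point count, feature percentages, binned percentages."""

    nb_tot: float
    feature_pct: dict[str, float]
    dist_pct: dict[tuple[str, str], float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.nb_tot <= 0:
            raise ValueError("nb_tot must be positive")
        missing = set(FEATURES) - set(self.feature_pct)
        if missing:
            raise ValueError(f"missing feature percentages: {sorted(missing)}")
        total = sum(self.feature_pct[f] for f in FEATURES)
        if abs(total - 100.0) > _PCT_TOL:
            raise ValueError(f"feature percentages sum to {total!r}, expected 100")
        if self.dist_pct:
            for f in FEATURES:
                s = sum(self.dist_pct.get((f, b), 0.0) for b in DISTANCE_BINS)
                if abs(s - self.feature_pct[f]) > _PCT_TOL:
                    raise ValueError(
                        f"distance-binned percentages for feature {f!r} sum to "
                        f"{s!r}, expected {self.feature_pct[f]!r}"
                    )

    def feature_counts(self) -> dict[str, float]:
        """Point counts per feature (percent x total / 100); kept as reals."""
        return {f: self.feature_pct[f] * self.nb_tot / 100.0 for f in FEATURES}


def combine_subpockets(subs: Sequence[SubPocketRecord]) -> SubPocketRecord:
    """Merge sub-cavities into one pocket record.

    Totals add; per-(feature[, bin]) percentages are converted to counts,
    summed, and renormalised by the combined total.  A single record is
    returned unchanged.
    """
    if not subs:
        raise ValueError("need at least one sub-pocket")
    for s in subs:
        s.validate()
    if len(subs) == 1:
        return subs[0]
    nb_tot = sum(s.nb_tot for s in subs)
    feature_pct = {
        f: 100.0 * sum(s.feature_counts()[f] for s in subs) / nb_tot for f in FEATURES
    }
    dist_pct: dict[tuple[str, str], float] = {}
    if any(s.dist_pct for s in subs):
        for f in FEATURES:
            for b in DISTANCE_BINS:
                count = sum(
                    s.dist_pct.get((f, b), 0.0) * s.nb_tot / 100.0 for s in subs
                )
                dist_pct[(f, b)] = 100.0 * count / nb_tot
    return SubPocketRecord(nb_tot=nb_tot, feature_pct=feature_pct, dist_pct=dist_pct)


def distance_sums(record: SubPocketRecord) -> dict[str, float]:
    """Sum of the eight features' percentages at each of the 10 distances."""
    record.validate()
    if not record.dist_pct:
        raise ValueError("record has no distance-binned percentages")
    return {
        b: sum(record.dist_pct.get((f, b), 0.0) for f in FEATURES)
        for b in DISTANCE_BINS
    }


def pocket_vector_columns() -> list[str]:
    """The fixed 117-column order of a whole-pocket descriptor vector."""
    cols = ["nb_tot"]
    cols += [f"pct_{f}" for f in FEATURES]
    cols += [f"pct_{f}_{b}" for f in FEATURES for b in DISTANCE_BINS]
    cols += [f"dist_sum_{b}" for b in DISTANCE_BINS]
    cols += [f"shape_{s}" for s in SHAPE_DESCRIPTORS]
    return cols


def assemble_vector(
    combined: SubPocketRecord, shape: Mapping[str, float] | Sequence[float]
) -> pd.Series:
    """Assemble the 117-entry pocket vector from a combined record + shape.

    ``shape`` is either a mapping over :data:`SHAPE_DESCRIPTORS` or a
    sequence of 18 values in that order.
    """
    combined.validate()
    if isinstance(shape, Mapping):
        missing = set(SHAPE_DESCRIPTORS) - set(shape)
        if missing:
            raise ValueError(f"missing shape descriptors: {sorted(missing)}")
        shape_vals = [float(shape[s]) for s in SHAPE_DESCRIPTORS]
    else:
        shape_vals = [float(v) for v in shape]
        if len(shape_vals) != len(SHAPE_DESCRIPTORS):
            raise ValueError(
                f"expected {len(SHAPE_DESCRIPTORS)} shape descriptors, "
                f"got {len(shape_vals)}"
            )
    sums = distance_sums(combined)
    values = [float(combined.nb_tot)]
    values += [combined.feature_pct[f] for f in FEATURES]
    values += [combined.dist_pct.get((f, b), 0.0) for f in FEATURES for b in DISTANCE_BINS]
    values += [sums[b] for b in DISTANCE_BINS]
    values += shape_vals
    vec = pd.Series(values, index=pocket_vector_columns(), dtype=float)
    if not np.all(np.isfinite(vec.to_numpy())):
        raise ValueError("pocket vector contains non-finite values")
    return vec


def pocket_distances(
    vectors: pd.DataFrame | Sequence[pd.Series], standardize: bool = True
) -> pd.DataFrame:
    """Pairwise Euclidean distances between whole-pocket vectors.

    By default each descriptor is z-scored across pockets first (the 117
    descriptors mix counts, percentages and shape measures on very
    different scales); constant descriptors then contribute nothing.
    Set ``standardize=False`` for raw distances.
    """
    if not isinstance(vectors, pd.DataFrame):
        vectors = pd.DataFrame(list(vectors))
    if vectors.shape[0] < 2:
        raise ValueError("need at least two pocket vectors")
    if vectors.shape[1] != len(pocket_vector_columns()):
        raise ValueError(
            f"pocket vectors must have {len(pocket_vector_columns())} entries, "
            f"got {vectors.shape[1]}"
        )
    x = vectors.to_numpy(dtype=float)
    if standardize:
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=1)
        keep = sd > 0
        x = (x[:, keep] - mu[keep]) / sd[keep]
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(x, metric="euclidean"))
    return pd.DataFrame(d, index=vectors.index, columns=vectors.index)


# ---------------------------------------------------------------------------
# text round trips

def _flat_record(record: SubPocketRecord) -> dict[str, float]:
    row: dict[str, float] = {"nb_tot": record.nb_tot}
    for f in FEATURES:
        row[f"pct_{f}"] = record.feature_pct[f]
    for f in FEATURES:
        for b in DISTANCE_BINS:
            row[f"pct_{f}_{b}"] = record.dist_pct.get((f, b), 0.0)
    return row


def write_subpockets(records: Sequence[SubPocketRecord], path) -> None:
    pd.DataFrame([_flat_record(r) for r in records]).to_csv(path, index=False, float_format="%.17g")


def read_subpockets(path) -> list[SubPocketRecord]:
    frame = pd.read_csv(path, float_precision="round_trip")
    records = []
    for _, row in frame.iterrows():
        records.append(
            SubPocketRecord(
                nb_tot=float(row["nb_tot"]),
                feature_pct={f: float(row[f"pct_{f}"]) for f in FEATURES},
                dist_pct={
                    (f, b): float(row[f"pct_{f}_{b}"])
                    for f in FEATURES
                    for b in DISTANCE_BINS
                },
            )
        )
    return records


def write_pocket_vectors(vectors: pd.DataFrame, path) -> None:
    vectors.to_csv(path, index=True, index_label="pocket", float_format="%.17g")


def read_pocket_vectors(path) -> pd.DataFrame:
    return pd.read_csv(path, index_col="pocket", float_precision="round_trip")


def subpocket_from_points(points: pd.DataFrame) -> SubPocketRecord:
    """Tally a probe-point table (x, y, z, feature) into a sub-pocket record.

    The projection distance of each point is its Euclidean distance to the
    point-cloud centroid, binned over :data:`DISTANCE_BIN_EDGES` (distances
    beyond the last edge land in the final bin).
    """
    required = {"x", "y", "z", "feature"}
    if not required <= set(points.columns):
        raise ValueError(f"point table needs columns {sorted(required)}")
    unknown = set(points["feature"]) - set(FEATURES)
    if unknown:
        raise ValueError(f"unknown feature labels: {sorted(unknown)}")
    xyz = points[["x", "y", "z"]].to_numpy(dtype=float)
    dist = np.linalg.norm(xyz - xyz.mean(axis=0), axis=1)
    idx = np.clip(
        np.searchsorted(DISTANCE_BIN_EDGES[1:], dist, side="left"),
        0,
        len(DISTANCE_BINS) - 1,
    )
    n = len(points)
    feature_pct = {f: 0.0 for f in FEATURES}
    dist_pct = {(f, b): 0.0 for f in FEATURES for b in DISTANCE_BINS}
    for f, i in zip(points["feature"], idx):
        feature_pct[f] += 100.0 / n
        dist_pct[(f, DISTANCE_BINS[i])] += 100.0 / n
    return SubPocketRecord(nb_tot=float(n), feature_pct=feature_pct, dist_pct=dist_pct)
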