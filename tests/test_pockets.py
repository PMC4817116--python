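"""Sub-pocket combination arithmetic and the 117-descriptor pocket vector."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ippispace import (
    SubPocketRecord,
    assemble_vector,
    combine_subpockets,
    distance_sums,
    generate_subpockets,
    pocket_distances,
)
from ippispace.pockets import (
    DISTANCE_BINS,
    FEATURES,
    SHAPE_DESCRIPTORS,
    pocket_vector_columns,
    read_pocket_vectors,
    read_subpockets,
    subpocket_from_points,
    write_pocket_vectors,
    write_subpockets,
)

PROFILE = {
    "hydrophobic": 40.0,
    "aromatic": 20.0,
    "h_bond_acceptor": 10.0,
    "negative_ionizable": 5.0,
    "h_bond_acceptor_donor": 5.0,
    "h_bond_donor": 10.0,
    "positive_ionizable": 5.0,
    "dummy": 5.0,
}


def simple_record(nb_tot, hyd_pct, spread_bin="40-50"):
    """A record with hyd_pct hydrophobic and the remainder dummy points,
    all mass in one distance bin per feature."""
    pct = {f: 0.0 for f in FEATURES}
    pct["hydrophobic"] = hyd_pct
    pct["dummy"] = 100.0 - hyd_pct
    dist = {(f, b): 0.0 for f in FEATURES for b in DISTANCE_BINS}
    dist[("hydrophobic", spread_bin)] = hyd_pct
    dist[("dummy", spread_bin)] = 100.0 - hyd_pct
    return SubPocketRecord(nb_tot=nb_tot, feature_pct=pct, dist_pct=dist)


class TestCombine:
    def test_count_weighted_percentages(self):
        # 100 points at 40% + 50 points at 20% -> 150 points, 50/150 = 33.33%
        combined = combine_subpockets([simple_record(100, 40.0), simple_record(50, 20.0)])
        assert combined.nb_tot == 150
        assert combined.feature_pct["hydrophobic"] == pytest.approx(100 * 50 / 150)
        assert combined.dist_pct[("hydrophobic", "40-50")] == pytest.approx(100 * 50 / 150)

    def test_single_record_identity(self):
        rec = simple_record(100, 40.0)
        assert combine_subpockets([rec]) is rec

    def test_identical_records_keep_percentages(self):
        rec = simple_record(80, 25.0)
        combined = combine_subpockets([rec, simple_record(80, 25.0)])
        assert combined.nb_tot == 160
        for f in FEATURES:
            assert combined.feature_pct[f] == pytest.approx(rec.feature_pct[f])

    def test_point_conservation_is_exact(self):
        recs = generate_subpockets(5, PROFILE, seed=10)
        combined = combine_subpockets(recs)
        assert combined.nb_tot == sum(r.nb_tot for r in recs)

    def test_percentage_conservation(self):
        recs = generate_subpockets(4, PROFILE, seed=11)
        combined = combine_subpockets(recs)
        assert sum(combined.feature_pct.values()) == pytest.approx(100.0, abs=1e-6)
        for f in FEATURES:
            binned = sum(combined.dist_pct[(f, b)] for b in DISTANCE_BINS)
            assert binned == pytest.approx(combined.feature_pct[f], abs=1e-6)

    def test_associativity(self):
        a, b, c = generate_subpockets(3, PROFILE, seed=12)
        left = combine_subpockets([combine_subpockets([a, b]), c])
        flat = combine_subpockets([a, b, c])
        assert left.nb_tot == flat.nb_tot
        for f in FEATURES:
            assert left.feature_pct[f] == pytest.approx(flat.feature_pct[f], abs=1e-9)
            for bin_ in DISTANCE_BINS:
                assert left.dist_pct[(f, bin_)] == pytest.approx(
                    flat.dist_pct[(f, bin_)], abs=1e-9
                )

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(
            st.tuples(st.integers(10, 500), st.floats(0.0, 100.0)),
            min_size=2,
            max_size=5,
        )
    )
    def test_conservation_property(self, recs):
        """Counts add exactly and percentages stay on the simplex for any
        stack of valid sub-pockets."""
        subs = [simple_record(nb, hyd) for nb, hyd in recs]
        combined = combine_subpockets(subs)
        assert combined.nb_tot == sum(nb for nb, _ in recs)
        assert sum(combined.feature_pct.values()) == pytest.approx(100.0, abs=1e-6)
        lo = min(h for _, h in recs)
        hi = max(h for _, h in recs)
        assert lo - 1e-9 <= combined.feature_pct["hydrophobic"] <= hi + 1e-9

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            combine_subpockets([])

    def test_invalid_record_rejected_with_feature_name(self):
        rec = simple_record(100, 40.0)
        rec.dist_pct[("hydrophobic", "40-50")] = 10.0  # breaks the per-feature sum
        with pytest.raises(ValueError, match="hydrophobic"):
            combine_subpockets([rec, simple_record(50, 20.0)])


class TestDistanceSums:
    def test_all_mass_in_one_bin(self):
        sums = distance_sums(simple_record(100, 40.0, spread_bin="40-50"))
        assert sums["40-50"] == pytest.approx(100.0)
        assert all(v == 0.0 for b, v in sums.items() if b != "40-50")

    def test_uniform_record_sums_to_ten_each(self):
        pct = {f: 12.5 for f in FEATURES}
        dist = {(f, b): 1.25 for f in FEATURES for b in DISTANCE_BINS}
        sums = distance_sums(SubPocketRecord(200, pct, dist))
        assert all(v == pytest.approx(10.0) for v in sums.values())

    def test_total_conservation(self):
        rec = generate_subpockets(1, PROFILE, seed=13)[0]
        assert sum(distance_sums(rec).values()) == pytest.approx(100.0, abs=1e-6)

    def test_missing_bins_rejected(self):
        rec = simple_record(100, 40.0)
        rec.dist_pct = {}
        with pytest.raises(ValueError, match="no distance"):
            distance_sums(rec)


class TestAssembleVector:
    def test_length_is_117(self):
        rec = generate_subpockets(1, PROFILE, seed=14)[0]
        vec = assemble_vector(rec, {s: 1.0 for s in SHAPE_DESCRIPTORS})
        assert len(vec) == 117
        assert list(vec.index) == pocket_vector_columns()

    def test_zero_shape_values(self):
        rec = generate_subpockets(1, PROFILE, seed=15)[0]
        vec = assemble_vector(rec, np.zeros(18))
        assert (vec.iloc[-18:] == 0.0).all()
        assert vec.iloc[0] == rec.nb_tot

    def test_wrong_shape_count_rejected(self):
        rec = generate_subpockets(1, PROFILE, seed=16)[0]
        with pytest.raises(ValueError, match="18"):
            assemble_vector(rec, np.zeros(17))

    def test_round_trip_preserves_values(self, tmp_path):
        recs = generate_subpockets(3, PROFILE, seed=17)
        vec = assemble_vector(combine_subpockets(recs), np.arange(18.0))
        frame = vec.to_frame().T
        frame.index = ["p1"]
        path = tmp_path / "vectors.csv"
        write_pocket_vectors(frame, path)
        back = read_pocket_vectors(path)
        assert np.array_equal(back.to_numpy(), frame.to_numpy())

    def test_subpocket_round_trip(self, tmp_path):
        recs = generate_subpockets(2, PROFILE, seed=18)
        path = tmp_path / "subs.csv"
        write_subpockets(recs, path)
        back = read_subpockets(path)
        assert back[0].nb_tot == recs[0].nb_tot
        for f in FEATURES:
            assert back[1].feature_pct[f] == pytest.approx(recs[1].feature_pct[f])


def _vector(seed, **shape_overrides):
    rec = generate_subpockets(1, PROFILE, seed=seed)[0]
    shape = {s: 1.0 for s in SHAPE_DESCRIPTORS}
    shape.update(shape_overrides)
    return assemble_vector(rec, shape)


class TestPocketDistances:
    def test_identical_vectors_distance_zero(self):
        v = _vector(20)
        d = pocket_distances([v, v.copy(), _vector(21)], standardize=False)
        assert d.iloc[0, 1] == 0.0

    def test_single_coordinate_difference(self):
        v1 = _vector(22, vol=10.0)
        v2 = _vector(22, vol=13.0)
        d = pocket_distances([v1, v2], standardize=False)
        assert d.iloc[0, 1] == pytest.approx(3.0)

    def test_triangle_inequality(self):
        vs = [_vector(s) for s in (30, 31, 32)]
        d = pocket_distances(vs, standardize=True).to_numpy()
        for i, j, k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9

    def test_wrong_length_rejected(self):
        frame = pd.DataFrame(np.ones((3, 50)))
        with pytest.raises(ValueError, match="117"):
            pocket_distances(frame)


class TestPointTally:
    def test_counts_and_percentages(self, rng):
        n = 400
        points = pd.DataFrame({
            "x": rng.normal(0, 5, n), "y": rng.normal(0, 5, n), "z": rng.normal(0, 5, n),
            "feature": rng.choice(FEATURES, n),
        })
        rec = subpocket_from_points(points)
        rec.validate()
        assert rec.nb_tot == n

    def test_unknown_feature_rejected(self):
        points = pd.DataFrame({"x": [0.0], "y": [0.0], "z": [0.0], "feature": ["weird"]})
        with pytest.raises(ValueError, match="unknown feature"):
            subpocket_from_points(points)
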