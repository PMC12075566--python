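"""Matching, screen scores, TPS_S aggregation and the D_T threshold."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from metscreen.hypotheses import Hypothesis
from metscreen.mol import FeatureSet, PharmacophoreFeature
from metscreen.screening import (
    ConfigError,
    MatchResult,
    aggregate_tpss,
    docking_threshold,
    first_pass_filter,
    match_to_hypothesis,
    screen_score,
)
from oracles import brute_force_match, horn_rmsd


def make_hypothesis(typed_positions, hid="h"):
    return Hypothesis(
        hid,
        [PharmacophoreFeature(t, np.asarray(p, float)) for t, p in typed_positions],
    )


def make_featureset(typed_positions, mol_id="m"):
    return FeatureSet(
        mol_id, 0,
        [PharmacophoreFeature(t, np.asarray(p, float)) for t, p in typed_positions],
    )


SQUARE = [("A", [0, 0, 0]), ("P", [4, 0, 0]), ("R", [4, 3, 0]), ("R", [0, 3, 0])]


class TestMatch:
    def test_exact_coordinates_zero_rmsd(self):
        m = match_to_hypothesis(make_featureset(SQUARE), make_hypothesis(SQUARE))
        assert m.rmsd == pytest.approx(0.0, abs=1e-9)
        assert m.matched_fraction == 1.0

    def test_rigid_motion_invariance(self):
        R = np.array([[0, -1, 0], [1, 0, 0], [0, 0, 1]], dtype=float)  # 90° about z
        t = np.array([10.0, 0.0, 0.0])
        moved = make_featureset(
            [(ty, R @ np.asarray(p, float) + t) for ty, p in SQUARE]
        )
        m = match_to_hypothesis(moved, make_hypothesis(SQUARE))
        assert m.rmsd == pytest.approx(0.0, abs=1e-6)

    def test_displaced_feature_matches_superposition_oracle(self):
        displaced = [("A", [0, 0, 2.0])] + SQUARE[1:]
        fs = make_featureset(displaced)
        h = make_hypothesis(SQUARE)
        m = match_to_hypothesis(fs, h, rmsd_max=5.0)
        want, _ = brute_force_match(
            h.positions(), [f.ftype for f in h.features],
            fs.positions(), [f.ftype for f in fs.features], rmsd_max=5.0,
        )
        assert m.rmsd == pytest.approx(want, abs=1e-6)

    def test_gate_discards_poor_geometry(self):
        displaced = [("A", [0, 0, 4.0])] + SQUARE[1:]
        assert match_to_hypothesis(make_featureset(displaced), make_hypothesis(SQUARE)) is None

    def test_small_hypothesis_rejected(self):
        h = make_hypothesis(SQUARE)
        h.features = h.features[:2]
        with pytest.raises(ConfigError):
            match_to_hypothesis(make_featureset(SQUARE), h)

    def test_matches_brute_force_on_random_instances(self, rng):
        """Exhaustive-correspondence oracle equivalence (≤6 features/type)."""
        types = list("APRRHD")
        for _ in range(30):
            k = rng.integers(3, 6)
            hyp_types = [types[rng.integers(len(types))] for _ in range(k)]
            h = make_hypothesis(
                [(t, rng.uniform(-5, 5, 3)) for t in hyp_types]
            )
            n = rng.integers(3, 9)
            fs_types = hyp_types + [types[rng.integers(len(types))]
                                    for _ in range(max(0, n - k))]
            fs = make_featureset([(t, rng.uniform(-5, 5, 3)) for t in fs_types])
            got = match_to_hypothesis(fs, h, rmsd_max=3.0)
            want = brute_force_match(
                h.positions(), hyp_types, fs.positions(), fs_types, rmsd_max=3.0
            )
            if want is None:
                assert got is None
            else:
                assert got.rmsd == pytest.approx(want[0], abs=1e-6)


class TestScreenScore:
    def test_perfect_match_reaches_scale(self):
        m = MatchResult("m", "h", (), rmsd=0.0, matched_fraction=1.0,
                        vector_alignment=1.0)
        h = make_hypothesis(SQUARE)
        assert screen_score(m, h, scale=1.0) == pytest.approx(1.0)
        assert screen_score(m, h, scale=3.0) == pytest.approx(3.0)

    def test_match_at_gate_rmsd_scores_two_thirds(self):
        m = MatchResult("m", "h", (), rmsd=1.0, matched_fraction=1.0,
                        vector_alignment=1.0)
        assert screen_score(m, make_hypothesis(SQUARE), rmsd_max=1.0) == pytest.approx(2 / 3)

    def test_score_decreases_with_planted_noise(self):
        """Median screen score falls as coordinate noise grows."""
        from metscreen.synth import PlantedSpec, gen_planted_set

        medians = []
        for sigma in (0.1, 0.4, 0.8):
            scores = []
            for seed in range(5):
                actives, _, truth = gen_planted_set(
                    PlantedSpec(sigma=sigma, n_actives=10, n_decoys_per_active=0,
                                seed=seed)
                )
                for fs in actives:
                    m = match_to_hypothesis(fs, truth, rmsd_max=3.0)
                    scores.append(0.0 if m is None else m.screen_score)
            medians.append(np.median(scores))
        assert medians[0] > medians[1] > medians[2]


class TestAggregation:
    def test_tpss_is_sum_over_hypotheses(self):
        sm = aggregate_tpss(pd.DataFrame(
            {"molecule_id": ["a", "a", "b"], "hypothesis_id": ["h1", "h2", "h1"],
             "score": [0.8, 0.4, 0.1]}
        ))
        assert sm.tpss["a"] == pytest.approx(1.2)
        assert sm.tpss["b"] == pytest.approx(0.1)

    def test_protomers_collapse_by_maximum(self):
        sm = aggregate_tpss(pd.DataFrame(
            {"molecule_id": ["c|2plus", "c|3plus", "d"],
             "hypothesis_id": ["h1", "h1", "h1"],
             "score": [0.8, 0.6, 0.2]}
        ))
        assert sm.tpss["c"] == pytest.approx(0.8)

    def test_duplicate_entries_rejected_without_collapsing(self):
        df = pd.DataFrame(
            {"molecule_id": ["a", "a"], "hypothesis_id": ["h1", "h1"],
             "score": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicated"):
            aggregate_tpss(df, collapse_protomers=False)

    def test_unmatched_molecules_contribute_zero(self):
        sm = aggregate_tpss(pd.DataFrame(
            {"molecule_id": ["a", "b"], "hypothesis_id": ["h1", "h2"],
             "score": [1.0, 2.0]}
        ))
        assert sm.table.loc["a", "h2"] == 0.0
        assert sm.tpss["a"] == pytest.approx(1.0)


def matrix_from_tpss(values):
    df = pd.DataFrame(
        {"molecule_id": [f"m{i}" for i in range(len(values))],
         "hypothesis_id": "h1", "score": values}
    )
    return aggregate_tpss(df)


class TestDockingThreshold:
    def test_hand_arithmetic_example(self):
        # tpss [1,2,3,4,10]: mean 4, sample SD sqrt(12.5)=3.53553, D_T 11.0711
        sm = matrix_from_tpss([1.0, 2.0, 3.0, 4.0, 10.0])
        d_t, selected = docking_threshold(sm)
        assert d_t == pytest.approx(4 + 2 * np.sqrt(12.5), abs=1e-9)
        assert selected == []

    def test_zero_variance_selects_everyone(self):
        sm = matrix_from_tpss([5.0, 5.0, 5.0])
        d_t, selected = docking_threshold(sm)
        assert d_t == pytest.approx(5.0)
        assert len(selected) == 3

    def test_single_molecule_rejected(self):
        df = pd.DataFrame(
            {"molecule_id": ["a"], "hypothesis_id": ["h1"], "score": [1.0]}
        )
        with pytest.raises(ConfigError):
            aggregate_tpss(df)

    @given(
        st.lists(st.floats(0, 100, allow_nan=False), min_size=3, max_size=30),
        st.floats(0.1, 10),
        st.floats(0, 50),
    )
    def test_affine_invariance_of_selection(self, values, a, b):
        if np.ptp(values) == 0:
            values = list(values) + [values[0] + 1.0]
        sm1 = matrix_from_tpss(values)
        sm2 = matrix_from_tpss([a * v + b for v in values])
        d1, s1 = docking_threshold(sm1)
        d2, s2 = docking_threshold(sm2)
        assert d2 == pytest.approx(a * d1 + b, rel=1e-9, abs=1e-7)
        assert s1 == s2

    def test_selection_equals_definition_on_random_vectors(self, rng):
        """Threshold selection replayed against its literal definition."""
        for _ in range(200):
            v = rng.exponential(2.0, size=rng.integers(2, 40))
            sm = matrix_from_tpss(list(v))
            d_t, selected = docking_threshold(sm)
            mean, sd = v.mean(), v.std(ddof=1)
            assert d_t == pytest.approx(mean + 2 * sd, rel=1e-12, abs=1e-12)
            want = {f"m{i}" for i, x in enumerate(v) if x >= mean + 2 * sd - 1e-12}
            assert set(selected) == want


class TestFirstPassFilter:
    def test_requires_membership_under_min_hypotheses(self):
        df = pd.DataFrame(
            {"molecule_id": ["X", "X", "Y", "Z"],
             "hypothesis_id": ["h1", "h2", "h1", "h2"],
             "rmsd": [0.1, 0.2, 0.3, 0.4]}
        )
        assert first_pass_filter(df, min_hypotheses=2) == ["X"]

    def test_tie_break_by_molecule_id(self):
        df = pd.DataFrame(
            {"molecule_id": ["b", "a", "c"], "hypothesis_id": "h1",
             "rmsd": [0.5, 0.5, 0.5]}
        )
        assert first_pass_filter(df, top_n=1, min_hypotheses=1) == ["a"]

    def test_exactly_top_n_kept_per_hypothesis(self):
        df = pd.DataFrame(
            {"molecule_id": [f"m{i}" for i in range(10)], "hypothesis_id": "h1",
             "rmsd": np.linspace(0.1, 1.0, 10)}
        )
        assert len(first_pass_filter(df, top_n=5, min_hypotheses=1)) == 5

    def test_nonpositive_top_n_rejected(self):
        df = pd.DataFrame(
            {"molecule_id": ["a"], "hypothesis_id": ["h1"], "rmsd": [0.1]}
        )
        with pytest.raises(ConfigError):
            first_pass_filter(df, top_n=0)


def test_kabsch_agrees_with_quaternion_superposition(rng):
    for _ in range(20):
        P = rng.normal(size=(rng.integers(3, 8), 3))
        Q = rng.normal(size=P.shape)
        from metscreen.geometry import kabsch

        _, _, got = kabsch(P, Q)
        assert got == pytest.approx(horn_rmsd(P, Q), abs=1e-9)
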