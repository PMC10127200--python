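import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy.stats import ks_2samp

from conftest import oracle_signed_ks
from phenoselect.profiling import (
    build_control_profiles,
    build_profile,
    profile_screen,
    signed_ks,
    signed_ks_profile,
)

samples = st.lists(
    st.floats(-50, 50, allow_nan=False, allow_infinity=False), min_size=1, max_size=30
)


class TestSignedKS:
    @pytest.mark.parametrize(
        "treated, control, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),            # identical multisets
            ([10, 11, 12], [1, 2, 3], 1.0),         # complete separation upward
            ([1, 3], [2, 4], -0.5),                 # dominant downward branch
            ([1, 2, 3], [10, 11, 12], -1.0),
            ([5, 5, 5], [5, 5], 0.0),
        ],
    )
    def test_known_values(self, treated, control, expected):
        assert signed_ks(treated, control) == pytest.approx(expected)

    @pytest.mark.parametrize("side, args", [("treated", ([], [1])), ("control", ([1], []))])
    def test_empty_sample_names_side(self, side, args):
        with pytest.raises(ValueError, match=side):
            signed_ks(*args)

    @given(samples, samples)
    def test_antisymmetry_and_bounds(self, a, b):
        s = signed_ks(a, b)
        r = signed_ks(b, a)
        assert -1 <= s <= 1
        # swapping samples flips the sign except at the tie D+ == D-, where
        # the convention returns the positive branch from either direction
        assert r == pytest.approx(-s) or r == pytest.approx(s) == abs(s)

    @given(samples, samples)
    def test_magnitude_matches_two_sided_ks(self, a, b):
        # independent route: scipy's two-sided statistic equals |signed value|
        assert abs(signed_ks(a, b)) == pytest.approx(ks_2samp(a, b).statistic)

    @given(samples, samples)
    def test_invariant_under_monotone_transform(self, a, b):
        f = lambda x: np.expm1(np.asarray(x) / 25.0)  # strictly increasing
        assert signed_ks(a, b) == pytest.approx(signed_ks(f(a), f(b)))

    def test_matches_exhaustive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a = rng.integers(0, 8, size=rng.integers(1, 7)).tolist()
            b = rng.integers(0, 8, size=rng.integers(1, 7)).tolist()
            assert signed_ks(a, b) == pytest.approx(oracle_signed_ks(a, b))


# toy table: one cell line, 6 treated + 6 control cells, two features
TOY_TREATED = np.array(
    [[1.0, 0.4], [1.2, 0.5], [1.4, 0.3], [1.6, 0.6], [1.8, 0.2], [2.0, 0.5]]
)
TOY_CONTROL = np.array(
    [[0.2, 0.4], [0.4, 0.5], [0.6, 0.3], [0.8, 0.6], [1.0, 0.2], [1.2, 0.5]]
)


def _toy_cells():
    rows = []
    for mat, treatment, role, well in [
        (TOY_TREATED, "c1", "compound", "W1"),
        (TOY_CONTROL, "DMSO", "control", "D1"),
    ]:
        for f1, f2 in mat:
            rows.append(
                {"cell_line": "A", "plate": "P1", "well": well,
                 "treatment": treatment, "role": role, "f_1": f1, "f_2": f2}
            )
    return pd.DataFrame(rows)


class TestBuildProfile:
    def test_toy_table_matches_per_feature_oracle(self):
        prof = build_profile(_toy_cells(), "c1")
        for j, col in enumerate(["f_1", "f_2"]):
            expected = oracle_signed_ks(TOY_TREATED[:, j], TOY_CONTROL[:, j])
            assert prof[col] == pytest.approx(expected)
        assert prof["n_cells_treated"] == 6 and prof["n_cells_control"] == 6

    def test_identical_treated_and_control_gives_zero_vector(self):
        cells = _toy_cells()
        cells.loc[cells.treatment == "c1", ["f_1", "f_2"]] = TOY_CONTROL
        prof = build_profile(cells, "c1")
        assert prof["f_1"] == 0.0 and prof["f_2"] == 0.0

    def test_single_shifted_feature_only_moves_that_coordinate(self):
        cells = _toy_cells()
        cells.loc[cells.treatment == "c1", "f_1"] = TOY_CONTROL[:, 0]  # undo f_1 shift
        prof = build_profile(cells, "c1")
        assert prof["f_1"] == 0.0
        assert prof["f_2"] == pytest.approx(
            oracle_signed_ks(TOY_TREATED[:, 1], TOY_CONTROL[:, 1])
        )

    def test_invariant_to_cell_row_order(self):
        cells = _toy_cells()
        shuffled = cells.sample(frac=1, random_state=5).reset_index(drop=True)
        pd.testing.assert_series_equal(build_profile(cells, "c1"),
                                       build_profile(shuffled, "c1"))

    def test_no_control_on_matching_plate_errors_with_plates(self):
        cells = _toy_cells()
        cells.loc[cells.treatment == "DMSO", "plate"] = "P2"
        with pytest.raises(ValueError, match="P1"):
            build_profile(cells, "c1")


class TestControlProfiles:
    def _dmso_cells(self, n_wells, cells_per_well=200, rng=None, plate="P1"):
        rng = rng or np.random.default_rng(0)
        rows = []
        for w in range(n_wells):
            for v in rng.normal(size=(cells_per_well, 2)):
                rows.append({"cell_line": "A", "plate": plate, "well": f"D{w}",
                             "treatment": "DMSO", "role": "control",
                             "f_1": v[0], "f_2": v[1]})
        return pd.DataFrame(rows)

    def test_two_identical_wells_give_exact_zero_vectors(self):
        cells = self._dmso_cells(1, 10)
        dup = cells.copy()
        dup["well"] = "D9"
        profs = build_control_profiles(pd.concat([cells, dup], ignore_index=True))
        assert len(profs) == 2
        assert (profs[["f_1", "f_2"]].to_numpy() == 0).all()

    def test_single_dmso_well_plate_skipped_with_warning(self):
        cells = self._dmso_cells(1, 20)
        with pytest.warns(UserWarning, match="single DMSO well"):
            profs = build_control_profiles(cells)
        assert profs.empty

    def test_null_profiles_concentrate_near_zero(self):
        # one distribution for all wells: entries should rarely leave [-0.25, 0.25]
        rng = np.random.default_rng(21)
        entries = []
        for _ in range(10):
            profs = build_control_profiles(self._dmso_cells(8, 200, rng))
            entries.append(profs[["f_1", "f_2"]].to_numpy().ravel())
        entries = np.concatenate(entries)
        assert (np.abs(entries) < 0.25).mean() >= 0.99


class TestProfileScreen:
    def test_replicate_wells_pooled_one_profile_per_compound(self, small_screen):
        profiles = profile_screen(small_screen.cells)
        comp = profiles[profiles.role == "compound"]
        per_line = comp.groupby("cell_line").size()
        assert (per_line == len(small_screen.truth.compounds)).all()

    def test_planted_sign_recovery(self):
        # strong planted effect: profile signs match effect-vector signs on
        # coordinates well above the profile noise scale
        from phenoselect.simulate import SyntheticScreenConfig, generate_screen

        cfg = SyntheticScreenConfig(
            n_cell_lines=1, n_features=8, n_active_features=4, n_moas=2,
            compounds_per_moa=2, cells_per_well=300, n_dmso_wells_per_plate=6,
            compound_wells_per_plate=4, effect_magnitude=3.0, heterogeneity=0.0,
            seed=3,
        )
        screen = generate_screen(cfg)
        profiles = profile_screen(screen.cells)
        feats = [f"f_{j + 1}" for j in range(8)]
        for ci, c in enumerate(screen.truth.compounds):
            v = screen.truth.effects[ci, 0]
            prof = profiles.loc[
                (profiles.treatment == c) & (profiles.cell_line == "L1"), feats
            ].to_numpy()[0]
            strong = np.abs(v) > 0.5  # well above null KS noise at 300 cells
            assert (np.sign(prof[strong]) == np.sign(v[strong])).all()

    def test_per_well_mode_names_wells(self, small_screen):
        line = small_screen.cells_by_line["L1"]
        profiles = profile_screen(line, per_well=True)
        comp = profiles[profiles.role == "compound"]
        assert comp.treatment.str.contains("@P").all()
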