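import numpy as np
import pandas as pd
import pytest

from riverchem.errors import ValidationError
from riverchem.transformations import (
    compare_profiles,
    match_keys,
    match_transformations,
    match_transformations_bruteforce,
    profile_mass_sets,
    profile_sample,
)

ALANINE = 71.037114


class TestMatching:
    def test_alanine_worked_example(self, bundled_refs):
        masses = np.array([200.0, 200.0 + ALANINE])
        matches = match_transformations(masses, bundled_refs)
        alanine = matches[matches["name"] == "alanine"]
        assert len(alanine) == 1
        assert alanine["error_ppm"].abs().iloc[0] < 1e-3
        assert alanine["observed_delta"].iloc[0] == pytest.approx(71.0371, abs=5e-5)

    def test_off_grid_difference_yields_no_match(self, bundled_refs):
        alanine_refs = bundled_refs[bundled_refs["name"] == "alanine"]
        matches = match_transformations(np.array([200.0, 260.0]), alanine_refs)
        assert matches.empty

    def test_empty_inputs(self, bundled_refs):
        assert match_transformations(np.array([]), bundled_refs).empty
        assert match_transformations(np.array([200.0, 300.0]), bundled_refs.iloc[:0]).empty

    def test_unsorted_masses_rejected(self, bundled_refs):
        with pytest.raises(ValidationError):
            match_transformations(np.array([300.0, 200.0]), bundled_refs)

    def test_matches_pure_python_enumeration(self, small_refs):
        rng = np.random.default_rng(5)
        base = np.sort(rng.uniform(200, 400, 8))
        masses = np.unique(np.concatenate([base, base[:3] + 71.037114]))
        fast = match_keys(match_transformations(masses, small_refs))
        brute = match_keys(match_transformations_bruteforce(masses, small_refs))
        slow = set()
        for i in range(len(masses)):
            for j in range(i + 1, len(masses)):
                for r, ref_mass in enumerate(small_refs["mass"]):
                    if abs((masses[j] - masses[i]) - ref_mass) <= 1e-6 * ref_mass:
                        slow.add((i, j, r))
        assert fast == slow
        assert brute == slow

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_random_sets(self, seed, bundled_refs):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 120))
        masses = np.sort(rng.uniform(200, 900, n))
        planted = masses[rng.integers(0, n, 10)] + rng.choice(bundled_refs["mass"], 10)
        masses = np.unique(np.concatenate([masses, planted[planted < 900]]))
        fast = match_transformations(masses, bundled_refs)
        brute = match_transformations_bruteforce(masses, bundled_refs)
        assert match_keys(fast) == match_keys(brute)

    def test_tolerance_monotonicity(self, bundled_refs):
        rng = np.random.default_rng(17)
        masses = np.sort(rng.uniform(200, 900, 80))
        tight = match_keys(match_transformations(masses, bundled_refs, tolerance_ppm=0.5))
        loose = match_keys(match_transformations(masses, bundled_refs, tolerance_ppm=5.0))
        assert tight <= loose

    def test_translation_invariance(self, bundled_refs):
        rng = np.random.default_rng(23)
        masses = np.sort(rng.uniform(200, 700, 60))
        a = match_transformations(masses, bundled_refs)
        b = match_transformations(masses + 100.0, bundled_refs)
        key_a = sorted(zip(a["i"], a["j"], a["ref_index"]))
        key_b = sorted(zip(b["i"], b["j"], b["ref_index"]))
        assert key_a == key_b

    def test_pair_tolerance_basis(self, small_refs):
        # at basis="pair" the window scales with the heavier peak, so a
        # deviation inside 1 ppm of the peak but outside 1 ppm of the
        # reference matches only in "pair" mode
        delta = 71.037114 + 2.0e-4  # ~2.8 ppm of ref, ~0.24 ppm of peak
        masses = np.array([800.0, 800.0 + delta])
        assert match_transformations(masses, small_refs, basis="ref").empty
        assert len(match_transformations(masses, small_refs, basis="pair")) == 1


class TestProfiles:
    def _matches(self, names, refs):
        idx = [refs.index[refs["name"] == n][0] for n in names]
        return pd.DataFrame({
            "i": range(len(idx)), "j": range(1, len(idx) + 1),
            "ref_index": idx, "name": names,
            "low_mass": 200.0, "high_mass": 300.0,
            "observed_delta": 100.0, "error_ppm": 0.0,
        })

    def test_category_arithmetic(self, small_refs):
        matches = self._matches(["alanine"] * 3 + ["phosphate"], small_refs)
        profile = profile_sample(matches, small_refs)
        assert profile.total == 4
        assert profile.category_abundance["N"] == pytest.approx(0.75)
        assert profile.category_abundance["P"] == pytest.approx(0.25)
        assert profile.category_abundance["CHO"] == 0.0

    def test_cho_only_matches(self, small_refs):
        profile = profile_sample(self._matches(["water", "water"], small_refs), small_refs)
        assert profile.category_abundance["CHO"] == pytest.approx(1.0)

    def test_totals_conserved(self, small_refs):
        matches = self._matches(["water", "alanine", "sulfonation", "phosphate"], small_refs)
        profile = profile_sample(matches, small_refs)
        assert profile.total == len(matches)
        assert profile.category_counts.sum() == profile.total  # single-category refs

    def test_multi_membership_vs_exclusive(self, small_refs):
        matches = self._matches(["taurine"], small_refs)  # contains N and S
        multi = profile_sample(matches, small_refs, mode="multi")
        assert multi.category_counts["N"] == 1 and multi.category_counts["S"] == 1
        excl = profile_sample(matches, small_refs, mode="exclusive")
        assert excl.category_counts["N"] == 1 and excl.category_counts["S"] == 0
        assert excl.category_abundance.sum() == pytest.approx(1.0)

    def test_zero_matches_flagged_missing(self, small_refs):
        profile = profile_sample(self._matches([], small_refs).iloc[:0], small_refs)
        assert profile.total == 0
        assert profile.category_abundance.isna().all()

    def test_abundances_sum_to_one_for_single_category_refs(self, small_refs):
        pure = small_refs[small_refs["name"] != "taurine"].reset_index(drop=True)
        rng = np.random.default_rng(2)
        base = np.sort(rng.uniform(200, 600, 40))
        planted = np.concatenate([base[:10] + m for m in pure["mass"]])
        masses = np.unique(np.concatenate([base, planted]))
        profiles = profile_mass_sets({"s": masses}, pure)
        cats = profiles.loc["s", ["abund_CHO", "abund_N", "abund_S", "abund_P"]]
        assert cats.sum() == pytest.approx(1.0, abs=1e-12)


class TestCompareProfiles:
    def test_identical_groups_give_p_one(self, small_refs):
        profiles = pd.DataFrame({
            "abund_CHO": [0.5] * 6, "abund_N": [0.3] * 6,
            "abund_S": [0.1] * 6, "abund_P": [0.1] * 6,
        }, index=[f"s{i}" for i in range(6)])
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=profiles.index)
        out = compare_profiles(profiles, groups)
        assert (out["p_value"] == 1.0).all()
        assert (out["p_adjusted"] == 1.0).all()

    def test_small_group_rejected_with_name(self, small_refs):
        profiles = pd.DataFrame({
            "abund_CHO": [0.5, 0.4, 0.3], "abund_N": [0.2] * 3,
            "abund_S": [0.2] * 3, "abund_P": [0.1] * 3,
        }, index=["s1", "s2", "s3"])
        groups = pd.Series(["a", "a", "lonely"], index=profiles.index)
        with pytest.raises(ValidationError, match="lonely"):
            compare_profiles(profiles, groups)
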