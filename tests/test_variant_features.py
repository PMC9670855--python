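import numpy as np
import pandas as pd
import pytest

from dropscape import (
    MutationSpec,
    RegionMap,
    apply_mutations,
    assign_region,
    double_mutant_features,
    filter_by_effect,
    profile_sequence,
    single_mutant_features,
)
from dropscape.variant_features import features_table


def make_mutation(seq, position, mut="W"):
    wt = seq.residue_at(position)
    if wt == mut:
        mut = "H"
    return MutationSpec(wt, position, mut)


@pytest.fixture(scope="module")
def mutant_case(lc_sequence, lc_profile):
    mut = make_mutation(lc_sequence, 315)
    mut_seq = apply_mutations(lc_sequence, [mut])
    return mut, profile_sequence(mut_seq)


class TestSingleMutantFeatures:
    def test_identity_variant_is_zero(self, lc_sequence, lc_profile):
        mut = make_mutation(lc_sequence, 315)
        vf = single_mutant_features(lc_profile, lc_profile.copy(), mut)
        # same profile on both sides: deltas must vanish exactly
        assert (vf.delta_p_dp, vf.delta_p_ap, vf.delta_mbm) == (0.0, 0.0, 0.0)

    def test_deltas_equal_row_subtraction(self, lc_profile, mutant_case):
        mut, mut_profile = mutant_case
        vf = single_mutant_features(lc_profile, mut_profile, mut)
        wt_row = lc_profile.set_index("position").loc[mut.position]
        mut_row = mut_profile.set_index("position").loc[mut.position]
        assert vf.delta_p_dp == pytest.approx(mut_row["p_dp"] - wt_row["p_dp"], abs=1e-15)
        assert vf.delta_p_ap == pytest.approx(mut_row["p_ap"] - wt_row["p_ap"], abs=1e-15)
        assert vf.delta_mbm == pytest.approx(mut_row["mbm"] - wt_row["mbm"], abs=1e-15)

    def test_reads_mutated_row_not_neighbor(self, lc_sequence, lc_profile, mutant_case):
        mut, mut_profile = mutant_case
        # corrupt the neighbouring rows: result must not change
        corrupted = mut_profile.copy()
        for off in (-1, 1):
            corrupted.loc[corrupted["position"] == mut.position + off, "p_dp"] = 0.123
        vf = single_mutant_features(lc_profile, mut_profile, mut)
        vf2 = single_mutant_features(lc_profile, corrupted, mut)
        assert vf.delta_p_dp == vf2.delta_p_dp

    def test_antisymmetric_under_profile_swap(self, lc_sequence, lc_profile, mutant_case):
        mut, mut_profile = mutant_case
        back = MutationSpec(mut.mut_residue, mut.position, mut.wt_residue)
        fwd = single_mutant_features(lc_profile, mut_profile, mut)
        rev = single_mutant_features(mut_profile, lc_profile, back)
        assert rev.delta_p_dp == -fwd.delta_p_dp
        assert rev.delta_p_ap == -fwd.delta_p_ap
        assert rev.delta_mbm == -fwd.delta_mbm

    def test_wt_letter_checked_against_profile(self, lc_sequence, lc_profile, mutant_case):
        _, mut_profile = mutant_case
        wrong_wt = "W" if lc_sequence.residue_at(315) != "W" else "H"
        bad = MutationSpec(wrong_wt, 315, "Y")
        with pytest.raises(ValueError, match="wild-type"):
            single_mutant_features(lc_profile, mut_profile, bad)


@pytest.fixture(scope="module")
def double_case(lc_sequence, lc_profile):
    muts = [make_mutation(lc_sequence, 318), make_mutation(lc_sequence, 330, "F")]
    mut_seq = apply_mutations(lc_sequence, muts)
    return muts, profile_sequence(mut_seq)


class TestDoubleMutantFeatures:
    def test_identity_profiles_give_zero(self, lc_sequence, lc_profile):
        muts = [make_mutation(lc_sequence, 318), make_mutation(lc_sequence, 330, "F")]
        vf = double_mutant_features(lc_profile, lc_profile.copy(), muts)
        assert (vf.delta_p_dp, vf.delta_p_ap, vf.delta_mbm) == (0.0, 0.0, 0.0)

    def test_equals_mean_then_subtract_oracle(self, lc_profile, double_case):
        muts, mut_profile = double_case
        vf = double_mutant_features(lc_profile, mut_profile, muts)
        mask = lc_profile["position"].between(312, 341)
        assert mask.sum() == 30
        for feat, col in [("delta_p_dp", "p_dp"), ("delta_p_ap", "p_ap"), ("delta_mbm", "mbm")]:
            expected = mut_profile.loc[mask, col].mean() - lc_profile.loc[mask, col].mean()
            assert getattr(vf, feat) == pytest.approx(expected, abs=1e-12)

    def test_length_one_region_degenerates_to_single_site(
        self, lc_sequence, lc_profile, double_case
    ):
        muts, mut_profile = double_case
        vf = double_mutant_features(lc_profile, mut_profile, muts, region=(318, 318))
        wt_row = lc_profile.set_index("position").loc[318]
        mut_row = mut_profile.set_index("position").loc[318]
        assert vf.delta_p_dp == pytest.approx(mut_row["p_dp"] - wt_row["p_dp"], abs=1e-12)

    def test_region_outside_profile_rejected(self, lc_profile, double_case):
        muts, mut_profile = double_case
        with pytest.raises(ValueError, match="not fully covered"):
            double_mutant_features(lc_profile, mut_profile, muts, region=(400, 430))

    def test_antisymmetric_under_profile_swap(self, lc_profile, double_case):
        muts, mut_profile = double_case
        fwd = double_mutant_features(lc_profile, mut_profile, muts)
        rev = double_mutant_features(mut_profile, lc_profile, muts)
        assert rev.delta_p_dp == pytest.approx(-fwd.delta_p_dp, abs=1e-15)
        assert rev.delta_mbm == pytest.approx(-fwd.delta_mbm, abs=1e-15)


class TestAssignRegion:
    def test_amyloid_core_pair(self):
        muts = [MutationSpec("A", 321, "T"), MutationSpec("A", 329, "T")]
        assert assign_region(muts) == "amyloid_core"

    def test_hotspot_spans_both_ranges(self):
        muts = [MutationSpec("A", 313, "T"), MutationSpec("A", 335, "T")]
        assert assign_region(muts) == "hotspot"

    def test_cross_region_pair_is_mixed(self):
        muts = [MutationSpec("A", 280, "T"), MutationSpec("A", 325, "T")]
        assert assign_region(muts) == "mixed"

    def test_droplet_single(self):
        assert assign_region([MutationSpec("A", 400, "T")]) == "droplet"

    def test_position_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            assign_region([MutationSpec("A", 100, "T")])

    def test_overlapping_region_map_rejected(self):
        with pytest.raises(ValueError, match="both"):
            RegionMap(amyloid_core=((321, 330),), hotspot=((325, 341),))


class TestFilterByEffect:
    def _table(self, e_tox):
        return pd.DataFrame(
            {"variant_id": [f"v{i}" for i in range(len(e_tox))], "e_tox": e_tox}
        )

    def test_all_equal_values_all_retained(self):
        kept, meta = filter_by_effect(self._table([2.0, 2.0, 2.0]))
        assert len(kept) == 3 and meta["sigma"] == 0.0

    def test_hand_computed_sd_mode(self):
        # e_tox = {0,0,0,10}: sd = sqrt(mean((x-2.5)^2)) = sqrt(18.75) ~ 4.33
        kept, meta = filter_by_effect(self._table([0.0, 0.0, 0.0, 10.0]), k=3)
        assert meta["sigma"] == pytest.approx(np.sqrt(18.75))
        assert len(kept) == 0  # threshold 12.99 > 10

    def test_hand_computed_mean_abs_mode(self):
        # mean|e| = 2.5 -> threshold 7.5: only the 10 survives
        kept, meta = filter_by_effect(
            self._table([0.0, 0.0, 0.0, 10.0]), k=3, sigma_mode="mean_abs"
        )
        assert meta["sigma"] == 2.5
        assert list(kept["variant_id"]) == ["v3"]

    def test_k_zero_is_identity(self):
        table = self._table([-1.0, 0.5, 2.0])
        kept, _ = filter_by_effect(table, k=0)
        assert len(kept) == len(table)

    def test_idempotent(self, rng):
        table = self._table(list(rng.normal(size=200)))
        once, meta = filter_by_effect(table, k=1.5)
        # re-filtering at the recorded absolute threshold changes nothing
        again = once.loc[np.abs(once["e_tox"]) >= meta["threshold"]]
        assert again.equals(once)

    def test_filter_is_on_absolute_value(self):
        kept, _ = filter_by_effect(self._table([-10.0, 0.0, 0.0, 10.0]), k=1)
        assert set(kept["variant_id"]) == {"v0", "v3"}

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            filter_by_effect(self._table([]))


def test_features_table_empty_has_header():
    table = features_table([])
    assert list(table.columns)[:4] == ["variant_id", "mutations", "n_mutations", "region_label"]
    assert table.empty
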