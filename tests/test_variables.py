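"""Variable registry computation: worked examples, missing rules, oracle."""

import pytest

from epgkit import (
    ComputeOptions,
    GeneratorProfile,
    ValidationFailed,
    compute_all,
    generate_recording,
    shared_with_sarria,
    treatment_percentages,
    validate,
)
from epgkit.registry import ACRONYMS, REGISTRY

from naive_oracle import naive_variables


def as_dict(results):
    return {r.acronym: r.value for r in results}


def flag_of(results, acronym):
    return next(r for r in results if r.acronym == acronym).truncation_flag


class TestRegistryShape:
    def test_exactly_127_unique_acronyms(self):
        assert len(REGISTRY) == 127
        assert len(set(ACRONYMS)) == 127

    def test_sarria_overlap_partition(self):
        shared = shared_with_sarria()
        assert len(shared) == 53
        assert len(REGISTRY) - len(shared) == 74

    def test_compute_all_emits_registry_bijectively(self, aphid_recording):
        res = compute_all(aphid_recording)
        assert [r.acronym for r in res] == list(ACRONYMS)

    def test_identical_recordings_identical_vectors(self, aphid_recording):
        a = as_dict(compute_all(aphid_recording))
        b = as_dict(compute_all(aphid_recording))
        assert a == b

    def test_validation_issues_block_without_force(self, build):
        rec = build([("Np", 5), ("E1", 10), ("C", 20)])
        issues = validate(rec)
        with pytest.raises(ValidationFailed):
            compute_all(rec, issues=issues)
        assert len(compute_all(rec, issues=issues, force=True)) == 127


class TestNonsequentialExamples:
    def test_family_statistics_by_hand(self, build):
        rec = build([("Np", 10), ("C", 20), ("Np", 5), ("C", 30), ("Np", 30), ("C", 1)])
        v = as_dict(compute_all(rec))
        assert v["n_Np"] == 3 and v["a_Np"] == 15 and v["m_Np"] == 10
        assert v["s_Np"] == 45 and v["mx_Np"] == 30
        assert v["n_bPr"] == 1  # the 1-min probe

    def test_absent_waveform_zero_counts_missing_stats(self, build):
        rec = build([("Np", 10), ("C", 470)])
        res = compute_all(rec)
        v = as_dict(res)
        assert v["n_G"] == 0 and v["s_G"] == 0
        assert v["a_G"] is None and v["m_G"] is None
        reasons = {r.acronym: r.missing_reason for r in res}
        assert reasons["a_G"] == "waveform-absent"

    def test_singleton_e2_statistics(self, build):
        rec = build([("Np", 10), ("C", 20), ("E1", 1), ("E2", 12.5), ("Np", 30)])
        v = as_dict(compute_all(rec))
        assert v["n_E2"] == 1
        assert v["a_E2"] == v["m_E2"] == v["s_E2"] == v["mx_E2"] == 12.5
        assert v["n_sE2"] == 1  # 12.5 > 10 min


class TestSequentialExamples:
    def test_times_from_conventional_starting_points(self, build):
        # first probe at 7 min; first E1 at 30 min within the second probe
        rec = build([("Np", 7), ("C", 10), ("Np", 8), ("C", 5), ("E1", 2),
                     ("E2", 40), ("Np", 30)])
        v = as_dict(compute_all(rec))
        assert v["t > 1Pr"] == 7
        assert v["t > 1E"] == 23  # 30 - 7
        assert v["tPr > 1E/1Pr"] == 5  # probe starts at 25, E1 at 30
        assert v["t > 1E2"] == 25
        assert v["n_Pr > 1E"] == 1
        assert v["n_Pr.after1E"] == 0

    def test_c_time_before_first_e(self, build):
        # 12 min of C (interrupted by a pd group) precede the first E1
        rec = build([("Np", 5), ("C", 8), ("pd", 0.2), ("pdII-2", 0.2),
                     ("pdII-3", 0.1), ("C", 4), ("E1", 2), ("E2", 30), ("Np", 10)])
        v = as_dict(compute_all(rec))
        assert v["tC > 1E/1Pr"] == pytest.approx(12.0)
        assert v["atC > 1E/Pr"] == pytest.approx(12.0)
        assert v["mntC > 1E/Pr"] == pytest.approx(12.0)

    def test_counts_before_first_e(self, build):
        rec = build([("Np", 5), ("C", 1), ("Np", 5), ("C", 40), ("Np", 5),
                     ("C", 5), ("E1", 2), ("E2", 30), ("Np", 10)])
        v = as_dict(compute_all(rec))
        assert v["n_Pr > 1E"] == 2
        assert v["n_brPr > 1E"] == 1
        assert v["s_np.1E"] == 15

    def test_e1_followed_by_e2_durations(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 3), ("E2", 30), ("E1", 2),
                     ("E2", 5), ("C", 4), ("E1", 7), ("C", 10)])
        v = as_dict(compute_all(rec))
        assert v["d_E1followedbyE2"] == 5  # 3 + 2
        assert v["d_E1followedbysE2"] == 3  # only the 30-min E2 is sustained
        assert v["a_1st E1_followed_E2"] == 3
        assert v["d_1st_E"] == 40  # E1+E2+E1+E2 contiguous
        assert v["n_sgE1"] == 1 and v["s_sgE1"] == 7


class TestPotentialIndices:
    def test_probing_time_shares(self, build):
        rec = build([("Np", 80), ("C", 100), ("F", 60), ("G", 40), ("E1", 50),
                     ("E2", 150)])
        v = as_dict(compute_all(rec))
        assert v["%probtimeinC"] == pytest.approx(25.0)
        assert v["%probtimeinE2"] == pytest.approx(37.5)
        assert v["E2/C_ratio"] == pytest.approx(1.5)

    def test_e2_index_measures_post_onset_share(self, build):
        # first E2 at minute 400 of a 480-min recording; E2 totals 60 after onset
        rec = build([("Np", 10), ("C", 389), ("E1", 1), ("E2", 60), ("C", 20)])
        v = as_dict(compute_all(rec))
        assert v["E2_index"] == pytest.approx(75.0)  # 100 * 60 / 80

    def test_phloem_phase_failure_share(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 2), ("C", 5), ("E1", 1),
                     ("E2", 30), ("C", 5), ("E1", 1), ("E2", 4), ("Np", 10)])
        v = as_dict(compute_all(rec))
        assert v["%Phloem_ph_fail"] == pytest.approx(100.0 / 3)

    def test_all_percentages_within_bounds(self, aphid_recording):
        v = as_dict(compute_all(aphid_recording))
        for acr, val in v.items():
            if acr.startswith("%") and val is not None:
                assert 0.0 <= val <= 100.0, acr


class TestPdVariables:
    def _pd(self, ii3=0.02):
        return [("pd", 0.05), ("pdII-2", 0.03), ("pdII-3", ii3)]

    def test_ii3_sum_over_first_groups(self, build):
        seq = [("Np", 5)]
        for ii3 in (0.02, 0.03, 0.01):
            seq += [("C", 2)] + self._pd(ii3)
        seq += [("C", 2), ("Np", 10)]
        res = compute_all(build(seq))
        v = as_dict(res)
        assert v["s_pdII-3/5pd"] == pytest.approx(0.06)
        assert flag_of(res, "s_pdII-3/5pd") == "fewer-than-5-pds"

    def test_share_of_probes_with_pd(self, build):
        seq = []
        for k in range(10):
            seq += [("Np", 2)]
            if k < 4:
                seq += [("C", 2)] + self._pd() + [("C", 1)]
            else:
                seq += [("C", 3)]
        seq += [("Np", 5)]
        v = as_dict(compute_all(build(seq)))
        assert v["%_Pr_pd"] == pytest.approx(40.0)

    def test_pd_rate_per_minute_of_pathway(self, build):
        seq = [("Np", 5)]
        for _ in range(40):
            seq += [("C", 1)] + self._pd()
        seq += [("C", 40), ("Np", 10)]
        v = as_dict(compute_all(build(seq)))
        assert v["n_pd"] == 40 and v["s_C"] == pytest.approx(80)
        assert v["n_pd/minC"] == pytest.approx(0.5)

    def test_p_pd_family_disjoint_from_pd(self, build):
        rec = build([("Np", 5), ("C", 5), ("p-pd", 0.08), ("C", 2),
                     ("pd", 0.05), ("pdII-2", 0.03), ("pdII-3", 0.02), ("C", 3)])
        v = as_dict(compute_all(rec))
        assert v["n_pd"] == 1 and v["n_p-pd"] == 1
        assert v["s_p-pd"] == pytest.approx(0.08)


class TestTruncationIntegration:
    def _rec(self, build):
        # ends mid-E2 with prior E2 durations [2, 10]
        return build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 2), ("E1", 1),
                      ("E2", 10), ("E1", 1), ("E2", 5)])

    def test_criterion_off_plain_statistics(self, build):
        v = as_dict(compute_all(self._rec(build), ComputeOptions(truncated_criterion=False)))
        assert v["m_E2"] == 5 and v["a_E2"] == pytest.approx(17 / 3)

    def test_criterion_on_midpoint_median(self, build):
        res = compute_all(self._rec(build), ComputeOptions(truncated_criterion=True))
        v = as_dict(res)
        assert v["m_E2"] == pytest.approx(7.5)
        assert v["a_E2"] == pytest.approx(6.0)
        assert flag_of(res, "m_E2") == "midpoint"

    def test_untruncated_waveforms_unaffected(self, build):
        on = as_dict(compute_all(self._rec(build), ComputeOptions(truncated_criterion=True)))
        off = as_dict(compute_all(self._rec(build), ComputeOptions(truncated_criterion=False)))
        for acr in ("a_E1", "m_E1", "a_C", "m_C", "a_Np", "m_Np"):
            assert on[acr] == off[acr]

    def test_recording_ending_in_np_leaves_e2_alone(self, build):
        seq = [("Np", 5), ("C", 5), ("E1", 1), ("E2", 2), ("E1", 1), ("E2", 10),
               ("Np", 30)]
        on = as_dict(compute_all(build(seq), ComputeOptions(truncated_criterion=True)))
        off = as_dict(compute_all(build(seq), ComputeOptions(truncated_criterion=False)))
        assert on["m_E2"] == off["m_E2"] and on["a_E2"] == off["a_E2"]
        assert on["m_Np"] != off["m_Np"] or on["a_Np"] != off["a_Np"]


class TestMissingDataRules:
    def test_no_phloem_activity(self, build):
        # 6 probes, 2 brief, no E anywhere; first probe at 7 min; total 480
        seq = [("Np", 7), ("C", 1)]
        for k in range(5):
            seq += [("Np", 10), ("C", 2 if k == 0 else 40)]
        seq += [("Np", 480 - sum(d for _, d in seq))]
        rec = build(seq)
        assert rec.total_duration == 480
        v = as_dict(compute_all(rec))
        assert v["t > 1E"] == 473  # first-probe start to end of recording
        assert v["t > 1E2"] == 473 and v["t > 1sE2"] == 473
        assert v["tPr > 1E/1Pr"] is None
        assert v["n_Pr > 1E"] == 6 and v["n_brPr > 1E"] == 2
        assert v["n_Pr.after1E"] is None
        assert v["s_np.1E"] is None and v["tC > 1E/1Pr"] is None
        assert v["E2_index"] is None and v["d_1st_E"] is None

    def test_e1_without_e2(self, build):
        rec = build([("Np", 7), ("C", 10), ("E1", 5), ("C", 10), ("Np", 448)])
        v = as_dict(compute_all(rec))
        assert v["t > 1E"] == 10  # E present
        assert v["t > 1E2"] == 480 - 7  # no E2: set to first probe -> end
        assert v["d_1st_E2"] is None and v["E2_index"] is None
        assert v["%_sE2"] is None  # no E2 periods at all
        assert v["n_sgE1"] == 1

    def test_no_probes_at_all(self, build):
        rec = build([("Np", 480)])
        v = as_dict(compute_all(rec))
        assert v["t > 1Pr"] == 480  # set to total duration
        assert v["n_Pr"] == 0 and v["s_Pr"] == 0
        assert v["%probtimeinC"] is None
        assert v["d_1Pr"] is None and v["a_Pr"] is None
        assert v["t > 1pd"] == 480


class TestOracleEquivalence:
    @pytest.mark.parametrize("preset", ["aphid", "psyllid"])
    def test_every_variable_matches_naive_rescan(self, preset):
        for seed in range(20):
            rec, _ = generate_recording(GeneratorProfile(seed=seed, preset=preset))
            mine = as_dict(compute_all(rec))
            naive = naive_variables(rec)
            assert set(mine) == set(naive)
            for acr in mine:
                a, b = mine[acr], naive[acr]
                if b is None:
                    assert a is None, acr
                else:
                    assert a == pytest.approx(b, abs=1e-9), (acr, seed, preset)

    def test_conservation_identities(self):
        for seed in range(10):
            rec, _ = generate_recording(GeneratorProfile(seed=seed))
            v = as_dict(compute_all(rec))
            assert v["s_Np"] + v["s_Pr"] == pytest.approx(rec.total_duration, abs=1e-9)
            waveform_sum = (v["s_C"] + v["s_F"] + v["s_G"] + v["s_E1e"] + v["s_E1"]
                            + v["s_E2"] + v["s_pd"] + v["s_D"] + v["s_p-pd"])
            assert waveform_sum == pytest.approx(v["s_Pr"], abs=1e-9)


class TestTreatmentPercentages:
    def test_share_of_insects_with_e2(self, build):
        with_e2 = build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 30), ("Np", 5)])
        without = build([("Np", 5), ("C", 10), ("Np", 5)])
        results = [compute_all(with_e2)] * 4 + [compute_all(without)]
        tr = {r.acronym: r.value for r in treatment_percentages(results)}
        assert tr["%_E2/Tr"] == pytest.approx(80.0)
        assert tr["%_sE2/Tr"] == pytest.approx(80.0)  # the 30-min E2 is sustained

    def test_zero_share(self, build):
        rec = build([("Np", 5), ("C", 10), ("Np", 5)])
        tr = {r.acronym: r.value for r in treatment_percentages([compute_all(rec)] * 5)}
        assert tr["%_E2/Tr"] == 0.0 and tr["%_sE2/Tr"] == 0.0

    def test_single_recording(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 30), ("Np", 5)])
        tr = {r.acronym: r.value for r in treatment_percentages([compute_all(rec)])}
        assert tr["%_E2/Tr"] == 100.0
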