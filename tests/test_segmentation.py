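"""Probes, potential-drop groups, phloem phases and derived period classes."""

import pytest

from epgkit import (
    GeneratorProfile,
    classify_periods,
    find_phloem_phases,
    find_probes,
    generate_recording,
    group_pd_subphases,
)


class TestProbes:
    def test_maximal_runs_between_np(self, build):
        rec = build([("Np", 5), ("C", 10), ("Np", 5), ("C", 4), ("E1", 2),
                     ("E2", 20), ("Np", 30)])
        probes = find_probes(rec)
        assert len(probes) == 2
        assert [p.label for p in probes[0].periods] == ["C"]
        assert [p.label for p in probes[1].periods] == ["C", "E1", "E2"]
        assert probes[1].duration == pytest.approx(26.0)

    def test_brief_flag_strictly_under_three_minutes(self, build):
        rec = build([("Np", 5), ("C", 2.9), ("Np", 5), ("C", 120), ("Np", 5), ("C", 3.0)])
        flags = [p.brief for p in find_probes(rec)]
        assert flags == [True, False, False]

    def test_no_probes_when_only_np(self, build):
        rec = build([("Np", 480)])
        assert find_probes(rec) == []

    def test_partition_identity_on_generated_recording(self, aphid_recording):
        probes = find_probes(aphid_recording)
        s_probe = sum(p.duration for p in probes)
        s_np = sum(p.duration for p in aphid_recording.periods if p.label == "Np")
        assert s_probe + s_np == pytest.approx(aphid_recording.total_duration, abs=1e-9)


class TestPdGroups:
    def test_subphase_durations_by_differencing(self, build):
        rec = build([("Np", 5), ("C", 5), ("pd", 0.05), ("pdII-2", 0.03),
                     ("pdII-3", 0.02), ("C", 5), ("Np", 10)])
        (group,) = group_pd_subphases(rec)
        assert group.dur_II1 == pytest.approx(0.05)
        assert group.dur_II2 == pytest.approx(0.03)
        assert group.dur_II3 == pytest.approx(0.02)
        assert group.total == pytest.approx(0.10)
        assert group.kind == "standard-pd"

    def test_group_count(self, build):
        seq = [("Np", 5)]
        for _ in range(5):
            seq += [("C", 2), ("pd", 0.05), ("pdII-2", 0.03), ("pdII-3", 0.02)]
        seq += [("C", 2), ("Np", 10)]
        assert len(group_pd_subphases(build(seq))) == 5

    def test_code11_p_pd_mode_yields_p_pd_kind(self, build):
        rec = build([("Np", 5), ("C", 5), ("p-pd", 0.08), ("C", 5)], code11="p-pd")
        (group,) = group_pd_subphases(rec)
        assert group.kind == "p-pd"

    def test_incomplete_group_flagged_not_dropped(self, build):
        rec = build([("Np", 5), ("C", 5), ("pd", 0.05), ("C", 5)])
        (group,) = group_pd_subphases(rec)
        assert not group.complete and group.dur_II2 is None


class TestPhloemPhases:
    def test_single_phase_with_alternation(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 2), ("E2", 20), ("E1", 1),
                     ("E2", 30), ("C", 5)])
        (phase,) = find_phloem_phases(rec)
        assert len(phase.periods) == 4
        assert phase.reaches_E2

    def test_failing_then_successful_phase(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 2), ("C", 5), ("E1", 2),
                     ("E2", 20), ("Np", 10)])
        phases = find_phloem_phases(rec)
        assert [ph.reaches_E2 for ph in phases] == [False, True]

    def test_no_phloem_activity(self, build):
        rec = build([("Np", 5), ("C", 10), ("Np", 5)])
        assert find_phloem_phases(rec) == []

    def test_phases_nest_within_probes(self, aphid_recording):
        probes = find_probes(aphid_recording)
        for phase in find_phloem_phases(aphid_recording):
            containing = [
                pr for pr in probes
                if pr.start - 1e-12 <= phase.start and phase.end <= pr.end + 1e-12
            ]
            assert len(containing) == 1


class TestPeriodClasses:
    def test_sustained_e2_strict_threshold(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 9.9), ("E1", 1),
                     ("E2", 10.1), ("C", 5)])
        tags = classify_periods(rec)
        flagged = [rec.periods[i].duration for i in sorted(tags.sE2)]
        assert flagged == pytest.approx([10.1])

    def test_fractionating_vs_initial_e1(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 1), ("E2", 20), ("E1", 2),
                     ("E2", 30), ("C", 5)])
        tags = classify_periods(rec)
        assert [rec.periods[i].label for i in tags.initial_E1_followed_E2] == ["E1"]
        assert sorted(tags.initial_E1_followed_E2) == [2]
        assert sorted(tags.frE1) == [4]

    def test_lone_e1_phase_tagged_single(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 3), ("C", 5)])
        tags = classify_periods(rec)
        assert sorted(tags.sgE1) == [2]
        assert not tags.frE1 and not tags.E12

    def test_e12_pseudo_period_spans_whole_phase(self, build):
        rec = build([("Np", 5), ("C", 5), ("E1", 2), ("E2", 20), ("E1", 1),
                     ("E2", 30), ("C", 5)])
        tags = classify_periods(rec)
        assert tags.E12 == [(10.0, 53.0)]

    def test_single_d_is_d_not_followed_by_e1(self, build):
        rec = build([("Np", 5), ("C", 5), ("D", 1), ("C", 3), ("D", 1),
                     ("E1", 2), ("E2", 20), ("Np", 10)], code11="D")
        tags = classify_periods(rec)
        assert sorted(tags.sgD) == [2]

    def test_tag_consistency_identity(self, aphid_recording):
        # phases without E2 hold the single-E1 periods; with the grammar in
        # force each failing phase is exactly one E1
        phases = find_phloem_phases(aphid_recording)
        tags = classify_periods(aphid_recording, phases)
        n_fail = sum(1 for ph in phases if not ph.reaches_E2)
        assert len(tags.sgE1) == n_fail
        assert len(tags.E12) + n_fail == len(phases)
        assert not (tags.sgE1 & tags.frE1)
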