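import math

import pytest

from c4recruit.c4families import DUPLICATE_PROFILES
from c4recruit.diurnal import (
    TimeCourse,
    compare_duplicates,
    detect_duplicates,
    normalize_timecourse,
    summarize_timecourse,
)
from c4recruit.simulate import SimulationConfig, simulate_time_course


def profiles_and_assignment():
    profiles = {
        row["gene"]: {s: float(row[s]) for s in "ABCD"}
        for row in DUPLICATE_PROFILES
    }
    assignment = {
        row["gene"]: (row["family"], row["lineage"], row["species"])
        for row in DUPLICATE_PROFILES
    }
    return profiles, assignment


class TestDetectDuplicates:
    def test_groups_by_lineage_and_species(self):
        profiles, assignment = profiles_and_assignment()
        groups = detect_duplicates(assignment, profiles)
        keys = {(g.family_id, g.species_id) for g in groups}
        assert ("beta-CA", "Setaria") in keys
        assert ("beta-CA", "Zea") in keys
        zea_bca = next(
            g for g in groups
            if g.family_id == "beta-CA" and g.species_id == "Zea"
        )
        assert len(zea_bca.profiles) == 3

    def test_single_gene_makes_no_group(self):
        groups = detect_duplicates(
            {"g1": ("F", "1", "Zea")}, {"g1": dict(A=1, B=2, C=3, D=4)}
        )
        assert groups == []

    def test_identical_cds_pair_merged_by_averaging(self):
        profiles = {
            "g1": dict(A=100.0, B=0.0, C=0.0, D=0.0),
            "g2": dict(A=200.0, B=0.0, C=0.0, D=0.0),
            "g3": dict(A=5.0, B=5.0, C=5.0, D=5.0),
        }
        assignment = {g: ("F", "1", "Setaria") for g in profiles}
        groups = detect_duplicates(
            assignment, profiles, identical_cds=[frozenset({"g1", "g2"})]
        )
        assert len(groups) == 1
        assert groups[0].profiles["g1/g2"]["A"] == pytest.approx(150.0)

    def test_merging_is_idempotent(self):
        profiles, assignment = profiles_and_assignment()
        groups = detect_duplicates(assignment, profiles)
        # feed the merged output back in: nothing changes
        profiles2 = {
            g: dict(p) for grp in groups for g, p in grp.profiles.items()
        }
        assignment2 = {
            g: (grp.family_id, grp.lineage_id, grp.species_id)
            for grp in groups
            for g in grp.profiles
        }
        groups2 = detect_duplicates(assignment2, profiles2)
        assert {
            (g.family_id, g.species_id): sorted(g.profiles) for g in groups
        } == {
            (g.family_id, g.species_id): sorted(g.profiles) for g in groups2
        }


class TestCompareDuplicates:
    def test_published_setaria_beta_ca_dominance(self):
        """The published Setaria beta-CA pair: one duplicate strongly
        development-regulated, the merged identical-CDS pair barely
        detected."""
        profiles, assignment = profiles_and_assignment()
        groups = detect_duplicates(assignment, profiles)
        seta = next(g for g in groups if g.species_id == "Setaria")
        report = compare_duplicates(seta)
        assert report.dominant_gene == "Si003882"
        assert report.max_rpkm["Si003882"] == 8297
        assert report.dev_increase["Si003882"]
        assert report.dominance_ratio == pytest.approx(8297 / 56)

    def test_hundredfold_dominance(self):
        from c4recruit.diurnal import DuplicateGroup

        group = DuplicateGroup(
            "F", "1", "Zea",
            profiles={
                "g1": dict(A=0.0, B=0.0, C=400.0, D=800.0),
                "g2": dict(A=0.0, B=0.0, C=4.0, D=8.0),
            },
        )
        report = compare_duplicates(group)
        assert report.dominant_gene == "g1"
        assert report.dominance_ratio == pytest.approx(100.0)
        assert report.dev_increase == {"g1": True, "g2": True}

    def test_tie_and_zero_runner_up(self):
        from c4recruit.diurnal import DuplicateGroup

        equal = DuplicateGroup(
            "F", "1", "Zea",
            profiles={"b": dict(A=1.0, B=1.0, C=1.0, D=1.0),
                      "a": dict(A=1.0, B=1.0, C=1.0, D=1.0)},
        )
        rep = compare_duplicates(equal)
        assert rep.tie and rep.dominance_ratio == 1.0
        assert rep.dominant_gene == "a"  # deterministic id order

        silent = DuplicateGroup(
            "F", "1", "Zea",
            profiles={"g1": dict(A=2.0, B=0.0, C=0.0, D=0.0),
                      "g2": dict(A=0.0, B=0.0, C=0.0, D=0.0)},
        )
        assert math.isinf(compare_duplicates(silent).dominance_ratio)

    def test_permutation_invariant(self):
        profiles, assignment = profiles_and_assignment()
        groups = detect_duplicates(assignment, profiles)
        for group in groups:
            rep = compare_duplicates(group)
            reversed_group = type(group)(
                group.family_id, group.lineage_id, group.species_id,
                profiles=dict(reversed(list(group.profiles.items()))),
            )
            rep2 = compare_duplicates(reversed_group)
            assert rep.dominant_gene == rep2.dominant_gene
            assert rep.dominance_ratio == rep2.dominance_ratio


class TestTimeCourse:
    def test_normalization_examples(self):
        tc = TimeCourse(
            gene_id="g", species_id="A", photo_type="C4",
            times=[0, 4, 8],
            signals=[[2.0], [1.0], [3.0]],
            reference=[[1.0], [1.0], [1.0]],
        )
        norm = normalize_timecourse(tc)
        assert norm.mean == pytest.approx([2.0, 1.0, 3.0])

        flat = TimeCourse(
            gene_id="g", species_id="A", photo_type="C4",
            times=[0, 4], signals=[[5.0, 5.0], [7.0, 7.0]],
            reference=[[5.0, 5.0], [7.0, 7.0]],
        )
        n = normalize_timecourse(flat)
        assert n.mean == pytest.approx([1.0, 1.0])
        assert n.se == pytest.approx([0.0, 0.0])

    def test_zero_reference_names_the_point(self):
        tc = TimeCourse(
            gene_id="g", species_id="A", photo_type="C4",
            times=[0, 4], signals=[[1.0], [1.0]],
            reference=[[1.0], [0.0]],
        )
        with pytest.raises(ValueError, match="t=4"):
            normalize_timecourse(tc)

    def test_summary_peak_trough_amplitude(self):
        cfg = SimulationConfig(seed=0)
        tc = simulate_time_course(cfg, seed=0, peak_time=4.0)
        norm = normalize_timecourse(tc)
        summary = summarize_timecourse(tc.times, norm.mean)
        assert summary.peak_time == 4.0
        assert summary.trough_time == 16.0
        assert summary.in_phase_with_light

        const = summarize_timecourse([0, 4, 8], [2.0, 2.0, 2.0])
        assert const.amplitude == 0.0

        night_peak = summarize_timecourse([0, 8, 16], [1.0, 2.0, 5.0])
        assert not night_peak.in_phase_with_light

    def test_scale_equivariance(self):
        cfg = SimulationConfig(seed=0)
        tc = simulate_time_course(cfg, seed=0, peak_time=8.0, amplitude=2.0)
        norm = normalize_timecourse(tc)
        scaled = TimeCourse(
            gene_id=tc.gene_id, species_id=tc.species_id,
            photo_type=tc.photo_type, times=tc.times,
            signals=tc.signals * 3.5, reference=tc.reference,
        )
        norm_s = normalize_timecourse(scaled)
        assert norm_s.mean == pytest.approx(3.5 * norm.mean)
        s1 = summarize_timecourse(tc.times, norm.mean)
        s2 = summarize_timecourse(tc.times, norm_s.mean)
        assert (s1.peak_time, s1.trough_time, s1.in_phase_with_light) == (
            s2.peak_time, s2.trough_time, s2.in_phase_with_light
        )

    def test_c4_c3_peak_ratio(self):
        cfg = SimulationConfig(seed=0)
        c4 = simulate_time_course(cfg, seed=0, photo_type="C4", amplitude=3.0)
        c3 = simulate_time_course(cfg, seed=0, photo_type="C3")
        m4 = normalize_timecourse(c4).mean
        m3 = normalize_timecourse(c3).mean
        summary = summarize_timecourse(c4.times, m4, c3_means=m3)
        assert summary.c4_c3_peak_ratio == pytest.approx(4.0)
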