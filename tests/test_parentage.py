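"""Haplotype matching, multi-locus assignment, ambiguity classes, unknown
parents, and cross tabulation against the simulator's truth."""

import numpy as np
import pandas as pd
import pytest

import bryoparent as bp
from bryoparent.panel import class_id
from bryoparent.parentage import (
    CLASS_RESOLVED,
    CONFLICT,
    RESOLVED,
    STATUS_AMBIGUOUS,
    UNKNOWN_PARENT,
    LocusMatch,
    UnknownRegistry,
    assign_parentage,
    match_haplotype,
    tabulate_crosses,
)


def _mask(hap: str, positions) -> str:
    out = list(hap)
    for p in positions:
        out[p] = "N"
    return "".join(out)


class TestMatchHaplotype:
    def test_exact_match_names_the_parent(self, study_panel):
        hap = study_panel.haplotype("M5", "L1")
        m = match_haplotype(hap, study_panel, "L1", min_overlap=3)
        assert "M5" in m.candidates
        assert m.n_mismatch == 0
        # every candidate shares M5's profile at this locus
        vp = study_panel.locus("L1").variant_positions
        for c in m.candidates:
            other = study_panel.haplotype(c, "L1")
            assert all(other[p] == hap[p] for p in vp)

    def test_all_n_haplotype_abstains(self, study_panel):
        m = match_haplotype("N" * 300, study_panel, "L1", min_overlap=3)
        assert m.insufficient and m.candidates == frozenset()

    def test_n_at_diagnostic_sites_triggers_abstention(self, study_panel):
        vp = study_panel.locus("L1").variant_positions
        hap = _mask(study_panel.haplotype("F1", "L1"), vp[:1])
        m = match_haplotype(hap, study_panel, "L1", min_overlap=3)
        assert m.insufficient  # 2 of 3 sites comparable < min_overlap 3

    def test_ambiguous_pair_matched_as_a_set(self):
        panel = bp.simulate_panel(6, 9, force_ambiguous_female_pair=True, seed=3)
        group = panel.ambiguity_groups[0]
        member = sorted(group)[0]
        for locus in panel.loci:
            m = match_haplotype(panel.haplotype(member, locus.locus_id), panel,
                                locus.locus_id, min_overlap=3)
            assert group <= m.candidates

    def test_private_variant_outside_diagnostics_excludes_parent(self, study_panel):
        hap = list(study_panel.haplotype("M5", "L1"))
        vp = set(study_panel.locus("L1").variant_positions)
        pos = next(p for p in range(50, 260) if p not in vp)
        hap[pos] = "A" if hap[pos] != "A" else "G"
        m = match_haplotype("".join(hap), study_panel, "L1", min_overlap=3)
        assert m.candidates == frozenset()  # foreign: private mutation counted
        assert m.n_mismatch == 1

    def test_wrong_length_rejected(self, study_panel):
        with pytest.raises(ValueError, match="length"):
            match_haplotype("ACGT", study_panel, "L1")


def _true_matches(panel, mother, father, mask_sites=None, drop_loci=()):
    """Per-locus matches for an error-free sporophyte of (mother, father),
    optionally masking diagnostic positions to N."""
    matches = []
    for locus in panel.loci:
        if locus.locus_id in drop_loci:
            continue
        for label, parent in (("a", mother), ("b", father)):
            hap = panel.haplotype(parent, locus.locus_id)
            if mask_sites:
                hap = _mask(hap, mask_sites.get(locus.locus_id, ()))
            matches.append(
                match_haplotype(hap, panel, locus.locus_id, min_overlap=3,
                                sporophyte_id="S1", hap_label=label)
            )
    return matches


class TestAssignParentage:
    def test_full_information_resolves(self, study_panel):
        a = assign_parentage(_true_matches(study_panel, "F7", "M5"), study_panel)
        assert (a.mother, a.father, a.status) == ("F7", "M5", RESOLVED)

    def test_forced_pair_class_resolves_never_single_member(self):
        panel = bp.simulate_panel(6, 9, force_ambiguous_female_pair=True, seed=3)
        group = panel.ambiguity_groups[0]
        merged = class_id(group)
        for member in sorted(group):
            a = assign_parentage(_true_matches(panel, member, "M2"), panel)
            assert a.status == CLASS_RESOLVED
            assert a.mother == merged
            assert a.father == "M2"

    def test_foreign_bundle_reported_unknown_with_stable_id(self, study_panel):
        foreign = {}
        for locus in study_panel.loci:
            hap = list(locus.reference_seq)
            hap[5] = "A" if hap[5] != "A" else "C"  # private variant everywhere
            foreign[locus.locus_id] = "".join(hap)
        matches = []
        bundle_seqs = {"a": {}, "b": {}}
        for locus in study_panel.loci:
            mhap = study_panel.haplotype("F4", locus.locus_id)
            matches.append(match_haplotype(mhap, study_panel, locus.locus_id,
                                           min_overlap=3, sporophyte_id="S1",
                                           hap_label="a"))
            bundle_seqs["a"][locus.locus_id] = mhap
            matches.append(match_haplotype(foreign[locus.locus_id], study_panel,
                                           locus.locus_id, min_overlap=3,
                                           sporophyte_id="S1", hap_label="b"))
            bundle_seqs["b"][locus.locus_id] = foreign[locus.locus_id]
        reg = UnknownRegistry()
        a = assign_parentage(matches, study_panel, unknown_registry=reg,
                             bundle_seqs=bundle_seqs)
        assert a.status == UNKNOWN_PARENT
        assert a.mother == "F4"
        assert a.father == "U1"
        # the same foreign genotype seen again gets the same id
        b = assign_parentage(matches, study_panel, unknown_registry=reg,
                             bundle_seqs=bundle_seqs)
        assert b.father == "U1"

    def test_two_same_sex_bundles_conflict(self, study_panel):
        a = assign_parentage(_true_matches(study_panel, "F7", "F3"), study_panel)
        assert a.status == CONFLICT

    def test_zero_informative_loci_raises(self, study_panel):
        matches = [
            match_haplotype("N" * 300, study_panel, locus.locus_id, min_overlap=3,
                            sporophyte_id="S1", hap_label=label)
            for locus in study_panel.loci
            for label in ("a", "b")
        ]
        with pytest.raises(ValueError, match="informative"):
            assign_parentage(matches, study_panel)

    def test_masked_diagnostics_demote_to_ambiguous_not_wrong(self, study_panel):
        # mask every diagnostic site at every locus for the maternal hap
        mask = {l.locus_id: l.variant_positions for l in study_panel.loci}
        matches = []
        for locus in study_panel.loci:
            mhap = _mask(study_panel.haplotype("F7", locus.locus_id),
                         mask[locus.locus_id])
            matches.append(match_haplotype(mhap, study_panel, locus.locus_id,
                                           min_overlap=3, sporophyte_id="S1",
                                           hap_label="a"))
            matches.append(match_haplotype(study_panel.haplotype("M5", locus.locus_id),
                                           study_panel, locus.locus_id, min_overlap=3,
                                           sporophyte_id="S1", hap_label="b"))
        a = assign_parentage(matches, study_panel)
        assert a.status == STATUS_AMBIGUOUS
        assert a.father == "M5"

    def test_intersection_shrinks_with_added_loci(self, study_panel):
        """Adding an informative locus never grows the candidate intersection."""
        sizes = []
        for n_loci in (1, 2, 3, 4, 5):
            drop = [l.locus_id for l in study_panel.loci[n_loci:]]
            matches = [m for m in _true_matches(study_panel, "F7", "M5", drop_loci=drop)
                       if m.hap_label == "a"]
            inter = frozenset.intersection(*(m.candidates for m in matches if m.candidates))
            sizes.append(len(inter))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] == 1


def _sheet_for(ids, treatment="arthropod"):
    return pd.DataFrame(
        {
            "sample_id": ids,
            "i5_index": ["AAAAAAAA"] * len(ids),
            "i7_index": [f"{'ACGT'[i % 4] * 8}" for i in range(len(ids))],
            "mesocosm_id": ["A1"] * len(ids),
            "treatment": [treatment] * len(ids),
            "distance_cm": [10.0] * len(ids),
            "angle_deg": [0.0] * len(ids),
        }
    )


class TestTabulateCrosses:
    def test_empty_input_gives_empty_table(self):
        table = tabulate_crosses([], _sheet_for([]))
        assert len(table.counts) == 0 and table.total == 0

    def test_single_cell_count(self, study_panel):
        assignments = [
            assign_parentage(
                [m for m in _true_matches(study_panel, "F7", "M5")],
                study_panel,
            )
            for _ in range(10)
        ]
        for i, a in enumerate(assignments):
            a.sporophyte_id = f"S{i}"
        table = tabulate_crosses(assignments, _sheet_for([f"S{i}" for i in range(10)]))
        assert len(table.counts) == 1
        row = table.counts.iloc[0]
        assert (row["mother"], row["father"], row["count"]) == ("F7", "M5", 10)

    def test_cross_table_matches_truth_join_on_clean_run(self, study_panel):
        design = bp.MesocosmDesign(
            female_ids=study_panel.females(), male_ids=study_panel.males(),
            n_sporophytes=40,
        )
        truth = bp.simulate_crosses(study_panel, design, seed=31)
        sheet = bp.make_sample_sheet(truth, seed=32)
        assignments = []
        for t in truth:
            matches = _true_matches(study_panel, t.mother_id, t.father_id)
            a = assign_parentage(matches, study_panel)
            a.sporophyte_id = t.sporophyte_id
            assignments.append(a)
        table = tabulate_crosses(assignments, sheet)
        expected = (
            bp.synth.truth_frame(truth)
            .groupby(["mother_id", "father_id", "treatment", "mesocosm_id"])
            .size()
            .reset_index(name="count")
        )
        got = table.counts.sort_values(list(table.counts.columns)).reset_index(drop=True)
        expected.columns = list(table.counts.columns)
        expected = expected.sort_values(list(expected.columns)).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, expected, check_dtype=False)
        assert table.total == len(truth)
        assert not table.excluded
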