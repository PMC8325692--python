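"""The candidate cascade against the packaged family tables.

Stage-by-stage survivor counts and the surviving gene identifiers are
pinned to the published screen of the two Fragaria RNase T2 families.
"""

from itertools import permutations

import pytest

from srnase.candidate_screen import (
    ScreenConfig,
    filter_domain_integrity,
    filter_intron_count,
    filter_pattern4,
    filter_pi,
    filter_signal_peptide,
    pair_alleles,
    run_screen,
)
from srnase.datasets import CROSSTRIBE_REF_IDS
from srnase.io_formats import FeatureTable, IdentityMatrix
from srnase.protein_features import ABOVE_060, RNaseT2Record

VESCA_FOUR = {"FvH4_1g10040.1", "FvH4_5g33850.1", "FvH4_1g19170.1", "FvH4_4g18130.1"}
VIRIDIS_FOUR = {"Unigene23139.1", "CL6424.Contig1.1", "Unigene10929.1", "Unigene7320.1"}


def _chain(records, *filters):
    for f in filters:
        records = f(records)
    return records


class TestFilters:
    def test_signal_peptide_survivors(self, fvesca, fviridis):
        assert len(filter_signal_peptide(fvesca.records)) == 12
        assert len(filter_signal_peptide(fviridis.records)) == 8
        assert filter_signal_peptide([]) == []

    def test_domain_integrity_removals(self, fvesca, fviridis):
        vesca_sp = filter_signal_peptide(fvesca.records)
        viridis_sp = filter_signal_peptide(fviridis.records)
        assert len(filter_domain_integrity(vesca_sp)) == 9  # 3 removed
        assert len(filter_domain_integrity(viridis_sp)) == 7  # 1 removed

    def test_numeric_coverage_wins_and_061_passes(self):
        rec = RNaseT2Record(gene_id="g", species="sp", domain_coverage=0.61)
        assert filter_domain_integrity([rec]) == [rec]
        rec_low = RNaseT2Record(gene_id="h", species="sp", domain_coverage=0.60)
        assert filter_domain_integrity([rec_low]) == []  # strict >

    def test_pi_removals(self, fvesca, fviridis):
        vesca = _chain(fvesca.records, filter_signal_peptide, filter_domain_integrity)
        viridis = _chain(fviridis.records, filter_signal_peptide, filter_domain_integrity)
        assert len(filter_pi(vesca)) == 6  # 3 removed
        assert len(filter_pi(viridis)) == 4  # 3 removed

    def test_pi_boundary_inclusive(self):
        rec = RNaseT2Record(gene_id="g", species="sp", pI=8.0)
        assert filter_pi([rec]) == [rec]
        rec10 = RNaseT2Record(gene_id="h", species="sp", pI=10.0)
        assert filter_pi([rec10]) == [rec10]

    def test_intron_filter_names_the_four_survivors(self, fvesca, fviridis):
        vesca = _chain(
            fvesca.records, filter_signal_peptide, filter_domain_integrity, filter_pi
        )
        viridis = _chain(
            fviridis.records, filter_signal_peptide, filter_domain_integrity, filter_pi
        )
        assert {r.gene_id for r in filter_intron_count(vesca)} == VESCA_FOUR
        assert {r.gene_id for r in filter_intron_count(viridis)} == VIRIDIS_FOUR

    def test_three_introns_removed(self):
        rec = RNaseT2Record(gene_id="g", species="sp", intron_count=3)
        assert filter_intron_count([rec]) == []

    def test_pattern4_removal_and_toggle(self):
        hit = RNaseT2Record(gene_id="g", species="sp", pattern4_motif="CPSSNG")
        clean = RNaseT2Record(gene_id="h", species="sp")
        assert filter_pattern4([hit, clean]) == [clean]
        off = ScreenConfig(pattern4_excludes=False)
        assert filter_pattern4([hit, clean], off) == [hit, clean]

    def test_pattern4_detected_from_sequence(self):
        seq_hit = RNaseT2Record(gene_id="g", species="sp", sequence="MKCPSSNGQ")
        assert filter_pattern4([seq_hit]) == []

    def test_absent_feature_is_error(self):
        no_pi = RNaseT2Record(gene_id="g", species="sp")
        with pytest.raises(ValueError, match="pI absent"):
            filter_pi([no_pi])
        with pytest.raises(ValueError, match="coverage absent"):
            filter_domain_integrity([no_pi])
        with pytest.raises(ValueError, match="intron count absent"):
            filter_intron_count([no_pi])


class TestPairAlleles:
    def _candidates(self, fviridis):
        return [r for r in fviridis.records if r.gene_id in VIRIDIS_FOUR]

    def test_stage1_identity_window(self, fviridis, candidate_identities):
        stage1, _ = pair_alleles(self._candidates(fviridis), candidate_identities)
        assert {frozenset((a, b)): x for a, b, x in stage1} == {
            frozenset(("Unigene10929.1", "Unigene7320.1")): 56.48,
            frozenset(("Unigene23139.1", "Unigene7320.1")): 30.88,
        }

    def test_stage2_crosstribe_rule_selects_single_pair(
        self, fviridis, candidate_identities, crosstribe
    ):
        _, selected = pair_alleles(
            self._candidates(fviridis),
            candidate_identities,
            crosstribe=crosstribe,
            crosstribe_refs=CROSSTRIBE_REF_IDS,
        )
        assert [frozenset((a, b)) for a, b, _ in selected] == [
            frozenset(("Unigene10929.1", "Unigene7320.1"))
        ]

    def test_single_candidate_yields_no_pairs(self, fviridis, candidate_identities):
        one = self._candidates(fviridis)[:1]
        assert pair_alleles(one, candidate_identities) == ([], [])

    def test_missing_matrix_entry_is_error(self, fviridis):
        with pytest.raises(KeyError):
            pair_alleles(self._candidates(fviridis), IdentityMatrix())


class TestRunScreen:
    def test_full_viridis_final_candidates(
        self, fviridis, candidate_identities, crosstribe
    ):
        rep = run_screen(
            fviridis,
            candidate_identities,
            crosstribe=crosstribe,
            crosstribe_refs=CROSSTRIBE_REF_IDS,
        )
        sp = rep.species_reports["F. viridis"]
        assert set(sp.final_candidates) == {"Unigene10929.1", "Unigene7320.1"}

    def test_full_vesca_has_no_eligible_pairs(
        self, fvesca, candidate_identities, crosstribe
    ):
        rep = run_screen(
            fvesca,
            candidate_identities,
            crosstribe=crosstribe,
            crosstribe_refs=CROSSTRIBE_REF_IDS,
        )
        sp = rep.species_reports["F. vesca"]
        assert sp.allele_pairs == []
        assert sp.final_candidates == []

    @pytest.mark.parametrize(
        "fixture_name,counts",
        [("fvesca", [14, 12, 9, 6, 4]), ("fviridis", [13, 8, 7, 4, 4])],
    )
    def test_stage_counts_chain(self, request, fixture_name, counts):
        table = request.getfixturevalue(fixture_name)
        rep = run_screen(table)
        (sp_rep,) = rep.species_reports.values()
        assert [len(s.input_ids) for s in sp_rep.stages] == counts[:-1] + [counts[-1]]
        assert [len(s.kept_ids) for s in sp_rep.stages] == counts[1:] + [counts[-1]]
        # stages chain: stage k input is stage k-1 kept
        for prev, nxt in zip(sp_rep.stages, sp_rep.stages[1:]):
            assert nxt.input_ids == prev.kept_ids

    def test_kept_plus_removed_partitions_input(self, fviridis):
        rep = run_screen(fviridis)
        for stage in rep.species_reports["F. viridis"].stages:
            removed_ids = [i for i, _ in stage.removed]
            assert sorted(stage.kept_ids + removed_ids) == sorted(stage.input_ids)
            assert len(set(removed_ids)) == len(removed_ids)

    def test_empty_table_gives_empty_report(self):
        rep = run_screen(FeatureTable(records=[]))
        assert rep.species_reports == {}

    def test_filter_order_does_not_change_final_set(self, fvesca, fviridis):
        """As pure predicates the five filters commute."""
        from srnase.candidate_screen import _FILTERS

        cfg = ScreenConfig()
        for table in (fvesca, fviridis):
            reference = None
            for order in list(permutations(_FILTERS.values()))[:12]:
                result = list(table.records)
                for f in order:
                    result = f(result, cfg)
                ids = {r.gene_id for r in result}
                reference = ids if reference is None else reference
                assert ids == reference
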