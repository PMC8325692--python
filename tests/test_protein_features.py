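"""Feature primitives checked against independent oracles.

The pI bisection is checked against a fine-grid scan of the charge
curve and against Biopython's implementation of the same Bjellqvist
model; the aligner is checked against exhaustive enumeration of all
global alignments on short pairs.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from alignment_oracle import brute_force_alignments
from srnase.io_formats import DomainHit
from srnase.protein_features import (
    AlignmentScoring,
    RegionSpec,
    align_global,
    compute_isoelectric_point,
    compute_molecular_weight,
    count_introns,
    domain_coverage,
    net_charge,
    pairwise_identity,
    project_regions,
    scan_pattern4,
)

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_strategy = st.text(alphabet=AA, min_size=1, max_size=60)


def grid_scan_pi(sequence: str, step: float = 1e-4) -> float:
    """Independent oracle: locate the charge-curve zero on a fine pH grid."""
    grid = np.arange(0.0, 14.0 + step, step)
    charges = np.array([net_charge(sequence, ph) for ph in grid[:: 1000]])
    # Coarse bracket first, then fine scan inside it (keeps the oracle exact
    # to `step` without evaluating the full 140001-point grid per sequence).
    sign_flip = np.nonzero(np.diff(np.sign(charges)))[0]
    lo = grid[sign_flip[0] * 1000] if len(sign_flip) else 0.0
    fine = np.arange(max(0.0, lo - 0.2), min(14.0, lo + 0.3), step)
    fine_charges = np.array([net_charge(sequence, ph) for ph in fine])
    return float(fine[np.argmin(np.abs(fine_charges))])


class TestIsoelectricPoint:
    def test_charge_is_zero_at_pi(self):
        for seq in ("GGGG", "MKVDEHRKY", "ACDEFGHIKLMNPQRSTVWY"):
            pi = compute_isoelectric_point(seq)
            assert abs(net_charge(seq, pi)) < 1e-2

    def test_gggg_matches_fine_grid_oracle(self):
        assert compute_isoelectric_point("GGGG") == pytest.approx(
            grid_scan_pi("GGGG"), abs=2e-3
        )

    def test_acidic_below_basic(self):
        assert compute_isoelectric_point("DDDD") < compute_isoelectric_point("KKKK")

    @given(seq=seq_strategy)
    def test_bisection_agrees_with_grid(self, seq):
        assert compute_isoelectric_point(seq) == pytest.approx(
            grid_scan_pi(seq), abs=2e-3
        )

    # Insertion is internal: appending would swap the residue-specific
    # terminal pK (Bjellqvist), which can shift pI the other way.
    @given(seq=st.text(alphabet=AA, min_size=2, max_size=60))
    def test_basic_residue_never_decreases_pi(self, seq):
        base = compute_isoelectric_point(seq)
        mid = len(seq) // 2
        for aa in "KR":
            inserted = seq[:mid] + aa + seq[mid:]
            assert compute_isoelectric_point(inserted) >= base - 2e-3

    @given(seq=st.text(alphabet=AA, min_size=2, max_size=60))
    def test_acidic_residue_never_increases_pi(self, seq):
        base = compute_isoelectric_point(seq)
        mid = len(seq) // 2
        for aa in "DE":
            inserted = seq[:mid] + aa + seq[mid:]
            assert compute_isoelectric_point(inserted) <= base + 2e-3

    @given(seq=st.text(alphabet=AA, min_size=5, max_size=80))
    def test_agrees_with_biopython_same_model(self, seq):
        from Bio.SeqUtils.IsoelectricPoint import IsoelectricPoint

        # full [0, 14] bracket: Biopython's default bracket floor is 4.05
        assert compute_isoelectric_point(seq) == pytest.approx(
            IsoelectricPoint(seq).pi(7.0, 0.0, 14.0), abs=5e-3
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_isoelectric_point("")

    def test_nonstandard_residues_warn(self):
        with pytest.warns(UserWarning, match="nonstandard"):
            compute_isoelectric_point("MKXVB")


class TestMolecularWeight:
    def test_glycine(self):
        assert compute_molecular_weight("G") == pytest.approx(0.07507, abs=1e-4)

    @given(s1=seq_strategy, s2=seq_strategy)
    def test_condensation_additivity(self, s1, s2):
        water_kda = 0.01801524
        assert compute_molecular_weight(s1 + s2) == pytest.approx(
            compute_molecular_weight(s1) + compute_molecular_weight(s2) - water_kda,
            abs=1e-9,
        )

    @given(seq=seq_strategy)
    def test_agrees_with_biopython_average_masses(self, seq):
        from Bio.SeqUtils import molecular_weight

        assert compute_molecular_weight(seq) * 1000 == pytest.approx(
            molecular_weight(seq, seq_type="protein"), rel=1e-4
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            compute_molecular_weight("")


class TestPattern4:
    @pytest.mark.parametrize(
        "sequence,expected",
        [
            ("MKCPSSNGQ", [(3, "CPSSNG")]),
            ("MKCPSSSGQ", [(3, "CPSSSG")]),
            ("CPSTNG", []),
            ("", []),
            ("CPSSNGCPSSSG", [(1, "CPSSNG"), (7, "CPSSSG")]),
        ],
    )
    def test_motif_scan(self, sequence, expected):
        assert scan_pattern4(sequence) == expected


class TestDomainCoverage:
    def _hit(self, lo, hi, model=100):
        return DomainHit("t", "RNaseT2", model, lo, hi)

    @pytest.mark.parametrize(
        "spans,model,expected",
        [
            ([(1, 100)], 200, 0.5),
            ([(1, 60), (41, 100)], 100, 1.0),
            ([(1, 10), (91, 100)], 100, 0.2),
        ],
    )
    def test_union_coverage(self, spans, model, expected):
        hits = [DomainHit("t", "m", model, lo, hi) for lo, hi in spans]
        assert domain_coverage(hits) == pytest.approx(expected)

    def test_invariant_under_order_and_duplication(self):
        hits = [self._hit(1, 60), self._hit(41, 100), self._hit(5, 20)]
        baseline = domain_coverage(hits)
        assert domain_coverage(hits[::-1]) == baseline
        assert domain_coverage(hits + [hits[0]]) == baseline

    def test_mixed_model_lengths_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            domain_coverage([self._hit(1, 10, 100), self._hit(1, 10, 200)])

    def test_empty_hits_give_zero(self):
        assert domain_coverage([]) == 0.0


class TestIntronCount:
    @pytest.mark.parametrize("n_exons,expected", [(3, 2), (1, 0), (10, 9)])
    def test_exons_minus_one(self, n_exons, expected):
        exons = [(i * 100 + 1, i * 100 + 50) for i in range(n_exons)]
        assert count_introns(exons) == expected

    def test_zero_exons_rejected(self):
        with pytest.raises(ValueError):
            count_introns([])

    def test_overlapping_exons_rejected(self):
        with pytest.raises(ValueError):
            count_introns([(1, 50), (40, 90)])


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("MKVLI", "MKVLI") == 100.00

    def test_disjoint_sequences(self):
        assert pairwise_identity("AAAA", "TTTT") == 0.00

    @given(a=st.text(alphabet="ACDE", min_size=1, max_size=6),
           b=st.text(alphabet="ACDE", min_size=1, max_size=6))
    @settings(max_examples=40)
    def test_matches_brute_force_enumeration(self, a, b):
        best_score, identities = brute_force_alignments(a, b)
        _, _, score = align_global(a, b)
        assert score == pytest.approx(best_score)
        assert pairwise_identity(a, b) in identities

    @given(a=seq_strategy, b=seq_strategy)
    @settings(max_examples=30)
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b) == pairwise_identity(b, a)

    @given(a=st.text(alphabet=AA, min_size=1, max_size=25),
           b=st.text(alphabet=AA, min_size=1, max_size=25))
    @settings(max_examples=30)
    def test_hundred_iff_identical(self, a, b):
        assert (pairwise_identity(a, b) == 100.0) == (a == b)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "MKV")


class TestProjectRegions:
    def test_whole_width_single_sequence(self):
        spec = RegionSpec(regions={"ALL": (1, 5)})
        assert project_regions([("q", "MKVLI")], spec, "q") == {"ALL": "MKVLI"}

    def test_all_gap_span_is_empty(self):
        spec = RegionSpec(regions={"C1": (1, 2), "C2": (3, 4)})
        out = project_regions([("q", "MK--"), ("r", "MKVL")], spec, "q")
        assert out == {"C1": "MK", "C2": ""}

    def test_toy_alignment_manual_indexing(self):
        aln = [
            ("s1", "MK-VLID"),
            ("s2", "MKQV-ID"),
            ("s3", "MKQVLID"),
        ]
        spec = RegionSpec(regions={"C1": (1, 3), "RHV": (4, 5), "C2": (6, 7)})
        assert project_regions(aln, spec, "s1") == {"C1": "MK", "RHV": "VL", "C2": "ID"}
        assert project_regions(aln, spec, "s2") == {"C1": "MKQ", "RHV": "V", "C2": "ID"}
        assert project_regions(aln, spec, "s3") == {"C1": "MKQ", "RHV": "VL", "C2": "ID"}

    def test_span_beyond_width_rejected(self):
        spec = RegionSpec(regions={"C1": (1, 9)})
        with pytest.raises(ValueError, match="beyond"):
            project_regions([("q", "MKV")], spec, "q")

    def test_region_ordering_enforced(self):
        with pytest.raises(ValueError):
            RegionSpec(regions={"C2": (5, 8), "C1": (1, 6)})
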