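"""Per-protein features consumed by the S-RNase candidate screen.

S-RNases are style-expressed members of the RNase T2 family and can be
distinguished from their non-S relatives by a small set of physicochemical
and structural features: a secretory signal peptide, an intact RNase T2
domain, a basic isoelectric point (pI 8-10), at most two introns, and the
absence of the diagnostic "pattern 4" motif that marks non-S family
members.  This module computes those features from sequence, exon and
domain-hit inputs; signal-peptide calls are consumed as annotations, never
predicted here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

__all__ = [
    "RNaseT2Record",
    "RegionSpec",
    "AlignmentScoring",
    "ABOVE_060",
    "BELOW_060",
    "STANDARD_AA",
    "net_charge",
    "compute_isoelectric_point",
    "compute_molecular_weight",
    "scan_pattern4",
    "domain_coverage",
    "count_introns",
    "build_feature_table",
    "pairwise_identity",
    "align_global",
    "project_regions",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Categorical domain-coverage labels used when only a ">60%"/"<60%" call is
# available rather than a numeric fraction.
ABOVE_060 = "above_060"
BELOW_060 = "below_060"


@dataclass
class RNaseT2Record:
    """One RNase T2 family gene/protein with its screening features.

    ``domain_coverage`` is either a fraction in [0, 1] or one of the
    categorical labels :data:`ABOVE_060` / :data:`BELOW_060`.  Absent
    values are ``None``.
    """

    gene_id: str
    species: str
    chromosome: Optional[str] = None
    position: Optional[int] = None
    intron_count: Optional[int] = None
    pI: Optional[float] = None
    mw: Optional[float] = None  # kDa
    signal_peptide_present: bool = False
    signal_peptide_length: Optional[int] = None
    domain_coverage: Union[float, str, None] = None
    pattern4_motif: Optional[str] = None
    n_amino_acids: Optional[int] = None
    sequence: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.species:
            raise ValueError(f"record {self.gene_id!r}: species must be non-empty")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if self.n_amino_acids is None:
                self.n_amino_acids = len(self.sequence)
            elif self.n_amino_acids != len(self.sequence):
                raise ValueError(
                    f"record {self.gene_id!r}: n_amino_acids "
                    f"{self.n_amino_acids} != sequence length {len(self.sequence)}"
                )
        if self.pI is not None and not (0.0 < self.pI < 14.0):
            raise ValueError(f"record {self.gene_id!r}: pI {self.pI} outside (0, 14)")
        if self.signal_peptide_length is not None and not self.signal_peptide_present:
            raise ValueError(
                f"record {self.gene_id!r}: signal peptide length given "
                "but signal_peptide_present is False"
            )
        if isinstance(self.domain_coverage, str) and self.domain_coverage not in (
            ABOVE_060,
            BELOW_060,
        ):
            raise ValueError(
                f"record {self.gene_id!r}: bad categorical coverage "
                f"{self.domain_coverage!r}"
            )


# ---------------------------------------------------------------------------
# Isoelectric point
# ---------------------------------------------------------------------------

# Bjellqvist pK set (the table behind the ExPASy Compute pI/MW tool).
# Side chains plus free termini; the N-terminal pK depends on the first
# residue, the C-terminal pK on the last.
BJELLQVIST = {
    "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm_default": 7.5,
    "nterm": {"A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7, "G": 7.5},
    "cterm_default": 3.55,
    "cterm": {"D": 4.55, "E": 4.75},
}


def _charged_counts(sequence: str) -> tuple[dict, dict, str, str, int]:
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    pos: dict = {}
    neg: dict = {}
    n_nonstandard = 0
    for aa in seq:
        if aa in BJELLQVIST["positive"]:
            pos[aa] = pos.get(aa, 0) + 1
        elif aa in BJELLQVIST["negative"]:
            neg[aa] = neg.get(aa, 0) + 1
        elif aa not in STANDARD_AA:
            n_nonstandard += 1
    return pos, neg, seq[0], seq[-1], n_nonstandard


def net_charge(sequence: str, pH: float, pk_table: Mapping = BJELLQVIST) -> float:
    """Net protein charge at ``pH`` under the Henderson-Hasselbalch model.

    Positive groups (free N terminus, K, R, H side chains) contribute
    ``1 / (1 + 10**(pH - pK))``; negative groups (free C terminus and
    D, E, C, Y side chains) contribute ``-1 / (1 + 10**(pK - pH))``.
    Nonstandard residues carry no charge.
    """
    pos, neg, first, last, _ = _charged_counts(sequence)
    charge = 0.0
    nterm_pk = pk_table["nterm"].get(first, pk_table["nterm_default"])
    charge += 1.0 / (1.0 + 10.0 ** (pH - nterm_pk))
    for aa, n in pos.items():
        charge += n / (1.0 + 10.0 ** (pH - pk_table["positive"][aa]))
    cterm_pk = pk_table["cterm"].get(last, pk_table["cterm_default"])
    charge -= 1.0 / (1.0 + 10.0 ** (cterm_pk - pH))
    for aa, n in neg.items():
        charge -= n / (1.0 + 10.0 ** (pk_table["negative"][aa] - pH))
    return charge


def compute_isoelectric_point(
    sequence: str,
    pk_table: Mapping = BJELLQVIST,
    tol: float = 1e-3,
) -> float:
    """pH at which the net charge of ``sequence`` is zero.

    Solved by bisection on [0, 14]; the charge curve is strictly
    decreasing in pH, so the zero crossing is unique.  Nonstandard
    residues are ignored for charge with a warning.
    """
    _, _, _, _, n_nonstandard = _charged_counts(sequence)
    if n_nonstandard:
        warnings.warn(
            f"{n_nonstandard} nonstandard residue(s) ignored for charge",
            stacklevel=2,
        )
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(sequence, mid, pk_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


# ---------------------------------------------------------------------------
# Molecular weight
# ---------------------------------------------------------------------------

# Average residue masses in Da (monomer mass minus one water).
_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
_RESIDUE_MASS["B"] = (_RESIDUE_MASS["N"] + _RESIDUE_MASS["D"]) / 2.0
_RESIDUE_MASS["Z"] = (_RESIDUE_MASS["Q"] + _RESIDUE_MASS["E"]) / 2.0
_RESIDUE_MASS["X"] = sum(_RESIDUE_MASS[a] for a in STANDARD_AA) / 20.0
_WATER = 18.01524


def compute_molecular_weight(sequence: str) -> float:
    """Average molecular weight of a peptide in kilodaltons.

    Sum of average residue masses plus one water (one condensation per
    peptide bond).  Ambiguity codes B, Z and X take the mean mass of
    their constituent residues.
    """
    seq = sequence.upper()
    if not seq:
        raise ValueError("empty sequence")
    try:
        dalton = sum(_RESIDUE_MASS[a] for a in seq) + _WATER
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    return dalton / 1000.0


# ---------------------------------------------------------------------------
# Pattern 4
# ---------------------------------------------------------------------------

# The diagnostic motif marking non-S RNase T2 members.  The default covers
# the two observed forms, CPSSNG and CPSSSG; position 5 is N or S.
DEFAULT_PATTERN4 = "CPSS[NS]G"


def _expand_pattern(pattern: str) -> list[set]:
    """Expand a simple bracket motif expression into per-position residue sets."""
    positions: list[set] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            positions.append(set(pattern[i + 1 : j]))
            i = j + 1
        else:
            positions.append({ch})
            i += 1
    return positions


def scan_pattern4(
    sequence: str, pattern: str = DEFAULT_PATTERN4
) -> list[tuple[int, str]]:
    """All non-overlapping pattern-4 matches as (1-based position, text)."""
    seq = sequence.upper()
    spec = _expand_pattern(pattern)
    k = len(spec)
    out: list[tuple[int, str]] = []
    i = 0
    while i + k <= len(seq):
        window = seq[i : i + k]
        if all(window[p] in spec[p] for p in range(k)):
            out.append((i + 1, window))
            i += k
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Domain coverage and introns
# ---------------------------------------------------------------------------

def domain_coverage(hits: Sequence) -> float:
    """Fraction of the domain model covered by the union of hit envelopes.

    ``hits`` carry 1-based inclusive coordinates on the model
    (``hit_from``/``hit_to``) and a shared ``model_length``.
    """
    if not hits:
        return 0.0
    lengths = {h.model_length for h in hits}
    if len(lengths) > 1:
        raise ValueError(f"mixed model lengths: {sorted(lengths)}")
    model_length = lengths.pop()
    spans = sorted((h.hit_from, h.hit_to) for h in hits)
    covered = 0
    cur_from, cur_to = spans[0]
    for s, e in spans[1:]:
        if s <= cur_to + 1:
            cur_to = max(cur_to, e)
        else:
            covered += cur_to - cur_from + 1
            cur_from, cur_to = s, e
    covered += cur_to - cur_from + 1
    return covered / model_length


def count_introns(exons: Sequence[tuple[int, int]]) -> int:
    """Number of introns implied by an ordered, non-overlapping exon list."""
    if not exons:
        raise ValueError("gene with zero exons")
    prev_end = None
    for start, end in exons:
        if start > end:
            raise ValueError(f"exon ({start}, {end}) has start > end")
        if prev_end is not None and start <= prev_end:
            raise ValueError("exons overlap or are unsorted")
        prev_end = end
    return len(exons) - 1


# ---------------------------------------------------------------------------
# Global alignment identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoring:
    """Needleman-Wunsch scoring.

    The default (+1 match, 0 mismatch, -1 gap) is the scheme checked
    against the exhaustive-enumeration oracle; a substitution matrix
    (mapping residue pairs to scores) may replace match/mismatch.
    """

    match: float = 1.0
    mismatch: float = 0.0
    gap: float = -1.0
    substitution: Optional[Mapping[tuple[str, str], float]] = None

    def score(self, a: str, b: str) -> float:
        if self.substitution is not None:
            try:
                return self.substitution[(a, b)]
            except KeyError:
                return self.substitution[(b, a)]
        return self.match if a == b else self.mismatch


def align_global(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> tuple[str, str, float]:
    """End-to-end alignment of two sequences by dynamic programming.

    Ties are broken toward the upper-left: diagonal preferred, then up
    (gap in ``seq_b``), then left.  Returns the two gapped rows and the
    alignment score.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    a, b = seq_a.upper(), seq_b.upper()
    n, m = len(a), len(b)
    gap = scoring.gap
    # F[i][j]: best score aligning a[:i] with b[:j]; P: traceback pointer.
    F = [[0.0] * (m + 1) for _ in range(n + 1)]
    P = [[""] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        F[i][0] = i * gap
        P[i][0] = "U"
    for j in range(1, m + 1):
        F[0][j] = j * gap
        P[0][j] = "L"
    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            diag = F[i - 1][j - 1] + scoring.score(ai, b[j - 1])
            up = F[i - 1][j] + gap
            left = F[i][j - 1] + gap
            best, ptr = diag, "D"
            if up > best:
                best, ptr = up, "U"
            if left > best:
                best, ptr = left, "L"
            F[i][j] = best
            P[i][j] = ptr
    row_a: list[str] = []
    row_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        ptr = P[i][j]
        if ptr == "D":
            row_a.append(a[i - 1])
            row_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif ptr == "U":
            row_a.append(a[i - 1])
            row_b.append("-")
            i -= 1
        else:
            row_a.append("-")
            row_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(row_a)), "".join(reversed(row_b)), F[n][m]


def pairwise_identity(
    seq_a: str, seq_b: str, scoring: AlignmentScoring = AlignmentScoring()
) -> float:
    """Percent identity over a global alignment, to two decimals.

    Identity counts identical aligned columns and divides by the total
    number of alignment columns — internal and terminal gap columns
    included in the denominator.
    """
    row_a, row_b, _ = align_global(seq_a, seq_b, scoring)
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return round(100.0 * matches / len(row_a), 2)


# ---------------------------------------------------------------------------
# Conserved-region projection
# ---------------------------------------------------------------------------

@dataclass
class RegionSpec:
    """Named alignment-column spans for the Rosaceae S-RNase architecture.

    Conventionally C1, C2, RHV, C3, RC4, C5 — five conserved regions and
    one hypervariable region — as (start, end) columns, 1-based
    inclusive, non-overlapping and in ascending order.
    """

    regions: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        prev_end = 0
        for name, (start, end) in self.regions.items():
            if not (1 <= start <= end):
                raise ValueError(f"region {name}: bad span ({start}, {end})")
            if start <= prev_end:
                raise ValueError(f"region {name}: overlaps or out of order")
            prev_end = end


def build_feature_table(
    sequences: Sequence[tuple[str, str]],
    species: str,
    signal_peptides: Mapping[str, Optional[int]],
    exons: Optional[Mapping[str, Sequence[tuple[int, int]]]] = None,
    domain_hits: Optional[Mapping[str, Sequence]] = None,
    positions: Optional[Mapping[str, tuple[str, int]]] = None,
):
    """Compute a screening feature table from sequences plus annotations.

    ``sequences`` are (id, amino-acid sequence) pairs (e.g. from
    :func:`srnase.io_formats.read_fasta`); ``signal_peptides`` maps id to
    peptide length, or ``None`` for "no signal peptide" (calls come from
    an external predictor — this package ships none); ``exons`` gives
    genomic exon spans per gene for intron counting; ``domain_hits``
    model-coordinate hit envelopes for coverage; ``positions`` optional
    (chromosome, bp) locations.  pI, molecular weight, pattern-4 motif
    and amino-acid count are computed from the sequence.  The result
    serializes through :func:`srnase.io_formats.write_feature_table` in
    the same schema the packaged fixtures use.
    """
    from .io_formats import FeatureTable  # deferred: io_formats imports this module

    records = []
    for gene_id, seq in sequences:
        sp_len = signal_peptides.get(gene_id)
        matches = scan_pattern4(seq)
        chrom, pos = (positions or {}).get(gene_id, (None, None))
        records.append(
            RNaseT2Record(
                gene_id=gene_id,
                species=species,
                chromosome=chrom,
                position=pos,
                intron_count=count_introns(exons[gene_id])
                if exons and gene_id in exons
                else None,
                pI=round(compute_isoelectric_point(seq), 2),
                mw=round(compute_molecular_weight(seq), 1),
                signal_peptide_present=sp_len is not None,
                signal_peptide_length=sp_len,
                domain_coverage=domain_coverage(domain_hits[gene_id])
                if domain_hits and gene_id in domain_hits
                else None,
                pattern4_motif=matches[0][1] if matches else None,
                sequence=seq,
            )
        )
    return FeatureTable(records=records, source="computed from sequences")


def project_regions(
    reference_alignment: Sequence[tuple[str, str]],
    region_spec: RegionSpec,
    query_id: str,
) -> dict[str, str]:
    """Extract a query's ungapped subsequence for each named region.

    ``reference_alignment`` is a list of (id, gapped row) with equal row
    widths; the query must be one of its rows.  A region in which the
    query is all-gap maps to the empty string.
    """
    rows = dict(reference_alignment)
    if query_id not in rows:
        raise KeyError(f"query {query_id!r} not in alignment")
    row = rows[query_id]
    width = len(row)
    if any(len(r) != width for r in rows.values()):
        raise ValueError("alignment rows have unequal widths")
    out: dict[str, str] = {}
    for name, (start, end) in region_spec.regions.items():
        if end > width:
            raise ValueError(f"region {name}: span end {end} beyond width {width}")
        out[name] = row[start - 1 : end].replace("-", "")
    return out
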