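"""The S-RNase identification cascade.

Starting from an RNase T2 family feature table, candidates for the
style determinant of gametophytic self-incompatibility are narrowed by
five sequential filters — secretory signal peptide, RNase T2 domain
integrity above 60%, basic isoelectric point (8-10), at most two
introns, absence of the diagnostic pattern-4 motif — and finally paired
into putative alleles by percent identity: allelic S-RNases within one
species diverge strongly (30-90% identity) yet remain more similar to
each other than either is to S-RNases from other tribes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .io_formats import FeatureTable, IdentityMatrix
from .protein_features import ABOVE_060, BELOW_060, RNaseT2Record, scan_pattern4

__all__ = [
    "ScreenConfig",
    "StageResult",
    "SpeciesScreenReport",
    "ScreenReport",
    "filter_signal_peptide",
    "filter_domain_integrity",
    "filter_pi",
    "filter_intron_count",
    "filter_pattern4",
    "pair_alleles",
    "run_screen",
]

STAGE_ORDER = ["signal_peptide", "domain_integrity", "pI", "intron_count", "pattern4"]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the candidate cascade.

    Domain integrity is strict (>0.60); the pI window, intron bound and
    identity window are inclusive on both sides.
    """

    domain_threshold: float = 0.60
    pi_low: float = 8.0
    pi_high: float = 10.0
    max_introns: int = 2
    identity_low: float = 30.0
    identity_high: float = 90.0
    pattern4_excludes: bool = True

    def __post_init__(self) -> None:
        if not self.pi_low < self.pi_high:
            raise ValueError("require pi_low < pi_high")
        if not self.identity_low < self.identity_high:
            raise ValueError("require identity_low < identity_high")


@dataclass
class StageResult:
    name: str
    input_ids: list[str]
    kept_ids: list[str]
    removed: list[tuple[str, str]]  # (gene_id, reason)

    def to_dict(self) -> dict:
        return {
            "stage": self.name,
            "input": self.input_ids,
            "kept": self.kept_ids,
            "removed": [{"id": i, "reason": r} for i, r in self.removed],
        }


@dataclass
class SpeciesScreenReport:
    species: str
    stages: list[StageResult] = field(default_factory=list)
    allele_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    selected_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    final_candidates: list[str] = field(default_factory=list)

    def stage(self, name: str) -> StageResult:
        for st in self.stages:
            if st.name == name:
                return st
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "species": self.species,
            "stages": [s.to_dict() for s in self.stages],
            "allele_pairs": [
                {"pair": [a, b], "identity": x} for a, b, x in self.allele_pairs
            ],
            "selected_pairs": [
                {"pair": [a, b], "identity": x} for a, b, x in self.selected_pairs
            ],
            "final_candidates": self.final_candidates,
        }


@dataclass
class ScreenReport:
    species_reports: dict[str, SpeciesScreenReport] = field(default_factory=dict)

    def final_candidates(self) -> dict[str, list[str]]:
        return {sp: rep.final_candidates for sp, rep in self.species_reports.items()}

    def to_dict(self) -> dict:
        return {
            "species": {
                sp: rep.to_dict() for sp, rep in sorted(self.species_reports.items())
            }
        }


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def filter_signal_peptide(records: Sequence[RNaseT2Record]) -> list[RNaseT2Record]:
    """Keep proteins with a secretory signal peptide (prerequisite for export)."""
    return [r for r in records if r.signal_peptide_present]


def _coverage_passes(record: RNaseT2Record, config: ScreenConfig) -> bool:
    cov = record.domain_coverage
    if cov is None:
        raise ValueError(f"record {record.gene_id!r}: domain coverage absent")
    if isinstance(cov, str):
        # Categorical labels only support the default 0.60 cut.
        return cov == ABOVE_060
    return cov > config.domain_threshold


def filter_domain_integrity(
    records: Sequence[RNaseT2Record], config: ScreenConfig = ScreenConfig()
) -> list[RNaseT2Record]:
    """Keep proteins whose RNase T2 domain coverage is strictly above the threshold."""
    return [r for r in records if _coverage_passes(r, config)]


def filter_pi(
    records: Sequence[RNaseT2Record], config: ScreenConfig = ScreenConfig()
) -> list[RNaseT2Record]:
    """Keep proteins with basic pI in the inclusive [pi_low, pi_high] window."""
    out = []
    for r in records:
        if r.pI is None:
            raise ValueError(f"record {r.gene_id!r}: pI absent")
        if config.pi_low <= r.pI <= config.pi_high:
            out.append(r)
    return out


def filter_intron_count(
    records: Sequence[RNaseT2Record], config: ScreenConfig = ScreenConfig()
) -> list[RNaseT2Record]:
    """Keep genes with at most ``max_introns`` introns."""
    out = []
    for r in records:
        if r.intron_count is None:
            raise ValueError(f"record {r.gene_id!r}: intron count absent")
        if r.intron_count <= config.max_introns:
            out.append(r)
    return out


def _has_pattern4(record: RNaseT2Record) -> bool:
    if record.pattern4_motif is not None:
        return True
    if record.sequence is not None:
        return bool(scan_pattern4(record.sequence))
    return False


def filter_pattern4(
    records: Sequence[RNaseT2Record], config: ScreenConfig = ScreenConfig()
) -> list[RNaseT2Record]:
    """Remove proteins carrying the pattern-4 motif (marks non-S family members)."""
    if not config.pattern4_excludes:
        return list(records)
    return [r for r in records if not _has_pattern4(r)]


_FILTERS = {
    "signal_peptide": lambda recs, cfg: filter_signal_peptide(recs),
    "domain_integrity": filter_domain_integrity,
    "pI": filter_pi,
    "intron_count": filter_intron_count,
    "pattern4": filter_pattern4,
}

_REASONS = {
    "signal_peptide": "no signal peptide",
    "domain_integrity": "domain coverage not above threshold",
    "pI": "pI outside window",
    "intron_count": "too many introns",
    "pattern4": "pattern-4 motif present",
}


# ---------------------------------------------------------------------------
# Allele pairing
# ---------------------------------------------------------------------------

def pair_alleles(
    candidates: Sequence[RNaseT2Record],
    identities: IdentityMatrix,
    config: ScreenConfig = ScreenConfig(),
    crosstribe: Optional[IdentityMatrix] = None,
    crosstribe_refs: Optional[Sequence[str]] = None,
) -> tuple[list[tuple[str, str, float]], list[tuple[str, str, float]]]:
    """Two-stage allele pairing among screen survivors of one species.

    Stage 1 keeps unordered candidate pairs whose identity lies in the
    inclusive [identity_low, identity_high] polymorphism window.  Stage
    2 applies the within-genus > cross-tribe rule: a pair survives only
    if its within-pair identity exceeds each member's maximum identity
    to every cross-tribe reference S-RNase.  With no reference set,
    stage 2 is the identity.

    Returns (stage-1 pairs, stage-2 selected pairs), each as
    (id_a, id_b, identity%).
    """
    ids = [r.gene_id for r in candidates]
    stage1: list[tuple[str, str, float]] = []
    for a, b in combinations(ids, 2):
        x = identities.get(a, b)  # KeyError on a missing entry, by design
        if config.identity_low <= x <= config.identity_high:
            stage1.append((a, b, x))
    if crosstribe is None or not crosstribe_refs:
        return stage1, list(stage1)
    selected: list[tuple[str, str, float]] = []
    for a, b, x in stage1:
        max_ref = max(
            crosstribe.get(member, ref) for member in (a, b) for ref in crosstribe_refs
        )
        if x > max_ref:
            selected.append((a, b, x))
    return stage1, selected


# ---------------------------------------------------------------------------
# Full cascade
# ---------------------------------------------------------------------------

def run_screen(
    table: FeatureTable,
    identities: Optional[IdentityMatrix] = None,
    config: ScreenConfig = ScreenConfig(),
    crosstribe: Optional[IdentityMatrix] = None,
    crosstribe_refs: Optional[Sequence[str]] = None,
) -> ScreenReport:
    """Apply the full cascade, each species independently.

    Filter order: signal peptide -> domain integrity -> pI -> intron
    count -> pattern 4, then allele pairing.  When ``identities`` is
    ``None``, pairing is skipped and ``final_candidates`` lists the
    filter survivors.
    """
    report = ScreenReport()
    for species, records in table.by_species().items():
        rep = SpeciesScreenReport(species=species)
        current = list(records)
        for stage_name in STAGE_ORDER:
            input_ids = [r.gene_id for r in current]
            try:
                kept = _FILTERS[stage_name](current, config)
            except ValueError as exc:
                raise ValueError(f"stage {stage_name!r}: {exc}") from None
            kept_ids = {r.gene_id for r in kept}
            rep.stages.append(
                StageResult(
                    name=stage_name,
                    input_ids=input_ids,
                    kept_ids=[r.gene_id for r in kept],
                    removed=[
                        (i, _REASONS[stage_name]) for i in input_ids if i not in kept_ids
                    ],
                )
            )
            current = kept
        if identities is None:
            rep.final_candidates = [r.gene_id for r in current]
        else:
            try:
                stage1, selected = pair_alleles(
                    current, identities, config, crosstribe, crosstribe_refs
                )
            except KeyError as exc:
                raise KeyError(f"stage 'allele_pairing': {exc}") from None
            rep.allele_pairs = stage1
            rep.selected_pairs = selected
            final: list[str] = []
            for a, b, _ in selected:
                for gid in (a, b):
                    if gid not in final:
                        final.append(gid)
            rep.final_candidates = final
        report.species_reports[species] = rep
    return report
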