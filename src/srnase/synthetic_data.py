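"""Seedable generators emulating every input the analysis consumes.

Each generator plants a known truth — an S-RNase allele pair among
decoy RNase T2 records, progeny genotypes behind band patterns, an
overlap behind a set of collinear blocks — so the downstream operations
can be tested end to end without any external data.  Decoy feature
distributions mirror the empirical ranges of real RNase T2 family
screens (acidic-to-neutral pI for non-S members, basic pI for S-like
ones, amino-acid counts from truncated ORFs to large fusion proteins).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import FeatureTable, IdentityMatrix
from .protein_features import STANDARD_AA, RNaseT2Record, pairwise_identity
from .si_genetics import BandPattern, SGenotype, simulate_progeny_individuals
from .synteny_mapping import CollinearBlock, GenomicInterval

__all__ = [
    "DEFAULT_ALLELE_SIZES",
    "GeneratorConfig",
    "SyntheticScreen",
    "generate_feature_table",
    "generate_sequences_for_pair",
    "generate_progeny_bands",
    "generate_block_set",
]

DEFAULT_ALLELE_SIZES = {"Sa": 350.0, "Sb": 359.0}  # 9-bp inter-allele offset


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the feature-table generator.

    Decoy pI is drawn uniformly from 4-8 (non-S members are acidic to
    neutral), planted S-like pI uniformly from the 8-10 S-RNase window.
    Optional Gaussian jitter on coverage and pI models feature noise.
    """

    seed: int = 0
    species: str = "synthetic"
    n_decoys: int = 20
    planted_pair_identities: tuple[float, ...] = (56.48,)
    sequence_length: int = 230
    decoy_pi_range: tuple[float, float] = (4.0, 8.0)
    s_pi_range: tuple[float, float] = (8.0, 10.0)
    coverage_jitter_sd: float = 0.0
    pi_jitter_sd: float = 0.0
    identity_window: tuple[float, float] = (30.0, 90.0)

    def __post_init__(self) -> None:
        for t in self.planted_pair_identities:
            if not (0.0 < t < 100.0):
                raise ValueError(f"planted identity {t} outside (0, 100)")
            lo, hi = self.identity_window
            if not (lo <= t <= hi):
                raise ValueError(
                    f"planted pair identity {t} outside the screen window [{lo}, {hi}]"
                )


@dataclass
class SyntheticScreen:
    """A generated feature table with its sidecar truth labels."""

    table: FeatureTable
    identities: IdentityMatrix
    crosstribe: IdentityMatrix
    crosstribe_refs: list[str]
    truth_pairs: list[tuple[str, str]]
    truth_ids: set[str]
    sequences: dict[str, str]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_AA), size=length))


def generate_sequences_for_pair(
    target_identity: float,
    length: int,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, str]:
    """Two amino-acid sequences with (approximately) a target percent identity.

    The second sequence is the first with substitutions planted at a
    fraction ``1 - target/100`` of positions; the realized global-
    alignment identity lands within about three points of the target for
    lengths of 150 and up.
    """
    if not (0.0 < target_identity <= 100.0):
        raise ValueError("target identity must lie in (0, 100]")
    if length < 20:
        raise ValueError("length must be at least 20")
    if rng is None:
        rng = np.random.default_rng(seed)
    seq_a = _random_sequence(rng, length)
    n_subst = int(round(length * (1.0 - target_identity / 100.0)))
    positions = rng.choice(length, size=n_subst, replace=False)
    chars = list(seq_a)
    for pos in positions:
        alternatives = [c for c in STANDARD_AA if c != chars[pos]]
        chars[pos] = alternatives[rng.integers(0, len(alternatives))]
    return seq_a, "".join(chars)


def _planted_record(
    rng: np.random.Generator,
    config: GeneratorConfig,
    gene_id: str,
    sequence: str,
) -> RNaseT2Record:
    pi = rng.uniform(*config.s_pi_range)
    coverage = rng.uniform(0.70, 0.95)
    if config.pi_jitter_sd > 0:
        pi = float(np.clip(pi + rng.normal(0.0, config.pi_jitter_sd), 0.5, 13.5))
    if config.coverage_jitter_sd > 0:
        coverage = float(np.clip(coverage + rng.normal(0.0, config.coverage_jitter_sd), 0.0, 1.0))
    return RNaseT2Record(
        gene_id=gene_id,
        species=config.species,
        intron_count=int(rng.integers(0, 3)),
        pI=round(pi, 2),
        signal_peptide_present=True,
        signal_peptide_length=int(rng.integers(18, 30)),
        domain_coverage=round(coverage, 3),
        pattern4_motif=None,
        n_amino_acids=len(sequence),
        sequence=sequence,
    )


_DECOY_FAILURES = ("no_signal_peptide", "low_coverage", "pi_out", "many_introns", "pattern4")


def _decoy_record(
    rng: np.random.Generator, config: GeneratorConfig, gene_id: str
) -> RNaseT2Record:
    failure = _DECOY_FAILURES[rng.integers(0, len(_DECOY_FAILURES))]
    pi = rng.uniform(*config.s_pi_range)
    coverage = rng.uniform(0.70, 0.95)
    has_sp = True
    introns = int(rng.integers(0, 3))
    pattern4 = None
    n_aa = int(rng.integers(50, 917))
    if failure == "no_signal_peptide":
        has_sp = False
    elif failure == "low_coverage":
        coverage = rng.uniform(0.10, 0.55)
    elif failure == "pi_out":
        pi = rng.uniform(*config.decoy_pi_range)
    elif failure == "many_introns":
        introns = int(rng.integers(3, 8))
    else:
        pattern4 = "CPSSNG" if rng.random() < 0.5 else "CPSSSG"
    if config.pi_jitter_sd > 0:
        pi = float(np.clip(pi + rng.normal(0.0, config.pi_jitter_sd), 0.5, 13.5))
    if config.coverage_jitter_sd > 0:
        coverage = float(np.clip(coverage + rng.normal(0.0, config.coverage_jitter_sd), 0.0, 1.0))
    return RNaseT2Record(
        gene_id=gene_id,
        species=config.species,
        intron_count=introns,
        pI=round(pi, 2),
        signal_peptide_present=has_sp,
        signal_peptide_length=int(rng.integers(15, 30)) if has_sp else None,
        domain_coverage=round(coverage, 3),
        pattern4_motif=pattern4,
        n_amino_acids=n_aa,
    )


def generate_feature_table(config: GeneratorConfig) -> SyntheticScreen:
    """A feature table in which exactly the planted records are S-like.

    Every decoy carries at least one disqualifying feature; every
    planted pair carries all-pass features and a sequence pair with the
    requested identity.  Identity entries for all candidate pairs and a
    low-identity cross-tribe reference are included so the full cascade
    (filters plus two-stage allele pairing) can run.
    """
    rng = np.random.default_rng(config.seed)
    records: list[RNaseT2Record] = []
    sequences: dict[str, str] = {}
    truth_pairs: list[tuple[str, str]] = []
    for k, target in enumerate(config.planted_pair_identities, start=1):
        id_a, id_b = f"planted{k}a", f"planted{k}b"
        seq_a, seq_b = generate_sequences_for_pair(
            target, config.sequence_length, rng=rng
        )
        records.append(_planted_record(rng, config, id_a, seq_a))
        records.append(_planted_record(rng, config, id_b, seq_b))
        sequences[id_a], sequences[id_b] = seq_a, seq_b
        truth_pairs.append((id_a, id_b))
    for k in range(1, config.n_decoys + 1):
        records.append(_decoy_record(rng, config, f"decoy{k}"))
    order = rng.permutation(len(records))
    table = FeatureTable(
        records=[records[i] for i in order],
        source=f"synthetic feature table, seed {config.seed}",
    )
    # Identity entries cover every pair, as a real all-vs-all matrix would:
    # planted pairs from their sequences, everything else unrelated-low.
    identities = IdentityMatrix()
    planted_ids = [gid for pair in truth_pairs for gid in pair]
    all_ids = [r.gene_id for r in records]
    for i, a in enumerate(all_ids):
        for b in all_ids[i + 1 :]:
            if a in sequences and b in sequences:
                identities.set(a, b, pairwise_identity(sequences[a], sequences[b]))
            else:
                identities.set(a, b, float(rng.uniform(5.0, 25.0)))
    crosstribe = IdentityMatrix()
    refs = ["crosstribe_ref1"]
    for gid in all_ids:
        for ref in refs:
            crosstribe.set(gid, ref, float(rng.uniform(10.0, 25.0)))
    return SyntheticScreen(
        table=table,
        identities=identities,
        crosstribe=crosstribe,
        crosstribe_refs=refs,
        truth_pairs=truth_pairs,
        truth_ids=set(planted_ids),
        sequences=sequences,
    )


def generate_progeny_bands(
    mother: SGenotype,
    father: SGenotype,
    n: int,
    mode: str = "mendelian",
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    allele_sizes: Mapping[str, float] = DEFAULT_ALLELE_SIZES,
    tolerance: Optional[float] = None,
) -> tuple[dict[str, BandPattern], dict[str, SGenotype]]:
    """Amplicon band patterns for a simulated progeny population.

    Each offspring shows one band per distinct allele, with Gaussian
    size noise.  Refuses a noise level at or above half the smallest
    inter-allele size offset, which would make calls ambiguous by
    construction.  The default matching ``tolerance`` stamped on each
    pattern is the widest unambiguous window — just under half that
    offset — which amounts to nearest-allele assignment.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    sizes = sorted(allele_sizes.values())
    min_offset = min(
        (b - a for a, b in zip(sizes, sizes[1:])), default=float("inf")
    )
    if noise_sd >= min_offset / 2.0:
        raise ValueError(
            f"noise sd {noise_sd} >= half the allele size offset {min_offset}"
        )
    if tolerance is None:
        tolerance = 2.0 if min_offset == float("inf") else 0.499 * min_offset
    rng = np.random.default_rng(seed)
    offspring = simulate_progeny_individuals(mother, father, n, mode, rng=rng)
    bands: dict[str, BandPattern] = {}
    truth: dict[str, SGenotype] = {}
    for i, genotype in enumerate(offspring, start=1):
        name = f"progeny{i:04d}"
        observed = [
            allele_sizes[a] + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
            for a in set(genotype.alleles)
        ]
        bands[name] = BandPattern(sizes=observed, tolerance=tolerance)
        truth[name] = genotype
    return bands, truth


def generate_block_set(
    planted_overlap: Optional[GenomicInterval],
    n_blocks: int,
    jitter: int = 1_000_000,
    seed: Optional[int] = None,
    source_genomes: Optional[Sequence[str]] = None,
    chromosome: str = "Chr6",
) -> list[CollinearBlock]:
    """Collinear blocks whose target-span intersection is the planted overlap.

    One block's target start sits exactly at the planted start and one
    block's end exactly at the planted end; the rest extend outward by
    random jitter (starts clipped at 1).  With ``planted_overlap=None``
    the generated target spans are pairwise disjoint.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be at least 1")
    rng = np.random.default_rng(seed)
    names = list(source_genomes or (f"genome{i + 1}" for i in range(n_blocks)))
    if len(names) != n_blocks:
        raise ValueError("source_genomes length must equal n_blocks")
    blocks: list[CollinearBlock] = []
    if planted_overlap is None:
        cursor = 1
        for i in range(n_blocks):
            length = int(rng.integers(10_000, max(20_000, jitter)))
            target = GenomicInterval(chromosome, cursor, cursor + length)
            cursor = target.end + int(rng.integers(10_000, max(20_000, jitter)))
            blocks.append(
                CollinearBlock(
                    source_genome=names[i],
                    source=GenomicInterval(f"{names[i]}_chr", target.start, target.end),
                    target=target,
                )
            )
        return blocks
    chrom = planted_overlap.chromosome
    anchor_start = int(rng.integers(0, n_blocks))
    anchor_end = int(rng.integers(0, n_blocks))
    for i in range(n_blocks):
        left = 0 if i == anchor_start else int(rng.integers(0, jitter + 1))
        right = 0 if i == anchor_end else int(rng.integers(0, jitter + 1))
        target = GenomicInterval(
            chrom,
            max(1, planted_overlap.start - left),
            planted_overlap.end + right,
        )
        source_start = int(rng.integers(1, 50_000_000))
        blocks.append(
            CollinearBlock(
                source_genome=names[i],
                source=GenomicInterval(
                    f"{names[i]}_chr", source_start, source_start + target.length - 1
                ),
                target=target,
            )
        )
    return blocks
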