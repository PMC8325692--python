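"""Gametophytic self-incompatibility (GSI) genetics.

Under GSI the haploid pollen grain carries one S-haplotype, and the
style rejects any pollen whose haplotype matches either of its own two
S-alleles.  Heterozygous styles therefore reject pollen from both
homozygotes and from themselves, while a homozygous style accepts half
the pollen of a heterozygous donor.  This module calls diploid
S-genotypes from allele-specific amplicon band patterns, predicts cross
outcomes, simulates progeny populations (with an optional strict-GSI
pollen filter), and tests observed genotype counts against a Mendelian
segregation ratio by chi-square goodness of fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_ALLELES",
    "SGenotype",
    "BandPattern",
    "CrossOutcome",
    "SegregationResult",
    "call_genotype",
    "predict_cross",
    "simulate_progeny",
    "simulate_progeny_individuals",
    "segregation_test",
    "classify_lines",
]

DEFAULT_ALLELES = ("Sa", "Sb")


@dataclass(frozen=True)
class SGenotype:
    """An unordered diploid pair of S-haplotype labels (homozygotes allowed)."""

    alleles: tuple[str, str]

    def __post_init__(self) -> None:
        if len(self.alleles) != 2:
            raise ValueError("an S genotype has exactly two alleles")
        object.__setattr__(self, "alleles", tuple(sorted(self.alleles)))

    @classmethod
    def from_string(cls, text: str) -> "SGenotype":
        """Parse compact genotype names such as ``SaSb``, ``SbSa`` or ``S1/S3``."""
        text = text.strip()
        parts = [p for p in text.split("/") if p]
        if len(parts) != 2:
            # Split a concatenated form at the second 'S'.
            cut = text.find("S", 1)
            if not text.startswith("S") or cut <= 0:
                raise ValueError(f"cannot parse genotype {text!r}")
            parts = [text[:cut], text[cut:]]
        return cls(alleles=(parts[0], parts[1]))

    @property
    def name(self) -> str:
        return "".join(self.alleles)

    @property
    def is_heterozygous(self) -> bool:
        return self.alleles[0] != self.alleles[1]

    def haplotypes(self) -> tuple[str, str]:
        """The two (possibly identical) haplotypes transmitted to gametes."""
        return self.alleles


@dataclass(frozen=True)
class BandPattern:
    """A set of amplicon sizes (bp) from one lane, with a matching tolerance."""

    sizes: frozenset
    tolerance: float = 2.0

    def __init__(self, sizes, tolerance: float = 2.0):
        object.__setattr__(self, "sizes", frozenset(float(s) for s in sizes))
        object.__setattr__(self, "tolerance", float(tolerance))
        if any(s <= 0 for s in self.sizes):
            raise ValueError("band sizes must be positive")
        if self.tolerance < 0:
            raise ValueError("tolerance must be non-negative")


@dataclass(frozen=True)
class CrossOutcome:
    outcome: str  # "compatible" | "incompatible"
    compatible_fraction: float


@dataclass
class SegregationResult:
    observed: list[int]
    expected_ratio: list[int]
    expected: list[float]
    chi2: float
    df: int
    p_value: float

    def rejects(self, alpha: float = 0.05) -> bool:
        return self.p_value < alpha


# ---------------------------------------------------------------------------
# Genotype calling
# ---------------------------------------------------------------------------

def call_genotype(
    pattern: BandPattern, allele_sizes: Mapping[str, float]
) -> Optional[SGenotype]:
    """Call a diploid S-genotype from a band pattern.

    An allele is present iff some band lies within ``pattern.tolerance``
    of its expected amplicon size.  One allele present means a
    homozygote, two a heterozygote, none a null call (``None``).  A band
    that matches two allele sizes is an ambiguity error; allele sizes
    must therefore be separated by more than twice the tolerance.
    """
    labels = sorted(allele_sizes)
    tol = pattern.tolerance
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            if abs(allele_sizes[a] - allele_sizes[b]) <= 2 * tol:
                raise ValueError(
                    f"allele sizes for {a!r} and {b!r} are within 2x tolerance"
                )
    present: list[str] = []
    for band in sorted(pattern.sizes):
        matches = [lab for lab in labels if abs(band - allele_sizes[lab]) <= tol]
        if len(matches) > 1:
            raise ValueError(f"band {band} matches multiple alleles {matches}")
        if matches and matches[0] not in present:
            present.append(matches[0])
    if not present:
        return None
    if len(present) == 1:
        return SGenotype(alleles=(present[0], present[0]))
    if len(present) == 2:
        return SGenotype(alleles=(present[0], present[1]))
    raise ValueError(f"more than two alleles present: {present}")


# ---------------------------------------------------------------------------
# Cross prediction and progeny simulation
# ---------------------------------------------------------------------------

def predict_cross(style: SGenotype, pollen_parent: SGenotype) -> CrossOutcome:
    """GSI outcome of a style x pollen-parent cross.

    Each pollen haplotype (the two in equal proportion) is rejected iff
    it matches either style allele; the compatible fraction is the
    proportion of accepted pollen (0, 0.5 or 1) and the cross is scored
    compatible iff that fraction is positive, matching field phenotype
    scoring where half-compatible pollinations still set fruit.
    """
    accepted = [h for h in pollen_parent.haplotypes() if h not in style.alleles]
    fraction = len(accepted) / 2.0
    return CrossOutcome(
        outcome="compatible" if fraction > 0 else "incompatible",
        compatible_fraction=fraction,
    )


def simulate_progeny_individuals(
    mother: SGenotype,
    father: SGenotype,
    n: int,
    mode: str = "mendelian",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[SGenotype]:
    """Simulate ``n`` offspring genotypes one by one.

    ``mendelian`` draws one maternal and one paternal haplotype
    uniformly (models the leaky SI that yields selfed seed); ``gsi``
    draws the paternal haplotype uniformly from the haplotypes the
    maternal style accepts, returning no offspring when all pollen is
    rejected.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    if mode not in ("mendelian", "gsi"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    paternal = list(father.haplotypes())
    if mode == "gsi":
        paternal = [h for h in paternal if h not in mother.alleles]
        if not paternal:
            return []
    maternal = list(mother.haplotypes())
    mi = rng.integers(0, 2, size=n)
    pi = rng.integers(0, len(paternal), size=n)
    return [
        SGenotype(alleles=(maternal[a], paternal[b])) for a, b in zip(mi, pi)
    ]


def simulate_progeny(
    mother: SGenotype,
    father: SGenotype,
    n: int,
    mode: str = "mendelian",
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    alleles: Sequence[str] = DEFAULT_ALLELES,
) -> dict[str, int]:
    """Genotype counts over all diploid classes of the allele universe.

    Deterministic under a fixed seed.  In ``gsi`` mode with all pollen
    rejected, every count is zero.
    """
    offspring = simulate_progeny_individuals(mother, father, n, mode, seed, rng)
    classes = _genotype_classes(alleles)
    counts = {name: 0 for name in classes}
    for g in offspring:
        counts[g.name] = counts.get(g.name, 0) + 1
    return counts


def _genotype_classes(alleles: Sequence[str]) -> list[str]:
    labs = sorted(alleles)
    out = []
    for i, a in enumerate(labs):
        for b in labs[i:]:
            out.append(SGenotype(alleles=(a, b)).name)
    return out


# ---------------------------------------------------------------------------
# Segregation testing and tallies
# ---------------------------------------------------------------------------

def segregation_test(
    observed: Sequence[int], expected_ratio: Sequence[Union[int, float]]
) -> SegregationResult:
    """Chi-square goodness of fit of genotype counts against a Mendelian ratio.

    Expected counts allocate the observed total proportionally to the
    ratio; df = classes - 1.
    """
    obs = [int(x) for x in observed]
    ratio = list(expected_ratio)
    if len(obs) != len(ratio):
        raise ValueError("observed and expected_ratio lengths differ")
    if len(obs) < 2:
        raise ValueError("need at least two genotype classes")
    if any(r <= 0 for r in ratio):
        raise ValueError("expected ratio terms must be positive")
    total = sum(obs)
    if total == 0:
        raise ValueError("zero total count")
    ratio_sum = sum(ratio)
    expected = [total * r / ratio_sum for r in ratio]
    chi2, p = stats.chisquare(obs, f_exp=expected)
    return SegregationResult(
        observed=obs,
        expected_ratio=[int(r) if float(r).is_integer() else r for r in ratio],
        expected=expected,
        chi2=float(chi2),
        df=len(obs) - 1,
        p_value=float(p),
    )


def classify_lines(
    genotypes: Mapping[str, SGenotype], alleles: Sequence[str] = DEFAULT_ALLELES
) -> dict[str, int]:
    """Tally lines per diploid genotype class of the allele universe."""
    universe = set(alleles)
    counts = {name: 0 for name in _genotype_classes(alleles)}
    for line, g in genotypes.items():
        unknown = [a for a in g.alleles if a not in universe]
        if unknown:
            raise ValueError(f"line {line!r}: unknown allele label(s) {unknown}")
        counts[g.name] += 1
    return counts
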