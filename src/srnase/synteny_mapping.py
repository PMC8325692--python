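"""S-locus mapping by collinearity: flank, project, intersect.

When a locus has a known position in related genomes (here the S-RNase
positions in rose and almond), its counterpart in a genome lacking
direct evidence can be mapped by flanking the known positions, locating
the collinear blocks each flanked region projects onto the target
genome, and intersecting the projected spans.  All coordinates are
1-based inclusive; interval length counts both endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "GenomicInterval",
    "CollinearBlock",
    "flank_locus",
    "intersect_blocks",
    "span_mb",
    "genes_in_region",
    "fraction_of_chromosome",
    "interval_to_bed_line",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based inclusive chromosomal span."""

    chromosome: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise ValueError("coordinates must be positive")
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass(frozen=True)
class CollinearBlock:
    """A collinear span pair: a source-genome interval and its target counterpart."""

    source_genome: str
    source: GenomicInterval
    target: GenomicInterval


def flank_locus(position: GenomicInterval, flank_bp: int) -> GenomicInterval:
    """Extend a locus by ``flank_bp`` on both sides, clipping the start at 1."""
    if flank_bp < 0:
        raise ValueError("flank_bp must be non-negative")
    return GenomicInterval(
        chromosome=position.chromosome,
        start=max(1, position.start - flank_bp),
        end=position.end + flank_bp,
    )


def intersect_blocks(
    intervals: Sequence[GenomicInterval],
) -> Optional[GenomicInterval]:
    """Common overlap of same-chromosome intervals, or ``None`` when disjoint."""
    if not intervals:
        raise ValueError("need at least one interval")
    chroms = {iv.chromosome for iv in intervals}
    if len(chroms) > 1:
        raise ValueError(f"intervals on mixed chromosomes: {sorted(chroms)}")
    start = max(iv.start for iv in intervals)
    end = min(iv.end for iv in intervals)
    if start > end:
        return None
    return GenomicInterval(chromosome=chroms.pop(), start=start, end=end)


def span_mb(interval: GenomicInterval, decimals: int = 1) -> float:
    """Interval length in megabases, rounded half-up to ``decimals``."""
    mb = Decimal(interval.length) / Decimal(1_000_000)
    quantum = Decimal(1).scaleb(-decimals)
    return float(mb.quantize(quantum, rounding=ROUND_HALF_UP))


def genes_in_region(
    genes: Iterable[tuple[str, str, int, str]],
    region: GenomicInterval,
) -> dict[str, list[str]]:
    """Group resident gene ids by family label.

    ``genes`` yields (gene_id, chromosome, position, family); a gene is
    resident when its point position falls inside ``region`` on the
    same chromosome.
    """
    out: dict[str, list[str]] = {}
    for gene_id, chromosome, position, family in genes:
        if chromosome == region.chromosome and region.contains(position):
            out.setdefault(family, []).append(gene_id)
    return out


def fraction_of_chromosome(
    region: GenomicInterval, chromosome_length: int
) -> tuple[float, float]:
    """Start and end of a region as percent of chromosome length, 2 decimals."""
    if chromosome_length < region.end:
        raise ValueError(
            f"chromosome length {chromosome_length} < region end {region.end}"
        )
    return (
        round(100.0 * region.start / chromosome_length, 2),
        round(100.0 * region.end / chromosome_length, 2),
    )


def interval_to_bed_line(interval: GenomicInterval, name: str = "") -> str:
    """BED (0-based half-open) line for a 1-based inclusive interval."""
    fields = [interval.chromosome, str(interval.start - 1), str(interval.end)]
    if name:
        fields.append(name)
    return "\t".join(fields)
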