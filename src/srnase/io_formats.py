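"""Readers and writers for the external table formats.

Everything the analysis consumes travels as plain text: FASTA for
sequences, header-bearing TSV for feature tables, identity matrices,
collinear blocks, genotype and band tables, and a whitespace-delimited
dialect for domain-search hits.  Missing values are written as an em
dash and parsed back to ``None`` (the source tables also use ``nr.``
for unavailable coordinates).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .protein_features import ABOVE_060, BELOW_060, RNaseT2Record

__all__ = [
    "FeatureTable",
    "DomainHit",
    "IdentityMatrix",
    "read_fasta",
    "write_fasta",
    "read_feature_table",
    "write_feature_table",
    "read_domain_hits",
    "read_exons_gff3",
    "read_blocks",
    "write_blocks",
    "read_identity_matrix",
    "read_genotype_table",
    "write_genotype_table",
    "read_band_table",
    "write_band_table",
    "write_report_json",
]

MISSING = "—"  # em dash
_MISSING_TOKENS = {MISSING, "-", "", "nr.", "nr", "NA", "na", "None"}


@dataclass
class FeatureTable:
    """A set of RNase T2 records plus free-text provenance."""

    records: list[RNaseT2Record]
    source: str = ""

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for rec in self.records:
            if rec.gene_id in seen:
                raise ValueError(f"duplicate gene id {rec.gene_id!r}")
            seen.add(rec.gene_id)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    def by_species(self) -> dict[str, list[RNaseT2Record]]:
        out: dict[str, list[RNaseT2Record]] = {}
        for rec in self.records:
            out.setdefault(rec.species, []).append(rec)
        return out


@dataclass(frozen=True)
class DomainHit:
    """One domain-search hit envelope in model coordinates (1-based inclusive)."""

    target_id: str
    model_name: str
    model_length: int
    hit_from: int
    hit_to: int

    def __post_init__(self) -> None:
        if not (1 <= self.hit_from <= self.hit_to <= self.model_length):
            raise ValueError(
                f"hit {self.target_id!r}: require 1 <= {self.hit_from} <= "
                f"{self.hit_to} <= {self.model_length}"
            )


class IdentityMatrix:
    """Symmetric percent-identity lookup between sequence identifiers."""

    def __init__(self, entries: Optional[dict[frozenset, float]] = None):
        self._entries: dict[frozenset, float] = dict(entries or {})

    def set(self, a: str, b: str, identity: float) -> None:
        self._entries[frozenset((a, b))] = float(identity)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 100.0
        try:
            return self._entries[frozenset((a, b))]
        except KeyError:
            raise KeyError(f"no identity entry for pair ({a!r}, {b!r})") from None

    def has(self, a: str, b: str) -> bool:
        return a == b or frozenset((a, b)) in self._entries

    def ids(self) -> set[str]:
        out: set[str] = set()
        for key in self._entries:
            out |= set(key)
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> list[tuple[str, str]]:
    """Read FASTA into (id, uppercased sequence) pairs.

    The identifier is the first whitespace-delimited token of the
    header.  Sequence text before the first header is a parse error
    naming the offending line.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path.name}:{lineno}: sequence before first FASTA header"
                )
            break
    return [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(path: Union[str, Path], records: Iterable[tuple[str, str]]) -> None:
    seqs = [
        SeqRecord(Seq(seq.upper()), id=name, description="") for name, seq in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_FEATURE_COLUMNS = [
    "gene_id",
    "species",
    "chromosome",
    "position",
    "intron_count",
    "pI",
    "mw",
    "signal_peptide",
    "signal_peptide_length",
    "domain_coverage",
    "pattern4",
    "n_amino_acids",
]


def _absent(value) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip() in _MISSING_TOKENS


def _parse_coverage(value) -> Union[float, str, None]:
    if _absent(value):
        return None
    text = str(value).strip()
    if text in (">60%", ABOVE_060):
        return ABOVE_060
    if text in ("<60%", BELOW_060):
        return BELOW_060
    return float(text)


def read_feature_table(path: Union[str, Path]) -> FeatureTable:
    """Read a family-characteristics feature TSV into a :class:`FeatureTable`.

    Raises a schema error when a mandatory column is missing and a row
    error (naming the row index) when a numeric field fails to parse.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing_cols = [c for c in _FEATURE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path.name}: missing mandatory column(s) {missing_cols}")
    records: list[RNaseT2Record] = []
    for idx, row in df.iterrows():
        try:
            sp_flag = str(row["signal_peptide"]).strip().upper()
            if sp_flag not in ("Y", "N"):
                raise ValueError(f"signal_peptide must be Y or N, got {sp_flag!r}")
            records.append(
                RNaseT2Record(
                    gene_id=str(row["gene_id"]).strip(),
                    species=str(row["species"]).strip(),
                    chromosome=None if _absent(row["chromosome"]) else str(row["chromosome"]).strip(),
                    position=None if _absent(row["position"]) else int(row["position"]),
                    intron_count=None if _absent(row["intron_count"]) else int(row["intron_count"]),
                    pI=None if _absent(row["pI"]) else float(row["pI"]),
                    mw=None if _absent(row["mw"]) else float(row["mw"]),
                    signal_peptide_present=sp_flag == "Y",
                    signal_peptide_length=None
                    if _absent(row["signal_peptide_length"])
                    else int(row["signal_peptide_length"]),
                    domain_coverage=_parse_coverage(row["domain_coverage"]),
                    pattern4_motif=None if _absent(row["pattern4"]) else str(row["pattern4"]).strip(),
                    n_amino_acids=None if _absent(row["n_amino_acids"]) else int(row["n_amino_acids"]),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path.name}: row {idx}: {exc}") from None
    return FeatureTable(records=records, source=str(path))


def _format_coverage(value) -> str:
    if value is None:
        return MISSING
    if value == ABOVE_060:
        return ">60%"
    if value == BELOW_060:
        return "<60%"
    return f"{float(value):g}"


def write_feature_table(path: Union[str, Path], table: FeatureTable) -> None:
    rows = []
    for r in table.records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "species": r.species,
                "chromosome": r.chromosome if r.chromosome is not None else MISSING,
                "position": r.position if r.position is not None else MISSING,
                "intron_count": r.intron_count if r.intron_count is not None else MISSING,
                "pI": r.pI if r.pI is not None else MISSING,
                "mw": r.mw if r.mw is not None else MISSING,
                "signal_peptide": "Y" if r.signal_peptide_present else "N",
                "signal_peptide_length": r.signal_peptide_length
                if r.signal_peptide_length is not None
                else MISSING,
                "domain_coverage": _format_coverage(r.domain_coverage),
                "pattern4": r.pattern4_motif if r.pattern4_motif is not None else MISSING,
                "n_amino_acids": r.n_amino_acids if r.n_amino_acids is not None else MISSING,
            }
        )
    pd.DataFrame(rows, columns=_FEATURE_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Domain hits
# ---------------------------------------------------------------------------

def read_domain_hits(path: Union[str, Path]) -> list[DomainHit]:
    """Whitespace-delimited hit table with columns target, model, model_len, hmm_from, hmm_to."""
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    required = ["target", "model", "model_len", "hmm_from", "hmm_to"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    return [
        DomainHit(
            target_id=str(row.target),
            model_name=str(row.model),
            model_length=int(row.model_len),
            hit_from=int(row.hmm_from),
            hit_to=int(row.hmm_to),
        )
        for row in df.itertuples()
    ]


def read_exons_gff3(path: Union[str, Path]) -> dict[str, list[tuple[int, int]]]:
    """Per-transcript sorted exon spans from a GFF3 subset.

    Only gene/mRNA/exon features are used; exons attach to their parent
    mRNA (or to their parent gene when no mRNA level is present).  Spans
    are 1-based inclusive, sorted by start, ready for
    :func:`srnase.protein_features.count_introns`.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    exons: dict[str, list[tuple[int, int]]] = {}
    for featuretype in ("mRNA", "gene"):
        for parent in db.features_of_type(featuretype):
            spans = sorted(
                (e.start, e.end) for e in db.children(parent, featuretype="exon")
            )
            if spans and parent.id not in exons:
                exons[parent.id] = spans
    return exons


# ---------------------------------------------------------------------------
# Collinear blocks
# ---------------------------------------------------------------------------

def read_blocks(path: Union[str, Path]):
    """Read a collinear-block TSV into :class:`~srnase.synteny_mapping.CollinearBlock` values.

    Coordinates are normalized so start <= end; all spans are 1-based
    inclusive.  Non-positive coordinates are an error.
    """
    from .synteny_mapping import CollinearBlock, GenomicInterval

    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    required = [
        "source_genome",
        "source_chrom",
        "source_start",
        "source_end",
        "target_chrom",
        "target_start",
        "target_end",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    blocks = []
    for row in df.itertuples():
        coords = [int(row.source_start), int(row.source_end), int(row.target_start), int(row.target_end)]
        if any(c <= 0 for c in coords):
            raise ValueError(f"{path.name}: non-positive coordinate in block {row.Index}")
        s1, e1 = sorted(coords[:2])
        s2, e2 = sorted(coords[2:])
        blocks.append(
            CollinearBlock(
                source_genome=str(row.source_genome),
                source=GenomicInterval(str(row.source_chrom), s1, e1),
                target=GenomicInterval(str(row.target_chrom), s2, e2),
            )
        )
    return blocks


def write_blocks(path: Union[str, Path], blocks) -> None:
    rows = [
        {
            "source_genome": b.source_genome,
            "source_chrom": b.source.chromosome,
            "source_start": b.source.start,
            "source_end": b.source.end,
            "target_chrom": b.target.chromosome,
            "target_start": b.target.start,
            "target_end": b.target.end,
        }
        for b in blocks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Identity matrices
# ---------------------------------------------------------------------------

def read_identity_matrix(path: Union[str, Path]) -> IdentityMatrix:
    """Long-format TSV (id_a, id_b, identity) into a symmetric lookup."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = ["id_a", "id_b", "identity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {missing}")
    matrix = IdentityMatrix()
    for row in df.itertuples():
        matrix.set(str(row.id_a), str(row.id_b), float(row.identity))
    return matrix


# ---------------------------------------------------------------------------
# Genotype and band tables
# ---------------------------------------------------------------------------

def read_genotype_table(path: Union[str, Path]) -> dict:
    """TSV (line_id, genotype) -> ordered mapping line id -> SGenotype."""
    from .si_genetics import SGenotype

    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("line_id", "genotype"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    out: dict[str, "SGenotype"] = {}
    for row in df.itertuples():
        line = str(row.line_id)
        if line in out:
            raise ValueError(f"duplicate line id {line!r}")
        out[line] = SGenotype.from_string(str(row.genotype))
    return out


def write_genotype_table(path: Union[str, Path], genotypes: dict) -> None:
    rows = [{"line_id": k, "genotype": g.name} for k, g in genotypes.items()]
    pd.DataFrame(rows, columns=["line_id", "genotype"]).to_csv(path, sep="\t", index=False)


def read_band_table(path: Union[str, Path]) -> dict[str, list[float]]:
    """TSV (sample, bands) with comma-separated band sizes in bp."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sample", "bands"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    out: dict[str, list[float]] = {}
    for row in df.itertuples():
        text = "" if _absent(row.bands) else str(row.bands).strip()
        out[str(row.sample)] = [float(t) for t in text.split(",") if t.strip()]
    return out


def write_band_table(path: Union[str, Path], bands: dict[str, Sequence[float]]) -> None:
    rows = [
        {"sample": k, "bands": ",".join(f"{b:g}" for b in v) or MISSING}
        for k, v in bands.items()
    ]
    pd.DataFrame(rows, columns=["sample", "bands"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report_json(path: Union[str, Path], report: dict) -> None:
    """Emit a report dict as JSON with stable, insertion-ordered keys."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
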