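"""Loaders for the packaged reference fixtures.

The fixtures transcribe the published RNase T2 family feature tables
for *F. vesca* (14 genes) and *F. viridis* (13 genes), the 29 selfed-
line S-genotype table, the 214-progeny selfing population, and the
three chromosome-6 collinear blocks used for S-locus mapping.  The two
identity fixtures mix measured values with clearly marked synthetic
placeholders where the underlying values were never published (see the
file headers).
"""

from __future__ import annotations

from importlib import resources

from .io_formats import (
    FeatureTable,
    IdentityMatrix,
    read_blocks,
    read_feature_table,
    read_genotype_table,
    read_identity_matrix,
)

__all__ = [
    "fixture_path",
    "load_fvesca_features",
    "load_fviridis_features",
    "load_candidate_identities",
    "load_crosstribe_identities",
    "CROSSTRIBE_REF_IDS",
    "load_table2_genotypes",
    "load_progeny_214",
    "load_fig4_blocks",
]

CROSSTRIBE_REF_IDS = ["crosstribe_SRNase_ref"]


def fixture_path(name: str):
    return resources.files("srnase.data").joinpath(name)


def load_fvesca_features() -> FeatureTable:
    """The 14 *F. vesca* RNase T2 family records."""
    return read_feature_table(fixture_path("table_1_fvesca.tsv"))


def load_fviridis_features() -> FeatureTable:
    """The 13 *F. viridis* RNase T2 family records."""
    return read_feature_table(fixture_path("table_1_fviridis.tsv"))


def load_candidate_identities() -> IdentityMatrix:
    """Pairwise identities among intron-filter survivors (partly placeholders)."""
    return read_identity_matrix(fixture_path("candidate_identities.tsv"))


def load_crosstribe_identities() -> IdentityMatrix:
    """Synthetic cross-tribe reference identities for allele pairing."""
    return read_identity_matrix(fixture_path("synthetic_crosstribe_identities.tsv"))


def load_table2_genotypes() -> dict:
    """S genotypes of the 29 wild + selfed *F. viridis* lines."""
    return read_genotype_table(fixture_path("table_2_genotypes.tsv"))


def load_progeny_214() -> dict:
    """Genotypes of the 214 progeny from selfing a SaSb heterozygote."""
    return read_genotype_table(fixture_path("progeny_214_genotypes.tsv"))


def load_fig4_blocks() -> list:
    """The three collinear blocks projecting rose/almond S loci onto chromosome 6."""
    return read_blocks(fixture_path("fig4_blocks.tsv"))
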