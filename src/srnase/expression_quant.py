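"""Relative expression by the 2^-ddCt method.

Target-gene Ct values are normalized against a reference gene (EF-1a by
default) within each sample, then against a calibrator sample:
fold change = 2**-((Ct_tgt,s - Ct_ref,s) - (Ct_tgt,c - Ct_ref,c)).
Technical replicates are averaged by arithmetic mean before the
difference is taken.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import mean, pstdev
from typing import Sequence

import pandas as pd

__all__ = ["DEFAULT_REFERENCE_GENE", "CtMeasurement", "ddct_fold_change", "fold_changes_from_table"]

DEFAULT_REFERENCE_GENE = "EF-1a"


@dataclass
class CtMeasurement:
    """Replicate Ct values for one (sample, gene) pair."""

    sample: str
    gene: str
    ct_values: list[float]

    def __post_init__(self) -> None:
        if not self.ct_values:
            raise ValueError("at least one Ct replicate required")
        if any(not (0.0 < ct < 50.0) for ct in self.ct_values):
            raise ValueError("Ct values must lie in (0, 50) cycles")

    @property
    def mean_ct(self) -> float:
        return mean(self.ct_values)

    @property
    def sd_ct(self) -> float:
        return pstdev(self.ct_values)


def ddct_fold_change(
    target_sample: Sequence[float],
    reference_sample: Sequence[float],
    target_calibrator: Sequence[float],
    reference_calibrator: Sequence[float],
) -> float:
    """2^-ddCt fold change from four replicate Ct series.

    All four series are required; each is averaged before the delta
    deltas are formed.
    """
    series = {
        "target_sample": target_sample,
        "reference_sample": reference_sample,
        "target_calibrator": target_calibrator,
        "reference_calibrator": reference_calibrator,
    }
    for name, values in series.items():
        if values is None or len(values) == 0:
            raise ValueError(f"missing Ct series: {name}")
    dct_sample = mean(target_sample) - mean(reference_sample)
    dct_calibrator = mean(target_calibrator) - mean(reference_calibrator)
    return 2.0 ** -(dct_sample - dct_calibrator)


def fold_changes_from_table(
    df: pd.DataFrame,
    target_gene: str,
    calibrator_sample: str,
    reference_gene: str = DEFAULT_REFERENCE_GENE,
) -> dict[str, float]:
    """Per-sample fold changes from a long-format Ct table.

    ``df`` needs columns ``sample``, ``gene`` and ``ct`` (one row per
    technical replicate).  Returns sample -> fold change relative to the
    calibrator; the calibrator itself maps to 1.0 by construction.
    """
    for col in ("sample", "gene", "ct"):
        if col not in df.columns:
            raise ValueError(f"Ct table missing column {col!r}")

    def series(sample: str, gene: str) -> list[float]:
        values = df[(df["sample"] == sample) & (df["gene"] == gene)]["ct"].tolist()
        if not values:
            raise ValueError(f"no Ct values for sample {sample!r}, gene {gene!r}")
        return [float(v) for v in values]

    tgt_cal = series(calibrator_sample, target_gene)
    ref_cal = series(calibrator_sample, reference_gene)
    out: dict[str, float] = {}
    for sample in df["sample"].unique():
        out[str(sample)] = ddct_fold_change(
            series(str(sample), target_gene),
            series(str(sample), reference_gene),
            tgt_cal,
            ref_cal,
        )
    return out
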