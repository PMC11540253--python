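"""Shared domain containers for the BarSeq/TnSeq fitness pipeline.

These are thin, validated wrappers around pandas objects so that every
pipeline stage speaks the same types: sample metadata, barcode extraction
flank specifications, and the central barcode x sample count matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

_DNA = set("ACGT")

SAMPLE_COLUMNS = ["condition", "regime", "generation", "replicate"]
REGIMES = ("continuous", "pulsed", "batch")


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one sequenced competition sample.

    Parameters
    ----------
    sample_id:
        Unique sample label, used as the column name in count matrices.
    condition:
        Growth condition label (e.g. ``fructose``, ``formate``,
        ``lithoautotrophic``).
    regime:
        Feeding regime: ``continuous`` (chemostat), ``pulsed``
        (turbidostat-style substrate pulses) or ``batch``.
    generation:
        Population doublings elapsed since the T0 reference sample
        (dimensionless, >= 0; T0 samples have generation 0).
    replicate:
        Biological replicate index (1-based by convention).
    """

    sample_id: str
    condition: str
    regime: str = "continuous"
    generation: float = 0.0
    replicate: int = 1

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise ValueError(f"unknown feeding regime {self.regime!r}; expected one of {REGIMES}")
        if self.generation < 0:
            raise ValueError("generation must be >= 0")


def samples_to_frame(samples: Iterable[SampleMeta]) -> pd.DataFrame:
    """Tabulate sample metadata, indexed by sample_id."""
    rows = list(samples)
    if not rows:
        return pd.DataFrame(columns=SAMPLE_COLUMNS)
    df = pd.DataFrame(
        {
            "condition": [s.condition for s in rows],
            "regime": [s.regime for s in rows],
            "generation": [s.generation for s in rows],
            "replicate": [s.replicate for s in rows],
        },
        index=pd.Index([s.sample_id for s in rows], name="sample_id"),
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].tolist()
        raise ValueError(f"duplicate sample ids: {dups}")
    return df


def frame_to_samples(df: pd.DataFrame) -> list[SampleMeta]:
    return [
        SampleMeta(
            sample_id=str(idx),
            condition=str(row["condition"]),
            regime=str(row["regime"]),
            generation=float(row["generation"]),
            replicate=int(row["replicate"]),
        )
        for idx, row in df.iterrows()
    ]


@dataclass(frozen=True)
class FlankSpec:
    """Constant sequences flanking the random barcode in an amplicon read.

    The barcode is located by finding ``left`` (allowing up to
    ``max_flank_mismatch`` substitutions, no indels), taking the next
    ``barcode_length`` bases, and verifying the first ``right_anchor_len``
    bases of ``right`` with the same mismatch budget.
    """

    left: str
    right: str
    barcode_length: int = 20
    max_flank_mismatch: int = 0
    right_anchor_len: int = 6

    def __post_init__(self) -> None:
        if not self.left or not self.right:
            raise ValueError("flank sequences must be non-empty")
        if self.barcode_length <= 0:
            raise ValueError("barcode_length must be positive")
        if self.max_flank_mismatch < 0:
            raise ValueError("max_flank_mismatch must be >= 0")
        if not (1 <= self.right_anchor_len <= len(self.right)):
            raise ValueError("right_anchor_len must lie in [1, len(right)]")
        for s in (self.left, self.right):
            if set(s) - _DNA:
                raise ValueError(f"flank contains non-ACGT characters: {s!r}")

    @property
    def right_anchor(self) -> str:
        return self.right[: self.right_anchor_len]

    @property
    def min_read_length(self) -> int:
        return len(self.left) + self.barcode_length + self.right_anchor_len


# Default flanks: the universal priming sites bracketing the N20 barcode in
# standard RB-TnSeq transposon constructs (U1 upstream, U2 downstream).
DEFAULT_FLANKS = FlankSpec(left="GATGTCCACGAGGTCTCT", right="CGTACGCTGCAGGTCGAC")


@dataclass
class BarcodeCountMatrix:
    """Barcode x sample matrix of raw read counts with sample metadata.

    ``counts`` is indexed by barcode with one column per sample_id;
    ``samples`` is indexed by sample_id and carries condition, regime,
    generation and replicate for every column.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64, copy=False)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate barcodes in count matrix")
        missing = set(map(str, self.counts.columns)) - set(map(str, self.samples.index))
        if missing:
            raise ValueError(f"samples metadata missing for columns: {sorted(missing)}")

    @property
    def barcodes(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> list[str]:
        return [str(c) for c in self.counts.columns]

    def meta(self, sample_id: str) -> SampleMeta:
        row = self.samples.loc[sample_id]
        return SampleMeta(
            sample_id=sample_id,
            condition=str(row["condition"]),
            regime=str(row["regime"]),
            generation=float(row["generation"]),
            replicate=int(row["replicate"]),
        )

    def t0_sample_ids(self) -> list[str]:
        meta = self.samples.loc[self.sample_ids]
        return [s for s in self.sample_ids if float(meta.loc[s, "generation"]) == 0.0]

    def subset_barcodes(self, barcodes: Sequence[str]) -> "BarcodeCountMatrix":
        return BarcodeCountMatrix(self.counts.loc[list(barcodes)], self.samples)
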