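"""Barcode extraction and counting from BarSeq amplicon reads.

Reads have the fixed structure ``left_flank + N20 barcode + right_flank``
(plus adapter padding). Extraction is substitution-only: the left flank is
located allowing up to ``max_flank_mismatch`` mismatches, the next
``barcode_length`` bases are taken as the barcode, and a short right-flank
anchor is verified with the same mismatch budget. Failed reads are
tallied, not raised. Unknown barcodes are dropped by default (the library
is pre-mapped) with optional collapse to a unique known barcode at
Hamming distance 1.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import BarcodeCountMatrix, FlankSpec, SampleMeta, samples_to_frame
from .io import iter_read_sequences


@dataclass
class CountReport:
    """Per-sample extraction statistics for a counting run."""

    total_reads: dict[str, int] = field(default_factory=dict)
    extracted: dict[str, int] = field(default_factory=dict)
    matched: dict[str, int] = field(default_factory=dict)
    collapsed: dict[str, int] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "total_reads": self.total_reads,
                "extracted": self.extracted,
                "matched": self.matched,
                "collapsed": self.collapsed,
            }
        ).fillna(0).astype(int)


def _hamming_leq(a: str, b: str, budget: int) -> bool:
    mism = 0
    for x, y in zip(a, b):
        if x != y:
            mism += 1
            if mism > budget:
                return False
    return True


def extract_barcode(read: str, flanks: FlankSpec) -> str | None:
    """Extract the barcode from one read, or None if no acceptable match.

    The leftmost offset at which both the left flank and the right-flank
    anchor match within the mismatch budget wins. Reads shorter than
    ``left + barcode + anchor`` always fail.
    """
    left, bl = flanks.left, flanks.barcode_length
    ll = len(left)
    anchor = flanks.right_anchor
    al = len(anchor)
    if len(read) < ll + bl + al:
        return None
    m = flanks.max_flank_mismatch
    if m == 0:
        start = 0
        while True:
            i = read.find(left, start)
            if i < 0:
                return None
            j = i + ll + bl
            if read[j : j + al] == anchor:
                return read[i + ll : j]
            start = i + 1
    # mismatch-tolerant scan, leftmost acceptable offset wins
    last = len(read) - (ll + bl + al)
    for i in range(last + 1):
        if _hamming_leq(read[i : i + ll], left, m):
            j = i + ll + bl
            if _hamming_leq(read[j : j + al], anchor, m):
                return read[i + ll : j]
    return None


def _distance1_neighbor(barcode: str, known: set[str]) -> str | None:
    """The unique known barcode at Hamming distance exactly 1, if any."""
    hit = None
    for i, orig in enumerate(barcode):
        prefix, suffix = barcode[:i], barcode[i + 1 :]
        for b in "ACGT":
            if b == orig:
                continue
            cand = prefix + b + suffix
            if cand in known:
                if hit is not None and hit != cand:
                    return None  # ambiguous
                hit = cand
    return hit


def count_barcodes(
    reads_by_sample: Mapping[str, object],
    flanks: FlankSpec,
    known_barcodes: Sequence[str] | None = None,
    sample_meta: Iterable[SampleMeta] | None = None,
    collapse_distance1: bool = False,
) -> tuple[BarcodeCountMatrix, CountReport]:
    """Count barcodes per sample from raw reads.

    ``reads_by_sample`` maps sample_id to a read source: a FASTQ path (str
    or Path, plain or gzip), a list of paths, or any iterable of read
    sequences / (id, seq, qual) tuples. With ``known_barcodes`` given,
    unknown extractions are dropped, or — with ``collapse_distance1`` —
    attributed to a known barcode at Hamming distance 1 when that
    neighbour is unique. Without ``known_barcodes`` every extracted
    barcode is counted.

    Returns the count matrix (rows = known barcodes if given, else all
    observed barcodes) and a per-sample extraction report.
    """
    known = set(known_barcodes) if known_barcodes is not None else None
    report = CountReport()
    per_sample: dict[str, dict[str, int]] = {}

    left, bl = flanks.left, flanks.barcode_length
    ll = len(left)
    anchor, al = flanks.right_anchor, flanks.right_anchor_len
    exact_only = flanks.max_flank_mismatch == 0

    for sample_id, source in reads_by_sample.items():
        tally: dict[str, int] = {}
        total = extracted = matched = collapsed = 0
        for read in iter_read_sequences(source):
            total += 1
            if exact_only:
                # inlined fast path of extract_barcode
                bc = None
                start = 0
                while True:
                    i = read.find(left, start)
                    if i < 0:
                        break
                    j = i + ll + bl
                    if read[j : j + al] == anchor and len(read) >= j + al:
                        bc = read[i + ll : j]
                        break
                    start = i + 1
                if bc is not None and len(bc) < bl:
                    bc = None
            else:
                bc = extract_barcode(read, flanks)
            if bc is None:
                continue
            extracted += 1
            if known is not None and bc not in known:
                if collapse_distance1:
                    neighbor = _distance1_neighbor(bc, known)
                    if neighbor is None:
                        continue
                    bc = neighbor
                    collapsed += 1
                else:
                    continue
            matched += 1
            tally[bc] = tally.get(bc, 0) + 1
        per_sample[sample_id] = tally
        report.total_reads[sample_id] = total
        report.extracted[sample_id] = extracted
        report.matched[sample_id] = matched
        report.collapsed[sample_id] = collapsed

    if known_barcodes is not None:
        index = pd.Index(list(known_barcodes), name="barcode")
    else:
        observed = sorted(set().union(*per_sample.values())) if per_sample else []
        index = pd.Index(observed, name="barcode")
    counts = pd.DataFrame(
        {s: pd.Series(t, dtype=np.int64).reindex(index, fill_value=0) for s, t in per_sample.items()},
        index=index,
    ).astype(np.int64)

    if sample_meta is not None:
        samples = samples_to_frame(sample_meta)
    else:
        samples = pd.DataFrame(
            {
                "condition": "unknown",
                "regime": "continuous",
                "generation": 0.0,
                "replicate": 1,
            },
            index=pd.Index(list(per_sample), name="sample_id"),
        )
    return BarcodeCountMatrix(counts=counts, samples=samples), report


def filter_counts(matrix: BarcodeCountMatrix, min_t0_count: float = 10) -> BarcodeCountMatrix:
    """Drop barcodes whose mean count over T0 samples is below threshold.

    Barcodes that start too rare give unstable log2 fold changes; removing
    them before scoring is standard practice. Idempotent; preserves column
    metadata. Raises if the matrix has no T0 (generation 0) columns.
    """
    t0 = matrix.t0_sample_ids()
    if not t0:
        raise ValueError("count matrix has no T0 (generation 0) samples")
    keep = matrix.counts[t0].mean(axis=1) >= min_t0_count
    return BarcodeCountMatrix(counts=matrix.counts.loc[keep], samples=matrix.samples)
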