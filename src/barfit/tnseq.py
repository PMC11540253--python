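"""Mapping barcodes to transposon insertion sites from junction reads.

A TnSeq junction read carries the barcode (between its usual flanks)
followed by a stretch of genomic DNA starting at the first base after the
transposon junction. The genomic tail is located by exact substring
search against both strands of every replicon, using a sorted 2-bit k-mer
seed index with full-tail verification — sufficient and dependency-free at
bacterial genome scale (an external aligner can be slotted in by replacing
:class:`GenomeIndex`).

Status rules per barcode: ``unique`` if all reads agree on one locus
within a small jitter window, or a majority (default >= 75% of mapped
reads) does; ``ambiguous`` if any read's tail matches several genomic
loci or the reads disagree beyond the majority rule; ``unmapped`` if no
read could be placed.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .barseq import _hamming_leq
from .containers import FlankSpec
from .genome import AnnotatedGenome
from .io import iter_read_sequences
from .simulate import revcomp

MAP_COLUMNS = ["barcode", "replicon", "position", "strand", "support_reads", "status", "gene"]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i


class GenomeIndex:
    """Sorted k-mer index over the forward strand of every replicon.

    Queries search the forward strands; reverse-strand hits are found by
    querying the reverse complement of the tail.
    """

    def __init__(self, genome: AnnotatedGenome, k: int = 20):
        if not genome.replicons or genome.total_length == 0:
            raise ValueError("cannot index an empty genome")
        if not (4 <= k <= 31):
            raise ValueError("seed length k must lie in [4, 31]")
        self.k = k
        self.replicon_names: list[str] = []
        self.offsets: list[int] = [0]
        self.seqs: dict[str, str] = genome.replicons
        codes_all: list[np.ndarray] = []
        pos_all: list[np.ndarray] = []
        offset = 0
        for name, seq in genome.replicons.items():
            self.replicon_names.append(name)
            n = len(seq)
            if n >= k:
                raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
                enc = _CODE[raw].astype(np.uint64)
                km = np.zeros(n - k + 1, dtype=np.uint64)
                for j in range(k):
                    km = (km << np.uint64(2)) | enc[j : j + n - k + 1]
                codes_all.append(km)
                pos_all.append(np.arange(n - k + 1, dtype=np.int64) + offset)
            offset += n
            self.offsets.append(offset)
        codes = np.concatenate(codes_all) if codes_all else np.empty(0, dtype=np.uint64)
        pos = np.concatenate(pos_all) if pos_all else np.empty(0, dtype=np.int64)
        order = np.argsort(codes, kind="stable")
        self._codes = codes[order]
        self._pos = pos[order]
        self._bounds = np.asarray(self.offsets)

    def _global_to_local(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self._bounds, gpos, side="right") - 1)
        return self.replicon_names[i], int(gpos - self._bounds[i])

    def find(self, query: str) -> list[tuple[str, int]]:
        """All forward-strand occurrences of ``query`` as (replicon, start)."""
        k = self.k
        if len(query) < k or set(query) - set("ACGT"):
            return []
        code = np.uint64(0)
        for ch in query[:k]:
            code = (code << np.uint64(2)) | np.uint64(_CODE[ord(ch)])
        lo = int(np.searchsorted(self._codes, code, side="left"))
        hi = int(np.searchsorted(self._codes, code, side="right"))
        hits = []
        for gpos in self._pos[lo:hi]:
            rep, p = self._global_to_local(int(gpos))
            if self.seqs[rep][p : p + len(query)] == query:
                hits.append((rep, p))
        return hits


@dataclass
class InsertionMap:
    """Barcode -> insertion locus with mapping status and read support."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reindex(columns=MAP_COLUMNS).reset_index(drop=True)

    def unique_entries(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "unique"]

    def barcode_to_gene(self) -> pd.Series:
        """Gene assignment (empty string = intergenic/unassigned/non-unique)."""
        return self.table.set_index("barcode")["gene"]

    def gene_insertion_counts(self) -> pd.Series:
        assigned = self.table[(self.table["status"] == "unique") & (self.table["gene"] != "")]
        return assigned.groupby("gene").size()


def _extract_barcode_and_tail(read: str, flanks: FlankSpec) -> tuple[str, str] | None:
    """Barcode plus everything after the full right flank, or None."""
    left, bl, right = flanks.left, flanks.barcode_length, flanks.right
    ll, rl = len(left), len(right)
    anchor, al = flanks.right_anchor, flanks.right_anchor_len
    m = flanks.max_flank_mismatch
    if len(read) < ll + bl + al:
        return None
    if m == 0:
        start = 0
        while True:
            i = read.find(left, start)
            if i < 0:
                return None
            j = i + ll + bl
            if read[j : j + al] == anchor:
                return read[i + ll : j], read[j + rl :]
            start = i + 1
    for i in range(len(read) - (ll + bl + al) + 1):
        if _hamming_leq(read[i : i + ll], left, m):
            j = i + ll + bl
            if _hamming_leq(read[j : j + al], anchor, m):
                return read[i + ll : j], read[j + rl :]
    return None


def map_insertions(
    tnseq_reads,
    genome: AnnotatedGenome,
    flanks: FlankSpec,
    min_genomic_len: int = 20,
    jitter: int = 3,
    majority: float = 0.75,
    seed_k: int = 20,
) -> InsertionMap:
    """Locate every barcode's insertion site from TnSeq junction reads.

    ``tnseq_reads`` is a FASTQ path or an iterable of read sequences /
    (id, seq, qual) tuples. Tails shorter than ``min_genomic_len`` are not
    searched. The insertion position is the first genome base after the
    transposon junction (0-based); a tail found on the reverse strand
    implies a ``-``-strand insertion at the 3' end of the match.
    """
    if not genome.replicons or genome.total_length == 0:
        raise ValueError("cannot map against an empty genome")
    index = GenomeIndex(genome, k=min(seed_k, min_genomic_len))

    per_barcode_loci: dict[str, Counter] = {}
    per_barcode_reads: dict[str, int] = {}
    multimapped: set[str] = set()
    for read in iter_read_sequences(tnseq_reads):
        hit = _extract_barcode_and_tail(read, flanks)
        if hit is None:
            continue
        barcode, tail = hit
        per_barcode_reads[barcode] = per_barcode_reads.get(barcode, 0) + 1
        if len(tail) < min_genomic_len:
            continue
        loci = [(rep, p, "+") for rep, p in index.find(tail)]
        loci += [(rep, p + len(tail) - 1, "-") for rep, p in index.find(revcomp(tail))]
        if not loci:
            continue
        if len(loci) > 1:
            multimapped.add(barcode)
            continue
        per_barcode_loci.setdefault(barcode, Counter())[loci[0]] += 1

    rows = []
    for barcode, n_reads in per_barcode_reads.items():
        loci = per_barcode_loci.get(barcode, Counter())
        mapped = sum(loci.values())
        if barcode in multimapped:
            rows.append((barcode, "", -1, "", mapped, "ambiguous", ""))
            continue
        if mapped == 0:
            rows.append((barcode, "", -1, "", 0, "unmapped", ""))
            continue
        (rep, pos, strand), _ = loci.most_common(1)[0]
        support = sum(
            c for (r, p, s), c in loci.items() if r == rep and s == strand and abs(p - pos) <= jitter
        )
        if support / mapped >= majority:
            rows.append((barcode, rep, pos, strand, support, "unique", ""))
        else:
            rows.append((barcode, "", -1, "", mapped, "ambiguous", ""))
    return InsertionMap(pd.DataFrame(rows, columns=MAP_COLUMNS))


def assign_genes(
    insertion_map: InsertionMap,
    genome: AnnotatedGenome,
    central_window: tuple[float, float] = (0.1, 0.9),
) -> InsertionMap:
    """Assign uniquely mapped insertions to genes via a central window.

    An insertion is assigned to a gene iff its position lies inside the
    gene interval and its relative position along the gene — measured from
    the gene's 5' end, i.e. strand-aware — falls in ``[lo, hi)``.
    Insertions in the gene termini (outside the window) or intergenic
    regions stay unassigned (empty gene) but are retained; they still
    contribute to frequency normalization downstream.
    """
    lo, hi = central_window
    if not (0.0 <= lo < hi <= 1.0):
        raise ValueError("central_window must satisfy 0 <= lo < hi <= 1")
    lookups = {}
    for rep in genome.replicons:
        g = genome.genes_on(rep).sort_values("start")
        lookups[rep] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["strand"].to_numpy(),
            g["locus_tag"].to_numpy(),
        )
    table = insertion_map.table.copy()
    genes = []
    for _, row in table.iterrows():
        gene = ""
        if row["status"] == "unique" and row["replicon"] in lookups:
            starts, ends, strands, tags = lookups[row["replicon"]]
            pos = int(row["position"])
            i = int(np.searchsorted(starts, pos, side="right") - 1)
            if i >= 0 and pos < ends[i]:
                length = ends[i] - starts[i]
                rel = (pos - starts[i]) / length if strands[i] == "+" else (ends[i] - 1 - pos) / length
                if lo <= rel < hi:
                    gene = tags[i]
        genes.append(gene)
    table["gene"] = genes
    return InsertionMap(table)
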