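"""End-to-end composition of the pipeline stages.

``analyze`` is the analysis path shared by the CLI and the benchmarks:
count matrix -> T0 filter -> frequencies -> log2 fold changes -> gene
fitness. ``run_synthetic_benchmark`` wraps the full closed loop on
simulated data — generate reads from a library with planted fitness
effects, recount, remap, rescore — and returns everything needed to
compare estimates against the planted truth.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .barseq import CountReport, count_barcodes, filter_counts
from .containers import DEFAULT_FLANKS, BarcodeCountMatrix, FlankSpec, SampleMeta
from .fitness import GeneFitnessTable, barcode_log2fc, gene_fitness, normalize
from .genome import AnnotatedGenome
from .simulate import MutantLibrary, simulate_competition, simulate_reads
from .tnseq import InsertionMap, assign_genes, map_insertions


def analyze(
    counts: BarcodeCountMatrix,
    barcode_gene_map,
    min_t0_count: float = 10,
    pseudocount: float = 0.5,
    generations: list[float] | None = None,
) -> GeneFitnessTable:
    """Score gene fitness from a barcode count matrix and a gene map."""
    filtered = filter_counts(counts, min_t0_count=min_t0_count)
    freqs = normalize(filtered, pseudocount=pseudocount)
    trajectories = barcode_log2fc(freqs, filtered.samples)
    return gene_fitness(trajectories, barcode_gene_map, generations=generations)


@dataclass
class BenchmarkResult:
    true_counts: BarcodeCountMatrix
    counted: BarcodeCountMatrix
    count_report: CountReport
    insertion_map: InsertionMap
    fitness: GeneFitnessTable

    def comparison(self, library: MutantLibrary, generation: float = 8.0, condition: str | None = None) -> pd.DataFrame:
        """Planted vs. estimated gene effect at one generation.

        The planted gene-level effect is ``g * (w - 1)`` for the gene's
        (shared) mutant fitness w. Returns columns planted, estimated.
        """
        t = self.fitness.table
        t = t[t["generation"] == generation]
        if condition is not None:
            t = t[t["condition"] == condition]
        est = t.groupby("gene")["f"].mean()
        genic = library.table[library.table["gene"] != ""]
        planted = (genic.groupby("gene")["w"].mean() - 1.0) * generation
        out = pd.DataFrame({"planted": planted, "estimated": est}).dropna()
        return out


def run_synthetic_benchmark(
    genome: AnnotatedGenome,
    library: MutantLibrary,
    samples: list[SampleMeta],
    depth: int,
    seed: int = 0,
    flanks: FlankSpec = DEFAULT_FLANKS,
    error_rate: float = 0.0,
    tnseq_reads_per_barcode: int = 5,
    genomic_tail_len: int = 30,
    min_t0_count: float = 10,
    central_window: tuple[float, float] = (0.1, 0.9),
    generations: list[float] | None = None,
) -> BenchmarkResult:
    """Simulate a competition, regenerate raw reads, and re-analyze them.

    Every stage runs through the same code paths a real dataset would:
    BarSeq reads are counted back into a matrix, TnSeq junction reads are
    mapped to rebuild the barcode -> gene assignment, and fitness scores
    come from the recovered (not the simulated) tables.
    """
    true_counts = simulate_competition(library, samples, depth, seed=seed)

    barseq_reads = simulate_reads(
        library, true_counts, mode="barseq", flanks=flanks,
        error_rate=error_rate, seed=seed + 1, seq_only=True,
    )
    counted, report = count_barcodes(
        barseq_reads, flanks, known_barcodes=list(library.barcodes),
        sample_meta=[true_counts.meta(s) for s in true_counts.sample_ids],
        collapse_distance1=error_rate > 0,
    )

    tn_counts = BarcodeCountMatrix(
        counts=pd.DataFrame({"tnseq": tnseq_reads_per_barcode}, index=library.barcodes),
        samples=pd.DataFrame(
            {"condition": ["mapping"], "regime": ["batch"], "generation": [0.0], "replicate": [1]},
            index=pd.Index(["tnseq"], name="sample_id"),
        ),
    )
    tn_reads = simulate_reads(
        library, tn_counts, mode="tnseq", flanks=flanks, genome=genome,
        genomic_tail_len=genomic_tail_len, error_rate=error_rate, seed=seed + 2, seq_only=True,
    )
    imap = map_insertions(tn_reads["tnseq"], genome, flanks, min_genomic_len=min(20, genomic_tail_len))
    imap = assign_genes(imap, genome, central_window=central_window)

    table = analyze(counted, imap.barcode_to_gene(), min_t0_count=min_t0_count, generations=generations)
    return BenchmarkResult(
        true_counts=true_counts,
        counted=counted,
        count_report=report,
        insertion_map=imap,
        fitness=table,
    )
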