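"""Annotated genomes and a deterministic synthetic-genome generator.

The generator emulates the genome organisation of *Cupriavidus necator*
H16 at configurable scale: roughly 6,600 protein-coding genes spread over
two chromosomes and a much smaller megaplasmid. Genes are tiled
non-overlapping along each replicon with fixed intergenic gaps, which keeps
interval arithmetic exact and makes insertion-to-gene assignment testable
against ground truth.

Coordinates are 0-based half-open internally; GFF3 output converts to the
1-based closed convention.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GENE_COLUMNS = ["locus_tag", "replicon", "start", "end", "strand", "pathway"]

#: Generic pathway labels used to tag synthetic genes; enrichment tests
#: only need a categorical annotation, not real KEGG identifiers.
DEFAULT_PATHWAY_LABELS = (
    "glycolysis",
    "tca_cycle",
    "calvin_cycle",
    "hydrogen_oxidation",
    "formate_oxidation",
    "nitrate_respiration",
    "phb_synthesis",
    "amino_acid_biosynthesis",
    "cofactor_biosynthesis",
    "transport",
    "regulation",
    "unknown",
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class AnnotatedGenome:
    """Replicon sequences plus a gene table.

    ``replicons`` maps replicon name to its DNA sequence. ``genes`` has
    columns locus_tag, replicon, start, end, strand, pathway with 0-based
    half-open coordinates. Gene intervals must lie within their replicon
    and locus tags must be unique; both are enforced at construction.
    """

    replicons: dict[str, str]
    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))

    def __post_init__(self) -> None:
        g = self.genes
        if list(g.columns) != GENE_COLUMNS:
            g = g.reindex(columns=GENE_COLUMNS)
        self.genes = g.reset_index(drop=True)
        if self.genes["locus_tag"].duplicated().any():
            dups = self.genes.loc[self.genes["locus_tag"].duplicated(), "locus_tag"].tolist()
            raise ValueError(f"duplicate locus_tags: {dups[:5]}")
        for _, row in self.genes.iterrows():
            rep = row["replicon"]
            if rep not in self.replicons:
                raise ValueError(f"gene {row['locus_tag']} on undeclared replicon {rep!r}")
            if not (0 <= row["start"] < row["end"] <= len(self.replicons[rep])):
                raise ValueError(
                    f"gene {row['locus_tag']} interval [{row['start']}, {row['end']}) "
                    f"outside replicon {rep!r} of length {len(self.replicons[rep])}"
                )

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.replicons.values())

    def gene_span(self) -> int:
        """Total number of bases covered by annotated genes."""
        return int((self.genes["end"] - self.genes["start"]).sum())

    def sequence(self, replicon: str, start: int, end: int) -> str:
        return self.replicons[replicon][start:end]

    def genes_on(self, replicon: str) -> pd.DataFrame:
        return self.genes[self.genes["replicon"] == replicon]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def make_genome(
    n_genes: int = 6600,
    n_replicons: int = 3,
    mean_gene_len: int = 900,
    intergenic_len: int = 100,
    replicon_weights: tuple[float, ...] | None = None,
    pathway_labels: tuple[str, ...] = DEFAULT_PATHWAY_LABELS,
    seed: int = 0,
) -> AnnotatedGenome:
    """Generate a synthetic annotated genome.

    Genes are tiled left to right on each replicon, separated by fixed
    ``intergenic_len`` gaps; gene lengths are drawn from a normal
    distribution around ``mean_gene_len`` (sd 30%, floor 150 bp). Gene
    counts per replicon follow ``replicon_weights`` (default 55/35/10%,
    mimicking two chromosomes plus a small megaplasmid when
    ``n_replicons`` is 3). Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If any size parameter is negative or non-positive where a positive
        value is required.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be >= 0")
    if n_replicons <= 0:
        raise ValueError("n_replicons must be >= 1")
    if mean_gene_len <= 0 or intergenic_len <= 0:
        raise ValueError("mean_gene_len and intergenic_len must be > 0")

    rng = np.random.default_rng(seed)
    if replicon_weights is None:
        replicon_weights = (0.55, 0.35, 0.10) if n_replicons == 3 else tuple([1.0 / n_replicons] * n_replicons)
    if len(replicon_weights) != n_replicons:
        raise ValueError("replicon_weights length must equal n_replicons")
    w = np.asarray(replicon_weights, dtype=float)
    w = w / w.sum()

    names = [f"replicon_{i + 1}" for i in range(n_replicons)]
    if n_replicons == 3:
        names = ["chromosome1", "chromosome2", "megaplasmid"]

    # Largest-remainder split of genes over replicons.
    raw = w * n_genes
    counts = np.floor(raw).astype(int)
    for i in np.argsort(raw - counts)[::-1][: n_genes - counts.sum()]:
        counts[i] += 1

    replicons: dict[str, str] = {}
    rows: list[tuple] = []
    gene_no = 0
    for rep_idx, (name, k) in enumerate(zip(names, counts)):
        lengths = rng.normal(mean_gene_len, 0.3 * mean_gene_len, size=k)
        lengths = np.maximum(lengths.round().astype(int), 150)
        cursor = intergenic_len
        for glen in lengths:
            gene_no += 1
            start, end = cursor, cursor + int(glen)
            strand = "+" if rng.random() < 0.5 else "-"
            pathway = pathway_labels[rng.integers(0, len(pathway_labels))]
            rows.append((f"SYNT_{gene_no:05d}", name, start, end, strand, pathway))
            cursor = end + intergenic_len
        replicons[name] = _random_sequence(rng, cursor)

    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    return AnnotatedGenome(replicons=replicons, genes=genes)
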