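"""File I/O: FASTQ/FASTA/GFF3 writers, TSV round-trips for the pipeline tables.

Internal coordinates are 0-based half-open; GFF3 output uses the 1-based
closed convention. FASTQ reading goes through Biopython's fast iterator
and transparently handles gzip.
"""
from __future__ import annotations

import gzip
from pathlib import Path
from typing import IO, Iterable, Iterator

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import BarcodeCountMatrix, FlankSpec, SAMPLE_COLUMNS
from .genome import AnnotatedGenome


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (title, sequence, quality) from a FASTQ file (plain or .gz).

    Malformed records raise a ValueError naming the file.
    """
    with _open_text(path) as fh:
        try:
            yield from FastqGeneralIterator(fh)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record in {path}: {exc}") from exc


def iter_read_sequences(source) -> Iterator[str]:
    """Normalize a read source to an iterator of sequences.

    Accepts a FASTQ path, a list of FASTQ paths, or an iterable of read
    sequences / (id, seq, qual) tuples.
    """
    if isinstance(source, (str, Path)):
        for _, seq, _ in iter_fastq(source):
            yield seq
        return
    peekable = iter(source)
    for item in peekable:
        if isinstance(item, (str, Path)) and Path(str(item)).suffix in (".fastq", ".fq", ".gz"):
            for _, seq, _ in iter_fastq(item):
                yield seq
        elif isinstance(item, str):
            yield item
        else:
            yield item[1]


def write_fastq(reads: Iterable[tuple[str, str, str]], path: str | Path) -> int:
    """Write (id, seq, qual) records as 4-line FASTQ (Phred+33); returns count."""
    n = 0
    with _open_text(path, "wt") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_fasta(genome: AnnotatedGenome, path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as fh:
        for name, seq in genome.replicons.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    """Write gene annotation as GFF3 (1-based closed output coordinates)."""
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.replicons.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for _, row in genome.genes.iterrows():
            attrs = f"ID={row['locus_tag']};locus_tag={row['locus_tag']};pathway={row['pathway']}"
            fh.write(
                "\t".join(
                    [
                        row["replicon"],
                        "barfit",
                        "gene",
                        str(int(row["start"]) + 1),
                        str(int(row["end"])),
                        ".",
                        row["strand"],
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def read_gff3_genes(path: str | Path) -> pd.DataFrame:
    """Read gene features from GFF3 into the internal 0-based gene table."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9 or parts[2] != "gene":
                continue
            attrs = dict(kv.split("=", 1) for kv in parts[8].split(";") if "=" in kv)
            tag = attrs.get("locus_tag", attrs.get("ID", ""))
            rows.append(
                (tag, parts[0], int(parts[3]) - 1, int(parts[4]), parts[6], attrs.get("pathway", ""))
            )
    return pd.DataFrame(rows, columns=["locus_tag", "replicon", "start", "end", "strand", "pathway"])


def read_fasta(path: str | Path) -> dict[str, str]:
    replicons: dict[str, str] = {}
    name, chunks = None, []
    with _open_text(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    replicons[name] = "".join(chunks)
                name, chunks = line[1:].split()[0], []
            elif line:
                chunks.append(line)
    if name is not None:
        replicons[name] = "".join(chunks)
    return replicons


def read_genome(fasta_path: str | Path, gff_path: str | Path) -> AnnotatedGenome:
    return AnnotatedGenome(replicons=read_fasta(fasta_path), genes=read_gff3_genes(gff_path))


def write_counts(matrix: BarcodeCountMatrix, path: str | Path) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="barcode")


def read_counts(path: str | Path, samples: pd.DataFrame) -> BarcodeCountMatrix:
    counts = pd.read_csv(path, sep="\t", index_col="barcode")
    return BarcodeCountMatrix(counts=counts, samples=samples)


def write_samples(samples: pd.DataFrame, path: str | Path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample_id")


def read_samples(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    df.index = df.index.astype(str)
    return df


def write_library(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_library(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False)


def read_flanks(path: str | Path) -> FlankSpec:
    """Read a FlankSpec from YAML (keys: left, right, barcode_length, ...)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return FlankSpec(**cfg)
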