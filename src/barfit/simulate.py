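"""Forward simulation of a barcoded transposon mutant pool.

Three stages mirror the experimental workflow that the analysis side of
this package inverts:

1. :func:`make_library` — place barcoded transposon insertions on an
   annotated genome (uniformly, or a fixed number per gene), excluding
   essential genes, and record a planted relative fitness ``w`` per mutant.
2. :func:`simulate_competition` — propagate mutant frequencies through a
   pooled growth competition and draw sequencing read counts.
3. :func:`simulate_reads` — emit the raw amplicon reads (BarSeq) or
   transposon-junction reads (TnSeq) those counts correspond to.

Relative fitness ``w`` is defined as doublings per population doubling
(neutral ``w`` = 1), so the expected log2 fold change of a rare mutant
after ``g`` population doublings is ``g * (w - 1)``. Essential genes are
modelled as yielding no viable insertion mutants at all.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

from .containers import DEFAULT_FLANKS, BarcodeCountMatrix, FlankSpec, SampleMeta, samples_to_frame
from .genome import AnnotatedGenome

LIBRARY_COLUMNS = ["barcode", "replicon", "position", "strand", "gene", "w"]

_RC = str.maketrans("ACGT", "TGCA")


def revcomp(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass
class MutantLibrary:
    """Barcode -> insertion locus table with planted relative fitness.

    ``table`` columns: barcode (20-nt), replicon, position (0-based, first
    genome base after the transposon junction), strand, gene (locus_tag or
    empty string for intergenic), w (planted relative fitness; only
    meaningful in synthetic mode).
    """

    table: pd.DataFrame
    barcode_length: int = 20

    def __post_init__(self) -> None:
        t = self.table.reindex(columns=LIBRARY_COLUMNS).reset_index(drop=True)
        if t["barcode"].duplicated().any():
            raise ValueError("barcodes must be unique")
        if len(t) and not (t["barcode"].str.len() == self.barcode_length).all():
            raise ValueError(f"all barcodes must have length {self.barcode_length}")
        self.table = t

    def __len__(self) -> int:
        return len(self.table)

    @property
    def barcodes(self) -> pd.Index:
        return pd.Index(self.table["barcode"])

    def planted_fitness(self) -> pd.Series:
        return self.table.set_index("barcode")["w"]

    def barcode_to_gene(self) -> pd.Series:
        """Ground-truth barcode -> locus_tag map (empty string = intergenic)."""
        return self.table.set_index("barcode")["gene"]

    def validate_against(self, genome: AnnotatedGenome) -> None:
        for _, row in self.table.iterrows():
            rep = row["replicon"]
            if rep not in genome.replicons:
                raise ValueError(f"insertion on undeclared replicon {rep!r}")
            if not (0 <= row["position"] < len(genome.replicons[rep])):
                raise ValueError(f"insertion position {row['position']} outside {rep!r}")


def _draw_barcodes(rng: np.random.Generator, n: int, length: int = 20) -> list[str]:
    if n > 4 ** min(length, 30) // 4:
        raise RuntimeError("barcode space exhausted for requested library size")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        batch = bases[rng.integers(0, 4, size=(n - len(out) + 8, length))]
        for row in batch:
            bc = row.tobytes().decode("ascii")
            if bc not in seen:
                seen.add(bc)
                out.append(bc)
                if len(out) == n:
                    break
    return out


def _gene_at(genome: AnnotatedGenome, lookup: dict, replicon: str, pos: int) -> str:
    starts, ends, tags = lookup[replicon]
    i = np.searchsorted(starts, pos, side="right") - 1
    if i >= 0 and pos < ends[i]:
        return tags[i]
    return ""


def _gene_lookup(genome: AnnotatedGenome) -> dict:
    lookup = {}
    for rep in genome.replicons:
        g = genome.genes_on(rep).sort_values("start")
        lookup[rep] = (
            g["start"].to_numpy(),
            g["end"].to_numpy(),
            g["locus_tag"].to_numpy(),
        )
    return lookup


def make_library(
    genome: AnnotatedGenome,
    n_mutants: int = 60_000,
    essential_genes: Iterable[str] = (),
    fitness_spec: Mapping[str, float] | None = None,
    seed: int = 0,
    placement: str = "uniform",
    barcodes_per_gene: int = 5,
    intergenic_fraction: float = 0.1,
    end_margin: int = 50,
) -> MutantLibrary:
    """Create a barcoded insertion library on ``genome``.

    ``placement="uniform"`` draws ``n_mutants`` insertion sites uniformly
    over the genome excluding essential genes (which yield no viable
    mutants). ``placement="per_gene"`` instead plants exactly
    ``barcodes_per_gene`` insertions inside every non-essential gene plus
    ``intergenic_fraction`` (of the genic total) intergenic insertions —
    convenient for benchmarking gene-level recovery.

    ``fitness_spec`` maps locus_tag -> planted relative fitness ``w``;
    unlisted genes and all intergenic insertions are neutral (w = 1).
    Insertions avoid ``end_margin`` bases at each replicon terminus so a
    junction read's genomic tail never runs off the (linearised) sequence.
    """
    if n_mutants < 0:
        raise ValueError("n_mutants must be >= 0")
    if placement not in ("uniform", "per_gene"):
        raise ValueError(f"unknown placement {placement!r}")
    rng = np.random.default_rng(seed)
    essential = set(essential_genes)
    fitness_spec = dict(fitness_spec or {})
    lookup = _gene_lookup(genome)

    loci: list[tuple[str, int]] = []
    if placement == "per_gene":
        genic = genome.genes[~genome.genes["locus_tag"].isin(essential)]
        for _, row in genic.iterrows():
            lo = max(int(row["start"]), end_margin)
            hi = min(int(row["end"]), len(genome.replicons[row["replicon"]]) - end_margin)
            if hi <= lo:
                continue
            for pos in rng.integers(lo, hi, size=barcodes_per_gene):
                loci.append((row["replicon"], int(pos)))
        n_intergenic = int(round(intergenic_fraction * len(loci)))
        loci.extend(_sample_uniform_loci(genome, rng, n_intergenic, set(genome.genes["locus_tag"]), end_margin, lookup))
    else:
        loci = _sample_uniform_loci(genome, rng, n_mutants, essential, end_margin, lookup)

    barcodes = _draw_barcodes(rng, len(loci))
    strands = np.where(rng.random(len(loci)) < 0.5, "+", "-")
    rows = []
    for bc, (rep, pos), strand in zip(barcodes, loci, strands):
        gene = _gene_at(genome, lookup, rep, pos)
        w = float(fitness_spec.get(gene, 1.0)) if gene else 1.0
        rows.append((bc, rep, pos, strand, gene, w))
    return MutantLibrary(pd.DataFrame(rows, columns=LIBRARY_COLUMNS))


def _sample_uniform_loci(
    genome: AnnotatedGenome,
    rng: np.random.Generator,
    n: int,
    excluded_genes: set[str],
    end_margin: int,
    lookup: dict,
) -> list[tuple[str, int]]:
    """Sample n loci uniformly over allowed intervals (margins and excluded
    gene bodies removed), by cumulative-length inversion."""
    intervals: list[tuple[str, int, int]] = []  # (replicon, start, end)
    for rep, seq in genome.replicons.items():
        lo, hi = end_margin, len(seq) - end_margin
        if hi <= lo:
            continue
        cursor = lo
        g = genome.genes_on(rep).sort_values("start")
        for _, row in g.iterrows():
            if row["locus_tag"] not in excluded_genes:
                continue
            s, e = max(int(row["start"]), lo), min(int(row["end"]), hi)
            if s > cursor:
                intervals.append((rep, cursor, s))
            cursor = max(cursor, e)
        if cursor < hi:
            intervals.append((rep, cursor, hi))
    if not intervals:
        if n > 0:
            raise RuntimeError("no genomic space available for insertions")
        return []
    lengths = np.array([e - s for _, s, e in intervals], dtype=np.int64)
    cum = np.concatenate([[0], np.cumsum(lengths)])
    draws = rng.integers(0, cum[-1], size=n)
    idx = np.searchsorted(cum, draws, side="right") - 1
    return [
        (intervals[i][0], int(intervals[i][1] + draws[k] - cum[i]))
        for k, i in enumerate(idx)
    ]


def expected_log2fc(w: float, g: float) -> float:
    """Expected log2 frequency change of a rare mutant: g * (w - 1)."""
    return g * (w - 1.0)


def plant_gene_effects(
    genome: AnnotatedGenome,
    effect_fractions: Mapping[float, float] | None = None,
    generation: float = 8.0,
    seed: int = 0,
) -> tuple[dict[str, float], pd.Series]:
    """Assign gene-level fitness effects f* and convert them to mutant w.

    ``effect_fractions`` maps a fitness effect f* (log2 units at
    ``generation``) to the fraction of genes carrying it; unassigned genes
    are neutral (f* = 0). The default plants -3, -2 and +1 on 10% of genes
    each — most genes in a pooled screen are phenotypically neutral in any
    one condition. Mutant relative fitness follows w = 1 + f*/g, so the
    expected gene score at ``generation`` equals f*.

    Returns (fitness_spec for :func:`make_library`, per-gene f* Series).
    """
    if effect_fractions is None:
        effect_fractions = {-3.0: 0.1, -2.0: 0.1, 1.0: 0.1}
    if sum(effect_fractions.values()) > 1.0 + 1e-12:
        raise ValueError("effect fractions must sum to <= 1")
    rng = np.random.default_rng(seed)
    tags = genome.genes["locus_tag"].to_numpy().copy()
    rng.shuffle(tags)
    effects = pd.Series(0.0, index=genome.genes["locus_tag"], name="f_star")
    start = 0
    for f_star, frac in effect_fractions.items():
        k = int(round(frac * len(tags)))
        effects.loc[tags[start : start + k]] = f_star
        start += k
    spec = {tag: 1.0 + f / generation for tag, f in effects.items()}
    return spec, effects


def simulate_competition(
    library: MutantLibrary,
    samples: Iterable[SampleMeta],
    depth: int,
    seed: int = 0,
    p0_sigma: float = 0.5,
    pulse_dilution: float = 0.062,
    pulse_n_eff: int = 10_000_000,
) -> BarcodeCountMatrix:
    """Simulate pooled competition and sequencing of a mutant library.

    Mutant frequencies follow the deterministic selection model
    ``p_i(g) = p_i(0) * 2**(g*w_i) / sum_j p_j(0) * 2**(g*w_j)``;
    sequencing draws each sample's counts multinomially at ``depth``, so
    every column sums to ``depth`` exactly.

    Starting frequencies are drawn once per (condition, replicate) group
    with log-normal abundance spread ``p0_sigma`` (all samples of a
    replicate share the same T0 pool). Under the ``pulsed`` regime the
    population additionally passes a genetic-drift bottleneck at every
    substrate pulse: each pulse replaces ``pulse_dilution`` of the culture
    volume with fresh medium (default 6.2%, i.e. ~0.092 doublings of
    regrowth per pulse) and the surviving pool is resampled multinomially
    at effective size ``pulse_n_eff``. Continuous and batch regimes have
    no bottleneck. Deterministic for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    samples = list(samples)
    if not samples:
        raise ValueError("no samples given")
    n = len(library)
    if n == 0:
        raise ValueError("empty mutant library")
    w = library.table["w"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)

    # Draw one T0 pool per (condition, replicate) group, in first-seen order.
    groups: dict[tuple[str, int], np.ndarray] = {}
    for s in samples:
        key = (s.condition, s.replicate)
        if key not in groups:
            x = np.exp(rng.normal(0.0, p0_sigma, size=n))
            groups[key] = x / x.sum()

    g_pulse = float(np.log2(1.0 / (1.0 - pulse_dilution)))
    columns: dict[str, np.ndarray] = {}
    for s in samples:
        p0 = groups[(s.condition, s.replicate)]
        if s.regime == "pulsed" and s.generation > 0:
            p = p0.copy()
            g_done = 0.0
            while g_done + g_pulse <= s.generation:
                p = p * np.exp2(g_pulse * w)
                p /= p.sum()
                cells = rng.multinomial(pulse_n_eff, p)
                p = cells / float(pulse_n_eff)
                g_done += g_pulse
            rest = s.generation - g_done
            if rest > 0:
                p = p * np.exp2(rest * w)
                p /= p.sum()
        else:
            p = p0 * np.exp2(s.generation * w)
            p = p / p.sum()
        columns[s.sample_id] = rng.multinomial(depth, p)

    counts = pd.DataFrame(columns, index=library.barcodes)
    counts.index.name = "barcode"
    return BarcodeCountMatrix(counts=counts, samples=samples_to_frame(samples))


def _genomic_tail(genome: AnnotatedGenome, replicon: str, pos: int, strand: str, length: int) -> tuple[str, bool]:
    """Genome sequence read off the transposon junction; truncated flag if
    the tail would run past the replicon end."""
    seq = genome.replicons[replicon]
    if strand == "+":
        tail = seq[pos : pos + length]
    else:
        lo = max(0, pos - length + 1)
        tail = revcomp(seq[lo : pos + 1])
    return tail, len(tail) < length


def simulate_reads(
    library: MutantLibrary,
    counts: BarcodeCountMatrix,
    mode: str = "barseq",
    flanks: FlankSpec = DEFAULT_FLANKS,
    genome: AnnotatedGenome | None = None,
    genomic_tail_len: int = 30,
    error_rate: float = 0.0,
    read_length: int | None = None,
    quality: int = 33,
    seed: int = 0,
    seq_only: bool = False,
) -> dict[str, Iterator]:
    """Emit raw reads for every sample in ``counts``.

    Returns ``{sample_id: iterator}`` where each iterator yields
    ``(read_id, sequence, quality)`` tuples (or bare sequences with
    ``seq_only=True``). BarSeq reads are ``left_flank + barcode +
    right_flank`` padded to ``read_length``; TnSeq reads append
    ``genomic_tail_len`` bases of genome sequence downstream of the
    insertion junction (requires ``genome``). Tails that would run past a
    replicon end are truncated and flagged ``truncated`` in the read name.
    Substitution errors are injected i.i.d. per base at ``error_rate``.
    The number of reads per barcode equals the count matrix entry exactly.
    """
    if mode not in ("barseq", "tnseq"):
        raise ValueError(f"mode must be 'barseq' or 'tnseq', got {mode!r}")
    if mode == "tnseq" and genome is None:
        raise ValueError("tnseq mode requires a genome")
    if not (0.0 <= error_rate < 1.0):
        raise ValueError("error_rate must lie in [0, 1)")

    lib = library.table
    missing = set(counts.barcodes) - set(lib["barcode"])
    if missing:
        raise ValueError(f"count matrix contains {len(missing)} barcodes absent from the library")
    loci = lib.set_index("barcode")[["replicon", "position", "strand"]]

    ss = np.random.SeedSequence(seed)
    child_seeds = ss.generate_state(len(counts.sample_ids))
    out: dict[str, Iterator] = {}
    for child, sample_id in zip(child_seeds, counts.sample_ids):
        out[sample_id] = _sample_reads(
            lib, loci, counts.counts[sample_id], sample_id, mode, flanks, genome,
            genomic_tail_len, error_rate, read_length, quality, int(child), seq_only,
        )
    return out


_MUT = {b: "ACGT".replace(b, "") for b in "ACGT"}


def _inject_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for i in rng.choice(len(seq), size=n_err, replace=False):
        chars[i] = _MUT[chars[i]][rng.integers(0, 3)]
    return "".join(chars)


def _sample_reads(
    lib: pd.DataFrame,
    loci: pd.DataFrame,
    col: pd.Series,
    sample_id: str,
    mode: str,
    flanks: FlankSpec,
    genome: AnnotatedGenome | None,
    tail_len: int,
    error_rate: float,
    read_length: int | None,
    quality: int,
    seed: int,
    seq_only: bool,
) -> Iterator:
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    pad = bases[rng.integers(0, 4, size=(read_length or 0) + 8)].tobytes().decode("ascii")
    qchar = chr(33 + quality)
    read_no = 0
    for bc, count in col.items():
        if count == 0:
            continue
        truncated = False
        if mode == "barseq":
            template = flanks.left + bc + flanks.right
        else:
            rep, pos, strand = loci.loc[bc]
            tail, truncated = _genomic_tail(genome, rep, int(pos), strand, tail_len)
            template = flanks.left + bc + flanks.right + tail
        if read_length is not None:
            template = (template + pad)[:read_length]
        qual = qchar * len(template)
        flag = ":truncated" if truncated else ""
        if error_rate == 0.0 and seq_only:
            for _ in range(int(count)):
                yield template
            continue
        for _ in range(int(count)):
            read_no += 1
            seq = _inject_errors(rng, template, error_rate) if error_rate > 0 else template
            if seq_only:
                yield seq
            else:
                yield (f"{sample_id}:{read_no}{flag}", seq, qual)
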