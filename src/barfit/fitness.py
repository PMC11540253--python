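"""Gene fitness scores and mutant growth-rate estimates from barcode counts.

The scoring chain is: per-sample frequency normalization (with a
pseudocount), per-barcode log2 fold change against the matched T0 sample
of the same condition and replicate, gene-level aggregation (unweighted
mean over a gene's barcodes, averaged over replicates) and per-condition
median centering. A negative fitness score means the mutant washed out of
the pool (the gene matters in that condition); positive means it was
enriched.

Growth-rate estimation inverts the exponential competition model: for a
rare mutant growing at rate ``mu`` in a population growing at ``mu_pop``,
the expected log2 frequency change after ``g`` population doublings is
``delta = g * (mu / mu_pop - 1)``, hence ``mu = mu_pop * (1 + delta / g)``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import BarcodeCountMatrix

FITNESS_COLUMNS = ["gene", "condition", "generation", "f", "n_barcodes", "sd"]


def normalize(matrix: BarcodeCountMatrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Per-sample relative frequencies: (count + pc) / sum(count + pc).

    Raises on non-positive pseudocount and on samples with zero total raw
    counts (naming the offending sample).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    totals = matrix.counts.sum(axis=0)
    dead = totals[totals == 0]
    if len(dead):
        raise ValueError(f"sample(s) with all-zero counts: {list(dead.index)}")
    shifted = matrix.counts + pseudocount
    return shifted / shifted.sum(axis=0)


def barcode_log2fc(frequencies: pd.DataFrame, samples: pd.DataFrame) -> pd.DataFrame:
    """Per-barcode log2 fold change vs. the matched T0, long format.

    ``frequencies`` is barcode x sample (from :func:`normalize`);
    ``samples`` is the sample sheet indexed by sample_id. Every
    (condition, replicate) group must contain a generation-0 sample; if it
    has several their frequencies are averaged. Returns columns barcode,
    condition, replicate, generation, sample_id, log2fc (T0 rows carry
    log2fc = 0 by construction).
    """
    meta = samples.loc[[c for c in frequencies.columns]]
    out = []
    for (condition, replicate), grp in meta.groupby(["condition", "replicate"], sort=False):
        t0_cols = grp.index[grp["generation"] == 0].tolist()
        if not t0_cols:
            raise ValueError(f"no T0 sample for condition={condition!r} replicate={replicate}")
        f0 = frequencies[t0_cols].mean(axis=1)
        for sample_id, row in grp.iterrows():
            delta = np.log2(frequencies[sample_id] / f0)
            out.append(
                pd.DataFrame(
                    {
                        "barcode": frequencies.index,
                        "condition": condition,
                        "replicate": replicate,
                        "generation": float(row["generation"]),
                        "sample_id": sample_id,
                        "log2fc": delta.to_numpy(),
                    }
                )
            )
    return pd.concat(out, ignore_index=True)


@dataclass
class GeneFitnessTable:
    """Gene x condition fitness scores with per-cell metadata.

    ``table`` columns: gene, condition, generation, f, n_barcodes, sd.
    Cells exist only where at least one barcode was scored — never
    zero-filled. Scores are median-centered within each (condition,
    generation), so the median over scored genes is 0.
    """

    table: pd.DataFrame

    def matrix(self, generation: float | None = 8.0) -> pd.DataFrame:
        t = self.table
        if generation is not None:
            t = t[t["generation"] == generation]
        return t.pivot_table(index="gene", columns="condition", values="f", aggfunc="first")

    def generations(self) -> list[float]:
        return sorted(self.table["generation"].unique())


def gene_fitness(
    trajectories: pd.DataFrame,
    barcode_gene_map: Mapping[str, str] | pd.Series,
    generations: list[float] | None = None,
) -> GeneFitnessTable:
    """Aggregate barcode log2 fold changes into gene fitness scores.

    For every condition and generation: barcode log2FCs are averaged per
    gene within each replicate, replicate means are averaged, and the
    resulting scores are centered by subtracting the per-condition median
    over all scored genes. ``barcode_gene_map`` assigns barcodes to genes
    (empty string / missing = unassigned, excluded from scoring).
    ``generations`` restricts scoring to the given generations (default:
    all non-zero generations present).
    """
    gene_map = pd.Series(dict(barcode_gene_map)) if not isinstance(barcode_gene_map, pd.Series) else barcode_gene_map
    gene_map = gene_map[gene_map != ""]
    if gene_map.empty:
        raise ValueError("barcode -> gene mapping is empty")
    t = trajectories[trajectories["generation"] > 0].copy()
    if generations is not None:
        t = t[t["generation"].isin(generations)]
    t["gene"] = t["barcode"].map(gene_map)
    t = t.dropna(subset=["gene"])
    if t.empty:
        raise ValueError("no scorable barcodes after gene assignment")

    per_rep = (
        t.groupby(["gene", "condition", "generation", "replicate"])["log2fc"]
        .mean()
        .reset_index()
    )
    agg = (
        per_rep.groupby(["gene", "condition", "generation"])["log2fc"]
        .agg(f="mean", sd="std")
        .reset_index()
    )
    n_bc = (
        t.groupby(["gene", "condition", "generation"])["barcode"]
        .nunique()
        .rename("n_barcodes")
        .reset_index()
    )
    out = agg.merge(n_bc, on=["gene", "condition", "generation"])
    out["f"] = out.groupby(["condition", "generation"])["f"].transform(lambda s: s - s.median())
    return GeneFitnessTable(out[FITNESS_COLUMNS])


def significant_genes(
    table: GeneFitnessTable,
    threshold: float = 2.0,
    min_generations: float = 8.0,
) -> tuple[set[str], dict[str, set[str]]]:
    """Genes with |f| >= threshold after at least ``min_generations``.

    Returns the overall set (significant in ANY condition) and a
    per-condition breakdown. The threshold is inclusive.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    t = table.table
    hits = t[(t["generation"] >= min_generations) & (t["f"].abs() >= threshold)]
    per_condition = {c: set(g["gene"]) for c, g in hits.groupby("condition")}
    return set(hits["gene"]), per_condition


@dataclass(frozen=True)
class GrowthEstimate:
    """Mutant growth rate inferred from competition log2 fold change."""

    name: str
    mu: float
    mu_pop: float
    g: float
    delta: float


def estimate_growth_rate(delta, g: float, mu_pop: float):
    """Invert the rare-mutant competition model: mu = mu_pop * (1 + delta/g).

    ``delta`` is the log2 fold change of mutant frequency after ``g``
    population doublings at nominal population growth rate ``mu_pop``
    (1/h). delta = 0 returns mu_pop exactly; delta = -g returns 0. Accepts
    scalars or arrays. The small correction from the mutant's own
    contribution to the population mean is neglected (each mutant is a
    ~1/60,000 fraction of the pool).
    """
    if g <= 0:
        raise ValueError("g must be > 0")
    if mu_pop <= 0:
        raise ValueError("mu_pop must be > 0")
    out = mu_pop * (1.0 + np.asarray(delta, dtype=float) / g)
    return float(out) if np.ndim(delta) == 0 else out


def gene_growth_rates(
    table: GeneFitnessTable,
    mu_pop: float,
    generation: float = 8.0,
) -> pd.DataFrame:
    """Per-gene growth-rate estimates from fitness scores at one generation.

    Returns columns gene, condition, generation, delta, mu, mu_pop.
    """
    t = table.table[table.table["generation"] == generation].copy()
    t = t.rename(columns={"f": "delta"})[["gene", "condition", "generation", "delta"]]
    t["mu"] = estimate_growth_rate(t["delta"].to_numpy(), generation, mu_pop)
    t["mu_pop"] = mu_pop
    return t
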