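"""Operon-aware protein cost of gene knockouts.

The protein-cost hypothesis: a cell's capacity to make protein is
limited, so every expressed-but-unused enzyme is a burden and knocking it
out frees proteome capacity and can raise growth rate. The *individual*
cost of a knockout is the proteome mass fraction of the gene's own
product. Transposon insertions are polar, so the *total* cost also
includes every gene downstream in the same transcription unit — and,
transitively, every transcription unit whose promoter depends on a
regulator that is itself silenced.

The packaged hox/hyp fixture encodes the hydrogenase gene arrangement of
*C. necator* megaplasmid pHG1: the membrane-bound hydrogenase (MBH)
operon, the soluble hydrogenase (SH) operon, the accessory *hyp* operon
and the regulatory *hoxABCJ* unit, with the HoxA master regulator
activating the MBH and SH promoters. Its mass-fraction table is
synthetic (shaped like proteomics data, not measured values).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import pearsonr


@dataclass(frozen=True)
class TranscriptionUnit:
    unit_id: str
    promoter: str
    genes: tuple[str, ...]  # ordered, promoter-proximal first


@dataclass
class OperonModel:
    """Transcription units plus regulator -> promoter dependencies.

    Each gene belongs to at most one transcription unit; the dependency
    graph (knockout -> silenced genes) must be acyclic, which is checked
    at construction.
    """

    units: dict[str, TranscriptionUnit]
    regulators: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for unit in self.units.values():
            for gene in unit.genes:
                if gene in seen:
                    raise ValueError(f"gene {gene!r} appears in units {seen[gene]!r} and {unit.unit_id!r}")
                seen[gene] = unit.unit_id
        self._unit_of = seen
        self._units_by_promoter: dict[str, list[str]] = {}
        for unit in self.units.values():
            self._units_by_promoter.setdefault(unit.promoter, []).append(unit.unit_id)
        self._check_acyclic()

    def _silenced_by(self, gene: str) -> set[str]:
        """Genes directly silenced by knocking out ``gene`` (one step)."""
        out: set[str] = set()
        uid = self._unit_of.get(gene)
        if uid is not None:
            genes = self.units[uid].genes
            out.update(genes[genes.index(gene) + 1 :])
        for promoter in self.regulators.get(gene, ()):
            for dep_uid in self._units_by_promoter.get(promoter, ()):
                out.update(self.units[dep_uid].genes)
        return out

    def _check_acyclic(self) -> None:
        WHITE, GRAY, BLACK = 0, 1, 2
        color: dict[str, int] = {}

        def visit(gene: str) -> None:
            color[gene] = GRAY
            for nxt in self._silenced_by(gene):
                c = color.get(nxt, WHITE)
                if c == GRAY:
                    raise ValueError(f"cyclic regulator dependency involving {nxt!r}")
                if c == WHITE:
                    visit(nxt)
            color[gene] = BLACK

        for gene in self._unit_of:
            if color.get(gene, WHITE) == WHITE:
                visit(gene)

    def all_genes(self) -> set[str]:
        return set(self._unit_of)


def load_mass_table(source) -> pd.Series:
    """Load a gene -> proteome mass fraction table (percent of total mass).

    Accepts a TSV path with columns (gene, psi_percent, ...) or a mapping.
    Fractions must be non-negative and sum to <= 100 (missing genes are
    allowed).
    """
    if isinstance(source, (dict, pd.Series)):
        psi = pd.Series(source, dtype=float)
    else:
        df = pd.read_csv(source, sep="\t")
        psi = df.set_index(df.columns[0])[df.columns[1]].astype(float)
    if (psi < 0).any():
        raise ValueError("mass fractions must be non-negative")
    if psi.sum() > 100.0 + 1e-9:
        raise ValueError("mass fractions sum to more than 100% of the proteome")
    return psi


def individual_cost(gene: str, mass_table: Mapping[str, float] | pd.Series) -> float:
    """Proteome mass fraction (%) of the gene's own product.

    A gene absent from the table costs 0 (with a warning) — unmeasured
    proteins are treated as negligibly expressed.
    """
    if gene not in mass_table:
        warnings.warn(f"gene {gene!r} absent from mass-fraction table; cost = 0", stacklevel=2)
        return 0.0
    return float(mass_table[gene])


def affected_genes(knockout: str, model: OperonModel, polar: bool = True) -> set[str]:
    """Closure of genes whose expression a knockout abolishes.

    With ``polar=True`` (transposon insertion) the set contains the
    knocked-out gene, every downstream gene of its transcription unit, and
    — iterated to a fixed point — every gene of every unit whose promoter
    depends on a regulator already in the set. ``polar=False`` models an
    in-frame deletion that affects only the gene itself.
    """
    if not polar:
        return {knockout}
    closure = {knockout}
    frontier = [knockout]
    while frontier:
        gene = frontier.pop()
        for nxt in model._silenced_by(gene):
            if nxt not in closure:
                closure.add(nxt)
                frontier.append(nxt)
    return closure


def total_cost(
    knockout: str,
    model: OperonModel,
    mass_table: Mapping[str, float] | pd.Series,
    polar: bool = True,
) -> float:
    """Summed proteome mass fraction (%) over all affected genes."""
    psi = mass_table
    return float(sum(psi[g] for g in affected_genes(knockout, model, polar=polar) if g in psi))


def cost_report(
    knockouts,
    model: OperonModel,
    mass_table: Mapping[str, float] | pd.Series,
) -> pd.DataFrame:
    """Individual vs. total cost per knockout (columns gene, individual,
    total, n_affected)."""
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for gene in knockouts:
            affected = affected_genes(gene, model)
            rows.append((gene, individual_cost(gene, mass_table), total_cost(gene, model, mass_table), len(affected)))
    return pd.DataFrame(rows, columns=["gene", "individual", "total", "n_affected"])


def cost_rate_correlation(
    total_costs: Mapping[str, float] | pd.Series,
    growth_gains: Mapping[str, float] | pd.Series,
) -> tuple[float, int]:
    """Pearson correlation between total protein cost and growth-rate gain.

    ``growth_gains`` maps mutant/gene to ``mu - mu_pop``. Returns (r, n)
    over the genes present in both tables; r is NaN when either vector has
    zero variance. Requires at least 3 paired observations.
    """
    costs = pd.Series(dict(total_costs), dtype=float)
    gains = pd.Series(dict(growth_gains), dtype=float)
    common = costs.index.intersection(gains.index)
    n = len(common)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    x, y = costs[common].to_numpy(), gains[common].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), n
    return float(pearsonr(x, y).statistic), n


def read_operon_model(units_path, regulators_path=None) -> OperonModel:
    """Build an OperonModel from TSV tables.

    ``units_path``: columns (unit_id, promoter, position, gene), position
    ordering promoter-proximal first. ``regulators_path``: columns
    (regulator, promoter).
    """
    units_df = pd.read_csv(units_path, sep="\t")
    units: dict[str, TranscriptionUnit] = {}
    for uid, grp in units_df.groupby("unit_id", sort=False):
        grp = grp.sort_values("position")
        promoters = grp["promoter"].unique()
        if len(promoters) != 1:
            raise ValueError(f"unit {uid!r} lists several promoters: {promoters}")
        units[str(uid)] = TranscriptionUnit(str(uid), str(promoters[0]), tuple(grp["gene"]))
    regulators: dict[str, frozenset[str]] = {}
    if regulators_path is not None:
        reg_df = pd.read_csv(regulators_path, sep="\t")
        for gene, grp in reg_df.groupby("regulator"):
            regulators[str(gene)] = frozenset(grp["promoter"].astype(str))
    return OperonModel(units=units, regulators=regulators)


def load_hox_hyp_fixture() -> tuple[OperonModel, pd.Series]:
    """The packaged hox/hyp hydrogenase operon model and its synthetic
    mass-fraction table.

    Topology: MBH operon (hoxK..hoxV, promoter P_MBH), SH operon
    (hoxF..hoxI, promoter P_SH), accessory hyp operon (hypA1..hypX,
    promoter P_hyp) and the regulatory hoxABCJ unit. HoxA activates P_MBH
    and P_SH; the regulatory unit's own promoter is driven by the
    secondary P_hypA/P_hypB promoters inside the hyp operon, encoded here
    as dependency edges from hypA1/hypB1 (a hypothesis-level edge: primary
    hyp knockouts also silence hoxA). Mass fractions are synthetic
    placeholders with the observed rank structure (SH >> hyp > MBH).
    """
    data = resources.files("barfit.data")
    with resources.as_file(data / "hox_hyp_units.tsv") as units_p, \
            resources.as_file(data / "hox_hyp_regulators.tsv") as reg_p:
        model = read_operon_model(units_p, reg_p)
    with resources.as_file(data / "hox_hyp_mass_fractions_synthetic.tsv") as mass_p:
        psi = load_mass_table(mass_p)
    return model, psi
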