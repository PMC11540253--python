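"""Forward simulator: library placement, competition model, read synthesis."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barfit import (
    DEFAULT_FLANKS,
    SampleMeta,
    make_library,
    plant_gene_effects,
    simulate_competition,
    simulate_reads,
)
from barfit.simulate import MutantLibrary, expected_log2fc, revcomp

from conftest import two_point_samples


class TestMakeLibrary:
    def test_empty_library(self, small_genome):
        lib = make_library(small_genome, n_mutants=0, seed=0)
        assert len(lib) == 0

    def test_total_essentiality_forces_intergenic(self, small_genome):
        all_genes = set(small_genome.genes["locus_tag"])
        lib = make_library(small_genome, n_mutants=200, essential_genes=all_genes, seed=1)
        assert (lib.table["gene"] == "").all()

    def test_barcodes_unique_and_20nt(self, small_library):
        t = small_library.table
        assert t["barcode"].is_unique
        assert (t["barcode"].str.len() == 20).all()
        assert t["barcode"].str.fullmatch("[ACGT]{20}").all()

    def test_positions_on_declared_replicons(self, small_genome, small_library):
        small_library.validate_against(small_genome)

    def test_uniform_placement_is_binomial_per_gene(self, small_genome):
        """Per-gene insertion counts follow Binomial(n, len_i/allowed_len);
        chi-square goodness of fit against the closed-form expectation."""
        n = 50_000
        margin = 50
        lib = make_library(small_genome, n_mutants=n, seed=7, end_margin=margin)
        allowed_total = sum(len(s) - 2 * margin for s in small_genome.replicons.values())
        gene_len = (small_genome.genes["end"] - small_genome.genes["start"]).to_numpy()
        observed = (
            lib.table.groupby("gene").size().reindex(small_genome.genes["locus_tag"], fill_value=0).to_numpy()
        )
        n_intergenic = (lib.table["gene"] == "").sum()
        expected = n * gene_len / allowed_total
        obs = np.append(observed, n_intergenic)
        exp = np.append(expected, n - expected.sum())
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01

    def test_per_gene_placement_plants_fixed_barcode_count(self, small_genome):
        lib = make_library(
            small_genome, placement="per_gene", barcodes_per_gene=5, intergenic_fraction=0.1, seed=2
        )
        per_gene = lib.table[lib.table["gene"] != ""].groupby("gene").size()
        assert (per_gene == 5).all()
        assert len(per_gene) == small_genome.n_genes
        n_intergenic = (lib.table["gene"] == "").sum()
        assert n_intergenic == round(0.1 * 5 * small_genome.n_genes)

    def test_fitness_spec_applied_to_genic_insertions_only(self, small_genome):
        tag = small_genome.genes["locus_tag"].iloc[0]
        lib = make_library(
            small_genome, placement="per_gene", barcodes_per_gene=3,
            intergenic_fraction=0.2, fitness_spec={tag: 0.5}, seed=3,
        )
        t = lib.table
        assert (t.loc[t["gene"] == tag, "w"] == 0.5).all()
        assert (t.loc[t["gene"] != tag, "w"] == 1.0).all()

    def test_negative_n_mutants_raises(self, small_genome):
        with pytest.raises(ValueError):
            make_library(small_genome, n_mutants=-1)


class TestPlantGeneEffects:
    def test_fractions_and_conversion(self, small_genome):
        spec, effects = plant_gene_effects(small_genome, {-2.0: 0.2, 1.0: 0.1}, generation=8.0, seed=4)
        assert (effects == -2.0).sum() == 20
        assert (effects == 1.0).sum() == 10
        assert (effects == 0.0).sum() == 70
        tag = effects.index[effects == -2.0][0]
        assert spec[tag] == pytest.approx(1.0 - 2.0 / 8.0)

    def test_overcommitted_fractions_raise(self, small_genome):
        with pytest.raises(ValueError):
            plant_gene_effects(small_genome, {-2.0: 0.7, 1.0: 0.5})


class TestSimulateCompetition:
    def test_columns_sum_to_depth_exactly(self, small_library):
        samples = two_point_samples()
        cm = simulate_competition(small_library, samples, depth=12345, seed=5)
        assert (cm.counts.sum(axis=0) == 12345).all()

    def test_neutral_pool_frequencies_match_t0(self, small_library):
        """All-neutral pool: g=8 frequencies stay within 4 SE of the shared
        uniform starting frequency."""
        depth = 1_000_000
        samples = two_point_samples(replicates=(1,))
        cm = simulate_competition(small_library, samples, depth=depth, seed=6, p0_sigma=0.0)
        p0 = 1.0 / len(small_library)
        se = np.sqrt(p0 * (1 - p0) / depth)
        freq8 = cm.counts["fructose_g8_r1"] / depth
        assert (np.abs(freq8 - p0) < 4 * se).mean() > 0.99

    def test_rare_beneficial_mutant_log_linear(self, small_genome):
        """Mean log2 frequency change of a rare w=1.5 mutant over many
        multinomial draws matches the closed form g*(w-1) = 2."""
        n, g = 10_000, 4.0
        rng = np.random.default_rng(0)
        barcodes = ["".join("ACGT"[b] for b in rng.integers(0, 4, 20)) for _ in range(n)]
        table = pd.DataFrame(
            {
                "barcode": barcodes,
                "replicon": "r1",
                "position": 0,
                "strand": "+",
                "gene": "",
                "w": [1.5] + [1.0] * (n - 1),
            }
        )
        lib = MutantLibrary(table)
        n_draws = 300
        samples = [SampleMeta(f"s{i}", "c", "continuous", g, i) for i in range(n_draws)]
        cm = simulate_competition(lib, samples, depth=1_000_000, seed=7, p0_sigma=0.0)
        freq = (cm.counts + 0.5) / (cm.counts + 0.5).sum(axis=0)
        delta = np.log2(freq.iloc[0] / (1.0 / n))
        sem = delta.std(ddof=1) / np.sqrt(n_draws)
        assert abs(delta.mean() - expected_log2fc(1.5, g)) < 3 * sem + 0.05

    def test_pulsed_regime_bottleneck_preserves_depth_and_mean(self, small_library):
        depth = 200_000
        samples = two_point_samples(regime="pulsed", replicates=(1,))
        cm = simulate_competition(
            small_library, samples, depth=depth, seed=8, p0_sigma=0.0, pulse_n_eff=100_000
        )
        assert (cm.counts.sum(axis=0) == depth).all()
        # neutral drift is unbiased: pool mean frequency unchanged
        f8 = cm.counts["fructose_g8_r1"] / depth
        assert f8.mean() == pytest.approx(1.0 / len(small_library))
        # drift adds dispersion relative to the continuous regime
        cm_cont = simulate_competition(
            small_library, two_point_samples(replicates=(1,)), depth=depth, seed=8, p0_sigma=0.0
        )
        assert f8.var() > (cm_cont.counts["fructose_g8_r1"] / depth).var()

    def test_invalid_depth_and_empty_inputs(self, small_library):
        with pytest.raises(ValueError):
            simulate_competition(small_library, two_point_samples(), depth=0)
        with pytest.raises(ValueError):
            simulate_competition(small_library, [], depth=100)


class TestSimulateReads:
    def test_error_free_barseq_reads_contain_barcode_verbatim(self, small_genome, small_library):
        samples = [SampleMeta("s0", "c", "continuous", 0.0, 1)]
        cm = simulate_competition(small_library, samples, depth=2000, seed=9)
        streams = simulate_reads(small_library, cm, mode="barseq", seed=10)
        L, R = DEFAULT_FLANKS.left, DEFAULT_FLANKS.right
        n = 0
        for _, seq, qual in streams["s0"]:
            assert seq.startswith(L) and seq.endswith(R)
            assert len(seq) == len(L) + 20 + len(R)
            assert len(qual) == len(seq)
            n += 1
        assert n == 2000

    def test_tnseq_tail_equals_reference_substring(self, small_genome, small_library):
        cm = simulate_competition(
            small_library, [SampleMeta("s0", "c", "continuous", 0.0, 1)], depth=3000, seed=11
        )
        streams = simulate_reads(
            small_library, cm, mode="tnseq", genome=small_genome, genomic_tail_len=30, seed=12,
            seq_only=True,
        )
        prefix_len = len(DEFAULT_FLANKS.left) + 20 + len(DEFAULT_FLANKS.right)
        loci = small_library.table.set_index("barcode")
        for seq in streams["s0"]:
            bc = seq[len(DEFAULT_FLANKS.left) : len(DEFAULT_FLANKS.left) + 20]
            rep, pos, strand = loci.loc[bc, ["replicon", "position", "strand"]]
            tail = seq[prefix_len:]
            ref = small_genome.replicons[rep]
            if strand == "+":
                assert tail == ref[pos : pos + 30]
            else:
                assert tail == revcomp(ref[pos - 29 : pos + 1])

    def test_substitution_error_rate_binomial(self):
        """Mean substitutions per 75-bp read at 1% error within 3 SE."""
        table = pd.DataFrame(
            {"barcode": ["A" * 20], "replicon": "r1", "position": 0, "strand": "+", "gene": "", "w": 1.0}
        )
        lib = MutantLibrary(table)
        n_reads = 10_000
        cm_counts = pd.DataFrame({"s0": [n_reads]}, index=pd.Index(["A" * 20], name="barcode"))
        from barfit.containers import BarcodeCountMatrix

        samples = pd.DataFrame(
            {"condition": ["c"], "regime": ["batch"], "generation": [0.0], "replicate": [1]},
            index=pd.Index(["s0"], name="sample_id"),
        )
        cm = BarcodeCountMatrix(counts=cm_counts, samples=samples)
        clean = next(iter(simulate_reads(lib, cm, read_length=75, seed=13, seq_only=True)["s0"]))
        noisy = simulate_reads(lib, cm, read_length=75, error_rate=0.01, seed=13, seq_only=True)
        subs = [sum(a != b for a, b in zip(seq, clean)) for seq in noisy["s0"]]
        expect = 75 * 0.01
        se = np.sqrt(75 * 0.01 * 0.99 / n_reads)
        assert abs(np.mean(subs) - expect) < 3 * se

    def test_truncated_tail_flagged_in_read_name(self, small_genome):
        rep = next(iter(small_genome.replicons))
        L = len(small_genome.replicons[rep])
        table = pd.DataFrame(
            {
                "barcode": ["C" * 20],
                "replicon": rep,
                "position": L - 5,
                "strand": "+",
                "gene": "",
                "w": 1.0,
            }
        )
        lib = MutantLibrary(table)
        from barfit.containers import BarcodeCountMatrix

        cm = BarcodeCountMatrix(
            counts=pd.DataFrame({"s0": [3]}, index=pd.Index(["C" * 20], name="barcode")),
            samples=pd.DataFrame(
                {"condition": ["c"], "regime": ["batch"], "generation": [0.0], "replicate": [1]},
                index=pd.Index(["s0"], name="sample_id"),
            ),
        )
        reads = list(simulate_reads(lib, cm, mode="tnseq", genome=small_genome, genomic_tail_len=30, seed=1)["s0"])
        assert all(rid.endswith(":truncated") for rid, _, _ in reads)
        assert all(len(seq) < len(DEFAULT_FLANKS.left) + 20 + len(DEFAULT_FLANKS.right) + 30 for _, seq, _ in reads)

    def test_read_count_per_barcode_equals_matrix_entry(self, small_library):
        cm = simulate_competition(
            small_library, [SampleMeta("s0", "c", "continuous", 0.0, 1)], depth=5000, seed=14
        )
        streams = simulate_reads(small_library, cm, seq_only=True, seed=15)
        from collections import Counter

        tally = Counter(
            seq[len(DEFAULT_FLANKS.left) : len(DEFAULT_FLANKS.left) + 20] for seq in streams["s0"]
        )
        for bc, count in cm.counts["s0"].items():
            assert tally.get(bc, 0) == count

    def test_unknown_barcodes_in_counts_raise(self, small_library):
        from barfit.containers import BarcodeCountMatrix

        cm = BarcodeCountMatrix(
            counts=pd.DataFrame({"s0": [1]}, index=pd.Index(["G" * 20], name="barcode")),
            samples=pd.DataFrame(
                {"condition": ["c"], "regime": ["batch"], "generation": [0.0], "replicate": [1]},
                index=pd.Index(["s0"], name="sample_id"),
            ),
        )
        with pytest.raises(ValueError, match="absent from the library"):
            next(iter(simulate_reads(small_library, cm, seed=0)["s0"]))
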