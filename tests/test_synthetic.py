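"""Synthetic study generator: construction invariants, reproducibility,
and the NB sampling contract."""

import numpy as np
import pandas as pd
import pytest

from srnakit.io import read_fastq
from srnakit.synthetic import (
    GenomeDesign,
    LibraryDesign,
    build_truth,
    make_gene_tables,
    make_genome_and_annotation,
    make_interaction_databases,
    mature_sequence,
    simulate_count_matrix,
    simulate_libraries,
)


class TestGenomeAndAnnotation:
    def test_default_feature_count_and_bounds(self):
        genome, ann = make_genome_and_annotation(seed=1)
        assert len(ann) == 95
        L = len(genome["chr1"])
        assert all(0 <= f.start < f.end <= L for f in ann)

    def test_features_non_overlapping(self):
        _, ann = make_genome_and_annotation(seed=1)
        ivals = sorted((f.start, f.end) for f in ann)
        assert all(a[1] <= b[0] for a, b in zip(ivals, ivals[1:]))

    def test_multicopy_loci_share_mature_sequence(self):
        genome, ann = make_genome_and_annotation(seed=1)
        multi = [f for f in ann if f.feature_id == "mir-1"]
        assert len(multi) == 3
        seqs = {mature_sequence(genome, f) for f in multi}
        assert len(seqs) == 1

    def test_minus_strand_reads_are_revcomp_of_genome(self):
        genome, ann = make_genome_and_annotation(seed=1)
        minus = next(f for f in ann if f.strand == "-" and f.feature_class == "miRNA")
        gslice = genome[minus.chrom][minus.start:minus.end]
        mat = mature_sequence(genome, minus)
        comp = str.maketrans("ACGT", "TGCA")
        assert mat == gslice.translate(comp)[::-1]

    def test_mirna_lengths_in_range(self):
        _, ann = make_genome_and_annotation(seed=1)
        lens = {f.length for f in ann if f.feature_class == "miRNA"}
        assert lens <= {20, 21, 22, 23}

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            make_genome_and_annotation(GenomeDesign(genome_length=500), seed=1)


class TestTruthAndCounts:
    def test_spiked_subset_and_magnitude(self, small_genome, small_design):
        _, ann = small_genome
        truth = build_truth(ann, small_design, n_spiked=4, seed=3)
        classes = {f.feature_id: f.feature_class for f in ann}
        for f, fc in truth.spiked_log2fc.items():
            assert classes[f] in ("miRNA", "snoRNA")
            assert abs(fc) >= 1
        assert (truth.feature_expression.loc[list(truth.spiked_log2fc)]["control"] >= 100).all()

    def test_zero_mean_feature_yields_no_reads(self, small_genome, small_design, tmp_path):
        genome, ann = small_genome
        truth = build_truth(ann, small_design, n_spiked=2, seed=3)
        victim = truth.features[0]
        truth.feature_expression.loc[victim] = 0.0
        sim = simulate_libraries(genome, ann, truth, small_design, 5, tmp_path)
        assert (sim.true_counts.loc[victim] == 0).all()

    def test_same_seed_byte_identical(self, small_genome, small_design, tmp_path):
        genome, ann = small_genome
        truth = build_truth(ann, small_design, n_spiked=2, seed=3)
        design = LibraryDesign(n_pairs=2, reads_per_library=1500)
        sim1 = simulate_libraries(genome, ann, truth, design, 5, tmp_path / "a")
        sim2 = simulate_libraries(genome, ann, truth, design, 5, tmp_path / "b")
        for lib in design.libraries:
            assert sim1.fastq_paths[lib].read_bytes() == sim2.fastq_paths[lib].read_bytes()

    def test_library_totals_exact(self, small_genome, small_design, tmp_path):
        genome, ann = small_genome
        truth = build_truth(ann, small_design, n_spiked=2, seed=3)
        sim = simulate_libraries(genome, ann, truth, small_design, 5, tmp_path)
        for lib, path in sim.fastq_paths.items():
            n = sum(1 for _ in read_fastq(path))
            assert n == sim.library_totals[lib]

    def test_spiked_ratio_within_nb_sampling_band(self):
        # log2fc = +2 at high depth: cancer/control mean ratio near 4.
        # Band [3.0, 5.3] computed from the NB sampling oracle: with
        # mu>=100, alpha=0.1, 60 libraries per group the ratio of group
        # means stays within ~30% of 4 with overwhelming probability.
        genome, ann = make_genome_and_annotation(
            GenomeDesign(genome_length=30_000, n_mirna=12, n_snorna=3, n_trf=2,
                         n_exon=4, n_multicopy=1), seed=11)
        design = LibraryDesign(n_pairs=60, reads_per_library=4000)
        truth = build_truth(ann, design, n_spiked=4, seed=11)
        counts, s = simulate_count_matrix(truth, design, seed=11)
        norm = counts.div(s, axis=1)
        up = [f for f, fc in truth.spiked_log2fc.items() if fc > 0]
        ctrl = [l for l in design.libraries if l.startswith("N")]
        canc = [l for l in design.libraries if l.startswith("C")]
        for f in up:
            ratio = norm.loc[f, canc].mean() / norm.loc[f, ctrl].mean()
            assert 3.0 <= ratio <= 5.3

    def test_singletons_present(self, small_genome, small_design, tmp_path):
        genome, ann = small_genome
        truth = build_truth(ann, small_design, n_spiked=2, seed=3)
        sim = simulate_libraries(genome, ann, truth, small_design, 5, tmp_path)
        from srnakit.collapse import collapse
        from srnakit.preprocess import preprocess_reads
        from srnakit.config import RunConfig
        cfg = RunConfig()
        processed = {
            lib: preprocess_reads(read_fastq(p), cfg)[0]
            for lib, p in sim.fastq_paths.items()
        }
        _, singles = collapse(processed)
        assert singles >= 10 * small_design.n_pairs * 2  # >=10 per library

    def test_truth_serialisation_round_trip(self, small_truth, tmp_path):
        small_truth.to_files(tmp_path)
        expr = pd.read_csv(tmp_path / "truth_expression.tsv", sep="\t", index_col=0)
        assert np.allclose(expr["control"], small_truth.feature_expression["control"])
        assert (tmp_path / "truth.yaml").exists()


class TestInteractionDatabases:
    def test_true_pairs_have_min_support(self, small_truth):
        inter, info = make_interaction_databases(small_truth, seed=4)
        support = inter.groupby(["mirna", "gene"])["database"].nunique()
        for m, genes in small_truth.true_targets.items():
            for g in genes:
                assert support[(m, g)] >= 3

    def test_no_duplicate_triples(self, small_truth):
        inter, _ = make_interaction_databases(small_truth, seed=4)
        assert not inter.duplicated(["mirna", "gene", "database"]).any()

    def test_decoy_classes_planted(self, small_truth):
        _, info = make_interaction_databases(small_truth, seed=4)
        kinds = set(info["kind"])
        assert {"true", "decoy_low_support", "decoy_same_direction"} <= kinds
        low = info[info["kind"] == "decoy_low_support"]
        assert (low["support"] <= 2).all()

    def test_too_few_databases_warns(self, small_truth):
        with pytest.warns(UserWarning, match="empty"):
            make_interaction_databases(small_truth, n_databases=2, seed=4)


class TestGeneTables:
    def test_targets_placed_in_opposite_list(self, small_truth):
        tables = make_gene_tables(small_truth, seed=4)
        for m, genes in small_truth.true_targets.items():
            target_list = (
                tables.up_genes if small_truth.spiked_log2fc[m] < 0 else tables.down_genes
            )
            assert genes <= set(target_list)

    def test_lists_disjoint_and_unique(self, small_truth):
        tables = make_gene_tables(small_truth, seed=4)
        assert not set(tables.up_genes) & set(tables.down_genes)
        assert len(set(tables.up_genes)) == len(tables.up_genes)

    def test_planted_term_enriched(self, small_truth):
        from srnakit.network import go_enrichment

        tables = make_gene_tables(small_truth, seed=4)
        res = go_enrichment(tables.up_genes, tables.go_map, go_fdr=0.05)
        row = res.set_index("term").loc[tables.enriched_term]
        assert row["pvalue"] < 1e-6 and bool(row["enriched"])

    def test_empty_truth_empty_tables(self):
        from srnakit.synthetic import SyntheticTruth

        empty = SyntheticTruth(
            pd.DataFrame(columns=["control", "cancer"]), {}, pd.Series(dtype=float)
        )
        tables = make_gene_tables(empty, seed=1, n_up=0, n_down=0)
        assert tables.up_genes == [] and tables.down_genes == []
        assert list(tables.go_map.columns) == ["gene", "term"]
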