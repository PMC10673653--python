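import numpy as np
import pandas as pd
import pytest

from vaccpav import (
    SimulationParams,
    classify,
    emit_anchors,
    emit_annotations,
    emit_expression,
    emit_orthogroups,
    emit_terms,
    filter_ortholog_calls,
    generate_truth,
)
from vaccpav.classify import anchor_distance
from vaccpav.simulate import MIN_MISMERGE_DISTANCE, write_outputs


class TestGenerateTruth:
    def test_core_fraction_one_means_every_group_full(self):
        p = SimulationParams(n_accessions=4, n_orthogroups=50, core_fraction=1.0, seed=3)
        truth = generate_truth(p)
        assert (truth.groups["occupancy"] == 4).all()
        assert (truth.groups["label"] == "core").all()

    def test_same_seed_reproduces_identical_truth(self, small_params):
        t1 = generate_truth(small_params)
        t2 = generate_truth(small_params)
        pd.testing.assert_frame_equal(t1.genes, t2.genes)
        pd.testing.assert_frame_equal(t1.groups, t2.groups)
        assert t1.og_terms == t2.og_terms

    def test_same_seed_emits_byte_identical_files(self, small_params, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        write_outputs(generate_truth(small_params), d1)
        write_outputs(generate_truth(small_params), d2)
        files1 = sorted(f.name for f in d1.iterdir())
        assert files1 == sorted(f.name for f in d2.iterdir())
        for name in files1:
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_aux_occupancy_stays_below_n(self, small_truth):
        aux = small_truth.groups[small_truth.groups["label"] == "auxiliary"]
        assert aux["occupancy"].between(1, 4).all()

    def test_beta_occupancy_model_supported(self):
        p = SimulationParams(
            n_accessions=6, n_orthogroups=300, core_fraction=0.0,
            occupancy_model=("beta", 0.5, 0.5), seed=4,
        )
        occ = generate_truth(p).groups["occupancy"]
        assert occ.between(1, 5).all()
        # U-shape: extremes more common than the middle
        vc = occ.value_counts()
        assert vc.get(1, 0) + vc.get(5, 0) > 2 * vc.get(3, 0)

    def test_capacity_error_suggests_larger_chromosomes(self):
        p = SimulationParams(
            n_accessions=2, n_orthogroups=1000, chrom_count=1, chrom_length=100_000, seed=0
        )
        with pytest.raises(ValueError, match="chrom_length"):
            generate_truth(p)

    def test_noiseless_classifier_recovers_core_fraction(self):
        p = SimulationParams(n_accessions=11, n_orthogroups=2000, core_fraction=0.53, seed=7)
        truth = generate_truth(p)
        table = emit_orthogroups(truth).table
        anchors = emit_anchors(truth)
        labels = classify(table, filter_ortholog_calls(table, truth.genes, anchors))
        assert labels.core_fraction == pytest.approx(0.53, abs=1e-12)


class TestEmitAnnotations:
    def test_gene_present_exactly_where_truth_says(self, small_truth):
        anns = emit_annotations(small_truth)
        emitted = {
            (acc, g.gene_id) for acc, ann in anns.items() for g in ann.genes
        }
        expected = set(zip(small_truth.genes["accession"], small_truth.genes["gene_id"]))
        assert emitted == expected

    def test_no_overlapping_genes_within_accession(self, small_truth):
        for ann in emit_annotations(small_truth).values():
            df = ann.to_frame().sort_values(["seq_id", "start"])
            for _, chrom in df.groupby("seq_id"):
                starts = chrom["start"].to_numpy()
                ends = chrom["end"].to_numpy()
                assert (starts[1:] > ends[:-1]).all()

    def test_zero_jitter_gives_identical_coordinates_across_accessions(self, small_truth):
        spans = small_truth.genes.groupby("orthogroup")[["start", "end"]].nunique()
        assert (spans == 1).all().all()

    def test_class_feature_means_recovered(self):
        p = SimulationParams(n_accessions=2, n_orthogroups=10_000, core_fraction=0.5, seed=5)
        truth = generate_truth(p)
        for cls, fp in (("core", p.core_features), ("auxiliary", p.aux_features)):
            lengths = truth.groups.loc[truth.groups["label"] == cls, "gene_length"]
            mean, n = fp.mean_gene_length, len(lengths)
            sd = mean * np.sqrt(np.exp(fp.gene_length_sigma**2) - 1)
            assert abs(lengths.mean() - mean) < 3 * sd / np.sqrt(n)


class TestEmitOrthogroups:
    def test_zero_error_equals_truth_partition(self, small_truth):
        table = emit_orthogroups(small_truth, og_error_rate=0.0).table
        assert set(table.gene_uids()) == set(small_truth.genes["uid"])
        assert table.occupancy().sort_index().tolist() == (
            small_truth.groups["occupancy"].sort_index().tolist()
        )

    def test_mismerge_count_is_binomial(self):
        p = SimulationParams(n_accessions=6, n_orthogroups=4000, core_fraction=0.5, seed=9)
        truth = generate_truth(p)
        occ = truth.groups["occupancy"]
        n_singletons = int((occ == 1).sum())
        eps = 0.1
        injected = emit_orthogroups(truth, og_error_rate=eps).injected
        se = np.sqrt(n_singletons * eps * (1 - eps))
        assert abs(len(injected) - eps * n_singletons) < 3 * se

    def test_mismerged_member_is_non_syntenic(self):
        p = SimulationParams(n_accessions=6, n_orthogroups=2000, core_fraction=0.5, seed=9)
        truth = generate_truth(p)
        injected = emit_orthogroups(truth, og_error_rate=0.2).injected
        assert len(injected) > 0
        for row in injected.itertuples():
            src = truth.groups.loc[row.source_og]
            dst = truth.groups.loc[row.target_og]
            assert (
                src["chrom"] != dst["chrom"]
                or abs(int(src["slot_start"]) - int(dst["slot_start"]))
                >= MIN_MISMERGE_DISTANCE
            )


class TestEmitAnchors:
    def test_zero_dropout_covers_every_syntenic_pair(self, small_truth, small_params):
        anchors = emit_anchors(small_truth, dropout=0.0, jitter_sd=0.0)
        anns = emit_annotations(small_truth)
        # spot-check a handful of multi-accession orthogroups
        multi = small_truth.genes.groupby("orthogroup").filter(
            lambda g: g["accession"].nunique() >= 2
        )
        by_gene = {
            (acc, g.gene_id): g
            for acc, ann in anns.items()
            for g in ann.genes
        }
        some = multi.groupby("orthogroup").head(2).groupby("orthogroup")
        checked = 0
        for og, sub in list(some)[:10]:
            rows = list(sub.itertuples())
            if len(rows) < 2:
                continue
            a, b = rows[0], rows[1]
            d = anchor_distance(
                by_gene[(a.accession, a.gene_id)], a.accession,
                by_gene[(b.accession, b.gene_id)], b.accession, anchors,
            )
            assert d == 0
            checked += 1
        assert checked > 0

    def test_full_dropout_empties_the_set(self, small_truth):
        assert len(emit_anchors(small_truth, dropout=1.0)) == 0

    def test_dropout_rate_is_binomial(self):
        p = SimulationParams(n_accessions=5, n_orthogroups=2000, core_fraction=0.8, seed=13)
        truth = generate_truth(p)
        n_pairs = len(emit_anchors(truth, dropout=0.0)) // 2  # undirected count
        kept = len(emit_anchors(truth, dropout=0.05)) // 2
        se = np.sqrt(n_pairs * 0.05 * 0.95)
        assert abs(kept - 0.95 * n_pairs) < 3 * se


class TestExpressionAndTerms:
    def test_tpm_nonnegative_and_complete(self, small_truth):
        expr = emit_expression(small_truth)
        assert (expr.tpm >= 0).all()
        assert set(expr.tpm.index) == set(small_truth.genes["uid"])

    def test_terms_shared_within_orthogroup(self, small_truth):
        tm = emit_terms(small_truth)
        genes = small_truth.genes
        for og, sub in list(genes.groupby("orthogroup"))[:20]:
            term_sets = {frozenset(tm.terms_for(uid)) for uid in sub["uid"]}
            assert len(term_sets) == 1

    def test_planted_term_more_frequent_in_auxiliary(self, small_truth):
        planted = small_truth.params.enrich_params[0]
        groups = small_truth.groups
        has = np.array(
            [planted.term_id in small_truth.og_terms[og] for og in groups.index]
        )
        aux_rate = has[groups["label"] == "auxiliary"].mean()
        core_rate = has[groups["label"] == "core"].mean()
        assert aux_rate > core_rate
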