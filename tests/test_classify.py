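import numpy as np
import pandas as pd
import pytest

from vaccpav import (
    AnchorSet,
    GenomeAnnotation,
    OrthogroupTable,
    SimulationParams,
    classify,
    emit_anchors,
    emit_orthogroups,
    filter_ortholog_calls,
    generate_truth,
    project_to_reference,
    summarize,
)
from vaccpav.classify import anchor_distance

from conftest import make_gene

ANCHOR_COLS = ["acc_a", "seq_a", "start_a", "end_a", "acc_b", "seq_b", "start_b", "end_b"]


def anchors_of(rows, accessions):
    return AnchorSet.from_records(
        pd.DataFrame(rows, columns=ANCHOR_COLS), accessions
    )


class TestAnchorDistance:
    def setup_method(self):
        self.ga = make_gene("g1", 10_000, 12_000)
        self.gb = make_gene("h1", 20_000, 22_000)

    def test_overlapping_both_sides_gives_zero(self):
        a = anchors_of([("A", "chr1", 11_000, 11_500, "B", "chr1", 20_500, 21_000)], ["A", "B"])
        assert anchor_distance(self.ga, "A", self.gb, "B", a) == 0

    def test_gap_on_one_side_is_the_distance(self):
        # anchor ends 6000 bp before gene_a starts, overlaps gene_b
        a = anchors_of([("A", "chr1", 3_000, 4_000, "B", "chr1", 20_500, 21_000)], ["A", "B"])
        assert anchor_distance(self.ga, "A", self.gb, "B", a) == 6_000

    def test_minimum_over_anchors(self):
        a = anchors_of(
            [
                ("A", "chr1", 1_000, 3_000, "B", "chr1", 20_500, 21_000),   # 7000
                ("A", "chr1", 5_000, 6_800, "B", "chr1", 20_500, 21_000),   # 3200
            ],
            ["A", "B"],
        )
        assert anchor_distance(self.ga, "A", self.gb, "B", a) == 3_200

    def test_no_qualifying_anchor_is_infinite(self):
        a = anchors_of([("A", "chr9", 1, 10, "B", "chr1", 20_500, 21_000)], ["A", "B"])
        assert anchor_distance(self.ga, "A", self.gb, "B", a) == np.inf

    def test_undeclared_accession_rejected(self):
        a = anchors_of([("A", "chr1", 1, 10, "B", "chr1", 1, 10)], ["A", "B"])
        with pytest.raises(ValueError, match="not declared"):
            anchor_distance(self.ga, "A", self.gb, "Z", a)


def two_acc_fixture(anchor_rows):
    """Two accessions, one shared orthogroup (g1~h1) plus one singleton."""
    annotations = {
        "A": GenomeAnnotation("A", [make_gene("g1", 10_000, 12_000)]),
        "B": GenomeAnnotation("B", [make_gene("h1", 20_000, 22_000),
                                    make_gene("h9", 90_000, 91_000)]),
    }
    table = OrthogroupTable(
        accessions=["A", "B"],
        groups={"OG1": {"A": ["g1"], "B": ["h1"]}, "OG2": {"B": ["h9"]}},
    )
    anchors = anchors_of(anchor_rows, ["A", "B"]) if anchor_rows else None
    return table, annotations, anchors


class TestFilterAndClassify:
    def test_boundary_window_is_inclusive(self):
        # anchor exactly 5000 bp from g1, overlapping h1
        rows = [("A", "chr1", 4_000, 5_000, "B", "chr1", 20_500, 21_000)]
        table, anns, anchors = two_acc_fixture(rows)
        filt = filter_ortholog_calls(table, anns, anchors, W=5_000)
        assert filt.n_retained == 1
        assert filt.calls["min_anchor_distance"].iloc[0] == 5_000
        # one bp further and the call drops
        filt2 = filter_ortholog_calls(table, anns, anchors, W=4_999)
        assert filt2.n_retained == 0

    def test_supported_everywhere_is_core(self):
        rows = [("A", "chr1", 11_000, 11_500, "B", "chr1", 20_500, 21_000)]
        table, anns, anchors = two_acc_fixture(rows)
        labels = classify(table, filter_ortholog_calls(table, anns, anchors))
        assert labels.og_labels["OG1"] == "core"
        assert labels.og_labels["OG2"] == "auxiliary"  # singleton never core
        assert labels.gene_labels["A|g1"] == "core"

    def test_missing_accession_means_auxiliary(self):
        table = OrthogroupTable(
            accessions=["A", "B", "C"],
            groups={"OG1": {"A": ["g1"], "B": ["h1"]}},
        )
        anns = {
            "A": GenomeAnnotation("A", [make_gene("g1", 10_000, 12_000)]),
            "B": GenomeAnnotation("B", [make_gene("h1", 20_000, 22_000)]),
            "C": GenomeAnnotation("C", []),
        }
        anchors = anchors_of(
            [("A", "chr1", 11_000, 11_500, "B", "chr1", 20_500, 21_000)], ["A", "B", "C"]
        )
        labels = classify(table, filter_ortholog_calls(table, anns, anchors))
        assert labels.og_labels["OG1"] == "auxiliary"

    def test_filter_removal_demotes_group_and_gene(self):
        # no anchor near g1: the only cross-accession call drops
        table, anns, anchors = two_acc_fixture(
            [("A", "chr1", 100_000, 101_000, "B", "chr1", 20_500, 21_000)]
        )
        labels = classify(table, filter_ortholog_calls(table, anns, anchors))
        assert labels.og_labels["OG1"] == "auxiliary"
        assert set(labels.demoted) == {"A|g1", "B|h1"}
        # demoted genes re-enter the occupancy structure as singletons
        assert labels.occupancy.sum() == 3

    def test_unresolvable_gene_id_is_an_error(self):
        table, anns, anchors = two_acc_fixture([])
        table.groups["OG1"]["A"].append("ghost")
        table.singleton.clear()
        with pytest.raises(ValueError, match="ghost"):
            filter_ortholog_calls(table, anns, anchors, W=5_000)

    def test_infinite_window_reduces_to_occupancy_classification(self):
        table, anns, _ = two_acc_fixture([])
        labels = classify(table, filter_ortholog_calls(table, anns, None, W=np.inf))
        assert labels.og_labels["OG1"] == "core"
        assert len(labels.demoted) == 0

    def test_negative_window_makes_everything_auxiliary(self):
        rows = [("A", "chr1", 11_000, 11_500, "B", "chr1", 20_500, 21_000)]
        table, anns, anchors = two_acc_fixture(rows)
        labels = classify(table, filter_ortholog_calls(table, anns, anchors, W=-1))
        assert (labels.og_labels == "auxiliary").all()

    def test_monotone_in_window_on_noisy_synthetic_data(self):
        p = SimulationParams(
            n_accessions=6, n_orthogroups=500, core_fraction=0.5,
            anchor_jitter_sd=300.0, og_error_rate=0.1, seed=21,
        )
        truth = generate_truth(p)
        table = emit_orthogroups(truth).table
        anchors = emit_anchors(truth)
        retained, cores = [], []
        for W in [0, 1_000, 5_000, 50_000, np.inf]:
            filt = filter_ortholog_calls(table, truth.genes, anchors, W=W)
            retained.append(filt.n_retained)
            cores.append(classify(table, filt).n_core_groups)
        assert retained == sorted(retained)
        assert cores == sorted(cores)

    def test_label_partition_covers_every_gene(self, small_truth):
        table = emit_orthogroups(small_truth).table
        anchors = emit_anchors(small_truth)
        labels = classify(table, filter_ortholog_calls(table, small_truth.genes, anchors))
        assert set(labels.gene_labels.index) == set(small_truth.genes["uid"])
        n = len(labels.gene_labels)
        assert (labels.gene_labels == "core").sum() + (
            labels.gene_labels == "auxiliary"
        ).sum() == n


class TestProjectToReference:
    def _setup(self, anchor_rows, accessions=("R", "X")):
        ref = GenomeAnnotation(
            "R",
            [make_gene("r1", 1_000, 2_000), make_gene("r2", 10_000, 11_000)],
        )
        anchors = anchors_of(anchor_rows, list(accessions))
        return ref, anchors

    def test_fully_covered_gene_is_core(self):
        ref, anchors = self._setup(
            [("R", "chr1", 500, 2_500, "X", "chr1", 600, 2_600),
             ("R", "chr1", 9_000, 12_000, "X", "chr1", 9_100, 12_100)]
        )
        m = project_to_reference(ref, anchors, ["R", "X"])
        assert list(m.core_genes()) == ["R|r1", "R|r2"]

    def test_zero_coverage_gene_is_auxiliary(self):
        ref, anchors = self._setup(
            [("R", "chr1", 500, 2_500, "X", "chr1", 600, 2_600)]
        )
        m = project_to_reference(ref, anchors, ["R", "X"])
        assert m.labels()["R|r2"] == "auxiliary"
        assert not m.matrix.loc["R|r2", "X"]

    def test_partial_coverage_below_threshold_is_absent(self):
        # covers 1000..1400 of r1 (401/1001 ≈ 40%)
        ref, anchors = self._setup(
            [("R", "chr1", 900, 1_400, "X", "chr1", 900, 1_400)]
        )
        m = project_to_reference(ref, anchors, ["R", "X"], coverage_threshold=0.5)
        assert not m.matrix.loc["R|r1", "X"]
        m2 = project_to_reference(ref, anchors, ["R", "X"], coverage_threshold=0.4)
        assert m2.matrix.loc["R|r1", "X"]

    def test_missing_accession_listed_in_error(self):
        ref, anchors = self._setup(
            [("R", "chr1", 500, 2_500, "X", "chr1", 600, 2_600)], accessions=("R", "X", "Y")
        )
        with pytest.raises(ValueError, match="Y"):
            project_to_reference(ref, anchors, ["R", "X", "Y"])


class TestSummarize:
    def _labels_from_counts(self, n_core, n_aux):
        from vaccpav.classify import PavLabels

        uids = [f"acc|g{i}" for i in range(n_core + n_aux)]
        lab = pd.Series(
            ["core"] * n_core + ["auxiliary"] * n_aux, index=uids, name="label"
        )
        ogs = pd.Series(
            ["core"] * n_core + ["auxiliary"] * n_aux,
            index=[f"OG{i}" for i in range(n_core + n_aux)],
            name="label",
        )
        occ = pd.Series(1, index=ogs.index)
        return PavLabels(
            og_labels=ogs, gene_labels=lab, occupancy=occ,
            demoted=pd.Index([]), n_accessions=2, window=5000.0,
        )

    def test_cranberry_style_integer_percentages(self):
        labels = self._labels_from_counts(14_553, 12_910)
        row = summarize(labels, precision=0)
        acc_row = row[row["accession"] == "acc"].iloc[0]
        assert acc_row["pct_core"] == 53
        assert acc_row["pct_auxiliary"] == 47
        assert acc_row["n_total"] == 27_463

    def test_two_decimal_percentages(self):
        labels = self._labels_from_counts(70_073, 104_552 - 70_073)
        row = summarize(labels, precision=2)
        assert row[row["accession"] == "acc"].iloc[0]["pct_core"] == 67.02

    def test_all_core_is_one_hundred_percent(self):
        labels = self._labels_from_counts(10, 0)
        row = summarize(labels, precision=0)
        assert row[row["accession"] == "acc"].iloc[0]["pct_core"] == 100

    def test_partition_per_accession(self, small_truth):
        table = emit_orthogroups(small_truth).table
        anchors = emit_anchors(small_truth)
        labels = classify(table, filter_ortholog_calls(table, small_truth.genes, anchors))
        summary = summarize(labels)
        genes = summary[summary["unit"] == "gene"]
        assert (genes["n_core"] + genes["n_auxiliary"] == genes["n_total"]).all()
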