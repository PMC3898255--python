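"""MORPH matrices, Ward clustering, summaries and rendering."""

import numpy as np
import pytest

from degmotif.core_io import EndCountTable, RegionLabel
from degmotif.morph import (
    Anchor,
    AnchorSet,
    MorphMatrix,
    anchors_from_features,
    anchors_from_motif,
    build_matrix,
    frame_to_genomic,
    linkage_to_newick,
    render_heatmap,
    summarize,
    ward_cluster,
)


class TestFrame:
    def test_anchor_base_is_plus_one(self):
        a = Anchor("c1", "+", 1000)
        assert frame_to_genomic(a, 1) == 1000
        assert frame_to_genomic(a, -1) == 999
        assert frame_to_genomic(a, 8) == 1007

    def test_minus_strand_mirrors(self):
        a = Anchor("c1", "-", 1000)
        assert frame_to_genomic(a, 1) == 1000
        assert frame_to_genomic(a, -1) == 1001
        assert frame_to_genomic(a, 8) == 993

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            frame_to_genomic(Anchor("c1", "+", 0), 0)


class TestAnchorsFromMotif:
    def test_planted_motif_found_in_region(self, bundle17):
        anchors = anchors_from_motif(
            bundle17.annotation, bundle17.genome, "TGTACATA", RegionLabel.THREE_UTR
        )
        truth = bundle17.truth
        planted = truth[truth["class"] == "motif_peak"]
        planted_anchors = {
            (r.chrom, r.strand, int(r.anchor_pos) - 1)
            for r in planted.itertuples(index=False)
        }
        found = {(a.chrom, a.strand, a.anchor_pos) for a in anchors.anchors}
        assert planted_anchors <= found

    def test_absent_motif_yields_empty_set(self, toy_annotation, toy_genome):
        anchors = anchors_from_motif(
            toy_annotation, toy_genome, "ACGTACGTACGT", RegionLabel.CDS
        )
        assert len(anchors) == 0

    def test_self_overlapping_run_keeps_both_anchors(self, toy_annotation, toy_genome):
        import copy

        genome = copy.deepcopy(toy_genome)
        seq = list(genome["c1"])
        seq[250:260] = list("CACACACACA")  # inside geneA CDS, + strand
        genome["c1"] = "".join(seq)
        anchors = anchors_from_motif(toy_annotation, genome, "CACACACA", RegionLabel.CDS)
        positions = {a.anchor_pos for a in anchors.anchors if a.strand == "+"}
        assert {250, 252} <= positions


class TestAnchorsFromFeatures:
    def test_five_prime_anchor_by_strand(self, bundle17):
        anchors = anchors_from_features(bundle17.annotation)
        by_pos = {(a.chrom, a.strand, a.anchor_pos) for a in anchors.anchors}
        for nc in bundle17.annotation.ncrnas:
            expected = nc.start if nc.strand == "+" else nc.end - 1
            assert (nc.chrom, nc.strand, expected) in by_pos

    def test_class_filter_cardinality(self, bundle17):
        cd = anchors_from_features(bundle17.annotation, "CD_box")
        assert len(cd) == 20


def _table_with(rows):
    t = EndCountTable()
    for chrom, strand, pos, c in rows:
        t.add(chrom, strand, pos, c)
    return t


def _anchorset(*positions, strand="+"):
    return AnchorSet([Anchor("c1", strand, p) for p in positions])


class TestBuildMatrix:
    def test_all_reads_at_minus_three(self):
        table = _table_with([("c1", "+", 997, 12)])  # frame -3 of anchor 1000
        m = build_matrix(_anchorset(1000), table)
        assert m.n_retained == 1
        assert m.values[0, m.column_index(-3)] == 1.0

    def test_filter_boundary_greater_than_five(self):
        t5 = _table_with([("c1", "+", 997, 5)])
        t6 = _table_with([("c1", "+", 997, 6)])
        assert build_matrix(_anchorset(1000), t5).n_retained == 0
        assert build_matrix(_anchorset(1000), t6).n_retained == 1

    def test_filter_off_keeps_low_rows_but_drops_empty(self):
        table = _table_with([("c1", "+", 997, 2)])
        m = build_matrix(_anchorset(1000, 5000), table, filter_on=False)
        assert m.n_retained == 1  # zero-read anchor still dropped

    def test_filter_monotone(self):
        rng = np.random.default_rng(2)
        rows = [("c1", "+", int(p), int(c)) for p, c in
                zip(rng.integers(0, 3000, 200), rng.integers(1, 5, 200))]
        table = _table_with(rows)
        anchors = _anchorset(*range(50, 2950, 100))
        with_filter = build_matrix(anchors, table, filter_on=True)
        without = build_matrix(anchors, table, filter_on=False)
        kept_on = {a.anchor_pos for a in with_filter.anchors}
        kept_off = {a.anchor_pos for a in without.anchors}
        assert kept_on <= kept_off

    def test_rows_sum_to_one(self, bundle17):
        anchors = anchors_from_motif(
            bundle17.annotation, bundle17.genome, "TGTACATA", RegionLabel.THREE_UTR
        )
        m = build_matrix(anchors, bundle17.table)
        assert np.allclose(m.values.sum(axis=1), 1.0, atol=1e-9)

    def test_pure_function_of_coordinates(self):
        rows = [("c1", "+", 995, 3), ("c1", "+", 1004, 4)]
        m1 = build_matrix(_anchorset(1000), _table_with(rows))
        m2 = build_matrix(_anchorset(1000), _table_with(list(reversed(rows))))
        assert np.array_equal(m1.values, m2.values)

    def test_truncated_window_at_chromosome_start(self):
        table = _table_with([("c1", "+", 2, 8)])
        m = build_matrix(_anchorset(3), table)
        assert m.n_retained == 1
        assert m.values[0, m.column_index(-1)] == 1.0

    def test_halfwidth_validated(self):
        with pytest.raises(ValueError):
            build_matrix(_anchorset(10), _table_with([("c1", "+", 9, 9)]), halfwidth=0)


from helpers_ward import merge_steps_from_linkage, naive_ward_steps


class TestWardCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        X = np.array([[1.0, 0, 0], [1.0, 0, 0], [0, 0, 1.0]])
        m = MorphMatrix([None] * 3, X, np.ones(3), halfwidth=1, n_total_anchors=3)
        # halfwidth 1 -> 2 columns; fake 3 columns is fine for clustering alone
        m = ward_cluster(m)
        assert m.linkage[0, 2] == pytest.approx(0.0)
        assert set(m.linkage[0, :2].astype(int)) == {0, 1}

    def test_two_separated_patterns_split_at_top(self):
        rng = np.random.default_rng(0)
        a = np.zeros((10, 20)); a[:, 7] = 1.0
        b = np.zeros((10, 20)); b[:, 17] = 1.0
        X = np.vstack([a, b]) + rng.normal(0, 0.01, (20, 20))
        m = MorphMatrix([None] * 20, X, np.ones(20), 10, 20)
        m = ward_cluster(m)
        # the last merge joins one cluster of rows 0-9 and one of rows 10-19
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(m.linkage, t=2, criterion="maxclust")
        assert len(set(labels[:10])) == 1 and len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_single_row_trivial_tree(self):
        m = MorphMatrix([None], np.ones((1, 20)), np.ones(1), 10, 1)
        m = ward_cluster(m)
        assert list(m.leaf_order) == [0]

    def test_merge_heights_non_decreasing(self):
        rng = np.random.default_rng(4)
        X = rng.random((25, 20))
        m = ward_cluster(MorphMatrix([None] * 25, X, np.ones(25), 10, 25))
        heights = m.linkage[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_matches_naive_agglomeration_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(3, 31))
            X = rng.random((n, 20))
            expected = naive_ward_steps(X)
            m = ward_cluster(MorphMatrix([None] * n, X, np.ones(n), 10, n))
            got = merge_steps_from_linkage(m.linkage, n)
            assert len(got) == len(expected)
            for (gs, gh), (es, eh) in zip(got, expected):
                assert gs == es
                assert gh == pytest.approx(eh, rel=1e-8)


class TestSummarize:
    def test_all_rows_modal_at_minus_three(self):
        X = np.zeros((5, 20)); X[:, 7] = 1.0  # column index 7 = offset -3
        m = MorphMatrix([None] * 5, X, np.full(5, 10.0), 10, 5)
        s = summarize(m)
        assert s.top_modal_offset == -3
        assert s.modal_fraction_at(-3) == 1.0

    def test_modal_fractions_sum_to_one(self):
        rng = np.random.default_rng(9)
        X = rng.random((40, 20))
        X /= X.sum(axis=1, keepdims=True)
        s = summarize(MorphMatrix([None] * 40, X, np.ones(40), 10, 40))
        assert s.modal_fraction.sum() == pytest.approx(1.0)

    def test_near_uniform_rows_spread_modal_mass(self):
        rng = np.random.default_rng(10)
        X = np.ones((400, 20)) + rng.normal(0, 1e-3, (400, 20))
        X /= X.sum(axis=1, keepdims=True)
        s = summarize(MorphMatrix([None] * 400, X, np.ones(400), 10, 400))
        assert s.modal_fraction.max() < 0.15  # ~1/20 each

    def test_tied_row_counts_once_at_most_upstream_column(self):
        X = np.zeros((1, 20))
        X[0, 3] = X[0, 12] = 0.5
        s = summarize(MorphMatrix([None], X, np.ones(1), 10, 1))
        assert s.modal_fraction.sum() == 1.0
        assert s.modal_fraction[3] == 1.0

    def test_empty_matrix_requires_allow_empty(self):
        m = MorphMatrix([], np.empty((0, 20)), np.array([]), 10, 4)
        with pytest.raises(ValueError):
            summarize(m)
        s = summarize(m, allow_empty=True)
        assert s.top_modal_fraction == 0.0


class TestRendering:
    def _matrix(self):
        X = np.zeros((3, 20)); X[:, 7] = 1.0
        m = MorphMatrix([Anchor("c1", "+", i) for i in range(3)], X,
                        np.full(3, 9.0), 10, 3)
        return ward_cluster(m)

    @pytest.mark.parametrize("ext", ["png", "svg"])
    def test_writes_image(self, tmp_path, ext):
        path = tmp_path / f"hm.{ext}"
        render_heatmap(self._matrix(), path, motif_width=8)
        assert path.stat().st_size > 0

    def test_empty_matrix_is_an_error(self, tmp_path):
        m = MorphMatrix([], np.empty((0, 20)), np.array([]), 10, 0)
        with pytest.raises(ValueError, match="no loci retained"):
            render_heatmap(m, tmp_path / "x.png")

    def test_newick_export(self):
        nwk = linkage_to_newick(self._matrix())
        assert nwk.endswith(";") and "L0" in nwk
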