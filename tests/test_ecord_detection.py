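import numpy as np
import pytest

from ecordkit.ecord_detection import (GeneCluster, assign_tads, call_clusters,
                                      curve_from_clusters, ecord_overlap,
                                      filter_ecords, shuffle_probability_curve,
                                      static_fraction)
from ecordkit.genome_model import (GeneClass, GeneRecord, TadInterval,
                                   ValidationError)
from ecordkit import synthetic_data as sd

from conftest import linear_genes, make_deg


class TestClusterWalk:
    def test_two_interruption_rules_manual_trace(self, one_tad):
        # UP,UP,STATIC,UP,UP,DOWN -> one UP cluster of 4, one DOWN of 1
        genes, degs = linear_genes(
            ["DEG_UP", "DEG_UP", "STATIC", "DEG_UP", "DEG_UP", "DEG_DOWN"])
        clusters = call_clusters(genes, degs, one_tad)
        assert [(c.direction, c.deg_count) for c in clusters] == \
            [("UP", 4), ("DOWN", 1)]
        assert clusters[0].member_deg_ids == ["g1", "g2", "g4", "g5"]

    def test_tad_boundary_splits_run(self):
        genes, degs = linear_genes(["DEG_UP"] * 4)
        boundary = (genes[1].end + genes[2].start) // 2
        tads = [TadInterval("chr1", 0, boundary, "t1"),
                TadInterval("chr1", boundary, 10**7, "t2")]
        clusters = call_clusters(genes, degs, tads)
        assert [c.deg_count for c in clusters] == [2, 2]
        assert [c.tad_id for c in clusters] == ["t1", "t2"]

    def test_opposite_breaker_splits_same_direction_skips(self, one_tad):
        genes, degs = linear_genes(
            ["DEG_UP", "DEG_UP", "BREAKER_DOWN", "DEG_UP",
             "BREAKER_UP", "DEG_UP"])
        clusters = call_clusters(genes, degs, one_tad)
        # the down breaker splits; the up breaker neither breaks nor extends
        assert [c.deg_count for c in clusters] == [2, 2]
        assert clusters[1].member_deg_ids == ["g4", "g6"]

    def test_unexpressed_genes_are_skipped(self, one_tad):
        genes, degs = linear_genes(
            ["DEG_UP", "UNEXPRESSED", None, "DEG_UP"])
        clusters = call_clusters(genes, degs, one_tad)
        assert [c.deg_count for c in clusters] == [2]

    def test_no_degs_gives_empty_list(self, one_tad):
        genes, degs = linear_genes(["STATIC", "STATIC"])
        assert call_clusters(genes, degs, one_tad) == []

    def test_unsorted_genes_rejected(self, one_tad):
        genes, degs = linear_genes(["DEG_UP", "DEG_UP"])
        with pytest.raises(ValidationError, match="sorted"):
            call_clusters(list(reversed(genes)), degs, one_tad)

    def test_deg_absent_from_annotation_is_error(self, one_tad):
        genes, degs = linear_genes(["DEG_UP"])
        degs["ghost"] = make_deg("ghost", "DEG_UP")
        with pytest.raises(ValidationError, match="ghost"):
            call_clusters(genes, degs, one_tad)

    def test_genes_outside_tads_form_singletons(self):
        # no TADs at all: consecutive DEGs cannot cluster
        genes, degs = linear_genes(["DEG_UP"] * 3)
        clusters = call_clusters(genes, degs, tads=[])
        assert [c.deg_count for c in clusters] == [1, 1, 1]

    def test_every_deg_in_exactly_one_cluster(self, one_tad, rng):
        # partition property over random class sequences
        classes = list(rng.choice(
            ["DEG_UP", "DEG_DOWN", "BREAKER_UP", "BREAKER_DOWN", "STATIC"],
            size=200, p=[0.15, 0.15, 0.05, 0.05, 0.6]))
        genes, degs = linear_genes(classes)
        clusters = call_clusters(genes, degs, one_tad)
        member = [g for c in clusters for g in c.member_deg_ids]
        deg_ids = [g.gene_id for g in genes
                   if degs[g.gene_id].klass in (GeneClass.DEG_UP,
                                                GeneClass.DEG_DOWN)]
        assert sorted(member) == sorted(deg_ids)
        assert len(member) == len(set(member))
        for c in clusters:
            assert all(degs[g].klass == f"DEG_{c.direction}"
                       for g in c.member_deg_ids)


class TestStaticFraction:
    def _cluster(self, genes, degs, tads):
        return call_clusters(genes, degs, tads, direction_filter="UP")[0]

    def test_one_static_inside_span(self, one_tad):
        genes, degs = linear_genes(
            ["DEG_UP", "DEG_UP", "STATIC", "DEG_UP", "DEG_UP"])
        c = self._cluster(genes, degs, one_tad)
        assert c.static_fraction == pytest.approx(0.2)
        assert static_fraction(c, genes, degs) == pytest.approx(0.2)

    def test_no_statics_in_span(self, one_tad):
        genes, degs = linear_genes(["DEG_UP"] * 4 + ["STATIC"])
        c = self._cluster(genes, degs, one_tad)
        assert c.static_fraction == 0.0

    def test_half_static_fails_strict_filter(self, one_tad):
        genes, degs = linear_genes(
            ["DEG_UP", "STATIC", "DEG_UP", "STATIC", "DEG_UP",
             "STATIC", "DEG_UP", "STATIC", "DEG_UP"])
        # 5 DEGs, 4 interior statics; add one static overlapping the span end
        clusters = call_clusters(genes, degs, one_tad)
        (c,) = clusters
        assert c.deg_count == 5 and c.static_count == 4

    def test_boundary_static_fraction_strictness(self):
        c = GeneCluster("c", "chr1", "UP", ["a"] * 0 + ["g1", "g2", "g3", "g4"],
                        0, 100, "t", static_count=4)
        assert c.static_fraction == 0.5
        assert filter_ecords([c], 4, 0.5, strict=True) == []
        assert len(filter_ecords([c], 4, 0.5, strict=False)) == 1


class TestFilterEcords:
    def test_defaults_retain_passing_cluster(self):
        c = GeneCluster("c", "chr1", "UP", ["a", "b", "c", "d"], 0, 100, "t",
                        static_count=1)
        (e,) = filter_ecords([c])
        assert e.deg_count == 4 and e.static_fraction == pytest.approx(0.2)

    def test_below_min_degs_rejected(self):
        c = GeneCluster("c", "chr1", "UP", ["a", "b", "c"], 0, 100, "t")
        assert filter_ecords([c]) == []

    def test_min_degs_below_one_is_error(self):
        with pytest.raises(ValueError):
            filter_ecords([], min_degs=0)

    def test_threshold_monotonicity(self, one_tad, rng):
        classes = list(rng.choice(["DEG_UP", "STATIC"], size=300, p=[0.2, 0.8]))
        genes, degs = linear_genes(classes)
        clusters = call_clusters(genes, degs, one_tad)
        counts = [len(filter_ecords(clusters, min_degs=k)) for k in (1, 2, 3, 4)]
        assert counts == sorted(counts, reverse=True)
        sf = [len(filter_ecords(clusters, min_degs=1, max_static_fraction=f))
              for f in (0.7, 0.5, 0.3, 0.1)]
        assert sf == sorted(sf, reverse=True)


class TestTadAssignment:
    def test_tss_containment_and_singletons(self):
        tads = [TadInterval("chr1", 0, 1000, "t1"),
                TadInterval("chr1", 1000, 2000, "t2")]
        genes = [GeneRecord("a", "chr1", 900, 1100, "+"),   # tss 900 -> t1
                 GeneRecord("b", "chr1", 900, 1100, "-"),   # tss 1099 -> t2
                 GeneRecord("c", "chr1", 5000, 5100, "+")]  # outside
        asg = assign_tads(genes, tads)
        assert asg["a"] == "t1" and asg["b"] == "t2"
        assert asg["c"].startswith("__singleton__")


class TestShuffleCurve:
    def test_zero_degs_gives_zero_curve(self, one_tad):
        genes, _ = linear_genes(["STATIC"] * 20)
        curve = shuffle_probability_curve(genes, one_tad, n_deg=0,
                                          n_iterations=5, seed=0)
        assert np.all(curve.fraction_passing == 0)

    def test_exhaustive_labeling_limit(self):
        # every gene a DEG, one TAD per chromosome, no statics anywhere:
        # a qualifying cluster of any n up to the per-TAD gene count exists
        genes, _ = linear_genes(["STATIC"] * 10)
        tads = [TadInterval("chr1", 0, 10**7, "t1")]
        curve = shuffle_probability_curve(genes, tads, n_deg=10,
                                          n_iterations=3, seed=0, max_n=12)
        assert np.all(curve.fraction_passing[:10] == 1.0)
        assert np.all(curve.fraction_passing[10:] == 0.0)

    def test_curve_is_non_increasing(self, one_tad, rng):
        genes, _ = linear_genes(["STATIC"] * 100)
        curve = shuffle_probability_curve(genes, one_tad, n_deg=10,
                                          n_iterations=50, seed=1)
        assert np.all(np.diff(curve.fraction_passing) <= 0)

    def test_matches_brute_force_oracle(self):
        """Independent per-TAD re-scan: with all shuffled DEGs one direction
        and nothing to interrupt, each TAD's chosen genes form one cluster."""
        genes, tads = sd.make_genome(n_chrom=5, chrom_len=2_000_000,
                                     n_tads_per_chrom=20, n_genes=2000, seed=7)
        n_iter, n_deg = 500, 20
        curve = shuffle_probability_curve(genes, tads, n_deg=n_deg,
                                          n_iterations=n_iter, seed=3)

        # oracle: naive re-scan with its own RNG stream
        from ecordkit.ecord_detection import assign_tads
        asg = assign_tads(genes, tads)
        by_id = {g.gene_id: g for g in genes}
        ids = [g.gene_id for g in genes]
        oracle_rng = np.random.default_rng(999)
        hits = 0
        for _ in range(n_iter):
            chosen = oracle_rng.choice(ids, size=n_deg, replace=False)
            chosen_set = set(chosen)
            per_tad: dict[str, list[str]] = {}
            for gid in chosen:
                per_tad.setdefault(asg[gid], []).append(gid)
            ok = False
            for tad, members in per_tad.items():
                if len(members) < 4:
                    continue
                span_lo = min(by_id[g].start for g in members)
                span_hi = max(by_id[g].end for g in members)
                chrom = by_id[members[0]].chrom
                statics = sum(1 for g in genes
                              if g.chrom == chrom and g.start < span_hi
                              and g.end > span_lo
                              and g.gene_id not in chosen_set)
                if statics / (statics + len(members)) < 0.5:
                    ok = True
            hits += ok
        p_impl = curve.fraction_passing[3]
        p_oracle = hits / n_iter
        se = np.sqrt(0.05 * 0.95 / n_iter)
        assert abs(p_impl - p_oracle) < 4 * se + 1e-9


class TestEcordOverlap:
    def _e(self, chrom, start, end):
        return GeneCluster("c", chrom, "UP", ["x"], start, end, "t")

    def test_identical_sets_all_overlap(self):
        a = [self._e("chr1", 0, 100), self._e("chr2", 50, 80)]
        res = ecord_overlap(a, a)
        assert res["a_overlapping_b"] == res["b_overlapping_a"] == 2

    def test_disjoint_chromosomes_zero_overlap(self):
        res = ecord_overlap([self._e("chr1", 0, 100)],
                            [self._e("chr2", 0, 100)])
        assert res["a_overlapping_b"] == 0

    def test_half_shifted_span_counts(self):
        res = ecord_overlap([self._e("chr1", 0, 100)],
                            [self._e("chr1", 50, 150)])
        assert res["a_overlapping_b"] == res["b_overlapping_a"] == 1


class TestPlantedRecovery:
    def test_exact_recovery_with_no_background(self):
        for seed in range(5):
            genes, tads = sd.make_genome(seed=seed)
            rng = np.random.default_rng(seed)
            chosen = rng.choice(len(tads), size=6, replace=False)
            planted = [sd.ClusterSpec(tads[int(t)].tad_id, k=int(k),
                                      n_static=int(s))
                       for t, k, s in zip(chosen, [4, 5, 6, 7, 8, 10],
                                          [0, 1, 1, 2, 0, 2])]
            degs, truth = sd.make_deg_table(genes, tads, planted,
                                            background_deg_rate=0.0, seed=seed)
            ecords = filter_ecords(call_clusters(genes, degs, tads,
                                                 direction_filter="UP"))
            score = sd.score_cluster_recovery(truth, ecords)
            assert score["recovery_rate"] == 1.0 and score["n_false"] == 0

    def test_observed_curve_indicator(self, one_tad):
        genes, degs = linear_genes(["DEG_UP"] * 5)
        clusters = call_clusters(genes, degs, one_tad)
        ind = curve_from_clusters(clusters, 1, 8)
        assert list(ind) == [1, 1, 1, 1, 1, 0, 0, 0]
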