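"""Gene-set definition, transcriptional noise, gating, clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from germcomp import scrna
from germcomp.synthetic import SimulationConfig, gen_marker_matrix


def matrix_from(values, genes=None, cells=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    cells = cells or [f"c{i}" for i in range(values.shape[1])]
    return pd.DataFrame(values, index=genes, columns=cells)


class TestDefineGeneSet:
    def _two_group(self, target_counts, bgd_counts, extra_rows=()):
        """One gene of interest plus constant filler genes."""
        n_t, n_b = len(target_counts), len(bgd_counts)
        rows = [list(target_counts) + list(bgd_counts)]
        rows += [r for r in extra_rows]
        rows += [[5] * (n_t + n_b)] * 3  # keeps per-cell totals nonzero
        counts = matrix_from(rows)
        target = list(counts.columns[:n_t])
        bgd = list(counts.columns[n_t:])
        return counts, target, bgd

    def test_clear_marker_is_member(self):
        counts, target, bgd = self._two_group([9] * 60 + [0] * 140,
                                              [0] * 180 + [1] * 20)
        res = scrna.define_gene_set(counts, target, bgd)
        row = res.table.iloc[0]
        assert row.member and row.pct1 == 0.3 and row.pct2 == 0.1

    def test_pct1_boundary_is_strict(self):
        # expressed in exactly 20% of target cells -> excluded
        counts, target, bgd = self._two_group([9] * 10 + [0] * 40,
                                              [0] * 50)
        res = scrna.define_gene_set(counts, target, bgd)
        row = res.table.iloc[0]
        assert row.pct1 == pytest.approx(0.2) and not row.member

    def test_pct2_boundary_is_strict(self):
        counts, target, bgd = self._two_group([9] * 40 + [0] * 10,
                                              [1] * 20 + [0] * 30)
        res = scrna.define_gene_set(counts, target, bgd)
        row = res.table.iloc[0]
        assert row.pct2 == pytest.approx(0.4) and not row.member

    def test_downregulated_gene_never_member(self):
        counts, target, bgd = self._two_group([0] * 50, [9] * 30 + [0] * 20)
        res = scrna.define_gene_set(counts, target, bgd)
        assert not res.table.iloc[0].member

    def test_invariant_to_cell_and_gene_permutation(self, rng):
        counts, target, bgd = self._two_group(
            list(rng.integers(0, 10, 40)), list(rng.integers(0, 3, 40)),
            extra_rows=[list(rng.integers(0, 5, 80))],
        )
        res1 = scrna.define_gene_set(counts, target, bgd)
        shuffled = counts.sample(frac=1, axis=1, random_state=5)
        shuffled = shuffled.sample(frac=1, axis=0, random_state=6)
        res2 = scrna.define_gene_set(shuffled, target, bgd)
        t1 = res1.table.sort_index()
        t2 = res2.table.sort_index()
        pd.testing.assert_frame_equal(t1, t2)

    def test_overlapping_cell_sets_rejected(self):
        counts = matrix_from([[1, 2, 3]])
        with pytest.raises(ValueError):
            scrna.define_gene_set(counts, ["c0", "c1"], ["c1", "c2"])

    def test_planted_markers_recovered_and_verified_by_permutation(self):
        """All 20 planted markers pass; nulls don't; an independent
        permutation test on mean normalized expression agrees."""
        counts, target, markers = gen_marker_matrix(SimulationConfig(seed=3))
        bgd = [c for c in counts.columns if c not in target]
        res = scrna.define_gene_set(counts, target, bgd)
        assert set(res.members) == set(markers)

        # independent oracle: permutation test of the mean difference
        norm = counts / counts.sum(axis=0) * 1e4
        prng = np.random.default_rng(12345)
        n_t = len(target)
        cols = list(counts.columns)
        for gene in markers[:5] + res.table.index[-5:].tolist():
            vals = norm.loc[gene].to_numpy()
            obs = vals[:n_t].mean() - vals[n_t:].mean()
            null = np.empty(999)
            for b in range(999):
                perm = prng.permutation(vals)
                null[b] = perm[:n_t].mean() - perm[n_t:].mean()
            p = (1 + np.sum(np.abs(null) >= abs(obs))) / 1000
            if gene in markers:
                assert p <= 0.005
            else:
                assert p > 0.005


class TestTranscriptionalNoise:
    def _noise_matrix(self):
        """Four cells over four genes with engineered rank structure:
        B duplicates A (rho=1), C reverses A (rho=-1), D is the
        rho=0 permutation of A."""
        counts = matrix_from(
            np.array([[1, 1, 4, 2],
                      [2, 2, 3, 4],
                      [3, 3, 2, 1],
                      [4, 4, 1, 3]]),
            cells=["A", "B", "C", "D"],
        )
        meta = pd.DataFrame({"stage": ["s"] * 4}, index=counts.columns)
        return counts, meta

    def test_closed_forms_at_rho_1_minus1_0(self):
        counts, meta = self._noise_matrix()
        res = scrna.transcriptional_noise(counts, meta, "s",
                                          n_variable_genes=4)
        d = pd.Series(
            res.distances,
            index=[(a, b) for i, a in enumerate("ABCD")
                   for b in "ABCD"[i + 1:]],
        )
        assert d[("A", "B")] == pytest.approx(0.0)
        assert d[("A", "C")] == pytest.approx(1.0)
        assert d[("A", "D")] == pytest.approx(np.sqrt(0.5))

    def test_distances_bounded(self, dataset):
        res = scrna.transcriptional_noise(dataset.umi.counts,
                                          dataset.umi.meta, "ESC")
        assert np.all(res.distances >= 0) and np.all(res.distances <= 1)

    def test_lower_dispersion_stage_has_lower_noise(self, dataset):
        medians = {
            stage: scrna.transcriptional_noise(
                dataset.umi.counts, dataset.umi.meta, stage).median
            for stage in ("ESC", "EpiLC", "EpiSC")
        }
        assert medians["EpiLC"] < medians["ESC"]
        assert medians["EpiLC"] < medians["EpiSC"]

    def test_constant_cell_excluded_with_warning(self):
        counts, meta = self._noise_matrix()
        counts["E"] = [3, 3, 3, 3]
        meta = pd.DataFrame({"stage": ["s"] * 5}, index=counts.columns)
        with pytest.warns(UserWarning):
            res = scrna.transcriptional_noise(counts, meta, "s",
                                              n_variable_genes=4)
        assert res.n_excluded_pairs == 4
        assert len(res.distances) == 6

    def test_too_few_cells_errors(self):
        counts, meta = self._noise_matrix()
        meta.loc[:, "stage"] = ["s", "s", "t", "t"]
        with pytest.raises(ValueError):
            scrna.transcriptional_noise(counts, meta, "s", n_variable_genes=4)


class TestGating:
    def _matrix(self, dppa3, prdm1, klf4):
        counts = matrix_from(
            np.array([[dppa3], [prdm1], [klf4], [5]]),
            genes=["Dppa3", "Prdm1", "Klf4", "filler"], cells=["c"],
        )
        return counts

    def _gated(self, dppa3, prdm1, klf4):
        counts = self._matrix(dppa3, prdm1, klf4)
        # pass pre-normalized values so thresholds apply to them directly
        return scrna.gate_pgclc_cells(counts, normalized=counts) == ["c"]

    def test_dppa3_positive_klf4_negative_in(self):
        assert self._gated(0.5, 0, 0)

    def test_klf4_vetoes_even_with_prdm1(self):
        assert not self._gated(0.05, 2, 2)

    def test_all_low_out(self):
        assert not self._gated(0, 0, 0)

    def test_prdm1_alone_suffices(self):
        assert self._gated(0, 1.5, 0.5)

    def test_klf4_veto_is_unconditional(self, rng):
        for _ in range(20):
            d, p = rng.uniform(0, 5, 2)
            assert not self._gated(d, p, 1.0 + rng.uniform(0, 5))

    def test_missing_gene_named_in_error(self):
        counts = matrix_from([[1]], genes=["Dppa3"], cells=["c"])
        with pytest.raises(ValueError, match="Prdm1"):
            scrna.gate_pgclc_cells(counts)


class TestClusterCells:
    def test_two_blobs_recovered(self, rng):
        emb = np.vstack([rng.normal(0, 0.3, (30, 2)),
                         rng.normal(8, 0.3, (30, 2))])
        labels = scrna.cluster_cells(emb, k=2, seed=0)
        truth = np.repeat([0, 1], 30)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic_for_seed(self, rng):
        emb = rng.normal(size=(100, 2))
        a = scrna.cluster_cells(emb, k=4, seed=11)
        b = scrna.cluster_cells(emb, k=4, seed=11)
        assert np.array_equal(a, b)

    def test_four_planted_blobs(self, dataset):
        emb = dataset.umi.embedding
        truth = dataset.umi.meta.loc[emb.index, "cluster"]
        labels = scrna.cluster_cells(emb.to_numpy(), k=4, seed=11)
        assert adjusted_rand_score(truth.to_numpy(), labels) >= 0.99

    def test_k_exceeding_cells_errors(self):
        with pytest.raises(ValueError):
            scrna.cluster_cells(np.zeros((3, 2)), k=5)


class TestAnnotateClusters:
    def test_planted_tissues_recovered(self, dataset):
        emb = dataset.umi.embedding
        truth = dataset.umi.meta.loc[emb.index, "cluster"].to_numpy()
        marker_sets = dict(dataset.umi.tissue_markers)
        marker_sets["PGCLC"] = dataset.umi.marker_genes
        ann = scrna.annotate_clusters(dataset.umi.counts[emb.index], truth,
                                      marker_sets)
        assert sorted(a.label for a in ann) == sorted(marker_sets)

    def test_invariant_to_marker_list_order(self, dataset):
        emb = dataset.umi.embedding
        truth = dataset.umi.meta.loc[emb.index, "cluster"].to_numpy()
        sets_fwd = dict(dataset.umi.tissue_markers)
        sets_fwd["PGCLC"] = dataset.umi.marker_genes
        sets_rev = {k: list(reversed(v)) for k, v in
                    reversed(list(sets_fwd.items()))}
        a = scrna.annotate_clusters(dataset.umi.counts[emb.index], truth,
                                    sets_fwd)
        b = scrna.annotate_clusters(dataset.umi.counts[emb.index], truth,
                                    sets_rev)
        assert [(x.cluster, x.label) for x in a] == \
               [(x.cluster, x.label) for x in b]

    def test_no_marker_expression_is_undefined(self, rng):
        counts = matrix_from(rng.integers(1, 5, size=(20, 30)))
        labels = np.repeat([0, 1], 15)
        ann = scrna.annotate_clusters(counts, labels, {"tissueA": ["g0", "g1"]})
        assert all(a.label == "undefined" for a in ann)

    def test_empty_marker_set_rejected(self, rng):
        counts = matrix_from(rng.integers(1, 5, size=(5, 10)))
        with pytest.raises(ValueError):
            scrna.annotate_clusters(counts, np.zeros(10), {"t": []})


class TestMeanGeneSetExpression:
    def test_two_gene_mean(self):
        expr = matrix_from([[2.0], [4.0]], genes=["g1", "g2"], cells=["c"])
        assert scrna.mean_gene_set_expression(expr, ["g1", "g2"])["c"] == 3.0

    def test_all_zero_cell(self):
        expr = matrix_from([[0.0], [0.0]], genes=["g1", "g2"], cells=["c"])
        assert scrna.mean_gene_set_expression(expr, ["g1", "g2"])["c"] == 0.0

    def test_singleton_identity(self):
        expr = matrix_from([[7.0]], genes=["g1"], cells=["c"])
        assert scrna.mean_gene_set_expression(expr, ["g1"])["c"] == 7.0

    def test_empty_intersection_errors(self):
        expr = matrix_from([[1.0]], genes=["g1"], cells=["c"])
        with pytest.raises(ValueError):
            scrna.mean_gene_set_expression(expr, ["nope"])


class TestClusterFraction:
    def test_study_scale_percentages(self):
        wt = np.array(["PGCLC"] * 162 + ["other"] * (1416 - 162))
        mut = np.array(["PGCLC"] * 8 + ["other"] * (1699 - 8))
        assert scrna.cluster_fraction(wt, "PGCLC") == 11.4
        assert scrna.cluster_fraction(mut, "PGCLC") == 0.5
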