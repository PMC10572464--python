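import numpy as np
import pytest

from tfconn import (
    TFCEParams,
    extract_report,
    nbs,
    permutation_inference,
    sort_rois,
    tfce_enhance,
)
from tfconn.connectivity import connectivity_matrix
from tfconn.io import read_report, write_report
from tfconn.network_stats import Cluster, _components_from_mask
from tfconn.simulate import SimulationScenario, generate_cohort

from conftest import make_design, make_z_matrices
from oracles import tfce_bruteforce


def _random_symmetric(rng, n, signed=True):
    m = rng.standard_normal((n, n))
    if not signed:
        m = np.abs(m)
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m


class TestSortRois:
    def test_block_structure_stays_contiguous(self):
        # 6 ROIs, two 3-ROI blocks of high mutual |z|
        z = np.full((6, 6), 0.05)
        for block in ([0, 1, 2], [3, 4, 5]):
            for i in block:
                for j in block:
                    z[i, j] = 0.8
        np.fill_diagonal(z, 0.0)
        labels = tuple(f"N.r{i}" for i in range(6))
        mats = make_z_matrices([z], labels=labels)
        order = sort_rois(mats)
        positions = {i: int(np.where(order == i)[0][0]) for i in range(6)}
        for block in ([0, 1, 2], [3, 4, 5]):
            pos = sorted(positions[i] for i in block)
            assert pos[2] - pos[0] == 2  # contiguous run

    def test_shuffled_blocks_regroup(self):
        z = np.full((6, 6), 0.05)
        for block in ([0, 2, 4], [1, 3, 5]):
            for i in block:
                for j in block:
                    z[i, j] = 0.8
        np.fill_diagonal(z, 0.0)
        mats = make_z_matrices([z], labels=tuple(f"N.r{i}" for i in range(6)))
        order = sort_rois(mats)
        positions = {i: int(np.where(order == i)[0][0]) for i in range(6)}
        for block in ([0, 2, 4], [1, 3, 5]):
            pos = sorted(positions[i] for i in block)
            assert pos[2] - pos[0] == 2

    def test_two_rois_tie_break_to_input_order(self):
        mats = make_z_matrices([0.3], labels=("N.a", "N.b"))
        np.testing.assert_array_equal(sort_rois(mats), [0, 1])

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        z = _random_symmetric(rng, 10)
        mats = make_z_matrices([z], labels=tuple(f"N.r{i}" for i in range(10)))
        np.testing.assert_array_equal(sort_rois(mats), sort_rois(mats))


class TestTfceEnhance:
    def test_all_zero_map(self):
        assert not tfce_enhance(np.zeros((6, 6))).any()

    @pytest.mark.parametrize("neighborhood", ["matrix_image_4", "edge_graph"])
    def test_single_edge_closed_form(self, neighborhood):
        # lone edge of height v: e(h) = 1 for h <= v, so the integral tends
        # to v^(H+1)/(H+1) = 9.0 for v = 3, H = 2
        m = np.zeros((8, 8))
        m[1, 5] = m[5, 1] = 3.0
        params = TFCEParams(neighborhood=neighborhood)
        out = tfce_enhance(m, params=params)
        assert out[1, 5] == pytest.approx(9.0, rel=0.02)
        assert out[5, 1] == out[1, 5]

    def test_uniform_map_closed_form_edge_graph(self):
        # every edge's component is all m = K(K-1)/2 edges at every level:
        # TFCE -> m^E * v^(H+1)/(H+1)
        K, v = 5, 2.0
        m_edges = K * (K - 1) // 2
        mat = np.full((K, K), v)
        np.fill_diagonal(mat, 0.0)
        out = tfce_enhance(mat, params=TFCEParams(neighborhood="edge_graph"))
        expected = m_edges**0.5 * v**3 / 3.0
        iu = np.triu_indices(K, k=1)
        np.testing.assert_allclose(out[iu], expected, rtol=0.02)

    @pytest.mark.parametrize("neighborhood", ["matrix_image_4", "edge_graph"])
    def test_matches_bruteforce_oracle(self, neighborhood):
        rng = np.random.default_rng(42)
        params = TFCEParams(n_steps=40, neighborhood=neighborhood)
        for _ in range(25):
            stat = _random_symmetric(rng, 8)
            order = rng.permutation(8)
            ours = tfce_enhance(stat, order, params)
            oracle = tfce_bruteforce(
                stat, order, n_steps=40, neighborhood=neighborhood
            )
            np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)

    def test_negative_tail_carries_negative_sign(self):
        m = np.zeros((6, 6))
        m[0, 1] = m[1, 0] = -2.5
        out = tfce_enhance(m)
        assert out[0, 1] < 0
        one_sided = tfce_enhance(m, params=TFCEParams(two_sided=False))
        assert not one_sided.any()

    def test_scaling_strictly_increases_scores(self):
        rng = np.random.default_rng(7)
        stat = _random_symmetric(rng, 8)
        base = tfce_enhance(stat)
        scaled = tfce_enhance(1.7 * stat)
        nz = np.abs(base) > 0
        assert (np.abs(scaled[nz]) > np.abs(base[nz])).all()
        # exact scaling law: same relative grid, heights scale by c
        np.testing.assert_allclose(scaled, 1.7**3 * base, rtol=1e-10)

    def test_threshold_free_discretization_stability(self):
        # no user threshold enters beyond discretization: doubling n_steps
        # moves the peak score by < 1% on smooth maps (edges right at a
        # component-merge height can shift a few % individually)
        rng = np.random.default_rng(8)
        for _ in range(5):
            u = rng.standard_normal((10, 2))
            stat = u @ u.T
            np.fill_diagonal(stat, 0.0)
            a = tfce_enhance(stat, params=TFCEParams(n_steps=100))
            b = tfce_enhance(stat, params=TFCEParams(n_steps=200))
            peak_change = abs(np.abs(b).max() - np.abs(a).max()) / np.abs(a).max()
            assert peak_change < 0.01
            assert np.linalg.norm(b - a) < 0.02 * np.linalg.norm(a)


class TestComponents:
    def test_toy_edge_graph_components(self):
        # suprathreshold edges {(1,2),(2,3),(4,5)} on 6 nodes (hand union-find:
        # (1,2)-(2,3) share node 2 -> one component; (4,5) alone)
        mask = np.zeros((6, 6), bool)
        for a, b in [(1, 2), (2, 3), (4, 5)]:
            mask[a, b] = mask[b, a] = True
        comps = _components_from_mask(mask, np.arange(6), "edge_graph")
        sizes = sorted(len(c) for c in comps)
        assert sizes == [1, 2]

    def test_single_component_conserves_edge_count(self):
        mask = np.zeros((5, 5), bool)
        edges = [(0, 1), (1, 2), (2, 3), (3, 4), (0, 4)]
        for a, b in edges:
            mask[a, b] = mask[b, a] = True
        comps = _components_from_mask(mask, np.arange(5), "edge_graph")
        assert len(comps) == 1
        assert len(comps[0]) == len(edges)

    def test_image_components_merge_mirror_halves(self):
        mask = np.zeros((6, 6), bool)
        for a, b in [(0, 1), (0, 2)]:
            mask[a, b] = mask[b, a] = True
        comps = _components_from_mask(mask, np.arange(6), "matrix_image_4")
        assert len(comps) == 1  # (0,1),(0,2) adjacent in row 0; mirrors merged
        assert {tuple(e) for e in comps[0]} == {(0, 1), (0, 2)}


def _null_cohort_mats(atlas, n_per_group, seed, n_timepoints=100):
    sc = SimulationScenario(
        n_per_group=n_per_group,
        n_timepoints=n_timepoints,
        planted_edges=[],
        affected_group=list(n_per_group)[-1],
        seed=seed,
    )
    series, design = generate_cohort(sc, atlas)
    return [connectivity_matrix(ts) for ts in series], design


class TestPermutationInference:
    def test_identical_subjects_make_null_equal_observed(self, small_atlas):
        rng = np.random.default_rng(0)
        z = _random_symmetric(rng, 8) * 0.2
        mats = make_z_matrices([z] * 12, labels=small_atlas.roi_labels)
        design = make_design({"HC": 6, "AD": 6})
        res = permutation_inference(
            mats, design, "HC-AD", n_permutations=100, seed=1
        )
        assert (res.null_peaks == np.abs(res.tfce_map).max()).all()
        for cl in res.clusters:
            assert cl.peak_p_fwe == 1.0
            assert cl.p_uncorrected == 1.0

    def test_strong_effect_hits_p_floor(self, small_atlas):
        sc = SimulationScenario(
            n_per_group={"HC": 12, "AD": 12},
            n_timepoints=150,
            planted_edges=[
                ("NetA.R1", "NetA.R2 (L)", 0.7),
                ("NetA.R1", "NetA.R2 (R)", 0.7),
                ("NetA.R2 (L)", "NetA.R2 (R)", 0.7),
                ("NetA.R1", "NetA.R3", 0.7),
                ("NetA.R2 (L)", "NetA.R3", 0.7),
            ],
            seed=5,
        )
        series, design = generate_cohort(sc, small_atlas)
        mats = [connectivity_matrix(ts) for ts in series]
        res = permutation_inference(mats, design, "HC-AD", n_permutations=200, seed=6)
        best = min(res.clusters, key=lambda c: c.peak_p_fwe)
        assert best.peak_p_fwe == pytest.approx(1.0 / 201.0)
        assert best.sign == "positive"

    def test_deterministic_given_seed(self, small_atlas):
        mats, design = _null_cohort_mats(small_atlas, {"HC": 8, "AD": 8}, seed=3)
        a = permutation_inference(mats, design, "HC-AD", n_permutations=120, seed=9)
        b = permutation_inference(mats, design, "HC-AD", n_permutations=120, seed=9)
        np.testing.assert_array_equal(a.null_peaks, b.null_peaks)
        np.testing.assert_array_equal(a.tfce_map, b.tfce_map)
        assert [c.edges for c in a.clusters] == [c.edges for c in b.clusters]

    def test_pvalues_respect_add_one_floor(self, small_atlas):
        mats, design = _null_cohort_mats(small_atlas, {"HC": 8, "AD": 8}, seed=4)
        res = permutation_inference(mats, design, "HC-AD", n_permutations=150, seed=10)
        for cl in res.clusters:
            assert cl.peak_p_fwe >= 1.0 / 151.0
            assert cl.p_uncorrected >= 1.0 / 151.0

    def test_too_few_permutations_rejected(self, small_atlas):
        mats, design = _null_cohort_mats(small_atlas, {"HC": 8, "AD": 8}, seed=4)
        with pytest.raises(ValueError, match="n_permutations"):
            permutation_inference(mats, design, "HC-AD", n_permutations=50, seed=0)


class TestNBS:
    def test_threshold_above_everything_gives_empty(self, small_atlas):
        mats, design = _null_cohort_mats(small_atlas, {"HC": 8, "AD": 8}, seed=12)
        assert nbs(None, mats, design, "HC-AD", edge_threshold=1e6,
                   n_permutations=100, seed=0) == []

    def test_detects_planted_component(self, small_atlas):
        sc = SimulationScenario(
            n_per_group={"HC": 15, "AD": 15},
            n_timepoints=200,
            planted_edges=[
                ("NetA.R1", "NetA.R2 (L)", 1.0),
                ("NetA.R1", "NetA.R2 (R)", 1.0),
            ],
            seed=13,
        )
        series, design = generate_cohort(sc, small_atlas)
        mats = [connectivity_matrix(ts) for ts in series]
        clusters = nbs(None, mats, design, "HC-AD", edge_threshold=3.0,
                       n_permutations=200, seed=14)
        assert clusters
        top = clusters[0]
        assert top.peak_p_fwe < 0.05
        planted = {("NetA.R1", "NetA.R2 (L)"), ("NetA.R1", "NetA.R2 (R)")}
        found = {tuple(sorted(e)) for e in top.edges}
        assert planted <= found

    def test_tfce_and_nbs_agree_on_strong_compact_cluster(self, small_atlas):
        sc = SimulationScenario(
            n_per_group={"HC": 15, "AD": 15},
            n_timepoints=250,
            planted_edges=[
                ("NetA.R1", "NetA.R2 (L)", 0.7),
                ("NetA.R1", "NetA.R2 (R)", 0.7),
                ("NetA.R2 (L)", "NetA.R2 (R)", 0.7),
                ("NetA.R1", "NetA.R3", 0.7),
                ("NetA.R2 (L)", "NetA.R3", 0.7),
            ],
            seed=15,
        )
        series, design = generate_cohort(sc, small_atlas)
        mats = [connectivity_matrix(ts) for ts in series]
        res = permutation_inference(mats, design, "HC-AD", n_permutations=150, seed=16)
        nbs_clusters = nbs(None, mats, design, "HC-AD", edge_threshold=3.0,
                           n_permutations=150, seed=17)

        def top5(cluster):
            order = np.argsort([-abs(s) for s in cluster.edge_stats])[:5]
            return {tuple(sorted(cluster.edges[i])) for i in order}

        tfce_top = max(res.clusters, key=lambda c: c.mass)
        nbs_top = max(nbs_clusters, key=lambda c: c.mass)
        assert top5(tfce_top) & top5(nbs_top)
        assert len(top5(tfce_top) & top5(nbs_top)) >= 3


class TestExtractReport:
    def _cluster(self):
        return Cluster(
            cluster_id="COI1",
            edges=[("DefaultMode.PCC", "SensoriMotor.Superior"),
                   ("DefaultMode.MPFC", "DefaultMode.PCC")],
            mass=7.5,
            p_uncorrected=0.02,
            peak_tfce=30.0,
            peak_p_fwe=0.01,
            sign="positive",
            edge_stats=[3.5, 4.0],
        )

    def test_edges_ordered_by_stat_magnitude(self, atlas):
        report = extract_report([self._cluster()], atlas)
        assert list(report["stat"]) == [4.0, 3.5]
        assert report.iloc[0]["roi_a"] == "DefaultMode.MPFC"

    def test_labels_resolve_in_atlas(self, atlas):
        report = extract_report([self._cluster()], atlas)
        for roi in list(report["roi_a"]) + list(report["roi_b"]):
            assert roi in atlas.roi_labels

    def test_empty_cluster_list_gives_header_only(self):
        report = extract_report([])
        assert report.empty
        assert list(report.columns)[:4] == ["cluster_id", "sign", "mass", "p_uncorrected"]

    def test_round_trip(self, tmp_path):
        report = extract_report([self._cluster()])
        path = tmp_path / "report.tsv"
        write_report(report, path)
        back = read_report(path)
        assert list(back.columns) == list(report.columns)
        assert list(back["roi_a"]) == list(report["roi_a"])
        np.testing.assert_allclose(back["stat"], report["stat"])
        # write(read(write(x))) is byte-stable
        path2 = tmp_path / "report2.tsv"
        write_report(back, path2)
        assert path.read_bytes() == path2.read_bytes()
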