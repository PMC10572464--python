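
import numpy as np
import pytest

from tfconn import default_scenario, generate_cohort, generate_nuisance
from tfconn.simulate import (
    ConfigurationError,
    SimulationScenario,
    population_correlation,
)


def _corr(ts, a, b):
    i, j = ts.roi_labels.index(a), ts.roi_labels.index(b)
    return np.corrcoef(ts.data[:, i], ts.data[:, j])[0, 1]


class TestGenerateCohort:
    def test_deterministic_given_seed(self, atlas):
        sc = default_scenario(n_per_group={"HC": 3, "AD": 3}, n_timepoints=50, seed=11)
        series1, design1 = generate_cohort(sc, atlas)
        series2, design2 = generate_cohort(sc, atlas)
        for a, b in zip(series1, series2):
            assert a.subject_id == b.subject_id
            np.testing.assert_array_equal(a.data, b.data)
        assert design1.cdr == design2.cdr
        assert design1.mmse == design2.mmse

    def test_zero_loading_no_planted_gives_null_connectivity(self, atlas):
        sc = SimulationScenario(
            n_per_group={"HC": 50},
            n_timepoints=120,
            within_network_loading=0.0,
            planted_edges=[],
            affected_group="HC",
            seed=21,
        )
        series, _ = generate_cohort(sc, atlas)
        iu = np.triu_indices(atlas.n_rois, k=1)
        mean_z = np.array(
            [np.arctanh(np.corrcoef(ts.data, rowvar=False)[iu]).mean() for ts in series]
        )
        se = mean_z.std(ddof=1) / np.sqrt(len(mean_z))
        assert abs(mean_z.mean()) < 3 * se

    def test_within_network_population_correlation_matches_loading(self, atlas):
        # variance decomposition: corr = loading^2 / (loading^2 + (1 - loading^2))
        lam = 0.6
        expected = lam**2
        sc = SimulationScenario(
            n_per_group={"HC": 100},
            n_timepoints=200,
            within_network_loading=lam,
            planted_edges=[],
            affected_group="HC",
            seed=5,
        )
        series, _ = generate_cohort(sc, atlas)
        pair = ("DefaultMode.MPFC", "DefaultMode.PCC")
        rs = np.array([_corr(ts, *pair) for ts in series])
        se = rs.std(ddof=1) / np.sqrt(len(rs))
        assert abs(rs.mean() - expected) < 3 * se + 0.005

    def test_large_t_simulation_oracle_confirms_loading_formula(self, atlas):
        # one long series is an independent check of the closed form
        sc = SimulationScenario(
            n_per_group={"HC": 1},
            n_timepoints=200_000,
            within_network_loading=0.6,
            ar1_coefficient=0.0,
            planted_edges=[],
            affected_group="HC",
            seed=17,
        )
        series, _ = generate_cohort(sc, atlas)
        assert abs(_corr(series[0], "Visual.Medial", "Visual.Occipital") - 0.36) < 0.01

    def test_planted_effect_recovers_delta_z(self, atlas):
        sc = default_scenario(
            n_per_group={"HC": 50, "AD": 50}, n_timepoints=500, seed=33
        )
        series, design = generate_cohort(sc, atlas)
        idx = {r: i for i, r in enumerate(atlas.roi_labels)}
        diffs = []
        for a, b, dz in sc.planted_edges:
            z = {
                g: np.array(
                    [
                        np.arctanh(_corr(ts, a, b))
                        for ts in series
                        if design.group_of[ts.subject_id] == g
                    ]
                )
                for g in ("HC", "AD")
            }
            delta = z["HC"].mean() - z["AD"].mean()
            se = np.sqrt(
                z["HC"].var(ddof=1) / len(z["HC"]) + z["AD"].var(ddof=1) / len(z["AD"])
            )
            diffs.append((delta, se, dz))
        for delta, se, dz in diffs:
            assert abs(delta - dz) < 3 * se

    def test_non_planted_edges_unaffected(self, atlas):
        sc = default_scenario(n_per_group={"HC": 50, "AD": 50}, n_timepoints=500, seed=34)
        series, design = generate_cohort(sc, atlas)
        planted_rois = {r for a, b, _ in sc.planted_edges for r in (a, b)}
        # a cross-network edge far from the planted cluster
        a, b = "Visual.Medial", "Language.IFG (L)"
        assert a not in planted_rois and b not in planted_rois
        z = {
            g: np.array(
                [
                    np.arctanh(_corr(ts, a, b))
                    for ts in series
                    if design.group_of[ts.subject_id] == g
                ]
            )
            for g in ("HC", "AD")
        }
        delta = z["HC"].mean() - z["AD"].mean()
        se = np.sqrt(sum(v.var(ddof=1) / len(v) for v in z.values()))
        assert abs(delta) < 3 * se

    def test_standardized_columns(self, atlas):
        sc = default_scenario(n_per_group={"HC": 2, "AD": 2}, n_timepoints=60, seed=3)
        series, _ = generate_cohort(sc, atlas)
        for ts in series:
            np.testing.assert_allclose(ts.data.mean(axis=0), 0.0, atol=1e-12)
            np.testing.assert_allclose(ts.data.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_cdr_tracks_group_structure(self, atlas):
        sc = default_scenario(seed=8)
        _, design = generate_cohort(sc, atlas)
        means = {
            g: np.mean([design.cdr[s] for s in design.subjects_in(g)])
            for g in ("HC", "MCI", "AD")
        }
        assert means["HC"] < means["MCI"] < means["AD"]

    def test_realistic_cdr_mode_is_half_point_scale(self, atlas):
        sc = default_scenario(n_per_group={"HC": 5, "AD": 5}, n_timepoints=50,
                              realistic_cdr=True, seed=9)
        _, design = generate_cohort(sc, atlas)
        for v in design.cdr.values():
            assert 0.0 <= v <= 3.0
            assert v * 2 == int(v * 2)


class TestScenarioValidation:
    def test_unknown_planted_roi_rejected(self, atlas):
        sc = default_scenario(planted_edges=[("Nope.ROI", "DefaultMode.PCC", 0.4)])
        with pytest.raises(ConfigurationError, match="Nope.ROI"):
            generate_cohort(sc, atlas)

    def test_non_finite_delta_rejected(self, atlas):
        sc = default_scenario(
            planted_edges=[("DefaultMode.MPFC", "DefaultMode.PCC", float("inf"))]
        )
        with pytest.raises(ConfigurationError):
            generate_cohort(sc, atlas)

    def test_overloaded_effect_breaks_positive_definiteness(self, atlas):
        rois = [r for r in atlas.roi_labels if atlas.network_of[r] == "Salience"]
        edges = [
            (a, b, 2.0) for i, a in enumerate(rois) for b in rois[i + 1:]
        ]
        sc = default_scenario(planted_edges=edges)
        with pytest.raises(ConfigurationError, match="positive definite"):
            generate_cohort(sc, atlas)

    def test_too_short_series_rejected(self, atlas):
        with pytest.raises(ConfigurationError):
            generate_cohort(default_scenario(n_timepoints=5), atlas)

    def test_population_correlation_targets(self, atlas):
        sc = default_scenario()
        C_hc = population_correlation(sc, atlas, "HC")
        C_ad = population_correlation(sc, atlas, "AD")
        i = atlas.index_of("DefaultMode.MPFC")
        j = atlas.index_of("DefaultMode.PCC")
        assert C_hc[i, j] == pytest.approx(0.36)
        assert C_ad[i, j] == pytest.approx(np.tanh(np.arctanh(0.36) - 0.4))


class TestGenerateNuisance:
    def test_zero_spike_fraction_never_crosses_thresholds(self):
        sc = default_scenario(n_per_group={"HC": 4}, affected_group="HC",
                              planted_edges=[], nuisance_spike_fraction=0.0, seed=2)
        for tr in generate_nuisance(sc).values():
            assert (tr.fd <= 0.9).all()
            assert not tr.spiked.any()

    def test_spike_count_is_exact(self):
        sc = default_scenario(n_per_group={"HC": 3}, affected_group="HC",
                              planted_edges=[], n_timepoints=200,
                              nuisance_spike_fraction=0.05, seed=2)
        for tr in generate_nuisance(sc).values():
            assert tr.spiked.sum() == 10
            assert (tr.fd[tr.spiked] > 0.9).all()

    def test_deterministic_given_seed(self):
        sc = default_scenario(n_per_group={"HC": 3}, affected_group="HC",
                              planted_edges=[], seed=44)
        t1 = generate_nuisance(sc)
        t2 = generate_nuisance(sc)
        for sid in t1:
            np.testing.assert_array_equal(t1[sid].fd, t2[sid].fd)
            np.testing.assert_array_equal(t1[sid].global_signal, t2[sid].global_signal)
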