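"""Synthetic-cohort generator: planted structure, motion, phenotypes, I/O."""

import json

import numpy as np
import pytest
from scipy.stats import skew

from modcart import motion, stats, synthetic


def small_spec(**overrides):
    base = dict(
        n_subjects=5,
        n_nodes=20,
        n_volumes=100,
        module_sizes=(10, 10),
        within_corr=0.4,
        between_corr=0.05,
        seed=3,
    )
    base.update(overrides)
    return synthetic.CohortSpec(**base)


class TestCohortSpec:
    def test_module_sizes_must_cover_nodes(self):
        with pytest.raises(ValueError, match="module sizes"):
            small_spec(module_sizes=(10, 5))

    def test_between_bounded_by_within(self):
        with pytest.raises(ValueError):
            small_spec(within_corr=0.1, between_corr=0.3)

    def test_effect_size_range_enforced(self):
        with pytest.raises(ValueError, match="effect_size"):
            small_spec(effect_size=1.2, effect_nodes=(0,))

    def test_non_psd_block_rejected_with_diagnostic(self):
        # strongly negative between-correlation over many modules breaks PSD
        with pytest.raises(ValueError, match="positive semi-definite"):
            synthetic.CohortSpec(
                n_subjects=3,
                n_nodes=200,
                n_volumes=50,
                module_sizes=(50, 50, 50, 50),
                within_corr=0.1,
                between_corr=-0.1,
                seed=0,
            )


class TestTimeseries:
    def test_unstructured_spec_gives_null_correlations(self):
        spec = small_spec(within_corr=0.0, between_corr=0.0, n_volumes=2000)
        ts = synthetic.generate_modular_timeseries(spec, 1)
        r = np.corrcoef(ts, rowvar=False)
        off = r[~np.eye(20, dtype=bool)]
        assert abs(off.mean()) < 0.02

    def test_planted_within_block_level_recovered(self):
        spec = small_spec(within_corr=0.6, between_corr=0.05, n_volumes=2000)
        ts = synthetic.generate_modular_timeseries(spec, 2)
        r = np.corrcoef(ts, rowvar=False)
        lab = synthetic.module_labels(spec)
        within = (lab[:, None] == lab[None, :]) & ~np.eye(20, dtype=bool)
        assert abs(r[within].mean() - 0.6) < 0.05

    def test_deterministic_given_seeds(self):
        spec = small_spec()
        a = synthetic.generate_modular_timeseries(spec, 7)
        b = synthetic.generate_modular_timeseries(spec, 7)
        assert np.array_equal(a, b)

    def test_empirical_correlations_converge_with_volumes(self):
        target = synthetic.block_correlation(small_spec())
        devs = []
        for n_vol in (500, 5000):
            spec = small_spec(n_volumes=n_vol)
            ts = synthetic.generate_modular_timeseries(spec, 11)
            devs.append(np.abs(np.corrcoef(ts, rowvar=False) - target).max())
        assert devs[1] < devs[0]

    def test_effect_boost_raises_cross_module_correlation(self):
        spec = small_spec(effect_nodes=(0, 1), effect_size=0.4, n_volumes=4000)
        ts0 = synthetic.generate_modular_timeseries(spec, 5, between_boost=0.0)
        ts1 = synthetic.generate_modular_timeseries(spec, 5, between_boost=0.2)
        lab = synthetic.module_labels(spec)
        other = np.where(lab != lab[0])[0]
        r0 = np.corrcoef(ts0, rowvar=False)[0, other].mean()
        r1 = np.corrcoef(ts1, rowvar=False)[0, other].mean()
        assert r1 > r0 + 0.1


class TestMotionTrace:
    def test_zero_target_gives_still_trace(self):
        trace = synthetic.generate_motion_trace(50, 0.0, 0.02, 1)
        assert np.array_equal(trace, np.zeros((50, 6)))
        assert motion.framewise_displacement(trace).max() == 0.0

    def test_mean_fd_hits_target_within_ten_percent(self):
        trace = synthetic.generate_motion_trace(116, 0.1, 0.04, 2)
        fd = motion.framewise_displacement(trace)
        assert 0.09 <= fd.mean() <= 0.11

    def test_high_motion_subject_flagged_by_exclusion_rule(self):
        trace = synthetic.generate_motion_trace(150, 0.3, 0.05, 3)
        summary = motion.qc_summary({"sub": trace})
        assert summary["excluded"].item()

    def test_too_few_volumes_rejected(self):
        with pytest.raises(ValueError):
            synthetic.generate_motion_trace(1, 0.1, 0.02, 0)


class TestPhenotypes:
    def test_null_effect_calibration(self):
        """With no planted effect, spurious partial r is small in >= 95 % of runs."""
        hits = 0
        for rep in range(100):
            spec = small_spec(n_subjects=200, effect_size=0.0, seed=rep)
            rng = np.random.default_rng(50_000 + rep)
            truth = rng.standard_normal(200)
            ph = synthetic.generate_phenotypes(
                spec, seed_seq=synthetic.child_seed(rep, 2, 0)
            )
            design = stats.covariate_design(ph)
            r = stats.partial_correlation(
                ph["adhd_index"].to_numpy(), truth, design
            ).r_part
            hits += abs(r) < 0.15
        assert hits >= 95

    def test_planted_effect_recovered_in_expectation(self):
        """Mean recovered partial r over 100 replicate cohorts is within 0.05."""
        rs = []
        for rep in range(100):
            spec = small_spec(
                n_subjects=200, effect_nodes=(0,), effect_size=0.4, seed=rep
            )
            rng = np.random.default_rng(60_000 + rep)
            truth = rng.standard_normal(200)
            ph = synthetic.generate_phenotypes(
                spec, nodal_truth=truth, seed_seq=synthetic.child_seed(rep, 2, 0)
            )
            design = stats.covariate_design(ph)
            rs.append(
                stats.partial_correlation(
                    ph["adhd_index"].to_numpy(), truth, design
                ).r_part
            )
        assert abs(np.mean(rs) - 0.4) < 0.05

    def test_symptom_scores_right_skewed_in_range(self):
        spec = small_spec(n_subjects=300)
        ph = synthetic.generate_phenotypes(spec)
        scores = ph["adhd_index"].to_numpy()
        assert skew(scores) > 0
        assert scores.min() >= 0 and scores.max() <= synthetic.ADHD_MAX

    def test_covariates_complete_and_realistic(self):
        ph = synthetic.generate_phenotypes(small_spec(n_subjects=100))
        assert not ph.drop(columns="subject_id").isna().any().any()
        assert ph["age"].between(18, 60).all()
        assert 80 < ph["fsiq"].mean() < 120
        assert set(ph["handedness"]) <= {"right", "left", "ambidextrous"}

    def test_effect_requires_truth(self):
        spec = small_spec(effect_nodes=(0,), effect_size=0.3)
        with pytest.raises(ValueError, match="nodal_truth"):
            synthetic.generate_phenotypes(spec)


class TestCohortIO:
    def test_round_trip_preserves_data(self, tmp_path):
        cohort = synthetic.generate_cohort(small_spec())
        synthetic.write_cohort(cohort, tmp_path / "c")
        loaded = synthetic.read_cohort(tmp_path / "c")
        assert loaded.spec == cohort.spec
        assert loaded.subject_ids == cohort.subject_ids
        np.testing.assert_allclose(
            loaded.timeseries[0], cohort.timeseries[0], atol=1e-6
        )

    def test_serialized_cohort_is_deterministic(self, tmp_path):
        import hashlib

        digests = []
        for sub in ("a", "b"):
            cohort = synthetic.generate_cohort(small_spec())
            out = synthetic.write_cohort(cohort, tmp_path / sub)
            h = hashlib.sha256()
            for f in sorted(out.rglob("*")):
                if f.is_file():
                    h.update(f.read_bytes())
            digests.append(h.hexdigest())
        assert digests[0] == digests[1]

    def test_manifest_holds_spec(self, tmp_path):
        cohort = synthetic.generate_cohort(small_spec())
        out = synthetic.write_cohort(cohort, tmp_path / "c")
        manifest = json.loads((out / "manifest.json").read_text())
        assert manifest["spec"]["n_subjects"] == 5


class TestLatticeAndNetworks:
    def test_lattice_spacing_controls_distance_exclusion(self):
        coords = synthetic.lattice_coordinates(27, spacing=12.0)
        xyz = coords[["x", "y", "z"]].to_numpy()
        from modcart import graphs

        conn = graphs.apply_distance_exclusion(np.eye(27), xyz)
        # 12-mm neighbours and 17-mm face diagonals are pruned; 24 mm survives
        assert conn.n_admissible_pairs < 27 * 26 // 2
        d01 = np.linalg.norm(xyz[0] - xyz[1])
        assert d01 == pytest.approx(12.0) and not conn.admissible[0, 1]

    def test_network_assignment_covers_all_seven(self):
        table = synthetic.synthetic_network_assignment(70)
        from modcart.posthoc import NETWORKS_7

        assert set(table["network"]) == set(NETWORKS_7)
        assert len(table) == 70


def test_planted_partition_graph_edge_rates(rng):
    g, labels = synthetic.planted_partition_graph(120, 4, 0.5, 0.05, seed=9)
    adj = g.adjacency()
    same = labels[:, None] == labels[None, :]
    triu = np.triu(np.ones((120, 120), dtype=bool), 1)
    within_rate = adj[same & triu].mean()
    between_rate = adj[~same & triu].mean()
    assert abs(within_rate - 0.5) < 0.05
    assert abs(between_rate - 0.05) < 0.02
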