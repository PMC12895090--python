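"""Generator calibration and bookkeeping: reach geometry, kernel variance
identity, degenerate-parameter limits and dataset round trips."""

import math

import numpy as np
import pytest

import streammove as sm
from streammove.synthetic import Trajectories, _lognormal_params


class TestGenerateReach:
    def test_default_geometry(self):
        reach = sm.generate_reach(seed=0)
        assert reach.n_sections == 43
        assert reach.L == 430.0
        assert np.allclose(reach.midpoints, np.arange(5.0, 430.0, 10.0))
        assert len(reach.occasions) == 15
        intervals = [o.interval_to_next for o in reach.occasions[:-1]]
        assert intervals.count(93.0) == 13 and intervals.count(171.0) == 1

    def test_habitat_scales_match_targets(self):
        """Empirical HRA/velocity/area means over many sections sit within
        10% of the field-study scales the generator mimics."""
        reach = sm.generate_reach(S=43, T=250, seed=5)  # 43*250 > 1e4 draws
        hab = reach.habitat
        assert hab["hra_m2"].mean() == pytest.approx(0.45, rel=0.10)
        assert hab["velocity_ms"].mean() == pytest.approx(0.06, rel=0.10)
        assert hab.groupby("section")["area_m2"].first().mean() == pytest.approx(
            32.51, rel=0.15
        )

    def test_seed_reproducibility(self):
        a = sm.generate_reach(seed=9)
        b = sm.generate_reach(seed=9)
        assert a.habitat.equals(b.habitat)

    def test_geometry_conflict_rejected(self):
        with pytest.raises(ValueError):
            sm.generate_reach(S=43, section_length=10.0, L=400.0)

    def test_lognormal_moment_matching(self):
        mu, tau = _lognormal_params(32.51, 9.21)
        assert math.exp(mu + tau**2 / 2) == pytest.approx(32.51)
        var = (math.exp(tau**2) - 1) * math.exp(2 * mu + tau**2)
        assert math.sqrt(var) == pytest.approx(9.21)


class TestSimulateReplicates:
    def test_displacement_sd_matches_t_variance_identity(self):
        """At fixed sigma the kernel's displacement sd is sigma*sqrt(5/3)
        (variance of t_5 is nu/(nu-2))."""
        n = 100_000
        beta0, eta = math.log(0.3), 93.0
        sigma = math.exp(beta0) * eta
        reps = sm.simulate_replicates(
            n, beta0, {}, phi=0.9, seed=4, L=1e12, eta_days=eta
        )
        disp = np.array([r.x1 - r.x0 for r in reps if r.y == 1])
        assert disp.std(ddof=1) == pytest.approx(
            sigma * math.sqrt(5.0 / 3.0), rel=0.02
        )

    def test_perfect_observation_recaptured_in_place(self):
        """phi = 1 with a near-degenerate kernel: every replicate is
        recaptured essentially where it started."""
        reps = sm.simulate_replicates(
            500, -20.0, {}, phi=1.0 - 1e-12, seed=2
        )
        assert all(r.y == 1 for r in reps)
        assert max(abs(r.x1 - r.x0) for r in reps) < 1e-3

    def test_recapture_fraction_tracks_phi(self):
        """With a tight kernel (no emigration) the recapture fraction
        estimates phi itself."""
        reps = sm.simulate_replicates(20_000, -20.0, {}, phi=0.37, seed=6)
        frac = np.mean([r.y for r in reps])
        assert frac == pytest.approx(0.37, abs=0.01)

    def test_size_effect_induces_size_distance_correlation(self):
        def corr(beta_size, seed=8):
            reps = sm.simulate_replicates(
                30_000, math.log(0.3), {"body_size": beta_size}, phi=0.9,
                seed=seed, L=1e12,
            )
            x = np.array([r.covariates["body_size"] for r in reps if r.y])
            d = np.array([abs(r.x1 - r.x0) for r in reps if r.y])
            return np.corrcoef(x, np.log(d + 1e-9))[0, 1]

        assert corr(0.0) == pytest.approx(0.0, abs=0.03)
        assert corr(0.6) > corr(0.2) > 0.05

    def test_replicates_pass_datamodel_validation(self):
        reps = sm.simulate_replicates(
            200, math.log(0.3), {"body_size": 0.4}, 0.5, seed=1
        )
        for r in reps:
            assert 0.0 <= r.x0 <= 430.0
            assert r.eta_days > 0
            if r.y:
                assert 0.0 <= r.x1 <= 430.0
            else:
                assert r.x1 is None
            assert r.x0 == sm.section_midpoint(r.section_t, 10.0)


class TestSimulateIndividuals:
    def test_degenerate_kernel_freezes_positions(self, small_reach):
        truth = sm.SpeciesTruth(
            "creek_chub", 60, 90.0, 15.0, beta0=-20.0, beta={},
            phi=0.95, p_detect=1.0,
        )
        traj = sm.simulate_individuals(truth, small_reach, seed=3)
        for i in range(traj.positions.shape[0]):
            pos = traj.positions[i][traj.alive[i]]
            # sigma ~ 2e-7 m; even heavy-tailed t draws stay sub-millimetre
            assert np.ptp(pos) < 1e-3 if pos.size else True

    def test_perfect_observation_all_recaptured_in_own_section(
        self, small_reach
    ):
        truth = sm.SpeciesTruth(
            "creek_chub", 60, 90.0, 15.0, beta0=-20.0, beta={},
            phi=1.0 - 1e-9, p_detect=1.0,
        )
        traj = sm.simulate_individuals(truth, small_reach, seed=3)
        # every individual alive at t is captured at t, in a fixed section
        assert np.array_equal(traj.captured, traj.alive)
        ds = sm.emit_dataset([traj], small_reach)
        per_tag = ds.captures.groupby("tag_id")
        assert (per_tag["section"].nunique() == 1).all()
        assert (per_tag["occasion"].count() == len(small_reach.occasions)).all()

    def test_lengths_truncated_at_tagging_threshold(self, small_reach):
        truth = sm.SpeciesTruth(
            "creek_chub", 400, 65.0, 20.0, beta0=-1.0, beta={},
            phi=0.3, p_detect=0.5,
        )
        traj = sm.simulate_individuals(truth, small_reach, seed=5)
        assert traj.lengths.min() > 60.0


class TestEmitDataset:
    def test_study_scale_scenario_shape(self, tiny_study):
        caps = tiny_study.captures
        assert set(caps["species"]) == {"creek_chub", "green_sunfish"}
        counts = caps.groupby("species")["tag_id"].nunique()
        assert counts["creek_chub"] > counts["green_sunfish"]
        assert caps["total_length_mm"].min() > 60.0

    def test_default_scenario_abundance_ranks(self):
        """Species abundances keep the study's ordering: creek chub most
        abundant, bluehead chub ~ green sunfish, redbreast sunfish least."""
        truths = {t.name: t for t in sm.study_scenario()}
        n = {name: t.n_initial for name, t in truths.items()}
        assert (
            n["creek_chub"] > n["bluehead_chub"]
            and n["creek_chub"] > n["green_sunfish"]
            and min(n["bluehead_chub"], n["green_sunfish"])
            > n["redbreast_sunfish"]
        )

    def test_round_trip_through_files(self, tmp_path, tiny_study):
        tiny_study.write(tmp_path)
        back = sm.SyntheticDataset.load(tmp_path)
        assert back.captures.equals(tiny_study.captures)
        assert back.truths == tiny_study.truths
        assert (
            back.planted_consecutive_recaptures
            == tiny_study.planted_consecutive_recaptures
        )
        # emitted tables pass the io validators end to end
        records = sm.read_captures(
            tmp_path / "captures.csv",
            species_set=list(back.truths),
            n_occasions=len(back.occasions),
            n_sections=int(back.habitat["section"].max()),
        )
        assert len(records) == len(back.captures)
        reps = sm.build_replicates(records, back.occasions)
        assert reps


class TestRecoveryExperiment:
    def test_single_rep_table_structure(self):
        result = sm.recovery_experiment(
            math.log(0.3), {"body_size": 0.4}, 0.5, n_reps=1,
            sampler_cfg=sm.SamplerConfig(
                n_iter=400, burn_in=200, thin=2, n_chains=2, seed=0
            ),
            seed=0, n_replicates=80,
        )
        assert sorted(result.table["parameter"]) == sorted(
            ["beta0", "beta_body_size", "phi"]
        )
        summary = result.summary()
        assert set(summary.index) == {"beta0", "beta_body_size", "phi"}
        assert (summary["n_reps"] == 1).all()

    def test_posterior_concentrates_with_much_data(self):
        """Consistency: with 2000 replicates the posterior median of the
        intercept lands within 0.1 of the truth."""
        result = sm.recovery_experiment(
            math.log(0.3), {}, 0.5, n_reps=1,
            sampler_cfg=sm.SamplerConfig(
                n_iter=2000, burn_in=800, thin=4, n_chains=2, seed=1
            ),
            seed=1, n_replicates=2000,
        )
        row = result.table.set_index("parameter").loc["beta0"]
        assert abs(row["error"]) < 0.1
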