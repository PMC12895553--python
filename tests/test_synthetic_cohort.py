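import numpy as np
import pandas as pd
import pytest

from twinbrain import glm
from twinbrain import synthetic_cohort as sc
from twinbrain.regions import MODEL_REGIONS_20, RIGHT_AMYGDALA
from twinbrain.task_codec import EF_TASK, STROOP_TASK


def traits(affective=0.0, cognitive=0.0, n_nuisance=3):
    return sc.LatentTraits(affective, cognitive, np.zeros(n_nuisance))


class TestGenerateSchedule:
    def test_emotional_faces_fits_grid_and_duration(self):
        events = sc.generate_schedule(EF_TASK, 394.6, 0.08, seed=1)
        n_steps = int(np.floor(394.6 / 0.08))
        assert n_steps == 4932
        assert len(events) > 0
        assert (events["onset"] + events["duration"]).max() <= 394.6
        steps = events["onset"] / 0.08
        np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)

    def test_zero_duration_gives_empty_events(self):
        events = sc.generate_schedule(STROOP_TASK, 0.0, 0.08, seed=0)
        assert events.empty

    def test_same_seed_identical(self):
        a = sc.generate_schedule(STROOP_TASK, 200.0, 0.08, seed=42)
        b = sc.generate_schedule(STROOP_TASK, 200.0, 0.08, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_onsets_strictly_increasing(self):
        events = sc.generate_schedule(EF_TASK, 300.0, 0.08, seed=3)
        assert events["onset"].is_monotonic_increasing
        assert events["onset"].diff().dropna().gt(0).all()

    def test_blocked_conditions(self):
        cfg = sc.ScheduleConfig(block_size=4)
        events = sc.generate_schedule(EF_TASK, 394.6, 0.08, cfg, seed=0)
        first_eight = events["trial_type"].iloc[:8].tolist()
        assert first_eight == ["face"] * 4 + ["shape"] * 4

    def test_overlapping_config_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sc.generate_schedule(EF_TASK, 100.0, 0.08, sc.ScheduleConfig(stim_s=0.0))


class TestSimulateBehavior:
    def _events(self, n=6):
        return sc.generate_schedule(EF_TASK, 12.0 * n + 6, 0.08, seed=5)

    def test_degenerate_config_gives_equal_latencies(self):
        cfg = sc.BehaviorConfig(latency_slope_s=0.0, latency_noise_sd_s=0.0)
        out = sc.simulate_behavior(self._events(), traits(cognitive=1.3), cfg, seed=0)
        assert out["response_time"].nunique() == 1
        assert out["response_time"].iloc[0] == pytest.approx(cfg.base_latency_s)

    def test_cognitive_trait_monotone_in_latency(self):
        cfg = sc.BehaviorConfig(latency_slope_s=0.1, latency_noise_sd_s=0.01)
        slow = sc.simulate_behavior(self._events(), traits(cognitive=2.0), cfg, seed=1)
        fast = sc.simulate_behavior(self._events(), traits(cognitive=-2.0), cfg, seed=1)
        assert slow["response_time"].mean() > fast["response_time"].mean()

    def test_error_probability_limit_zero(self):
        cfg = sc.BehaviorConfig(error_p0=-1e9)
        out = sc.simulate_behavior(self._events(), traits(), cfg, seed=2)
        assert (out["response"] == out["correct_response"]).all()

    def test_negative_base_latency_rejected(self):
        with pytest.raises(ValueError, match="base_latency"):
            sc.simulate_behavior(self._events(), traits(),
                                 sc.BehaviorConfig(base_latency_s=-0.1))

    def test_latency_at_least_one_step(self):
        cfg = sc.BehaviorConfig(base_latency_s=0.0, latency_slope_s=0.0,
                                latency_noise_sd_s=0.5)
        out = sc.simulate_behavior(self._events(), traits(), cfg, seed=3)
        assert (out["response_time"] >= 0.08).all()

    def test_already_responded_rejected(self):
        done = sc.simulate_behavior(self._events(), traits(), seed=0)
        with pytest.raises(ValueError, match="already"):
            sc.simulate_behavior(done, traits(), seed=0)


class TestSimulateBold:
    def test_zero_amplitudes_and_noise_give_zero_signal(self):
        events = sc.generate_schedule(EF_TASK, 60.0, 0.08, seed=0)
        cfg = sc.BoldConfig(amygdala_face_a0=0.0, amygdala_face_a1=0.0,
                            base_amplitude_sd=0.0, noise_sd=0.0)
        ts = sc.simulate_bold(events, traits(), MODEL_REGIONS_20, cfg, seed=0,
                              duration_s=60.0)
        np.testing.assert_array_equal(ts.values, 0.0)

    def test_single_trial_is_shifted_hrf(self):
        """Direct-convolution oracle for one face trial without noise."""
        events = pd.DataFrame([{"onset": 4.0, "duration": 2.0, "trial_type": "face"}])
        cfg = sc.BoldConfig(amygdala_face_a0=1.0, amygdala_face_a1=0.0,
                            base_amplitude_sd=0.0, noise_sd=0.0)
        ts = sc.simulate_bold(events, traits(), MODEL_REGIONS_20, cfg, seed=0,
                              duration_s=60.0)
        n = ts.values.shape[1]
        kernel = glm.glover_hrf(np.arange(0.0, 32.04, 0.08))
        box = np.zeros(n)
        box[50:75] = 1.0  # 4.0 s to 6.0 s at 0.08 s
        expected = np.convolve(box, kernel)[:n]
        amy = MODEL_REGIONS_20.index(RIGHT_AMYGDALA)
        np.testing.assert_allclose(ts.values[amy], expected, atol=1e-12)
        # all other regions have zero amplitude here
        others = [i for i in range(20) if i != amy]
        np.testing.assert_array_equal(ts.values[others], 0.0)

    def test_phi_zero_gives_white_noise_with_configured_sd(self):
        events = pd.DataFrame(columns=["onset", "duration", "trial_type"])
        cfg = sc.BoldConfig(base_amplitude_sd=0.0, noise_sd=0.5, ar1_phi=0.0)
        ts = sc.simulate_bold(events, traits(), MODEL_REGIONS_20, cfg, seed=1,
                              duration_s=400.0)
        assert ts.values.std() == pytest.approx(0.5, rel=0.05)
        lag1 = np.mean([np.corrcoef(row[:-1], row[1:])[0, 1] for row in ts.values])
        assert abs(lag1) < 0.05

    def test_ar1_autocorrelation_matches_phi(self):
        events = pd.DataFrame(columns=["onset", "duration", "trial_type"])
        cfg = sc.BoldConfig(base_amplitude_sd=0.0, noise_sd=0.5, ar1_phi=0.6)
        ts = sc.simulate_bold(events, traits(), MODEL_REGIONS_20, cfg, seed=1,
                              duration_s=400.0)
        lag1 = np.mean([np.corrcoef(row[:-1], row[1:])[0, 1] for row in ts.values])
        assert lag1 == pytest.approx(0.6, abs=0.05)

    def test_amygdala_required(self):
        with pytest.raises(ValueError, match="amygdala"):
            sc.simulate_bold(pd.DataFrame(columns=["onset", "duration", "trial_type"]),
                             traits(), ["a", "b"], duration_s=10.0)


class TestEmbedRsfcm:
    def test_446_regions_vector_length(self):
        rsfcm = sc.embed_rsfcm(traits(), 446, seed=0)
        assert rsfcm.edges.shape == (99235,)

    def test_zero_traits_zero_noise_identical(self):
        cfg = sc.EmbedConfig(noise_scale=0.0)
        basis = sc.make_embedding_basis(30, cfg, seed=7)
        a = sc.embed_rsfcm(traits(), 30, cfg, basis, seed=1)
        b = sc.embed_rsfcm(traits(), 30, cfg, basis, seed=2)
        np.testing.assert_array_equal(a.edges, b.edges)

    def test_trait_recoverable_by_linear_regression(self):
        """Oracle: least-squares regression of the affective trait on rsFCM
        edges explains > 90% of variance on a 200-participant cohort."""
        rng = np.random.default_rng(0)
        cfg = sc.EmbedConfig(noise_scale=0.005)
        basis = sc.make_embedding_basis(15, cfg, seed=3)
        X, y = [], []
        for _ in range(200):
            t = sc.LatentTraits(rng.standard_normal(), rng.standard_normal(),
                                rng.standard_normal(3))
            X.append(sc.embed_rsfcm(t, 15, cfg, basis, rng).edges)
            y.append(t.affective)
        X = np.column_stack([np.ones(200), np.asarray(X).reshape(200, -1)])
        y = np.asarray(y)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        r2 = 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        assert r2 > 0.9

    def test_min_regions(self):
        with pytest.raises(ValueError, match="n_regions"):
            sc.embed_rsfcm(traits(), 1)


class TestCohort:
    def test_full_determinism(self):
        cfg = sc.CohortConfig(n_participants=3, tasks=[EF_TASK], ef_duration_s=60.0)
        a = sc.generate_cohort(cfg, seed=9)
        b = sc.generate_cohort(cfg, seed=9)
        for pa, pb in zip(a.participants, b.participants):
            np.testing.assert_array_equal(pa.rsfcm.edges, pb.rsfcm.edges)
            np.testing.assert_array_equal(pa.sessions[EF_TASK].sensory,
                                          pb.sessions[EF_TASK].sensory)
            np.testing.assert_array_equal(pa.sessions[EF_TASK].bold,
                                          pb.sessions[EF_TASK].bold)
            pd.testing.assert_frame_equal(pa.events[EF_TASK], pb.events[EF_TASK])

    def test_planted_rt_monotonicity(self):
        """Across a 100-participant cohort, corr(cognitive trait, mean RT) is
        positive (the configured sign) and |r| > 0.8."""
        cfg = sc.CohortConfig(n_participants=100, tasks=[EF_TASK], ef_duration_s=60.0)
        cohort = sc.generate_cohort(cfg, seed=2)
        cog = [p.traits.cognitive for p in cohort.participants]
        rt = [p.events[EF_TASK]["response_time"].mean() for p in cohort.participants]
        r = np.corrcoef(cog, rt)[0, 1]
        assert r > 0.8

    def test_glm_recovers_amplitude_ratio_on_noiseless_bold(self):
        """Ground-truth GLM recovery: noiseless simulated BOLD gives condition
        betas whose ratio matches the planted amplitudes to < 1% relative."""
        events = sc.generate_schedule(EF_TASK, 200.0, 0.08, seed=4)
        cfg = sc.BoldConfig(amygdala_face_a0=1.2, amygdala_face_a1=0.0,
                            base_amplitude_sd=0.0, noise_sd=0.0)
        t = traits()
        base_rng = np.random.default_rng(0)
        ts = sc.simulate_bold(events, t, MODEL_REGIONS_20, cfg, seed=0,
                              duration_s=200.0, base_rng=base_rng)
        amy = MODEL_REGIONS_20.index(RIGHT_AMYGDALA)
        # plant a known shape amplitude directly
        amp = sc.condition_amplitudes(t, MODEL_REGIONS_20, ["face", "shape"],
                                      cfg, np.random.default_rng(0))
        design = glm.build_design(events, ts.values.shape[1], 0.08, 0.0,
                                  conditions=["face", "shape"])
        fit = glm.fit_glm(design, ts.values[amy])
        beta_face = fit.beta[fit.column_names.index("face_hrf")]
        assert beta_face == pytest.approx(amp[amy, 0], rel=0.01)

    def test_write_load_round_trip(self, tmp_path, tiny_cohort):
        out = str(tmp_path / "cohort")
        sc.write_cohort(tiny_cohort, out)
        loaded = sc.load_cohort(out)
        assert loaded.n_participants == tiny_cohort.n_participants
        for pa, pb in zip(tiny_cohort.participants, loaded.participants):
            np.testing.assert_allclose(pa.rsfcm.edges, pb.rsfcm.edges, atol=1e-12)
            np.testing.assert_allclose(pa.sessions[EF_TASK].sensory,
                                       pb.sessions[EF_TASK].sensory, atol=1e-12)
            np.testing.assert_allclose(pa.sessions[EF_TASK].action,
                                       pb.sessions[EF_TASK].action, atol=1e-12)
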