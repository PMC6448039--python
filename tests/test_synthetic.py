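"""Generator contracts: design counts, determinism, symmetry, and recovery
of injected ground truth by the extraction stage."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

import dcnlearn as d
from dcnlearn.features import extract_features
from dcnlearn.synthetic import make_cohort, ground_truth_features, trial_seed


def _fixed_animal(cfg, lf=None, hf=None, uniform_gain=False):
    animal = make_cohort(cfg)[0]
    if lf is not None:
        animal.lf_params = {n: dict(lf) for n in d.NERVES}
    if hf is not None:
        animal.hf_params = {n: dict(hf) for n in d.NERVES}
    if uniform_gain:
        animal.attenuation_length_mm = 1e6
    return animal


class TestCohort:
    def test_default_cohort_has_seven_animals(self):
        assert len(make_cohort(d.GeneratorConfig())) == 7

    def test_same_seed_gives_identical_cohorts(self):
        cfg = d.GeneratorConfig(rng_seed=42)
        a, b = make_cohort(cfg), make_cohort(cfg)
        for x, y in zip(a, b):
            assert x.animal_id == y.animal_id
            assert x.hotspots == y.hotspots
            assert x.lf_params == y.lf_params
            assert x.hf_params == y.hf_params
            assert x.electrode_shift_um == y.electrode_shift_um

    def test_bilateral_hotspots_mirror_without_asymmetry(self):
        cfg = d.GeneratorConfig(asymmetry_scale=0.0, electrode_shift_sd=0.0)
        for animal in make_cohort(cfg):
            for left, right in (("LSN", "RSN"), ("LPN", "RPN")):
                lx, ly = animal.hotspots[left]
                rx, ry = animal.hotspots[right]
                assert abs(lx + rx) < 1e-9
                assert abs(ly - ry) < 1e-9

    def test_null_cohort_has_identical_nerve_parameters(self):
        cfg = d.GeneratorConfig(effect_scale=0.0)
        for animal in make_cohort(cfg):
            ref = animal.lf_params["RSN"]
            assert all(animal.lf_params[n] == ref for n in d.NERVES)
            ref_hf = animal.hf_params["RSN"]
            assert all(animal.hf_params[n] == ref_hf for n in d.NERVES)
            ref_hs = animal.hotspots["RSN"]
            assert all(
                np.allclose(animal.hotspots[n], ref_hs) for n in d.NERVES
            )

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"effect_scale": 1.5},
            {"asymmetry_scale": -0.1},
            {"n_animals": 0},
            {"sample_rate": 6000.0},
            {"trace_window_ms": (10.0, 80.0)},
            {"trace_window_ms": (20.0, 50.0)},
            {"noise_sd": -1.0},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            d.GeneratorConfig(**kwargs)

    def test_physiological_invariants_hold(self):
        for animal in make_cohort(d.GeneratorConfig(rng_seed=3)):
            for nerve in d.NERVES:
                lf = animal.lf_params[nerve]
                assert lf["n1_latency_ms"] > lf["p1_latency_ms"] > 5.0
                assert lf["p1_amplitude_uv"] > 0
                assert lf["n1_amplitude_uv"] < 0


class TestTrials:
    def test_trial_shape_and_sample_rate(self, small_config):
        animal = make_cohort(small_config)[0]
        trace = d.synthesize_trial(animal, "LSN", small_config, 1)
        pre, post = small_config.trace_window_ms
        n_expected = int((pre + post) * small_config.sample_rate / 1000)
        assert trace.samples.shape == (7, n_expected)
        assert trace.sample_rate == 40_000.0
        assert trace.t0_index == int(pre * small_config.sample_rate / 1000)

    def test_unknown_nerve_rejected(self, small_config):
        animal = make_cohort(small_config)[0]
        with pytest.raises(ValueError, match="unknown nerve"):
            d.synthesize_trial(animal, "XXX", small_config, 1)

    def test_same_seed_gives_bit_identical_trace(self, small_config):
        animal = make_cohort(small_config)[0]
        a = d.synthesize_trial(animal, "RPN", small_config, 7)
        b = d.synthesize_trial(animal, "RPN", small_config, 7)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_dataset_design_counts(self):
        """The full design: 880 trials per animal, 6160 pooled, balanced
        220 per nerve (labels only — traces stay lazy)."""
        ts = d.generate_dataset(d.GeneratorConfig())
        assert len(ts) == 6160
        per_animal = ts.labels.groupby("animal").size()
        assert (per_animal == 880).all()
        per_nerve = ts.labels.groupby(["animal", "nerve"]).size()
        assert (per_nerve == 220).all()

    def test_dataset_reproducible_from_seed(self):
        cfg = d.GeneratorConfig(n_animals=2, n_sets=1, trials_per_set=3)
        a, b = d.generate_dataset(cfg), d.generate_dataset(cfg)
        pd.testing.assert_frame_equal(a.labels, b.labels)


class TestGroundTruthRecovery:
    def test_null_ground_truth_identical_across_nerves(self):
        cfg = d.GeneratorConfig(effect_scale=0.0, electrode_shift_sd=0.0)
        animal = make_cohort(cfg)[0]
        ref = ground_truth_features(animal, "RSN", config=cfg)
        for nerve in d.NERVES:
            pd.testing.assert_frame_equal(
                ground_truth_features(animal, nerve, config=cfg), ref
            )

    def test_symmetric_animal_mirrors_left_right_truth(self):
        cfg = d.GeneratorConfig(asymmetry_scale=0.0, electrode_shift_sd=0.0)
        animal = make_cohort(cfg)[0]
        lsn = ground_truth_features(animal, "LSN", config=cfg)
        rsn = ground_truth_features(animal, "RSN", config=cfg)
        # e1/e2 (left) mirror e6/e7 (right)
        np.testing.assert_allclose(
            lsn.loc[["e1", "e2"]].to_numpy(), rsn.loc[["e6", "e7"]].to_numpy()
        )

    def test_lf_injection_recovered_exactly(self):
        """Injected P1 (12 ms, +80 uV) and N1 (20 ms, -120 uV) come back
        within one sample / 1e-6 uV when no noise or burst is present."""
        cfg = d.GeneratorConfig(
            n_animals=1, noise_sd=0.0, animal_variability_sd=0.0,
            electrode_shift_sd=0.0,
        )
        animal = _fixed_animal(
            cfg,
            lf=dict(p1_latency_ms=12.0, n1_latency_ms=20.0,
                    p1_amplitude_uv=80.0, n1_amplitude_uv=-120.0),
            hf=dict(rate_per_ms=0.0, amplitude_uv=0.0),
        )
        trace = d.synthesize_trial(animal, "RSN", cfg, 5)
        fv = extract_features(trace, seed=0)
        gt = ground_truth_features(animal, "RSN", config=cfg)
        dt_ms = 1000.0 / cfg.sample_rate
        for e in range(1, 8):
            assert abs(fv.values[f"e{e}_n1_latency"] - 20.0) <= dt_ms
            assert (
                abs(fv.values[f"e{e}_p1n1_amplitude"] - gt["p1n1_amplitude"][f"e{e}"])
                < 1e-6
            )

    def test_n1_latency_dial(self):
        """Moving the generator's N1 latency to 18 ms moves the extracted
        latency to 18 ms within one sample period."""
        cfg = d.GeneratorConfig(
            n_animals=1, noise_sd=0.0, animal_variability_sd=0.0,
            electrode_shift_sd=0.0,
        )
        animal = _fixed_animal(
            cfg,
            lf=dict(p1_latency_ms=10.0, n1_latency_ms=18.0,
                    p1_amplitude_uv=60.0, n1_amplitude_uv=-120.0),
            hf=dict(rate_per_ms=0.0, amplitude_uv=0.0),
        )
        fv = extract_features(d.synthesize_trial(animal, "LPN", cfg, 9), seed=0)
        for e in range(1, 8):
            assert abs(fv.values[f"e{e}_n1_latency"] - 18.0) <= 1000.0 / cfg.sample_rate

    def test_no_burst_no_noise_yields_zero_peaks(self):
        cfg = d.GeneratorConfig(
            n_animals=1, noise_sd=0.0, animal_variability_sd=0.0,
            electrode_shift_sd=0.0,
        )
        animal = _fixed_animal(cfg, hf=dict(rate_per_ms=0.0, amplitude_uv=0.0))
        fv = extract_features(d.synthesize_trial(animal, "RSN", cfg, 2), seed=0)
        assert all(fv.values[f"e{e}_hf_peak_count"] == 0 for e in range(1, 8))

    def test_peak_count_recovers_injected_event_count(self):
        """Sparse single-lobe regime: the extracted count equals the
        realized Poisson event count in >= 95% of trials and its median
        equals the expected count exactly."""
        cfg = d.GeneratorConfig(
            n_animals=1, noise_sd=0.0, animal_variability_sd=0.0,
            electrode_shift_sd=0.0,
        )
        animal = _fixed_animal(
            cfg,
            lf=dict(p1_latency_ms=10.0, n1_latency_ms=20.0,
                    p1_amplitude_uv=5.0, n1_amplitude_uv=-10.0),
            hf=dict(rate_per_ms=0.05, amplitude_uv=1.5),
            uniform_gain=True,
        )
        gt = ground_truth_features(animal, "RPN", config=cfg)
        counts, matches = [], 0
        n_trials = 150
        for i in range(n_trials):
            seed = 15_000 + i
            fv = extract_features(
                d.synthesize_trial(animal, "RPN", cfg, seed), seed=i
            )
            per_e = [fv.values[f"e{e}_hf_peak_count"] for e in range(1, 8)]
            counts.append(per_e)
            n_true = np.random.default_rng(seed).poisson(0.05 * 40)
            matches += all(v == n_true for v in per_e)
        assert matches / n_trials >= 0.95
        np.testing.assert_allclose(
            np.median(counts, axis=0), gt["hf_peak_count"].to_numpy()
        )

    def test_integral_expectation_recovered_within_5pct(self):
        """Sparse high-SNR regime: the mean extracted HF integral over 400
        trials matches the closed-form expectation within 5% on every
        electrode."""
        cfg = d.GeneratorConfig(
            n_animals=1, noise_sd=0.0, animal_variability_sd=0.0,
            electrode_shift_sd=0.0,
        )
        animal = _fixed_animal(
            cfg,
            lf=dict(p1_latency_ms=10.0, n1_latency_ms=20.0,
                    p1_amplitude_uv=5.0, n1_amplitude_uv=-10.0),
            hf=dict(rate_per_ms=0.1, amplitude_uv=25.0),
            uniform_gain=True,
        )
        gt = ground_truth_features(animal, "RPN", config=cfg)["hf_integral"]
        vals = []
        for i in range(400):
            fv = extract_features(
                d.synthesize_trial(animal, "RPN", cfg, 21_000 + i), seed=i
            )
            vals.append([fv.values[f"e{e}_hf_integral"] for e in range(1, 8)])
        rel = np.abs(np.mean(vals, axis=0) - gt.to_numpy()) / gt.to_numpy()
        assert rel.max() < 0.05

    def test_lf_truth_recovered_at_low_noise(self):
        """With realistic low noise and no burst, per-electrode medians of
        the LF features match ground truth within 5%."""
        cfg = d.GeneratorConfig(
            n_animals=1, noise_sd=0.15, animal_variability_sd=0.0,
            electrode_shift_sd=0.0,
        )
        animal = _fixed_animal(cfg, hf=dict(rate_per_ms=0.0, amplitude_uv=0.0))
        gt = ground_truth_features(animal, "LSN", config=cfg)
        vals = {sf: [] for sf in ("n1_latency", "p1n1_slope", "p1n1_amplitude")}
        for i in range(100):
            fv = extract_features(
                d.synthesize_trial(animal, "LSN", cfg, 31_000 + i), seed=i
            )
            for sf in vals:
                vals[sf].append([fv.values[f"e{e}_{sf}"] for e in range(1, 8)])
        for sf, arr in vals.items():
            g = gt[sf].to_numpy()
            rel = np.abs(np.median(arr, axis=0) - g) / np.abs(g)
            assert rel.max() < 0.05, sf

    def test_trial_seed_is_deterministic_32bit(self):
        cfg = d.GeneratorConfig()
        s = trial_seed(cfg, 0, "RSN", 0)
        assert s == trial_seed(cfg, 0, "RSN", 0)
        assert 0 <= s < 2**32
        assert s != trial_seed(cfg, 0, "RSN", 1)
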