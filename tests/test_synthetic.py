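"""Generator law, determinism, contour templates, and ID corruption."""

import numpy as np
import pandas as pd
import pytest

from contactcalls import (
    ConfigurationError,
    ContourTemplate,
    GeneratorConfig,
    VARIANTS,
    corrupt_ids,
    default_templates,
    dtw_distance,
    simulate_contours,
    simulate_model_level,
)


class TestSimulateModelLevel:
    def test_degenerate_variances_give_zero_response(self):
        cfg = GeneratorConfig(
            n_cities=2, parks_per_city=2, inds_per_park=2, calls_per_ind=3,
            sigma_city=0, sigma_park=0, sigma_ind=0, sigma_obs=0, mu_city_sd=0, seed=1,
        )
        md, _ = simulate_model_level(cfg)
        assert np.all(md["y"] == 0.0)

    def test_zero_ind_and_obs_noise_means_identical_within_individual(self):
        cfg = GeneratorConfig(
            n_cities=2, parks_per_city=2, inds_per_park=2, calls_per_ind=4,
            sigma_ind=0, sigma_obs=0, seed=2,
        )
        md, truth = simulate_model_level(cfg)
        md["ind"] = md["call_id"].map(truth.call_to_individual)
        assert (md.groupby("ind")["y"].nunique() == 1).all()

    def test_city_effect_sd_matches_configuration(self):
        # Monte-Carlo check of the generator law on a 1000-city draw
        cfg = GeneratorConfig(
            n_cities=1000, parks_per_city=1, inds_per_park=1, calls_per_ind=1,
            sigma_city=0.4, sigma_park=0.2, sigma_ind=0.5, sigma_obs=0.5, seed=3,
        )
        _, truth = simulate_model_level(cfg)
        sd = np.std(list(truth.alpha_city.values()), ddof=1)
        assert sd == pytest.approx(0.4, rel=0.10)

    def test_all_level_sds_within_monte_carlo_error(self):
        cfg = GeneratorConfig(
            n_cities=50, parks_per_city=4, inds_per_park=5, calls_per_ind=1,
            sigma_city=0.4, sigma_park=0.2, sigma_ind=0.5, sigma_obs=0.5, seed=4,
        )
        _, truth = simulate_model_level(cfg)
        for values, sigma in (
            (truth.alpha_city.values(), 0.4),
            (truth.alpha_park.values(), 0.2),
            (truth.alpha_ind.values(), 0.5),
        ):
            vals = np.fromiter(values, float)
            centered = vals - (truth.mu_city if sigma == 0.4 else 0.0)
            mc_se = sigma / np.sqrt(2 * (len(vals) - 1))
            assert abs(np.std(centered, ddof=1) - sigma) < 3 * mc_se

    def test_seed_determinism(self):
        cfg = GeneratorConfig(n_cities=3, parks_per_city=2, inds_per_park=2, calls_per_ind=3, seed=9)
        md1, t1 = simulate_model_level(cfg)
        md2, t2 = simulate_model_level(cfg)
        pd.testing.assert_frame_equal(md1, md2)
        assert t1.alpha_city == t2.alpha_city

    def test_invalid_counts_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_cities=2, parks_per_city=0)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(sigma_city=-0.1)
        with pytest.raises(ConfigurationError):
            GeneratorConfig(variant_mix=(0.5, 0.5, 0, 0, 0, 0.1))

    def test_truth_covers_every_call_exactly_once(self):
        cfg = GeneratorConfig(n_cities=2, parks_per_city=3, inds_per_park=2, calls_per_ind=5, seed=5)
        md, truth = simulate_model_level(cfg)
        assert sorted(truth.call_to_individual) == sorted(md["call_id"])
        assert len(truth.call_to_individual) == len(md)


class TestSimulateContours:
    def test_zero_variance_gives_identical_contours_per_variant(self):
        cfg = GeneratorConfig(
            n_cities=2, parks_per_city=1, inds_per_park=2, calls_per_ind=3,
            sigma_city=0, sigma_park=0, sigma_ind=0, sigma_obs=0, mu_city_sd=0, seed=6,
        )
        traces, md, _ = simulate_contours(cfg, noise_hz=0.0)
        by_variant = {}
        for tr, variant in zip(traces, md["variant"]):
            by_variant.setdefault(variant, []).append(tr.f0)
        for f0s in by_variant.values():
            for f in f0s[1:]:
                np.testing.assert_array_equal(f, f0s[0])

    def test_disjoint_variants_separate_under_dtw(self):
        # two variants with disjoint frequency ranges: cross-variant DTW
        # distances strictly exceed within-variant ones on a 10-call draw
        templates = default_templates()
        templates["typical"] = ContourTemplate("typical", base_hz=1200.0, depth_hz=200.0)
        templates["four_triangle"] = ContourTemplate("four_triangle", base_hz=3000.0, depth_hz=200.0)
        cfg = GeneratorConfig(
            n_cities=1, parks_per_city=1, inds_per_park=1, calls_per_ind=10,
            sigma_city=0, sigma_park=0, sigma_ind=0, sigma_obs=0.1,
            variant_mix=(0.5, 0.5, 0, 0, 0, 0), seed=7,
        )
        traces, md, _ = simulate_contours(cfg, templates=templates, noise_hz=5.0)
        variants = md["variant"].to_numpy()
        within, cross = [], []
        for i in range(len(traces)):
            for j in range(i + 1, len(traces)):
                d = dtw_distance(traces[i].f0, traces[j].f0)
                (within if variants[i] == variants[j] else cross).append(d)
        assert min(cross) > max(within)

    def test_fully_labeled_metadata_has_no_missing_individuals(self):
        cfg = GeneratorConfig(
            n_cities=2, parks_per_city=1, inds_per_park=2, calls_per_ind=3,
            p_labeled=1.0, seed=8,
        )
        _, md, _ = simulate_contours(cfg)
        assert md["individual"].notna().all()

    def test_template_invariants(self):
        with pytest.raises(ConfigurationError):
            ContourTemplate("typical", base_hz=-100.0)
        with pytest.raises(ConfigurationError):
            ContourTemplate("typical", n_components=2)
        for name, tpl in default_templates().items():
            assert tpl.n_components >= 3
            assert np.all(tpl.render(0.001) > 0)


class TestCorruptIds:
    def _md(self, offsets, labels=None, recording="r1"):
        n = len(offsets)
        return pd.DataFrame(
            {
                "call_id": [f"c{i}" for i in range(n)],
                "city": "cityA",
                "park": "park1",
                "recording": recording,
                "offset_s": offsets,
                "individual": labels if labels is not None else [None] * n,
            }
        )

    def test_five_minute_window_shares_pseudo_id(self):
        md = corrupt_ids(self._md([0.0, 100.0, 250.0]))
        assert md["individual"].nunique() == 1

    def test_calls_beyond_window_get_distinct_ids(self):
        md = corrupt_ids(self._md([0.0, 400.0]))
        assert md["individual"].nunique() == 2

    def test_fully_labeled_input_unchanged(self):
        src = self._md([0.0, 100.0, 400.0], labels=["a", "b", "a"])
        out = corrupt_ids(src, mode="strip_unlabeled")
        pd.testing.assert_frame_equal(out, src)

    def test_split_creates_fresh_ids(self):
        src = self._md([10.0 * i for i in range(20)], labels=["a"] * 20)
        out = corrupt_ids(src, mode="split", rate=0.5, seed=1)
        assert out["individual"].nunique() > 1
        assert (out["individual"].str.startswith("a")).all()

    def test_merge_collapses_ids_within_recording(self):
        src = self._md([10.0 * i for i in range(12)], labels=["a", "b", "c", "d"] * 3)
        out = corrupt_ids(src, mode="merge", rate=1.0, seed=2)
        assert out["individual"].nunique() == 2

    def test_never_touches_city_or_park(self):
        src = self._md([0.0, 100.0, 400.0, 900.0])
        out = corrupt_ids(src, mode="merge", rate=1.0, seed=3)
        pd.testing.assert_series_equal(out["city"], src["city"])
        pd.testing.assert_series_equal(out["park"], src["park"])

    def test_deterministic_under_seed(self):
        src = self._md([50.0 * i for i in range(10)], labels=list("ababababab"))
        out1 = corrupt_ids(src, mode="split", rate=0.4, seed=11)
        out2 = corrupt_ids(src, mode="split", rate=0.4, seed=11)
        pd.testing.assert_frame_equal(out1, out2)

    def test_negative_offsets_rejected(self):
        with pytest.raises(ValueError):
            corrupt_ids(self._md([-1.0, 10.0]))
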