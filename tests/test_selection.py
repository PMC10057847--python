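"""In silico selection: correction fit, success probabilities, ranking."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import sensortune as st
from sensortune.hill import HillPosterior


def posterior_from_linear(g0, ginf, ec50, n):
    """Posterior whose draws are given explicitly on linear scales."""
    cols = np.column_stack([np.log10(g0), np.log10(ginf), np.log10(ec50), n])
    return HillPosterior(cols)


class TestEc50Correction:
    def test_identity_data_gives_identity_map(self, rng):
        x = rng.lognormal(3, 1, 30)
        m = st.fit_ec50_correction(x, x)
        assert m.slope == pytest.approx(1.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(m.apply(x), x)

    def test_two_point_line_by_hand(self):
        # (ln x, ln y) = (0, 0.5), (1, 1) -> slope 0.5, intercept 0.5
        m = st.fit_ec50_correction(
            [1.0, math.e], [math.exp(0.5), math.e]
        )
        assert m.slope == pytest.approx(0.5)
        assert m.intercept == pytest.approx(0.5)

    def test_shrinking_slope_compresses_extremes(self, rng):
        # cytometry higher than dataset at low EC50, lower at high EC50
        x = np.geomspace(1, 1000, 40)
        y = np.exp(1.5 + 0.6 * np.log(x))
        m = st.fit_ec50_correction(x, y)
        assert m.slope < 1
        assert m.apply(1.0) > 1.0  # low values raised
        assert m.apply(1e4) < 1e4  # high values lowered

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            st.fit_ec50_correction([5.0, 5.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            st.fit_ec50_correction([1.0], [1.0])


class TestSuccessProbability:
    def test_all_draws_inside(self):
        post = posterior_from_linear(
            np.full(10, 100.0), np.full(10, 16000.0), np.full(10, 30.0), np.full(10, 1.5)
        )
        spec = st.preset_specs("multiobjective", target_ec50=30.0, target_ginf=16000.0)
        assert st.success_probability(post, spec) == 1.0

    def test_no_draw_inside(self):
        post = posterior_from_linear(
            np.full(10, 100.0), np.full(10, 16000.0), np.full(10, 500.0), np.full(10, 1.5)
        )
        spec = st.preset_specs("multiobjective", target_ec50=30.0, target_ginf=16000.0)
        assert st.success_probability(post, spec) == 0.0

    def test_hand_constructed_fraction(self):
        ec50 = np.array([30, 30, 31, 29, 100, 100, 100, 100, 100, 100.0])
        post = posterior_from_linear(
            np.full(10, 100.0), np.full(10, 16000.0), ec50, np.full(10, 1.5)
        )
        spec = st.preset_specs("multiobjective", target_ec50=30.0, target_ginf=16000.0)
        assert st.success_probability(post, spec) == pytest.approx(0.4)

    def test_equals_draw_counting_oracle(self, rng):
        spec = st.Specification(
            ec50_target=50.0, ec50_fold_band=1.3, ginf_target=20000.0,
            ginf_fold_band=1.2, g0_band=(None, 2000.0),
        )
        corr = st.CorrectionModel(slope=0.9, intercept=0.2)
        for _ in range(20):
            S = int(rng.integers(5, 60))
            post = HillPosterior(
                np.column_stack([
                    rng.normal(2.3, 0.5, S),
                    rng.normal(4.2, 0.3, S),
                    rng.normal(1.7, 0.4, S),
                    rng.uniform(0.5, 3, S),
                ])
            )
            for c in (None, corr):
                count = 0
                for row in post.samples:
                    g0, ginf, ec50 = 10 ** row[0], 10 ** row[1], 10 ** row[2]
                    if c is not None:
                        ec50 = float(c.apply(ec50))
                    ok = (50 / 1.3 <= ec50 <= 50 * 1.3) and \
                         (20000 / 1.2 <= ginf <= 20000 * 1.2) and (g0 < 2000)
                    count += ok
                assert st.success_probability(post, spec, c) == pytest.approx(count / S)

    @settings(max_examples=40, derandomize=True)
    @given(
        band1=hst.floats(1.01, 2.0),
        widen=hst.floats(1.0, 2.0),
        seed=hst.integers(0, 10_000),
    )
    def test_widening_band_never_decreases_probability(self, band1, widen, seed):
        r = np.random.default_rng(seed)
        post = HillPosterior(
            np.column_stack([
                r.normal(2.2, 0.4, 40), r.normal(4.2, 0.3, 40),
                r.normal(1.5, 0.5, 40), r.uniform(0.5, 3, 40),
            ])
        )
        narrow = st.Specification(ec50_target=30.0, ec50_fold_band=band1)
        wide = st.Specification(ec50_target=30.0, ec50_fold_band=band1 * widen)
        assert st.success_probability(post, wide) >= st.success_probability(post, narrow)


class TestPresets:
    def test_multiobjective_bands_by_fold_arithmetic(self):
        spec = st.preset_specs("multiobjective", target_ec50=30.0, target_ginf=16000.0)
        lo, hi = spec.ec50_band()
        assert lo == pytest.approx(25.0) and hi == pytest.approx(36.0)
        lo, hi = spec.ginf_band()
        assert lo == pytest.approx(16000 / 1.1) and hi == pytest.approx(17600.0)
        assert spec.g0_band == (None, 2000.0)

    def test_inverted_band(self):
        spec = st.preset_specs("inverted", target_ec50=100.0)
        lo, hi = spec.ec50_band()
        assert lo == pytest.approx(100 / 1.5) and hi == pytest.approx(150.0)
        assert spec.ginf_upper == 12500.0
        assert spec.g0_band == (19200.0, 32500.0)
        assert spec.phenotype_class == "inverted"

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="multiobjective"):
            st.preset_specs("bogus")


class TestSelectVariants:
    def test_dominant_variant_ranked_first(self):
        # hand-built landscape: one variant whose whole posterior sits at
        # the target, two with posteriors straddling the band edge
        import pandas as pd

        rng = np.random.default_rng(0)
        S = 200
        rows = {
            "hero": np.tile([np.log10(158), np.log10(8000), 1.0, 1.5], (S, 1)),
            "edge": np.column_stack([
                np.full(S, np.log10(158)), np.full(S, np.log10(8000)),
                rng.normal(np.log10(11.5), 0.1, S), np.full(S, 1.5),
            ]),
            "edge2": np.column_stack([
                np.full(S, np.log10(158)), rng.normal(np.log10(8700), 0.05, S),
                np.full(S, 1.0), np.full(S, 1.5),
            ]),
        }
        samples = np.stack(list(rows.values()))
        mean, sd = samples.mean(axis=1), samples.std(axis=1, ddof=1)
        summaries = pd.DataFrame({
            "variant": list(rows),
            "mutation_codes": ["A5C", "A5C,S7R", "G9D"],
            "log_g0": mean[:, 0], "log_g0_err": sd[:, 0],
            "log_ginf": mean[:, 1], "log_ginf_err": sd[:, 1],
            "log_ec50": mean[:, 2], "log_ec50_err": sd[:, 2],
            "n": mean[:, 3], "n_err": sd[:, 3],
            "quality": 1.0,
        })
        land = st.Landscape(summaries, samples)
        spec = st.preset_specs("multiobjective", target_ec50=10.0, target_ginf=8000.0)
        res = st.select_variants(land, spec, top_k=3)
        assert res.variants[0] == "hero"
        assert res.entries[0][1] == 1.0

    def test_min_prob_filters_all(self, small_landscape):
        land, _ = small_landscape
        spec = st.preset_specs("multiobjective", target_ec50=100.0, target_ginf=25000.0)
        res = st.select_variants(land, spec, top_k=3, min_prob=1.01)
        assert len(res) == 0
        assert "min_prob" in res.status

    def test_top_k_respected(self, small_landscape):
        land, _ = small_landscape
        spec = st.preset_specs("multiobjective", target_ec50=100.0, target_ginf=25000.0)
        res = st.select_variants(land, spec, top_k=3, min_prob=0.0)
        assert len(res) == 3
        probs = [p for _, p in res.entries]
        assert probs == sorted(probs, reverse=True)

    def test_empty_landscape_warns(self, small_landscape):
        land, _ = small_landscape
        empty = land.subset(np.zeros(len(land), dtype=bool))
        spec = st.preset_specs("multiobjective", target_ec50=30.0, target_ginf=16000.0)
        res = st.select_variants(empty, spec)
        assert len(res) == 0 and "empty" in res.status

    def test_specification_validation(self):
        with pytest.raises(ValueError):
            st.Specification()  # no criteria
        with pytest.raises(ValueError):
            st.Specification(ec50_target=10.0, ec50_fold_band=0.8)
        with pytest.raises(ValueError):
            st.Specification(g0_band=(100.0, 50.0))
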