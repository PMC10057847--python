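"""Latent landscape model: encoding, training, prediction, effect reports."""

import numpy as np
import pytest

import sensortune as st
from sensortune.latent import encode_genotypes, predict_phenotype, train_latent_model


@pytest.fixture(scope="module")
def vocab():
    return [st.MutationCode.parse(c) for c in ("A10C", "S70R", "V80L", "V136E", "G200C")]


class TestEncoding:
    def test_wild_type_is_zero_row(self, vocab):
        X = encode_genotypes(st.Genotype.wild_type(), vocab)
        assert X.shape == (1, 5) and not X.any()

    def test_double_mutant_two_ones(self, vocab):
        g = st.Genotype((vocab[1], vocab[3]))
        X = encode_genotypes([g], vocab)
        assert X.sum() == 2
        assert X[0, 1] == 1 and X[0, 3] == 1

    def test_unknown_mutation_named_in_error(self, vocab):
        g = st.Genotype((st.MutationCode.parse("M254I"),))
        with pytest.raises(ValueError, match="M254I"):
            encode_genotypes([g], vocab)

    def test_row_sums_equal_mutation_counts(self, small_landscape):
        land, _ = small_landscape
        X = encode_genotypes(land, land.mutation_vocabulary)
        counts = np.array([len(g) for g in land.genotypes])
        assert np.array_equal(X.sum(axis=1), counts)


def _binary_design(rng, n, p, density=0.15):
    return (rng.random((n, p)) < density).astype(float)


class TestTraining:
    def test_additive_landscape_recovers_effects(self):
        rng = np.random.default_rng(1)
        p, n = 40, 2500
        X = _binary_design(rng, n, p)
        beta = rng.standard_normal(p) * 0.4
        y = X @ beta + rng.standard_normal(n) * 0.05
        Y = np.column_stack([y, 0.3 * y])
        m = train_latent_model(X, Y, K=1, seed=0)
        r = np.corrcoef(m.W[0], beta)[0, 1]
        assert abs(r) >= 0.95

    def test_planted_nonlinearity_beats_linear_baseline(self):
        rng = np.random.default_rng(2)
        p, n = 30, 3000
        X = _binary_design(rng, n, p)
        beta = np.abs(rng.standard_normal(p)) * 0.8
        z = X @ beta
        y = np.tanh(z - 2.0) + rng.standard_normal(n) * 0.03  # saturating trait
        Y = np.column_stack([y, y])
        tr, te = np.arange(n) < 2400, np.arange(n) >= 2400
        m = train_latent_model(X[tr], Y[tr], K=1, seed=0)
        Xe = X[te]
        pred = m.surface_mean(Xe @ m.W.T)[:, 0]
        # additive linear baseline (ridge)
        lam = 1.0
        B = np.linalg.solve(X[tr].T @ X[tr] + lam * np.eye(p), X[tr].T @ (Y[tr] - Y[tr].mean(0)))
        lin = Xe @ B[:, 0] + Y[tr].mean(0)[0]
        rmse_model = np.sqrt(np.mean((pred - Y[te, 0]) ** 2))
        rmse_lin = np.sqrt(np.mean((lin - Y[te, 0]) ** 2))
        assert rmse_model < rmse_lin

    def test_constant_phenotype_gives_null_model(self):
        rng = np.random.default_rng(3)
        X = _binary_design(rng, 500, 20)
        Y = np.full((500, 2), 3.0) + rng.standard_normal((500, 2)) * 1e-3
        m = train_latent_model(X, Y, K=2, seed=0)
        assert np.abs(m.W).max() < 0.01  # all latent effects ~ 0
        report = m.latent_effects_report()
        for k in range(2):
            assert not report[f"significant_{k}"].any()
        pred = predict_phenotype(m, st.Genotype.wild_type(), n_draws=100, seed=0)
        assert np.allclose(pred.mean, 3.0, atol=0.05)

    def test_configuration_errors(self):
        X = np.zeros((10, 4))
        Y = np.zeros((10, 2))
        with pytest.raises(ValueError):
            train_latent_model(X, Y, K=4)
        with pytest.raises(ValueError):
            train_latent_model(X, Y[:5], K=1)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(4)
        X = _binary_design(rng, 400, 15)
        Y = np.column_stack([X @ rng.standard_normal(15)] * 2)
        m1 = train_latent_model(X, Y, K=2, seed=7)
        m2 = train_latent_model(X, Y, K=2, seed=7)
        assert np.array_equal(m1.W, m2.W)


@pytest.fixture(scope="module")
def trained():
    rng = np.random.default_rng(5)
    X = _binary_design(rng, 1500, 25)
    beta = rng.standard_normal(25) * 0.5
    y = X @ beta + rng.standard_normal(1500) * 0.05
    return train_latent_model(X, np.column_stack([y, -y]), K=1, seed=0)


class TestPrediction:
    def test_embedding_additive_by_construction(self, trained):
        X = np.zeros((3, 25))
        X[0, 3] = 1
        X[1, 7] = 1
        X[2, 3] = X[2, 7] = 1
        Z = trained.embed(X)
        assert np.allclose(Z[2], Z[0] + Z[1])

    def test_single_draw_degenerate(self, trained):
        res = predict_phenotype(trained, st.Genotype.wild_type(), n_draws=1, seed=0)
        assert res.degenerate
        assert np.all(res.sd == 0)

    def test_mean_sd_recomputable_from_draws(self, trained):
        res = predict_phenotype(
            trained, st.Genotype.wild_type(), n_draws=50, seed=1, return_draws=True
        )
        assert res.draws.shape == (50, 1, 2)
        assert np.allclose(res.draws.mean(axis=0), res.mean)
        assert np.allclose(res.draws.std(axis=0, ddof=1), res.sd)

    def test_mc_error_shrinks_with_draws(self, trained):
        # spread of the predictive mean over repeats shrinks ~1/sqrt(draws)
        means10 = [
            predict_phenotype(trained, st.Genotype.wild_type(), n_draws=10, seed=s).mean[0, 0]
            for s in range(25)
        ]
        means1000 = [
            predict_phenotype(trained, st.Genotype.wild_type(), n_draws=1000, seed=s).mean[0, 0]
            for s in range(25)
        ]
        assert np.std(means1000) < np.std(means10)


class TestEffectsReport:
    def test_planted_large_effect_flagged_on_its_dimension(self):
        rng = np.random.default_rng(6)
        p, n = 20, 3000
        X = _binary_design(rng, n, p)
        beta1 = rng.standard_normal(p) * 0.5
        beta2 = np.zeros(p)
        beta2[13] = 3.0  # large effect on an independent second trait
        y1 = X @ beta1 + rng.standard_normal(n) * 0.05
        y2 = X @ beta2 + rng.standard_normal(n) * 0.05
        m = train_latent_model(X, np.column_stack([y1, y2]), K=2, seed=0)
        report = m.latent_effects_report()
        assert len(report) == p
        # the mutation must be significant on the dimension that carries
        # the second trait, whichever of the two that is after ordering
        sig = report.loc[13, [f"significant_{k}" for k in range(2)]]
        assert sig.any()

    def test_zero_effect_mutation_not_significant(self):
        rng = np.random.default_rng(7)
        p, n = 15, 2000
        X = _binary_design(rng, n, p)
        beta = rng.standard_normal(p) * 0.5
        beta[4] = 0.0
        y = X @ beta + rng.standard_normal(n) * 0.05
        m = train_latent_model(X, np.column_stack([y, y]), K=1, seed=0)
        report = m.latent_effects_report()
        assert not report.loc[4, "significant_0"]

    def test_propose_improvement_mutations(self):
        rng = np.random.default_rng(8)
        p, n = 20, 3000
        X = _binary_design(rng, n, p)
        beta2 = np.zeros(p)
        beta2[5] = 2.5
        beta2[9] = -2.0
        y1 = X @ (rng.standard_normal(p) * 0.5) + rng.standard_normal(n) * 0.05
        y2 = X @ beta2 + rng.standard_normal(n) * 0.05
        m = train_latent_model(X, np.column_stack([y1, y2]), K=2, seed=0)
        report = m.latent_effects_report()
        # find the dimension carrying trait 2 (largest |effect| for mutation 5)
        dim = int(np.argmax([abs(report.loc[5, f"effect_{k}"]) for k in range(2)]))
        sign = int(np.sign(report.loc[5, f"effect_{dim}"]))
        ranked = st.propose_improvement_mutations(m, dimension=dim, direction=sign, top_m=3)
        assert ranked[0][0] == report.loc[5, "mutation"]
        flipped = st.propose_improvement_mutations(m, dimension=dim, direction=-sign, top_m=3)
        assert all(np.sign(e) == -sign for _, e in flipped)
        with pytest.raises(ValueError):
            st.propose_improvement_mutations(m, dimension=5, direction=1)


class TestSerialization:
    def test_save_load_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        X = _binary_design(rng, 600, 12)
        y = X @ rng.standard_normal(12)
        m = train_latent_model(X, np.column_stack([y, y]), K=2, seed=0)
        m.save(tmp_path / "model.npz")
        back = st.LatentModel.load(tmp_path / "model.npz")
        assert np.allclose(back.W, m.W)
        g = st.Genotype.wild_type()
        a = predict_phenotype(m, g, n_draws=20, seed=3).mean
        b = predict_phenotype(back, g, n_draws=20, seed=3).mean
        assert np.allclose(a, b)
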