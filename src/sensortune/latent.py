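"""Interpretable latent model of a genotype-phenotype landscape.

The model follows the structure of interpretable landscape learners:
a one-hot genotype ``x in {0,1}^p`` is projected to a low-dimensional
latent space ``z = W x`` (so the latent effect of a multi-mutant is
exactly the sum of its mutations' latent vectors), and a smooth
nonlinear surface maps the latent coordinates to the phenotypes
``y = f(z)`` (here log10 EC50 and log10 Ginf).  ``K`` is small
(default 3) and much less than the mutation count ``p``.

The surface is a probabilistic polynomial basis expansion over the
latent space fitted with Bayesian ridge regression: it has a
differentiable mean, a Gaussian coefficient posterior that can be
sampled, and trains on 10^4 variants in seconds on one CPU.  ``W`` and
the surface are learned by alternating surface refits with L-BFGS
updates of ``W`` (analytic gradients).  Predictive uncertainty is
summarized from Monte Carlo draws of the surface posterior plus
observation noise (fifty draws by default).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.linear_model import BayesianRidge

from .landscape import Genotype, Landscape, MutationCode

__all__ = [
    "LatentModel",
    "PredictionResult",
    "encode_genotypes",
    "train_latent_model",
    "predict_phenotype",
    "latent_effects_report",
    "training_mask",
    "PHENOTYPES",
]

#: modeled phenotype columns, in order
PHENOTYPES = ("log_ec50", "log_ginf")


def _as_code(m) -> str:
    return str(m)


def encode_genotypes(
    genotypes: Landscape | Sequence[Genotype] | Genotype,
    vocabulary: Sequence[MutationCode | str],
) -> np.ndarray:
    """One-hot encode genotypes against a fixed mutation vocabulary.

    Column order follows ``vocabulary``; the wild type encodes to the
    zero row and row sums equal mutation counts.  Unknown mutations
    raise a ValueError naming the offender.
    """
    if isinstance(genotypes, Landscape):
        genotypes = genotypes.genotypes
    elif isinstance(genotypes, Genotype):
        genotypes = [genotypes]
    vocab = [_as_code(v) for v in vocabulary]
    index = {c: j for j, c in enumerate(vocab)}
    if len(index) != len(vocab):
        raise ValueError("vocabulary contains duplicate mutation codes")
    X = np.zeros((len(genotypes), len(vocab)))
    for i, g in enumerate(genotypes):
        for m in g:
            j = index.get(str(m))
            if j is None:
                raise ValueError(f"mutation {m} not in model vocabulary")
            X[i, j] = 1.0
    return X


# ---------------------------------------------------------------------------
# polynomial basis over the latent space


def _exponents(k: int, degree: int) -> np.ndarray:
    """All monomial exponent tuples over k variables with total degree <= degree."""
    exps = [
        e
        for e in itertools.product(range(degree + 1), repeat=k)
        if sum(e) <= degree
    ]
    exps.sort(key=lambda e: (sum(e), e))
    return np.array(exps, dtype=int)


def _basis(U: np.ndarray, exps: np.ndarray) -> np.ndarray:
    """Monomial design matrix: (n, m) from latent coords (n, k)."""
    return np.prod(U[:, None, :] ** exps[None, :, :], axis=2)


def _basis_grad(U: np.ndarray, exps: np.ndarray) -> np.ndarray:
    """d(basis)/dU: (n, m, k)."""
    n, k = U.shape
    m = exps.shape[0]
    out = np.zeros((n, m, k))
    for kk in range(k):
        e = exps.copy()
        coeff = e[:, kk].astype(float)
        e[:, kk] = np.maximum(e[:, kk] - 1, 0)
        out[:, :, kk] = coeff[None, :] * np.prod(U[:, None, :] ** e[None, :, :], axis=2)
    return out


@dataclass
class _Surface:
    """Bayesian-ridge polynomial surface for one phenotype."""

    coef_mean: np.ndarray  # (m,)
    coef_cov: np.ndarray  # (m, m)
    noise_var: float

    @classmethod
    def fit(cls, Phi: np.ndarray, y: np.ndarray) -> "_Surface":
        br = BayesianRidge(fit_intercept=False, compute_score=False)
        br.fit(Phi, y)
        return cls(
            coef_mean=br.coef_.copy(),
            coef_cov=br.sigma_.copy(),
            noise_var=1.0 / br.alpha_,
        )

    def mean(self, Phi: np.ndarray) -> np.ndarray:
        return Phi @ self.coef_mean

    def draw(self, Phi: np.ndarray, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """(n_draws, n) posterior-predictive draws (coefficients + noise)."""
        jitter = 1e-12 * np.trace(self.coef_cov) / self.coef_cov.shape[0]
        chol = np.linalg.cholesky(
            self.coef_cov + jitter * np.eye(self.coef_cov.shape[0])
        )
        coefs = self.coef_mean[None, :] + rng.standard_normal(
            (n_draws, self.coef_mean.size)
        ) @ chol.T
        draws = coefs @ Phi.T
        if n_draws > 1:
            draws += rng.standard_normal(draws.shape) * np.sqrt(self.noise_var)
        return draws


@dataclass
class PredictionResult:
    """Monte Carlo predictive summary: mean and SD per phenotype."""

    mean: np.ndarray  # (n, D)
    sd: np.ndarray  # (n, D)
    phenotypes: tuple[str, ...]
    n_draws: int
    draws: np.ndarray | None = None  # (n_draws, n, D) when requested

    @property
    def degenerate(self) -> bool:
        """True when a single draw was taken (SD is 0 by convention)."""
        return self.n_draws == 1

    def to_dataframe(self) -> pd.DataFrame:
        data = {}
        for d, name in enumerate(self.phenotypes):
            data[name] = self.mean[:, d]
            data[f"{name}_sd"] = self.sd[:, d]
        return pd.DataFrame(data)


@dataclass
class LatentModel:
    """Trained latent landscape model (W, surfaces, and metadata)."""

    vocabulary: list[str]
    W: np.ndarray  # (K, p) latent effect vectors per mutation (columns)
    W_se: np.ndarray  # (K, p) approximate standard errors
    z_scale: np.ndarray  # (K,) latent standardization used by the surfaces
    exponents: np.ndarray  # (m, K) monomial exponents
    surfaces: list[_Surface]
    y_mean: np.ndarray  # (D,) phenotype centering
    phenotypes: tuple[str, ...] = PHENOTYPES
    importance: np.ndarray | None = None  # (K,) explained-MSE ordering scores
    seed: int = 0

    @property
    def n_dims(self) -> int:
        return self.W.shape[0]

    @property
    def n_mutations(self) -> int:
        return self.W.shape[1]

    def embed(self, X: np.ndarray) -> np.ndarray:
        """Latent coordinates z = W x (additive across mutations)."""
        return X @ self.W.T

    def surface_mean(self, Z: np.ndarray) -> np.ndarray:
        U = Z / self.z_scale
        Phi = _basis(U, self.exponents)
        return np.column_stack([s.mean(Phi) for s in self.surfaces]) + self.y_mean

    def latent_effects_report(self) -> pd.DataFrame:
        """Per-mutation latent effects with significance flags.

        One row per vocabulary mutation; an effect is flagged
        significant on a dimension when |effect| > 2 x its standard
        error and the dimension itself is informative (its
        contribution to the training fit exceeds the observation-noise
        floor — a guard against post-selection artifacts on null
        dimensions).
        """
        noise_floor = 0.5 * sum(s.noise_var for s in self.surfaces)
        data = {"mutation": list(self.vocabulary)}
        for k in range(self.n_dims):
            informative = (
                True if self.importance is None else self.importance[k] > noise_floor
            )
            data[f"effect_{k}"] = self.W[k]
            data[f"se_{k}"] = self.W_se[k]
            data[f"significant_{k}"] = (
                np.abs(self.W[k]) > 2.0 * self.W_se[k]
            ) & informative
        return pd.DataFrame(data)

    # -- serialization -------------------------------------------------
    def save(self, path) -> None:
        arrays = {
            "W": self.W,
            "W_se": self.W_se,
            "z_scale": self.z_scale,
            "exponents": self.exponents,
            "y_mean": self.y_mean,
            "vocabulary": np.array(self.vocabulary, dtype=object),
            "phenotypes": np.array(self.phenotypes, dtype=object),
            "importance": self.importance if self.importance is not None else np.zeros(0),
            "seed": np.array([self.seed]),
            "noise_var": np.array([s.noise_var for s in self.surfaces]),
        }
        for d, s in enumerate(self.surfaces):
            arrays[f"coef_mean_{d}"] = s.coef_mean
            arrays[f"coef_cov_{d}"] = s.coef_cov
        np.savez(path, **{k: np.asarray(v) for k, v in arrays.items()})

    @classmethod
    def load(cls, path) -> "LatentModel":
        with np.load(path, allow_pickle=True) as f:
            noise = f["noise_var"]
            surfaces = [
                _Surface(f[f"coef_mean_{d}"], f[f"coef_cov_{d}"], float(noise[d]))
                for d in range(noise.size)
            ]
            return cls(
                vocabulary=[str(v) for v in f["vocabulary"]],
                W=f["W"],
                W_se=f["W_se"],
                z_scale=f["z_scale"],
                exponents=f["exponents"],
                surfaces=surfaces,
                y_mean=f["y_mean"],
                phenotypes=tuple(str(p) for p in f["phenotypes"]),
                importance=f["importance"] if f["importance"].size else None,
                seed=int(f["seed"][0]),
            )


def training_mask(landscape: Landscape) -> np.ndarray:
    """Rows of a landscape suitable for phenotype modeling.

    Excludes inverted records (posterior-median Ginf < G0) and records
    whose EC50 is effectively unidentified (flat dynamic range or very
    wide EC50 posterior), mirroring the practice of training only on
    well-defined, non-inverted dose-response fits.
    """
    med = np.median(landscape.samples, axis=1)
    dyn = med[:, 1] - med[:, 0]  # decades of dynamic range
    ec50_err = landscape.summaries["log_ec50_err"].to_numpy()
    return (dyn > 0.2) & (ec50_err < 0.3)


def train_latent_model(
    X: np.ndarray,
    Y: np.ndarray,
    K: int = 3,
    seed: int = 0,
    degree: int = 3,
    n_rounds: int = 20,
    tol: float = 1e-7,
    w_penalty: float = 1e-3,
    phenotypes: tuple[str, ...] = PHENOTYPES,
) -> LatentModel:
    """Learn the embedding W and the nonlinear surface from encoded data.

    ``X`` is the (n, p) one-hot genotype matrix, ``Y`` the (n, D)
    phenotype matrix (log10 scales).  Training alternates Bayesian
    ridge surface fits over the current latent coordinates with L-BFGS
    updates of W (analytic gradients), starting from a ridge-regression
    initialization, until the training loss stops improving (relative
    change below ``tol``) or ``n_rounds`` alternations.  Latent
    dimensions are ordered most-significant first by their contribution
    to training fit; deterministic for a given seed.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with aligned rows")
    if not np.all(np.isfinite(Y)):
        raise ValueError("Y must be finite (drop ill-defined fits upstream)")
    n, p = X.shape
    D = Y.shape[1]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= p:
        raise ValueError(f"K={K} must be smaller than the mutation count p={p}")
    if K > n:
        raise ValueError("more latent dimensions than training variants")

    rng = np.random.default_rng(seed)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    exps = _exponents(K, degree)

    # ridge initialization of the embedding
    lam = 1.0
    B = np.linalg.solve(X.T @ X + lam * np.eye(p), X.T @ Yc)  # (p, D)
    W = np.zeros((K, p))
    for k in range(min(K, D)):
        W[k] = B[:, k]
    for k in range(D, K):
        W[k] = rng.standard_normal(p) * 0.05

    def z_scale_of(Z):
        return np.maximum(Z.std(axis=0), 1e-6)

    def surfaces_for(W):
        Z = X @ W.T
        s = z_scale_of(Z)
        Phi = _basis(Z / s, exps)
        return s, [_Surface.fit(Phi, Yc[:, d]) for d in range(D)]

    def loss_and_grad(w_flat, s, surfaces):
        W_ = w_flat.reshape(K, p)
        Z = X @ W_.T
        U = Z / s
        Phi = _basis(U, exps)
        dPhi = _basis_grad(U, exps)  # (n, m, K)
        loss = w_penalty * float(np.sum(W_ ** 2))
        dU = np.zeros((n, K))
        for d, surf in enumerate(surfaces):
            r = Phi @ surf.coef_mean - Yc[:, d]
            loss += float(r @ r) / n
            dU += (2.0 / n) * r[:, None] * np.einsum("nmk,m->nk", dPhi, surf.coef_mean)
        dZ = dU / s
        grad = dZ.T @ X + 2.0 * w_penalty * W_
        return loss, grad.ravel()

    s, surfaces = surfaces_for(W)
    prev_loss = np.inf
    for _ in range(n_rounds):
        res = minimize(
            loss_and_grad,
            W.ravel(),
            args=(s, surfaces),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 60},
        )
        W = res.x.reshape(K, p)
        s, surfaces = surfaces_for(W)
        if prev_loss - res.fun < tol * max(abs(prev_loss), 1.0):
            break
        prev_loss = res.fun

    # order dimensions by contribution to training fit
    Z = X @ W.T
    U = Z / s
    Phi = _basis(U, exps)
    full_mse = sum(
        float(np.mean((Phi @ surf.coef_mean - Yc[:, d]) ** 2))
        for d, surf in enumerate(surfaces)
    )
    importance = np.zeros(K)
    for k in range(K):
        U0 = U.copy()
        U0[:, k] = 0.0
        Phi0 = _basis(U0, exps)
        mse_k = sum(
            float(np.mean((Phi0 @ surf.coef_mean - Yc[:, d]) ** 2))
            for d, surf in enumerate(surfaces)
        )
        importance[k] = mse_k - full_mse
    order = np.argsort(-importance)
    W = W[order]
    importance = importance[order]
    s, surfaces = surfaces_for(W)

    # Gauss-Newton standard errors for the entries of W, from the full
    # (K*p x K*p) observed-information approximation
    Z = X @ W.T
    U = Z / s
    dPhi = _basis_grad(U, exps)
    info = np.zeros((K * p, K * p))
    for d, surf in enumerate(surfaces):
        g = np.einsum("nmk,m->nk", dPhi, surf.coef_mean) / s  # (n, K) d f_d / d z
        J = np.einsum("nk,nj->nkj", g, X).reshape(X.shape[0], K * p)
        info += J.T @ J / max(surf.noise_var, 1e-12)
    jitter = 1e-9 * max(float(np.max(np.diag(info))), 1.0)
    cov = np.linalg.pinv(info + jitter * np.eye(K * p))
    W_se = np.sqrt(np.maximum(np.diag(cov), 0.0)).reshape(K, p)

    return LatentModel(
        vocabulary=[str(v) for v in _vocab_placeholder(p)],
        W=W,
        W_se=W_se,
        z_scale=s,
        exponents=exps,
        surfaces=surfaces,
        y_mean=y_mean,
        phenotypes=phenotypes,
        importance=importance,
        seed=seed,
    )


def _vocab_placeholder(p: int) -> list[str]:
    # train_latent_model works on encoded matrices; callers that have a
    # vocabulary attach it afterwards (see train_on_landscape).
    return [f"m{j}" for j in range(p)]


def train_on_landscape(
    landscape: Landscape,
    K: int = 3,
    seed: int = 0,
    degree: int = 3,
    n_rounds: int = 4,
) -> LatentModel:
    """Convenience wrapper: encode, filter ill-defined records, train."""
    vocab = landscape.mutation_vocabulary
    X = encode_genotypes(landscape, vocab)
    Y = landscape.summaries[["log_ec50", "log_ginf"]].to_numpy(float)
    mask = training_mask(landscape)
    model = train_latent_model(
        X[mask], Y[mask], K=K, seed=seed, degree=degree, n_rounds=n_rounds
    )
    model.vocabulary = [str(v) for v in vocab]
    return model


def predict_phenotype(
    model: LatentModel,
    genotypes: Landscape | Sequence[Genotype] | Genotype,
    n_draws: int = 50,
    seed: int = 0,
    return_draws: bool = False,
) -> PredictionResult:
    """Monte Carlo predictive mean and SD for the given genotype(s).

    Each draw samples the surface-coefficient posterior and adds
    observation noise; with ``n_draws=1`` the SD is zero by convention
    and the result is flagged degenerate.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    X = encode_genotypes(genotypes, model.vocabulary)
    rng = np.random.default_rng(seed)
    U = model.embed(X) / model.z_scale
    Phi = _basis(U, model.exponents)
    all_draws = np.empty((n_draws, X.shape[0], len(model.surfaces)))
    for d, surf in enumerate(model.surfaces):
        all_draws[:, :, d] = surf.draw(Phi, n_draws, rng) + model.y_mean[d]
    mean = all_draws.mean(axis=0)
    sd = (
        all_draws.std(axis=0, ddof=1)
        if n_draws > 1
        else np.zeros_like(mean)
    )
    return PredictionResult(
        mean=mean,
        sd=sd,
        phenotypes=model.phenotypes,
        n_draws=n_draws,
        draws=all_draws if return_draws else None,
    )


def latent_effects_report(model: LatentModel) -> pd.DataFrame:
    """Table of per-mutation latent effects and significance flags."""
    return model.latent_effects_report()
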