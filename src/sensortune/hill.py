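"""Hill dose-response model and Bayesian parameter estimation.

The dose-response curve of a genetic sensor is modeled with the Hill
equation

    G(L) = G0 + (Ginf - G0) / (1 + (EC50 / L)^n),

where ``L`` is the ligand (inducer) concentration in umol/L, ``G0`` the
basal output, ``Ginf`` the saturating output (both in MEF, molecules of
equivalent fluorescein), ``EC50`` the concentration of half-maximal
response and ``n`` the Hill coefficient.  An *inverted* sensor has
``Ginf < G0``.

Parameters are estimated from calibrated flow-cytometry geometric means
by MCMC sampling of a lognormal-noise likelihood, with posterior draws
stored on the scales used throughout the package: base-10 logarithms of
G0, Ginf and EC50, and linear Hill coefficient n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "HillParams",
    "HillPosterior",
    "DoseResponseCurve",
    "PriorConfig",
    "hill_response",
    "filter_outlier_replicates",
    "fit_hill",
    "geometric_stats",
]

#: column order of posterior-sample matrices throughout the package
SAMPLE_COLUMNS = ("log_g0", "log_ginf", "log_ec50", "n")

OUTLIER_FOLD = 1.25  # replicate Ginf disagreement threshold (fold)


@dataclass(frozen=True)
class HillParams:
    """The four Hill-equation parameters on natural (linear) scales."""

    g0: float
    ginf: float
    ec50: float
    n: float

    def __post_init__(self) -> None:
        for name in ("g0", "ginf", "ec50", "n"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"HillParams.{name} must be finite and > 0, got {v!r}")

    @property
    def inverted(self) -> bool:
        """True when output decreases with ligand (Ginf < G0)."""
        return self.ginf < self.g0

    def as_log_array(self) -> np.ndarray:
        """(log10 G0, log10 Ginf, log10 EC50, n)."""
        return np.array(
            [math.log10(self.g0), math.log10(self.ginf), math.log10(self.ec50), self.n]
        )

    @classmethod
    def from_log_array(cls, arr: Sequence[float]) -> "HillParams":
        lg0, lginf, lec50, n = arr
        return cls(10.0 ** lg0, 10.0 ** lginf, 10.0 ** lec50, float(n))


def hill_response(params: HillParams, L) -> np.ndarray | float:
    """Evaluate the Hill curve G(L) at ligand concentration(s) ``L`` (umol/L).

    ``L = 0`` is handled as the analytic limit ``G0``.
    """
    L = np.asarray(L, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentration must be non-negative")
    scalar = L.ndim == 0
    L = np.atleast_1d(L)
    out = np.full(L.shape, params.g0, dtype=float)
    pos = L > 0
    ratio = (params.ec50 / L[pos]) ** params.n
    out[pos] = params.g0 + (params.ginf - params.g0) / (1.0 + ratio)
    return float(out[0]) if scalar else out


def _hill_curve_log(theta: np.ndarray, L: np.ndarray) -> np.ndarray:
    """ln G(L) for theta = (log10 g0, log10 ginf, log10 ec50, n); L > 0 mask-safe."""
    g0 = 10.0 ** theta[0]
    ginf = 10.0 ** theta[1]
    ec50 = 10.0 ** theta[2]
    n = theta[3]
    out = np.full(L.shape, g0)
    pos = L > 0
    out[pos] = g0 + (ginf - g0) / (1.0 + (ec50 / L[pos]) ** n)
    return np.log(out)


@dataclass(frozen=True)
class DoseResponseCurve:
    """One replicate's dose-response measurements.

    points: (ligand umol/L, geometric-mean MEF, geometric-mean error MEF)
    replicate_id: opaque label (e.g. clone/date-plate/row).
    """

    ligand: np.ndarray
    geo_mean: np.ndarray
    geo_mean_err: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        lig = np.asarray(self.ligand, dtype=float)
        gm = np.asarray(self.geo_mean, dtype=float)
        ge = np.asarray(self.geo_mean_err, dtype=float)
        if not (lig.shape == gm.shape == ge.shape):
            raise ValueError("ligand, geo_mean, geo_mean_err must have equal length")
        if np.any(lig < 0):
            raise ValueError("ligand concentrations must be non-negative")
        if np.any(gm <= 0):
            raise ValueError("geometric means must be strictly positive")
        if np.any(ge < 0):
            raise ValueError("geometric-mean errors must be non-negative")
        object.__setattr__(self, "ligand", lig)
        object.__setattr__(self, "geo_mean", gm)
        object.__setattr__(self, "geo_mean_err", ge)


@dataclass
class HillPosterior:
    """Posterior draws over Hill parameters.

    ``samples`` has one row per draw and columns
    (log10 G0, log10 Ginf, log10 EC50, n) — the convention of the
    landscape summary tables.  ``converged`` is False when the sampler's
    split R-hat diagnostic exceeded its threshold.
    """

    samples: np.ndarray
    converged: bool = True
    rhat: float = float("nan")

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 4 or s.shape[0] < 1:
            raise ValueError("samples must be an (S, 4) array with S >= 1")
        if not np.all(np.isfinite(s)):
            raise ValueError("posterior samples must be finite")
        if np.any(s[:, 3] <= 0):
            raise ValueError("Hill-coefficient draws must be positive")
        self.samples = s

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def summary(self) -> dict[str, tuple[float, float]]:
        """Per-parameter posterior (mean, SD) on the stored scales."""
        mean = self.samples.mean(axis=0)
        sd = self.samples.std(axis=0, ddof=1) if self.n_samples > 1 else np.zeros(4)
        return {c: (float(m), float(s)) for c, m, s in zip(SAMPLE_COLUMNS, mean, sd)}

    def median_params(self) -> HillParams:
        """Posterior-median point estimate on linear scales."""
        med = np.median(self.samples, axis=0)
        return HillParams.from_log_array(med)

    def param_draws(self) -> Iterable[HillParams]:
        for row in self.samples:
            yield HillParams.from_log_array(row)

    @classmethod
    def from_point(cls, params: HillParams, n_samples: int = 1) -> "HillPosterior":
        """Degenerate posterior concentrated on a single parameter set."""
        row = params.as_log_array()
        return cls(np.tile(row, (n_samples, 1)))


def geometric_stats(values: Sequence[float]) -> tuple[float, float]:
    """Geometric mean and geometric SD (as a fold factor >= 1).

    gmean = exp(mean(ln v)); gSD = exp(sample SD of ln v).  A single
    value has gSD 1.0 by convention.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one value")
    if np.any(v <= 0) or not np.all(np.isfinite(v)):
        raise ValueError("geometric statistics require positive finite values")
    logs = np.log(v)
    gmean = float(np.exp(logs.mean()))
    gsd = 1.0 if v.size == 1 else float(np.exp(logs.std(ddof=1)))
    return gmean, gsd


def filter_outlier_replicates(
    ginf_by_replicate: Mapping[str, float] | Sequence[tuple[str, float]],
) -> tuple[list[str], list[str]]:
    """Split replicates into kept / dropped by the 1.25-fold Ginf rule.

    A replicate is an outlier when its saturating output differs from the
    consensus of the kept replicates by more than 1.25-fold in either
    direction.  Consensus is the geometric median (median of log Ginf),
    recomputed and re-applied until the kept set is stable, which makes
    the filter idempotent.  At least one replicate (the one closest to
    consensus) is always kept.
    """
    items = list(ginf_by_replicate.items()) if isinstance(ginf_by_replicate, Mapping) else list(ginf_by_replicate)
    if not items:
        raise ValueError("need at least one replicate")
    labels = [lab for lab, _ in items]
    vals = np.array([v for _, v in items], dtype=float)
    if np.any(vals <= 0) or not np.all(np.isfinite(vals)):
        raise ValueError("Ginf estimates must be positive and finite")
    logs = np.log(vals)
    thresh = math.log(OUTLIER_FOLD)

    kept = np.ones(len(items), dtype=bool)
    for _ in range(len(items) + 1):
        consensus = np.median(logs[kept])
        dev = np.abs(logs - consensus)
        new_kept = dev <= thresh
        if not new_kept.any():
            new_kept = dev == dev.min()
        if np.array_equal(new_kept, kept):
            break
        kept = new_kept
    kept_labels = [lab for lab, k in zip(labels, kept) if k]
    dropped_labels = [lab for lab, k in zip(labels, kept) if not k]
    return kept_labels, dropped_labels


# ---------------------------------------------------------------------------
# Bayesian fitting


@dataclass
class PriorConfig:
    """Weakly-informative priors for the Hill fit.

    G0 and Ginf get lognormal priors centered on the low/high end of the
    observed data (SD in decades); EC50 a log-uniform prior over a range
    wide enough to cover all phenotypes seen in practice; n a normal
    prior truncated to (0, n_max].
    """

    log_ec50_range: tuple[float, float] = (-1.0, 4.0)  # log10 umol/L
    log_g_sd: float = 1.0  # decades
    n_loc: float = 1.5
    n_scale: float = 1.0
    n_max: float = 6.0
    noise_floor: float = 0.02  # minimum relative (lognormal) noise scale


def _pool_curves(curves: Sequence[DoseResponseCurve]):
    L = np.concatenate([c.ligand for c in curves])
    gm = np.concatenate([c.geo_mean for c in curves])
    ge = np.concatenate([c.geo_mean_err for c in curves])
    return L, gm, ge


def _log_prob_factory(L, log_gm, sigma, prior: PriorConfig, lg_lo: float, lg_hi: float):
    lo, hi = prior.log_ec50_range
    inv_var = 1.0 / sigma ** 2

    def log_prob(theta: np.ndarray) -> float:
        lg0, lginf, lec50, n = theta
        if not (lo <= lec50 <= hi) or not (0.0 < n <= prior.n_max):
            return -np.inf
        lp = (
            -0.5 * ((lg0 - lg_lo) / prior.log_g_sd) ** 2
            - 0.5 * ((lginf - lg_hi) / prior.log_g_sd) ** 2
            - 0.5 * ((n - prior.n_loc) / prior.n_scale) ** 2
        )
        resid = log_gm - _hill_curve_log(theta, L)
        return lp - 0.5 * float(np.sum(resid ** 2 * inv_var))

    return log_prob


def fit_hill(
    curves: DoseResponseCurve | Sequence[DoseResponseCurve],
    priors: PriorConfig | None = None,
    seed: int = 0,
    n_walkers: int = 32,
    n_burn: int = 800,
    n_steps: int = 600,
    thin: int = 16,
) -> HillPosterior:
    """Fit the Hill equation to one or more replicate curves by MCMC.

    Replicates are pooled (outlier replicates should be removed first
    with :func:`filter_outlier_replicates`).  The likelihood is
    lognormal with per-point relative scale
    ``max(geo_mean_err / geo_mean, noise_floor)``.  Sampling is an
    affine-invariant ensemble (emcee); the result records a split-R-hat
    convergence diagnostic and is flagged, not rejected, on failure.
    Deterministic for a given seed.
    """
    import emcee

    if priors is None:
        priors = PriorConfig()
    if isinstance(curves, DoseResponseCurve):
        curves = [curves]
    if not curves:
        raise ValueError("need at least one dose-response curve")
    L, gm, ge = _pool_curves(curves)
    if np.unique(L).size < 2:
        raise ValueError("unidentifiable model: need at least 2 distinct ligand levels")

    log_gm = np.log(gm)
    sigma = np.maximum(ge / gm, priors.noise_floor)
    lg_lo = math.log10(gm.min())
    lg_hi = math.log10(gm.max())
    log_prob = _log_prob_factory(L, log_gm, sigma, priors, lg_lo, lg_hi)

    rng = np.random.default_rng(seed)
    pos_L = L[L > 0]
    ec50_guess = float(np.exp(np.mean(np.log(pos_L)))) if pos_L.size else 10.0
    lo, hi = priors.log_ec50_range
    guess = np.array([lg_lo, lg_hi, np.clip(math.log10(ec50_guess), lo, hi), 1.2])
    p0 = guess + rng.normal(scale=[0.15, 0.15, 0.3, 0.15], size=(n_walkers, 4))
    p0[:, 2] = np.clip(p0[:, 2], lo + 1e-6, hi - 1e-6)
    p0[:, 3] = np.clip(p0[:, 3], 0.05, priors.n_max - 1e-6)

    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    sampler = emcee.EnsembleSampler(n_walkers, 4, log_prob, moves=moves)
    sampler._random = np.random.RandomState(rng.integers(2 ** 31 - 1))
    state = sampler.run_mcmc(p0, n_burn, progress=False)
    sampler.reset()
    sampler.run_mcmc(state, n_steps, progress=False)

    chain = sampler.get_chain()  # (steps, walkers, 4)
    rhat = _max_split_rhat(chain)
    flat = sampler.get_chain(flat=True, thin=thin)
    return HillPosterior(flat, converged=bool(rhat <= 1.05), rhat=float(rhat))


def _max_split_rhat(chain: np.ndarray) -> float:
    """Max split-R-hat across the four parameters; chain is (steps, walkers, dim)."""
    import arviz as az

    # arviz expects (chains, draws); treat each walker as a chain
    arr = np.moveaxis(chain, 0, 1)  # (walkers, steps, dim)
    rhats = [float(az.rhat(np.ascontiguousarray(arr[:, :, d]))) for d in range(chain.shape[2])]
    return max(rhats)
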