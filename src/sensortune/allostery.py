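"""Thermodynamic (MWC-style) model of an allosteric repressor.

The repressor switches between an active state (binds the operator,
represses output) and an inactive state.  Ligand binds the two states
with different dissociation constants ``K_A`` (active) and ``K_I``
(inactive); two ligand-binding sites per functional repressor.  The
probability of the active state at ligand concentration ``c`` is

    p_act(c) = (1 + c/K_A)^2 / [ (1 + c/K_A)^2 + exp(-dEps_AI) (1 + c/K_I)^2 ],

and the fold-change in output relative to an unrepressed promoter is

    fold_change(c) = 1 / [ 1 + p_act(c) * (R / N_NS) * exp(-dEps_RA) ],

with ``dEps_RA`` the repressor-operator binding free energy, ``dEps_AI``
the log allosteric constant (both in units of kT), ``R`` the repressor
copy number and ``N_NS`` the number of nonspecific genomic sites.  The
observable output is ``G(c) = G_max * fold_change(c)``.

For this functional form G(c) is monotone in c, with direction set by
the sign of ``K_A - K_I``: the usual induction curve for ``K_A > K_I``
and an inverted (output falls with ligand) curve for ``K_A < K_I``.
Each such curve maps exactly onto Hill parameters, which is how the
synthetic-landscape generator turns latent mutational effects into
phenotypes, and how biophysical intuition (e.g. "reduce K_A to lower
both EC50 and Ginf of an inverted sensor") is turned into candidate
mutations via a trained latent model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .hill import HillParams

__all__ = [
    "BiophysParams",
    "WT_BIOPHYS",
    "fold_change",
    "biophys_to_hill",
    "propose_improvement_mutations",
]


@dataclass(frozen=True)
class BiophysParams:
    """Biophysical parameters of the allosteric repressor.

    Units: free energies in kT; dissociation constants in umol/L;
    ``r`` (repressor copies) and ``n_ns`` (nonspecific sites)
    dimensionless counts; ``g_max`` the unrepressed output in MEF.
    """

    eps_ra: float  # operator binding free energy, kT (negative = strong)
    eps_ai: float  # log allosteric constant, kT
    k_a: float  # active-state ligand dissociation constant, umol/L
    k_i: float  # inactive-state ligand dissociation constant, umol/L
    r: float = 500.0
    n_ns: float = 4.6e6
    g_max: float = 30600.0

    def __post_init__(self) -> None:
        for name in ("k_a", "k_i", "r", "n_ns", "g_max"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"BiophysParams.{name} must be finite and > 0")
        for name in ("eps_ra", "eps_ai"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"BiophysParams.{name} must be finite")

    def replace(self, **kw) -> "BiophysParams":
        return replace(self, **kw)


#: Wild-type-like anchor: strong repression without ligand (G0 ~ 158 MEF),
#: ~150-fold dynamic range, EC50 in the hundred-umol/L range.
WT_BIOPHYS = BiophysParams(
    eps_ra=-14.4, eps_ai=4.5, k_a=139.0, k_i=0.53, r=500.0, n_ns=4.6e6, g_max=30600.0
)


def _p_act(c, k_a, k_i, eps_ai):
    a = (1.0 + c / k_a) ** 2
    i = (1.0 + c / k_i) ** 2
    return a / (a + np.exp(-eps_ai) * i)


def fold_change(bp: BiophysParams, c) -> np.ndarray | float:
    """Repression fold-change in (0, 1] at ligand concentration(s) ``c``."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("ligand concentration must be non-negative")
    scalar = c.ndim == 0
    rho = (bp.r / bp.n_ns) * np.exp(-bp.eps_ra)
    fc = 1.0 / (1.0 + _p_act(c, bp.k_a, bp.k_i, bp.eps_ai) * rho)
    return float(fc) if scalar else fc


def _hill_from_arrays(eps_ra, eps_ai, k_a, k_i, r, n_ns, g_max):
    """Vectorized biophysics -> (g0, ginf, ec50, n, well_defined).

    ``well_defined`` is False where the curve is (numerically) flat so
    EC50/n are meaningless; those entries carry placeholder values.
    """
    eps_ra, eps_ai, k_a, k_i, r, n_ns, g_max = np.broadcast_arrays(
        *map(np.atleast_1d, (eps_ra, eps_ai, k_a, k_i, r, n_ns, g_max))
    )
    rho = (r / n_ns) * np.exp(-eps_ra)
    p0 = 1.0 / (1.0 + np.exp(-eps_ai))
    pinf = 1.0 / (1.0 + np.exp(-eps_ai) * (k_a / k_i) ** 2)
    g0 = g_max / (1.0 + p0 * rho)
    ginf = g_max / (1.0 + pinf * rho)

    with np.errstate(divide="ignore", invalid="ignore"):
        # midpoint output -> required activity -> required state ratio h
        g_mid = 0.5 * (g0 + ginf)
        p_mid = (g_max / g_mid - 1.0) / rho
        h2 = (1.0 / p_mid - 1.0) * np.exp(eps_ai)
        s = np.sqrt(np.maximum(h2, 0.0))
        # solve (1 + c/K_I) / (1 + c/K_A) = s for c
        ec50 = (s - 1.0) / (1.0 / k_i - s / k_a)

    well = np.abs(np.log(ginf / g0)) > 1e-3
    well &= np.isfinite(ec50) & (ec50 > 0)
    ec50 = np.where(well, ec50, 100.0)

    # Hill coefficient from the log-slope at EC50:
    # n = 4 * (dG/dln c at EC50) / (Ginf - G0)
    d = 1e-4
    c_hi = ec50 * np.exp(d)
    c_lo = ec50 * np.exp(-d)
    g_hi = g_max / (1.0 + _p_act(c_hi, k_a, k_i, eps_ai) * rho)
    g_lo = g_max / (1.0 + _p_act(c_lo, k_a, k_i, eps_ai) * rho)
    with np.errstate(divide="ignore", invalid="ignore"):
        n = 4.0 * (g_hi - g_lo) / (2.0 * d) / (ginf - g0)
    n = np.where(well, n, 1.0)
    n = np.clip(n, 1e-3, None)
    return g0, ginf, ec50, n, well


def biophys_to_hill(bp: BiophysParams) -> HillParams:
    """Map biophysical parameters to the equivalent Hill parameters.

    G0 and Ginf are the closed-form c -> 0 and c -> infinity limits;
    EC50 is the (unique, closed-form) concentration where the output is
    midway between them; n is the Hill-equivalent log-slope at EC50.

    Raises ValueError for (numerically) flat curves, where EC50 is
    undefined, and checks monotonicity on a coarse grid as a guard
    against non-Hill phenotypes.
    """
    g0, ginf, ec50, n, well = _hill_from_arrays(
        bp.eps_ra, bp.eps_ai, bp.k_a, bp.k_i, bp.r, bp.n_ns, bp.g_max
    )
    if not well[0]:
        raise ValueError(
            "dose-response is flat (K_A ~ K_I or repression saturated); "
            "EC50 is undefined so the phenotype has no Hill representation"
        )
    grid = np.geomspace(1e-3, 1e6, 64)
    g = bp.g_max * fold_change(bp, grid)
    dg = np.diff(g)
    if not (np.all(dg >= -1e-9 * bp.g_max) or np.all(dg <= 1e-9 * bp.g_max)):
        raise ValueError("dose-response is non-monotone; not a Hill phenotype")
    return HillParams(float(g0[0]), float(ginf[0]), float(ec50[0]), float(n[0]))


def propose_improvement_mutations(
    model, dimension: int, direction: int, top_m: int = 3
):
    """Rank mutations by their (significant) effect along one latent dimension.

    Given a trained latent landscape model, returns up to ``top_m``
    mutations whose effect on latent dimension ``dimension`` is
    significant and has the sign of ``direction`` (+1 or -1), sorted by
    effect magnitude.  This is the forward-engineering step: pick the
    latent dimension believed to track a biophysical parameter (e.g.
    K_A) and ask which mutations push it the desired way.

    Returns a list of (mutation_code, signed_effect) pairs.
    """
    if direction not in (-1, 1):
        raise ValueError("direction must be +1 or -1")
    if top_m < 1:
        raise ValueError("top_m must be >= 1")
    report = model.latent_effects_report()
    k = model.n_dims
    if not (0 <= dimension < k):
        raise ValueError(f"dimension {dimension} out of range for K={k} model")
    eff = report[f"effect_{dimension}"].to_numpy()
    sig = report[f"significant_{dimension}"].to_numpy()
    keep = sig & (np.sign(eff) == direction)
    sub = report.loc[keep].copy()
    sub = sub.sort_values(f"effect_{dimension}", ascending=(direction < 0))
    out = list(zip(sub["mutation"].tolist(), sub[f"effect_{dimension}"].tolist()))
    return out[:top_m]
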