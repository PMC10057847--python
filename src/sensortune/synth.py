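"""Synthetic genotype-phenotype landscapes with realistic structure.

The generator emulates the statistical shape of a large-scale deep
mutational scan of an allosteric sensor protein: ~10^4-10^5 variants
carrying Poisson-distributed numbers of missense mutations (mean 4.4),
Hill parameters spanning several decades of EC50, a dense non-inverted
mode near the wild type, a sparse inverted tail, and heteroscedastic
posterior uncertainty inflated for variants depleted by a FACS
pre-screen against high basal output.

Mutational effects are additive in a K=3 latent space; the summed
latent vector perturbs the biophysical parameters of the MWC repressor
model (operator binding energy, active-state ligand constant K_A, and
allosteric constant), which then determine the true Hill parameters.
Most mutations are near-neutral with heavy-tailed effect sizes; a
small fraction are strongly deleterious (operator binding lost, flat
high output) and a small fraction are inversion-prone (large decrease
of K_A).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .allostery import WT_BIOPHYS, BiophysParams, _hill_from_arrays
from .hill import SAMPLE_COLUMNS, DoseResponseCurve, HillParams, hill_response
from .landscape import AA_ALPHABET, Genotype, Landscape, MutationCode

__all__ = [
    "EffectModel",
    "NoiseModel",
    "ligand_grid",
    "simulate_library",
    "simulate_landscape",
    "simulate_curves",
]

#: latent dimensions of the generator: (operator binding energy shift in kT,
#: decades of K_A decrease, allosteric-constant shift in kT)
LATENT_DIMS = ("d_eps_ra", "neg_log10_ka", "d_eps_ai")


def ligand_grid(top: float = 2048.0) -> np.ndarray:
    """The measurement concentration design: zero plus an 11-point
    2-fold serial dilution ending at ``top`` (umol/L), ascending."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    serial = top / 2.0 ** np.arange(10, -1, -1)
    return np.concatenate([[0.0], serial])


@dataclass
class EffectModel:
    """Per-mutation latent effect vectors plus the latent -> phenotype map."""

    vocabulary: list[MutationCode]
    effects: np.ndarray  # (p, 3), rows follow vocabulary order
    wild_type: BiophysParams = WT_BIOPHYS
    deleterious_fraction: float = 0.05
    inversion_fraction: float = 0.03
    #: decades of K_I increase per decade of K_A decrease along the
    #: ligand-binding axis (binding-pocket mutations shift the two
    #: states' affinities in opposite directions)
    ki_coupling: float = 0.5

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (len(self.vocabulary), 3):
            raise ValueError("effects must be (len(vocabulary), 3)")
        self._index = {m: i for i, m in enumerate(self.vocabulary)}

    @classmethod
    def random(
        cls,
        vocabulary_size: int = 100,
        seed: int = 0,
        deleterious_fraction: float = 0.05,
        inversion_fraction: float = 0.03,
        neutral_scales: tuple[float, float, float] = (0.6, 0.12, 0.5),
        wild_type: BiophysParams = WT_BIOPHYS,
    ) -> "EffectModel":
        """Draw a random effect model.

        Near-neutral effects are heavy-tailed (Student-t, df=3) per
        latent dimension; deleterious mutations additionally weaken
        operator binding by 3-7 kT; inversion-prone mutations decrease
        K_A by 0.9-1.4 decades and the allosteric constant by
        3.5-6.5 kT.  A single inversion-prone mutation is an
        intermediate (reduced dynamic range, elevated basal output);
        combinations of two or more flip the response into the rare
        inverted tail: high basal output with repression restored by
        ligand.
        """
        rng = np.random.default_rng(seed)
        positions = rng.choice(np.arange(2, 331), size=vocabulary_size, replace=False)
        vocab = []
        for pos in np.sort(positions):
            wt_aa, new_aa = rng.choice(list(AA_ALPHABET), size=2, replace=False)
            vocab.append(MutationCode(int(pos), wt_aa, new_aa))
        eff = rng.standard_t(df=3, size=(vocabulary_size, 3)) * np.asarray(neutral_scales)
        u = rng.random(vocabulary_size)
        deleterious = u < deleterious_fraction
        inverting = (u >= deleterious_fraction) & (
            u < deleterious_fraction + inversion_fraction
        )
        eff[deleterious, 0] += rng.uniform(3.0, 7.0, deleterious.sum())
        eff[inverting, 1] += rng.uniform(0.9, 1.4, inverting.sum())
        eff[inverting, 2] -= rng.uniform(3.5, 6.5, inverting.sum())
        return cls(
            vocabulary=vocab,
            effects=eff,
            wild_type=wild_type,
            deleterious_fraction=deleterious_fraction,
            inversion_fraction=inversion_fraction,
        )

    def latent_sum(self, genotypes: Sequence[Genotype]) -> np.ndarray:
        """Summed latent vectors, one row per genotype (wild type -> 0)."""
        z = np.zeros((len(genotypes), 3))
        for i, g in enumerate(genotypes):
            for m in g:
                if m not in self._index:
                    raise ValueError(f"mutation {m} not in effect model vocabulary")
                z[i] += self.effects[self._index[m]]
        return z

    def biophys_arrays(self, z: np.ndarray):
        """Map latent sums to arrays of biophysical parameters."""
        wt = self.wild_type
        eps_ra = wt.eps_ra + z[:, 0]
        k_a = wt.k_a * 10.0 ** (-z[:, 1])
        k_i = wt.k_i * 10.0 ** (self.ki_coupling * z[:, 1])
        eps_ai = wt.eps_ai + z[:, 2]
        return eps_ra, eps_ai, k_a, k_i

    def true_hill(self, genotypes: Sequence[Genotype]) -> pd.DataFrame:
        """True Hill parameters per genotype (columns g0, ginf, ec50, n,
        well_defined); flat curves get placeholder EC50/n and
        ``well_defined=False``."""
        z = self.latent_sum(genotypes)
        eps_ra, eps_ai, k_a, k_i = self.biophys_arrays(z)
        wt = self.wild_type
        g0, ginf, ec50, n, well = _hill_from_arrays(
            eps_ra, eps_ai, k_a, k_i, wt.r, wt.n_ns, wt.g_max
        )
        return pd.DataFrame(
            {"g0": g0, "ginf": ginf, "ec50": ec50, "n": n, "well_defined": well}
        )


@dataclass
class NoiseModel:
    """Measurement-noise and posterior-width model.

    ``sigma_*`` are the base one-SD posterior widths on the landscape
    scales (decades for the log parameters, linear for n), calibrated
    to wild-type replicate variability of roughly 1.1-1.2-fold.
    Widths are inflated by ``1/sqrt(quality)`` for low-quality records
    and EC50/n widths are inflated further for flat (EC50-unidentified)
    curves.  ``curve_rel_noise`` is the lognormal noise scale of raw
    simulated dose-response points.
    """

    sigma_log_g0: float = 0.04
    sigma_log_ginf: float = 0.04
    sigma_log_ec50: float = 0.06
    sigma_n: float = 0.10
    flat_sigma_log_ec50: float = 1.0
    flat_sigma_n: float = 0.5
    curve_rel_noise: float = 0.05

    def widths(self, quality: np.ndarray, well_defined: np.ndarray) -> np.ndarray:
        """(n, 4) posterior SDs in the shared sample-column order."""
        base = np.array(
            [self.sigma_log_g0, self.sigma_log_ginf, self.sigma_log_ec50, self.sigma_n]
        )
        w = np.tile(base, (len(quality), 1))
        w[~well_defined, 2] = self.flat_sigma_log_ec50
        w[~well_defined, 3] = self.flat_sigma_n
        return w / np.sqrt(np.clip(quality, 1e-3, None))[:, None]


def simulate_library(
    n_variants: int,
    mean_missense: float = 4.4,
    vocabulary: Sequence[MutationCode] | None = None,
    vocabulary_size: int = 100,
    seed: int = 0,
) -> list[Genotype]:
    """Draw genotypes with Poisson-distributed missense counts.

    Mutations are sampled without replacement per variant from a
    vocabulary of substitutions at distinct positions (so genotype
    position-uniqueness holds by construction).  A count of zero yields
    a wild-type copy, as in real error-prone-PCR libraries.
    """
    if n_variants < 0:
        raise ValueError("n_variants must be >= 0")
    if mean_missense <= 0:
        raise ValueError("mean_missense must be > 0")
    rng = np.random.default_rng(seed)
    if vocabulary is None:
        vocabulary = EffectModel.random(vocabulary_size, seed=seed).vocabulary
    vocab = list(vocabulary)
    counts = np.minimum(rng.poisson(mean_missense, size=n_variants), len(vocab))
    out = []
    for c in counts:
        if c == 0:
            out.append(Genotype.wild_type())
        else:
            idx = rng.choice(len(vocab), size=int(c), replace=False)
            out.append(Genotype(tuple(vocab[j] for j in idx)))
    return out


def _prescreen_retention(log_g0: np.ndarray, midpoint: float, width: float) -> np.ndarray:
    """Probability of surviving the FACS pre-screen as a function of
    log10 basal output: logistic, dropping toward zero above the midpoint."""
    return 1.0 / (1.0 + np.exp((log_g0 - midpoint) / width))


def simulate_landscape(
    genotypes: Sequence[Genotype],
    effect_model: EffectModel,
    noise_model: NoiseModel | None = None,
    facs_prescreen: bool = True,
    seed: int = 0,
    n_draws: int = 100,
    prescreen_midpoint: float = 3.7,  # log10 MEF (~5 kMEF)
    prescreen_width: float = 0.3,
    min_quality: float = 0.05,
    planted: Sequence[tuple[Genotype, HillParams]] = (),
) -> tuple[Landscape, pd.DataFrame]:
    """Generate a landscape (posterior summaries + draws) from genotypes.

    For each genotype the true Hill parameters come from the summed
    latent effects through the biophysical map.  The emitted posterior
    is Gaussian on the landscape scales: its center is the truth plus
    measurement error of the same width, draws scatter around the
    center.  With the pre-screen on, high-basal records are dropped
    with probability rising along a logistic in log10 G0, and survivors
    keep a proportionally reduced quality (hence wider posteriors).

    ``planted`` appends extra variants with exactly the given true Hill
    parameters (quality 1), bypassing the latent map — used to place
    known-in-spec sequences in the landscape.

    Returns the landscape and a truth table aligned to its rows
    (columns g0, ginf, ec50, n, well_defined, planted).
    """
    if noise_model is None:
        noise_model = NoiseModel()
    rng = np.random.default_rng(seed)

    truth = effect_model.true_hill(genotypes)
    truth["planted"] = False
    genotypes = list(genotypes)
    if planted:
        extra = pd.DataFrame(
            {
                "g0": [p.g0 for _, p in planted],
                "ginf": [p.ginf for _, p in planted],
                "ec50": [p.ec50 for _, p in planted],
                "n": [p.n for _, p in planted],
                "well_defined": True,
                "planted": True,
            }
        )
        truth = pd.concat([truth, extra], ignore_index=True)
        genotypes = genotypes + [g for g, _ in planted]

    log_truth = np.column_stack(
        [
            np.log10(truth["g0"]),
            np.log10(truth["ginf"]),
            np.log10(truth["ec50"]),
            truth["n"],
        ]
    )

    quality = np.ones(len(truth))
    keep = np.ones(len(truth), dtype=bool)
    if facs_prescreen:
        p_keep = _prescreen_retention(log_truth[:, 0], prescreen_midpoint, prescreen_width)
        keep = rng.random(len(truth)) < p_keep
        keep |= truth["planted"].to_numpy()  # planted variants always retained
        quality = np.clip(p_keep, min_quality, 1.0)
        quality[truth["planted"].to_numpy()] = 1.0

    idx = np.flatnonzero(keep)
    log_truth = log_truth[idx]
    quality = quality[idx]
    truth = truth.iloc[idx].reset_index(drop=True)
    genotypes = [genotypes[i] for i in idx]
    well = truth["well_defined"].to_numpy()

    widths = noise_model.widths(quality, well)
    centers = log_truth + rng.standard_normal(log_truth.shape) * widths
    samples = centers[:, None, :] + rng.standard_normal(
        (len(truth), n_draws, 4)
    ) * widths[:, None, :]
    samples[:, :, 3] = np.clip(samples[:, :, 3], 0.05, None)

    variants = [f"v{i:06d}" for i in range(len(truth))]
    mean = samples.mean(axis=1)
    sd = samples.std(axis=1, ddof=1)
    summaries = pd.DataFrame(
        {
            "variant": variants,
            "mutation_codes": [str(g) for g in genotypes],
            "log_g0": mean[:, 0],
            "log_g0_err": sd[:, 0],
            "log_ginf": mean[:, 1],
            "log_ginf_err": sd[:, 1],
            "log_ec50": mean[:, 2],
            "log_ec50_err": sd[:, 2],
            "n": mean[:, 3],
            "n_err": sd[:, 3],
            "quality": quality,
        }
    )
    truth.insert(0, "variant", variants)
    return Landscape(summaries, samples), truth


def simulate_curves(
    params: HillParams,
    ligand: np.ndarray | None = None,
    rel_noise: float = 0.05,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[DoseResponseCurve]:
    """Simulate raw replicate dose-response curves with lognormal noise."""
    if ligand is None:
        ligand = ligand_grid()
    ligand = np.asarray(ligand, dtype=float)
    rng = np.random.default_rng(seed)
    truth = np.asarray(hill_response(params, ligand), dtype=float)
    out = []
    for r in range(n_replicates):
        gm = truth * np.exp(rng.standard_normal(ligand.size) * rel_noise)
        out.append(
            DoseResponseCurve(
                ligand=ligand,
                geo_mean=gm,
                geo_mean_err=gm * rel_noise,
                replicate_id=f"c{r + 1}/sim/A",
            )
        )
    return out
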