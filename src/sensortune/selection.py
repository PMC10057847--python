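"""In silico selection of variants against quantitative specifications.

The selection method treats the landscape as a lookup table: a
quantitative specification defines acceptance bands on EC50, Ginf
and/or G0 (plus an optional phenotype class), candidates are
pre-filtered on posterior medians, and the surviving variants are
ranked by their posterior probability of jointly meeting every
criterion — the fraction of posterior draws inside all bands.  A
systematic-error correction (a line fitted to ln EC50 of validation
measurements vs. landscape values) can be applied to every EC50 draw
before band membership is evaluated, so ranking and probabilities stay
coherent with the corrected scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hill import HillPosterior
from .landscape import Landscape, VariantRecord

__all__ = [
    "Specification",
    "CorrectionModel",
    "SelectionResult",
    "fit_ec50_correction",
    "success_probability",
    "select_variants",
    "preset_specs",
    "PRESETS",
]


@dataclass(frozen=True)
class CorrectionModel:
    """ln-ln linear map from landscape EC50 to expected measured EC50."""

    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.slope) and np.isfinite(self.intercept)):
            raise ValueError("correction coefficients must be finite")

    def apply(self, ec50):
        """Corrected EC50 prediction: exp(intercept + slope * ln ec50)."""
        ec50 = np.asarray(ec50, dtype=float)
        if np.any(ec50 <= 0):
            raise ValueError("EC50 must be positive")
        return np.exp(self.intercept + self.slope * np.log(ec50))


def fit_ec50_correction(
    dataset_ec50: Sequence[float], measured_ec50: Sequence[float]
) -> CorrectionModel:
    """OLS of ln(measured EC50) on ln(landscape EC50).

    A fitted slope below 1 means the landscape overstates the spread:
    the correction then raises low-EC50 predictions and lowers high
    ones.
    """
    x = np.asarray(dataset_ec50, dtype=float)
    y = np.asarray(measured_ec50, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need equal-length vectors with at least 2 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("EC50 values must be positive")
    lx, ly = np.log(x), np.log(y)
    if np.allclose(lx, lx[0]):
        raise ValueError("degenerate fit: all dataset EC50 values equal")
    res = stats.linregress(lx, ly)
    return CorrectionModel(slope=float(res.slope), intercept=float(res.intercept))


@dataclass(frozen=True)
class Specification:
    """Multi-objective quantitative target bands for a dose-response.

    Bands are fold-factors (>= 1) around targets: EC50 passes when it
    lies within ``ec50_fold_band`` of ``ec50_target``, similarly for
    Ginf; ``ginf_upper`` and the ``g0_band`` (lo, hi) are absolute MEF
    limits with open ends allowed; ``phenotype_class`` restricts to
    normal (Ginf > G0) or inverted (Ginf < G0) responses.
    """

    ec50_target: float | None = None
    ec50_fold_band: float = 1.2
    ginf_target: float | None = None
    ginf_fold_band: float = 1.1
    ginf_upper: float | None = None
    g0_band: tuple[float | None, float | None] | None = None
    phenotype_class: str | None = None

    def __post_init__(self) -> None:
        if self.ec50_fold_band < 1 or self.ginf_fold_band < 1:
            raise ValueError("fold bands must be >= 1")
        if self.phenotype_class not in (None, "normal", "inverted"):
            raise ValueError("phenotype_class must be 'normal' or 'inverted'")
        if self.g0_band is not None:
            lo, hi = self.g0_band
            if lo is not None and hi is not None and not lo < hi:
                raise ValueError("g0_band lower bound must be below upper bound")
        if not any(
            v is not None
            for v in (self.ec50_target, self.ginf_target, self.ginf_upper, self.g0_band, self.phenotype_class)
        ):
            raise ValueError("specification must contain at least one criterion")

    def ec50_band(self) -> tuple[float, float] | None:
        if self.ec50_target is None:
            return None
        return (self.ec50_target / self.ec50_fold_band, self.ec50_target * self.ec50_fold_band)

    def ginf_band(self) -> tuple[float, float] | None:
        if self.ginf_target is None:
            return None
        return (self.ginf_target / self.ginf_fold_band, self.ginf_target * self.ginf_fold_band)

    def satisfied(
        self,
        g0: np.ndarray,
        ginf: np.ndarray,
        ec50: np.ndarray,
        correction: CorrectionModel | None = None,
    ) -> np.ndarray:
        """Elementwise joint-criteria mask on linear-scale parameter arrays."""
        g0, ginf, ec50 = (np.asarray(a, dtype=float) for a in (g0, ginf, ec50))
        if correction is not None:
            ec50 = correction.apply(ec50)
        ok = np.ones(np.broadcast(g0, ginf, ec50).shape, dtype=bool)
        band = self.ec50_band()
        if band is not None:
            ok &= (ec50 >= band[0]) & (ec50 <= band[1])
        band = self.ginf_band()
        if band is not None:
            ok &= (ginf >= band[0]) & (ginf <= band[1])
        if self.ginf_upper is not None:
            ok &= ginf < self.ginf_upper
        if self.g0_band is not None:
            lo, hi = self.g0_band
            if lo is not None:
                ok &= g0 > lo
            if hi is not None:
                ok &= g0 < hi
        if self.phenotype_class == "normal":
            ok &= ginf > g0
        elif self.phenotype_class == "inverted":
            ok &= ginf < g0
        return ok


#: The two published selection presets (MEF / umol/L):
#: multiobjective — EC50 within 1.2-fold and Ginf within 1.1-fold of
#: target, basal output below 2 kMEF; inverted — EC50 within 1.5-fold,
#: Ginf < 12.5 kMEF and G0 between 19.2 and 32.5 kMEF.
PRESETS = ("multiobjective", "inverted")


def preset_specs(
    name: str,
    target_ec50: float | None = None,
    target_ginf: float | None = None,
) -> Specification:
    """Build one of the named selection presets around the given targets."""
    if name == "multiobjective":
        if target_ec50 is None or target_ginf is None:
            raise ValueError("multiobjective preset needs target_ec50 and target_ginf")
        return Specification(
            ec50_target=target_ec50,
            ec50_fold_band=1.2,
            ginf_target=target_ginf,
            ginf_fold_band=1.1,
            g0_band=(None, 2000.0),
        )
    if name == "inverted":
        if target_ec50 is None:
            raise ValueError("inverted preset needs target_ec50")
        return Specification(
            ec50_target=target_ec50,
            ec50_fold_band=1.5,
            ginf_upper=12500.0,
            g0_band=(19200.0, 32500.0),
            phenotype_class="inverted",
        )
    raise ValueError(f"unknown preset {name!r}; available presets: {PRESETS}")


def _samples_success(
    samples: np.ndarray, spec: Specification, correction: CorrectionModel | None
) -> np.ndarray:
    """Success probability per variant from an (n, S, 4) draw array."""
    g0 = 10.0 ** samples[..., 0]
    ginf = 10.0 ** samples[..., 1]
    ec50 = 10.0 ** samples[..., 2]
    ok = spec.satisfied(g0, ginf, ec50, correction)
    return ok.mean(axis=-1)


def success_probability(
    posterior: HillPosterior,
    spec: Specification,
    correction: CorrectionModel | None = None,
) -> float:
    """Fraction of posterior draws jointly satisfying every criterion."""
    return float(_samples_success(posterior.samples[None, :, :], spec, correction)[0])


@dataclass
class SelectionResult:
    """Ranked selection output: (record, probability) pairs plus context."""

    entries: list[tuple[VariantRecord, float]]
    spec: Specification
    correction: CorrectionModel | None = None
    status: str = "ok"

    def __post_init__(self) -> None:
        probs = [p for _, p in self.entries]
        if any(b > a + 1e-12 for a, b in zip(probs, probs[1:])):
            raise ValueError("selection probabilities must be non-increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def variants(self) -> list[str]:
        return [rec.variant for rec, _ in self.entries]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for rec, p in self.entries:
            med = rec.posterior.median_params()
            rows.append(
                {
                    "variant": rec.variant,
                    "mutation_codes": str(rec.genotype),
                    "probability": p,
                    "g0": med.g0,
                    "ginf": med.ginf,
                    "ec50": med.ec50,
                    "n": med.n,
                }
            )
        return pd.DataFrame(
            rows,
            columns=["variant", "mutation_codes", "probability", "g0", "ginf", "ec50", "n"],
        )


def select_variants(
    landscape: Landscape,
    spec: Specification,
    top_k: int = 3,
    min_prob: float = 0.0,
    correction: CorrectionModel | None = None,
) -> SelectionResult:
    """Rank landscape variants by posterior probability of meeting ``spec``.

    Candidates are first filtered on posterior medians satisfying all
    criteria (with the EC50 correction applied, when given), then
    ranked by joint success probability.  Up to ``top_k`` variants with
    probability >= ``min_prob`` are returned; ties are broken toward
    fewer mutations, then lexicographic genotype.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if len(landscape) == 0:
        return SelectionResult([], spec, correction, status="warning: empty landscape")

    med = np.median(landscape.samples, axis=1)
    mask = spec.satisfied(
        10.0 ** med[:, 0], 10.0 ** med[:, 1], 10.0 ** med[:, 2], correction
    )
    candidates = np.flatnonzero(mask)
    if candidates.size == 0:
        return SelectionResult(
            [], spec, correction, status="warning: no candidate passes the median pre-filter"
        )

    probs = _samples_success(landscape.samples[candidates], spec, correction)
    genotypes = landscape.genotypes
    order = sorted(
        range(candidates.size),
        key=lambda j: (
            -probs[j],
            len(genotypes[candidates[j]]),
            str(genotypes[candidates[j]]),
        ),
    )
    entries = []
    for j in order:
        if probs[j] < min_prob:
            continue
        entries.append((landscape.record(int(candidates[j])), float(probs[j])))
        if len(entries) == top_k:
            break
    status = "ok" if entries else "warning: no variant reaches min_prob"
    return SelectionResult(entries, spec, correction, status=status)
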