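"""Genotype-phenotype landscape data model and I/O.

A landscape is the lookup table that in silico selection mines: one
record per sensor variant, holding the variant's genotype (a set of
amino-acid substitutions relative to wild type), the posterior over its
Hill parameters, and a relative evidence weight ("quality", e.g. a
barcode-read-count proxy; FACS-prescreen survivors in the real data
have low quality and correspondingly wide posteriors).

On disk a landscape is two CSV files:

* a summary table with columns ``variant, mutation_codes, log_g0,
  log_g0_err, log_ginf, log_ginf_err, log_ec50, log_ec50_err, n, n_err,
  quality`` — posterior means and one-SD uncertainties, base-10 logs
  for G0/Ginf (MEF) and EC50 (umol/L), linear Hill coefficient;
* a posterior-sample sidecar with columns ``variant, draw, log_g0,
  log_ginf, log_ec50, n`` (same number of draws for every variant).

``mutation_codes`` is a comma-separated list of canonical codes such as
``V136E`` (1-based protein coordinates); the empty string is wild type.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .hill import SAMPLE_COLUMNS, HillPosterior

__all__ = [
    "MutationCode",
    "Genotype",
    "VariantRecord",
    "Landscape",
    "load_landscape",
    "query_landscape",
    "single_mutant_restriction",
    "parameter_range_predicate",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

SUMMARY_COLUMNS = [
    "variant",
    "mutation_codes",
    "log_g0",
    "log_g0_err",
    "log_ginf",
    "log_ginf_err",
    "log_ec50",
    "log_ec50_err",
    "n",
    "n_err",
    "quality",
]
SIDECAR_COLUMNS = ["variant", "draw", "log_g0", "log_ginf", "log_ec50", "n"]

_CODE_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True, order=True)
class MutationCode:
    """One amino-acid substitution, e.g. V136E (1-based coordinate)."""

    position: int
    wt_aa: str
    new_aa: str

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for aa in (self.wt_aa, self.new_aa):
            if aa not in AA_ALPHABET:
                raise ValueError(f"{aa!r} is not a standard amino acid")

    @property
    def is_missense(self) -> bool:
        return self.wt_aa != self.new_aa

    @classmethod
    def parse(cls, text: str) -> "MutationCode":
        m = _CODE_RE.match(text.strip())
        if not m:
            raise ValueError(f"malformed mutation code {text!r} (expected e.g. 'V136E')")
        return cls(position=int(m.group(2)), wt_aa=m.group(1), new_aa=m.group(3))

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.new_aa}"


@dataclass(frozen=True)
class Genotype:
    """An ordered (by position) set of substitutions; empty = wild type."""

    mutations: tuple[MutationCode, ...]

    def __post_init__(self) -> None:
        muts = tuple(sorted(self.mutations))
        positions = [m.position for m in muts]
        if len(set(positions)) != len(positions):
            raise ValueError(f"duplicate positions in genotype: {positions}")
        object.__setattr__(self, "mutations", muts)

    @classmethod
    def wild_type(cls) -> "Genotype":
        return cls(())

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        text = text.strip()
        if not text:
            return cls.wild_type()
        return cls(tuple(MutationCode.parse(t) for t in text.split(",")))

    @property
    def n_missense(self) -> int:
        return sum(m.is_missense for m in self.mutations)

    @property
    def is_wild_type(self) -> bool:
        return not self.mutations

    def __len__(self) -> int:
        return len(self.mutations)

    def __iter__(self) -> Iterator[MutationCode]:
        return iter(self.mutations)

    def __str__(self) -> str:
        return ",".join(str(m) for m in self.mutations)


@dataclass
class VariantRecord:
    """One landscape entry: genotype + Hill-parameter posterior + weight."""

    variant: str
    genotype: Genotype
    posterior: HillPosterior
    quality: float = 1.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.quality) and self.quality >= 0):
            raise ValueError("quality must be finite and >= 0")


class Landscape:
    """In-memory genotype-phenotype landscape.

    Holds the per-variant summary table and a dense
    ``(n_variants, n_draws, 4)`` posterior-sample array in the shared
    column order (log10 G0, log10 Ginf, log10 EC50, n).
    """

    def __init__(self, summaries: pd.DataFrame, samples: np.ndarray):
        summaries = summaries.reset_index(drop=True)
        missing = [c for c in SUMMARY_COLUMNS if c not in summaries.columns]
        if missing:
            raise ValueError(f"landscape summary missing columns: {missing}")
        samples = np.asarray(samples, dtype=float)
        if samples.ndim != 3 or samples.shape[2] != 4:
            raise ValueError("samples must have shape (n_variants, n_draws, 4)")
        if samples.shape[0] != len(summaries):
            raise ValueError("summaries and samples disagree on variant count")
        if summaries["variant"].duplicated().any():
            dup = summaries.loc[summaries["variant"].duplicated(), "variant"].tolist()
            raise ValueError(f"duplicate variant identifiers: {dup[:5]}")
        self.summaries = summaries
        self.samples = samples
        self._genotypes = [Genotype.parse(t) for t in summaries["mutation_codes"]]
        self._index = {v: i for i, v in enumerate(summaries["variant"])}

    # -- basic container protocol ------------------------------------
    def __len__(self) -> int:
        return len(self.summaries)

    @property
    def n_draws(self) -> int:
        return self.samples.shape[1]

    @property
    def genotypes(self) -> list[Genotype]:
        return list(self._genotypes)

    @property
    def mutation_vocabulary(self) -> list[MutationCode]:
        """All distinct mutation codes, in (position, aa) order."""
        seen = set()
        for g in self._genotypes:
            seen.update(g.mutations)
        return sorted(seen)

    def record(self, i: int) -> VariantRecord:
        row = self.summaries.iloc[i]
        return VariantRecord(
            variant=row["variant"],
            genotype=self._genotypes[i],
            posterior=HillPosterior(self.samples[i]),
            quality=float(row["quality"]),
        )

    def __iter__(self) -> Iterator[VariantRecord]:
        return (self.record(i) for i in range(len(self)))

    def get(self, variant: str) -> VariantRecord:
        if variant not in self._index:
            raise KeyError(f"no variant {variant!r} in landscape")
        return self.record(self._index[variant])

    def median_params(self) -> pd.DataFrame:
        """Posterior medians per variant, on linear scales (MEF / umol/L)."""
        med = np.median(self.samples, axis=1)
        return pd.DataFrame(
            {
                "variant": self.summaries["variant"],
                "g0": 10.0 ** med[:, 0],
                "ginf": 10.0 ** med[:, 1],
                "ec50": 10.0 ** med[:, 2],
                "n": med[:, 3],
            }
        )

    def subset(self, mask_or_indices) -> "Landscape":
        idx = np.asarray(mask_or_indices)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        idx = idx.astype(int)
        return Landscape(self.summaries.iloc[idx], self.samples[idx])

    # -- I/O -----------------------------------------------------------
    def save(self, summary_path, sidecar_path) -> None:
        """Write the summary CSV and the posterior-sample sidecar CSV."""
        self.summaries.to_csv(summary_path, index=False)
        n, s, _ = self.samples.shape
        side = pd.DataFrame(
            self.samples.reshape(n * s, 4), columns=list(SAMPLE_COLUMNS)
        )
        side.insert(0, "draw", np.tile(np.arange(s), n))
        side.insert(0, "variant", np.repeat(self.summaries["variant"].to_numpy(), s))
        side.to_csv(sidecar_path, index=False)


def _parse_codes_column(texts: Sequence[str]) -> list[Genotype]:
    errors = []
    out = []
    for i, t in enumerate(texts):
        t = "" if (t is None or (isinstance(t, float) and np.isnan(t))) else str(t)
        try:
            out.append(Genotype.parse(t))
        except ValueError as e:
            errors.append(f"row {i}: {e}")
    if errors:
        raise ValueError("malformed mutation codes:\n" + "\n".join(errors[:20]))
    return out


def load_landscape(summary_path, sidecar_path) -> Landscape:
    """Load a landscape from its summary CSV and posterior-sample sidecar.

    Raises ValueError listing offending rows for missing columns,
    unparseable mutation codes, or non-finite parameter values.
    """
    summary_path, sidecar_path = Path(summary_path), Path(sidecar_path)
    summ = pd.read_csv(summary_path, keep_default_na=False, na_values=[])
    missing = [c for c in SUMMARY_COLUMNS if c not in summ.columns]
    if missing:
        raise ValueError(f"{summary_path}: missing columns {missing}")
    summ["variant"] = summ["variant"].astype(str)
    num_cols = [c for c in SUMMARY_COLUMNS if c not in ("variant", "mutation_codes")]
    summ[num_cols] = summ[num_cols].apply(pd.to_numeric, errors="coerce")
    bad = np.flatnonzero(~np.isfinite(summ[num_cols]).all(axis=1).to_numpy())
    if bad.size:
        raise ValueError(f"{summary_path}: non-finite parameter values in rows {bad[:20].tolist()}")
    _parse_codes_column(summ["mutation_codes"].tolist())

    side = pd.read_csv(sidecar_path)
    missing = [c for c in SIDECAR_COLUMNS if c not in side.columns]
    if missing:
        raise ValueError(f"{sidecar_path}: missing columns {missing}")
    side["variant"] = side["variant"].astype(str)
    counts = side.groupby("variant", sort=False).size()
    if counts.nunique() != 1:
        raise ValueError(f"{sidecar_path}: unequal draw counts across variants")
    n_draws = int(counts.iloc[0])
    order = {v: i for i, v in enumerate(summ["variant"])}
    unknown = set(counts.index) - set(order)
    if unknown or len(counts) != len(order):
        raise ValueError(f"{sidecar_path}: variants do not match summary table")
    side = side.sort_values(["variant", "draw"], key=lambda s: s.map(order) if s.name == "variant" else s)
    samples = (
        side[list(SAMPLE_COLUMNS)].to_numpy(dtype=float).reshape(len(order), n_draws, 4)
    )
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{sidecar_path}: non-finite posterior draws")
    return Landscape(summ, samples)


def parameter_range_predicate(
    ec50=None, ginf=None, g0=None, n=None
) -> Callable[[pd.Series], bool]:
    """Build a predicate on posterior medians from (lo, hi) ranges.

    Each argument is an optional ``(lo, hi)`` pair on linear scales
    (umol/L for ec50, MEF for g0/ginf); ``None`` bounds are open.
    """
    ranges = {"ec50": ec50, "ginf": ginf, "g0": g0, "n": n}

    def predicate(row: pd.Series) -> bool:
        for key, rng in ranges.items():
            if rng is None:
                continue
            lo, hi = rng
            v = row[key]
            if lo is not None and v < lo:
                return False
            if hi is not None and v > hi:
                return False
        return True

    return predicate


def query_landscape(
    landscape: Landscape, predicate: Callable[[pd.Series], bool]
) -> list[VariantRecord]:
    """Records whose posterior-median parameters satisfy ``predicate``.

    The predicate receives a Series with linear-scale fields
    ``g0, ginf, ec50, n`` (plus ``variant``); record order is preserved.
    """
    med = landscape.median_params()
    hits = [i for i, (_, row) in enumerate(med.iterrows()) if predicate(row)]
    return [landscape.record(i) for i in hits]


def single_mutant_restriction(landscape: Landscape) -> Landscape:
    """Restrict the landscape to variants with exactly one missense mutation."""
    mask = np.array([g.n_missense == 1 for g in landscape.genotypes], dtype=bool)
    return landscape.subset(mask)
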