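"""Predict per-AA isotope values of archaeological C3 cereals.

Endogenous amino acids cannot be recovered from charred grain, so AA values
are inferred from bulk measurements: modern grains of the same species group
provide AA-minus-bulk offsets (Δ_AA-bulk, per element), archaeological bulk
values are first corrected for the isotopic shift induced by charring, and
the offsets are then added with full quadrature error propagation.

Offsets are pooled across species by default, mirroring a three-species
modern reference set (barley, einkorn, durum); per-species tables can be
built by filtering the input.  The method is applied symmetrically to δ13C
and δ15N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError, IsodietError

ValueSD = tuple[float, float]


@dataclass
class GrainSample:
    """One cereal grain sample: bulk values, and AA values if modern.

    ``aa_values[element][aa] = (delta, sd)``; charred samples carry bulk only.
    """

    sample_id: str
    species: str
    state: str  # "modern" | "charred"
    bulk_d13C: ValueSD
    bulk_d15N: ValueSD
    aa_values: dict[str, dict[str, ValueSD]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.state not in ("modern", "charred"):
            raise DomainError(f"state must be 'modern' or 'charred', got {self.state!r}")
        if self.state == "charred" and self.aa_values:
            raise DomainError("charred samples carry bulk values only")
        for mean, sd in (self.bulk_d13C, self.bulk_d15N):
            if sd < 0:
                raise DomainError("bulk sd must be >= 0")

    def bulk(self, element: str) -> ValueSD:
        return self.bulk_d13C if element == "C" else self.bulk_d15N


@dataclass(frozen=True)
class Offset:
    mean: float
    sd: float
    n_samples: int


class OffsetTable:
    """Δ_AA-bulk offsets keyed by (aa, element)."""

    def __init__(self, offsets: Mapping[tuple[str, str], Offset]):
        for (aa, el), off in offsets.items():
            if off.sd < 0 or off.n_samples < 1:
                raise DomainError(f"invalid offset for ({aa}, {el})")
        self._offsets = dict(offsets)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._offsets

    def __getitem__(self, key: tuple[str, str]) -> Offset:
        return self._offsets[key]

    def keys(self):
        return self._offsets.keys()

    def to_frame(self) -> pd.DataFrame:
        rows = [(aa, el, o.mean, o.sd, o.n_samples)
                for (aa, el), o in sorted(self._offsets.items())]
        return pd.DataFrame(rows, columns=["aa", "element", "mean", "sd", "n"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, lineterminator="\n")

    @classmethod
    def from_csv(cls, path: str | Path) -> "OffsetTable":
        df = pd.read_csv(path)
        return cls({(r.aa, r.element): Offset(float(r.mean), float(r.sd), int(r.n))
                    for r in df.itertuples()})


def compute_offsets(moderns: Sequence[GrainSample]) -> OffsetTable:
    """AA-minus-bulk offsets pooled across modern grain samples.

    offset(aa, el) = mean_j (δ_AA,j − δ_bulk,j); its SD combines the
    between-sample scatter with the (mean) per-sample measurement error of
    the offset, both at the scale of the pooled mean.
    """
    moderns = [g for g in moderns if g.state == "modern" and g.aa_values]
    if not moderns:
        raise IsodietError("no modern grain samples with AA values")
    keys = sorted({(aa, el) for g in moderns for el, aas in g.aa_values.items()
                   for aa in aas})
    out: dict[tuple[str, str], Offset] = {}
    for aa, el in keys:
        diffs, meas_vars = [], []
        for g in moderns:
            if el in g.aa_values and aa in g.aa_values[el]:
                aa_mean, aa_sd = g.aa_values[el][aa]
                b_mean, b_sd = g.bulk(el)
                diffs.append(aa_mean - b_mean)
                meas_vars.append(aa_sd**2 + b_sd**2)
        n = len(diffs)
        between = float(np.std(diffs, ddof=1)) if n > 1 else 0.0
        sd = math.sqrt(between**2 + float(np.mean(meas_vars)) / n)
        out[(aa, el)] = Offset(float(np.mean(diffs)), sd, n)
    return OffsetTable(out)


def correct_charring(bulk: ValueSD, element: str,
                     charring_offsets: Mapping[str, ValueSD]) -> ValueSD:
    """Remove the charring-induced isotopic shift from an archaeological
    bulk value; uncertainties combine in quadrature."""
    if element not in charring_offsets:
        raise ConfigError(f"no charring offset configured for element {element!r}")
    off_mean, off_sd = charring_offsets[element]
    mean, sd = bulk
    return mean - off_mean, math.sqrt(sd**2 + off_sd**2)


@dataclass
class PredictionResult:
    """Per-element, per-AA predicted values plus the skipped-AA report."""

    values: dict[str, dict[str, ValueSD]]
    skipped: list[tuple[str, str]]


def predict_aa_values(charred: GrainSample, offsets: OffsetTable,
                      charring_offsets: Mapping[str, ValueSD],
                      aas: Sequence[str] | None = None) -> PredictionResult:
    """Predict AA values for one charred grain: charring-corrected bulk plus
    the Δ_AA-bulk offset, with quadrature of bulk, charring and offset SDs.

    AAs requested but absent from the offset table are reported in
    ``skipped`` rather than silently zeroed.
    """
    available = sorted(offsets.keys())
    if aas is not None:
        wanted = [(aa, el) for aa in aas for el in ("C", "N")]
    else:
        wanted = available
    values: dict[str, dict[str, ValueSD]] = {"C": {}, "N": {}}
    skipped = []
    for aa, el in wanted:
        if (aa, el) not in offsets:
            skipped.append((aa, el))
            continue
        base, base_sd = correct_charring(charred.bulk(el), el, charring_offsets)
        off = offsets[(aa, el)]
        values[el][aa] = (base + off.mean, math.sqrt(base_sd**2 + off.sd**2))
    return PredictionResult(values, skipped)


def predict_pooled(charred_samples: Sequence[GrainSample], offsets: OffsetTable,
                   charring_offsets: Mapping[str, ValueSD],
                   aas: Sequence[str] | None = None) -> PredictionResult:
    """Pooled prediction across several archaeological grains: per-AA mean of
    the single-grain predictions, with the per-grain propagated variances
    averaged at the scale of the mean and combined with the between-grain
    scatter."""
    if not charred_samples:
        raise IsodietError("no charred samples supplied")
    singles = [predict_aa_values(g, offsets, charring_offsets, aas)
               for g in charred_samples]
    values: dict[str, dict[str, ValueSD]] = {"C": {}, "N": {}}
    for el in ("C", "N"):
        for aa in singles[0].values[el]:
            means = [s.values[el][aa][0] for s in singles]
            vars_ = [s.values[el][aa][1] ** 2 for s in singles]
            n = len(means)
            between = float(np.std(means, ddof=1)) if n > 1 else 0.0
            sd = math.sqrt(between**2 + float(np.mean(vars_)) / n)
            values[el][aa] = (float(np.mean(means)), sd)
    return PredictionResult(values, singles[0].skipped)
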