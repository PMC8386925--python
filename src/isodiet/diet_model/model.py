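"""Model-spec assembly: signals, routing, sources, and consumers."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ..defaults import (
    OLIVE_OIL_D13C,
    ROUTING_OFFSETS,
    SUESS_CORRECTION,
)
from ..errors import DomainError, ModelSpecError
from ..tables_io import VALID_MODELS

ValueSD = tuple[float, float]
SignalName = tuple[str, str]  # (element, analyte)

ROUTINGS = ("source_direct", "glycolytic", "carbon_pool", "nitrogen_pool",
            "bulk_protein", "bulk_scrambled")

#: model-1 signal set: source AAs reliably measured in ancient collagen
MODEL1_SIGNALS: tuple[SignalName, ...] = (
    ("C", "Leu"), ("C", "Val"), ("C", "Ile"), ("C", "Phe"),
    ("N", "Phe"), ("N", "Lys"),
)

#: trophic-AA signals added by model 2
MODEL2_EXTRA: tuple[tuple[SignalName, str], ...] = (
    (("C", "Ala"), "glycolytic"),
    (("C", "Glx"), "carbon_pool"),
    (("C", "Asx"), "carbon_pool"),
    (("N", "Glx"), "nitrogen_pool"),
)

MACROS = ("protein", "carbohydrate", "lipid")


@dataclass(frozen=True)
class SignalDef:
    """One model signal: an (element, analyte) pair, its metabolic routing,
    and the diet-to-consumer offset (‰ mean ± sd) applied on top of the
    concentration-weighted dietary mixture.  For trophic routings the offset
    carries the trophic fractionation (e.g. the Glx Δ15N)."""

    name: SignalName
    routing: str
    diet_to_consumer_offset: ValueSD

    def __post_init__(self) -> None:
        element = self.name[0]
        if self.routing not in ROUTINGS:
            raise ModelSpecError(f"unknown routing {self.routing!r}")
        if self.routing in ("glycolytic", "carbon_pool") and element != "C":
            raise ModelSpecError(f"{self.routing} routing is carbon-only")
        if self.routing == "nitrogen_pool" and element != "N":
            raise ModelSpecError("nitrogen_pool routing is nitrogen-only")
        if self.diet_to_consumer_offset[1] < 0:
            raise ModelSpecError("offset sd must be >= 0")


@dataclass
class SourceGroup:
    """A food group: measured signal values, AA composition of its protein,
    macronutrient composition (dry-weight fractions summing to 1), and the
    δ13C offsets of each macronutrient from the measured bulk value."""

    name: str
    signal_values: dict[SignalName, ValueSD]
    aa_concentrations: dict[str, float]
    macronutrients: dict[str, float]
    macronutrient_d13c_offsets: dict[str, ValueSD]

    def __post_init__(self) -> None:
        total = sum(self.macronutrients.get(m, 0.0) for m in MACROS)
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise DomainError(
                f"{self.name}: macronutrient fractions must sum to 1, got {total}")
        if any(not 0 <= self.macronutrients.get(m, 0.0) <= 1 for m in MACROS):
            raise DomainError(f"{self.name}: macronutrient fractions must be in [0,1]")
        if any(c < 0 for c in self.aa_concentrations.values()):
            raise DomainError(f"{self.name}: AA concentrations must be >= 0")

    def bulk(self, element: str) -> ValueSD:
        key = (element, "bulk")
        if key not in self.signal_values:
            raise ModelSpecError(f"source {self.name} lacks a bulk {element} value")
        return self.signal_values[key]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "signal_values": {f"{el}:{an}": [m, sd] for (el, an), (m, sd)
                              in sorted(self.signal_values.items())},
            "aa_concentrations": dict(sorted(self.aa_concentrations.items())),
            "macronutrients": self.macronutrients,
            "macronutrient_d13c_offsets": {
                k: list(v) for k, v in self.macronutrient_d13c_offsets.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SourceGroup":
        sig = {tuple(k.split(":")): (float(v[0]), float(v[1]))
               for k, v in d["signal_values"].items()}
        return cls(d["name"], sig, dict(d["aa_concentrations"]),
                   dict(d["macronutrients"]),
                   {k: (float(v[0]), float(v[1]))
                    for k, v in d["macronutrient_d13c_offsets"].items()})


@dataclass(frozen=True)
class ConsumerProfile:
    """One individual's measured bulk and per-AA values plus a sex label."""

    sample_id: str
    sex: str
    values: Mapping[SignalName, ValueSD]


def consumers_from_table(table) -> list[ConsumerProfile]:
    """Build consumer profiles from a long-format :class:`IsotopeTable`."""
    out = []
    for sample_id, sdf in table.df.groupby("sample_id", sort=True):
        sex = sdf["sex"].iloc[0]
        values = {(r.element, r.analyte): (float(r.delta), float(r.sd))
                  for r in sdf.itertuples()}
        out.append(ConsumerProfile(str(sample_id), sex, values))
    return out


@dataclass
class ModelSpec:
    """Everything the sampler needs: signal set with routing and offsets,
    sources, the fraction basis, and default MCMC settings."""

    model_name: str
    signals: list[SignalDef]
    sources: list[SourceGroup]
    fraction_basis: str  # "protein" | "whole_diet"
    glycolytic_fallback: bool = True
    mcmc: dict = field(default_factory=lambda: {"burn_in": 5000,
                                                "iterations": 10000, "seed": 0})

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


def source_signal_value(source: SourceGroup, signal: SignalDef,
                        glycolytic_fallback: bool = True) -> ValueSD:
    """Dietary-side isotope value of one source for one signal.

    * ``source_direct`` — the measured AA value.
    * ``glycolytic`` — carbohydrate δ13C: bulk + carbohydrate offset.  For a
      source with no carbohydrate mass the value falls back to the carbon
      pool (with a warning) when ``glycolytic_fallback`` is on.
    * ``carbon_pool`` — macronutrient-mass-weighted mean of protein /
      carbohydrate / lipid δ13C (each bulk + offset).
    * ``nitrogen_pool`` / ``bulk_protein`` (N) — bulk δ15N of the source's
      protein (dietary protein is the only nitrogen source); the trophic
      shift sits in the signal's diet-to-consumer offset, applied once at
      prediction time.
    * ``bulk_protein`` (C) — protein δ13C: bulk + protein offset.
    * ``bulk_scrambled`` — C: the carbon-pool value; N: bulk δ15N.

    Uncertainties propagate in quadrature with the mixture weights.
    """
    element, analyte = signal.name
    r = signal.routing
    if r == "source_direct":
        if signal.name not in source.signal_values:
            raise ModelSpecError(
                f"source {source.name} lacks a measured value for {signal.name}")
        return source.signal_values[signal.name]
    if r == "glycolytic":
        carb = source.macronutrients.get("carbohydrate", 0.0)
        if carb == 0.0:
            if not glycolytic_fallback:
                raise ModelSpecError(
                    f"source {source.name} has no carbohydrate mass for the "
                    f"glycolytic signal {signal.name}")
            warnings.warn(
                f"source {source.name}: no carbohydrate — glycolytic signal "
                f"{signal.name} falls back to the carbon pool", stacklevel=2)
            return _carbon_pool_value(source)
        return _macro_value(source, "carbohydrate")
    if r == "carbon_pool":
        return _carbon_pool_value(source)
    if r == "nitrogen_pool":
        return source.bulk("N")
    if r == "bulk_protein":
        if element == "C":
            return _macro_value(source, "protein")
        return source.bulk("N")
    if r == "bulk_scrambled":
        if element == "C":
            return _carbon_pool_value(source)
        return source.bulk("N")
    raise ModelSpecError(f"unknown routing {r!r}")


def _macro_value(source: SourceGroup, macro: str) -> ValueSD:
    bulk, bulk_sd = source.bulk("C")
    off, off_sd = source.macronutrient_d13c_offsets.get(macro, (0.0, 0.0))
    return bulk + off, math.sqrt(bulk_sd**2 + off_sd**2)


def _carbon_pool_value(source: SourceGroup) -> ValueSD:
    """Energy-weighted (dry-mass-weighted) mean δ13C over macronutrients."""
    masses = [source.macronutrients.get(m, 0.0) for m in MACROS]
    total = sum(masses)
    if total <= 0:
        raise ModelSpecError(f"source {source.name} has zero macronutrient mass")
    bulk, bulk_sd = source.bulk("C")
    mean = 0.0
    var = bulk_sd**2
    for m, mass in zip(MACROS, masses):
        w = mass / total
        off, off_sd = source.macronutrient_d13c_offsets.get(m, (0.0, 0.0))
        mean += w * (bulk + off)
        var += (w * off_sd) ** 2
    return mean, math.sqrt(var)


def signal_concentration(source: SourceGroup, signal: SignalDef,
                         fraction_basis: str,
                         glycolytic_fallback: bool = True) -> float:
    """Concentration of the signal's carrier in one unit of the source, on
    the model's fraction basis.

    Protein basis (models 0p, 1): AA signals use the AA's share of source
    protein; bulk-protein signals use 1 (per unit protein).  Whole-diet
    basis (models 0wd, 2): protein-borne signals additionally scale by the
    source's protein mass fraction; glycolytic signals use the carbohydrate
    mass (total dry mass under the carbon-pool fallback); carbon-pool
    signals use total dry mass (1); nitrogen-pool and bulk δ15N use the
    protein mass fraction.
    """
    element, analyte = signal.name
    r = signal.routing
    protein = source.macronutrients.get("protein", 0.0)
    if r == "source_direct":
        aa_conc = source.aa_concentrations.get(analyte, 0.0)
        return aa_conc if fraction_basis == "protein" else aa_conc * protein
    if r == "glycolytic":
        carb = source.macronutrients.get("carbohydrate", 0.0)
        if carb == 0.0 and glycolytic_fallback:
            return 1.0
        return carb
    if r == "carbon_pool":
        return 1.0
    if r == "nitrogen_pool":
        return protein if fraction_basis == "whole_diet" else \
            source.aa_concentrations.get(analyte, 0.0)
    if r == "bulk_protein":
        return 1.0
    if r == "bulk_scrambled":
        if element == "N":
            return protein
        return 1.0
    raise ModelSpecError(f"unknown routing {r!r}")


def build_model_spec(model_name: str, sources: Sequence[SourceGroup],
                     config: Mapping | None = None) -> ModelSpec:
    """Assemble the signal set for one of the four model structures.

    ``config`` may override per-routing diet-to-consumer offsets
    (``offsets: {routing: [mean, sd]}``), MCMC settings (``mcmc``) and the
    glycolytic fallback flag.  Missing source signals are reported together
    in a single error.
    """
    config = dict(config or {})
    if model_name not in VALID_MODELS:
        raise ModelSpecError(
            f"unknown model {model_name!r}; valid: {', '.join(VALID_MODELS)}")
    offsets_cfg = dict(config.get("offsets", {}))

    def off(routing: str, element: str) -> ValueSD:
        v = offsets_cfg.get(routing, ROUTING_OFFSETS[routing])
        if isinstance(v, dict):
            v = v[element]
        return (float(v[0]), float(v[1]))

    signals: list[SignalDef] = []
    if model_name in ("model0p", "model0wd"):
        routing = "bulk_protein" if model_name == "model0p" else "bulk_scrambled"
        for element in ("C", "N"):
            signals.append(SignalDef((element, "bulk"), routing, off(routing, element)))
        basis = "protein" if model_name == "model0p" else "whole_diet"
    else:
        for name in MODEL1_SIGNALS:
            signals.append(SignalDef(name, "source_direct",
                                     off("source_direct", name[0])))
        basis = "protein"
        if model_name == "model2":
            basis = "whole_diet"
            for name, routing in MODEL2_EXTRA:
                signals.append(SignalDef(name, routing, off(routing, name[0])))

    fallback = bool(config.get("glycolytic_fallback", True))
    if any(s.macronutrients.get("protein", 0.0) == 0.0 for s in sources) \
            and model_name in ("model0p", "model1"):
        bad = [s.name for s in sources if s.macronutrients.get("protein", 0) == 0]
        raise ModelSpecError(
            f"protein-basis {model_name} cannot include protein-free "
            f"source(s): {', '.join(bad)}")

    # verify every source can provide every signal
    gaps = []
    for src in sources:
        for sig in signals:
            q = signal_concentration(src, sig, basis, fallback)
            if q == 0.0:
                continue  # source simply does not carry this signal
            try:
                source_signal_value(src, sig, fallback)
            except ModelSpecError:
                gaps.append(f"{src.name}:{sig.name}")
    if gaps:
        raise ModelSpecError("missing source signal value(s): " + ", ".join(gaps))

    mcmc = {"burn_in": 5000, "iterations": 10000, "seed": 0}
    mcmc.update(config.get("mcmc", {}))
    return ModelSpec(model_name, signals, list(sources), basis, fallback, mcmc)


def add_olive_oil_source(sources: Sequence[SourceGroup],
                         modern_oil_d13C: ValueSD = OLIVE_OIL_D13C,
                         suess_correction: ValueSD = SUESS_CORRECTION,
                         model_name: str = "model2") -> list[SourceGroup]:
    """Append a lipid-only olive-oil source for the whole-diet model.

    Its δ13C is the modern Mediterranean olive-oil value shifted by the Suess
    correction (pre-industrial biosphere is ~1.9‰ heavier); with zero protein
    and carbohydrate it contributes only to carbon-pool signals and to
    glycolytic signals under the carbon-pool fallback, and has weight zero on
    every nitrogen signal.
    """
    if model_name != "model2":
        raise ModelSpecError(
            "the olive-oil extension requires model2 (oil carries no protein "
            "signals usable by " + model_name + ")")
    mean = modern_oil_d13C[0] + suess_correction[0]
    sd = math.sqrt(modern_oil_d13C[1] ** 2 + suess_correction[1] ** 2)
    oil = SourceGroup(
        name="olive_oil",
        signal_values={("C", "bulk"): (mean, sd)},
        aa_concentrations={},
        macronutrients={"protein": 0.0, "carbohydrate": 0.0, "lipid": 1.0},
        macronutrient_d13c_offsets={"lipid": (0.0, 0.0)},
    )
    return list(sources) + [oil]
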