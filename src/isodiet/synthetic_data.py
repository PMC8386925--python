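"""Synthetic inputs for every pipeline stage.

Generates source baselines, consumer AA profiles under the forward mixing
model, raw GC-C-IRMS sessions, and modern/charred grain sets, all as pure
functions of a :class:`SimScenario` (same scenario and seed → identical
outputs).  Default parameters emulate the structure of a first-century
Mediterranean coastal cohort: three isotopically separable food groups
(C3 cereals, terrestrial animals, marine fish), 17 consumers (11 male,
6 female) with sex-structured diets in which males obtain ~1.6× the marine
protein of females, AA-level measurement noise of 0.3–1.5‰, and triplicate
GC injections with bracketing standard-mixture runs.  All templates are
explicitly synthetic baselines, not measurements.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cereal_offsets import GrainSample
from .defaults import (
    AA_COMPOSITION_CEREAL_GRAIN,
    AA_COMPOSITION_MEAT,
    AA_COMPOSITION_FISH_MUSCLE,
    CHARRING_OFFSETS,
    MACRONUTRIENT_D13C_OFFSETS,
    MACRONUTRIENTS,
)
from .diet_model.mixing import build_design
from .diet_model.model import (
    ConsumerProfile,
    SourceGroup,
    add_olive_oil_source,
    build_model_spec,
)
from .errors import IsodietError
from .gc_reduction import default_carbon_counts

# ---------------------------------------------------------------------------
# Templates (synthetic; per-signal mean ± between-context sd, ‰)
# ---------------------------------------------------------------------------

# sds are the uncertainty of each source-group *mean* (standard-error scale,
# as baseline tables report), not the spread between individual specimens
SOURCE_TEMPLATES: dict[str, dict] = {
    "cereals": {
        "signals": {
            ("C", "bulk"): (-23.5, 0.3), ("N", "bulk"): (4.0, 0.5),
            ("C", "Leu"): (-28.0, 0.4), ("C", "Val"): (-24.5, 0.4),
            ("C", "Ile"): (-25.5, 0.4), ("C", "Phe"): (-27.0, 0.4),
            ("N", "Phe"): (2.5, 0.5), ("N", "Lys"): (1.5, 0.5),
        },
        "aa_concentrations": AA_COMPOSITION_CEREAL_GRAIN,
    },
    "terrestrial_animals": {
        "signals": {
            ("C", "bulk"): (-20.5, 0.3), ("N", "bulk"): (6.5, 0.5),
            ("C", "Leu"): (-25.5, 0.4), ("C", "Val"): (-21.5, 0.4),
            ("C", "Ile"): (-22.5, 0.4), ("C", "Phe"): (-24.0, 0.4),
            ("N", "Phe"): (6.0, 0.5), ("N", "Lys"): (5.0, 0.5),
        },
        "aa_concentrations": AA_COMPOSITION_MEAT,
    },
    "marine_fish": {
        "signals": {
            ("C", "bulk"): (-12.5, 0.4), ("N", "bulk"): (10.5, 0.5),
            ("C", "Leu"): (-17.5, 0.4), ("C", "Val"): (-14.5, 0.4),
            ("C", "Ile"): (-15.5, 0.4), ("C", "Phe"): (-16.5, 0.4),
            ("N", "Phe"): (8.0, 0.5), ("N", "Lys"): (9.5, 0.5),
        },
        "aa_concentrations": AA_COMPOSITION_FISH_MUSCLE,
    },
}

#: plausible ‰ windows per element for generated source means
PLAUSIBLE_RANGE = {"C": (-35.0, -8.0), "N": (-2.0, 16.0)}

# In-house standard mixture: true (EA-IRMS) values of the underivatized
# compounds and the true isotope values of the NAIP derivative carbon used
# to synthesize derivatized peaks.
STANDARD_TRUTHS: dict[tuple[str, str], tuple[float, float]] = {
    ("Ala", "C"): (-19.31, 0.02), ("Gly", "C"): (-33.31, 0.02),
    ("Val", "C"): (-10.89, 0.02), ("Leu", "C"): (-13.78, 0.06),
    ("Ile", "C"): (-24.89, 0.07), ("Nle", "C"): (-27.59, 0.02),
    ("Thr", "C"): (-10.46, 0.01), ("Ser", "C"): (-12.54, 0.09),
    ("Pro", "C"): (-12.33, 0.02), ("Asx", "C"): (-27.52, 0.12),
    ("Met", "C"): (-29.88, 0.14), ("Glx", "C"): (-28.57, 0.09),
    ("Hyp", "C"): (-12.52, 0.03), ("Phe", "C"): (-11.52, 0.05),
    ("Lys", "C"): (-13.7, 0.11), ("Tyr", "C"): (-24.85, 0.02),
    ("Ala", "N"): (43.25, 0.07), ("Gly", "N"): (1.76, 0.06),
    ("Val", "N"): (-5.21, 0.05), ("Leu", "N"): (6.22, 0.05),
    ("Nle", "N"): (14.31, 0.23), ("Asx", "N"): (35.2, 0.1),
    ("Glx", "N"): (-4.52, 0.06), ("Hyp", "N"): (-9.17, 0.1),
    ("Phe", "N"): (1.70, 0.06), ("Lys", "N"): (2.2, 0.1),
}

#: true δ13C of the NAIP derivative-group carbon per AA (‰)
TRUE_DERIVATIVE_D13C: dict[str, float] = {
    "Ala": -40.46, "Gly": -39.73, "Val": -45.57, "Leu": -45.03,
    "Ile": -46.31, "Nle": -43.43, "Thr": -48.52, "Ser": -46.56,
    "Pro": -42.27, "Asx": -37.27, "Met": -41.82, "Glx": -36.73,
    "Hyp": -47.97, "Phe": -45.36, "Lys": -48.29, "Tyr": -48.71,
}

#: generating Δ_AA-bulk offsets for grain simulation (‰), (aa, element)
GRAIN_TRUE_OFFSETS: dict[tuple[str, str], float] = {
    ("Leu", "C"): -4.5, ("Val", "C"): -1.0, ("Ile", "C"): -2.0,
    ("Phe", "C"): -3.5, ("Phe", "N"): -1.5, ("Lys", "N"): -2.5,
}


@dataclass
class SimScenario:
    """Study conditions for the synthetic cohort.

    ``true_diets`` gives per-sex mean diet fractions on the *whole-diet*
    (dry-weight) basis, in source order; individual diets are Dirichlet
    draws around them.  Protein-basis truths follow from the sources'
    protein contents.  Defaults mirror the cohort shape the pipeline is
    designed for (17 adults, 11 male / 6 female, three sources, males with
    ~1.6× the females' marine protein).
    """

    seed: int = 0
    n_individuals: int = 17
    n_males: int = 11
    include_olive_oil: bool = False
    true_diets: dict[str, tuple[float, ...]] = field(default_factory=dict)
    dirichlet_concentration: float = 200.0
    noise_sd_range: tuple[float, float] = (0.3, 1.5)
    sample_source_values: bool = True
    min_separation: float = 3.0
    source_jitter: float = 0.0
    session_drift: float = 0.0
    replicate_sd: float = 0.15
    n_grain_moderns: int = 3
    n_grain_charred: int = 4
    grain_noise_sd: float = 0.15

    def __post_init__(self) -> None:
        if not self.true_diets:
            if self.include_olive_oil:
                self.true_diets = {
                    "male": (0.34, 0.27, 0.09, 0.30),
                    "female": (0.35, 0.30, 0.05, 0.30),
                }
            else:
                self.true_diets = {
                    "male": (0.485, 0.380, 0.135),
                    "female": (0.490, 0.430, 0.080),
                }
        for sex, f in self.true_diets.items():
            if abs(sum(f) - 1) > 1e-9 or min(f) < 0:
                raise IsodietError(f"true diet for {sex} must lie on the simplex")
        lo, hi = self.noise_sd_range
        if lo < 0 or hi < lo:
            raise IsodietError("noise_sd_range must be 0 <= lo <= hi")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed) % 2**31, stream])


class SourceSet(list):
    """List of sources with the pairwise separation report attached."""

    separation: dict[tuple[str, str], float]
    degenerate: bool = False


def pairwise_separation(a: SourceGroup, b: SourceGroup,
                        signals: Sequence[tuple[str, str]]) -> float:
    """Mahalanobis-style distance in source-AA signal space."""
    d2 = 0.0
    for name in signals:
        m1, s1 = a.signal_values[name]
        m2, s2 = b.signal_values[name]
        d2 += (m1 - m2) ** 2 / (s1**2 + s2**2)
    return math.sqrt(d2)


def make_sources(scenario: SimScenario) -> SourceSet:
    """Three (or four, with olive oil) isotopically separable food groups.

    Source means come from the synthetic templates, optionally jittered;
    pairwise separation in source-AA space must reach
    ``scenario.min_separation`` or an error suggests wider templates.  A
    requested separation of zero marks the set degenerate.
    """
    rng = scenario.rng(1)
    sources = SourceSet()
    for name, tpl in SOURCE_TEMPLATES.items():
        sig = {}
        for key, (mean, sd) in tpl["signals"].items():
            jitter = rng.normal(0.0, scenario.source_jitter) \
                if scenario.source_jitter > 0 else 0.0
            sig[key] = (mean + jitter, sd)
        sources.append(SourceGroup(
            name=name,
            signal_values=sig,
            aa_concentrations=dict(tpl["aa_concentrations"]),
            macronutrients=dict(MACRONUTRIENTS[name]),
            macronutrient_d13c_offsets=dict(MACRONUTRIENT_D13C_OFFSETS[name]),
        ))
    if scenario.include_olive_oil:
        sources = SourceSet(add_olive_oil_source(sources))

    aa_signals = [("C", "Leu"), ("C", "Val"), ("C", "Ile"), ("C", "Phe"),
                  ("N", "Phe"), ("N", "Lys")]
    sources.separation = {}
    protein_sources = [s for s in sources if s.macronutrients["protein"] > 0]
    for a, b in itertools.combinations(protein_sources, 2):
        d = pairwise_separation(a, b, aa_signals)
        sources.separation[(a.name, b.name)] = d
        if scenario.min_separation > 0 and d < scenario.min_separation:
            raise IsodietError(
                f"sources {a.name} and {b.name} separated by only {d:.2f} "
                f"(< {scenario.min_separation}); widen the template means or "
                "reduce their sds")
    sources.degenerate = scenario.min_separation == 0
    return sources


def true_protein_fractions(whole_diet: Sequence[float],
                           sources: Sequence[SourceGroup]) -> np.ndarray:
    prot = np.array([s.macronutrients.get("protein", 0.0) for s in sources])
    t = np.asarray(whole_diet, float) * prot
    return t / t.sum()


def make_consumers(scenario: SimScenario, sources: Sequence[SourceGroup]
                   ) -> tuple[list[ConsumerProfile], pd.DataFrame]:
    """Simulate consumers under the whole-diet forward model.

    Per individual: a sex-specific Dirichlet diet draw; realized source
    signal values and diet-to-consumer offsets drawn from their priors;
    every model-2 signal plus the bulk pair predicted through the
    concentration-dependent mixture; Gaussian measurement noise at a
    per-signal sd drawn from ``noise_sd_range``.  Returns the consumers and
    a truth table (whole-diet and implied protein fractions per source).
    """
    rng = scenario.rng(2)
    spec2 = build_model_spec("model2", sources)
    spec0 = build_model_spec("model0wd", sources)
    d2 = build_design(spec2)
    d0 = build_design(spec0)
    lo, hi = scenario.noise_sd_range

    # one baseline realization per cohort: the true source values are a
    # single draw from their priors, shared by every individual (there is
    # one physical baseline); offsets vary per individual (physiology)
    shared_src = {}
    for d in (d2, d0):
        if scenario.sample_source_values:
            shared_src[id(d)] = d.mu + rng.normal(size=d.mu.shape) \
                * np.sqrt(d.var_src)
        else:
            shared_src[id(d)] = d.mu

    consumers: list[ConsumerProfile] = []
    rows = []
    conc = scenario.dirichlet_concentration
    for i in range(scenario.n_individuals):
        sex = "male" if i < scenario.n_males else "female"
        mean_diet = np.asarray(scenario.true_diets[sex], float)
        f = rng.dirichlet(conc * mean_diet)
        values: dict[tuple[str, str], tuple[float, float]] = {}
        for d in (d2, d0):
            src_draw = shared_src[id(d)]
            if scenario.sample_source_values:
                off_draw = d.off_mean + rng.normal(size=d.off_mean.shape) \
                    * np.sqrt(d.var_off)
            else:
                off_draw = d.off_mean
            t = f[:, None] * d.q
            w = t / t.sum(axis=0)
            pred = (w * src_draw).sum(axis=0) + off_draw
            for s, name in enumerate(d.signal_names):
                sd = rng.uniform(lo, hi)
                noise = rng.normal(0.0, sd) if sd > 0 else 0.0
                values[name] = (float(pred[s] + noise), float(sd))
        sample_id = f"IND{i + 1:02d}"
        consumers.append(ConsumerProfile(sample_id, sex, values))
        p = true_protein_fractions(f, sources)
        row = {"sample_id": sample_id, "sex": sex}
        for k, src in enumerate(sources):
            row[f"f_{src.name}"] = float(f[k])
            row[f"p_{src.name}"] = float(p[k])
        rows.append(row)
    return consumers, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# GC sessions
# ---------------------------------------------------------------------------

def make_gc_session(scenario: SimScenario,
                    true_aa_deltas: Mapping[tuple[str, str], float],
                    sample_id: str = "S1",
                    ) -> tuple[pd.DataFrame, dict[tuple[str, str], tuple[float, float]]]:
    """Raw triplicate GC-C-IRMS run tables for one sample.

    δ13C peaks are synthesized through the forward derivatization mass
    balance using the carbon-count table and the true derivative-carbon
    values; δ15N peaks get a mild instrument response (gain 0.98, offset
    +0.5‰).  Standards bracket every three sample injections; optional
    linear drift spans the run order; replicate noise is Gaussian.
    Returns (session table, standard truths) ready for ``reduce_session``.
    """
    rng = scenario.rng(3)
    counts = default_carbon_counts()
    aas_c = sorted({aa for (aa, el) in true_aa_deltas if el == "C"} | {"Nle"})
    aas_n = sorted({aa for (aa, el) in true_aa_deltas if el == "N"} | {"Nle"})
    sample_truth = dict(true_aa_deltas)
    sample_truth.setdefault(("Nle", "C"), STANDARD_TRUTHS[("Nle", "C")][0])
    sample_truth.setdefault(("Nle", "N"), STANDARD_TRUTHS[("Nle", "N")][0])

    def derivatized(aa: str, true_c: float) -> float:
        ent = counts[aa]
        return (ent.n_C * true_c + ent.n_D * TRUE_DERIVATIVE_D13C[aa]) / ent.n_DC

    def n_raw(true_n: float) -> float:
        return 0.98 * true_n + 0.5

    rows = []
    run_order = 0
    n_sample_inj = 3
    total_inj = n_sample_inj + math.ceil(n_sample_inj / 3) + 1
    drift_per_inj = (scenario.session_drift / max(total_inj - 1, 1))

    def emit(kind: str, sid: str, injection: int) -> None:
        nonlocal run_order
        drift = drift_per_inj * run_order
        if kind == "standard":
            for aa in sorted({a for (a, e) in STANDARD_TRUTHS if e == "C"}):
                v = derivatized(aa, STANDARD_TRUTHS[(aa, "C")][0]) + drift \
                    + rng.normal(0, scenario.replicate_sd)
                rows.append((run_order, kind, sid, injection, aa, "C", v))
            for aa in sorted({a for (a, e) in STANDARD_TRUTHS if e == "N"}):
                v = n_raw(STANDARD_TRUTHS[(aa, "N")][0]) + drift \
                    + rng.normal(0, scenario.replicate_sd)
                rows.append((run_order, kind, sid, injection, aa, "N", v))
        else:
            for aa in aas_c:
                v = derivatized(aa, sample_truth[(aa, "C")]) + drift \
                    + rng.normal(0, scenario.replicate_sd)
                rows.append((run_order, kind, sid, injection, aa, "C", v))
            for aa in aas_n:
                v = n_raw(sample_truth[(aa, "N")]) + drift \
                    + rng.normal(0, scenario.replicate_sd)
                rows.append((run_order, kind, sid, injection, aa, "N", v))
        run_order += 1

    std_count = 0
    emit("standard", f"STD{std_count}", 1)
    for inj in range(1, n_sample_inj + 1):
        emit("sample", sample_id, inj)
        if inj % 3 == 0 or inj == n_sample_inj:
            std_count += 1
            emit("standard", f"STD{std_count}", 1)

    session = pd.DataFrame(rows, columns=["run_order", "kind", "sample_id",
                                          "injection", "aa", "element", "delta"])
    return session, dict(STANDARD_TRUTHS)


# ---------------------------------------------------------------------------
# Grains
# ---------------------------------------------------------------------------

def make_grains(scenario: SimScenario
                ) -> tuple[list[GrainSample], list[GrainSample], dict]:
    """Modern and charred grain sets with a known offset vector.

    Moderns carry AA plus bulk values consistent with the generating
    Δ_AA-bulk offsets; charred grains carry bulk values shifted by the
    configured charring offsets, all with Gaussian measurement noise.
    Returns (moderns, charred, truth) where truth holds the generating
    offsets and the charred grains' true AA values.
    """
    rng = scenario.rng(4)
    species = ["Hordeum vulgare", "Triticum monococcum", "Triticum durum",
               "Triticum dicoccum"]
    sd = scenario.grain_noise_sd
    bulk_c_true, bulk_n_true = -23.5, 4.0

    moderns = []
    for i in range(scenario.n_grain_moderns):
        bc = bulk_c_true + rng.normal(0, 0.5)
        bn = bulk_n_true + rng.normal(0, 0.8)
        aa_values: dict[str, dict[str, tuple[float, float]]] = {"C": {}, "N": {}}
        for (aa, el), off in GRAIN_TRUE_OFFSETS.items():
            base = bc if el == "C" else bn
            noise = rng.normal(0, sd) if sd > 0 else 0.0
            aa_values[el][aa] = (base + off + noise, sd)
        moderns.append(GrainSample(f"MOD{i + 1}", species[i % len(species)],
                                   "modern", (bc, sd), (bn, sd), aa_values))

    charred = []
    truth_aa = {}
    for i in range(scenario.n_grain_charred):
        bc = bulk_c_true + rng.normal(0, 0.5)
        bn = bulk_n_true + rng.normal(0, 0.8)
        noise_c = rng.normal(0, sd) if sd > 0 else 0.0
        noise_n = rng.normal(0, sd) if sd > 0 else 0.0
        sid = f"ARCH{i + 1}"
        charred.append(GrainSample(
            sid, species[i % len(species)], "charred",
            (bc + CHARRING_OFFSETS["C"][0] + noise_c, sd),
            (bn + CHARRING_OFFSETS["N"][0] + noise_n, sd)))
        truth_aa[sid] = {(aa, el): (bc if el == "C" else bn) + off
                         for (aa, el), off in GRAIN_TRUE_OFFSETS.items()}
    truth = {"offsets": dict(GRAIN_TRUE_OFFSETS), "charred_aa": truth_aa,
             "charring": dict(CHARRING_OFFSETS)}
    return moderns, charred, truth


def consumers_to_table(consumers: Sequence[ConsumerProfile],
                       tissue: str = "bone collagen"):
    """Serialize consumer profiles to a validated :class:`IsotopeTable`."""
    from .tables_io import IsotopeTable

    rows = [(c.sample_id, c.sex, tissue, analyte, element, delta, sd, 3)
            for c in consumers
            for (element, analyte), (delta, sd) in sorted(c.values.items())]
    return IsotopeTable(pd.DataFrame(
        rows, columns=["sample_id", "sex", "tissue", "analyte", "element",
                       "delta", "sd", "n_replicates"]))
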