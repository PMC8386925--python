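"""Concentration-dependent mixing arithmetic and the grid-search oracle."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ..errors import DegenerateSignalError, DomainError
from .model import ConsumerProfile, ModelSpec, SignalDef, SourceGroup, \
    signal_concentration, source_signal_value


@dataclass
class FitDesign:
    """Numeric arrays for one (spec, consumer) fit.

    Shapes: K sources × S signals.  ``mu``/``var_src`` are the prior means /
    variances of the dietary-side source values, ``q`` the carrier
    concentrations, ``off_mean``/``var_off`` the diet-to-consumer offsets,
    ``x``/``var_meas`` the consumer's measured values and variances.
    """

    source_names: list[str]
    signal_names: list[tuple[str, str]]
    q: np.ndarray          # (K, S)
    mu: np.ndarray         # (K, S)
    var_src: np.ndarray    # (K, S)
    off_mean: np.ndarray   # (S,)
    var_off: np.ndarray    # (S,)
    x: np.ndarray          # (S,)
    var_meas: np.ndarray   # (S,)


def build_design(spec: ModelSpec,
                 consumer: ConsumerProfile | None = None) -> FitDesign:
    K, S = len(spec.sources), len(spec.signals)
    q = np.zeros((K, S))
    mu = np.zeros((K, S))
    var = np.zeros((K, S))
    off_mean = np.zeros(S)
    var_off = np.zeros(S)
    x = np.zeros(S)
    var_meas = np.zeros(S)
    for s, sig in enumerate(spec.signals):
        off_mean[s], off_sd = sig.diet_to_consumer_offset
        var_off[s] = off_sd**2
        for k, src in enumerate(spec.sources):
            q[k, s] = signal_concentration(src, sig, spec.fraction_basis,
                                           spec.glycolytic_fallback)
            if q[k, s] > 0:
                m, sd = source_signal_value(src, sig, spec.glycolytic_fallback)
                mu[k, s], var[k, s] = m, sd**2
        if not np.any(q[:, s] > 0):
            raise DegenerateSignalError(
                f"no source carries signal {sig.name} (all concentrations zero)")
        if consumer is not None:
            if sig.name not in consumer.values:
                raise DomainError(
                    f"consumer {consumer.sample_id} lacks signal {sig.name}")
            xv, xsd = consumer.values[sig.name]
            if not xsd > 0:
                raise DomainError(
                    f"consumer {consumer.sample_id} signal {sig.name} needs sd > 0")
            x[s], var_meas[s] = xv, xsd**2
    return FitDesign([s.name for s in spec.sources],
                     [s.name for s in spec.signals],
                     q, mu, var, off_mean, var_off, x, var_meas)


def concentration_weights(diet_fractions: Sequence[float], signal: SignalDef,
                          sources: Sequence[SourceGroup],
                          fraction_basis: str = "protein",
                          glycolytic_fallback: bool = True) -> np.ndarray:
    """Per-source mixing weights for one signal:
    w_i = f_i q_i / Σ_j f_j q_j, where q_i is the carrier concentration."""
    f = np.asarray(diet_fractions, float)
    if f.min() < -1e-12 or abs(f.sum() - 1) > 1e-9:
        raise DomainError("diet fractions must lie on the simplex")
    q = np.array([signal_concentration(s, signal, fraction_basis,
                                       glycolytic_fallback) for s in sources])
    t = f * q
    total = t.sum()
    if total <= 0:
        raise DegenerateSignalError(
            f"signal {signal.name}: zero total carrier concentration")
    return t / total


def forward_predict(diet_fractions: Sequence[float], spec: ModelSpec,
                    source_draws: Mapping[tuple[str, tuple[str, str]], float]
                    | None = None) -> dict[tuple[str, str], float]:
    """Predicted consumer value per signal: the concentration-weighted mean
    of source values plus the diet-to-consumer offset (its prior mean).

    ``source_draws`` may supply realized source values keyed by
    ``(source_name, signal_name)``; otherwise prior means are used.
    """
    f = np.asarray(diet_fractions, float)
    out: dict[tuple[str, str], float] = {}
    for sig in spec.signals:
        w = concentration_weights(f, sig, spec.sources, spec.fraction_basis,
                                  spec.glycolytic_fallback)
        total = 0.0
        for k, src in enumerate(spec.sources):
            if w[k] == 0.0:
                total += 0.0
                continue
            if source_draws is not None and (src.name, sig.name) in source_draws:
                v = source_draws[(src.name, sig.name)]
            else:
                v = source_signal_value(src, sig, spec.glycolytic_fallback)[0]
            total += w[k] * v
        out[sig.name] = total + sig.diet_to_consumer_offset[0]
    return out


def marginal_loglik(f: np.ndarray, d: FitDesign) -> float:
    """Marginal Gaussian log-likelihood of the consumer data given fractions,
    with source values and offsets integrated out analytically."""
    t = f[:, None] * d.q                      # (K, S)
    total = t.sum(axis=0)
    if np.any(total <= 0):  # a degenerate vertex (e.g. 100% of a source
        return -np.inf      # carrying none of some signal) has zero likelihood
    w = t / total
    m = (w * d.mu).sum(axis=0) + d.off_mean
    v = d.var_meas + d.var_off + (w**2 * d.var_src).sum(axis=0)
    r = d.x - m
    return float(-0.5 * np.sum(np.log(2 * np.pi * v) + r * r / v))


def grid_search_mode(design: FitDesign, step: float = 0.01) -> np.ndarray:
    """Brute-force maximum of the marginal likelihood over a simplex grid.

    Independent oracle for the sampler's posterior mode (the prior on
    fractions is flat, so the mode maximizes the likelihood).  Only
    practical for 3–4 sources.
    """
    K = len(design.source_names)
    n = int(round(1.0 / step))
    best, best_ll = None, -np.inf
    if K == 3:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                f = np.array([i, j, n - i - j], float) / n
                ll = marginal_loglik(f, design)
                if ll > best_ll:
                    best, best_ll = f, ll
    elif K == 4:
        for i in range(n + 1):
            for j in range(n + 1 - i):
                for k in range(n + 1 - i - j):
                    f = np.array([i, j, k, n - i - j - k], float) / n
                    ll = marginal_loglik(f, design)
                    if ll > best_ll:
                        best, best_ll = f, ll
    else:
        raise DomainError("grid search supports 3 or 4 sources only")
    return best
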