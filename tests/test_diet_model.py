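"""Mixing-model structure, routing values, and posterior sampling."""

import numpy as np
import pytest

from isodiet.diet_model import (
    ConsumerProfile,
    SignalDef,
    SourceGroup,
    add_olive_oil_source,
    build_model_spec,
    concentration_weights,
    fit,
    fit_protein_vs_wholediet_crosscheck,
    forward_predict,
    grid_search_mode,
)
from isodiet.diet_model.mixing import build_design, marginal_loglik
from isodiet.errors import DegenerateSignalError, ModelSpecError
from isodiet.synthetic_data import SimScenario, make_sources


def _consumer_at(truth, spec, noise_sd=0.0, sd=0.3, seed=0):
    """Consumer generated at known fractions from the spec's prior means."""
    d = build_design(spec)
    f = np.asarray(truth, float)
    t = f[:, None] * d.q
    w = t / t.sum(axis=0)
    pred = (w * d.mu).sum(axis=0) + d.off_mean
    rng = np.random.default_rng(seed)
    x = pred + (rng.normal(size=pred.shape) * noise_sd if noise_sd else 0.0)
    return ConsumerProfile("T", "unknown",
                           {n: (float(x[s]), sd) for s, n in
                            enumerate(d.signal_names)})


class TestSpecAssembly:
    def test_model1_has_six_direct_signals_with_zero_mean_offset(self, sources):
        spec = build_model_spec("model1", sources)
        assert len(spec.signals) == 6
        assert {s.routing for s in spec.signals} == {"source_direct"}
        assert all(s.diet_to_consumer_offset[0] == 0.0 for s in spec.signals)
        assert spec.fraction_basis == "protein"

    def test_model2_has_ten_signals(self, sources):
        spec = build_model_spec("model2", sources)
        assert len(spec.signals) == 10
        routings = {s.name: s.routing for s in spec.signals}
        assert routings[("C", "Ala")] == "glycolytic"
        assert routings[("C", "Glx")] == "carbon_pool"
        assert routings[("C", "Asx")] == "carbon_pool"
        assert routings[("N", "Glx")] == "nitrogen_pool"
        assert spec.fraction_basis == "whole_diet"

    def test_bulk_models_have_two_signals(self, sources):
        assert len(build_model_spec("model0p", sources).signals) == 2
        assert len(build_model_spec("model0wd", sources).signals) == 2

    def test_olive_oil_with_model1_is_a_spec_error(self, sources):
        with pytest.raises(ModelSpecError):
            add_olive_oil_source(sources, model_name="model1")
        oiled = add_olive_oil_source(sources)
        with pytest.raises(ModelSpecError):
            build_model_spec("model1", oiled)

    def test_missing_signal_lists_gaps(self, sources):
        crippled = [SourceGroup(
            s.name,
            {k: v for k, v in s.signal_values.items() if k != ("C", "Leu")},
            s.aa_concentrations, s.macronutrients,
            s.macronutrient_d13c_offsets) for s in sources]
        with pytest.raises(ModelSpecError, match="Leu"):
            build_model_spec("model1", crippled)

    def test_routing_element_consistency_enforced(self):
        with pytest.raises(ModelSpecError):
            SignalDef(("N", "Ala"), "glycolytic", (0.0, 0.5))
        with pytest.raises(ModelSpecError):
            SignalDef(("C", "Glx"), "nitrogen_pool", (0.0, 0.5))


class TestSourceSignalValues:
    @pytest.fixture()
    def synthetic_source(self):
        return SourceGroup(
            "mix", {("C", "bulk"): (0.0, 0.0), ("N", "bulk"): (5.0, 0.0)},
            {"Phe": 0.05},
            {"protein": 0.3, "carbohydrate": 0.5, "lipid": 0.2},
            {"protein": (-20.0, 0.0), "carbohydrate": (-24.0, 0.0),
             "lipid": (-28.0, 0.0)})

    def test_carbon_pool_is_energy_weighted_mean(self, synthetic_source):
        from isodiet.diet_model import source_signal_value

        sig = SignalDef(("C", "Glx"), "carbon_pool", (0.0, 0.0))
        mean, _ = source_signal_value(synthetic_source, sig)
        assert mean == pytest.approx(0.5 * -24 + 0.3 * -20 + 0.2 * -28)  # −23.6

    def test_carbon_pool_invariant_to_weights_when_macros_equal(self):
        from isodiet.diet_model import source_signal_value

        src = SourceGroup(
            "flat", {("C", "bulk"): (-21.0, 0.1)}, {},
            {"protein": 0.6, "carbohydrate": 0.1, "lipid": 0.3},
            {m: (-3.0, 0.0) for m in ("protein", "carbohydrate", "lipid")})
        sig = SignalDef(("C", "Asx"), "carbon_pool", (0.0, 0.0))
        assert source_signal_value(src, sig)[0] == pytest.approx(-24.0)

    def test_nitrogen_pool_offset_shifts_prediction_exactly(self, sources):
        spec = build_model_spec("model2", sources)
        f = [0.4, 0.4, 0.2]
        base = forward_predict(f, spec)
        shifted_spec = build_model_spec(
            "model2", sources, {"offsets": {"nitrogen_pool": (9.5, 1.0)}})
        shifted = forward_predict(f, shifted_spec)
        assert shifted[("N", "Glx")] - base[("N", "Glx")] == pytest.approx(1.5)
        assert shifted[("C", "Leu")] == base[("C", "Leu")]


class TestConcentrationWeights:
    def test_equal_concentrations_reduce_to_fractions(self):
        srcs = [SourceGroup(f"s{i}", {("C", "Phe"): (-20.0 - i, 0.1),
                                      ("C", "bulk"): (-20.0, 0.1)},
                            {"Phe": 0.05},
                            {"protein": 1.0, "carbohydrate": 0.0, "lipid": 0.0},
                            {}) for i in range(3)]
        sig = SignalDef(("C", "Phe"), "source_direct", (0.0, 0.5))
        f = [0.2, 0.5, 0.3]
        np.testing.assert_allclose(concentration_weights(f, sig, srcs), f)

    def test_forced_two_source_arithmetic(self):
        srcs = [SourceGroup("a", {("C", "Phe"): (-20.0, 0.1)}, {"Phe": 0.10},
                            {"protein": 1.0, "carbohydrate": 0, "lipid": 0}, {}),
                SourceGroup("b", {("C", "Phe"): (-25.0, 0.1)}, {"Phe": 0.05},
                            {"protein": 1.0, "carbohydrate": 0, "lipid": 0}, {})]
        sig = SignalDef(("C", "Phe"), "source_direct", (0.0, 0.5))
        w = concentration_weights([0.5, 0.5], sig, srcs)
        np.testing.assert_allclose(w, [2 / 3, 1 / 3])

    def test_permutation_equivariance(self, sources):
        sig = SignalDef(("C", "Phe"), "source_direct", (0.0, 0.5))
        f = np.array([0.2, 0.5, 0.3])
        w = concentration_weights(f, sig, list(sources))
        perm = [2, 0, 1]
        w_perm = concentration_weights(f[perm], sig, [sources[i] for i in perm])
        np.testing.assert_allclose(w_perm, w[perm])

    def test_all_zero_concentration_is_degenerate(self):
        srcs = [SourceGroup("a", {("C", "Phe"): (-20.0, 0.1)}, {"Phe": 0.0},
                            {"protein": 1.0, "carbohydrate": 0, "lipid": 0}, {})]
        sig = SignalDef(("C", "Phe"), "source_direct", (0.0, 0.5))
        with pytest.raises(DegenerateSignalError):
            concentration_weights([1.0], sig, srcs)


class TestForwardPredict:
    def test_single_source_returns_value_plus_offset(self, sources, spec1):
        pred = forward_predict([1.0, 0.0, 0.0], spec1)
        for sig in spec1.signals:
            want = sources[0].signal_values[sig.name][0] \
                + sig.diet_to_consumer_offset[0]
            assert pred[sig.name] == pytest.approx(want)

    def test_equal_source_values_are_a_fixed_point(self):
        srcs = [SourceGroup(f"s{i}", {("C", "Phe"): (-21.0, 0.3),
                                      ("N", "Phe"): (4.0, 0.3),
                                      ("C", "bulk"): (-22.0, 0.3),
                                      ("N", "bulk"): (5.0, 0.3),
                                      ("C", "Leu"): (-25.0, 0.3),
                                      ("C", "Val"): (-22.0, 0.3),
                                      ("C", "Ile"): (-23.0, 0.3),
                                      ("N", "Lys"): (3.0, 0.3)},
                            {"Phe": 0.05 * (i + 1), "Leu": 0.05, "Val": 0.05,
                             "Ile": 0.05, "Lys": 0.05},
                            {"protein": 1.0, "carbohydrate": 0, "lipid": 0},
                            {}) for i in range(2)]
        spec = build_model_spec("model1", srcs)
        for f in ([0.5, 0.5], [0.9, 0.1], [0.1, 0.9]):
            pred = forward_predict(f, spec)
            assert pred[("C", "Phe")] == pytest.approx(-21.0)

    def test_posterior_mode_matches_grid_search(self, spec1):
        """Brute-force 0.01-step simplex grid and the sampler's modal draw
        agree within 0.02 on a 3-source toy."""
        consumer = _consumer_at([0.3, 0.5, 0.2], spec1, noise_sd=0.3, seed=5)
        post = fit(consumer, spec1, {"seed": 11})
        gmode = grid_search_mode(build_design(spec1, consumer), step=0.01)
        for k, name in enumerate(post.source_names):
            assert abs(post.map_estimate[name] - gmode[k]) <= 0.02


class TestFit:
    def test_degenerate_recovery_of_pure_diet(self, sources):
        # zero noise everywhere: tight source baselines and offsets, so the
        # posterior must collapse onto the generating vertex
        tight = [SourceGroup(s.name,
                             {k: (v[0], 0.05) for k, v in s.signal_values.items()},
                             s.aa_concentrations, s.macronutrients,
                             s.macronutrient_d13c_offsets) for s in sources]
        spec = build_model_spec("model1", tight,
                                {"offsets": {"source_direct": (0.0, 0.05)}})
        consumer = _consumer_at([1.0, 0.0, 0.0], spec, noise_sd=0.0, sd=0.05)
        post = fit(consumer, spec, {"seed": 3})
        assert post.median("cereals") >= 0.95

    def test_same_seed_gives_bit_identical_results(self, spec1, sources):
        consumer = _consumer_at([0.4, 0.4, 0.2], spec1, noise_sd=0.5, seed=2)
        p1 = fit(consumer, spec1, {"seed": 17})
        p2 = fit(consumer, spec1, {"seed": 17})
        assert p1.percentile_table.equals(p2.percentile_table)
        for n in p1.source_names:
            np.testing.assert_array_equal(p1.chains[n], p2.chains[n])

    def test_chains_stay_on_simplex(self, spec1):
        consumer = _consumer_at([0.4, 0.4, 0.2], spec1, noise_sd=0.5, seed=2)
        post = fit(consumer, spec1, {"seed": 23})
        mat = post.chain_matrix()
        assert mat.min() >= 0
        np.testing.assert_allclose(mat.sum(axis=1), 1.0, atol=1e-12)

    def test_percentile_table_is_monotone(self, spec1):
        consumer = _consumer_at([0.4, 0.4, 0.2], spec1, noise_sd=0.5, seed=2)
        post = fit(consumer, spec1, {"seed": 29})
        vals = post.percentile_table.to_numpy()
        assert (np.diff(vals, axis=1) >= 0).all()

    def test_source_reordering_permutes_output_exactly(self, sources):
        perm = [2, 0, 1]
        spec_a = build_model_spec("model1", list(sources))
        spec_b = build_model_spec("model1", [sources[i] for i in perm])
        consumer = _consumer_at([0.4, 0.4, 0.2], spec_a, noise_sd=0.5, seed=2)
        pa = fit(consumer, spec_a, {"seed": 31})
        pb = fit(consumer, spec_b, {"seed": 31})
        for name in pa.source_names:
            assert pa.percentile_table.loc[name].equals(
                pb.percentile_table.loc[name])

    def test_widening_measurement_sd_never_narrows_68ci(self, spec1):
        d = build_design(spec1)
        base = _consumer_at([0.4, 0.4, 0.2], spec1, noise_sd=0.4, sd=0.3, seed=4)
        wide = ConsumerProfile("T", "unknown",
                               {k: (v, 2.0) for k, (v, _) in base.values.items()})
        for seed in (1, 2, 3):
            p_base = fit(base, spec1, {"seed": seed})
            p_wide = fit(wide, spec1, {"seed": seed})
            for name in p_base.source_names:
                lo_b, hi_b = p_base.credible_interval(name, 68.0)
                lo_w, hi_w = p_wide.credible_interval(name, 68.0)
                assert (hi_w - lo_w) >= (hi_b - lo_b) * 0.95

    def test_identical_sources_return_flat_dirichlet_prior(self):
        """No-information limit: with all source signals equal the
        posterior must match the flat Dirichlet prior within MC error."""
        vals = {("C", "Leu"): (-25.0, 0.5), ("C", "Val"): (-22.0, 0.5),
                ("C", "Ile"): (-23.0, 0.5), ("C", "Phe"): (-21.0, 0.5),
                ("N", "Phe"): (4.0, 0.5), ("N", "Lys"): (3.0, 0.5),
                ("C", "bulk"): (-22.0, 0.5), ("N", "bulk"): (5.0, 0.5)}
        srcs = [SourceGroup(f"s{i}", dict(vals),
                            {"Leu": .05, "Val": .05, "Ile": .05, "Phe": .05,
                             "Lys": .05},
                            {"protein": 1.0, "carbohydrate": 0, "lipid": 0},
                            {}) for i in range(3)]
        spec = build_model_spec("model1", srcs)
        consumer = ConsumerProfile("T", "unknown",
                                   {k: (v, 0.5) for k, (v, _) in vals.items()
                                    if k[1] != "bulk"})
        post = fit(consumer, spec, {"seed": 7, "iterations": 20000})
        mat = post.chain_matrix()
        # Dirichlet(1,1,1) marginals: mean 1/3, sd sqrt(2)/3/sqrt(4)
        assert np.allclose(mat.mean(axis=0), 1 / 3, atol=0.03)
        assert np.allclose(mat.std(axis=0), np.sqrt(2 / 36), atol=0.03)

    def test_acceptance_rate_reported_and_reasonable(self, spec1):
        consumer = _consumer_at([0.4, 0.4, 0.2], spec1, noise_sd=0.5, seed=2)
        post = fit(consumer, spec1, {"seed": 37})
        assert 0.05 <= post.diagnostics["acceptance_rate"] <= 0.8
        assert post.diagnostics["warnings"] == []


class TestCrosscheck:
    def test_consistent_truth_overlaps_for_all_sources(self, sources, spec2):
        consumer = _consumer_at([0.45, 0.40, 0.15], spec2, noise_sd=0.4,
                                sd=0.5, seed=8)
        report = fit_protein_vs_wholediet_crosscheck(
            consumer, list(sources), mcmc={"seed": 41})
        assert report["consistent"]
        assert set(report["sources"]) == {s.name for s in sources}

    def test_adversarial_trophic_shift_flags_non_overlap(self, sources, spec2):
        """Carbon-pool/glycolytic signals depleted by an unmodelled 8‰
        (an oil-heavy diet fitted without an oil source) must break the
        protein/whole-diet agreement."""
        consumer = _consumer_at([0.45, 0.40, 0.15], spec2, noise_sd=0.0,
                                sd=0.15, seed=8)
        values = dict(consumer.values)
        for key in [("C", "Ala"), ("C", "Glx"), ("C", "Asx")]:
            v, sd = values[key]
            values[key] = (v - 8.0, sd)
        bad = ConsumerProfile("T", "unknown", values)
        report = fit_protein_vs_wholediet_crosscheck(
            bad, list(sources), mcmc={"seed": 43})
        assert not report["consistent"]

    def test_overlap_metric_is_symmetric(self):
        from isodiet.diet_model.fit import _interval_overlap

        a, b = (0.1, 0.4), (0.3, 0.6)
        assert _interval_overlap(a, b) == _interval_overlap(b, a)


class TestOliveOil:
    def test_zero_suess_keeps_modern_value(self, sources):
        oiled = add_olive_oil_source(sources, (-29.0, 0.5), (0.0, 0.0))
        oil = oiled[-1]
        assert oil.signal_values[("C", "bulk")][0] == pytest.approx(-29.0)

    def test_oil_has_zero_weight_on_nitrogen_signals(self, sources):
        oiled = add_olive_oil_source(sources)
        spec = build_model_spec("model2", oiled)
        sig = next(s for s in spec.signals if s.name == ("N", "Glx"))
        w = concentration_weights([0.25, 0.25, 0.25, 0.25], sig, oiled,
                                  "whole_diet")
        assert w[-1] == 0.0

    def test_marginal_loglik_handles_degenerate_vertex(self, sources):
        oiled = add_olive_oil_source(sources)
        spec = build_model_spec("model2", oiled)
        d = build_design(spec, _consumer_at([0.3, 0.3, 0.1, 0.3], spec,
                                            noise_sd=0.3, seed=1))
        assert marginal_loglik(np.array([0.0, 0.0, 0.0, 1.0]), d) == -np.inf
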