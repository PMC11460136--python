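"""Standard curve, the two-step mass arithmetic, qualitative calls and
whole-sample quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from herbq.errors import (
    DegenerateFitError,
    InputError,
    MissingDataError,
    NoValidStandardError,
    UnquantifiableSampleError,
    UnresolvedCompositionError,
)
from herbq.quantify import (
    MIXED,
    PURE_BACKGROUND,
    PURE_TARGET,
    Composition,
    QuantSample,
    SiteCall,
    call_presence,
    component_weight,
    compute_bias,
    fit_standard_curve,
    identify_composition,
    mean_bias,
    quantify_sample,
    select_external_standard,
    total_weight,
)
from herbq.simulate import (
    FrequencyMeasurement,
    MixtureSpec,
    simulate_dilution_series,
    simulate_measurements,
)


class TestStandardCurve:
    def test_identity_line_exact(self):
        curve = fit_standard_curve([(0.0, 0.0), (0.5, 0.5), (1.0, 1.0)])
        assert curve.slope == pytest.approx(1.0, abs=1e-12)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.passes_linearity

    def test_seven_level_noise_free_series_r2_one(self):
        """The 0/10/30/50/70/90/100% design recovers a perfect line."""
        props = [0.0, 0.1, 0.3, 0.5, 0.7, 0.9, 1.0]
        curve = fit_standard_curve([(p, p) for p in props])
        assert curve.r_squared == pytest.approx(1.0, abs=1e-12)
        assert curve.slope == pytest.approx(1.0, abs=1e-12)

    def test_simulated_series_recovers_distortion(self, panel):
        base = MixtureSpec(
            {"F. cirrhosa": 0.2}, noise_sd=0.003,
            distortion=(0.994, 0.002), seed=101,
        )
        levels = [0.01, 0.02, 0.04, 0.06, 0.08, 0.10, 0.20, 0.30, 0.40, 0.50]
        table = simulate_dilution_series(
            base, "F. hupehensis", levels, 3, panel=panel
        )
        site = panel.site_for("F. hupehensis")
        rows = table[
            (table["locus"] == site.locus)
            & (table["position"] == site.position)
            & (table["allele"] == site.target_allele)
        ]
        means = rows.groupby("level")["frequency"].mean()
        curve = fit_standard_curve(list(means.items()))
        assert 0.98 <= curve.slope <= 1.01
        assert curve.r_squared >= 0.99

    def test_noisy_points_fail_gate(self):
        rng = np.random.default_rng(0)
        x = np.linspace(0, 1, 8)
        y = x + rng.normal(0, 0.15, size=8)
        curve = fit_standard_curve(list(zip(x, y)))
        assert curve.r_squared < 0.99
        assert not curve.passes_linearity

    def test_too_few_points(self):
        with pytest.raises(InputError):
            fit_standard_curve([(0.0, 0.0), (1.0, 1.0)])

    def test_degenerate_proportions(self):
        with pytest.raises((DegenerateFitError, InputError)):
            fit_standard_curve([(0.5, 0.1), (0.5, 0.2), (0.5, 0.3)])

    def test_inversion(self):
        curve = fit_standard_curve([(0.0, 0.002), (0.5, 0.499), (1.0, 0.996)])
        assert curve.invert(curve.predict(0.3)) == pytest.approx(0.3)


class TestMassArithmetic:
    def test_capsule_worked_chain(self):
        """0.1001 g at 50% ⇒ 0.2002 g total; 33% ⇒ 0.0661 g; 20% ⇒ 0.0400 g."""
        w_total = total_weight(0.1001, 0.50)
        assert w_total == pytest.approx(0.2002, abs=1e-12)
        assert round(component_weight(w_total, 0.33), 4) == 0.0661
        assert round(component_weight(w_total, 0.20), 4) == 0.0400

    def test_mixed_powder_sample_one(self):
        assert round(component_weight(0.2003, 0.34), 4) == 0.0681

    def test_pure_standard_recovers_itself(self):
        assert total_weight(0.25, 1.0) == pytest.approx(0.25)

    def test_zero_frequency_unquantifiable(self):
        with pytest.raises(UnquantifiableSampleError):
            total_weight(0.1, 0.0)

    def test_frequency_above_one_rejected(self):
        with pytest.raises(InputError):
            total_weight(0.1, 1.2)

    def test_absent_species_weighs_nothing(self):
        assert component_weight(0.2, 0.0) == 0.0

    @given(
        w=st.floats(1e-6, 10.0, allow_nan=False),
        r=st.floats(1e-9, 1.0, allow_nan=False),
    )
    @settings(max_examples=200, derandomize=True)
    def test_step_composition_identity(self, w, r):
        """component_weight(total_weight(w, r), r) == w for all valid (w, r)."""
        assert component_weight(total_weight(w, r), r) == pytest.approx(
            w, rel=1e-12
        )


class TestBias:
    def test_identity_zero(self):
        assert compute_bias(0.5, 0.5).percent == 0.0

    def test_ten_percent_passes(self):
        b = compute_bias(1.1, 1.0)
        assert b.percent == pytest.approx(10.0)
        assert b.passes

    def test_bound_is_strict(self):
        assert not compute_bias(1.25, 1.0).passes

    def test_mean_of_reported_validation_biases(self):
        """The three mixed-powder biases average to the published 5.973%."""
        assert mean_bias([6.907, 7.075, 3.937]) == pytest.approx(5.973, abs=1e-9)

    def test_nonpositive_actual_rejected(self):
        with pytest.raises(InputError):
            compute_bias(0.1, 0.0)


def measurements_for(site, freq, n=3, sample_id="s"):
    out = []
    for rep in range(1, n + 1):
        out.append(
            FrequencyMeasurement(
                site.locus, site.position, site.target_allele, freq, rep, sample_id
            )
        )
        out.append(
            FrequencyMeasurement(
                site.locus, site.position, site.background_allele,
                1 - freq, rep, sample_id,
            )
        )
    return out


class TestPresenceCalls:
    def test_pure_target(self, panel):
        site = panel.primary
        call = call_presence(measurements_for(site, 1.0), site)
        assert call.call == PURE_TARGET

    def test_mixed(self, panel):
        site = panel.primary
        call = call_presence(measurements_for(site, 0.66), site)
        assert call.call == MIXED
        assert call.frequencies[site.target_allele] == pytest.approx(0.66)

    def test_trace_background_below_threshold_is_pure(self, panel):
        site = panel.primary
        call = call_presence(measurements_for(site, 0.985), site, threshold=0.02)
        assert call.call == PURE_TARGET

    def test_single_allele_rows_complemented(self, panel):
        site = panel.primary
        only_background = [
            FrequencyMeasurement(
                site.locus, site.position, site.background_allele, 1.0, 1, "s"
            )
        ]
        call = call_presence(only_background, site)
        assert call.call == PURE_BACKGROUND

    def test_no_measurements_missing_data(self, panel):
        with pytest.raises(MissingDataError):
            call_presence([], panel.primary)


def call(key, kind, taxon_allele_freq=1.0):
    return SiteCall(site_key=key, call=kind, frequencies={"X": taxon_allele_freq})


class TestComposition:
    def test_pure_group_only(self, grouping):
        comp = identify_composition({"FCB": call("ITS:341", PURE_TARGET)}, grouping)
        assert comp.group_present and not comp.adulterants and not comp.unresolved

    def test_mixed_with_typed_adulterant(self, grouping):
        comp = identify_composition(
            {
                "FCB": call("ITS:341", MIXED),
                "F. thunbergii": call("ITS:361", MIXED),
                "F. ussuriensis": call("ITS:366", PURE_BACKGROUND),
            },
            grouping,
        )
        assert comp.members == {"FCB", "F. thunbergii"}
        assert not comp.unresolved

    def test_mixed_with_no_positive_species_site_unresolved(self, grouping):
        comp = identify_composition(
            {
                "FCB": call("ITS:341", MIXED),
                "F. thunbergii": call("ITS:361", PURE_BACKGROUND),
            },
            grouping,
        )
        assert comp.unresolved

    def test_missing_species_data_degrades_to_unresolved(self, grouping):
        comp = identify_composition(
            {
                "FCB": call("ITS:341", MIXED),
                "F. thunbergii": call("ITS:361", MIXED),
            },
            grouping,
            expected_taxa=["F. thunbergii", "F. ussuriensis"],
        )
        assert comp.unresolved

    def test_group_call_required(self, grouping):
        with pytest.raises(MissingDataError):
            identify_composition({}, grouping)


class TestExternalStandardSelection:
    def test_first_absent_candidate(self):
        comp = Composition(True, frozenset({"F. ussuriensis"}), False, "FCB")
        assert (
            select_external_standard(
                comp, ["F. hupehensis", "F. thunbergii"]
            )
            == "F. hupehensis"
        )

    def test_unadulterated_sample_takes_first(self):
        comp = Composition(True, frozenset(), False, "FCB")
        assert select_external_standard(comp, ["F. thunbergii"]) == "F. thunbergii"

    def test_all_present_is_error(self):
        comp = Composition(True, frozenset({"a", "b"}), False, "FCB")
        with pytest.raises(NoValidStandardError):
            select_external_standard(comp, ["a", "b"])


def capsule_measurements(panel, f_std=0.50, f_fcb=0.33, f_uss=0.20, n=3):
    """Self-produced capsule scenario: standard / FCB / one adulterant."""
    meas = []
    meas += measurements_for(panel.site_for("F. thunbergii"), f_std, n)
    meas += measurements_for(panel.primary, f_fcb, n)
    meas += measurements_for(panel.site_for("F. ussuriensis"), f_uss, n)
    meas += measurements_for(panel.site_for("F. hupehensis"), 0.0, n)
    meas += measurements_for(panel.site_for("FPB"), 0.0, n)
    return meas


class TestQuantifySample:
    def test_capsule_scenario_reproduces_published_weights(self, panel):
        sample = QuantSample(
            "sdcb", "F. thunbergii", 0.1001, capsule_measurements(panel)
        )
        result = quantify_sample(sample, panel)
        # 0.50 + 0.33 + 0.20 = 1.03 sits inside the ±0.05 consistency band
        assert not result.warnings
        assert round(result.w_total, 4) == 0.2002
        assert round(result.component_weights["FCB"], 4) == 0.0661
        assert round(result.component_weights["F. ussuriensis"], 4) == 0.0400
        # the standard's own mass comes back exactly
        assert result.component_weights["F. thunbergii"] == pytest.approx(
            0.1001, abs=1e-15
        )

    def test_noise_free_simulation_round_trip(self, panel, grouping):
        truth = {
            "F. cirrhosa": 0.0661,
            "F. ussuriensis": 0.0400,
            "F. thunbergii": 0.1001,
        }
        mix = MixtureSpec(
            dict(truth), impurity_mass=0.03, noise_sd=0.0,
            distortion=(1.0, 0.0), seed=2,
        )
        meas = simulate_measurements(mix, panel, n_replicates=3, sample_id="x")
        sample = QuantSample("x", "F. thunbergii", 0.1001, meas)
        result = quantify_sample(sample, panel, grouping=grouping)
        assert result.w_total == pytest.approx(sum(truth.values()), abs=1e-12)
        assert result.component_weights["FCB"] == pytest.approx(
            truth["F. cirrhosa"], abs=1e-12
        )
        assert result.component_weights["F. ussuriensis"] == pytest.approx(
            truth["F. ussuriensis"], abs=1e-12
        )

    def test_scale_equivariance(self, panel, grouping):
        base = MixtureSpec(
            {"F. cirrhosa": 0.10, "F. ussuriensis": 0.05, "F. thunbergii": 0.08},
            noise_sd=0.0, distortion=(1.0, 0.0), seed=3,
        )
        results = []
        for c in (1.0, 3.5):
            mix = base.scaled(c)
            meas = simulate_measurements(mix, panel, n_replicates=2)
            sample = QuantSample("x", "F. thunbergii", 0.08 * c, meas)
            results.append(quantify_sample(sample, panel, grouping=grouping))
        for name, w in results[0].component_weights.items():
            assert results[1].component_weights[name] == pytest.approx(3.5 * w)
        assert results[1].w_total == pytest.approx(3.5 * results[0].w_total)

    def test_zero_standard_frequency_unquantifiable(self, panel):
        meas = capsule_measurements(panel, f_std=0.0, f_fcb=0.66, f_uss=0.34)
        sample = QuantSample("x", "F. thunbergii", 0.1, meas)
        with pytest.raises(UnquantifiableSampleError):
            quantify_sample(sample, panel)

    def test_unresolved_composition_refused(self, panel):
        # adulterant allele at the group site, but every species site negative
        meas = []
        meas += measurements_for(panel.primary, 0.66)
        for taxon in ("F. thunbergii", "F. ussuriensis", "F. hupehensis", "FPB"):
            meas += measurements_for(panel.site_for(taxon), 0.0)
        sample = QuantSample("x", "F. thunbergii", 0.1, meas)
        with pytest.raises(UnresolvedCompositionError):
            quantify_sample(sample, panel)

    def test_frequency_sum_warning(self, panel):
        # component frequencies sum to 0.85: a chunk of amplifying mass is
        # unexplained, so a consistency warning must surface
        meas = capsule_measurements(panel, f_std=0.40, f_fcb=0.30, f_uss=0.15)
        sample = QuantSample("x", "F. thunbergii", 0.1, meas)
        with pytest.warns(UserWarning, match="sum"):
            result = quantify_sample(sample, panel)
        assert result.warnings

    def test_biases_filled_from_actuals(self, panel):
        sample = QuantSample(
            "sdcb", "F. thunbergii", 0.1001, capsule_measurements(panel),
            actual_weights={"FCB": 0.0656, "F. ussuriensis": 0.0401},
        )
        result = quantify_sample(sample, panel)
        assert set(result.biases) == {"FCB", "F. ussuriensis"}
        assert all(b.passes for b in result.biases.values())

    def test_curve_inversion_optional(self, panel):
        curve = fit_standard_curve(
            [(p, 0.994 * p + 0.002) for p in (0.0, 0.25, 0.5, 0.75, 1.0)]
        )
        f_std, f_fcb, f_uss = (
            0.994 * 0.50 + 0.002, 0.994 * 0.33 + 0.002, 0.994 * 0.17 + 0.002
        )
        meas = capsule_measurements(panel, f_std, f_fcb, f_uss)
        sample = QuantSample("x", "F. thunbergii", 0.1001, meas)
        result = quantify_sample(sample, panel, curve=curve)
        assert result.w_total == pytest.approx(0.2002, abs=1e-9)
        assert result.component_weights["FCB"] == pytest.approx(
            0.2002 * 0.33, abs=1e-9
        )


class TestReports:
    def test_json_report_rounds_at_the_edge(self, panel, tmp_path):
        sample = QuantSample(
            "sdcb", "F. thunbergii", 0.1001, capsule_measurements(panel)
        )
        result = quantify_sample(sample, panel)
        d = result.to_dict()
        assert d["component_weights_g"]["FCB"] == 0.0661
        assert d["frequencies_percent"]["F. ussuriensis"] == 20
        path = tmp_path / "q.tsv"
        result.to_tsv(path)
        text = path.read_text()
        assert "0.0661" in text and "TOTAL" in text
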