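"""Preset invariants, Fridericia inversion, and Hill-type drug effects."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import apscreen as ap
from apscreen._errors import InvalidConfigError


class TestPhenotypePreset:
    def test_default_presets_store_uncorrected_targets(self):
        # corrected targets recover the published anchors after inversion
        for preset, anchors in [
            (ap.CT_PRESET, {0.20: 159.8, 0.50: 315.5, 0.90: 369.7}),
            (ap.AM_PRESET, {0.20: 69.8, 0.50: 114.9, 0.90: 156.1}),
        ]:
            corrected = preset.corrected_targets()
            for f, v in anchors.items():
                assert corrected[f] == pytest.approx(v, abs=1e-9)

    def test_fridericia_inversion_value(self):
        # AM APD90: 156.1 ms corrected at 237/min -> 156.1 * (60/237)^(1/3)
        unc = ap.fridericia_invert(156.1, 60.0 / 237.0)
        assert unc == pytest.approx(98.8, abs=0.1)
        assert ap.AM_PRESET.targets()[0.90] == pytest.approx(unc, abs=1e-9)

    def test_inversion_round_trip(self):
        for capd, rate in [(156.1, 237.0), (369.7, 83.7), (250.0, 60.0)]:
            ibi = 60.0 / rate
            assert ap.fridericia_correct(
                ap.fridericia_invert(capd, ibi), ibi) == pytest.approx(capd, rel=1e-12)

    def test_non_monotone_targets_rejected(self):
        with pytest.raises(InvalidConfigError):
            ap.PhenotypePreset(
                name="bad", beat_rate=60.0,
                apd_targets=((0.30, 200.0), (0.90, 200.0)),
            )

    def test_apd90_must_fit_inter_beat_interval(self):
        with pytest.raises(InvalidConfigError):
            ap.PhenotypePreset(
                name="bad", beat_rate=240.0,
                apd_targets=((0.30, 100.0), (0.90, 260.0)),  # IBI = 250 ms
            )

    @pytest.mark.parametrize("field,value", [
        ("amplitude", 0.0), ("noise_sd", -0.1), ("beat_rate", 0.0),
    ])
    def test_scalar_invariants(self, field, value):
        kwargs = dict(name="bad", beat_rate=60.0,
                      apd_targets=((0.30, 100.0), (0.90, 300.0)))
        kwargs[field] = value
        with pytest.raises(InvalidConfigError):
            ap.PhenotypePreset(**kwargs)


class TestDrugEffects:
    def _model(self, **kw):
        defaults = dict(target="beat_rate", direction="decrease",
                        emax=0.5, ec50=1.0, hill_coefficient=1.0)
        defaults.update(kw)
        return ap.DrugEffectModel("d", effects=(ap.DrugEffect(**defaults),))

    def test_zero_concentration_is_identity(self):
        out = ap.apply_drug_effect(ap.CT_PRESET, self._model(), 0.0)
        assert out == ap.CT_PRESET

    def test_hill_midpoint(self):
        # at c = EC50 the fractional change is emax/2
        out = ap.apply_drug_effect(ap.CT_PRESET, self._model(), 1.0)
        assert out.beat_rate == pytest.approx(ap.CT_PRESET.beat_rate * (1 - 0.25))

    def test_hill_evaluation_at_9x_ec50(self):
        # c = 9*EC50, h = 1 -> occupancy 0.9 -> rate scaled by 1 - 0.45
        out = ap.apply_drug_effect(ap.CT_PRESET, self._model(), 9.0)
        assert out.beat_rate == pytest.approx(ap.CT_PRESET.beat_rate * 0.55, rel=1e-12)

    def test_apd_scale_applies_uniformly(self):
        m = self._model(target="apd_scale", direction="increase", emax=0.3)
        out = ap.apply_drug_effect(ap.CT_PRESET, m, 1e6)
        for f, v in ap.CT_PRESET.targets().items():
            assert out.targets()[f] == pytest.approx(v * 1.3, rel=1e-6)

    def test_upstroke_effect_divides_time_constant(self):
        m = self._model(target="upstroke_velocity_scale", direction="decrease", emax=0.5)
        out = ap.apply_drug_effect(ap.CT_PRESET, m, 1e9)
        assert out.upstroke_time_constant == pytest.approx(
            ap.CT_PRESET.upstroke_time_constant / 0.5, rel=1e-6)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        emax=st.floats(0.0, 0.9), ec50=st.floats(0.01, 100.0),
        hill=st.floats(0.3, 4.0),
        concs=st.lists(st.floats(0.0, 1e3), min_size=2, max_size=6),
    )
    def test_hill_effect_monotone_in_concentration(self, emax, ec50, hill, concs):
        eff = ap.DrugEffect(target="beat_rate", direction="decrease",
                            emax=emax, ec50=ec50, hill_coefficient=hill)
        ordered = sorted(concs)
        scales = [eff.scale(c) for c in ordered]
        assert all(a >= b - 1e-12 for a, b in zip(scales, scales[1:]))

    def test_event_incidence_fractions_validated(self):
        with pytest.raises(InvalidConfigError):
            ap.DrugEffectModel("d", event_incidence=(
                ((10.0, "CT"), (("ead", 0.7), ("arrest", 0.5))),
            ))

    def test_incidence_lookup(self):
        m = ap.DrugEffectModel("d", event_incidence=(
            ((10.0, "CT"), (("ead", 2 / 6), ("arrest", 4 / 6))),
        ))
        assert m.incidence(10.0, "CT") == {"ead": pytest.approx(1 / 3), "arrest": pytest.approx(2 / 3)}
        assert m.incidence(10.0, "AM") == {}
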