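"""Control coefficients: oracle checks and composite behaviour."""

import math

import numpy as np
import pytest

import sifkit as sk
from sifkit.errors import ReadoutError, ValidationError
from sifkit.model import PerturbationSpec


def s_at_horizon(model):
    traj = sk.integrate(model)
    return float(traj.value("s")[-1])


class TestLinearDecayOracle:
    """ds/dt = -ks has the closed form s(T) = s0 exp(-kT), so the
    forward-difference coefficient is known analytically:
    C(delta) = (exp(-kT delta) - 1) / delta, tending to -kT."""

    def test_matches_closed_form_at_working_delta(self, decay):
        k, T, delta = decay.params["k"], decay.horizon, 0.1
        spec = PerturbationSpec((("decay", 1.0),), delta=delta)
        c = sk.control_coefficient(decay, s_at_horizon, spec)
        expected = (math.exp(-k * T * delta) - 1.0) / delta
        assert c.value == pytest.approx(expected, rel=1e-5)

    def test_richardson_extrapolation_reaches_derivative(self, decay):
        """2 C(d/2) - C(d) cancels the O(delta) error of the forward
        difference and lands on -kT to 1e-4."""
        k, T = decay.params["k"], decay.horizon
        cs = {}
        for d in (0.004, 0.002):
            spec = PerturbationSpec((("decay", 1.0),), delta=d)
            cs[d] = sk.control_coefficient(decay, s_at_horizon, spec).value
        richardson = 2.0 * cs[0.002] - cs[0.004]
        assert richardson == pytest.approx(-k * T, abs=1e-4)

    def test_halving_delta_halves_the_bias(self, decay):
        """Forward-difference bias is O(delta): halving delta roughly
        halves the distance to the analytic derivative."""
        k, T = decay.params["k"], decay.horizon
        err = {}
        for d in (0.08, 0.04):
            spec = PerturbationSpec((("decay", 1.0),), delta=d)
            err[d] = abs(sk.control_coefficient(decay, s_at_horizon,
                                                spec).value + k * T)
        assert err[0.04] == pytest.approx(err[0.08] / 2.0, rel=0.15)

    def test_dead_channel_has_zero_coefficient(self, decay):
        spec = PerturbationSpec((("dead_term", 1.0),), delta=0.1)
        c = sk.control_coefficient(decay, s_at_horizon, spec)
        assert abs(c.value) < 1e-8


class TestG2MSpecs:
    def test_published_weights(self):
        specs = sk.g2m_mutation_specs()
        assert dict(specs["kd_CycB"].components) == {
            "cycb_degradation": 0.3, "mpf_degradation": 0.7}
        assert dict(specs["kd_Cdk1"].components) == {"mpf_degradation": 1.0}
        assert dict(specs["J_combined"].components) == {
            "J_iwee": 0.9, "J_a25": 0.1}
        for spec in specs.values():
            assert sum(w for _, w in spec.components) == pytest.approx(1.0)
            assert spec.delta == 0.1

    def test_composite_linearity_at_small_delta(self, g2m, g2m_wt_readout):
        """At delta = 0.01 the coefficient of a weighted composite is the
        weighted sum of single-channel coefficients within 10%."""
        delta = 0.01
        singles = {}
        for ch in ("cycb_degradation", "mpf_degradation"):
            spec = PerturbationSpec(((ch, 1.0),), delta=delta)
            singles[ch] = sk.control_coefficient(
                g2m, sk.g2m_readout, spec,
                wild_type_value=g2m_wt_readout).value
        comb = PerturbationSpec((("cycb_degradation", 0.3),
                                 ("mpf_degradation", 0.7)), delta=delta)
        c = sk.control_coefficient(g2m, sk.g2m_readout, comb,
                                   wild_type_value=g2m_wt_readout).value
        expected = 0.3 * singles["cycb_degradation"] \
            + 0.7 * singles["mpf_degradation"]
        assert c == pytest.approx(expected, rel=0.10)

    def test_readout_failure_carries_spec_label(self):
        """A perturbation that pushes the steady state below the
        threshold turns the no-crossing failure into a ReadoutError
        labelled with the offending spec."""
        from sifkit.model import OdeModel

        saturating = OdeModel(
            name="saturating", species=("s",), params={"kin": 1.0,
                                                       "kout": 0.2},
            initial_conditions={"s": 0.0}, horizon=60.0,
            channels=("outflux",),
            rhs_factory=lambda p, m: (
                lambda t, y: [p["kin"] - m["outflux"] * p["kout"] * y[0]]))

        def crossing_readout(model):
            traj = sk.integrate(model)
            return sk.first_crossing(traj, "s", 4.8).time

        spec = PerturbationSpec((("outflux", 1.0),), delta=0.1,
                                label="probe")
        assert crossing_readout(saturating) > 0  # wild type crosses
        with pytest.raises(ReadoutError) as err:
            sk.control_coefficient(saturating, crossing_readout, spec)
        assert err.value.label == "probe"


class TestMapkControlVector:
    def test_erk_deactivation_lowers_amplitude(self, mapk, mapk_wt_metrics):
        spec = PerturbationSpec((("erk_inactivation", 1.0),), delta=0.1)
        cv = sk.mapk_control_vector(mapk, spec,
                                    wild_type_metrics=mapk_wt_metrics)
        assert cv["amplitude"].value < 0

    def test_ras_and_mek_specs_differ(self, mapk, mapk_wt_metrics):
        ras = sk.mapk_control_vector(
            mapk, PerturbationSpec((("ras_activation", 1.0),), delta=0.1),
            wild_type_metrics=mapk_wt_metrics)
        mek = sk.mapk_control_vector(
            mapk, PerturbationSpec((("mek_activation", 1.0),), delta=0.1),
            wild_type_metrics=mapk_wt_metrics)
        vras = [ras[n].value for n in ("amplitude", "duration", "peak_time")]
        vmek = [mek[n].value for n in ("amplitude", "duration", "peak_time")]
        assert not np.allclose(vras, vmek, rtol=0.2)

    def test_small_delta_deviations_vanish(self, mapk, mapk_wt_metrics):
        """Continuity at delta -> 0: the perturbed metrics converge to
        the wild-type metrics."""
        spec = PerturbationSpec((("mek_activation", 1.0),), delta=1e-4)
        pm = sk.mapk_metrics(sk.integrate(sk.apply_perturbation(mapk, spec)))
        assert pm.amplitude == pytest.approx(mapk_wt_metrics.amplitude,
                                             rel=1e-3)
        assert pm.duration == pytest.approx(mapk_wt_metrics.duration,
                                            rel=1e-3)


class TestSweep:
    def test_empty_targets_give_empty_table(self, g2m):
        df = sk.sensitivity_sweep(g2m, [])
        assert df.empty

    def test_unknown_target_recorded_not_raised(self, g2m):
        df = sk.sensitivity_sweep(g2m, ["mpf_degradation", "bogus"])
        assert len(df) == 2
        assert df.loc[df.target == "bogus", "error"].iloc[0] != ""
        assert df.loc[df.target == "mpf_degradation", "error"].iloc[0] == ""

    def test_mapk_initial_condition_sweep(self, mapk):
        df = sk.sensitivity_sweep(
            mapk, ["init:ShcGS", "init:Raf", "init:Mek", "init:Erk"])
        for col in ("C_amplitude", "C_duration", "C_peak_time"):
            assert np.isfinite(df[col]).all()

    def test_rows_keep_input_order(self, g2m):
        targets = ["J_i25", "cycb_synthesis", "J_awee"]
        df = sk.sensitivity_sweep(g2m, targets)
        assert list(df.target) == targets
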