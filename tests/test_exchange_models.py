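"""Forward-model correctness: closed forms vs matrix-exponential vs ODE."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metallonmr import (
    ExchangeSystem,
    MagnetizationState,
    NoePairSystem,
    VolumeSeries,
    propagate_rate_matrix,
    simulate_exchange_noe,
    simulate_nh2_nh_zz,
    simulate_two_site,
)
from metallonmr.exchange_models import (
    _propagate,
    nh2_nh_rate_matrix,
    noe_rate_matrix,
    read_volume_series_tsv,
    write_volume_series_tsv,
)

from conftest import ode_propagate


class TestExchangeSystem:
    def test_derived_quantities(self):
        s = ExchangeSystem(3.5, 7.7, 2.0)
        assert s.k_ex == pytest.approx(11.2)
        assert s.p_major + s.p_minor == pytest.approx(1.0)
        assert s.p_minor == pytest.approx(3.5 / 11.2)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k1"):
            ExchangeSystem(-1.0, 1.0, 1.0)

    def test_populations_undefined_without_exchange(self):
        with pytest.raises(ValueError, match="undefined"):
            ExchangeSystem(0.0, 0.0, 2.0).p_major


class TestVolumeSeries:
    def test_negative_time_names_index(self):
        with pytest.raises(ValueError, match="index 1"):
            VolumeSeries("AA", [0.0, -0.1, 0.2], [1.0, 1.0, 1.0])

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="label"):
            VolumeSeries("XX", [0.1], [1.0])

    def test_tsv_round_trip(self, tmp_path):
        s = VolumeSeries("aA", [0.01, 0.1, 0.3], [0.1, 0.5, 0.4], [0.01, 0.02, 0.01])
        path = tmp_path / "series.tsv"
        write_volume_series_tsv([s], path)
        back = read_volume_series_tsv(path)["aA"]
        np.testing.assert_allclose(back.times, s.times)
        np.testing.assert_allclose(back.volumes, s.volumes)
        np.testing.assert_allclose(back.sigma_volumes, s.sigma_volumes)


class TestPropagateRateMatrix:
    def test_zero_generator_is_identity(self):
        state = MagnetizationState(("A", "a"), np.array([0.3, 0.7]))
        out = propagate_rate_matrix(np.zeros((2, 2)), state, [0.0, 1.0, 5.0])
        for s in out:
            np.testing.assert_allclose(s.values, state.values)

    def test_single_pool_scalar_decay(self):
        state = MagnetizationState(("A",), np.array([2.0]))
        out = propagate_rate_matrix(np.array([[-3.0]]), state, [0.5])
        assert out[0]["A"] == pytest.approx(2.0 * np.exp(-1.5), rel=1e-12)

    def test_rejects_non_square_and_mismatch(self):
        state = MagnetizationState(("A", "a"), np.array([1.0, 0.0]))
        with pytest.raises(ValueError, match="square"):
            propagate_rate_matrix(np.zeros((2, 3)), state, [0.1])
        with pytest.raises(ValueError, match="mismatch"):
            propagate_rate_matrix(np.zeros((3, 3)), state, [0.1])

    def test_matches_ode_on_random_systems(self):
        rng = np.random.default_rng(42)
        t = np.linspace(0.0, 0.8, 7)
        for _ in range(100):
            k1, kr, r1 = rng.uniform(0.0, 50.0, 3)
            system = ExchangeSystem(k1, kr, r1)
            K = nh2_nh_rate_matrix(system, rng.uniform(0.0, 1.0))
            m0 = rng.uniform(0.0, 2.0, 2)
            state = MagnetizationState(("NH2", "NH"), m0)
            ours = np.array([s.values for s in propagate_rate_matrix(K, state, t)])
            oracle = ode_propagate(K, m0, t)
            np.testing.assert_allclose(ours, oracle, rtol=1e-8, atol=1e-10)


class TestSimulateTwoSite:
    def test_no_exchange_pure_decay(self):
        s = ExchangeSystem(0.0, 0.0, 2.0)
        out = simulate_two_site(s, [0.1])
        assert out["AA"].volumes[0] == pytest.approx(np.exp(-0.2), rel=1e-12)
        assert out["aA"].volumes[0] == 0.0

    def test_initial_condition_at_t_zero(self, zz_system):
        out = simulate_two_site(zz_system, [0.0])
        assert out["AA"].volumes[0] == pytest.approx(1.0)
        assert out["aA"].volumes[0] == pytest.approx(0.0, abs=1e-15)

    def test_normalized_cross_fraction(self, zz_system):
        out = simulate_two_site(zz_system, [0.1])
        frac = out["aA"].volumes[0] / (out["AA"].volumes[0] + out["aA"].volumes[0])
        expected = zz_system.p_minor * (1.0 - np.exp(-zz_system.k_ex * 0.1))
        assert frac == pytest.approx(expected, rel=1e-12)
        assert frac == pytest.approx(0.2105, abs=2e-4)

    def test_closed_form_equals_expm_oracle(self, delays):
        rng = np.random.default_rng(7)
        for _ in range(100):
            k1, kr, r1 = rng.uniform(0.0, 50.0, 3)
            system = ExchangeSystem(k1, kr, r1)
            out = simulate_two_site(system, delays)
            K = np.array([[-k1 - r1, kr], [k1, -kr - r1]])
            from_major = _propagate(K, np.array([1.0, 0.0]), delays)
            np.testing.assert_allclose(out["AA"].volumes, from_major[:, 0],
                                       rtol=1e-10, atol=1e-12)
            np.testing.assert_allclose(out["aA"].volumes, from_major[:, 1],
                                       rtol=1e-10, atol=1e-12)

    def test_closed_form_equals_ode(self, zz_system, delays):
        out = simulate_two_site(zz_system, delays)
        K = np.array([
            [-zz_system.k1 - zz_system.r1, zz_system.k_rev],
            [zz_system.k1, -zz_system.k_rev - zz_system.r1],
        ])
        oracle = ode_propagate(K, [1.0, 0.0], delays)
        np.testing.assert_allclose(out["AA"].volumes, oracle[:, 0], rtol=1e-8)
        np.testing.assert_allclose(out["aA"].volumes, oracle[:, 1], rtol=1e-8)

    def test_plateau_of_normalized_cross_peak_is_p_minor(self, zz_system):
        out = simulate_two_site(zz_system, [5.0])
        frac = out["aA"].volumes[0] / (out["AA"].volumes[0] + out["aA"].volumes[0])
        assert frac == pytest.approx(zz_system.p_minor, rel=1e-6)

    def test_detailed_balance_stationarity(self, zz_system):
        K = np.array([
            [-zz_system.k1, zz_system.k_rev],
            [zz_system.k1, -zz_system.k_rev],
        ])
        pi = np.array([zz_system.p_major, zz_system.p_minor])
        np.testing.assert_allclose(K @ pi, 0.0, atol=1e-14)

    def test_negative_delay_rejected(self, zz_system):
        with pytest.raises(ValueError, match="index 2"):
            simulate_two_site(zz_system, [0.0, 0.1, -0.2])


class TestNh2NhScheme:
    def test_retention_one_reduces_to_two_site(self, zz_system, delays):
        zz = simulate_nh2_nh_zz(zz_system, 1.0, delays)
        two = simulate_two_site(zz_system, delays)
        np.testing.assert_allclose(zz["NH2"].volumes, two["AA"].volumes, rtol=1e-10)
        np.testing.assert_allclose(zz["NH'"].volumes, two["aA"].volumes, rtol=1e-10)
        np.testing.assert_allclose(zz["NH"].volumes, two["aa"].volumes, rtol=1e-10)
        np.testing.assert_allclose(zz["NH2'"].volumes, two["Aa"].volumes, rtol=1e-10)

    def test_no_exchange_means_no_cross_peaks(self, delays):
        out = simulate_nh2_nh_zz(ExchangeSystem(0.0, 0.0, 2.0), 0.5, delays)
        np.testing.assert_allclose(out["NH'"].volumes, 0.0, atol=1e-14)
        np.testing.assert_allclose(out["NH2'"].volumes, 0.0, atol=1e-14)

    def test_exchange_peaks_peak_at_interior_delay(self, zz_system):
        dense = np.linspace(1e-4, 0.5, 2000)
        out = simulate_nh2_nh_zz(zz_system, 0.5, dense)
        for label in ("NH'", "NH2'"):
            idx = int(np.argmax(out[label].volumes))
            assert 0 < idx < len(dense) - 1
        oracle = ode_propagate(
            nh2_nh_rate_matrix(zz_system, 0.5), [1.0, 0.0], dense
        )
        np.testing.assert_allclose(out["NH'"].volumes, oracle[:, 1], rtol=1e-8,
                                   atol=1e-12)

    def test_retention_outside_unit_interval_rejected(self, zz_system, delays):
        with pytest.raises(ValueError, match="retention"):
            simulate_nh2_nh_zz(zz_system, 1.2, delays)

    def test_conservation_with_full_retention_and_no_relaxation(self, delays):
        system = ExchangeSystem(3.5, 7.7, 0.0)
        out = simulate_nh2_nh_zz(system, 1.0, delays)
        total = out["NH2"].volumes + out["NH'"].volumes
        np.testing.assert_allclose(total, 1.0, atol=1e-10)


class TestExchangeNoe:
    def test_no_noe_path_means_no_mediated_peaks(self, delays):
        system = NoePairSystem(ExchangeSystem(4.3, 8.8, 2.0), 0.0, 0.0)
        out = simulate_exchange_noe(system, delays)
        np.testing.assert_allclose(out["Ab"].volumes, 0.0, atol=1e-14)
        np.testing.assert_allclose(out["aB"].volumes, 0.0, atol=1e-14)

    def test_no_exchange_path_means_no_exchange_peaks(self, delays):
        system = NoePairSystem(ExchangeSystem(0.0, 0.0, 2.0), -1.0, -1.0)
        out = simulate_exchange_noe(system, delays)
        np.testing.assert_allclose(out["Aa"].volumes, 0.0, atol=1e-14)
        np.testing.assert_allclose(out["aA"].volumes, 0.0, atol=1e-14)

    def test_sigma_zero_reduces_to_independent_two_site(self, delays):
        ex = ExchangeSystem(4.3, 8.8, 2.0)
        out = simulate_exchange_noe(NoePairSystem(ex, 0.0, 0.0), delays)
        two = simulate_two_site(ex, delays)
        np.testing.assert_allclose(out["AA"].volumes, two["AA"].volumes, rtol=1e-9)
        np.testing.assert_allclose(out["aA"].volumes, two["aA"].volumes, rtol=1e-9)

    def test_agrees_with_ode_oracle(self, noesy_system, delays):
        K = noe_rate_matrix(noesy_system)
        out = simulate_exchange_noe(noesy_system, delays)
        for origin_idx, origin in enumerate(("A", "a", "B", "b")):
            m0 = np.zeros(4)
            m0[origin_idx] = 1.0
            oracle = ode_propagate(K, m0, delays)
            np.testing.assert_allclose(out["A" + origin].volumes, oracle[:, 0],
                                       rtol=1e-8, atol=1e-12)
            np.testing.assert_allclose(out["a" + origin].volumes, oracle[:, 1],
                                       rtol=1e-8, atol=1e-12)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    k1=st.floats(0.0, 50.0),
    kr=st.floats(0.0, 50.0),
    r1=st.floats(0.0, 20.0),
)
def test_property_triple_agreement_two_site(k1, kr, r1):
    """Closed form, eigen propagation and ODE integration coincide."""
    t = np.array([0.0, 0.03, 0.1, 0.4])
    system = ExchangeSystem(k1, kr, r1)
    out = simulate_two_site(system, t)
    K = np.array([[-k1 - r1, kr], [k1, -kr - r1]])
    eig = _propagate(K, np.array([1.0, 0.0]), t)
    ode = ode_propagate(K, [1.0, 0.0], t)
    np.testing.assert_allclose(out["AA"].volumes, eig[:, 0], rtol=1e-8, atol=1e-10)
    np.testing.assert_allclose(out["aA"].volumes, eig[:, 1], rtol=1e-8, atol=1e-10)
    np.testing.assert_allclose(eig, ode, rtol=1e-8, atol=1e-10)
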