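"""Model right-hand side, coupling structure, and parameter files."""

import numpy as np
import pytest

from delayosc.model import (ModelParams, CouplingMatrix, rhs, single_rhs,
                            load_param_sets, dump_param_sets,
                            default_param_sets, NamedParamSet, ConfigError)


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_coupling(rng, n, scale=0.5):
    m = rng.random((n, n)) * scale
    m = 0.5 * (m + m.T)
    np.fill_diagonal(m, 0.0)
    return m


class TestRHS:
    def test_rest_state_is_equilibrium(self, rng):
        """u = v = 0 with zero history is a fixed point for any coupling."""
        for n in (1, 3, 7):
            cpl = CouplingMatrix(random_coupling(rng, n), random_coupling(rng, n))
            p = ModelParams(delay=2.0, damping=1.3, gain_a=0.7, gain_b=2.0,
                            nl2=0.4, nl3=1.7)
            z = np.zeros(n)
            assert np.all(rhs(z, z, z, p, cpl) == 0.0)

    def test_diffusive_coupling_vanishes_on_synchronized_state(self, rng):
        p = ModelParams()
        n = 4
        cpl = CouplingMatrix(random_coupling(rng, n), random_coupling(rng, n))
        u = np.full(n, 0.37)
        v = np.full(n, -0.21)
        ud = np.full(n, 0.11)
        with_c = rhs(u, v, ud, p, cpl)
        without = rhs(u, v, ud, p, None)
        np.testing.assert_allclose(with_c, without, rtol=0, atol=1e-15)

    def test_linearized_rhs_term_by_term(self):
        """With nl2 = nl3 = 0 the output is the hand-written combination
        -2 g v - (g^2 - a) u - b u(t - tau)."""
        p = ModelParams(delay=1.5, damping=0.8, gain_a=0.3, gain_b=2.2,
                        nl2=0.0, nl3=0.0)
        u, v, ud = 0.43, -1.7, 0.91
        expected = (-2 * 0.8 * v - (0.8 ** 2 - 0.3) * u - 2.2 * ud)
        assert single_rhs(u, v, ud, p) == pytest.approx(expected, rel=1e-14)

    def test_nonlinear_terms_act_on_instantaneous_state(self):
        p = ModelParams(nl2=0.5, nl3=2.0)
        base = ModelParams(nl2=0.0, nl3=0.0, delay=p.delay, damping=p.damping,
                           gain_a=p.gain_a, gain_b=p.gain_b)
        u, v, ud = 0.6, 0.0, -0.9
        assert single_rhs(u, v, ud, p) == pytest.approx(
            single_rhs(u, v, ud, base) - 0.5 * u ** 2 - 2.0 * u ** 3, rel=1e-14)

    def test_permutation_equivariance(self, rng):
        n = 5
        p = [ModelParams(gain_a=float(a), gain_b=float(b))
             for a, b in zip(rng.random(n), 2 + rng.random(n))]
        cpl = CouplingMatrix(random_coupling(rng, n), random_coupling(rng, n))
        u, v, ud = rng.random(n), rng.random(n), rng.random(n)
        out = rhs(u, v, ud, p, cpl)
        perm = rng.permutation(n)
        out_p = rhs(u[perm], v[perm], ud[perm], [p[i] for i in perm],
                    cpl.permuted(perm))
        np.testing.assert_allclose(out_p, out[perm], rtol=1e-14)

    def test_all_to_all_coupling_conserves_total(self, rng):
        """For eps (ones - I) coupling the summed contribution is zero."""
        n = 6
        p = ModelParams()
        cpl = CouplingMatrix.all_to_all(n, eps_u=0.7, eps_v=0.3, normalize=False)
        u, v, ud = rng.random(n), rng.random(n), rng.random(n)
        contrib = rhs(u, v, ud, p, cpl) - rhs(u, v, ud, p, None)
        assert abs(contrib.sum()) < 1e-12

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            rhs(np.zeros(3), np.zeros(3), np.zeros(2), ModelParams())
        with pytest.raises(ValueError):
            rhs(np.zeros(3), np.zeros(3), np.zeros(3), ModelParams(),
                CouplingMatrix.none(2))

    def test_nonfinite_input_raises(self):
        with pytest.raises(FloatingPointError):
            rhs(np.array([np.nan]), np.zeros(1), np.zeros(1), ModelParams())


class TestCouplingMatrix:
    def test_rejects_asymmetric(self):
        m = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError):
            CouplingMatrix(m, np.zeros((2, 2)))

    def test_rejects_nonzero_diagonal(self):
        m = np.eye(2)
        with pytest.raises(ValueError):
            CouplingMatrix(m, np.zeros((2, 2)))


class TestParamFiles:
    def test_packaged_defaults_have_three_labelled_points(self, sets):
        assert set(sets) == {"A", "B", "C"}
        for s in sets.values():
            assert s.params.delay > 0 and s.params.damping > 0

    def test_a_and_b_share_the_same_offset_above_the_boundary(self, sets):
        from delayosc.stability import find_hopf
        offs = {}
        for lbl in ("A", "B"):
            p = sets[lbl].params
            offs[lbl] = p.gain_b - find_hopf(p).gain_critical
        assert offs["A"] == pytest.approx(offs["B"], abs=1e-9)

    def test_invalid_delay_rejected(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("sets:\n  - label: X\n    delay: -1.0\n    damping: 1.0\n"
                     "    gain_a: 0.0\n    gain_b: 1.0\n    nl2: 0.0\n    nl3: 1.0\n")
        with pytest.raises(ConfigError):
            load_param_sets(f)

    def test_missing_field_names_the_field(self, tmp_path):
        f = tmp_path / "bad.yaml"
        f.write_text("sets:\n  - label: X\n    delay: 1.0\n    damping: 1.0\n"
                     "    gain_a: 0.0\n    nl2: 0.0\n    nl3: 1.0\n")
        with pytest.raises(ConfigError, match="gain_b"):
            load_param_sets(f)

    def test_round_trip(self, tmp_path):
        custom = [NamedParamSet("X", ModelParams(delay=0.123456789012345,
                                                 damping=2.5, gain_a=-0.75,
                                                 gain_b=3.875, nl2=0.25,
                                                 nl3=1.5))]
        f = tmp_path / "sets.yaml"
        dump_param_sets(custom, f)
        back = load_param_sets(f)
        assert back[0].label == "X"
        assert back[0].params == custom[0].params
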