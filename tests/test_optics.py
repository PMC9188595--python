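"""Vector reflection, refraction, TIR and Fresnel reflectance."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adipolens import optics
from adipolens.optics import (ContractViolation, critical_angle,
                              fresnel_reflectance, interface_reflectance,
                              reflect, reflection_matrix, refract,
                              refract_components, snell_angle)


def unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


def random_units(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


class TestReflect:
    @pytest.mark.parametrize("e1,n,expected", [
        ((0, 0, 1), (0, 0, -1), (0, 0, -1)),          # retroreflection
        ((0.6, 0, 0.8), (0, 0, -1), (0.6, 0, -0.8)),  # mirror flips normal part
        ((0.6, 0, 0.8), (0, 1 / math.sqrt(2), -1 / math.sqrt(2)), (0.6, 0.8, 0.0)),
    ])
    def test_known_reflections(self, e1, n, expected):
        np.testing.assert_allclose(reflect(e1, n), expected, atol=1e-12)

    def test_involution_and_unit_norm(self, rng):
        e = random_units(rng, 10_000)
        n = random_units(rng, 10_000)
        for i in range(0, 10_000, 97):
            out = reflect(e[i], n[i])
            assert abs(np.linalg.norm(out) - 1.0) < 1e-12
            np.testing.assert_allclose(reflect(out, n[i]), e[i], atol=1e-12)

    def test_angle_preserved(self, rng):
        for _ in range(200):
            e, n = random_units(rng, 2)
            out = reflect(e, n)
            assert abs(abs(e @ n) - abs(out @ n)) < 1e-12

    def test_matrix_form_matches_vector_form(self, rng):
        for _ in range(200):
            e, n = random_units(rng, 2)
            np.testing.assert_allclose(reflection_matrix(n) @ e,
                                       e - 2 * (e @ n) * n, atol=1e-12)

    def test_non_unit_input_rejected(self):
        with pytest.raises(ContractViolation):
            reflect((0, 0, 2), (0, 0, -1))


class TestRefract:
    def test_matched_indices_pass_through(self, rng):
        for _ in range(50):
            e, n = random_units(rng, 2)
            if abs(e @ n) < 1e-3:
                continue
            np.testing.assert_allclose(refract(e, n, 1.0), e, atol=1e-9)

    def test_normal_incidence_undeviated(self):
        np.testing.assert_allclose(refract((0, 0, 1), (0, 0, -1), 2 / 3),
                                   (0, 0, 1), atol=1e-12)

    def test_snell_45deg_into_glass(self):
        e1 = unit((math.sin(math.radians(45)), 0, math.cos(math.radians(45))))
        out = refract(e1, (0, 0, -1), 1 / 1.5)
        at = math.radians(28.1255057)
        np.testing.assert_allclose(out, (math.sin(at), 0, math.cos(at)), atol=1e-6)

    def test_snell_consistency_and_coplanarity(self, rng):
        checked = 0
        while checked < 500:
            e, n = random_units(rng, 2)
            a = e @ n
            if abs(a) < 1e-3:
                continue
            mu = rng.uniform(0.5, 2.0)
            alpha_i = math.acos(abs(a))
            out = refract(e, n, mu)
            at = snell_angle(alpha_i, mu)
            if out is None:
                assert at is None
                checked += 1
                continue
            assert at is not None
            assert abs(np.linalg.norm(out) - 1.0) < 1e-9
            cos_out = abs(out @ n)
            assert abs(math.acos(min(1.0, cos_out)) - at) < 1e-9
            assert abs(out @ np.cross(e, n)) < 1e-9  # coplanar
            checked += 1

    def test_component_form_matches_vector_form(self, rng):
        for _ in range(500):
            e, n = random_units(rng, 2)
            if abs(e @ n) < 1e-3:
                continue
            mu = rng.uniform(0.5, 2.0)
            a = refract(e, n, mu)
            b = refract_components(e, n, mu)
            if a is None:
                assert b is None
            else:
                np.testing.assert_allclose(a, b, atol=1e-12)

    def test_grazing_incidence_rejected(self):
        with pytest.raises(ContractViolation):
            refract((1, 0, 0), (0, 0, -1), 1.5)


class TestSnellAngle:
    def test_normal_incidence(self):
        assert snell_angle(0.0, 1.5) == 0.0

    def test_tir_beyond_critical_angle(self):
        assert snell_angle(math.radians(80), 1.03) is None
        assert abs(math.degrees(critical_angle(1.03)) - 76.1376) < 1e-3

    def test_tir_onset_is_exactly_critical(self, rng):
        for _ in range(200):
            mu = rng.uniform(1.01, 2.0)
            ac = critical_angle(mu)
            assert snell_angle(ac - 1e-9, mu) is not None
            assert snell_angle(min(ac + 1e-9, math.pi / 2 - 1e-12), mu) is None


class TestFresnel:
    def test_matched_media_zero(self):
        assert fresnel_reflectance(0.3, 0.3).R == pytest.approx(0.0, abs=1e-12)

    def test_normal_incidence_limit(self):
        r = fresnel_reflectance(0.0, 0.0, mu=1 / 1.5)
        assert r.R == pytest.approx(0.04, abs=1e-9)

    def test_brewster_suppression(self):
        ai, at = math.radians(56.310), math.radians(33.690)
        r = fresnel_reflectance(ai, at)
        # at Brewster the tangent (p-polarization) term vanishes; R is the
        # s-term alone
        expected = 0.5 * math.sin(ai - at) ** 2 / math.sin(ai + at) ** 2
        assert r.R == pytest.approx(expected, abs=1e-6)
        assert r.R == pytest.approx(0.0739, abs=5e-4)

    def test_reciprocity(self, rng):
        for _ in range(300):
            mu = rng.uniform(0.5, 2.0)
            ai = rng.uniform(1e-5, math.pi / 2 - 1e-3)
            at = snell_angle(ai, mu)
            if at is None or at < 1e-5:
                continue
            assert (fresnel_reflectance(ai, at).R
                    == pytest.approx(fresnel_reflectance(at, ai).R, abs=1e-9))

    @pytest.mark.parametrize("mu", [1.03, 1.44])
    def test_monotone_in_incidence_below_critical(self, mu):
        ac = critical_angle(mu)
        grid = np.linspace(0.0, ac - 1e-6, 1000)
        R = np.array([interface_reflectance(a, mu).R for a in grid])
        assert np.all(np.diff(R) >= -1e-12)

    def test_tir_gives_unity(self):
        r = interface_reflectance(math.radians(80), 1.03)
        assert r.tir and r.R == 1.0

    def test_bounds_on_random_inputs(self, rng):
        for _ in range(10_000):
            mu = rng.uniform(0.5, 2.0)
            ai = rng.uniform(0, math.pi / 2 - 1e-6)
            r = interface_reflectance(ai, mu)
            assert 0.0 <= r.R <= 1.0


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.floats(0.0, math.pi / 2 - 1e-3), st.floats(0.2, 0.999))
def test_refraction_never_tir_into_denser_medium(alpha_i, mu):
    """Entering an optically denser medium (mu < 1) always refracts."""
    assert snell_angle(alpha_i, mu) is not None


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_reflect_refract_preserve_norm(seed):
    rng = np.random.default_rng(seed)
    e, n = (v / np.linalg.norm(v) for v in rng.normal(size=(2, 3)))
    if abs(e @ n) < 1e-3:
        return
    assert abs(np.linalg.norm(reflect(e, n)) - 1) < 1e-9
    out = refract(e, n, rng.uniform(0.5, 2.0))
    if out is not None:
        assert abs(np.linalg.norm(out) - 1) < 1e-9
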