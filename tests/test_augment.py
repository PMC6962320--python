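"""Geometric and sponge-model augmentation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lungtex.augment import (BalancingError, GeometricTransform,
                             SpongeParameterError, SpongeParams,
                             apply_geometric, balance_classes,
                             draw_sponge_params, sponge_augment)
from lungtex.sampling import PATCH, ROISample
from lungtex.tissue import TissueClass
from lungtex.volume import AnnotatedPoint


def _sample(data=None, mode="axial2d"):
    if data is None:
        data = np.random.default_rng(0).uniform(-1000, 100, (PATCH, PATCH))
    return ROISample(mode=mode, data=data, label=TissueClass.GG)


class TestGeometric:
    def test_identity_returns_input(self):
        s = _sample()
        out = apply_geometric(s, GeometricTransform())
        np.testing.assert_array_equal(out.data, s.data)

    def test_flip_twice_is_involution(self):
        s = _sample()
        t = GeometricTransform(flip_h=True)
        out = apply_geometric(apply_geometric(s, t), t)
        np.testing.assert_array_equal(out.data, s.data)

    def test_rotation_90_moves_bright_pixel_to_rotated_index(self):
        data = np.zeros((PATCH, PATCH))
        data[10, 20] = 1000.0
        s = _sample(data)
        out = apply_geometric(s, GeometricTransform(rotation=90.0), order=1)
        # rotation about the centre c=23.5: (i,j) -> (c+(j-c), c-(i-c))
        c = (PATCH - 1) / 2.0
        ti, tj = int(c + (20 - c)), int(c - (10 - c))
        assert out.data[ti, tj] == pytest.approx(1000.0, rel=1e-3)
        assert np.unravel_index(np.argmax(out.data), out.data.shape) == (ti, tj)

    def test_label_and_shape_preserved(self):
        s = _sample(mode="ortho2p5d",
                    data=np.random.default_rng(1).standard_normal(
                        (3, PATCH, PATCH)))
        out = apply_geometric(s, GeometricTransform(rotation=33.0,
                                                    shear=5.0, shift=(2, -1)))
        assert out.data.shape == s.data.shape
        assert out.label is s.label


class TestSponge:
    def test_delta_zero_is_identity(self):
        s = _sample()
        out = sponge_augment(s, SpongeParams(lung_volume=5000, delta_v=0.0))
        np.testing.assert_array_equal(out.data, s.data)

    def test_hand_computed_value(self):
        # V=5000 mL, dV=+100 mL, voxel -900 HU: density 100 is rescaled by
        # 5000/5100 to 98.0392 -> -901.96 HU
        s = _sample(np.full((PATCH, PATCH), -900.0))
        out = sponge_augment(s, SpongeParams(lung_volume=5000, delta_v=100.0))
        assert out.data[0, 0] == pytest.approx(-901.9608, abs=1e-3)

    def test_air_voxel_is_fixed_point(self):
        s = _sample(np.full((PATCH, PATCH), -1000.0))
        for dv in (-90.0, 50.0, 100.0):
            out = sponge_augment(s, SpongeParams(lung_volume=4000, delta_v=dv))
            np.testing.assert_array_equal(out.data, s.data)

    def test_nonphysical_volume_rejected(self):
        with pytest.raises(SpongeParameterError):
            SpongeParams(lung_volume=100.0, delta_v=-100.0)
        with pytest.raises(SpongeParameterError):
            SpongeParams(lung_volume=0.0)

    def test_inspiration_moves_density_toward_air_monotonically(self):
        s = _sample()
        rho = s.data + 1000.0
        inhale = sponge_augment(s, SpongeParams(5000, +80.0))
        exhale = sponge_augment(s, SpongeParams(5000, -80.0))
        assert np.all((inhale.data + 1000.0) <= rho + 1e-12)
        assert np.all((exhale.data + 1000.0) >= rho - 1e-12)

    @given(st.floats(2000, 8000), st.floats(-100, 100), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_mass_conservation(self, volume, dv, seed):
        data = np.random.default_rng(seed).uniform(-1000, 200, (PATCH, PATCH))
        s = ROISample(mode="axial2d", data=data, label=TissueClass.NP)
        p = SpongeParams(lung_volume=volume, delta_v=dv)
        out = sponge_augment(s, p)
        before = (data + 1000.0).mean() * volume
        after = (out.data + 1000.0).mean() * (volume + dv)
        assert after == pytest.approx(before, rel=1e-9)

    def test_two_step_composition_equals_single_step(self):
        s = _sample()
        v, d1, d2 = 5000.0, 60.0, -35.0
        step1 = sponge_augment(s, SpongeParams(v, d1))
        step2 = sponge_augment(step1, SpongeParams(v + d1, d2))
        direct = sponge_augment(s, SpongeParams(v, d1 + d2))
        np.testing.assert_allclose(step2.data, direct.data, rtol=1e-9)

    def test_draw_respects_range(self):
        rng = np.random.default_rng(0)
        draws = [draw_sponge_params(rng).delta_v for _ in range(200)]
        assert all(-100.0 <= d <= 100.0 for d in draws)


def _points(cls, n):
    return [AnnotatedPoint(f"s{i % 3}", (40 + i, 40, 40), cls,
                           subject_id=f"p{i % 3}") for i in range(n)]


class TestBalanceClasses:
    def test_deficit_class_keeps_all_originals_and_fills_to_target(self):
        rosters = balance_classes({TissueClass.GG: _points(TissueClass.GG, 103)},
                                  target=600, rng_seed=0)
        roster = rosters[TissueClass.GG]
        assert len(roster) == 600
        originals = [e for e in roster if not e.is_augmented]
        assert len(originals) == 103
        assert len({id(e.point) for e in originals}) == 103

    def test_class_at_target_is_passed_through(self):
        rosters = balance_classes({TissueClass.NP: _points(TissueClass.NP, 600)},
                                  target=600, rng_seed=0)
        assert all(not e.is_augmented for e in rosters[TissueClass.NP])
        assert len(rosters[TissueClass.NP]) == 600

    def test_cohort_skew_yields_4800_roster(self):
        from lungtex.published import COHORT_CLASS_COUNTS
        by_class = {c: _points(c, min(n, 900))  # cap NP/RETIC: counting only
                    for c, n in COHORT_CLASS_COUNTS.items()}
        rosters = balance_classes(by_class, target=600, rng_seed=1)
        assert sum(len(r) for r in rosters.values()) == 4800
        assert all(len(r) == 600 for r in rosters.values())

    def test_empty_class_raises(self):
        with pytest.raises(BalancingError):
            balance_classes({TissueClass.NOD: []}, target=10, rng_seed=0)

    def test_deterministic_under_seed(self):
        pts = {TissueClass.GG: _points(TissueClass.GG, 50),
               TissueClass.NP: _points(TissueClass.NP, 700)}
        r1 = balance_classes(pts, target=600, rng_seed=42)
        r2 = balance_classes(pts, target=600, rng_seed=42)
        for c in r1:
            assert [(e.point, e.transform) for e in r1[c]] == \
                   [(e.point, e.transform) for e in r2[c]]
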