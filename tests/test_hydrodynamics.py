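import numpy as np
import pytest

from hydrogait.body_model import SegmentFrustum, discretize
from hydrogait.gait_kinematics import SegmentKinematics, StrideMetrics
from hydrogait.hydrodynamics import (
    WaterProperties,
    segment_drag_series,
    strip_drag,
    stride_drag,
)

RHO = 995.7
DT = 1 / 60.0


def _translating_segment(name, y_top, length, v=0.5, n=120):
    """Vertical segment translating horizontally at constant speed."""
    prox = np.column_stack([v * np.arange(n) * DT, np.full(n, y_top)])
    dist = prox + [0.0, -length]
    return SegmentKinematics(
        name, prox, dist, np.zeros(n), np.zeros(n), np.gradient(prox, DT, axis=0)
    )


def _stride(n=120, sl=0.5, v=0.5):
    contact = np.zeros(60, dtype=bool)
    contact[:36] = True
    return StrideMetrics(0, 30, 90, sl, sl / v, v, contact, 0.2)


class TestStripDrag:
    def test_zero_velocity_gives_zero_force(self):
        water = WaterProperties(surface_height=1.0)
        assert strip_drag(0.0, 0.05, 0.1, 1.0, water, 1.0) == 0.0

    def test_nonfinite_velocity_rejected(self):
        water = WaterProperties(surface_height=1.0)
        with pytest.raises(ValueError, match="non-finite"):
            strip_drag(np.nan, 0.05, 0.1, 1.0, water, 1.0)

    @pytest.mark.parametrize("n_strips", [1, 5, 20, 50])
    def test_cylinder_in_uniform_flow_matches_closed_form(self, n_strips):
        """Half rho Cd (2 r L) v^2 for a fully immersed vertical cylinder,
        independent of the strip count."""
        kin = _translating_segment("shank", 0.5, 0.5, v=0.8, n=50)
        cyl = SegmentFrustum("shank", 0.5, 0.05, 0.05, "right")
        water = WaterProperties(surface_height=2.0)
        force_x, _ = segment_drag_series(kin, discretize(cyl, n_strips), water, DT)
        expected = 0.5 * RHO * 1.0 * 0.1 * 0.5 * 0.8**2
        assert -force_x[25] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(15.93, abs=0.01)

    def test_segment_above_surface_contributes_nothing(self):
        kin = _translating_segment("shank", 1.5, 0.5, v=0.8, n=50)
        cyl = SegmentFrustum("shank", 0.5, 0.05, 0.05, "right")
        water = WaterProperties(surface_height=0.5)  # waterline below segment
        force_x, _ = segment_drag_series(kin, discretize(cyl, 20), water, DT)
        assert np.allclose(force_x, 0.0)

    def test_partial_immersion_prorates_area(self):
        kin = _translating_segment("shank", 0.5, 0.5, v=0.8, n=50)
        cyl = SegmentFrustum("shank", 0.5, 0.05, 0.05, "right")
        full, _ = segment_drag_series(
            kin, discretize(cyl, 20), WaterProperties(surface_height=2.0), DT
        )
        half, _ = segment_drag_series(
            kin, discretize(cyl, 20), WaterProperties(surface_height=0.25), DT
        )
        assert half[25] == pytest.approx(0.5 * full[25], rel=1e-9)


class TestStrideDrag:
    def test_rigid_translation_matches_frustum_oracle(self, participant, frusta):
        """Uniform translation of the whole segmented body: the strip sum
        equals the closed-form frustum diameter integral for every segment."""
        v = 0.5
        segs = participant.segments
        states = {
            "foot": _translating_segment("foot", 0.9, segs["foot"].length, v),
            "shank": _translating_segment("shank", 1.0, segs["shank"].length, v),
            "thigh": _translating_segment("thigh", 1.2, segs["thigh"].length, v),
            "trunk": _translating_segment("trunk", 1.5, segs["trunk"].length, v),
        }
        water = WaterProperties(surface_height=2.0)  # fully immersed
        summary = stride_drag(states, frusta, _stride(v=v), water, DT, n_strips=20)
        oracle = sum(
            0.5 * RHO * 1.0 * (f.proximal_radius + f.distal_radius) * f.length * v**2
            for f in frusta
        )
        assert summary.drf == pytest.approx(oracle, rel=0.005)

    def test_zero_motion_gives_zero_drag(self, participant, frusta):
        segs = participant.segments
        states = {
            name: _translating_segment(name, 1.0, segs[name].length, v=0.0)
            for name in ("foot", "shank", "thigh", "trunk")
        }
        water = WaterProperties(surface_height=2.0)
        summary = stride_drag(states, frusta, _stride(), water, DT)
        assert summary.drf == 0.0

    def test_quadratic_velocity_scaling(self, states, frusta, strides):
        """Halving dt doubles every velocity and scales DrF by exactly 4."""
        water = WaterProperties(surface_height=0.85)
        s = strides[len(strides) // 2]
        base = stride_drag(states, frusta, s, water, dt=DT, n_strips=10)
        fast = stride_drag(states, frusta, s, water, dt=DT / 2, n_strips=10)
        assert fast.drf == pytest.approx(4.0 * base.drf, rel=1e-6)

    def test_drag_monotone_in_immersion_depth(self, states, frusta, strides):
        s = strides[len(strides) // 2]
        drfs = [
            stride_drag(
                states, frusta, s, WaterProperties(surface_height=h), DT, n_strips=10
            ).drf
            for h in (0.3, 0.6, 0.9, 1.2, 1.5)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(drfs, drfs[1:]))

    def test_strip_discretization_converged_at_default(self, states, frusta, strides):
        s = strides[len(strides) // 2]
        water = WaterProperties(surface_height=0.85)
        d20 = stride_drag(states, frusta, s, water, DT, n_strips=20).drf
        d40 = stride_drag(states, frusta, s, water, DT, n_strips=40).drf
        assert abs(d20 - d40) / d40 <= 0.01

    def test_phase_split_is_duration_weighted_average(self, states, frusta, strides):
        s = strides[len(strides) // 2]
        water = WaterProperties(surface_height=0.85)
        d = stride_drag(states, frusta, s, water, DT, n_strips=10)
        n_contact = int(s.contact_mask.sum())
        n_total = len(s.contact_mask)
        combined = (
            d.contact_drag * n_contact + d.swing_drag * (n_total - n_contact)
        ) / n_total
        assert d.drf == pytest.approx(combined, rel=1e-9)

    def test_reynolds_range_in_turbulent_regime(self, states, frusta, strides):
        s = strides[len(strides) // 2]
        water = WaterProperties(surface_height=0.85)
        lo, hi = stride_drag(states, frusta, s, water, DT).reynolds_range
        assert 0 <= lo < hi
        assert 1e4 < hi < 1e7
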