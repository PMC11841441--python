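import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasckit import (
    ImageStack,
    SynthSpec,
    compare_permeability,
    compute_permeability,
    compute_pore_stats,
    compute_printability,
    compute_viability,
    flanking_rois,
    generate_grid_print,
    generate_leak_series,
    generate_nuclei_field,
    generate_pore_texture,
)
from vasckit.metrics import PermeabilityResult


def _grid_stack(shape_name, seed=0):
    spec = SynthSpec(
        kind="grid", seed=seed, shape=(512, 512),
        params={"pore_shape": shape_name, "pore_size": 100.0,
                "wall_thickness": 20.0},
    )
    return generate_grid_print(spec)


class TestPrintability:
    @pytest.mark.parametrize(
        "shape_name,target,tol",
        [("square", 1.0, 0.02), ("circle", math.pi / 4, 0.02)],
    )
    def test_analytic_shapes(self, shape_name, target, tol):
        stack, _ = _grid_stack(shape_name)
        res = compute_printability(stack)
        assert len(res.pr_values) == 9
        assert res.mean_pr == pytest.approx(target, abs=tol)

    def test_star_is_jagged(self):
        stack, _ = _grid_stack("star")
        res = compute_printability(stack)
        assert res.mean_pr > 1.0

    def test_scale_invariance(self):
        """Imaging the same grid at 2x resolution (half the pixel size)
        changes the per-pore Pr by < 3% — only discretization differs."""
        results = []
        for px in (1.0, 0.5):
            spec = SynthSpec(
                kind="grid", seed=0, shape=(int(256 / px), int(256 / px)),
                pixel_size=px,
                params={"pore_shape": "circle", "pore_size": 50.0,
                        "wall_thickness": 12.0},
            )
            stack, _ = generate_grid_print(spec)
            results.append(compute_printability(stack).mean_pr)
        base, scaled = results
        assert abs(scaled - base) / base < 0.03

    def test_no_enclosed_pore(self):
        img = np.zeros((64, 64), dtype=np.uint16)
        img[10:50, 10:50] = 40000  # solid block, no hole
        with pytest.raises(ValueError, match="pore"):
            compute_printability(img)


class TestPoreStats:
    def test_generated_texture_recovered(self):
        spec = SynthSpec(
            kind="pores", seed=9, shape=(512, 512),
            params={"n_disks": 60, "r_min": 5.0, "r_max": 14.0},
        )
        stack, truth = generate_pore_texture(spec)
        stats = compute_pore_stats(stack)
        assert abs(stats.porosity - truth.data["porosity"]) <= 0.02
        est = np.sort(stats.radii_um)
        true = np.sort(truth.data["radii_um"])
        assert est.size == true.size
        assert np.max(np.abs(est - true)) <= stack.pixel_size
        # the histogram occupies the generated 5-14 um range
        occupied = np.nonzero(stats.histogram_counts)[0]
        assert stats.histogram_edges_um[occupied[0]] >= 4.0
        assert stats.histogram_edges_um[occupied[-1] + 1] <= 15.0

    @pytest.mark.parametrize("value,expected", [(45000, 0.0), (1000, 1.0)])
    def test_uniform_image_degenerate(self, value, expected):
        img = np.full((64, 64), value, dtype=np.uint16)
        with pytest.warns(UserWarning, match="uniform"):
            stats = compute_pore_stats(img, pixel_size=1.0)
        assert stats.porosity == expected
        assert stats.radii_um == []


class TestViability:
    def test_counts_exact_on_clean_field(self):
        spec = SynthSpec(
            kind="nuclei", seed=2, shape=(512, 512),
            params={"n_live": 90, "n_dead": 10, "blob_radius": 4.0,
                    "min_separation": 32.0},
        )
        stack, truth = generate_nuclei_field(spec)
        res = compute_viability(stack)
        assert res.n_live == 90 and res.n_dead == 10
        assert res.viability == pytest.approx(0.9)
        assert res.n_live + res.n_dead <= res.n_nuclei * 1.05

    def test_channel_swap_complements(self):
        spec = SynthSpec(
            kind="nuclei", seed=2, shape=(512, 512),
            params={"n_live": 90, "n_dead": 10, "blob_radius": 4.0,
                    "min_separation": 32.0},
        )
        stack, _ = generate_nuclei_field(spec)
        swapped = compute_viability(stack, live_channel=1, dead_channel=0)
        assert swapped.viability == pytest.approx(0.1)

    def test_empty_field_undefined(self):
        frames = np.zeros((3, 64, 64), dtype=np.uint16)
        stack = ImageStack(frames=frames, pixel_size=1.0)
        res = compute_viability(stack)
        assert res.undefined and res.viability is None


def _leak(slope, seed=0, d=100.0):
    spec = SynthSpec(
        kind="leak", seed=seed, shape=(64, 512), frame_interval=30.0,
        params={"channel_diameter": d, "I0": 15000, "Ib": 5000,
                "slope": slope, "duration": 1800.0},
    )
    return generate_leak_series(spec)


class TestPermeability:
    def test_endpoint_arithmetic(self):
        """I0-Ib = 100, It-I0 = 10 at t = 30 s, d = 1000 um ->
        P = 8.33e-5 cm/s."""
        frames = np.zeros((3, 32, 4096))
        frames[0] = 1000.0
        frames[1] = 1100.0
        frames[2] = 1110.0
        frames[:, :, 2000:2100] = 30000.0  # channel band, excluded from ROI
        stack = ImageStack(frames=frames.astype(np.uint16), pixel_size=1.0,
                           frame_interval=30.0)
        roi = np.zeros((32, 4096), dtype=bool)
        roi[:, :1000] = True
        res = compute_permeability(stack, roi, 1000.0, t_index=2)
        assert res.P == pytest.approx(8.33e-5, rel=1e-3)
        assert res.method == "endpoint"

    def test_no_accrual_is_zero(self):
        frames = np.zeros((4, 32, 64))
        frames[0] = 1000.0
        frames[1:] = 1100.0
        stack = ImageStack(frames=frames.astype(np.uint16), pixel_size=1.0,
                           frame_interval=30.0)
        roi = np.ones((32, 64), dtype=bool)
        res = compute_permeability(stack, roi, 500.0)
        assert res.P == 0.0

    def test_slope_estimator_exact_on_linear_series(self):
        stack, truth = _leak(10.0)
        roi = flanking_rois(stack.shape, stack.pixel_size,
                            truth.data["channel_center_col"], 100.0)
        res = compute_permeability(stack, roi, 100.0)
        assert res.P == pytest.approx(truth.data["P_true_cm_per_s"],
                                      rel=1e-9)

    def test_decreasing_intensity_warns_negative(self):
        frames = np.zeros((4, 32, 64))
        frames[0] = 1000.0
        for i, v in enumerate((1500.0, 1400.0, 1300.0), start=1):
            frames[i] = v
        stack = ImageStack(frames=frames.astype(np.uint16), pixel_size=1.0,
                           frame_interval=30.0)
        roi = np.ones((32, 64), dtype=bool)
        with pytest.warns(UserWarning, match="negative"):
            res = compute_permeability(stack, roi, 500.0)
        assert res.P < 0

    def test_background_above_initial_rejected(self):
        frames = np.zeros((3, 32, 64))
        frames[0] = 2000.0
        frames[1:] = 1000.0
        stack = ImageStack(frames=frames.astype(np.uint16), pixel_size=1.0,
                           frame_interval=30.0)
        with pytest.raises(ValueError, match="I0"):
            compute_permeability(stack, np.ones((32, 64), bool), 500.0)


class TestComparePermeability:
    def _res(self, P, d=100.0):
        return PermeabilityResult(P=P, I0=1, It=2, Ib=0, t=30, d_um=d)

    def test_identical_inputs(self):
        out = compare_permeability(self._res(1e-5), self._res(1e-5))
        assert out["ratio"] == pytest.approx(1.0)
        assert out["percent_reduction"] == pytest.approx(0.0)

    def test_halved_slope_doubles_ratio(self):
        stacks = {s: _leak(s, seed=4) for s in (10.0, 5.0)}
        results = {}
        for slope, (stack, truth) in stacks.items():
            roi = flanking_rois(stack.shape, stack.pixel_size,
                                truth.data["channel_center_col"], 100.0)
            results[slope] = compute_permeability(stack, roi, 100.0)
        out = compare_permeability(results[10.0], results[5.0])
        assert out["ratio"] == pytest.approx(2.0, rel=1e-6)

    def test_fivefold_reduction(self):
        out = compare_permeability(self._res(2.5e-6), self._res(0.5e-6))
        assert out["percent_reduction"] == pytest.approx(80.0, abs=5.0)

    def test_diameter_mismatch_rejected(self):
        with pytest.raises(ValueError, match="diameter"):
            compare_permeability(self._res(1e-5, d=100.0),
                                 self._res(1e-5, d=200.0))


@settings(deadline=None, max_examples=20)
@given(
    i0=st.floats(1000.0, 20000.0),
    ib_frac=st.floats(0.05, 0.95),
    slope=st.floats(0.01, 50.0),
    d=st.floats(10.0, 2000.0),
)
def test_slope_estimator_matches_closed_form(i0, ib_frac, slope, d):
    """On an exactly linear leak series the slope estimator returns the
    closed-form permeability k/(I0-Ib) * d_cm/4 to floating point."""
    ib = ib_frac * i0
    times = np.arange(6) * 30.0
    frames = np.empty((7, 8, 8))
    frames[0] = ib
    for i, t in enumerate(times, start=1):
        frames[i] = i0 + slope * t
    stack = ImageStack(frames=frames, pixel_size=1.0, frame_interval=30.0)
    res = compute_permeability(stack, np.ones((8, 8), bool), d)
    expected = slope / (i0 - ib) * (d * 1e-4) / 4.0
    assert res.P == pytest.approx(expected, rel=1e-9)
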