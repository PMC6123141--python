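"""Rasterization, DVH computation, and D/V endpoint evaluation."""

import numpy as np
import pytest

from dvhdb.dvh import (
    DoseVolumeHistogram,
    EndpointSpec,
    compute_dvh,
    dose_at_volume,
    rasterize_structure,
    volume_at_dose,
)
from dvhdb.fixtures import (
    Box,
    Cylinder,
    PhantomSpec,
    RingCylinder,
    Sphere,
    StructureSpec,
    ZGradientDose,
    make_phantom,
)
from dvhdb.geometry import build_slice_polygons


def _mask_and_grid(spec, name):
    grid, rois, truth = make_phantom(spec)
    roi = next(r for r in rois if r.roi_name == name)
    return rasterize_structure(roi, grid), grid, truth


def brute_force_dvh(doses, vols, bin_width):
    """Independent voxel-counting histogram oracle."""
    bins = np.floor(np.asarray(doses) / bin_width + 1e-9).astype(int)
    diff = np.zeros(bins.max() + 2)
    for b, v in zip(bins, vols):
        diff[b] += v
    cumulative = np.array([diff[i:].sum() for i in range(len(diff))])
    return diff, cumulative


class TestRasterize:
    def test_axis_aligned_exact_cover(self):
        """A 40x40x30 mm box on a 2 mm grid covers exactly 20x20x15 voxel
        centres on each intersected plane."""
        spec = PhantomSpec(
            grid_shape=(21, 30, 30),
            spacing=(2.0, 2.0, 2.0),
            structures=[StructureSpec("box", "PTV", Box(40.0, 40.0, 30.0))],
        )
        mask, grid, truth = _mask_and_grid(spec, "box")
        # 21 planes sit at even mm, so the box interior spans 15 planes,
        # each covering a 20x20 block of voxel centres
        assert len(mask) == 20 * 20 * 15
        assert mask.volume == pytest.approx(48.0)
        assert truth.volumes_cc["box"] == pytest.approx(48.0)

    def test_sphere_volume_within_3pct_at_2mm(self, sphere_phantom):
        grid, rois, truth = sphere_phantom
        mask = rasterize_structure(rois[0], grid)
        analytic = truth.volumes_cc["PTV_sph"]
        assert analytic == pytest.approx(65.4498, abs=1e-3)
        assert abs(mask.volume - analytic) / analytic < 0.03

    def test_ring_equals_outer_minus_inner(self):
        """Rasterizing an annulus gives outer-count minus inner-count voxels
        (two independent rasterizations as the oracle)."""
        base = dict(grid_shape=(16, 32, 32), spacing=(2.0, 2.0, 2.0))
        ring = PhantomSpec(
            **base, structures=[StructureSpec("ring", "ORGAN", RingCylinder(24, 12, 20))]
        )
        outer = PhantomSpec(
            **base, structures=[StructureSpec("outer", "ORGAN", Cylinder(24, 20))]
        )
        inner = PhantomSpec(
            **base, structures=[StructureSpec("inner", "ORGAN", Cylinder(12, 20))]
        )
        m_ring, _, _ = _mask_and_grid(ring, "ring")
        m_out, _, _ = _mask_and_grid(outer, "outer")
        m_in, _, _ = _mask_and_grid(inner, "inner")
        assert len(m_ring) == len(m_out) - len(m_in)

    def test_empty_outside_grid(self):
        from dvhdb.ingest import DoseGrid, RoiContours

        grid = DoseGrid(
            origin=(0.0, 0.0, 0.0),
            pixel_spacing=(2.0, 2.0),
            z_offsets=np.arange(4) * 2.0,
            values=np.zeros((4, 8, 8)),
            dose_scaling=1.0,
        )
        far = RoiContours(
            roi_name="far",
            roi_type="ORGAN",
            slices=[(100.0, [np.array([[0, 0], [5, 0], [5, 5], [0, 5]], dtype=float)])],
        )
        mask = rasterize_structure(far, grid)
        assert len(mask) == 0

    def test_grid_resolution_convergence(self):
        """Sphere volume error strictly decreases from 4 mm to 2 mm to 1 mm.

        The sphere centre is deliberately off-lattice: a centre aligned
        with the voxel lattice produces symmetric boundary cancellations
        that can mask the resolution dependence.
        """
        analytic = 4.0 / 3.0 * np.pi * 25.0**3 / 1000.0
        center = (0.5, 0.3, 0.7)
        errors = []
        for spacing, nz, nxy in ((4.0, 18, 20), (2.0, 34, 40), (1.0, 64, 72)):
            spec = PhantomSpec(
                grid_shape=(nz, nxy, nxy),
                spacing=(spacing, spacing, spacing),
                structures=[StructureSpec("s", "PTV", Sphere(25.0), center)],
            )
            mask, _, _ = _mask_and_grid(spec, "s")
            errors.append(abs(mask.volume - analytic))
        assert errors[0] > errors[1] > errors[2]


class TestComputeDvh:
    def test_uniform_step_dvh(self, box_phantom):
        grid, rois, _ = box_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid, bin_width=0.01)
        assert dvh.min_dose == pytest.approx(60.0, abs=0.01)
        assert dvh.mean_dose == pytest.approx(60.0, abs=0.01)
        assert dvh.max_dose == pytest.approx(60.0, abs=0.01)
        edges = dvh.dose_edges
        below = edges <= dvh.max_dose
        np.testing.assert_allclose(dvh.cumulative[below], dvh.volume, rtol=1e-12)
        assert dvh.cumulative[-1] >= 0

    def test_two_voxel_mean_and_half_step(self):
        """Hand-built two-voxel mask at 40 and 60 Gy: mean 50, cumulative
        halves above 40."""
        from dvhdb.dvh import VoxelMask
        from dvhdb.ingest import DoseGrid

        values = np.zeros((1, 1, 2))
        values[0, 0, 0], values[0, 0, 1] = 40.0, 60.0
        grid = DoseGrid(
            origin=(0, 0, 0), pixel_spacing=(10.0, 10.0),
            z_offsets=np.array([0.0]), values=values, dose_scaling=1.0,
        )
        mask = VoxelMask(
            grid_shape=values.shape,
            indices=np.array([[0, 0, 0], [0, 0, 1]]),
            voxel_volumes=np.array([1.0, 1.0]),
        )
        dvh = compute_dvh(mask, grid, bin_width=0.01)
        assert dvh.mean_dose == pytest.approx(50.0)
        assert np.interp(20.0, dvh.dose_edges, dvh.cumulative) == pytest.approx(2.0)
        assert np.interp(50.0, dvh.dose_edges, dvh.cumulative) == pytest.approx(1.0)

    def test_gradient_matches_voxel_counting_oracle(self, gradient_phantom):
        grid, rois, _ = gradient_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid, bin_width=0.01)
        k, j, i = mask.indices.T
        doses = grid.dose_gy[k, j, i]
        _, cum_oracle = brute_force_dvh(doses, mask.voxel_volumes, 0.01)
        n = min(len(cum_oracle), len(dvh.cumulative))
        np.testing.assert_allclose(dvh.cumulative[:n], cum_oracle[:n], atol=1e-12)

    def test_empty_mask_is_error(self, box_phantom):
        from dvhdb.dvh import VoxelMask

        grid, _, _ = box_phantom
        empty = VoxelMask(grid.values.shape, np.empty((0, 3), dtype=int), np.empty(0))
        with pytest.raises(ValueError, match="zero-volume"):
            compute_dvh(empty, grid)

    def test_cumulative_monotone_and_sums(self, gradient_phantom):
        grid, rois, _ = gradient_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid)
        assert np.all(np.diff(dvh.cumulative) <= 1e-12)
        assert dvh.cumulative[0] == pytest.approx(dvh.volume)
        assert dvh.diff_counts.sum() == pytest.approx(dvh.volume)
        assert dvh.min_dose <= dvh.mean_dose <= dvh.max_dose


def _linear_dvh(volume=10.0, lo=50.0, hi=60.0, bw=0.01, rx=70.0):
    """Cumulative = volume below lo, falling linearly to 0 at hi."""
    edges = np.arange(0, hi + bw, bw)
    cum = np.where(edges <= lo, volume, volume * (hi - edges) / (hi - lo))
    cum = np.clip(cum, 0, None)
    diff = cum - np.append(cum[1:], 0.0)
    return DoseVolumeHistogram(
        bin_width=bw, diff_counts=diff, cumulative=cum, volume=volume,
        min_dose=0.0, mean_dose=30.0, max_dose=hi, rx_dose=rx,
    )


class TestEndpoints:
    def test_uniform_dose_endpoints(self, box_phantom):
        grid, rois, _ = box_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid, rx_dose=70.0)
        d95 = dose_at_volume(dvh, EndpointSpec("D", 95, "%"))
        d2cc = dose_at_volume(dvh, EndpointSpec("D", 2, "cc"))
        assert d95 == pytest.approx(60.0, abs=dvh.bin_width)
        assert d2cc == pytest.approx(60.0, abs=dvh.bin_width)
        assert volume_at_dose(dvh, EndpointSpec("V", 50, "Gy")) == pytest.approx(dvh.volume)
        assert volume_at_dose(dvh, EndpointSpec("V", 70, "Gy")) == pytest.approx(0.0)

    def test_linear_interpolation_closed_form(self):
        dvh = _linear_dvh()
        # D_50%: 5 cc is reached halfway down the 50->60 Gy ramp
        assert dose_at_volume(dvh, EndpointSpec("D", 50, "%")) == pytest.approx(55.0, abs=0.011)

    def test_relative_dose_output(self):
        dvh = _linear_dvh(rx=70.0)
        d = dose_at_volume(dvh, EndpointSpec("D", 50, "%"))
        rel = dose_at_volume(dvh, EndpointSpec("D", 50, "%", output_units="relative"))
        assert rel == pytest.approx(100.0 * d / 70.0)

    def test_v100pct_equals_vrx(self):
        dvh = _linear_dvh(rx=60.0)
        assert volume_at_dose(dvh, EndpointSpec("V", 100, "%")) == pytest.approx(
            volume_at_dose(dvh, EndpointSpec("V", 60, "Gy"))
        )

    def test_volume_at_dose_matches_oracle_on_gradient(self, gradient_phantom):
        grid, rois, _ = gradient_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid)
        k, j, i = mask.indices.T
        doses = grid.dose_gy[k, j, i]
        for q in np.linspace(0.05, 0.95, 10):
            dose = float(np.quantile(doses, q))
            v = volume_at_dose(dvh, EndpointSpec("V", dose, "Gy"))
            oracle = mask.voxel_volumes[doses >= dose].sum()
            # interpolation can differ from the step oracle by at most the
            # volume that falls in the queried dose bin
            bin_mass = dvh.diff_counts[int(dose / dvh.bin_width)]
            assert abs(v - oracle) <= bin_mass + 1e-9

    def test_cc_spec_exceeding_volume_is_error(self):
        dvh = _linear_dvh(volume=10.0)
        with pytest.raises(ValueError, match="exceeds"):
            dose_at_volume(dvh, EndpointSpec("D", 11, "cc"))

    def test_consistency_roundtrip(self, gradient_phantom):
        """volume_at_dose(dose_at_volume(v)) >= v within one bin."""
        grid, rois, _ = gradient_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid)
        for frac in (20.0, 50.0, 80.0, 95.0):
            d = dose_at_volume(dvh, EndpointSpec("D", frac, "%"))
            v = volume_at_dose(dvh, EndpointSpec("V", max(d, 1e-9), "Gy"))
            target = dvh.volume * frac / 100.0
            assert v >= target - dvh.diff_counts.max() - 1e-9

    def test_monotone_in_spec(self, gradient_phantom):
        grid, rois, _ = gradient_phantom
        mask = rasterize_structure(rois[0], grid)
        dvh = compute_dvh(mask, grid)
        d_vals = [dose_at_volume(dvh, EndpointSpec("D", v, "%")) for v in (10, 30, 50, 70, 90)]
        assert all(a >= b - 1e-9 for a, b in zip(d_vals, d_vals[1:]))
        v_vals = [volume_at_dose(dvh, EndpointSpec("V", d, "Gy")) for d in (5, 6, 7, 8)]
        assert all(a >= b - 1e-9 for a, b in zip(v_vals, v_vals[1:]))

    def test_endpoint_parser(self):
        spec = EndpointSpec.parse("D_95%")
        assert (spec.kind, spec.value, spec.value_units) == ("D", 95.0, "%")
        assert EndpointSpec.parse("V_20Gy").value_units == "Gy"
        assert EndpointSpec.parse("D_2cc").value_units == "cc"
        with pytest.raises(ValueError):
            EndpointSpec.parse("X_5%")
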