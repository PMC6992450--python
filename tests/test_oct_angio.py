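"""Angiogram construction, capillary segmentation, and ring densitometry."""

import numpy as np
import pandas as pd
import pytest

from strokelab import oct_angio
from strokelab.synthetic import AngioPhantomSpec, gen_angiogram_phantom

SLAB = (60.0, 210.0)  # 150-um capillary slab below the pial stratum
SHAPE = (80, 120, 120)  # 3-um voxels -> 360 x 360 x 240 um


def _phantom(frac=0.05, radius=0.0, survival=1.0, seed=7, n_acq=5,
             noise_sd=0.05, shape=SHAPE):
    center = (shape[2] * 3.0 / 2, shape[1] * 3.0 / 2)
    spec = AngioPhantomSpec(volume_shape=shape, capillary_fraction=frac,
                            ablation_center_um=center,
                            ablation_radius_um=radius,
                            ablation_survival=survival)
    reps, truth = gen_angiogram_phantom(spec, seed=seed,
                                        n_acquisitions=n_acq,
                                        noise_sd=noise_sd)
    return spec, reps, truth


def _truth_capmask(truth, voxel=3.0, slab=SLAB):
    return oct_angio.CapillaryMask(mask=truth, slab_um=slab,
                                   voxel_size_um=voxel)


def test_pixel_size_closed_form():
    assert oct_angio.oct_pixel_size_um(600.0, 400) == pytest.approx(1.5)


class TestBuildAngiogram:
    def test_identical_repeats_give_zero_volume(self):
        reps = np.broadcast_to(np.random.default_rng(0).random((4, 4, 4)),
                               (2, 3, 4, 4, 4)).copy()
        vol = oct_angio.build_angiogram(reps)
        assert np.all(vol.voxels == 0.0)

    def test_flow_voxels_bright_exactly_where_truth_flows(self):
        spec, reps, truth = _phantom(noise_sd=0.0, n_acq=2)
        vol = oct_angio.build_angiogram(reps, voxel_size_um=3.0)
        flowing = vol.voxels > 0
        below_pial = int(spec.surface_vessel_depth_um / 3.0)
        assert np.array_equal(flowing[below_pial:], truth[below_pial:])

    def test_no_flow_no_noise_is_exactly_zero(self):
        spec = AngioPhantomSpec(volume_shape=(20, 30, 30),
                                capillary_fraction=0.0)
        reps, truth = gen_angiogram_phantom(spec, seed=1, n_acquisitions=2,
                                            noise_sd=0.0)
        vol = oct_angio.build_angiogram(reps)
        pial = int(spec.surface_vessel_depth_um / spec.voxel_size_um)
        assert not truth.any()
        assert np.all(vol.voxels[pial:] == 0.0)

    def test_averaging_reduces_background_variance(self):
        # static background only (below the pial stratum): averaging 20
        # acquisitions instead of 2 shrinks the noise variance ~10-fold
        spec = AngioPhantomSpec(volume_shape=(30, 24, 24),
                                capillary_fraction=0.0)
        many, _ = gen_angiogram_phantom(spec, seed=3, n_acquisitions=20)
        few, _ = gen_angiogram_phantom(spec, seed=3, n_acquisitions=2)
        below = int(spec.surface_vessel_depth_um / spec.voxel_size_um) + 1
        v20 = oct_angio.build_angiogram(many).voxels[below:].var()
        v2 = oct_angio.build_angiogram(few).voxels[below:].var()
        assert v2 / v20 == pytest.approx(10.0, rel=0.5)

    def test_insufficient_repeats_rejected(self):
        with pytest.raises(ValueError):
            oct_angio.build_angiogram(np.zeros((2, 1, 4, 4, 4)))
        with pytest.raises(ValueError):
            oct_angio.build_angiogram(np.zeros((4, 4)))


class TestSegmentCapillaries:
    def test_zero_volume_gives_empty_mask(self):
        vol = oct_angio.AngiogramVolume(np.zeros(SHAPE), voxel_size_um=3.0)
        m = oct_angio.segment_capillaries(vol, slab_um=SLAB)
        assert not m.mask.any() and m.density == 0.0

    def test_all_flow_gives_unit_density(self):
        vol = oct_angio.AngiogramVolume(np.ones(SHAPE), voxel_size_um=3.0)
        m = oct_angio.segment_capillaries(vol, slab_um=SLAB, min_voxels=1)
        assert m.density == 1.0

    def test_noise_free_phantom_recovered_with_high_dice(self):
        spec, reps, truth = _phantom(noise_sd=0.0, n_acq=2)
        vol = oct_angio.build_angiogram(reps, voxel_size_um=3.0)
        fp = oct_angio.surface_vessel_footprint(vol,
                                                spec.surface_vessel_depth_um)
        m = oct_angio.segment_capillaries(vol, slab_um=SLAB, exclusion=fp)
        z0, z1 = (int(s / 3.0) for s in SLAB)
        est = m.mask[z0:z1][:, ~fp]
        ref = truth[z0:z1][:, ~fp]
        dice = 2 * (est & ref).sum() / (est.sum() + ref.sum())
        assert dice > 0.95

    @pytest.mark.parametrize("frac", [0.02, 0.05, 0.10])
    def test_density_recovery_at_default_noise(self, frac):
        spec, reps, truth = _phantom(frac=frac)
        vol = oct_angio.build_angiogram(reps, voxel_size_um=3.0)
        fp = oct_angio.surface_vessel_footprint(vol,
                                                spec.surface_vessel_depth_um)
        m = oct_angio.segment_capillaries(vol, slab_um=SLAB, exclusion=fp)
        z0, z1 = (int(s / 3.0) for s in SLAB)
        ref = truth[z0:z1][:, ~fp]
        truth_density = ref.sum() / ref.size
        assert m.density == pytest.approx(truth_density, rel=0.10)

    def test_slab_outside_volume_rejected(self):
        vol = oct_angio.AngiogramVolume(np.zeros((20, 8, 8)),
                                        voxel_size_um=3.0)
        with pytest.raises(ValueError):
            oct_angio.segment_capillaries(vol, slab_um=(30.0, 300.0))

    def test_fully_excluded_slab_rejected(self):
        vol = oct_angio.AngiogramVolume(np.zeros(SHAPE), voxel_size_um=3.0)
        with pytest.raises(ValueError):
            oct_angio.segment_capillaries(
                vol, slab_um=SLAB,
                exclusion=np.ones(SHAPE[1:], dtype=bool))


class TestRingDensity:
    def test_rings_partition_the_annulus(self):
        """Every included lateral voxel between 100 and 300 um falls in
        exactly one half-open ring (brute-force distance check)."""
        mask = np.zeros((10, 80, 80), dtype=bool)
        cap = oct_angio.CapillaryMask(mask=mask, slab_um=(0.0, 30.0),
                                      voxel_size_um=3.0)
        center = (120.0, 120.0)
        prof = oct_angio.ring_density(cap, center)
        v = 3.0
        counted = 0
        for iy in range(80):
            for ix in range(80):
                d = np.hypot((ix + 0.5) * v - center[0],
                             (iy + 0.5) * v - center[1])
                hits = sum(1 for r in prof.radii_um if r <= d < r + 50.0)
                assert hits <= 1
                if 100.0 <= d < 300.0:
                    assert hits == 1
                    counted += 1
        assert counted > 0

    def test_uniform_random_mask_matches_global_density(self, rng):
        p = 0.1
        mask = rng.random((20, 100, 100)) < p
        cap = oct_angio.CapillaryMask(mask=mask, slab_um=(0.0, 60.0),
                                      voxel_size_um=3.0)
        prof = oct_angio.ring_density(cap, (150.0, 150.0))
        base = oct_angio.ring_density(cap, (150.0, 150.0))
        norm = oct_angio.ring_density(cap, (150.0, 150.0), baseline=base)
        ok = ~prof.missing
        assert ok.sum() >= 3
        assert np.allclose(prof.density[ok], p, atol=0.02)
        assert np.allclose(norm.normalized[ok], 1.0)

    def test_baseline_against_itself_is_unity(self):
        _, reps, truth = _phantom(noise_sd=0.0, n_acq=2)
        cap = _truth_capmask(truth)
        prof = oct_angio.ring_density(cap, (180.0, 180.0))
        norm = oct_angio.ring_density(cap, (180.0, 180.0), baseline=prof)
        assert np.allclose(norm.normalized[~norm.missing], 1.0)

    def test_ablation_depresses_only_inner_rings(self):
        """Capillaries removed within 175 um of the center: rings starting
        at 100 and 150 um fall, rings from 200 um out stay at baseline."""
        shape = (80, 200, 200)  # 600 x 600 um field
        _, _, truth_pre = _phantom(noise_sd=0.0, n_acq=1, shape=shape)
        _, _, truth_post = _phantom(noise_sd=0.0, n_acq=1, shape=shape,
                                    radius=175.0, survival=0.0)
        center = (300.0, 300.0)
        base = oct_angio.ring_density(_truth_capmask(truth_pre), center)
        norm = oct_angio.ring_density(_truth_capmask(truth_post), center,
                                      baseline=base)
        n = norm.normalized
        assert n[0] < 0.2          # [100, 150): fully inside ablation
        assert n[1] < 0.8          # [150, 200): straddles the 175-um edge
        assert n[2] > 0.85 and n[3] > 0.85  # outside: at baseline

    def test_recovery_ring_brackets_ablation_radius(self):
        shape = (80, 200, 200)
        _, _, truth_pre = _phantom(noise_sd=0.0, n_acq=1, shape=shape)
        _, _, truth_post = _phantom(noise_sd=0.0, n_acq=1, shape=shape,
                                    radius=175.0, survival=0.0)
        center = (300.0, 300.0)
        base = oct_angio.ring_density(_truth_capmask(truth_pre), center)
        norm = oct_angio.ring_density(_truth_capmask(truth_post), center,
                                      baseline=base)
        recovered = np.nonzero(norm.normalized >= 0.9)[0]
        first = recovered[0]
        assert norm.radii_um[first] >= 175.0
        assert norm.radii_um[first - 1] < 175.0

    def test_empty_mask_gives_zero_densities(self):
        cap = oct_angio.CapillaryMask(mask=np.zeros(SHAPE, bool),
                                      slab_um=SLAB, voxel_size_um=3.0)
        prof = oct_angio.ring_density(cap, (180.0, 180.0),
                                      radii_spec=(100.0, 170.0, 50.0))
        assert np.all(prof.density[~prof.missing] == 0.0)

    def test_out_of_field_rings_flagged_missing(self):
        cap = oct_angio.CapillaryMask(mask=np.zeros((10, 200, 200), bool),
                                      slab_um=(0.0, 30.0), voxel_size_um=3.0)
        prof = oct_angio.ring_density(cap, (300.0, 300.0),
                                      radii_spec=(100.0, 500.0, 50.0))
        assert prof.missing[-1]  # [450, 500) beyond the corner distance
        assert not prof.missing[0]
        with pytest.raises(ValueError):
            oct_angio.ring_density(cap, (700.0, 300.0))


class TestCompareGroups:
    def test_identical_groups_null_result(self):
        out = oct_angio.compare_groups({"a": np.array([0.2, 0.3]),
                                        "b": np.array([0.2, 0.3])})
        row = out.iloc[0]
        assert row.statistic == 0.0 and row.p == 1.0 and not row.significant

    def test_textbook_two_sample_t(self):
        """Hand-checkable toy densities 0.4-ish vs 0.2-ish: compare against
        the pooled-variance two-sample t formula evaluated inline."""
        a = np.array([0.38, 0.41, 0.42])
        b = np.array([0.19, 0.21, 0.20])
        out = oct_angio.compare_groups({"pre": a, "post": b})
        row = out[out.comparison == "pre vs post"].iloc[0]
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (2 / 3))
        assert row.statistic == pytest.approx(t_hand, rel=1e-12)
        assert row.significant and row.p < 0.05
        assert row.mean_a == pytest.approx(a.mean())

    def test_large_effect_flagged_significant(self, rng):
        a = 0.30 + 0.01 * rng.standard_normal(3)
        b = a - 0.03  # ~3 SD shift
        out = oct_angio.compare_groups({"pre": a, "post": b})
        assert out.iloc[0].significant

    def test_anova_row_for_three_groups(self):
        out = oct_angio.compare_groups({
            "a": np.array([1.0, 1.1, 0.9]),
            "b": np.array([2.0, 2.1, 1.9]),
            "c": np.array([1.0, 1.2, 1.1])})
        assert out.iloc[0].test == "anova"
        assert out.iloc[0].significant
        assert len(out) == 4  # ANOVA + three pairwise rows

    def test_single_observation_rejected(self):
        with pytest.raises(ValueError):
            oct_angio.compare_groups({"a": np.array([1.0]),
                                      "b": np.array([1.0, 2.0])})
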