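"""Voxel dose kernel, convolution dosimetry, gamma index, region stats."""

import numpy as np
import pytest

import dpkit as dk
from dpkit.dose import (
    KEV_TO_J,
    DoseMap,
    VoxelKernel,
    activity_from_counts,
    build_vdk,
    cumulated_activity,
    dose_convolve,
    gamma_index,
    region_stats,
)

SPACING = (1.0, 1.0, 1.0)


# ---------------------------------------------------------------- VDK


def test_vdk_seeded_reproducibility(beta_kernel_soft, demo_nuclide, soft_tissue):
    kw = dict(voxel_size_mm=1.0, n_pair_samples=300, seed=5, size=7)
    a = build_vdk(beta_kernel_soft, soft_tissue, demo_nuclide.spectrum.e_eff, **kw)
    b = build_vdk(beta_kernel_soft, soft_tissue, demo_nuclide.spectrum.e_eff, **kw)
    np.testing.assert_array_equal(a.values, b.values)
    kw["seed"] = 6
    c = build_vdk(beta_kernel_soft, soft_tissue, demo_nuclide.spectrum.e_eff, **kw)
    assert not np.array_equal(a.values, c.values)


def test_vdk_default_shape_is_23_cubed(beta_kernel_soft, demo_nuclide, soft_tissue):
    vdk = build_vdk(
        beta_kernel_soft, soft_tissue, demo_nuclide.spectrum.e_eff,
        n_pair_samples=100, seed=1,
    )
    assert vdk.values.shape == (23, 23, 23)


def test_vdk_requires_rn_scale_kernel(beta_kernel_soft, soft_tissue):
    from dpkit.beta import x90_rescale

    with pytest.raises(ValueError, match="rN scale"):
        build_vdk(x90_rescale(beta_kernel_soft), soft_tissue, 250.0, n_pair_samples=100)
    with pytest.raises(ValueError, match="n_pair_samples"):
        build_vdk(beta_kernel_soft, soft_tissue, 250.0, n_pair_samples=10)


def test_vdk_central_voxel_dominates(vdk_soft):
    center = vdk_soft.values[7, 7, 7]
    assert center == vdk_soft.values.max()
    flat = vdk_soft.values.ravel()
    assert np.count_nonzero(flat == center) == 1


def test_vdk_energy_bookkeeping_within_5pct(vdk_soft, beta_kernel_soft, soft_tissue):
    """Sum K * voxel mass ~ E_eff * (kernel integral): the shell-integral oracle."""
    voxel_mass_kg = soft_tissue.density * (0.1**3) * 1e-3
    absorbed_j = vdk_soft.values.sum() * voxel_mass_kg
    oracle_j = vdk_soft.e_eff_kev * KEV_TO_J * beta_kernel_soft.integral
    assert absorbed_j == pytest.approx(oracle_j, rel=0.05)


def test_vdk_mirror_symmetry(vdk_soft, beta_kernel_soft, demo_nuclide, soft_tissue):
    """Mirror-pair differences are consistent with the MC standard error."""
    reps = np.stack(
        [
            build_vdk(
                beta_kernel_soft, soft_tissue, demo_nuclide.spectrum.e_eff,
                n_pair_samples=10_000, seed=100 + s, size=7,
            ).values
            for s in range(6)
        ]
    )
    se = reps.std(axis=0, ddof=1)  # per-voxel SE of a single build
    k = reps[0]
    for axis in range(3):
        flipped = np.flip(k, axis=axis)
        se_f = np.flip(se, axis=axis)
        tol = 3.0 * np.sqrt(se**2 + se_f**2) + 1e-18
        frac_ok = np.mean(np.abs(k - flipped) <= tol)
        assert frac_ok > 0.97  # 3-sigma bound with a 5-dof SE estimate


def test_vdk_error_scales_as_inverse_sqrt_samples(beta_kernel_soft, demo_nuclide, soft_tissue):
    """Doubling the pair count shrinks the replicate SD by ~sqrt(2)."""

    def replicate_sd(n):
        reps = np.stack(
            [
                build_vdk(
                    beta_kernel_soft, soft_tissue, demo_nuclide.spectrum.e_eff,
                    n_pair_samples=n, seed=200 + s, size=5,
                ).values
                for s in range(20)
            ]
        )
        sd = reps.std(axis=0, ddof=1)
        # voxels touching the source voxel admit near-zero pair distances,
        # so their 1/r^2 estimator is heavy-tailed; pool the clean ones
        sd[1:4, 1:4, 1:4] = 0.0
        return np.sqrt(np.mean(sd**2))

    ratio = replicate_sd(500) / replicate_sd(1000)
    assert ratio == pytest.approx(np.sqrt(2.0), rel=0.25)


def test_vdk_warns_when_voxel_exceeds_kernel_support(beta_kernel_soft, soft_tissue):
    with pytest.warns(UserWarning, match="exceeds the kernel support"):
        build_vdk(
            beta_kernel_soft, soft_tissue, 250.0,
            voxel_size_mm=100.0, n_pair_samples=100, size=3,
        )


# ---------------------------------------------------------------- activity


def test_activity_proportionality_and_conservation():
    counts = np.zeros((4, 4, 4))
    counts[0, 0, :3] = [1.0, 1.0, 2.0]
    mask = counts > 0
    act = activity_from_counts(counts, mask, 4.0, SPACING)
    np.testing.assert_allclose(act.values[0, 0, :3], [1.0, 1.0, 2.0])
    assert act.values[mask].sum() == pytest.approx(4.0, rel=1e-9)


def test_activity_uniform_counts_split_evenly():
    counts = np.ones((3, 3, 3))
    mask = np.ones((3, 3, 3), bool)
    act = activity_from_counts(counts, mask, 27.0, SPACING)
    np.testing.assert_allclose(act.values, 1.0)


def test_activity_outside_mask_policy():
    counts = np.ones((3, 3, 3))
    mask = np.zeros((3, 3, 3), bool)
    mask[1, 1, 1] = True
    act = activity_from_counts(counts, mask, 10.0, SPACING)
    assert act.values.sum() == pytest.approx(10.0)  # outside zeroed
    kept = activity_from_counts(counts, mask, 10.0, SPACING, keep_outside=True)
    assert kept.values.sum() == pytest.approx(270.0)


def test_activity_requires_masked_counts():
    with pytest.raises(ValueError, match="no counts"):
        activity_from_counts(np.zeros((2, 2, 2)), np.ones((2, 2, 2), bool), 1.0, SPACING)


def test_cumulated_activity_arithmetic():
    counts = np.zeros((3, 3, 3))
    counts[1, 1, 1] = 1.0
    act = activity_from_counts(counts, counts > 0, 1.0, SPACING)
    cum = cumulated_activity(act, 64.2)
    assert cum[1, 1, 1] == pytest.approx(1.443 * 64.2 * 3600.0, rel=1e-12)  # ~3.335e5
    assert cum[0, 0, 0] == 0.0
    scaled = cumulated_activity(
        activity_from_counts(3.0 * counts, counts > 0, 3.0, SPACING), 64.2
    )
    assert scaled[1, 1, 1] == pytest.approx(3.0 * cum[1, 1, 1], rel=1e-12)


# ---------------------------------------------------------------- convolution


def _toy_kernel(size=5, seed=0):
    rng = np.random.default_rng(seed)
    v = rng.random((size, size, size))
    v[size // 2, size // 2, size // 2] = 2.0
    return VoxelKernel(v, 1.0, "Soft Tissue", 250.0, 100, seed)


def test_convolution_impulse_identity():
    k = _toy_kernel()
    cum = np.zeros((15, 15, 15))
    cum[7, 7, 7] = 1.0
    dose = dose_convolve(cum, k, SPACING)
    np.testing.assert_allclose(dose.values[5:10, 5:10, 5:10], k.values, rtol=1e-10)


def test_convolution_linearity_and_translation():
    k = _toy_kernel(seed=3)
    a = np.zeros((12, 12, 12))
    b = np.zeros((12, 12, 12))
    a[4, 4, 4] = 2.0
    b[6, 7, 5] = 1.0
    d_a = dose_convolve(a, k, SPACING).values
    d_b = dose_convolve(b, k, SPACING).values
    d_sum = dose_convolve(a + b, k, SPACING).values
    np.testing.assert_allclose(d_sum, d_a + d_b, atol=1e-9 * d_sum.max())
    # shifted impulse -> identically shifted dose (interior placement)
    np.testing.assert_allclose(
        d_b[4:9, 5:10, 3:8], 0.5 * d_a[2:7, 2:7, 2:7], rtol=1e-9
    )


def test_convolution_matches_bruteforce_oracle():
    """Frequency-domain result vs direct spatial summation on an 8³ map."""
    k = _toy_kernel(size=5, seed=9)
    rng = np.random.default_rng(4)
    cum = rng.random((8, 8, 8))
    fast = dose_convolve(cum, k, SPACING).values

    slow = np.zeros_like(cum)
    kh = 2
    for i in range(8):
        for j in range(8):
            for l in range(8):
                acc = 0.0
                for di in range(-kh, kh + 1):
                    for dj in range(-kh, kh + 1):
                        for dl in range(-kh, kh + 1):
                            si, sj, sl = i - di, j - dj, l - dl
                            if 0 <= si < 8 and 0 <= sj < 8 and 0 <= sl < 8:
                                acc += cum[si, sj, sl] * k.values[kh + di, kh + dj, kh + dl]
                slow[i, j, l] = acc
    np.testing.assert_allclose(fast, slow, rtol=1e-8)


def test_convolution_rejects_spacing_mismatch():
    k = _toy_kernel()
    with pytest.raises(ValueError, match="spacing"):
        dose_convolve(np.zeros((8, 8, 8)), k, (0.98, 0.98, 0.98))


# ---------------------------------------------------------------- gamma


def _blob_dose(shape=(24, 24, 24), seed=0):
    rng = np.random.default_rng(seed)
    z, y, x = np.indices(shape, dtype=float)
    c = (np.array(shape) - 1) / 2
    r2 = (z - c[0]) ** 2 + (y - c[1]) ** 2 + (x - c[2]) ** 2
    vals = 10.0 * np.exp(-r2 / 60.0)
    vals[vals < 1e-3] = 0.0
    return DoseMap(vals, SPACING)


def test_gamma_identity_maps():
    ref = _blob_dose()
    res = gamma_index(ref, ref)
    assert res.pass_rate == 100.0
    assert np.all(res.gamma[ref.values > 0] == 0.0)


def test_gamma_three_percent_global_offset():
    """+3% everywhere with global normalization: gamma <= 1, exactly 1 at the max."""
    ref = _blob_dose()
    ev = DoseMap(1.03 * ref.values, SPACING)
    res = gamma_index(ref, ev)
    g = res.gamma[ref.values > 0]
    assert res.pass_rate == 100.0
    assert g.max() <= 1.0 + 1e-9
    # on a uniform plateau the dose term alone fixes gamma = 1
    flat = DoseMap(np.full((10, 10, 10), 5.0), SPACING)
    res_flat = gamma_index(flat, DoseMap(1.03 * flat.values, SPACING))
    np.testing.assert_allclose(res_flat.gamma, 1.0, rtol=1e-9)
    assert res_flat.pass_rate == 100.0


def test_gamma_one_voxel_shift_passes_at_3mm():
    ref = _blob_dose()
    ev = DoseMap(np.roll(ref.values, 1, axis=0), SPACING)
    res = gamma_index(ref, ev)
    interior = np.zeros_like(ref.values, bool)
    interior[3:-3, 3:-3, 3:-3] = True
    assert np.all(res.gamma[interior & (ref.values > 0)] <= 1.0 + 1e-9)


def test_gamma_grid_mismatch_rejected():
    ref = _blob_dose()
    with pytest.raises(ValueError, match="grid"):
        gamma_index(ref, DoseMap(ref.values[:-1], SPACING))


def test_gamma_local_normalization_is_stricter():
    ref = _blob_dose()
    ev = DoseMap(1.05 * ref.values, SPACING)
    glob = gamma_index(ref, ev, normalization="global")
    loc = gamma_index(ref, ev, normalization="local", dose_threshold=1e-6)
    assert loc.pass_rate <= glob.pass_rate


def test_gamma_asymmetry_both_directions_computable():
    ref = _blob_dose()
    ev = DoseMap(np.roll(ref.values * 1.02, 2, axis=1), SPACING)
    fwd = gamma_index(ref, ev)
    rev = gamma_index(ev, ref)
    assert 0.0 <= fwd.pass_rate <= 100.0
    assert 0.0 <= rev.pass_rate <= 100.0


# ---------------------------------------------------------------- region stats


def test_region_stats_constant_and_additive():
    vals = np.zeros((6, 6, 6))
    vals[:3] = 4.0
    vals[3:] = 1.0
    dose = DoseMap(vals, SPACING)
    lower = np.zeros_like(vals, bool)
    lower[:3] = True
    upper = ~lower
    whole = np.ones_like(vals, bool)
    table = region_stats(dose, {"lower": lower, "upper": upper, "whole": whole})
    row = table.set_index("region")
    assert row.loc["lower", "sd_gy"] == 0.0
    assert row.loc["lower", "min_gy"] == row.loc["lower", "max_gy"] == 4.0
    # voxel-count-weighted means of disjoint parts reproduce the whole
    combined = (
        row.loc["lower", "mean_gy"] * row.loc["lower", "n_voxels"]
        + row.loc["upper", "mean_gy"] * row.loc["upper", "n_voxels"]
    ) / row.loc["whole", "n_voxels"]
    assert combined == pytest.approx(row.loc["whole", "mean_gy"], abs=1e-12)


def test_region_stats_gamma_pass_and_empty_mask():
    dose = _blob_dose()
    res = gamma_index(dose, dose)
    mask = dose.values > 1.0
    table = region_stats(dose, {"hot": mask}, res)
    assert table.loc[0, "gamma_pass_pct"] == 100.0
    with pytest.raises(ValueError, match="empty"):
        region_stats(dose, {"void": np.zeros_like(mask)})
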