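"""Feature panel: oracle equivalence, closed forms and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from petrim import (
    FEATURE_NAMES,
    LesionSample,
    RegionMask,
    SUVolume,
    basic_statistics,
    build_rim,
    extract_all,
    lesion_sample,
    mtv,
    peak,
    quarter_distribution,
    quarter_glycolysis,
    rim_average,
    sam,
    tlg,
)
from petrim.features import PEAK_SPHERE_RADIUS_MM

from conftest import bf_quarter_bins, bf_rim, bf_statistics


def make_sample(values, voxvol=1.0):
    return LesionSample(np.asarray(values, dtype=float), voxvol)


# --------------------------------------------------------------------------
# Basic statistics


def test_boxplot_statistics_on_outlier_sample():
    stats = basic_statistics(make_sample([1, 2, 3, 4, 100]))
    assert stats["Max"] == 100
    assert stats["Min"] == 1
    assert stats["Median"] == 3
    assert stats["1st Quartile"] == 2
    assert stats["3rd Quartile"] == 4
    # fence = 4 + 1.5*2 = 7, so the outlier is excluded
    assert stats["Upper Adjacent"] == 4


def test_constant_sample_collapses_all_statistics():
    stats = basic_statistics(make_sample([3.7] * 11))
    for key in ("Max", "Min", "Mean", "Median", "RMS", "Upper Adjacent"):
        assert stats[key] == pytest.approx(3.7)
    assert stats["Std"] == pytest.approx(0.0, abs=1e-12)


def test_rms_closed_form_two_values():
    stats = basic_statistics(make_sample([0.0, 5.0]))
    assert stats["RMS"] == pytest.approx(np.sqrt(25.0 / 2.0))


@settings(max_examples=300, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 50.0, allow_nan=False), min_size=1,
                max_size=40))
def test_statistics_match_brute_force_oracle(values):
    got = basic_statistics(make_sample(values))
    expect = bf_statistics(values)
    for key, val in expect.items():
        assert got[key] == pytest.approx(val, rel=1e-12, abs=1e-12)


def test_empty_sample_rejected():
    with pytest.raises(ValueError, match="empty"):
        make_sample([])


# --------------------------------------------------------------------------
# Volumes


def test_mtv_arithmetic_and_linearity():
    assert mtv(make_sample(np.ones(1000), 3.5 * 3.5 * 3.4 / 1000)) == \
        pytest.approx(41.65)
    assert mtv(make_sample([1.0], 0.001)) == pytest.approx(0.001)
    base = make_sample(np.ones(77), 2 * 2 * 2 / 1000)
    doubled_z = make_sample(np.ones(77), 2 * 2 * 4 / 1000)
    assert mtv(doubled_z) == pytest.approx(2 * mtv(base))


def test_tlg_is_mean_times_mtv():
    s = make_sample(np.full(10, 4.0), 1.0)
    assert tlg(s) == pytest.approx(40.0)
    assert tlg(make_sample(np.zeros(5), 1.0)) == 0.0


# --------------------------------------------------------------------------
# Grayscale quarters


def test_quarter_distribution_matches_binning_oracle_uniform_grid():
    values = np.linspace(0.0, 1.0, 1001)
    got = quarter_distribution(make_sample(values))
    bins = bf_quarter_bins(values)
    for k in range(4):
        assert got[f"Q{k + 1} Distribution"] == \
            pytest.approx(100.0 * len(bins[k]) / 1001)
    # first three quarters hold 250/1001 values each
    assert got["Q1 Distribution"] == pytest.approx(100 * 250 / 1001)


def test_quarter_distribution_degenerate_and_two_point():
    got = quarter_distribution(make_sample([2.0] * 7))
    assert got["Q1 Distribution"] == 100.0
    assert got["Q2 Distribution"] == got["Q4 Distribution"] == 0.0
    got = quarter_distribution(make_sample([0.0, 1.0]))
    assert got["Q1 Distribution"] == 50.0
    assert got["Q4 Distribution"] == 50.0


def test_quarter_glycolysis_hand_checked_bins():
    got = quarter_glycolysis(make_sample([1.0, 1.0, 1.0, 9.0], voxvol=1.0))
    assert got["Glycolysis Q1"] == pytest.approx(3.0)   # bin [1,3)
    assert got["Glycolysis Q2"] == got["Glycolysis Q3"] == 0.0
    assert got["Glycolysis Q4"] == pytest.approx(9.0)   # bin [7,9]


def test_quarter_glycolysis_degenerate_range():
    got = quarter_glycolysis(make_sample([2.5] * 4, voxvol=2.0))
    assert got["Glycolysis Q1"] == pytest.approx(2.5 * 8.0)
    assert got["Glycolysis Q4"] == 0.0


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.lists(st.floats(0.0, 30.0, allow_nan=False), min_size=1,
                max_size=30))
def test_quarter_partition_identities(values):
    s = make_sample(values, voxvol=0.04165)
    dist = quarter_distribution(s)
    glyc = quarter_glycolysis(s)
    assert sum(dist.values()) == pytest.approx(100.0, abs=1e-9)
    assert sum(glyc.values()) == pytest.approx(tlg(s), rel=1e-9, abs=1e-12)


# --------------------------------------------------------------------------
# Peak


def test_peak_equals_uptake_inside_large_uniform_lesion(uniform_phantom):
    volume, lesion, _, _ = uniform_phantom
    # lesion radius 14 mm > sphere radius 6.2 mm: some sphere fits inside
    assert peak(volume, lesion) == pytest.approx(8.0)


def test_peak_of_single_hot_voxel_is_sphere_average():
    spacing = (3.5, 3.5, 3.4)
    values = np.ones((9, 9, 9))
    values[4, 4, 4] = 10.0
    lesion = np.zeros((9, 9, 9), dtype=bool)
    lesion[4, 4, 4] = True
    volume = SUVolume(values, spacing)
    # enumerate the sphere membership by hand at this spacing
    r2 = PEAK_SPHERE_RADIUS_MM**2
    members = [
        (i, j, k)
        for i in range(-3, 4) for j in range(-3, 4) for k in range(-3, 4)
        if (i * 3.5) ** 2 + (j * 3.5) ** 2 + (k * 3.4) ** 2 <= r2
    ]
    expect = sum(values[4 + i, 4 + j, 4 + k] for i, j, k in members) / len(members)
    got = peak(volume, RegionMask(lesion, spacing))
    assert got == pytest.approx(expect)
    assert got < 10.0


def test_peak_never_exceeds_max(rng):
    for _ in range(100):
        shape = tuple(rng.integers(6, 12, size=3))
        values = rng.uniform(0.0, 10.0, size=shape)
        lesion = rng.uniform(size=shape) > 0.6
        if not lesion.any():
            lesion[tuple(rng.integers(0, s) for s in shape)] = True
        spacing = tuple(rng.uniform(2.0, 5.0, size=3))
        vol = SUVolume(values, spacing)
        assert peak(vol, RegionMask(lesion, spacing)) <= values.max() + 1e-12


# --------------------------------------------------------------------------
# Rim, RA, SAM


def test_rim_of_single_voxel_is_city_block_ball():
    lesion = np.zeros((9, 9, 9), dtype=bool)
    lesion[4, 4, 4] = True
    rim = build_rim(RegionMask(lesion, (3.5, 3.5, 3.4)), width_voxels=2)
    assert rim.n_voxels == 24  # 6 at distance 1 + 18 at distance 2
    np.testing.assert_array_equal(rim.values, bf_rim(lesion, 2))


@pytest.mark.parametrize("width", [1, 2, 3])
def test_rim_matches_city_block_oracle_on_random_blobs(rng, width):
    for _ in range(25):
        lesion = rng.uniform(size=(7, 7, 7)) > 0.85
        if not lesion.any():
            lesion[3, 3, 3] = True
        mask = RegionMask(lesion, (3.5, 3.5, 3.4))
        rim = build_rim(mask, width_voxels=width)
        np.testing.assert_array_equal(rim.values, bf_rim(lesion, width))
        assert not (rim.values & lesion).any()


def test_rim_clipped_at_image_boundary():
    lesion = np.zeros((5, 5, 5), dtype=bool)
    lesion[0, 0, 0] = True
    rim = build_rim(RegionMask(lesion, (1, 1, 1)), width_voxels=2)
    assert rim.values.shape == (5, 5, 5)
    np.testing.assert_array_equal(rim.values, bf_rim(lesion, 2))


def test_rim_average_of_hard_edged_sphere_is_background(uniform_phantom):
    volume, lesion, _, _ = uniform_phantom
    rim = build_rim(lesion, width_voxels=2)
    assert rim_average(volume, rim) == pytest.approx(1.0)


def test_rim_average_of_blurred_sphere_between_background_and_peak():
    from petrim import PhantomSpec, make_phantom

    volume, lesion, _, _ = make_phantom(PhantomSpec(profile="gaussian"))
    ra = rim_average(volume, build_rim(lesion, width_voxels=2))
    assert 1.0 < ra < 8.0


def test_sam_background_subtraction_and_linearity(uniform_phantom):
    volume, lesion, _, truth = uniform_phantom
    rim = build_rim(lesion, width_voxels=2)
    # uniform lesion L over uniform background B: SAM = (L-B) * V_lesion
    assert sam(volume, lesion, rim) == pytest.approx(truth["SAM"])
    # flat field: zero
    flat = SUVolume(np.full_like(volume.values, 2.3), volume.spacing)
    assert sam(flat, lesion, rim) == pytest.approx(0.0, abs=1e-9)
    # multiplicative scaling
    scaled = SUVolume(volume.values * 3.0, volume.spacing)
    assert sam(scaled, lesion, rim) == pytest.approx(
        3.0 * sam(volume, lesion, rim)
    )


def test_sam_voxelwise_summation_oracle(rng):
    spacing = (4.3, 4.3, 5.0)
    values = rng.uniform(0.5, 9.0, size=(8, 8, 8))
    lesion = np.zeros((8, 8, 8), dtype=bool)
    lesion[3:5, 3:5, 3:5] = True
    volume = SUVolume(values, spacing)
    mask = RegionMask(lesion, spacing)
    rim = build_rim(mask, width_voxels=2)
    voxvol = volume.voxel_volume_ml
    ra = values[rim.values].sum() / rim.n_voxels
    expect = 0.0
    for v in np.ndindex(values.shape):
        if lesion[v] or rim.values[v]:
            expect += (values[v] - ra) * voxvol
    assert sam(volume, mask, rim) == pytest.approx(expect, rel=1e-12)


def test_sam_rejects_overlapping_masks(uniform_phantom):
    volume, lesion, _, _ = uniform_phantom
    with pytest.raises(ValueError, match="overlap"):
        sam(volume, lesion, lesion)


# --------------------------------------------------------------------------
# Full panel


def test_extract_all_invariants_on_random_phantoms(rng):
    for _ in range(200):
        shape = tuple(rng.integers(8, 14, size=3))
        spacing = tuple(rng.uniform(2.0, 5.0, size=3))
        values = rng.uniform(0.0, 12.0, size=shape)
        lesion = np.zeros(shape, dtype=bool)
        cx = tuple(rng.integers(2, s - 2) for s in shape)
        lesion[cx[0] - 1:cx[0] + 2, cx[1] - 1:cx[1] + 2,
               cx[2] - 1:cx[2] + 2] = rng.uniform(size=(3, 3, 3)) > 0.3
        if not lesion.any():
            lesion[cx] = True
        fv = extract_all(SUVolume(values, spacing), RegionMask(lesion, spacing))
        assert fv["Min"] <= fv["1st Quartile"] <= fv["Median"] \
            <= fv["3rd Quartile"] <= fv["Max"]
        assert fv["3rd Quartile"] <= fv["Upper Adjacent"] <= fv["Max"]
        assert fv["Min"] <= fv["Mean"] <= fv["Max"]
        assert fv["Peak"] <= fv["Max"] + 1e-12
        assert fv["RMS"] ** 2 == pytest.approx(
            fv["Mean"] ** 2 + fv["Std"] ** 2, rel=1e-9
        )
        q_dist = sum(fv[f"Q{k} Distribution"] for k in range(1, 5))
        assert q_dist == pytest.approx(100.0, abs=1e-9)
        q_glyc = sum(fv[f"Glycolysis Q{k}"] for k in range(1, 5))
        assert q_glyc == pytest.approx(fv["TLG"], rel=1e-9, abs=1e-12)


def test_extract_all_uniform_phantom_closed_forms(uniform_phantom):
    volume, lesion, _, truth = uniform_phantom
    fv = extract_all(volume, lesion)
    for key in ("Max", "Mean", "Min", "Median", "RMS", "MTV", "TLG",
                "RA", "SAM"):
        assert fv[key] == pytest.approx(truth[key], rel=1e-12), key
    assert fv["Std"] == 0.0
    assert set(fv.values) == set(FEATURE_NAMES)


def test_intensity_features_invariant_to_voxel_spacing():
    from petrim import PhantomSpec, make_phantom

    centers = dict(lesion_center_mm=(50.0, 50.0, 50.0),
                   liver_center_mm=(100.0, 100.0, 90.0))
    fine = PhantomSpec(shape=(64, 64, 64), spacing=(2.0, 2.0, 2.0), **centers)
    coarse = PhantomSpec(shape=(40, 40, 32), spacing=(3.4, 3.4, 4.2),
                         **centers)
    fv_f = extract_all(*make_phantom(fine)[:2])
    fv_c = extract_all(*make_phantom(coarse)[:2])
    for key in ("Mean", "Max", "Min"):
        assert fv_f[key] == pytest.approx(fv_c[key])
    # MTV agrees up to one voxel shell of discretization error
    r, spacing = 14.0, 3.4
    analytic = 4.0 / 3.0 * np.pi * r**3 / 1000.0
    shell = 4.0 * np.pi * r**2 * max(coarse.spacing) / 1000.0
    assert abs(fv_c["MTV"] - analytic) < shell
    assert abs(fv_f["MTV"] - analytic) < abs(fv_c["MTV"] - analytic) + 0.5
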