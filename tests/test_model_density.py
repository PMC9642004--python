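"""Density simulation, Wilson curves, amplitude scaling, difference maps."""

import numpy as np
import pytest

from emval.model_density import (
    atomic_number,
    detect_oversharpening,
    difference_map,
    local_scale,
    scale_amplitudes_global,
    shell_index,
    simulate_map,
    wilson_curve,
)
from emval.structure_map_io import Atom, AtomicModel, Chain, DensityMap, Residue
from emval.synthetic_fixtures import make_helix, make_test_pair


def _template(n=32, voxel=1.0, origin=(0.0, 0.0, 0.0)):
    return DensityMap(np.zeros((n, n, n), np.float32), (voxel, voxel, voxel), origin)


def _point_model(entries):
    """entries: list of (element, coord, b, occ)."""
    atoms = [Atom("X", el, c, b, occ) for el, c, b, occ in entries]
    residues = [Residue("UNK", i + 1, atoms=[a]) for i, a in enumerate(atoms)]
    return AtomicModel([Chain("A", residues)])


def sharpen(density_map, b):
    """Multiply Fourier amplitudes by exp(+b s^2 / 4)."""
    shape = density_map.shape
    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(shape, density_map.voxel_size)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij", sparse=True)
    s2 = fx**2 + fy**2 + fz**2
    f = np.fft.fftn(density_map.data) * np.exp(b * s2 / 4.0)
    return density_map.copy(data=np.real(np.fft.ifftn(f)).astype(np.float32))


# ---------------------------------------------------------------------------
# simulate_map
# ---------------------------------------------------------------------------


def test_single_atom_peak_and_isotropy():
    tpl = _template(32)
    model = _point_model([("C", (16.0, 16.0, 16.0), 0.0, 1.0)])
    result = simulate_map(model, tpl, 3.0)
    assert np.unravel_index(np.argmax(result.data), result.shape) == (16, 16, 16)
    centre = result.data[16, 16, 16]
    neighbours = [result.data[17, 16, 16], result.data[16, 17, 16], result.data[16, 16, 17]]
    assert np.ptp(neighbours) < 1e-6 * centre


def test_integral_matches_total_weight():
    tpl = _template(48, voxel=1.0)
    entries = [
        ("C", (20.0, 20.0, 20.0), 20.0, 1.0),
        ("N", (26.0, 20.0, 20.0), 30.0, 1.0),
        ("O", (20.0, 27.0, 20.0), 40.0, 0.8),
        ("S", (24.0, 24.0, 26.0), 25.0, 1.0),
        ("C", (28.0, 28.0, 28.0), 35.0, 0.5),
    ]
    model = _point_model(entries)
    result = simulate_map(model, tpl, 4.0)
    # oracle: each normalised Gaussian integrates to occupancy * Z exactly
    expected = sum(occ * atomic_number(el) for el, _, _, occ in entries)
    integral = result.data.sum() * np.prod(result.voxel_size)
    assert integral == pytest.approx(expected, rel=0.01)


def test_doubling_b_lowers_peaks():
    tpl = _template(32)
    coords = [(14.0, 16.0, 16.0), (20.0, 15.0, 17.0)]
    low = _point_model([("C", c, 20.0, 1.0) for c in coords])
    high = _point_model([("C", c, 40.0, 1.0) for c in coords])
    map_low = simulate_map(low, tpl, 3.0)
    map_high = simulate_map(high, tpl, 3.0)
    for c in coords:
        idx = tuple(int(round(x)) for x in c)
        assert map_high.data[idx] < map_low.data[idx]


def test_occupancy_linearity():
    tpl = _template(32)
    full = _point_model([("C", (16.0, 16.0, 16.0), 25.0, 1.0)])
    half = _point_model([("C", (16.0, 16.0, 16.0), 25.0, 0.5)])
    m_full = simulate_map(full, tpl, 3.0)
    m_half = simulate_map(half, tpl, 3.0)
    assert np.allclose(m_half.data, 0.5 * m_full.data, atol=1e-6 * m_full.data.max())


def test_atom_outside_grid_skipped(caplog):
    tpl = _template(32)
    model = _point_model(
        [("C", (16.0, 16.0, 16.0), 20.0, 1.0), ("C", (200.0, 0.0, 0.0), 20.0, 1.0)]
    )
    with caplog.at_level("WARNING"):
        result = simulate_map(model, tpl, 3.0)
    assert any("skipped" in r.message for r in caplog.records)
    assert result.data.max() > 0


def test_nyquist_precondition():
    tpl = _template(32, voxel=2.0)
    model = _point_model([("C", (16.0, 16.0, 16.0), 20.0, 1.0)])
    with pytest.raises(ValueError, match="Nyquist"):
        simulate_map(model, tpl, 3.0)


# ---------------------------------------------------------------------------
# Wilson curves
# ---------------------------------------------------------------------------


def test_wilson_flat_for_white_noise():
    from conftest import make_noise_map

    for seed in range(3):
        curve = wilson_curve(make_noise_map(seed), 16)
        inner = curve.log_mean_amplitude[1:-1]
        assert np.ptp(inner) < 0.2


def test_wilson_shell_sums_match_oracle(noise_map_64):
    n_shells = 12
    curve = wilson_curve(noise_map_64, n_shells)
    # oracle: direct sums over an independently computed frequency grid
    f = np.abs(np.fft.fftn(noise_map_64.data))
    freqs = [np.fft.fftfreq(n, d=v) for n, v in zip(noise_map_64.shape, noise_map_64.voxel_size)]
    fx, fy, fz = np.meshgrid(*freqs, indexing="ij")
    s = np.sqrt(fx**2 + fy**2 + fz**2)
    ds = 0.5 / n_shells
    for i, s2 in enumerate(curve.s2_centres):
        k = int(round((np.sqrt(s2) - ds / 2) / ds))
        sel = (s >= k * ds) & (s < (k + 1) * ds)
        assert curve.log_mean_amplitude[i] == pytest.approx(
            np.log(f[sel].mean()), rel=1e-6
        )
        assert curve.counts[i] == sel.sum()


def test_wilson_sharpening_slope(noise_map_64):
    b = 100.0
    sharpened = sharpen(noise_map_64, b)
    base = wilson_curve(noise_map_64, 16)
    curve = wilson_curve(sharpened, 16)
    # analytic: log-amplitude difference is exactly b * s^2 / 4
    delta = curve.log_mean_amplitude - base.log_mean_amplitude
    slope = np.polyfit(curve.s2_centres, delta, 1)[0]
    assert slope == pytest.approx(b / 4.0, rel=0.10)


def test_wilson_monotone_falloff_high_b():
    helix = make_helix(15, b_factor=80.0)
    coords = helix.coordinates(True)
    lo = coords.min(axis=0) - 6
    span = (coords.max(axis=0) + 6) - lo
    voxel = 1.5  # resolution exactly 2 x voxel: no cutoff inside Nyquist
    shape = tuple(max(int(np.ceil(s / voxel)) + 1, 16) for s in span)
    tpl = DensityMap(np.zeros(shape, np.float32), (voxel, voxel, voxel), tuple(lo))
    sim = simulate_map(helix, tpl, 3.0)
    curve = wilson_curve(sim, 12)
    high = curve.log_mean_amplitude[len(curve.log_mean_amplitude) // 2:]
    assert np.all(np.diff(high) < 0)


def test_wilson_zero_map_error():
    with pytest.raises(ValueError, match="undefined"):
        wilson_curve(_template(32), 8)


def test_oversharpening_detection():
    helix = make_helix(20)
    density, _ = make_test_pair(helix, 3.0, noise_sigma=0.0, seed=0)
    # rebuild at voxel = resolution / 2 so the curve is cutoff-free
    coords = helix.coordinates(True)
    lo = coords.min(axis=0) - 6
    span = (coords.max(axis=0) + 6) - lo
    shape = tuple(max(int(np.ceil(s / 1.5)) + 1, 24) for s in span)
    tpl = DensityMap(np.zeros(shape, np.float32), (1.5, 1.5, 1.5), tuple(lo))
    sim = simulate_map(helix, tpl, 3.0)

    curve0 = wilson_curve(sim, 20)
    flag0, slope0 = detect_oversharpening(curve0, 0.3)
    assert flag0 is False

    b = 150.0
    curve1 = wilson_curve(sharpen(sim, b), 20)
    flag1, slope1 = detect_oversharpening(curve1, 0.3)
    assert flag1 is True
    # analytic composition: applied slope is recovered as the difference
    assert slope1 - slope0 == pytest.approx(b / 4.0, rel=0.15)


def test_oversharpening_band_too_small():
    curve = wilson_curve(make_helix_map(), 8)
    with pytest.raises(ValueError, match=">= 4"):
        detect_oversharpening(curve, 0.2)


def make_helix_map():
    density, _ = make_test_pair(make_helix(8), 4.0, noise_sigma=0.0, seed=0)
    return density


# ---------------------------------------------------------------------------
# amplitude scaling and difference maps
# ---------------------------------------------------------------------------


def test_scale_identity(noise_map_64):
    result = scale_amplitudes_global(noise_map_64, noise_map_64, 16)
    rms = np.sqrt(np.mean(noise_map_64.data.astype(float) ** 2))
    assert np.sqrt(np.mean((result.data - noise_map_64.data) ** 2)) < 1e-6 * rms


def test_scale_matches_reference_shells(noise_map_64, helix30, helix30_map):
    reference = noise_map_64
    target = DensityMap(
        np.random.default_rng(3).normal(size=(64, 64, 64)).astype(np.float32) * 5.0,
        (1.0, 1.0, 1.0),
    )
    n_shells = 16
    result = scale_amplitudes_global(target, reference, n_shells)
    # oracle: independent shell sums
    idx, _, _ = shell_index(result.shape, result.voxel_size, n_shells)
    f_res = np.abs(np.fft.fftn(result.data)).ravel()
    f_ref = np.abs(np.fft.fftn(reference.data)).ravel()
    flat = idx.ravel()
    for shell in range(n_shells):
        sel = flat == shell
        assert f_res[sel].mean() == pytest.approx(f_ref[sel].mean(), rel=1e-3)


def test_scale_preserves_phase(noise_map_64):
    reference = DensityMap(
        np.random.default_rng(9).normal(size=(64, 64, 64)).astype(np.float32) * 3.0,
        (1.0, 1.0, 1.0),
    )
    result = scale_amplitudes_global(noise_map_64, reference, 16)
    f_in = np.fft.fftn(noise_map_64.data).ravel()
    f_out = np.fft.fftn(result.data).ravel()
    significant = np.abs(f_in) > 1e-3 * np.abs(f_in).max()
    phases_in = np.angle(f_in[significant])
    phases_out = np.angle(f_out[significant])
    # float32 storage round-trip bounds the phase agreement
    assert np.allclose(np.exp(1j * phases_in), np.exp(1j * phases_out), atol=1e-3)
    # correlation of phase unit vectors is 1
    corr = np.abs(np.mean(np.exp(1j * (phases_in - phases_out))))
    assert corr == pytest.approx(1.0, abs=1e-6)


def test_difference_map_self_consistency(helix30, helix30_map):
    sim = simulate_map(helix30, helix30_map, 3.0)
    fwd, rev = difference_map(helix30_map, sim, 16)
    rms_exp = np.sqrt(np.mean(helix30_map.data.astype(float) ** 2))
    assert np.sqrt(np.mean(fwd.data.astype(float) ** 2)) < 0.05 * rms_exp
    assert np.array_equal(rev.data, -fwd.data)  # antisymmetry of the pair


def test_difference_map_deleted_residue(helix30, helix30_map):
    from emval.synthetic_fixtures import PerturbationSpec, perturb

    truncated = perturb(helix30, PerturbationSpec("delete_segment", 15, 15, 1.0))
    sim = simulate_map(truncated, helix30_map, 3.0)
    fwd, _ = difference_map(helix30_map, sim, 16)
    deleted = [r for _, r in helix30.residues() if r.number == 15][0]
    coords = np.array([a.coord for a in deleted.heavy_atoms()])
    near = np.zeros(fwd.shape, bool)
    axes = [fwd.voxel_centres_axis(a) for a in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    for c in coords:
        near |= (gx - c[0]) ** 2 + (gy - c[1]) ** 2 + (gz - c[2]) ** 2 <= 4.0
    background_rms = np.sqrt(np.mean(fwd.data[~near].astype(float) ** 2))
    assert fwd.data[near].mean() > 3.0 * background_rms


def test_difference_map_grid_mismatch(noise_map_64):
    other = _template(32)
    with pytest.raises(ValueError, match="grid"):
        difference_map(noise_map_64, other, 8)


# ---------------------------------------------------------------------------
# local scaling
# ---------------------------------------------------------------------------


@pytest.fixture(scope="module")
def small_pair():
    helix = make_helix(8)
    density, _ = make_test_pair(helix, 4.0, noise_sigma=0.0, seed=0)
    sim = simulate_map(helix, density, 4.0)
    return density, sim


def test_local_scale_identity(small_pair):
    density, sim = small_pair
    result = local_scale(sim.copy(), sim, window=8.0)
    region = result.data != 0
    rms = np.sqrt(np.mean(sim.data[region].astype(float) ** 2))
    err = np.sqrt(np.mean((result.data[region] - sim.data[region]) ** 2))
    assert err < 0.02 * rms


def test_local_scale_deterministic(small_pair):
    density, sim = small_pair
    sharpened = sharpen(density, 40.0)
    a = local_scale(sharpened, sim, window=8.0)
    b = local_scale(sharpened, sim, window=8.0)
    assert np.array_equal(a.data, b.data)
    assert not np.array_equal(a.data, sharpened.data)


def test_local_scale_restores_b_contrast():
    # two separated atoms with very different B; experimental map globally
    # sharpened destroys the contrast, local scaling restores its direction
    tpl = _template(40, voxel=1.0)
    model = _point_model(
        [("C", (12.0, 20.0, 20.0), 20.0, 1.0), ("C", (28.0, 20.0, 20.0), 120.0, 1.0)]
    )
    reference = simulate_map(model, tpl, 3.0)
    experimental = sharpen(reference, 80.0)
    result = local_scale(experimental, reference, window=10.0)

    def local_slope(density_map, centre):
        lo = [c - 8 for c in centre]
        sub = density_map.data[lo[0]:lo[0] + 16, lo[1]:lo[1] + 16, lo[2]:lo[2] + 16]
        curve = wilson_curve(
            DensityMap(sub.copy(), density_map.voxel_size), 6
        )
        return np.polyfit(curve.s2_centres, curve.log_mean_amplitude, 1)[0]

    low_b, high_b = (12, 20, 20), (28, 20, 20)
    ref_contrast = local_slope(reference, low_b) - local_slope(reference, high_b)
    out_contrast = local_slope(result, low_b) - local_slope(result, high_b)
    assert ref_contrast > 0  # low-B site has shallower falloff
    assert out_contrast > 0  # contrast direction follows the reference
    # at each site the local slope moves from the sharpened value toward
    # the reference value
    for site in (low_b, high_b):
        ref_s = local_slope(reference, site)
        exp_s = local_slope(experimental, site)
        out_s = local_slope(result, site)
        assert abs(out_s - ref_s) < abs(exp_s - ref_s)


def test_local_scale_window_validation(small_pair):
    density, sim = small_pair
    with pytest.raises(ValueError, match=">= 5"):
        local_scale(density, sim, window=3.0)
    with pytest.raises(ValueError, match="exceeds"):
        local_scale(density, sim, window=200.0)
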