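"""Filter-bank construction, the periodized 2D DWT, and LL-only pooling."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st

from wranet import (
    WAVELET_NAMES,
    FilterBank,
    WaveletSpec,
    build_filter_bank,
    dwt2,
    idwt2,
    validate_bank,
    wavelet_downsample,
)
from wranet.wavelets import SubbandSet, UnsupportedWaveletError

ORTHOGONAL = [n for n in WAVELET_NAMES if n == "haar" or n[:2] in ("db", "sy")]
BIORTHOGONAL = [n for n in WAVELET_NAMES if n.startswith(("bior", "rbio"))]


# -- independent oracle ------------------------------------------------------

def naive_filter_decimate(x, filt):
    """Periodized filter + keep-even decimation, one axis, by explicit loops."""
    n = len(x)
    out = np.zeros(n // 2)
    for k in range(n // 2):
        for i, fi in enumerate(filt):
            out[k] += fi * x[(2 * k + i) % n]
    return out


def naive_dwt2(x, bank):
    """Rows first, then columns, with the plain double-loop oracle."""
    h, w = x.shape
    l, hp = bank.analysis_low, bank.analysis_high
    row_low = np.stack([naive_filter_decimate(row, l) for row in x])
    row_high = np.stack([naive_filter_decimate(row, hp) for row in x])
    ll = np.stack([naive_filter_decimate(col, l) for col in row_low.T]).T
    lh = np.stack([naive_filter_decimate(col, l) for col in row_high.T]).T
    hl = np.stack([naive_filter_decimate(col, hp) for col in row_low.T]).T
    hh = np.stack([naive_filter_decimate(col, hp) for col in row_high.T]).T
    return ll, lh, hl, hh


# -- filter-bank construction ------------------------------------------------

def test_registry_has_all_family_variants():
    assert len(WAVELET_NAMES) == 21
    assert WAVELET_NAMES[0] == "haar"
    assert {"db2", "db7", "sym2", "sym7", "bior1.1", "rbio4.4"} <= set(WAVELET_NAMES)


def test_haar_bank_is_the_normalized_two_tap_pair():
    bank = build_filter_bank("haar")
    s = 1.0 / np.sqrt(2.0)
    np.testing.assert_allclose(bank.analysis_low, [s, s])
    np.testing.assert_allclose(bank.analysis_high, [s, -s])
    assert max(validate_bank(bank).values()) == pytest.approx(0.0, abs=1e-15)


def test_db1_is_haar():
    db1 = build_filter_bank(WaveletSpec("db", 1))
    haar = build_filter_bank("haar")
    np.testing.assert_array_equal(db1.analysis_low, haar.analysis_low)
    np.testing.assert_array_equal(db1.analysis_high, haar.analysis_high)


def test_sym6_filter_length_and_inner_products_by_direct_loop():
    bank = build_filter_bank("sym6")
    l, h = bank.analysis_low, bank.analysis_high
    assert len(l) == 12
    sum_sq = sum(float(c) ** 2 for c in l)
    cross = sum(float(a) * float(b) for a, b in zip(l, h))
    assert abs(sum_sq - 1.0) < 1e-10
    assert abs(cross) < 1e-10


@pytest.mark.parametrize("name", WAVELET_NAMES)
def test_every_bank_satisfies_its_identities(name):
    """QMF recurrences, orthonormality and the dual delta identity, < 1e-8."""
    bank = build_filter_bank(name)
    report = validate_bank(bank)
    assert max(report.values()) < 1e-8, report
    spec = bank.spec
    if spec.is_orthogonal:
        assert len(bank.analysis_low) == 2 * spec.order


@pytest.mark.parametrize("name", ORTHOGONAL)
def test_derived_high_pass_matches_published_tables_up_to_convention(name):
    w = pywt.Wavelet(name)
    derived = build_filter_bank(name).analysis_high
    table = np.asarray(w.dec_hi)[::-1]
    assert min(np.abs(derived - table).max(), np.abs(derived + table).max()) < 1e-12


def test_corrupted_bank_reports_large_residual():
    bank = build_filter_bank("db3")
    bad_low = bank.analysis_low.copy()
    bad_low[2] += 1e-3
    corrupted = FilterBank(bad_low, bank.analysis_high, bank.synthesis_low,
                           bank.synthesis_high, bank.spec)
    assert max(validate_bank(corrupted).values()) > 1e-4


@pytest.mark.parametrize("bad", ["coif1", "db8", "sym0", "bior5.5", "nonsense"])
def test_unsupported_wavelets_are_rejected_with_the_valid_set(bad):
    with pytest.raises(UnsupportedWaveletError, match="unsupported wavelet"):
        build_filter_bank(bad)


def test_haar_order_other_than_one_rejected():
    with pytest.raises(UnsupportedWaveletError):
        WaveletSpec("haar", 2)


# -- dwt2 / idwt2 ------------------------------------------------------------

def test_haar_on_two_by_two_toy_image():
    sb = dwt2(np.array([[[1.0, 2.0], [3.0, 4.0]]]), build_filter_bank("haar"))
    np.testing.assert_allclose(sb.ll, [[[5.0]]], atol=1e-12)
    np.testing.assert_allclose(sb.lh, [[[-1.0]]], atol=1e-12)
    np.testing.assert_allclose(sb.hl, [[[-2.0]]], atol=1e-12)
    np.testing.assert_allclose(sb.hh, [[[0.0]]], atol=1e-12)


@pytest.mark.parametrize("name", ["haar", "sym4", "bior2.2"])
def test_constant_image_lands_entirely_in_ll(name):
    c = 0.37
    sb = dwt2(np.full((2, 6, 8), c), build_filter_bank(name))
    np.testing.assert_allclose(sb.ll, 2.0 * c, atol=1e-10)
    for band in (sb.lh, sb.hl, sb.hh):
        np.testing.assert_allclose(band, 0.0, atol=1e-10)


@pytest.mark.parametrize("name", WAVELET_NAMES)
def test_fast_transform_equals_naive_loop_oracle(name, rng):
    bank = build_filter_bank(name)
    x = rng.normal(size=(3, 8, 8))
    sb = dwt2(x, bank)
    for c in range(3):
        ll, lh, hl, hh = naive_dwt2(x[c], bank)
        np.testing.assert_allclose(sb.ll[c], ll, atol=1e-10)
        np.testing.assert_allclose(sb.lh[c], lh, atol=1e-10)
        np.testing.assert_allclose(sb.hl[c], hl, atol=1e-10)
        np.testing.assert_allclose(sb.hh[c], hh, atol=1e-10)


@pytest.mark.parametrize("name", WAVELET_NAMES)
def test_perfect_reconstruction(name, rng):
    bank = build_filter_bank(name)
    x = rng.normal(size=(2, 16, 16))
    rec = idwt2(dwt2(x, bank), bank)
    tol = 1e-10 if bank.spec.is_orthogonal else 1e-6
    assert np.abs(rec - x).max() < tol


@pytest.mark.parametrize("name", ORTHOGONAL)
def test_orthogonal_energy_conservation(name, rng):
    bank = build_filter_bank(name)
    x = rng.normal(size=(1, 16, 16))
    sb = dwt2(x, bank)
    energy = sum(np.sum(b ** 2) for b in (sb.ll, sb.lh, sb.hl, sb.hh))
    assert abs(energy - np.sum(x ** 2)) < 1e-8


def test_dwt2_linearity(rng):
    bank = build_filter_bank("db3")
    x, y = rng.normal(size=(2, 1, 8, 8))
    a, b = 1.7, -0.3
    combined = dwt2(a * x + b * y, bank)
    sx, sy = dwt2(x, bank), dwt2(y, bank)
    for band in ("ll", "lh", "hl", "hh"):
        np.testing.assert_allclose(
            getattr(combined, band),
            a * getattr(sx, band) + b * getattr(sy, band), atol=1e-10)


def test_all_zero_subbands_reconstruct_to_zero():
    z = np.zeros((1, 4, 4))
    rec = idwt2(SubbandSet(z, z, z, z), build_filter_bank("bior3.3"))
    np.testing.assert_array_equal(rec, np.zeros((1, 8, 8)))


def test_odd_sizes_and_nan_inputs_are_rejected():
    bank = build_filter_bank("haar")
    with pytest.raises(ValueError, match="even"):
        dwt2(np.zeros((3, 5, 8)), bank)
    with pytest.raises(ValueError, match="even"):
        wavelet_downsample(np.zeros((3, 8, 7)), bank)
    with pytest.raises(ValueError, match="non-finite"):
        dwt2(np.full((1, 4, 4), np.nan), bank)


def test_mismatched_subband_shapes_rejected():
    with pytest.raises(ValueError, match="differ"):
        SubbandSet(np.zeros((1, 2, 2)), np.zeros((1, 2, 2)),
                   np.zeros((1, 2, 2)), np.zeros((1, 2, 3)))


# -- LL-only pooling ---------------------------------------------------------

def test_downsample_halves_spatial_size_and_keeps_channels(rng):
    bank = build_filter_bank("sym6")
    out = wavelet_downsample(rng.normal(size=(64, 32, 32)), bank)
    assert out.shape == (64, 16, 16)


def test_downsample_equals_ll_subband(rng):
    bank = build_filter_bank("bior4.4")
    x = rng.normal(size=(3, 16, 16))
    np.testing.assert_allclose(wavelet_downsample(x, bank), dwt2(x, bank).ll,
                               atol=1e-12)


def test_haar_ll_is_blind_to_checkerboard_noise(rng):
    bank = build_filter_bank("haar")
    clean = rng.random((2, 16, 16))
    yy, xx = np.mgrid[0:16, 0:16]
    noisy = clean + 0.25 * (-1.0) ** (yy + xx)
    np.testing.assert_allclose(wavelet_downsample(noisy, bank),
                               wavelet_downsample(clean, bank), atol=1e-10)


@given(name=st.sampled_from(WAVELET_NAMES),
       half_h=st.integers(2, 8), half_w=st.integers(2, 8),
       seed=st.integers(0, 2 ** 16))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_property_reconstruction_at_any_even_size(name, half_h, half_w, seed):
    bank = build_filter_bank(name)
    x = np.random.default_rng(seed).normal(size=(2 * half_h, 2 * half_w))
    rec = idwt2(dwt2(x, bank), bank)
    assert np.abs(rec - x).max() < 1e-6


@given(name=st.sampled_from(WAVELET_NAMES), seed=st.integers(0, 2 ** 16),
       a=st.floats(-3, 3), b=st.floats(-3, 3))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_property_downsampling_is_linear(name, seed, a, b):
    bank = build_filter_bank(name)
    rng = np.random.default_rng(seed)
    x, y = rng.normal(size=(2, 12, 10))
    np.testing.assert_allclose(
        wavelet_downsample(a * x + b * y, bank),
        a * wavelet_downsample(x, bank) + b * wavelet_downsample(y, bank),
        atol=1e-9)


def test_constant_image_doubles_under_one_level():
    bank = build_filter_bank("haar")
    out = wavelet_downsample(np.full((1, 8, 8), 3.0), bank)
    np.testing.assert_allclose(out, 6.0, atol=1e-12)
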