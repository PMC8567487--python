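"""Mineralization density distribution: histogram, five parameters, comparisons."""

import math

import numpy as np
import pytest
from scipy import stats

from bonematrix.bmdd import (
    CaHistogram,
    bmdd_parameters,
    bmdd_zscores,
    compare_compartments,
    compute_histogram,
)
from bonematrix.errors import EmptyRegionError, MissingReferenceError, ShapeMismatchError
from bonematrix.zscore import ReferenceStat
from conftest import make_gl_image

FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # 2.3548...


def gaussian_histogram(mu, sigma, bin_width=0.02):
    """Exact discretized normal density as a CaHistogram (no sampling noise)."""
    centers = np.arange(mu - 6 * sigma, mu + 6 * sigma, bin_width)
    return CaHistogram.from_density(centers, stats.norm.pdf(centers, mu, sigma), bin_width)


class TestComputeHistogram:
    def test_uniform_image_single_bin(self, cal):
        img = np.full((64, 64), 155, dtype=np.uint8)
        hist = compute_histogram(img, cal)
        assert np.count_nonzero(hist.frequencies) == 1
        ca = cal.gl_to_ca(155)
        idx = np.argmax(hist.frequencies)
        assert hist.bin_edges[idx] <= ca < hist.bin_edges[idx + 1]
        assert hist.frequencies[idx] == pytest.approx(100.0)

    def test_two_equal_halves(self, cal):
        img = np.full((10, 10), 100, dtype=np.uint8)
        img[5:] = 200
        hist = compute_histogram(img, cal)
        nonzero = hist.frequencies[hist.frequencies > 0]
        assert list(nonzero) == [50.0, 50.0]

    def test_large_gaussian_field_mean(self, cal, rng):
        ca_true = rng.normal(22.2, 1.0, size=1_000_000)
        img = make_gl_image(cal, ca_true, shape=(1000, 1000))
        hist = compute_histogram(img, cal)
        direct_mean = cal.gl_to_ca(img[img >= 55].astype(float)).mean()
        res = bmdd_parameters(hist)
        # histogram mean agrees with the direct pixel mean to half a bin,
        # and with the generating mean to sampling+quantization error
        assert res.ca_mean == pytest.approx(direct_mean, abs=hist.bin_width / 2)
        assert res.ca_mean == pytest.approx(22.2, abs=0.01)

    def test_sub_threshold_pixels_excluded(self, cal):
        img = np.full((10, 10), 155, dtype=np.uint8)
        img[0] = 10  # marrow
        hist = compute_histogram(img, cal)
        assert hist.n_pixels == 90
        hist.validate()

    def test_mask_restricts_and_must_match_shape(self, cal):
        img = np.full((10, 10), 155, dtype=np.uint8)
        mask = np.zeros((10, 10), dtype=bool)
        mask[:2] = True
        assert compute_histogram(img, cal, mask).n_pixels == 20
        with pytest.raises(ShapeMismatchError):
            compute_histogram(img, cal, np.ones((5, 5), dtype=bool))

    def test_empty_region_raises(self, cal):
        with pytest.raises(EmptyRegionError):
            compute_histogram(np.zeros((8, 8), dtype=np.uint8), cal)


class TestParameters:
    def test_delta_distribution(self):
        hist = CaHistogram.from_samples(np.full(1000, 22.0), bin_width=0.17)
        res = bmdd_parameters(hist, smooth_window=1)
        center = hist.bin_centers[np.argmax(hist.frequencies)]
        assert res.ca_mean == pytest.approx(center)
        assert res.ca_peak == pytest.approx(center)
        assert res.ca_width == pytest.approx(hist.bin_width, abs=1e-9)
        assert res.ca_low == 0.0
        assert res.ca_high == 0.0

    @pytest.mark.parametrize("sigma", [0.8, 1.4226, 2.0596])
    def test_fwhm_matches_gaussian_closed_form(self, sigma):
        res = bmdd_parameters(gaussian_histogram(21.0, sigma))
        assert res.ca_width == pytest.approx(FWHM * sigma, abs=0.02)

    def test_fwhm_healthy_reference_width(self):
        # sigma chosen so the closed-form FWHM is the healthy trabecular 3.35
        res = bmdd_parameters(gaussian_histogram(22.2, 1.4226))
        assert res.ca_width == pytest.approx(3.35, abs=0.02)

    def test_ca_low_matches_normal_cdf_oracle(self, cal, rng):
        mu, width = 20.63, 4.85
        sigma = width / FWHM
        ca = rng.normal(mu, sigma, size=500_000)
        # unquantized samples: the low cut (17.68) sits on a bin edge, so the
        # bin-center rule makes CaLow exactly the CDF at the cut
        res_raw = bmdd_parameters(CaHistogram.from_samples(ca))
        assert res_raw.ca_low == pytest.approx(
            100.0 * stats.norm.cdf(17.68, mu, sigma), abs=0.2
        )
        # 8-bit image: the effective cut moves to the gray-level quantization
        # boundary below 17.68; the oracle accounts for that explicitly
        img = make_gl_image(cal, ca, shape=(-1,)).reshape(500, 1000)
        hist = compute_histogram(img, cal)
        res = bmdd_parameters(hist)
        gl = np.arange(256)
        centers = np.floor(cal.gl_to_ca(gl.astype(float)) / hist.bin_width) * hist.bin_width + hist.bin_width / 2
        last_low_gl = gl[centers < 17.68].max()
        boundary_ca = cal.gl_to_ca(last_low_gl + 0.5)
        assert res.ca_low == pytest.approx(
            100.0 * stats.norm.cdf(boundary_ca, mu, sigma), abs=0.2
        )
        assert res.ca_width == pytest.approx(width, rel=0.03)

    def test_mass_partition_is_exact(self, cal, rng):
        ca = rng.normal(21.0, 2.0, size=100_000)
        hist = CaHistogram.from_samples(ca)
        res = bmdd_parameters(hist)
        centers = hist.bin_centers
        between = hist.frequencies[(centers >= res.low_cut) & (centers <= res.high_cut)].sum()
        assert res.ca_low + res.ca_high + between == pytest.approx(100.0, abs=1e-9)
        hist.validate()

    def test_shift_equivariance(self, rng):
        ca = rng.normal(21.0, 2.0, size=50_000)
        bw = 0.17
        delta = 6 * bw  # a multiple of the bin width shifts bins exactly
        a = bmdd_parameters(CaHistogram.from_samples(ca, bw))
        b = bmdd_parameters(CaHistogram.from_samples(ca + delta, bw))
        assert b.ca_mean - a.ca_mean == pytest.approx(delta, abs=1e-9)
        assert b.ca_peak - a.ca_peak == pytest.approx(delta, abs=1e-9)
        assert b.ca_width == pytest.approx(a.ca_width, abs=1e-9)

    def test_width_monotone_in_generating_sigma(self):
        widths = [
            bmdd_parameters(gaussian_histogram(21.0, s)).ca_width
            for s in (0.6, 1.0, 1.5, 2.2)
        ]
        assert widths == sorted(widths)

    def test_tied_peak_flagged_and_lowest_ca_wins(self):
        edges = np.arange(20.0, 21.02, 0.17)
        freqs = np.zeros(len(edges) - 1)
        freqs[1] = freqs[3] = 50.0
        res = bmdd_parameters(CaHistogram(edges, freqs), smooth_window=1)
        assert res.peak_tied
        centers = (edges[:-1] + edges[1:]) / 2
        assert res.ca_peak == pytest.approx(centers[1])

    def test_all_zero_histogram_raises(self):
        edges = np.arange(20.0, 21.0, 0.17)
        with pytest.raises(EmptyRegionError):
            bmdd_parameters(CaHistogram(edges, np.zeros(len(edges) - 1)))


class TestComparisons:
    def test_compartment_percent_differences(self):
        diffs = compare_compartments(
            {"CaMean": 22.39, "CaHigh": 4.48},
            {"CaMean": 20.86, "CaHigh": 2.22},
        )
        assert diffs["CaMean"] == 7.3
        assert diffs["CaHigh"] == 101.8

    def test_identical_compartments_zero(self):
        vals = {"CaMean": 21.0, "CaPeak": 21.5, "CaWidth": 4.0, "CaLow": 5.0, "CaHigh": 3.0}
        assert all(v == 0.0 for v in compare_compartments(vals, vals).values())

    def test_zero_trabecular_flags_nan(self):
        diffs = compare_compartments({"CaHigh": 4.0}, {"CaHigh": 0.0})
        assert math.isnan(diffs["CaHigh"])

    def test_zscores_against_reference(self):
        ref = {
            "CaPeak": ReferenceStat("CaPeak", 22.94, 0.39),
            "CaWidth": ReferenceStat("CaWidth", 3.35, 0.34),
        }
        zs = bmdd_zscores({"CaPeak": 21.49, "CaWidth": 5.89}, ref)
        assert zs["CaPeak"].z2 == -3.72
        assert zs["CaWidth"].z2 == 7.47
        assert zs["CaWidth"].flagged

    def test_value_at_reference_mean_is_zero(self):
        ref = {"CaMean": ReferenceStat("CaMean", 22.2, 0.45)}
        row = bmdd_zscores({"CaMean": 22.2}, ref)["CaMean"]
        assert row.z2 == 0.0 and not row.flagged

    def test_missing_reference_row_raises(self):
        with pytest.raises(MissingReferenceError):
            bmdd_zscores({"CaMean": 22.0}, {})
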