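"""Synchronous-scan, EEM-peak and UV-Vis shift tests."""

import numpy as np
import pytest

from fluorbind import (
    EEMatrix,
    RangeError,
    SynchronousScan,
    ValidationError,
    compare_scans,
    eem_peak_table,
    synchronous_scan,
    uvvis_shift,
)
from fluorbind.synthetic import generate_absorbance, generate_eem

# Published free/bound peak summaries used as frozen expectations:
# synchronous scans at offsets 15 nm (tyrosine) and 60 nm (tryptophan),
# and windowed EEM peaks (Rayleigh line and intrinsic tryptophan peak).
SYNCHRO_TABLE = {
    15.0: dict(free=4303.0, bound=3910.0, free_pos=302.0, bound_pos=302.0,
               pct=-9.1, shift=0.0),
    60.0: dict(free=12166.0, bound=11430.0, free_pos=346.0, bound_pos=348.0,
               pct=-6.0, shift=2.0),
}

EEM_REGIONS = (((350.0, 370.0), (350.0, 370.0)),
               ((270.0, 290.0), (320.0, 370.0)))


def _gauss(x, mu, sigma):
    return np.exp(-((np.asarray(x, dtype=float) - mu) ** 2) / (2 * sigma**2))


def _scan_from_peak(delta, center_em, width, amplitude,
                    ex_lo=200.0, ex_hi=400.0):
    ex = np.arange(ex_lo, ex_hi + 1.0)
    return SynchronousScan(delta, ex, amplitude * _gauss(ex + delta,
                                                         center_em, width))


class TestSynchronousScan:
    def test_separable_eem_reduces_to_excitation_profile(self):
        """If intensity depends only on the excitation wavelength, the scan
        equals that profile for any offset."""
        ex = np.arange(240.0, 321.0, 5.0)
        em = np.arange(260.0, 441.0, 5.0)
        profile = 1e3 * _gauss(ex, 280.0, 10.0)
        eem = EEMatrix(ex, em, np.tile(profile[:, None], (1, em.size)))
        for delta in (15.0, 60.0):
            scan = synchronous_scan(eem, delta)
            np.testing.assert_allclose(
                scan.intensities,
                1e3 * _gauss(scan.excitation_wavelengths, 280.0, 10.0),
                rtol=1e-12,
            )

    @pytest.mark.parametrize(
        "delta,expected_max_ex",
        [
            # product of Gaussians G(x;280,10)*G(x+d;340,20) peaks at
            # x = (280/100 + (340-d)/400) / (1/100 + 1/400)
            (60.0, 280.0),
            (50.0, 282.0),
            (20.0, 288.0),
        ],
    )
    def test_product_gaussian_peak_position(self, delta, expected_max_ex):
        """Scan maximum matches the closed-form product-Gaussian maximum."""
        ex = np.arange(200.0, 401.0, 1.0)
        em = np.arange(200.0, 501.0, 1.0)
        grid = np.outer(_gauss(ex, 280.0, 10.0), _gauss(em, 340.0, 20.0))
        scan = synchronous_scan(EEMatrix(ex, em, grid), delta)
        peak_ex = scan.excitation_wavelengths[np.argmax(scan.intensities)]
        analytic = (280.0 / 100.0 + (340.0 - delta) / 400.0) / (
            1.0 / 100.0 + 1.0 / 400.0
        )
        assert analytic == pytest.approx(expected_max_ex)
        assert peak_ex == pytest.approx(expected_max_ex, abs=0.5)

    def test_scan_commutes_with_intensity_scaling(self):
        ex = np.arange(240.0, 321.0, 10.0)
        em = np.arange(260.0, 441.0, 10.0)
        grid = np.outer(_gauss(ex, 280.0, 15.0), _gauss(em, 340.0, 25.0))
        base = synchronous_scan(EEMatrix(ex, em, grid), 60.0)
        scaled = synchronous_scan(EEMatrix(ex, em, 7.5 * grid), 60.0)
        np.testing.assert_allclose(scaled.intensities, 7.5 * base.intensities,
                                   rtol=1e-12)

    def test_offset_beyond_emission_range_is_range_error(self):
        ex = np.arange(300.0, 401.0, 10.0)
        em = np.arange(310.0, 411.0, 10.0)
        eem = EEMatrix(ex, em, np.ones((ex.size, em.size)))
        with pytest.raises(RangeError):
            synchronous_scan(eem, 500.0)


class TestCompareScans:
    @pytest.mark.parametrize("delta", sorted(SYNCHRO_TABLE))
    def test_published_peak_summaries(self, delta):
        """Scans synthesized at the published peak intensities/positions
        reproduce the published percent changes and shifts."""
        row = SYNCHRO_TABLE[delta]
        free = _scan_from_peak(delta, row["free_pos"], 12.0, row["free"])
        bound = _scan_from_peak(delta, row["bound_pos"], 12.0, row["bound"])
        summary = compare_scans(free, bound, rounding=1)
        assert summary.free_intensity == pytest.approx(row["free"], rel=1e-6)
        assert summary.bound_intensity == pytest.approx(row["bound"], rel=1e-6)
        assert summary.percent_change == pytest.approx(row["pct"], abs=0.051)
        assert summary.shift == pytest.approx(row["shift"], abs=1e-9)
        # no hidden absolute value: a quenched peak gives a negative change
        assert summary.percent_change < 0

    def test_identical_scans_give_zero_change(self):
        scan = _scan_from_peak(60.0, 346.0, 12.0, 1e4)
        summary = compare_scans(scan, scan)
        assert summary.percent_change == 0.0
        assert summary.shift == 0.0

    def test_offset_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            compare_scans(_scan_from_peak(15.0, 302.0, 10.0, 1e3),
                          _scan_from_peak(60.0, 346.0, 10.0, 1e3))


class TestEEMPeakTable:
    # free-peak intensities and the bound-state multipliers taken from the
    # published 3D-fluorescence table (two complex ratios, two peaks)
    FREE_PEAKS = [(360.0, 360.0, 252756.0, (12.0, 12.0)),
                  (280.0, 340.0, 9080.0, (10.0, 15.0))]
    CASES = {
        "1:1": dict(factors=(235360.0 / 252756.0, 8393.0 / 9080.0),
                    shifts=(0.0, 0.0), pct=(-6.9, -7.6), shift=(0.0, 0.0)),
        "2:1": dict(factors=(220564.0 / 252756.0, 8293.0 / 9080.0),
                    shifts=(0.0, 10.0), pct=(-12.7, -8.7), shift=(0.0, 10.0)),
    }

    def _matrices(self, case):
        return generate_eem(
            self.FREE_PEAKS, case["factors"], case["shifts"],
            ex_grid=(200.0, 500.0, 10.0), em_grid=(200.0, 600.0, 10.0),
        )

    @pytest.mark.parametrize("name", sorted(CASES))
    def test_published_percent_changes_and_shifts(self, name):
        """EEMs synthesized at the published peak intensities reproduce all
        published percent changes and emission shifts at 1-decimal
        rounding."""
        case = self.CASES[name]
        free, bound = self._matrices(case)
        (rows,) = eem_peak_table(free, [bound], EEM_REGIONS, rounding=1)
        for row, pct, shift in zip(rows, case["pct"], case["shift"]):
            assert row.percent_change == pytest.approx(pct, abs=0.05)
            assert row.shift == pytest.approx(shift, abs=1e-9)

    def test_peak_positions_reported_as_ex_em_pairs(self):
        free, bound = self._matrices(self.CASES["2:1"])
        (rows,) = eem_peak_table(free, [bound], EEM_REGIONS)
        assert rows[0].free_position == (360.0, 360.0)
        assert rows[1].free_position == (280.0, 340.0)
        assert rows[1].bound_position == (280.0, 350.0)

    def test_identical_matrices_give_zero_everywhere(self):
        free, _ = self._matrices(self.CASES["1:1"])
        (rows,) = eem_peak_table(free, [free], EEM_REGIONS)
        for row in rows:
            assert row.percent_change == 0.0
            assert row.shift == 0.0

    def test_empty_region_error_names_the_region(self):
        free, bound = self._matrices(self.CASES["1:1"])
        with pytest.raises(RangeError, match="700"):
            eem_peak_table(free, [bound], [((700.0, 710.0), (700.0, 710.0))])


class TestUVVisShift:
    def _spectrum(self, center, label=""):
        return generate_absorbance([(center, 12.0, 1.0e4)], 5e-6, 1.0,
                                   (200.0, 400.0, 1.0), label=label)

    def test_published_blue_and_red_shifts(self):
        """Complex maximum at 269 nm: an 8-nm blue shift from the free
        protein (277 nm) and a 3-nm red shift from the free ligand (266)."""
        report = uvvis_shift(
            free_protein=self._spectrum(277.0),
            complex_minus_ligand=self._spectrum(269.0),
            free_ligand=self._spectrum(266.0),
            window=(240.0, 320.0),
        )
        assert report.complex_lambda_max == 269.0
        assert report.shift_vs_protein == -8.0
        assert report.shift_vs_ligand == 3.0

    def test_identical_spectra_give_zero_shift(self):
        spec = self._spectrum(300.0)
        report = uvvis_shift(spec, spec, spec, window=(250.0, 350.0))
        assert report.shift_vs_protein == 0.0
        assert report.shift_vs_ligand == 0.0
        assert report.complex_lambda_max == 300.0  # argmax of the band

    def test_window_outside_spectrum_rejected(self):
        spec = self._spectrum(300.0)
        with pytest.raises(RangeError):
            uvvis_shift(spec, spec, spec, window=(100.0, 150.0))
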