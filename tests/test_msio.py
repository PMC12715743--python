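"""mzML round-trip, EIC extraction, and chromatographic peak detection."""

import shutil
import subprocess

import numpy as np
import pytest

from dfiscreen.msio import (
    EIC,
    Spectrum,
    SpectrumRun,
    UnsupportedDataError,
    detect_peaks,
    extract_eic,
    read_run,
    write_run,
)


def _dda_fixture():
    spectra = [
        Spectrum(0, 1, 1.00, [100.0, 151.0395, 300.0], [1e5, 8e5, 5e4]),
        Spectrum(1, 2, 1.002, [91.0184, 136.0160, 137.0239], [3e4, 6e4, 8e4],
                 collision_energy=10.0, acquisition="ddMS2",
                 precursor_mz=151.0395, isolation_width=1.5),
        Spectrum(2, 2, 1.004, [91.0184, 95.0133], [5e4, 2e4],
                 collision_energy=20.0, acquisition="ddMS2",
                 precursor_mz=151.0395, isolation_width=1.5),
        Spectrum(3, 2, 1.006, [91.0184], [9e4],
                 collision_energy=40.0, acquisition="ddMS2",
                 precursor_mz=151.0395, isolation_width=1.5),
        Spectrum(4, 1, 1.02, [], []),
    ]
    return SpectrumRun(spectra, mode="DDA", ce_scheme=(10.0, 20.0, 40.0))


def _assert_runs_equal(a: SpectrumRun, b: SpectrumRun):
    assert len(a) == len(b)
    for sa, sb in zip(a.spectra, b.spectra):
        assert sa.ms_level == sb.ms_level
        assert sa.acquisition == sb.acquisition
        assert sa.rt == pytest.approx(sb.rt, abs=1e-6)
        assert sa.collision_energy == pytest.approx(sb.collision_energy, abs=0.01)
        np.testing.assert_allclose(sa.mz, sb.mz, atol=1e-4)
        if sa.intensity.size:
            np.testing.assert_allclose(sa.intensity, sb.intensity, rtol=1e-3)
        if sa.precursor_mz is not None:
            assert sb.precursor_mz == pytest.approx(sa.precursor_mz, abs=1e-4)
            assert sb.isolation_width == pytest.approx(sa.isolation_width, abs=1e-3)


class TestMzmlRoundTrip:
    def test_dda_roundtrip(self, tmp_path):
        run = _dda_fixture()
        path = tmp_path / "run.mzML"
        write_run(run, path)
        back = read_run(path)
        assert back.mode == "DDA"
        _assert_runs_equal(run, back)

    def test_dia_roundtrip(self, tmp_path):
        spectra = [Spectrum(0, 1, 0.5, [200.0], [2e5])]
        for j, ce in enumerate((10.0, 20.0, 40.0)):
            spectra.append(
                Spectrum(j + 1, 2, 0.5 + (j + 1) * 2e-3, [95.0133], [1e4],
                         collision_energy=ce, acquisition="AIF",
                         precursor_mz=537.5, isolation_width=925.0)
            )
        run = SpectrumRun(spectra, mode="DIA")
        path = tmp_path / "dia.mzML"
        write_run(run, path)
        back = read_run(path)
        assert back.mode == "DIA"
        assert back.ce_scheme == (10.0, 20.0, 40.0)
        _assert_runs_equal(run, back)

    def test_empty_run_roundtrip(self, tmp_path):
        path = tmp_path / "empty.mzML"
        write_run(SpectrumRun([], mode="full_only"), path)
        assert len(read_run(path)) == 0

    def test_empty_file_is_parse_error(self, tmp_path):
        path = tmp_path / "broken.mzML"
        path.write_text("")
        with pytest.raises(Exception):
            read_run(path)

    def test_profile_data_rejected(self, tmp_path):
        run = _dda_fixture()
        path = tmp_path / "profile.mzML"
        write_run(run, path)
        text = path.read_text().replace(
            'accession="MS:1000127" name="centroid spectrum"',
            'accession="MS:1000128" name="profile spectrum"',
        )
        path.write_text(text)
        with pytest.raises(UnsupportedDataError, match="profile"):
            read_run(path)

    def test_isolation_width_preserved(self, tmp_path):
        path = tmp_path / "run.mzML"
        write_run(_dda_fixture(), path)
        back = read_run(path)
        assert back.spectra[1].isolation_width == pytest.approx(1.5, abs=1e-6)

    def test_mzr_reads_written_file(self, tmp_path):
        """Independent oracle: Bioconductor mzR must parse our mzML and
        report identical scan structure."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript unavailable; cannot run the mzR oracle")
        path = tmp_path / "oracle.mzML"
        write_run(_dda_fixture(), path)
        script = (
            'suppressMessages(library(mzR));'
            f'f <- openMSfile("{path}"); h <- header(f);'
            'cat(nrow(h), sum(h$msLevel==2), round(h$retentionTime[1], 3),'
            '    h$peaksCount[1], round(peaks(f, 2)[1, 1], 4), sep="\\n")'
        )
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
        )
        assert out.returncode == 0, out.stderr
        n, n_ms2, rt_sec, npeaks, first_mz = out.stdout.strip().splitlines()
        assert int(n) == 5
        assert int(n_ms2) == 3
        assert float(rt_sec) == pytest.approx(60.0, abs=0.01)  # 1.00 min
        assert int(npeaks) == 3
        assert float(first_mz) == pytest.approx(91.0184, abs=1e-4)


class TestSpectrumInvariants:
    def test_peaks_sorted_on_construction(self):
        s = Spectrum(0, 1, 0.0, [300.0, 100.0], [1.0, 2.0])
        assert list(s.mz) == [100.0, 300.0]
        assert list(s.intensity) == [2.0, 1.0]

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(0, 1, 0.0, [100.0], [-1.0])

    def test_ms2_requires_acquisition_tag(self):
        with pytest.raises(ValueError):
            Spectrum(0, 2, 0.0, [100.0], [1.0], acquisition="full")


class TestExtractEic:
    def test_matches_naive_per_scan_oracle(self):
        rng = np.random.default_rng(7)
        spectra = []
        for i in range(40):
            mz = np.sort(rng.uniform(80, 1000, 50))
            inten = rng.exponential(1e4, 50)
            spectra.append(Spectrum(i, 1, i * 0.02, mz, inten))
        run = SpectrumRun(spectra)
        target, tol = 500.0, 5000.0  # wide window to guarantee matches
        eic = extract_eic(run, target, tol)
        half = target * tol * 1e-6
        for k, s in enumerate(spectra):
            expected = s.intensity[(s.mz >= target - half) & (s.mz <= target + half)].sum()
            assert eic.intensity[k] == pytest.approx(expected, rel=1e-12)

    def test_absent_target_gives_zero_trace(self):
        run = SpectrumRun([Spectrum(0, 1, 0.0, [100.0], [1e5])])
        eic = extract_eic(run, 600.0, 10.0)
        assert np.all(eic.intensity == 0)

    def test_tolerance_windowing(self):
        # peak offset by 5 ppm: seen at 10 ppm, invisible at 1 ppm
        mz = 151.0395 * (1 + 5e-6)
        run = SpectrumRun([Spectrum(0, 1, 0.0, [mz], [1e5])])
        assert extract_eic(run, 151.0395, 10.0).intensity[0] > 0
        assert extract_eic(run, 151.0395, 1.0).intensity[0] == 0

    def test_nonpositive_tolerance_rejected(self):
        run = SpectrumRun([Spectrum(0, 1, 0.0, [100.0], [1.0])])
        with pytest.raises(ValueError):
            extract_eic(run, 100.0, 0.0)


def _gaussian_trace(rt, apex_rt, height, sigma=0.064):
    return height * np.exp(-0.5 * ((rt - apex_rt) / sigma) ** 2)


class TestDetectPeaks:
    def test_single_peak_high_snr(self):
        rt = np.arange(0, 4, 0.02)
        rng = np.random.default_rng(1)
        y = _gaussian_trace(rt, 2.0, 1e6) + rng.normal(1e3, 200, rt.size).clip(0)
        peaks = detect_peaks(EIC(100.0, 10.0, rt, y), min_snr=3.0)
        assert len(peaks) == 1
        assert peaks[0].rt == pytest.approx(2.0, abs=0.02)
        assert peaks[0].snr > 3
        assert peaks[0].rt_start <= peaks[0].rt <= peaks[0].rt_end
        assert peaks[0].height <= y.max()

    def test_flat_zero_trace(self):
        rt = np.arange(0, 1, 0.02)
        assert detect_peaks(EIC(100.0, 10.0, rt, np.zeros_like(rt))) == []

    def test_two_resolved_peaks(self):
        rt = np.arange(0, 6, 0.02)
        y = _gaussian_trace(rt, 2.0, 8e5) + _gaussian_trace(rt, 4.0, 5e5)
        peaks = detect_peaks(EIC(100.0, 10.0, rt, y))
        assert len(peaks) == 2
        apexes = sorted(p.rt for p in peaks)
        assert apexes[0] == pytest.approx(2.0, abs=0.03)
        assert apexes[1] == pytest.approx(4.0, abs=0.03)

    def test_recovery_rate_on_seeded_simulations(self):
        """>=95% of injected peaks with height >= 10x noise are recovered."""
        rng = np.random.default_rng(99)
        rt = np.arange(0, 6, 0.02)
        found = 0
        n_sim = 100
        for _ in range(n_sim):
            apex_rt = rng.uniform(1.0, 5.0)
            noise = rng.uniform(500, 5000)
            height = noise * rng.uniform(10, 100)
            y = _gaussian_trace(rt, apex_rt, height)
            y = y + rng.normal(0, noise, rt.size)
            y = np.clip(y, 0, None)
            peaks = detect_peaks(EIC(100.0, 10.0, rt, y), min_snr=3.0)
            if any(abs(p.rt - apex_rt) < 0.1 for p in peaks):
                found += 1
        assert found >= 0.95 * n_sim

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_peaks(EIC(100.0, 10.0, np.array([]), np.array([])))
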