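"""LC-MS quantification path: calibration, extraction, summation,
normalization — plus the UPLC normalization path."""

import warnings

import numpy as np
import pandas as pd
import pytest

import igglycome as ig
from igglycome import quantify
from igglycome.quantify import (CalibrationError, SpectrumPeakList,
                                calibrate_spectrum, collision_report,
                                extract_glycopeptide_signals, normalize_subclass,
                                normalize_uplc, sum_isotopologues)


@pytest.fixture(scope="module")
def clean_spectra(small_cohort):
    """Noise-free, drift-free spectra for three samples."""
    return ig.render_spectra(small_cohort, drift_ppm=0.0, n_noise_peaks=0,
                             samples=small_cohort.samples[:3])


class TestCalibration:
    def test_removes_injected_drift(self, small_cohort):
        spectra = ig.render_spectra(small_cohort, drift_ppm=30.0,
                                    samples=small_cohort.samples[:3])
        for (sample, subclass), spec in spectra.items():
            cal = calibrate_spectrum(spec)
            # gain must undo the 30 ppm stretch
            assert cal.a == pytest.approx(1.0 / (1.0 + 30e-6), rel=3e-6)
            assert cal.median_abs_residual_ppm < 2.0

    def test_identity_when_no_drift(self, clean_spectra, small_cohort):
        spec = clean_spectra[(small_cohort.samples[0], "IgG1")]
        cal = calibrate_spectrum(spec)
        assert cal.a == pytest.approx(1.0, abs=1e-9)
        assert abs(cal.b) < 1e-5
        # idempotence: calibrating a calibrated spectrum is a no-op
        cal2 = calibrate_spectrum(cal.apply(spec))
        assert cal2.a == pytest.approx(1.0, abs=1e-9)
        assert abs(cal2.b) < 1e-5

    def test_pure_noise_fails_naming_sample(self, rng):
        spec = SpectrumPeakList("noisy", "IgG1",
                                rng.uniform(600, 1800, 300),
                                rng.exponential(1.0, 300))
        with pytest.raises(CalibrationError, match="noisy"):
            calibrate_spectrum(spec)

    def test_k_min_enforced(self, clean_spectra, small_cohort):
        spec = clean_spectra[(small_cohort.samples[0], "IgG1")]
        with pytest.raises(CalibrationError):
            calibrate_spectrum(spec, k_min=13)  # only 12 candidates exist


class TestExtraction:
    def test_round_trip_noise_free(self, clean_spectra, small_cohort):
        """Extraction recovers exactly the rendered per-species signal."""
        for subclass in ("IgG1", "IgG2", "IgG4"):
            sample = small_cohort.samples[0]
            spec = clean_spectra[(sample, subclass)]
            extracted = extract_glycopeptide_signals(spec, warn_collisions=False)
            raw = sum_isotopologues(extracted)
            share = raw / raw.sum() * 100.0
            truth = small_cohort.compositions[subclass].loc[sample]
            assert np.max(np.abs(share - truth[share.index])) < 1e-9

    def test_boundary_is_half_open(self):
        entry = ig.default_panel()[0]
        gp = ig.Glycopeptide.from_subclass("IgG1", entry.glycan, entry.label)
        center = ig.glycopeptide_mz(gp, 2, 0)
        tol = center * 10e-6
        spec_inside = SpectrumPeakList("s", "IgG1", [center - tol], [5.0])
        spec_outside = SpectrumPeakList("s", "IgG1", [center + tol], [5.0])
        inside = extract_glycopeptide_signals(spec_inside, warn_collisions=False)
        outside = extract_glycopeptide_signals(spec_outside, warn_collisions=False)
        assert inside.loc[entry.label, (2, 0)] == 5.0
        assert outside.loc[entry.label, (2, 0)] == 0.0

    def test_no_collisions_at_default_tolerance(self):
        for subclass in ("IgG1", "IgG2", "IgG4"):
            assert len(collision_report(subclass=subclass, tol_ppm=10.0)) == 0

    def test_collisions_flagged_at_wide_tolerance(self):
        rep = collision_report(subclass="IgG1", tol_ppm=5000.0)
        assert len(rep) > 0
        spec = SpectrumPeakList("s", "IgG1", [1000.0], [1.0])
        with pytest.warns(UserWarning, match="overlapping extraction windows"):
            extract_glycopeptide_signals(spec, tol_ppm=5000.0)


class TestSummation:
    def test_eight_cells_sum(self):
        cols = pd.MultiIndex.from_product([(2, 3), range(4)],
                                          names=["charge", "offset"])
        tab = pd.DataFrame(1.0, index=["G0F"], columns=cols)
        assert sum_isotopologues(tab).loc["G0F"] == 8.0
        tab.loc["G0F", 3] = 0.0
        assert sum_isotopologues(tab).loc["G0F"] == 4.0


class TestNormalization:
    def test_simple_shares(self):
        tab = pd.DataFrame({"a": [1.0], "b": [1.0], "c": [2.0]})
        out = normalize_subclass(tab)
        assert out.iloc[0].tolist() == [25.0, 25.0, 50.0]

    def test_scale_invariance(self, rng):
        tab = pd.DataFrame(rng.uniform(0.1, 5.0, (4, 6)))
        assert np.allclose(normalize_subclass(tab), normalize_subclass(tab * 7.0))

    def test_rows_sum_to_100(self, rng):
        tab = pd.DataFrame(rng.uniform(0, 3.0, (5, 8)))
        out = normalize_subclass(tab)
        assert np.allclose(out.sum(axis=1), 100.0, atol=1e-9)

    def test_all_zero_subclass_is_missing(self):
        cols = pd.MultiIndex.from_product([("IgG1", "IgG2"), ("x", "y")])
        tab = pd.DataFrame([[1.0, 3.0, 0.0, 0.0]], columns=cols)
        out = normalize_subclass(tab)
        assert out[("IgG1", "x")].iloc[0] == 25.0
        assert out["IgG2"].isna().all().all()

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            normalize_subclass(pd.DataFrame({"a": [-1.0], "b": [1.0]}))


class TestUplcNormalization:
    def test_uniform_areas(self):
        labels = ig.default_uplc_schema().labels
        tab = pd.DataFrame([[3.0] * 24], columns=labels)
        out = normalize_uplc(tab)
        assert np.allclose(out.iloc[0], 100.0 / 24.0)

    def test_single_nonzero_peak(self):
        labels = ig.default_uplc_schema().labels
        tab = pd.DataFrame([[0.0] * 24], columns=labels)
        tab["GP4"] = 7.0
        out = normalize_uplc(tab)
        assert out["GP4"].iloc[0] == 100.0

    def test_wrong_column_count_rejected(self):
        tab = pd.DataFrame([[1.0, 2.0]], columns=["GP1", "GP2"])
        with pytest.raises(ValueError, match="schema"):
            normalize_uplc(tab)

    def test_round_trip_zero_noise(self, small_cohort):
        from igglycome.simulate import true_uplc_composition
        areas = ig.simulate_uplc_table(small_cohort, noise_cv=0.0)
        out = normalize_uplc(areas)
        truth = true_uplc_composition(small_cohort)
        assert np.max(np.abs(out.to_numpy() - truth.to_numpy())) < 1e-9


class TestFullTable:
    def test_twenty_glycoforms_per_subclass(self, small_cohort):
        spectra = ig.render_spectra(small_cohort, n_noise_peaks=50,
                                    samples=small_cohort.samples[:2])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table, qc = ig.quantify_fc_spectra(spectra.values())
        for subclass in ("IgG1", "IgG2", "IgG4"):
            assert table[subclass].shape[1] == 20
            assert np.allclose(table[subclass].sum(axis=1), 100.0, atol=1e-9)
        assert (qc["status"] == "ok").all()

    def test_calibration_failure_flagged_not_silent(self, rng):
        noise = SpectrumPeakList("bad", "IgG1",
                                 rng.uniform(600, 1800, 200),
                                 rng.exponential(1.0, 200))
        table, qc = ig.quantify_fc_spectra([noise])
        assert len(table) == 0
        assert qc["status"].str.startswith("calibration_failed").all()

    def test_truncation_loss_visible_with_full_envelope(self, small_cohort):
        """Rendering absolute envelope fractions and summing only the
        first four isotopologues distorts the composition measurably
        (the loss is species-dependent), unlike the default rendering."""
        sample = small_cohort.samples[0]
        spectra = ig.render_spectra(small_cohort, n_noise_peaks=0,
                                    samples=[sample], full_envelope=True)
        spec = spectra[(sample, "IgG1")]
        raw = sum_isotopologues(
            extract_glycopeptide_signals(spec, warn_collisions=False))
        share = raw / raw.sum() * 100.0
        truth = small_cohort.compositions["IgG1"].loc[sample]
        err = np.max(np.abs(share - truth[share.index]))
        assert 0.01 < err < 1.0
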