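"""Generator correctness: phenotype structure, fingerprints, spectra."""

import numpy as np
import pandas as pd
import pytest

from hepamark import synthetic as syn


class TestPhenotypes:
    def test_paper_scale_design(self):
        ph = syn.generate_phenotypes(seed=0)
        assert len(ph) == 64
        assert sorted(ph["day"].unique()) == [6, 8, 10, 12]
        assert ph["sample_id"].is_unique
        assert (ph.groupby("day").size() >= 2).all()
        assert ph["LW"].between(302.3, 914.9).all()
        assert ph["TY"].between(54.8, 99.5).all()

    def test_day_increasing_liver_weight(self):
        ph = syn.generate_phenotypes(n_per_day=200, seed=3)
        means = ph.groupby("day")["LW"].mean()
        assert means.is_monotonic_increasing

    def test_zero_target_correlation_gives_independence(self):
        ph = syn.generate_phenotypes(n_per_day=200, seed=5, target_corr=0.0)
        r = np.corrcoef(ph["LW"], ph["TY"])[0, 1]
        assert abs(r) < 0.12

    def test_large_sample_correlation_hits_target(self):
        # Monte-Carlo check against the sample-correlation oracle.
        ph = syn.generate_phenotypes(n_per_day=200, seed=1, target_corr=-0.80)
        r = np.corrcoef(ph["LW"], ph["TY"])[0, 1]
        assert -0.86 <= r <= -0.74

    def test_determinism(self):
        a = syn.generate_phenotypes(seed=11)
        b = syn.generate_phenotypes(seed=11)
        pd.testing.assert_frame_equal(a, b)
        c = syn.generate_phenotypes(seed=12)
        assert not a["LW"].equals(c["LW"])

    def test_calibration_across_replicate_studies(self):
        rs = [
            np.corrcoef(*(syn.generate_phenotypes(seed=s)[["LW", "TY"]].to_numpy().T))[0, 1]
            for s in range(50)
        ]
        assert abs(np.mean(rs) - (-0.80)) < 0.05

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            syn.generate_phenotypes(n_per_day=1)
        with pytest.raises(ValueError):
            syn.generate_phenotypes(target_corr=-1.0)


class TestPackagedFingerprints:
    def test_lactate_peaks(self, library):
        peaks = library.peaks_for("Lactate")
        assert len(peaks) == 2
        kinds = {(p.multiplicity, p.shift_lo, p.shift_hi) for p in peaks}
        assert ("doublet", 1.31, 1.32) in kinds
        assert ("quartet", 4.08, 4.12) in kinds

    def test_allantoin_is_one_singlet(self, library):
        peaks = library.peaks_for("Allantoin")
        assert len(peaks) == 1
        assert peaks[0].multiplicity == "singlet"
        assert peaks[0].shift_lo == peaks[0].shift_hi == 5.38

    def test_unknown_metabolite_returns_empty(self, library):
        assert library.peaks_for("unobtainium") == []

    def test_library_composition(self, library):
        assert len(library.decoys) >= 5
        assert len(library.non_decoys) >= 20
        for p in library.peaks:
            assert p.shift_lo <= p.shift_hi
            assert p.n_protons >= 1
        assert all(library.provenance[m] == "packaged" for m in library.metabolites)

    def test_decoys_occupy_empty_regions(self, library):
        # No decoy peak range intersects any real-metabolite peak range.
        real = [p for p in library.peaks if p.metabolite not in library.decoy_names]
        for d in library.peaks:
            if d.metabolite not in library.decoy_names:
                continue
            for r in real:
                assert d.shift_hi < r.shift_lo or d.shift_lo > r.shift_hi

    def test_tsv_round_trip(self, library, tmp_path):
        path = tmp_path / "lib.tsv"
        library.to_tsv(path)
        back = syn.FingerprintLibrary.from_tsv(path)
        assert back.metabolites == library.metabolites
        assert back.decoy_names == library.decoy_names
        assert len(back.peaks) == len(library.peaks)


class TestConcentrations:
    def test_null_effects_are_independent_of_traits(self, library):
        ph = syn.generate_phenotypes(n_per_day=100, seed=2)
        conc = syn.simulate_concentrations(ph, {}, metabolites=["Lactate"], seed=2)
        r = np.corrcoef(conc["Lactate"], ph["LW"])[0, 1]
        assert abs(r) < 0.15

    def test_strong_positive_effect(self, library):
        ph = syn.generate_phenotypes(seed=4)
        conc = syn.simulate_concentrations(
            ph, {"Lactate": ("LW", +1, 0.6)}, metabolites=["Lactate"],
            cv_noise=0.02, seed=4,
        )
        assert np.corrcoef(conc["Lactate"], ph["LW"])[0, 1] > 0.9

    def test_negative_effect_sign(self, library):
        # Glucose falls as liver weight rises (sign emulated, not magnitude).
        ph = syn.generate_phenotypes(seed=4)
        conc = syn.simulate_concentrations(
            ph, {"Glucose": ("LW", -1, 0.4)}, metabolites=["Glucose"], seed=4
        )
        assert np.corrcoef(conc["Glucose"], ph["LW"])[0, 1] < -0.5

    def test_unknown_trait_rejected(self, library):
        ph = syn.generate_phenotypes(seed=4)
        with pytest.raises(KeyError):
            syn.simulate_concentrations(
                ph, {"Lactate": ("BMI", 1, 0.4)}, metabolites=["Lactate"], seed=0
            )

    def test_nonnegative_and_deterministic(self, library):
        ph = syn.generate_phenotypes(seed=9)
        kw = dict(metabolites=library.non_decoys, seed=9)
        a = syn.simulate_concentrations(ph, syn.default_effects(), **kw)
        b = syn.simulate_concentrations(ph, syn.default_effects(), **kw)
        assert (a.to_numpy() >= 0).all()
        pd.testing.assert_frame_equal(a, b)


class TestRenderSpectrum:
    def test_singlet_area_matches_analytic_lorentzian_integral(self, tiny_library):
        # Unit-area Lorentzian line shape: integrated spectrum area must
        # equal concentration * n_protons to within 1%.
        s = syn.render_spectrum(
            {"metA": 1.7}, tiny_library, shift_jitter_sd=0.0, noise_sd=0.0
        )
        area = np.trapezoid(s.intensity, s.ppm)
        assert area == pytest.approx(1.7 * 3, rel=0.01)

    def test_zero_concentrations_flat_spectrum(self, tiny_library):
        s = syn.render_spectrum(
            {"metA": 0.0, "metB": 0.0}, tiny_library, shift_jitter_sd=0.0, noise_sd=0.0
        )
        assert np.all(s.intensity == 0.0)

    def test_doubling_concentration_doubles_peak_integral(self, tiny_library):
        kw = dict(shift_jitter_sd=0.0, noise_sd=0.0)
        s1 = syn.render_spectrum({"metA": 1.0}, tiny_library, **kw)
        s2 = syn.render_spectrum({"metA": 2.0}, tiny_library, **kw)
        window = (s1.ppm > 1.9) & (s1.ppm < 2.1)
        a1 = np.trapezoid(s1.intensity[window], s1.ppm[window])
        a2 = np.trapezoid(s2.intensity[window], s2.ppm[window])
        assert a2 == pytest.approx(2 * a1, rel=1e-9)

    def test_mixture_linearity(self, tiny_library):
        kw = dict(shift_jitter_sd=0.002, noise_sd=0.0, seed=13)
        mix = syn.render_spectrum({"metA": 1.0, "metB": 0.5}, tiny_library, **kw)
        sa = syn.render_spectrum({"metA": 1.0}, tiny_library, **kw)
        sb = syn.render_spectrum({"metB": 0.5}, tiny_library, **kw)
        np.testing.assert_allclose(mix.intensity, sa.intensity + sb.intensity, atol=1e-12)

    def test_multiplet_weights_and_width(self, tiny_library):
        # metB doublet: two sub-lines split by ~0.0117 ppm, equal heights.
        s = syn.render_spectrum({"metB": 1.0}, tiny_library, shift_jitter_sd=0, noise_sd=0)
        window = (s.ppm > 7.0) & (s.ppm < 7.12)
        x, v = s.ppm[window], s.intensity[window]
        # two local maxima of equal height
        peaks = [i for i in range(1, len(v) - 1) if v[i] > v[i - 1] and v[i] >= v[i + 1]]
        assert len(peaks) == 2
        assert v[peaks[0]] == pytest.approx(v[peaks[1]], rel=0.05)
        assert x[peaks[1]] - x[peaks[0]] == pytest.approx(7.0 / 600.0, abs=0.002)

    def test_grid_coarser_than_linewidth_refused(self, tiny_library):
        with pytest.raises(ValueError, match="coarser"):
            syn.render_spectrum({"metA": 1.0}, tiny_library, grid_step=0.01, linewidth=0.002)

    def test_render_determinism(self, tiny_library):
        kw = dict(shift_jitter_sd=0.002, noise_sd=0.3, seed=21, sample_id="s1")
        a = syn.render_spectrum({"metA": 1.0}, tiny_library, **kw)
        b = syn.render_spectrum({"metA": 1.0}, tiny_library, **kw)
        assert np.array_equal(a.intensity, b.intensity)


def test_spectra_csv_round_trip(tiny_library, tmp_path):
    conc = pd.DataFrame({"metA": [1.0, 2.0]}, index=["s1", "s2"])
    spectra = syn.render_study(conc, tiny_library, seed=3, noise_sd=0.1)
    path = tmp_path / "spectra.csv"
    syn.spectra_to_csv(spectra, path)
    back = syn.spectra_from_csv(path)
    assert [s.sample_id for s in back] == ["s1", "s2"]
    np.testing.assert_allclose(back[0].intensity, spectra[0].intensity, rtol=1e-12)
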