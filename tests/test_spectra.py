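import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from specfdr import (
    Peak,
    SpectralLibrary,
    Spectrum,
    SpectrumParseError,
    merge_collision_energies,
    passes_library_filters,
    read_massbank,
    read_mgf,
    write_massbank,
    write_mgf,
)
from specfdr.spectra import PROTON_MASS, mass_tolerance_da

MINIMAL_RECORD = """\
ACCESSION: TST001
CH$NAME: testol
CH$EXACT_MASS: 180.063388
AC$MASS_SPECTROMETRY: ION_MODE POSITIVE
MS$FOCUSED_ION: PRECURSOR_M/Z 181.070665
PK$NUM_PEAK: 3
PK$PEAK: m/z int. rel.int.
  163.060100 80.0 999
  145.049535 40.0 500
  85.028406 100.0 700
//
"""


class TestSpectrumModel:
    def test_peaks_sorted_and_deduplicated(self):
        s = Spectrum(
            "s", 200.0,
            peaks=(Peak(150.0, 5.0), Peak(100.0, 2.0), Peak(150.0, 9.0)),
        )
        assert s.masses == (100.0, 150.0)
        assert s.intensities == (2.0, 9.0)  # duplicate kept max intensity

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            Peak(-1.0, 1.0)
        with pytest.raises(ValueError):
            Peak(100.0, -0.5)
        with pytest.raises(ValueError):
            Spectrum("s", -5.0)

    def test_library_requires_unique_identifiers(self):
        a = Spectrum("x", 100.0, peaks=(Peak(50.0, 1.0),))
        with pytest.raises(ValueError, match="duplicate"):
            SpectralLibrary(entries=[a, a])


class TestMassBankIO:
    def test_minimal_record(self, tmp_path):
        p = tmp_path / "rec.txt"
        p.write_text(MINIMAL_RECORD)
        lib = read_massbank(p)
        assert len(lib) == 1
        s = lib.entries[0]
        assert s.identifier == "TST001"
        assert s.ion_mode == "positive"
        assert s.precursor_mass == pytest.approx(181.070665)
        assert s.compound_mass == pytest.approx(180.063388)
        assert s.masses == pytest.approx((85.028406, 145.049535, 163.060100))

    def test_roundtrip_preserves_peaks(self, tmp_path, glucose_spectrum):
        path = tmp_path / "lib.txt"
        write_massbank([glucose_spectrum], path)
        back = read_massbank(path).entries[0]
        for a, b in zip(glucose_spectrum.peaks, back.peaks):
            assert a.mass == pytest.approx(b.mass, abs=1e-6)
            assert a.intensity == pytest.approx(b.intensity, abs=1e-6)

    def test_declared_peak_count_mismatch_is_error(self, tmp_path):
        bad = MINIMAL_RECORD.replace("PK$NUM_PEAK: 3", "PK$NUM_PEAK: 5")
        p = tmp_path / "bad.txt"
        p.write_text(bad)
        with pytest.raises(SpectrumParseError, match="5 peaks"):
            read_massbank(p)

    def test_selected_ion_fallback_and_missing_both(self, tmp_path):
        no_prec = MINIMAL_RECORD.replace(
            "MS$FOCUSED_ION: PRECURSOR_M/Z 181.070665",
            "MS$FOCUSED_ION: BASE_PEAK 163.060100",
        )
        p = tmp_path / "sel.txt"
        p.write_text(no_prec)
        assert read_massbank(p).entries[0].precursor_mass == pytest.approx(163.0601)
        neither = MINIMAL_RECORD.replace(
            "MS$FOCUSED_ION: PRECURSOR_M/Z 181.070665\n", ""
        )
        p2 = tmp_path / "none.txt"
        p2.write_text(neither)
        with pytest.raises(SpectrumParseError, match="selected ion"):
            read_massbank(p2)

    def test_malformed_peak_line(self, tmp_path):
        bad = MINIMAL_RECORD.replace("  145.049535 40.0 500", "  145.049535 oops")
        p = tmp_path / "mal.txt"
        p.write_text(bad)
        with pytest.raises(SpectrumParseError, match="malformed peak line"):
            read_massbank(p)


class TestMgfIO:
    def test_roundtrip_two_blocks(self, tmp_path, glucose_spectrum):
        other = Spectrum(
            "NEG01", 255.23, ion_mode="negative",
            peaks=(Peak(97.1, 3.0), Peak(120.5, 8.0)),
        )
        path = tmp_path / "lib.mgf"
        write_mgf([glucose_spectrum, other], path)
        lib = read_mgf(path)
        assert len(lib) == 2
        assert lib["NEG01"].ion_mode == "negative"  # CHARGE=1- round-trips
        glc = lib["GLC001"]
        assert glc.masses == pytest.approx(glucose_spectrum.masses, abs=1e-5)
        assert glc.compound_id == "glucose"

    def test_empty_file_gives_empty_library(self, tmp_path):
        p = tmp_path / "empty.mgf"
        p.write_text("")
        assert len(read_mgf(p)) == 0

    def test_missing_pepmass_is_error(self, tmp_path):
        p = tmp_path / "nopep.mgf"
        p.write_text("BEGIN IONS\nTITLE=x\n100.0 1.0\nEND IONS\n")
        with pytest.raises(SpectrumParseError, match="PEPMASS"):
            read_mgf(p)


class TestLibraryFilters:
    def test_passing_spectrum(self, glucose_spectrum):
        res = passes_library_filters(glucose_spectrum)
        assert res.passed and res.reason == ""

    def test_negative_mode_rejected(self, glucose_spectrum):
        s = Spectrum(
            "n", glucose_spectrum.precursor_mass, ion_mode="negative",
            peaks=glucose_spectrum.peaks,
        )
        assert passes_library_filters(s).reason == "ion-mode"

    def test_compound_mass_bound_is_strict(self):
        peaks = tuple(Peak(100.0 + i, 50.0) for i in range(6))
        s = Spectrum("big", 1000.0 + PROTON_MASS, peaks=peaks, compound_mass=1000.0)
        assert passes_library_filters(s).reason == "compound-mass"
        s2 = Spectrum("ok", 999.9 + PROTON_MASS, peaks=peaks, compound_mass=999.9)
        assert passes_library_filters(s2).passed

    def test_too_few_informative_peaks(self):
        # 4 peaks above 2% of base, 30 below: fails the informative-peak rule
        strong = [Peak(100.0 + i, 100.0) for i in range(4)]
        weak = [Peak(200.0 + i, 1.0) for i in range(30)]
        s = Spectrum("w", 500.0, peaks=tuple(strong + weak))
        assert passes_library_filters(s).reason == "min-informative-peaks"

    def test_structure_mass_agreement_when_provided(self):
        peaks = tuple(Peak(100.0 + i, 50.0) for i in range(6))
        s = Spectrum("m", 181.1, peaks=peaks, compound_mass=180.063388)
        assert passes_library_filters(s).reason == "precursor-structure-mass-mismatch"

    def test_filter_is_pure(self, glucose_spectrum):
        first = passes_library_filters(glucose_spectrum)
        second = passes_library_filters(glucose_spectrum)
        assert (first.passed, first.reason) == (second.passed, second.reason)


class TestCollisionEnergyMerge:
    def test_idempotent_on_copies(self, glucose_spectrum):
        merged = merge_collision_energies([glucose_spectrum, glucose_spectrum])
        assert merged.masses == glucose_spectrum.masses
        assert merged.intensities == glucose_spectrum.intensities

    def test_disjoint_peaks_pooled(self):
        a = Spectrum("a", 300.0, peaks=(Peak(100.0, 10.0),), compound_id="c")
        b = Spectrum("b", 300.0, peaks=(Peak(200.0, 5.0),), compound_id="c")
        merged = merge_collision_energies([a, b])
        assert merged.masses == (100.0, 200.0)

    def test_close_peaks_merge_to_most_intense(self):
        # 100.0000 and 100.0005 are 5 p.p.m. apart, inside max(10 ppm, 2 mDa)
        a = Spectrum("a", 300.0, peaks=(Peak(100.0000, 10.0),), compound_id="c")
        b = Spectrum("b", 300.0, peaks=(Peak(100.0005, 30.0),), compound_id="c")
        merged = merge_collision_energies([a, b])
        assert merged.masses == (100.0005,)
        assert merged.intensities == (30.0,)

    def test_precursor_disagreement_is_error(self):
        a = Spectrum("a", 300.0, peaks=(Peak(100.0, 1.0),), compound_id="c")
        b = Spectrum("b", 301.0, peaks=(Peak(100.0, 1.0),), compound_id="c")
        with pytest.raises(ValueError, match="precursor"):
            merge_collision_energies([a, b])

    @settings(max_examples=50, deadline=None)
    @given(
        masses=st.lists(
            st.floats(min_value=60.0, max_value=290.0), min_size=1, max_size=12
        )
    )
    def test_merged_output_respects_separation(self, masses):
        """No two merged peaks ever lie within the merge tolerance of each other."""
        s = Spectrum(
            "h", 300.0, peaks=tuple(Peak(m, 1.0 + i) for i, m in enumerate(masses)),
            compound_id="c",
        )
        merged = merge_collision_energies([s, s])
        ms = merged.masses
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                assert abs(ms[i] - ms[j]) > mass_tolerance_da(max(ms[i], ms[j]))

    def test_merge_matches_bruteforce_clustering(self):
        """Cluster membership agrees with an exhaustive pairwise check."""
        peaks = [Peak(100.0, 5.0), Peak(100.0005, 9.0), Peak(100.01, 2.0), Peak(250.0, 7.0)]
        s1 = Spectrum("a", 300.0, peaks=tuple(peaks[:2]), compound_id="c")
        s2 = Spectrum("b", 300.0, peaks=tuple(peaks[2:]), compound_id="c")
        merged = merge_collision_energies([s1, s2])
        # brute force: greedy by intensity, reject anything within tolerance
        accepted = []
        for p in sorted(peaks, key=lambda p: -p.intensity):
            if all(
                abs(p.mass - q.mass) > mass_tolerance_da(max(p.mass, q.mass))
                for q in accepted
            ):
                accepted.append(p)
        assert sorted(merged.masses) == sorted(p.mass for p in accepted)
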