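"""Digestion, mass arithmetic and fragment scoring."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hapid import (
    PeptideIndex,
    SearchParams,
    SpectrumRecord,
    digest,
    match_spectrum,
    parse_external_psms,
    peptide_mass,
)
from hapid.constants import CARBAMIDOMETHYL, PROTON, WATER
from hapid.search_engine import PSM, fragment_mzs, write_psms
from hapid.sequence_db import ProteinRecord, build_database

from conftest import brute_force_digest

AA = "ACDEFGHIKLMNPQRSTVWY"
seq_st = st.text(alphabet=AA, min_size=1, max_size=60)


def digest_set(sequence: str, **kw) -> set[str]:
    params = SearchParams(
        trypsin_p=kw.get("trypsin_p", True),
        missed_cleavages_max=kw.get("missed", 0),
        semi_tryptic=kw.get("semi", False),
        min_peptide_length=kw.get("min_len", 1),
        max_peptide_length=kw.get("max_len", 50),
    )
    return {c.sequence for c in digest(sequence, params)}


class TestDigestion:
    @pytest.mark.parametrize(
        "seq,kw,expected",
        [
            ("MAKRGYK", dict(trypsin_p=False), {"MAK", "R", "GYK"}),
            (
                "MAKRGYK",
                dict(trypsin_p=False, missed=1),
                {"MAK", "R", "GYK", "MAKR", "RGYK"},
            ),
            ("AKPR", dict(trypsin_p=False), {"AKPR"}),
            ("AKPR", dict(trypsin_p=True), {"AK", "PR"}),
        ],
    )
    def test_worked_examples(self, seq, kw, expected):
        assert digest_set(seq, **kw) == expected

    @given(seq=seq_st)
    @settings(deadline=None, max_examples=40)
    @pytest.mark.parametrize("trypsin_p", [False, True])
    @pytest.mark.parametrize("missed", [0, 1, 2])
    @pytest.mark.parametrize("semi", [False, True])
    def test_matches_brute_force_enumeration(self, seq, trypsin_p, missed, semi):
        got = digest_set(
            seq, trypsin_p=trypsin_p, missed=missed, semi=semi, min_len=1
        )
        expected = brute_force_digest(seq, trypsin_p, missed, semi, 1, 50)
        assert got == expected

    def test_length_bounds_applied(self):
        peps = digest_set("MAKRGYK", trypsin_p=False, min_len=3)
        assert peps == {"MAK", "GYK"}


class TestMass:
    def test_peptide_reference_value(self):
        assert peptide_mass("PEPTIDE") == pytest.approx(799.3600, abs=5e-4)

    def test_glycine_is_residue_plus_water(self):
        assert peptide_mass("G") == pytest.approx(57.02146 + 18.010565, abs=5e-4)

    def test_fixed_carbamidomethyl_additive(self):
        base = peptide_mass("C")
        assert peptide_mass("C", fixed_mods=[("C", CARBAMIDOMETHYL)]) == pytest.approx(
            base + 57.02146
        )

    def test_unknown_residue_requires_configured_mass(self):
        with pytest.raises(ValueError, match="X"):
            peptide_mass("AXK")
        assert peptide_mass("AXK", unknown_residue_mass=110.0) == pytest.approx(
            peptide_mass("AK") + 110.0
        )

    @given(a=seq_st, b=seq_st)
    @settings(deadline=None, max_examples=50)
    def test_mass_additivity(self, a, b):
        assert peptide_mass(a + b) == pytest.approx(
            peptide_mass(a) + peptide_mass(b) - WATER
        )


def ladder_spectrum(peptide: str, sid: str = "s1", params: SearchParams | None = None):
    params = params or SearchParams()
    b, y = fragment_mzs(peptide, fixed_mods=params.fixed_mods)
    mz = np.sort(np.concatenate([b, y]))
    mass = peptide_mass(peptide, fixed_mods=params.fixed_mods)
    return SpectrumRecord(sid, (mass + 2 * PROTON) / 2, 2, mz, np.full(mz.size, 100.0))


class TestMatching:
    PROTEINS = [
        ProteinRecord("p1", "g1", "MAGWINDKSTELLARKVYQHPDR"),
        ProteinRecord("p2", "g2", "FFEQPLNTIKGGWVDSMCAKHHR"),
    ]

    def _index(self, params):
        return PeptideIndex.build(build_database(self.PROTEINS), params)

    def test_noiseless_ladder_recovers_true_peptide(self):
        params = SearchParams()
        index = self._index(params)
        spec = ladder_spectrum("STELLARK", params=params)
        psm = match_spectrum(spec, index, params)
        assert psm is not None and psm.peptide == "STELLARK"
        assert not psm.is_decoy and "p1" in psm.protein_ids

    def test_out_of_tolerance_candidate_excluded(self):
        params = SearchParams()
        index = self._index(params)
        spec = ladder_spectrum("STELLARK", params=params)
        spec.precursor_mz += 5.0  # far outside ppm window for every isotope error
        psm = match_spectrum(spec, index, params)
        assert psm is None or psm.peptide != "STELLARK"

    def test_zero_matched_fragments_scores_zero(self):
        params = SearchParams(min_peaks=1)
        from hapid.search_engine import score_candidate

        spec = SpectrumRecord(
            "s1", 500.0, 2, np.array([100.0, 200.0]), np.array([1.0, 1.0])
        )
        assert score_candidate(spec, "GGGGGG", (), params) == pytest.approx(0.0)

    def test_sparse_spectrum_skipped(self):
        params = SearchParams(min_peaks=10)
        index = self._index(params)
        spec = SpectrumRecord(
            "s1", 500.0, 2, np.array([100.0, 200.0]), np.array([1.0, 1.0])
        )
        assert match_spectrum(spec, index, params) is None

    def test_isotope_error_window_recovers_shifted_precursor(self):
        from hapid.constants import ISOTOPE_SPACING

        params = SearchParams()
        index = self._index(params)
        spec = ladder_spectrum("STELLARK", params=params)
        spec.precursor_mz += ISOTOPE_SPACING / 2  # +1 isotope at charge 2
        psm = match_spectrum(spec, index, params)
        assert psm is not None and psm.peptide == "STELLARK"

    def test_determinism_byte_identical_tables(self, tmp_path):
        params = SearchParams()
        index = self._index(params)
        spectra = [
            ladder_spectrum("STELLARK", "s1", params),
            ladder_spectrum("GGWVDSMCAK", "s2", params),
        ]
        tables = []
        for run in range(2):
            psms = [match_spectrum(s, index, params) for s in spectra]
            out = tmp_path / f"run{run}.tsv"
            write_psms([p for p in psms if p], out)
            tables.append(out.read_bytes())
        assert tables[0] == tables[1]


class TestExternalPSMs:
    def _write(self, tmp_path, rows):
        path = tmp_path / "psms.tsv"
        header = "spectrum_id\tpeptide\tscore\tprotein_ids\n"
        path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
        return path

    def test_best_per_spectrum_reduction(self, tmp_path):
        path = self._write(
            tmp_path, [("s1", "PEPTIDEK", 12.0, "p1"), ("s1", "OTHERK", 9.0, "p2")]
        )
        psms = parse_external_psms(path)
        assert len(psms) == 1 and psms[0].peptide == "PEPTIDEK"

    def test_decoy_prefix_rules(self, tmp_path):
        path = self._write(
            tmp_path,
            [("s1", "AAAK", 5.0, "XXX_p1"), ("s2", "CCCK", 5.0, "p1;XXX_p2")],
        )
        psms = {p.spectrum_id: p for p in parse_external_psms(path)}
        assert psms["s1"].is_decoy and not psms["s2"].is_decoy

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("spectrum_id\tpeptide\tprotein_ids\ns1\tAAAK\tp1\n")
        with pytest.raises(ValueError, match="score"):
            parse_external_psms(path)

    def test_roundtrip_with_builtin_writer(self, tmp_path):
        psms = [
            PSM("s1", "PEPTIDEK", 12.0, False, frozenset({"p1"}), frozenset({"g1"}))
        ]
        out = tmp_path / "psms.tsv"
        write_psms(psms, out)
        back = parse_external_psms(out)
        assert back[0].peptide == "PEPTIDEK" and back[0].score == 12.0
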