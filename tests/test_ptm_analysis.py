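"""Fragment ions, spectral matching, PTM enrichment and triage."""

import numpy as np
import pandas as pd
import pytest
from pyteomics import mass as pmass

from isletpep import ptm_analysis
from isletpep.ptm_analysis import (
    MatchThresholds,
    SpectrumPeaks,
    UnknownModificationError,
    classify_ptm_enrichment,
    match_spectra,
    precursor_mz,
    theoretical_fragments,
    triage_candidates,
    validate_ptm,
)

PROTON = ptm_analysis.PROTON
WATER = ptm_analysis.WATER


class TestTheoreticalFragments:
    def test_dipeptide_against_reference_values(self):
        ions = dict(theoretical_fragments("AG"))
        assert ions["b1"] == pytest.approx(72.0444, abs=1e-4)
        assert ions["y1"] == pytest.approx(76.0393, abs=1e-4)

    @pytest.mark.parametrize("peptide", ["PEPTIDE", "ACDEFGHIK", "WWYYMMNN"])
    def test_agrees_with_pyteomics_ion_masses(self, peptide):
        ions = dict(theoretical_fragments(peptide))
        n = len(peptide)
        for k in range(1, n):
            b = pmass.calculate_mass(sequence=peptide[:k], ion_type="b", charge=1)
            y = pmass.calculate_mass(sequence=peptide[n - k:], ion_type="y", charge=1)
            assert ions[f"b{k}"] == pytest.approx(b, abs=1e-6)
            assert ions[f"y{k}"] == pytest.approx(y, abs=1e-6)

    def test_mass_conservation_random_peptides(self):
        # complementary b/y pairs reconstruct the precursor:
        # b_k + y_(n-k) - proton == [M+H]+
        rng = np.random.default_rng(7)
        aas = list(ptm_analysis.AA_MONO)
        for _ in range(200):
            pep = "".join(rng.choice(aas, size=int(rng.integers(8, 15))))
            ions = dict(theoretical_fragments(pep))
            n = len(pep)
            mh = precursor_mz(pep)
            for k in range(1, n):
                assert ions[f"b{k}"] + ions[f"y{n - k}"] - PROTON == pytest.approx(mh, abs=1e-6)

    def test_phospho_shifts_exactly_the_site_containing_ions(self):
        pep = "SAMPLEKR"
        i = 1  # phospho on S (position 1)
        plain = dict(theoretical_fragments(pep))
        mod = dict(theoretical_fragments(pep, [(i, "phosphorylation")]))
        n = len(pep)
        for k in range(1, n):
            b_shift = mod[f"b{k}"] - plain[f"b{k}"]
            y_shift = mod[f"y{k}"] - plain[f"y{k}"]
            assert b_shift == pytest.approx(79.966331 if k >= i else 0.0, abs=1e-6)
            assert y_shift == pytest.approx(79.966331 if k >= n - i + 1 else 0.0, abs=1e-6)

    def test_unknown_modification_named_in_error(self):
        with pytest.raises(UnknownModificationError, match="sumoylation"):
            theoretical_fragments("PEPTIDE", [(2, "sumoylation")])

    def test_invalid_residue_rejected(self):
        with pytest.raises(ValueError, match="standard alphabet"):
            theoretical_fragments("PEPTIDEZ")


def spectrum(peaks, sid="s"):
    return SpectrumPeaks(sid, 500.0, 1, peaks=list(peaks))


class TestMatchSpectra:
    def test_identity(self):
        sp = spectrum([(100.0, 10.0), (200.0, 20.0), (300.0, 5.0)])
        mf, cos = match_spectra(sp, sp, 0.03)
        assert mf == 1.0
        assert cos == pytest.approx(1.0)

    def test_disjoint(self):
        a = spectrum([(100.0, 10.0), (200.0, 10.0)])
        b = spectrum([(150.0, 10.0), (250.0, 10.0)])
        assert match_spectra(a, b, 0.03) == (0.0, 0.0)

    def test_dropout_fraction(self):
        ref = spectrum([(100.0 + 10 * i, 10.0) for i in range(10)])
        obs = spectrum([(100.0 + 10 * i, 10.0) for i in range(8)])
        mf, _ = match_spectra(obs, ref, 0.03)
        assert mf == pytest.approx(0.8)

    def test_matched_fraction_monotone_in_tolerance(self):
        rng = np.random.default_rng(3)
        ref = spectrum([(float(m), 10.0) for m in sorted(rng.uniform(100, 1000, 30))])
        obs = spectrum([(m + float(rng.normal(0, 0.02)), 10.0) for m, _ in ref.peaks])
        fractions = [match_spectra(obs, ref, tol)[0] for tol in (0.005, 0.01, 0.03, 0.1)]
        assert fractions == sorted(fractions)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            match_spectra(spectrum([]), spectrum([(1.0, 1.0)]), 0.03)


class TestValidatePtm:
    def _triple(self, pep="ACDKSTYR", site=4, name="glutathionylation"):
        mods = [(site, name)]
        def noiseless(m):
            return spectrum([(mz, 100.0) for _, mz in theoretical_fragments(pep, m)])
        return noiseless(mods), noiseless([])

    def test_modified_observation_is_biological(self):
        syn_mod, syn_nat = self._triple()
        assert validate_ptm(syn_mod, syn_mod, syn_nat) == "biological"

    def test_native_observation_is_artifactual(self):
        syn_mod, syn_nat = self._triple()
        assert validate_ptm(syn_nat, syn_mod, syn_nat) == "artifactual"

    def test_noise_is_unvalidated(self):
        syn_mod, syn_nat = self._triple()
        noise = spectrum([(50.0 + 7.1 * i, 10.0) for i in range(20)])
        assert validate_ptm(noise, syn_mod, syn_nat) == "unvalidated"


class TestEnrichmentClassification:
    @pytest.mark.parametrize(
        "b,f,expected",
        [(0, 5, "ifn-enriched"), (3, 3, "shared"), (1, 4, "ifn-enriched"), (4, 1, "basal-enriched")],
    )
    def test_two_thirds_rule(self, b, f, expected):
        rows = [{"ptm_name": "deamidation", "peptide": f"B{i}", "condition": "basal"} for i in range(b)]
        rows += [{"ptm_name": "deamidation", "peptide": f"F{i}", "condition": "ifn"} for i in range(f)]
        out = classify_ptm_enrichment(pd.DataFrame(rows))
        assert out.ptm_class.iloc[0] == expected


class TestTriage:
    def _frame(self, name, position, peptide="ACDKSTYRQ", condition="ifn"):
        return pd.DataFrame([{
            "peptide": peptide, "ptm_name": name, "ptm_position": position,
            "condition": condition,
        }])

    def test_internal_glutathionylation_retained(self):
        out = triage_candidates(self._frame("glutathionylation", 2))
        assert out.retained.iloc[0]

    def test_oxidation_always_excluded(self):
        out = triage_candidates(self._frame("oxidation", 5))
        assert not out.retained.iloc[0]

    def test_terminal_position_excluded(self):
        out = triage_candidates(self._frame("deamidation", 9))
        assert not out.retained.iloc[0]

    def test_shared_class_excluded(self):
        df = pd.concat([
            self._frame("deamidation", 3, peptide="ACDKSTYRQ", condition="ifn"),
            self._frame("deamidation", 3, peptide="CDKSTYRQA", condition="basal"),
        ])
        out = triage_candidates(df)
        assert not out.retained.any()

    def test_unknown_ptm_errors(self):
        with pytest.raises(UnknownModificationError):
            triage_candidates(self._frame("citrullination", 3))
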