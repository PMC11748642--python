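"""Transcript filter cascade, alternative-stretch extraction, FASTA assembly."""

import numpy as np
import pytest
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from isletpep import variant_db
from isletpep.variant_db import (
    AlternativeStretch,
    IsoformRecord,
    build_search_database,
    extract_alternative_sequences,
    filter_expressed,
    filter_islet_enrichment,
    filter_islet_expression,
    filter_mtec,
    call_differential,
    parse_variant_header,
    variant_header,
)


def make_iso(islet_basal, islet_ifn, mtec_lo=(0.01,), mtec_hi=(0.01,),
             controls=None, de=None, iso_id="I1"):
    tpm = {
        "islet_basal": np.asarray(islet_basal, float),
        "islet_ifn": np.asarray(islet_ifn, float),
        "mtec_lo": np.asarray(mtec_lo, float),
        "mtec_hi": np.asarray(mtec_hi, float),
    }
    for name, vec in (controls or {"liver": (0.01,)}).items():
        tpm[name] = np.asarray(vec, float)
    return IsoformRecord(iso_id, "G1", "P1", False, "ATG", "M", tpm=tpm, de_stats=de)


class TestExpressedFilter:
    @pytest.mark.parametrize(
        "basal,ifn,expected",
        [
            # 2 of 10 pooled samples above 0.5 is exactly 20% -> pass
            ((0.6, 0.6, 0, 0, 0), (0, 0, 0, 0, 0), True),
            # 0.5 exactly is not > 0.5 -> fail
            ((0.5,) * 5, (0.5,) * 5, False),
            ((10.0,) * 5, (10.0,) * 5, True),
        ],
    )
    def test_threshold_rule(self, basal, ifn, expected):
        survivors, log = filter_expressed([make_iso(basal, ifn)])
        assert bool(survivors) is expected
        assert log.passed.iloc[0] == expected

    def test_empty_tpm_errors(self):
        with pytest.raises(ValueError):
            filter_expressed([make_iso((), ())])


class TestIsletExpressionFilter:
    @pytest.mark.parametrize(
        "basal,ifn,expected",
        [
            ((4.0,) * 3, (6.0,) * 3, True),   # either condition suffices
            ((5.0,) * 3, (5.0,) * 3, False),  # strict >
            ((100.0,) * 3, (100.0,) * 3, True),
        ],
    )
    def test_median_disjunction(self, basal, ifn, expected):
        survivors, _ = filter_islet_expression([make_iso(basal, ifn)])
        assert bool(survivors) is expected


class TestMtecFilter:
    def test_low_median_clause(self):
        iso = make_iso((1.0,) * 3, (1.0,) * 3, mtec_lo=(0.05,) * 3, mtec_hi=(0.2,) * 3)
        assert filter_mtec([iso])[0]

    def test_fold_clause(self):
        iso = make_iso((600.0,) * 3, (600.0,) * 3, mtec_lo=(0.5,) * 3, mtec_hi=(0.5,) * 3)
        # 600 / (0.5 + 0.01) > 100
        assert filter_mtec([iso], epsilon=0.01)[0]

    def test_fails_when_expressed_in_mtec(self):
        iso = make_iso((6.0,) * 3, (6.0,) * 3, mtec_lo=(5.0,) * 3, mtec_hi=(5.0,) * 3)
        assert not filter_mtec([iso])[0]


class TestIsletEnrichmentFilter:
    def test_pass_low_controls(self):
        iso = make_iso((110.0,) * 3, (110.0,) * 3, controls={"liver": (1.0,) * 3, "colon": (0.5,) * 3})
        assert filter_islet_enrichment([iso], epsilon=0.01)[0]

    def test_fail_one_high_control(self):
        iso = make_iso((110.0,) * 3, (110.0,) * 3, controls={"liver": (50.0,) * 3})
        # 110 / 50.01 < 10
        assert not filter_islet_enrichment([iso], epsilon=0.01)[0]

    def test_zero_islet_fails(self):
        iso = make_iso((0.0,) * 3, (0.0,) * 3)
        assert not filter_islet_enrichment([iso])[0]

    def test_neuroendocrine_control_rejected(self):
        iso = make_iso((10.0,) * 3, (10.0,) * 3, controls={"brain": (0.1,) * 3})
        with pytest.raises(ValueError, match="neuroendocrine"):
            filter_islet_enrichment([iso])


class TestDifferentialCall:
    @pytest.mark.parametrize(
        "de,expected",
        [((2.0, 0.01), True), ((1.50, 0.01), False), ((3.0, 0.05), False), (None, False)],
    )
    def test_thresholds_strict(self, de, expected):
        out = call_differential([make_iso((1,), (1,), de=de)])
        assert bool(out.de.iloc[0]) is expected


class TestCascadePurity:
    def test_sequential_equals_composed(self, fixture_bundle):
        isoforms = fixture_bundle.isoforms
        composed, log = variant_db.run_filter_cascade(isoforms)
        step = isoforms
        for fn in (filter_expressed, filter_islet_expression, filter_mtec, filter_islet_enrichment):
            step, _ = fn(step)
        assert [i.isoform_id for i in composed] == [i.isoform_id for i in step]
        # every isoform appears in the log exactly up to its drop stage
        first = log[log.stage == "expressed"]
        assert set(first.isoform_id) == {i.isoform_id for i in isoforms}


class TestAlternativeExtraction:
    def test_identity_is_empty(self):
        assert extract_alternative_sequences("MKLVGA", "MKLVGA") == []

    def test_simple_insertion(self):
        canonical = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"
        isoform = canonical[:15] + "WWW" + canonical[15:]
        got = extract_alternative_sequences(canonical, isoform)
        assert len(got) == 1
        st = got[0]
        assert st.origin == "insertion"
        assert st.core == "WWW"
        assert st.aa_sequence not in canonical
        # flanks are canonical context on both sides
        assert st.aa_sequence == isoform[st.start:st.end]

    def test_pure_prefix_truncation_is_empty(self):
        canonical = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEV"
        assert extract_alternative_sequences(canonical, canonical[:20]) == []

    def test_internal_deletion_yields_junction(self):
        canonical = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVWDNQTR"
        isoform = canonical[:14] + canonical[24:]
        got = extract_alternative_sequences(canonical, isoform)
        assert [st.origin for st in got] == ["junction"]
        assert got[0].core == ""
        assert got[0].aa_sequence not in canonical

    def test_every_core_absent_from_canonical(self, fixture_bundle):
        by_acc = {r.id: str(r.seq) for r in fixture_bundle.proteome}
        checked = 0
        for iso in fixture_bundle.isoforms:
            canonical = by_acc[iso.canonical_accession]
            for st in extract_alternative_sequences(canonical, iso.translation, iso.isoform_id):
                if st.core:
                    assert st.core not in canonical
                assert st.aa_sequence == iso.translation[st.start:st.end]
                checked += 1
        assert checked > 0


class TestSearchDatabase:
    def _stretch(self, seq="WWWHHHKKK", iso="ISOX"):
        return AlternativeStretch(iso, seq, "insertion", 10, 10 + len(seq), 3, 6, 3, 3)

    def test_entry_count(self):
        ref = [SeqRecord(Seq("MKTAYIAK"), id=f"P{i}") for i in range(10)]
        db = build_search_database(ref, [(self._stretch(iso=f"I{i}"), "P0") for i in range(3)])
        assert len(db) == 13

    def test_roundtrip(self, tmp_path):
        ref = [SeqRecord(Seq("MKTAYIAK"), id="P1", description="")]
        db = build_search_database(ref, [(self._stretch(), "P1")])
        path = tmp_path / "db.fasta"
        variant_db.write_fasta(db, path)
        back = variant_db.read_fasta(path)
        assert [(r.id, str(r.seq)) for r in back] == [(r.id, str(r.seq)) for r in db]

    def test_stop_symbol_rejected(self):
        with pytest.raises(ValueError, match="invalid residues"):
            build_search_database([], [(self._stretch(seq="WWW*HHH"), "P1")])

    def test_duplicate_accession_rejected(self):
        ref = [SeqRecord(Seq("MK"), id="P1"), SeqRecord(Seq("MK"), id="P1")]
        with pytest.raises(ValueError, match="duplicate"):
            build_search_database(ref, [])

    def test_header_roundtrip(self):
        st = self._stretch()
        hdr = variant_header(st, "P7")
        meta = parse_variant_header(hdr)
        assert meta["isoform_id"] == "ISOX"
        assert meta["canonical_accession"] == "P7"
        assert meta["origin"] == "insertion"
        assert (meta["start"], meta["end"]) == (st.start, st.end)
        assert (meta["core_start"], meta["core_end"]) == (st.core_start, st.core_end)
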