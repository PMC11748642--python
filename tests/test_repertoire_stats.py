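"""Protein counts, cleavage motifs, abundance aggregation, overlaps."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isletpep.repertoire_stats import (
    aggregate_abundance,
    classify_motif,
    count_by_protein,
    motif_enrichment_test,
    overlap_stats,
)
from oracles import fisher_exact_bruteforce, wilcoxon_signed_rank_bruteforce

AA = "ACDEFGHIKLMNPQRSTVWY"


def report_frame(rows):
    defaults = {"category": "conventional", "ptm_name": "", "ptm_verdict": ""}
    return pd.DataFrame([{**defaults, **r} for r in rows])


class TestProteinCounts:
    def _counts(self, n_basal, n_ifn):
        rows = [{"peptide": f"B{i}", "condition_class": "basal", "accessions": ["P1"]}
                for i in range(n_basal)]
        rows += [{"peptide": f"F{i}", "condition_class": "ifn", "accessions": ["P1"]}
                 for i in range(n_ifn)]
        return count_by_protein(report_frame(rows)).iloc[0]

    def test_log2fc_with_pseudocount(self):
        row = self._counts(4, 16)
        assert row.log2fc == pytest.approx(math.log2(16.5 / 4.5), abs=1e-9)
        assert row.enriched == "ifn"

    def test_symmetric_counts_zero_fc(self):
        row = self._counts(6, 6)
        assert row.log2fc == 0.0
        assert row.enriched == "none"

    def test_basal_enrichment(self):
        row = self._counts(8, 0)
        assert row.log2fc == pytest.approx(math.log2(0.5 / 8.5), abs=1e-9)
        assert row.enriched == "basal"

    def test_cis_spliced_excluded_and_percents_sum(self):
        rows = [
            {"peptide": "AAAA", "condition_class": "both", "accessions": ["P1"]},
            {"peptide": "CCCC", "condition_class": "ifn", "accessions": ["P2"]},
            {"peptide": "DDDD", "condition_class": "ifn", "accessions": ["P2"],
             "category": "cis-spliced-candidate"},
        ]
        out = count_by_protein(report_frame(rows))
        assert out.n_ifn.sum() == 2  # the cis-spliced row is gone
        assert out.percent_ifn.sum() == pytest.approx(100.0, abs=1e-9)

    def test_artifact_ptm_collapses_onto_native_sequence(self):
        rows = [
            {"peptide": "AAAA", "condition_class": "ifn", "accessions": ["P1"]},
            {"peptide": "AAAA", "condition_class": "ifn", "accessions": ["P1"],
             "category": "ptm", "ptm_name": "deamidation", "ptm_verdict": "artifactual"},
            {"peptide": "CCCC", "condition_class": "ifn", "accessions": ["P1"],
             "category": "ptm", "ptm_name": "deamidation", "ptm_verdict": "biological"},
        ]
        out = count_by_protein(report_frame(rows))
        # artifact PTM merges with the native sequence; biological PTM stays distinct
        assert out.n_ifn.iloc[0] == 2


class TestMotifClassification:
    def test_high_affinity(self):
        assert classify_motif("AAAAAAAF", ["A"]) == "high_affinity"

    def test_proline_blocks(self):
        assert classify_motif("AAAAAAAL", ["P"]) == "none"

    def test_outside_both_sets(self):
        assert classify_motif("AAAAAAAK", ["A"]) == "none"

    def test_any_mapping_rescues(self):
        assert classify_motif("AAAAAAAY", ["P", "G"]) == "high_affinity"

    def test_agrees_with_rule_table_everywhere(self):
        # independent rule table over all C-terminal x following combinations
        for ct in AA:
            for nxt in list(AA) + [None]:
                if ct in "YFW" and nxt != "P":
                    want = "high_affinity"
                elif ct in "ML" and nxt != "P":
                    want = "low_affinity"
                else:
                    want = "none"
                assert classify_motif("AAAA" + ct, [nxt]) == want

    def test_no_mapping_errors(self):
        with pytest.raises(ValueError):
            classify_motif("AAAA", [])


class TestMotifEnrichment:
    def test_fisher_value_from_counts(self):
        rows = [{"peptide": f"B{i}", "condition_class": "basal",
                 "motif_class": "high_affinity" if i < 10 else "none"} for i in range(100)]
        rows += [{"peptide": f"F{i}", "condition_class": "ifn",
                  "motif_class": "high_affinity" if i < 40 else "none"} for i in range(100)]
        out = motif_enrichment_test(pd.DataFrame(rows)).set_index("motif")
        want = fisher_exact_bruteforce([[10, 90], [40, 60]])
        assert out.loc["any_motif", "fisher_p"] == pytest.approx(want, rel=1e-9)

    def test_identical_proportions_p_one(self):
        rows = [{"peptide": f"{c}{i}", "condition_class": cc, "motif_class": m}
                for cc, c in (("basal", "B"), ("ifn", "F"))
                for i, m in enumerate(["low_affinity"] * 3 + ["none"] * 3)]
        out = motif_enrichment_test(pd.DataFrame(rows))
        assert (out.fisher_p == 1.0).all()


class TestAbundance:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=["peptide", "condition", "replicate", "abundance"])

    def test_mean_over_replicates(self):
        df = self._frame([("P", "basal", r, 10.0) for r in range(1, 5)])
        per_pep, _ = aggregate_abundance(df, n_replicates=4)
        assert per_pep.mean_basal.iloc[0] == pytest.approx(10.0)

    def test_missing_replicate_counts_zero(self):
        df = self._frame([("P", "basal", 1, 8.0), ("P", "basal", 2, 8.0)])
        per_pep, _ = aggregate_abundance(df, n_replicates=4)
        assert per_pep.mean_basal.iloc[0] == pytest.approx(4.0)

    def test_degenerate_pairs_report_p_one(self):
        rows = [(f"P{i}", c, 1, 5.0) for i in range(6) for c in ("basal", "ifn")]
        _, tests = aggregate_abundance(self._frame(rows), n_replicates=1)
        assert tests.p_value.iloc[0] == 1.0
        assert tests.degenerate.iloc[0]

    def test_wilcoxon_matches_bruteforce(self):
        rng = np.random.default_rng(17)
        basal = rng.uniform(1, 10, size=12)
        ifn = basal * rng.uniform(1.2, 3.0, size=12)
        rows = [(f"P{i}", "basal", 1, b) for i, b in enumerate(basal)]
        rows += [(f"P{i}", "ifn", 1, f) for i, f in enumerate(ifn)]
        _, tests = aggregate_abundance(self._frame(rows), n_replicates=1)
        w_oracle, p_oracle = wilcoxon_signed_rank_bruteforce(basal, ifn)
        scipy_stat, scipy_p = stats.wilcoxon(basal, ifn, alternative="two-sided")
        assert tests.p_value.iloc[0] == pytest.approx(p_oracle, rel=1e-9)
        assert tests.p_value.iloc[0] == pytest.approx(scipy_p, rel=1e-9)


class TestOverlap:
    def test_identical_sets(self):
        out = overlap_stats({"AAA", "CCC"}, {"AAA", "CCC"})
        assert out["frac_a"] == 1.0 and out["jaccard"] == 1.0

    def test_disjoint(self):
        out = overlap_stats({"AAA"}, {"CCC"})
        assert out["shared"] == 0 and out["jaccard"] == 0.0

    def test_reported_fraction(self):
        a = {f"PEP{i:03d}" for i in range(117)}
        b = {f"PEP{i:03d}" for i in range(40)} | {f"OTH{i}" for i in range(60)}
        out = overlap_stats(a, b)
        assert out["shared"] == 40
        assert out["frac_a"] == pytest.approx(40 / 117, abs=1e-4)

    def test_il_equivalent_matching(self):
        out = overlap_stats({"ALWK"}, {"AIWK"}, il_equivalent=True)
        assert out["shared"] == 1
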