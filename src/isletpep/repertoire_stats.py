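"""Repertoire-level statistics over annotated peptide reports.

Four families of summaries:

- per-source-protein distinct-peptide counts per condition with a
  pseudocounted log2 fold change (IFN vs basal) and enrichment labels
  at |log2FC| >= 1;
- chymotrypsin-like proteasomal cleavage-motif classification of the
  peptide C-terminus in its parent context (high affinity: Y/F/W not
  followed by P; low affinity: M/L not followed by P) with Fisher exact
  condition comparison;
- per-peptide mean total abundance across replicates with a paired
  Wilcoxon signed-rank comparison between conditions, split by
  secretory-granule membership and optionally by assigned locus;
- set overlaps between peptide repertoires (shared counts, per-set
  shared fractions, Jaccard), under exact or I/L-equivalent matching.
"""

from __future__ import annotations

import math
import warnings
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

HIGH_AFFINITY_CT = frozenset("YFW")
LOW_AFFINITY_CT = frozenset("ML")


# ---------------------------------------------------------------------------
# Source-protein counts


def count_by_protein(reports: pd.DataFrame, pseudocount: float = 0.5) -> pd.DataFrame:
    """Distinct peptides per source protein and condition, with log2FC.

    ``reports`` needs columns ``peptide``, ``category``,
    ``condition_class``, ``accessions`` (list of source accessions),
    and optionally ``ptm_name``/``ptm_verdict``. Peptides of category
    ``cis-spliced-candidate`` are excluded. A PTM peptide with a
    ``biological`` verdict counts as a distinct modified species;
    otherwise it collapses onto its unmodified sequence. Condition sets
    are inclusive (basal = basal+both, ifn = ifn+both).

    log2FC = log2((n_ifn + c) / (n_basal + c)) with pseudocount c;
    labels ``ifn`` at log2FC >= 1, ``basal`` at <= -1, else none.
    """
    per_protein: dict[str, dict[str, set]] = {}
    for row in reports.itertuples(index=False):
        if row.category == "cis-spliced-candidate":
            continue
        ptm_name = getattr(row, "ptm_name", None)
        verdict = getattr(row, "ptm_verdict", None)
        if ptm_name and verdict == "biological":
            key = (row.peptide, ptm_name)
        else:
            key = (row.peptide, None)
        for acc in row.accessions:
            slot = per_protein.setdefault(acc, {"basal": set(), "ifn": set()})
            if row.condition_class in ("basal", "both"):
                slot["basal"].add(key)
            if row.condition_class in ("ifn", "both"):
                slot["ifn"].add(key)

    tot_b = sum(len(v["basal"]) for v in per_protein.values())
    tot_f = sum(len(v["ifn"]) for v in per_protein.values())
    rows = []
    for acc in sorted(per_protein):
        nb, nf = len(per_protein[acc]["basal"]), len(per_protein[acc]["ifn"])
        l2 = math.log2((nf + pseudocount) / (nb + pseudocount))
        rows.append({
            "accession": acc,
            "n_basal": nb,
            "n_ifn": nf,
            "log2fc": l2,
            "percent_basal": 100.0 * nb / tot_b if tot_b else 0.0,
            "percent_ifn": 100.0 * nf / tot_f if tot_f else 0.0,
            "enriched": "ifn" if l2 >= 1 else ("basal" if l2 <= -1 else "none"),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Cleavage motifs


def classify_motif(peptide: str, following_residues: Sequence[str | None]) -> str:
    """Chymotrypsin-like cleavage motif class of a peptide C-terminus.

    ``following_residues`` holds, for each source mapping, the parent
    residue after the peptide's C-terminus (None when the peptide ends
    the protein). The C-terminal residue is mapping-independent; the
    "not followed by proline" test passes if it passes in any mapping
    (a protein-end context passes — nothing follows).
    """
    if not following_residues:
        raise ValueError("classify_motif requires at least one source mapping")
    ct = peptide[-1]
    not_p = any(nxt != "P" for nxt in following_residues)
    if ct in HIGH_AFFINITY_CT and not_p:
        return "high_affinity"
    if ct in LOW_AFFINITY_CT and not_p:
        return "low_affinity"
    return "none"


def motif_enrichment_test(reports: pd.DataFrame) -> pd.DataFrame:
    """Motif-bearing counts and percents per condition with Fisher tests.

    ``reports`` needs ``peptide``, ``condition_class`` and
    ``motif_class``. Condition sets are inclusive. Rows cover
    high+low combined and each class separately; the p-value is a
    two-sided Fisher exact on (motif vs none) x (basal vs ifn).
    """
    sets = {"basal": reports[reports.condition_class.isin(["basal", "both"])],
            "ifn": reports[reports.condition_class.isin(["ifn", "both"])]}
    for name, df in sets.items():
        if df.empty:
            raise ValueError(f"no peptides in {name} condition")
    rows = []
    for label, classes in [("any_motif", ("high_affinity", "low_affinity")),
                           ("high_affinity", ("high_affinity",)),
                           ("low_affinity", ("low_affinity",))]:
        nb = int(sets["basal"].motif_class.isin(classes).sum())
        nf = int(sets["ifn"].motif_class.isin(classes).sum())
        tb, tf = len(sets["basal"]), len(sets["ifn"])
        p = float(stats.fisher_exact([[nb, tb - nb], [nf, tf - nf]])[1])
        rows.append({
            "motif": label,
            "n_basal": nb, "total_basal": tb, "percent_basal": 100.0 * nb / tb,
            "n_ifn": nf, "total_ifn": tf, "percent_ifn": 100.0 * nf / tf,
            "fisher_p": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Abundance


def aggregate_abundance(
    abundances: pd.DataFrame,
    n_replicates: int = 4,
    granule_flags: Mapping[str, bool] | None = None,
    loci: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mean total abundance per peptide and condition, with Wilcoxon tests.

    ``abundances`` is long: ``peptide``, ``condition``, ``replicate``,
    ``abundance``. A replicate in which the peptide was not detected
    contributes 0 to the mean over ``n_replicates``. Peptides with no
    abundance in either condition are excluded with a warning.

    Returns (per-peptide table, comparison table). The comparison is a
    two-sided Wilcoxon signed-rank on paired per-peptide means (basal vs
    IFN) within each group (all peptides, and granule/other when flags
    are given). When every paired difference is zero the test is
    degenerate and reported as p = 1 with ``degenerate=True``.
    """
    sums = abundances.groupby(["peptide", "condition"])["abundance"].sum().unstack(fill_value=0.0)
    for cond in ("basal", "ifn"):
        if cond not in sums.columns:
            sums[cond] = 0.0
    means = sums / n_replicates
    empty = means[(means.basal == 0) & (means.ifn == 0)].index
    if len(empty):
        warnings.warn(f"{len(empty)} peptide(s) with no abundance excluded")
        means = means.drop(index=empty)
    per_pep = means.reset_index().rename(columns={"basal": "mean_basal", "ifn": "mean_ifn"})
    if granule_flags is not None:
        per_pep["granule"] = per_pep.peptide.map(lambda p: bool(granule_flags.get(p, False)))
    if loci is not None:
        per_pep["locus"] = per_pep.peptide.map(loci)

    def _test(df: pd.DataFrame, group: str) -> dict:
        diffs = df.mean_ifn - df.mean_basal
        if len(diffs) == 0 or (diffs == 0).all():
            return {"group": group, "n": len(diffs), "statistic": float("nan"),
                    "p_value": 1.0, "degenerate": True}
        stat, p = stats.wilcoxon(df.mean_basal, df.mean_ifn, alternative="two-sided")
        return {"group": group, "n": len(diffs), "statistic": float(stat),
                "p_value": float(p), "degenerate": False}

    comps = [_test(per_pep, "all")]
    if granule_flags is not None:
        comps.append(_test(per_pep[per_pep.granule], "granule"))
        comps.append(_test(per_pep[~per_pep.granule], "other"))
    return per_pep, pd.DataFrame(comps)


# ---------------------------------------------------------------------------
# Overlaps


def overlap_stats(
    set_a: Iterable[str], set_b: Iterable[str], il_equivalent: bool = False
) -> dict[str, float]:
    """Shared count, per-set shared fractions and Jaccard index."""
    def canon(xs: Iterable[str]) -> set[str]:
        return {x.replace("L", "I") for x in xs} if il_equivalent else set(xs)

    a, b = canon(set_a), canon(set_b)
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "shared": len(inter),
        "frac_a": len(inter) / len(a) if a else 0.0,
        "frac_b": len(inter) / len(b) if b else 0.0,
        "jaccard": len(inter) / len(union) if union else 0.0,
    }
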