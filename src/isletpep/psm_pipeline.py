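"""Identification filters for peptide-spectrum match (PSM) tables.

The search engine's PSM export is collapsed to peptide level and pushed
through the identification funnel: target-decoy FDR control (1% for the
main search, with a relaxed 5% level admitted for mRNA-variant matches),
the 8–14 aa HLA-I length window, per-condition classification, exact
mapping onto the combined search database, category routing
(conventional / variant / unexplained), and the β-cell-enriched
expression filter on source proteins.

FDR uses the separate-decoy ratio estimator: at a score threshold t,
FDR(t) = (#decoy peptides with score >= t) / (#target peptides >= t).
Ties at the threshold are retained. Isoleucine and leucine are treated
as distinct residues here; I/L equivalence is confined to the
cis-splice search where mass spectrometry genuinely cannot resolve it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.SeqRecord import SeqRecord

from . import variant_db

#: PSM table columns expected by this module
PSM_COLUMNS = [
    "peptide", "modifications", "score", "spectrum_id",
    "condition", "replicate", "abundance", "is_decoy",
]


@dataclass(frozen=True)
class SourceMapping:
    """One exact occurrence of a peptide in a database entry.

    ``start``/``end`` are 0-based half-open coordinates in the entry;
    ``next_residue`` is the parent residue immediately following the
    peptide's C-terminus (None at the protein end), kept for
    cleavage-motif analysis.
    """

    accession: str
    start: int
    end: int
    next_residue: str | None
    is_variant: bool


def collapse_to_peptides(psms: pd.DataFrame) -> pd.DataFrame:
    """Best score per peptide; a peptide is decoy if its best PSM is."""
    idx = psms.groupby("peptide")["score"].idxmax()
    return psms.loc[idx, ["peptide", "score", "is_decoy"]].reset_index(drop=True)


def compute_fdr_cutoff(psms: pd.DataFrame, fdr_level: float) -> tuple[float, pd.DataFrame]:
    """Score threshold controlling peptide-level FDR, and retained targets.

    PSMs are collapsed to peptide level first. Candidate thresholds are
    the observed peptide scores; the lowest threshold t with
    FDR(t) <= fdr_level is returned together with the target peptides
    scoring >= t (score ties retained).
    """
    if not 0 <= fdr_level < 1:
        raise ValueError("fdr_level must be in [0, 1)")
    pep = collapse_to_peptides(psms)
    if not pep.is_decoy.any():
        raise ValueError("no decoy peptides: FDR is undefined")
    if pep.is_decoy.all():
        raise ValueError("no target peptides")

    scores = pep.score.to_numpy()
    decoy = pep.is_decoy.to_numpy()
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_cum = np.cumsum(decoy[order])
    t_cum = np.cumsum(~decoy[order])
    # walk candidate thresholds from high to low score; FDR at each
    # distinct score uses counts inclusive of ties
    best_t: float | None = None
    n = len(s_sorted)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and s_sorted[j + 1] == s_sorted[i]:
            j += 1
        targets = t_cum[j]
        decoys = d_cum[j]
        if targets > 0 and decoys / targets <= fdr_level:
            best_t = float(s_sorted[i])
        i = j + 1
    if best_t is None:
        raise ValueError(f"no threshold achieves FDR <= {fdr_level}")
    retained = pep[(pep.score >= best_t) & (~pep.is_decoy)].reset_index(drop=True)
    return best_t, retained


def apply_fdr(
    psms: pd.DataFrame,
    fdr: float = 0.01,
    variant_fdr: float | None = 0.05,
    variant_peptides: set[str] | None = None,
) -> pd.DataFrame:
    """Retain target peptides at the main FDR, plus variant matches at 5%.

    ``variant_peptides`` names peptides that map only to mRNA-variant
    database entries; when given with ``variant_fdr``, those peptides
    are additionally admitted at the relaxed level.
    """
    t1, retained = compute_fdr_cutoff(psms, fdr)
    if variant_fdr is not None and variant_peptides:
        t5, relaxed = compute_fdr_cutoff(psms, variant_fdr)
        extra = relaxed[relaxed.peptide.isin(variant_peptides) & ~relaxed.peptide.isin(retained.peptide)]
        retained = pd.concat([retained, extra], ignore_index=True)
    return retained


def filter_length(peptides: Iterable[str], min_len: int = 8, max_len: int = 14) -> tuple[list[str], float]:
    """Keep peptides in the expected 8–14 aa HLA-I ligand range.

    Returns the retained list and the in-range fraction of the input.
    """
    peptides = list(peptides)
    kept = [p for p in peptides if min_len <= len(p) <= max_len]
    frac = len(kept) / len(peptides) if peptides else float("nan")
    return kept, frac


def classify_condition(occurrences: pd.DataFrame) -> pd.Series:
    """Per-peptide condition class: basal, ifn, or both.

    ``occurrences`` needs columns ``peptide`` and ``condition``. A
    peptide seen in at least one basal replicate and at least one IFN
    replicate (in any replicate pairing) is classified ``both``.
    """
    seen = occurrences.groupby("peptide")["condition"].agg(set)

    def _cls(s: set) -> str:
        if "basal" in s and "ifn" in s:
            return "both"
        return next(iter(s))

    return seen.map(_cls).rename("condition_class")


def map_peptides(
    peptides: Sequence[str],
    search_db: Sequence[SeqRecord],
) -> pd.DataFrame:
    """Exact substring search of peptides over the combined database.

    Category routing: ``conventional`` if the peptide occurs in any
    reference entry; ``variant`` if it occurs only in variant entries
    and the occurrence spans the entry's novel core (a junction core is
    spanned when the occurrence strictly crosses the junction point);
    ``unexplained`` otherwise (candidate for the cis-splice search).
    """
    entries = []
    for rec in search_db:
        hdr = rec.id
        is_var = variant_db.is_variant_entry(hdr)
        meta = variant_db.parse_variant_header(hdr) if is_var else None
        entries.append((hdr, str(rec.seq), is_var, meta))

    rows = []
    for pep in peptides:
        mappings: list[SourceMapping] = []
        ref_hit = False
        var_core_hit = False
        for hdr, seq, is_var, meta in entries:
            start = seq.find(pep)
            while start != -1:
                end = start + len(pep)
                nxt = seq[end] if end < len(seq) else None
                mappings.append(SourceMapping(hdr, start, end, nxt, is_var))
                if is_var:
                    cs, ce = meta["core_start"], meta["core_end"]
                    if ce > cs:
                        spans = start < ce and end > cs
                    else:  # junction: must strictly cross the junction point
                        spans = start < cs < end
                    var_core_hit = var_core_hit or spans
                else:
                    ref_hit = True
                start = seq.find(pep, start + 1)
        if ref_hit:
            category = "conventional"
        elif var_core_hit:
            category = "variant"
        else:
            category = "unexplained"
        rows.append({"peptide": pep, "category": category, "mappings": mappings})
    return pd.DataFrame(rows)


def apply_enrichment_filter(
    reports: pd.DataFrame,
    protein_annotations: pd.DataFrame,
) -> pd.DataFrame:
    """β-cell-enriched expression filter on mapped source proteins.

    A peptide is kept when ANY of its mapped source proteins has
    pancreas evidence (RNA or protein level) AND is endocrine-enriched.
    ``protein_annotations`` is indexed by accession with boolean columns
    ``pancreas_evidence`` and ``endocrine_enriched``. Variant-entry
    mappings are resolved to their canonical accession.
    """
    ann = protein_annotations.set_index("accession") if "accession" in protein_annotations.columns else protein_annotations

    def _qualifies(mappings: list[SourceMapping]) -> bool:
        ok = False
        for m in mappings:
            acc = m.accession
            if m.is_variant:
                acc = variant_db.parse_variant_header(acc)["canonical_accession"]
            if acc not in ann.index:
                raise KeyError(f"no annotation for accession {acc!r}")
            row = ann.loc[acc]
            ok = ok or bool(row.pancreas_evidence and row.endocrine_enriched)
        return ok

    out = reports.copy()
    out["beta_cell_enriched"] = out.mappings.map(_qualifies)
    return out[out.beta_cell_enriched].reset_index(drop=True)
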