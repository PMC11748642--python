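"""End-to-end orchestration: fixture -> search database -> peptide reports.

``make_fixture`` builds the full synthetic study (proteome, isoforms,
PSMs, ranks, validation spectra). ``run_pipeline`` pushes a PSM table
through the identification funnel — FDR control, length window,
condition classification, database mapping, cis-splice interpretation,
β-cell-enrichment filtering, PTM validation and HLA restriction — and
returns the annotated peptide reports plus the repertoire statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd
from Bio.SeqRecord import SeqRecord

from . import (
    cis_splice,
    hla_restriction,
    psm_pipeline,
    ptm_analysis,
    repertoire_stats,
    synthetic_data,
    variant_db,
)
from .synthetic_data import FixtureConfig


@dataclass
class Fixture:
    """The full synthetic study with its ground truth."""

    config: FixtureConfig
    proteome: list[SeqRecord]
    annotations: pd.DataFrame
    isoforms: list[variant_db.IsoformRecord]
    isoform_truth: pd.DataFrame
    planted_stretches: list
    psms: pd.DataFrame
    peptide_truth: pd.DataFrame
    ranks: pd.DataFrame
    ptm_spectra: list[dict] = field(default_factory=list)


def make_fixture(config: FixtureConfig | None = None, with_spectra: bool = True) -> Fixture:
    config = config or FixtureConfig()
    proteome, ann = synthetic_data.generate_proteome(config)
    isoforms, iso_truth, stretches = synthetic_data.generate_isoforms(proteome, ann, config)
    psms, truth = synthetic_data.generate_psm_table(proteome, ann, stretches, config)
    ranks = synthetic_data.generate_rank_table(truth, config)
    spectra = synthetic_data.validation_spectra(truth, config) if with_spectra else []
    return Fixture(config, proteome, ann, isoforms, iso_truth, stretches,
                   psms, truth, ranks, spectra)


@dataclass
class PipelineResult:
    reports: pd.DataFrame
    funnel: pd.DataFrame
    restriction_calls: dict
    locus_tally: pd.DataFrame
    protein_counts: pd.DataFrame
    motif_tests: pd.DataFrame
    abundance: pd.DataFrame
    abundance_tests: pd.DataFrame
    fdr_threshold: float


def build_database(fixture: Fixture) -> list[SeqRecord]:
    """Search database from the fixture's isoforms via the filter cascade."""
    survivors, _ = variant_db.run_filter_cascade(fixture.isoforms)
    by_acc = {r.id: str(r.seq) for r in fixture.proteome}
    stretches = []
    for iso in survivors:
        found = variant_db.extract_alternative_sequences(
            by_acc[iso.canonical_accession], iso.translation, isoform_id=iso.isoform_id
        )
        stretches.extend((st, iso.canonical_accession) for st in found)
    return variant_db.build_search_database(fixture.proteome, stretches)


def run_pipeline(
    psms: pd.DataFrame,
    search_db: Sequence[SeqRecord],
    annotations: pd.DataFrame,
    ranks: pd.DataFrame,
    ptm_spectra: Sequence[dict] = (),
    fdr: float = 0.01,
    variant_fdr: float = 0.05,
    fragment_tol_da: float = 0.03,
    il_equivalent: bool = True,
) -> PipelineResult:
    funnel = []

    # peptide-level FDR; variant-mapped peptides admitted at the relaxed level
    all_target_peps = psms.loc[~psms.is_decoy, "peptide"].unique().tolist()
    pre_map = psm_pipeline.map_peptides(all_target_peps, search_db)
    variant_peps = set(pre_map.loc[pre_map.category == "variant", "peptide"])
    threshold, _ = psm_pipeline.compute_fdr_cutoff(psms, fdr)
    retained = psm_pipeline.apply_fdr(psms, fdr=fdr, variant_fdr=variant_fdr,
                                      variant_peptides=variant_peps)
    funnel.append(("input_peptides", psms.loc[~psms.is_decoy, "peptide"].nunique()))
    funnel.append(("fdr_retained", len(retained)))

    # length window
    kept, frac = psm_pipeline.filter_length(retained.peptide)
    funnel.append(("length_retained", len(kept)))
    kept_set = set(kept)

    # condition classes from surviving occurrences
    occ = psms[~psms.is_decoy & psms.peptide.isin(kept_set)]
    cond = psm_pipeline.classify_condition(occ)

    # mapping and category routing
    mapped = psm_pipeline.map_peptides(kept, search_db)
    mods_by_pep = (
        occ.groupby("peptide")["modifications"].first().map(synthetic_data.parse_modifications)
    )

    reference = [r for r in search_db if not variant_db.is_variant_entry(r.id)]
    rows = []
    for row in mapped.itertuples(index=False):
        category = row.category
        mappings = row.mappings
        mods = mods_by_pep.get(row.peptide, [])
        if category == "conventional" and mods:
            category = "ptm"
        splice_candidates: list = []
        if category == "unexplained":
            splice_candidates = cis_splice.search_proteome(
                row.peptide, reference, annotations, il_equivalent=il_equivalent
            )
            if splice_candidates:
                category = "cis-spliced-candidate"
        rows.append({
            "peptide": row.peptide,
            "category": category,
            "condition_class": cond.get(row.peptide),
            "mappings": mappings,
            "splice_candidates": splice_candidates,
            "modifications": mods,
        })
    reports = pd.DataFrame(rows)
    funnel.append(("cis_spliced_candidates", int((reports.category == "cis-spliced-candidate").sum())))
    funnel.append(("unexplained_dropped", int((reports.category == "unexplained").sum())))
    reports = reports[reports.category != "unexplained"].reset_index(drop=True)

    # beta-cell-enrichment filter (mapped categories; cis candidates were
    # already filtered inside search_proteome)
    mapped_mask = reports.category.isin(["conventional", "variant", "ptm"])
    enriched = psm_pipeline.apply_enrichment_filter(reports[mapped_mask], annotations)
    spliced = reports[~mapped_mask].copy()
    spliced["beta_cell_enriched"] = True
    reports = pd.concat([enriched, spliced], ignore_index=True)
    funnel.append(("enrichment_retained", len(reports)))

    # PTM annotation and validation
    reports["ptm_name"] = reports.modifications.map(lambda ms: ms[0][1] if ms else "")
    reports["ptm_position"] = reports.modifications.map(lambda ms: ms[0][0] if ms else 0)
    verdicts = {}
    if ptm_spectra:
        for entry in ptm_spectra:
            verdicts[entry["peptide"]] = ptm_analysis.validate_ptm(
                entry["observed"], entry["synthetic_modified"], entry["synthetic_native"],
                fragment_tol_da=fragment_tol_da,
            )
    reports["ptm_verdict"] = reports.peptide.map(lambda p: verdicts.get(p, ""))

    # accessions for downstream statistics
    def _accessions(row) -> list[str]:
        if row.category == "cis-spliced-candidate":
            return sorted({c.parent_accession for c in row.splice_candidates})
        accs = []
        for m in row.mappings:
            acc = m.accession
            if m.is_variant:
                acc = variant_db.parse_variant_header(acc)["canonical_accession"]
            accs.append(acc)
        return sorted(set(accs))

    reports["accessions"] = [
        _accessions(row) for row in reports.itertuples(index=False)
    ]

    # HLA restriction on retained peptides
    retained_ranks = ranks[ranks.peptide.isin(reports.peptide)]
    calls = hla_restriction.call_restrictions(retained_ranks)
    cond_map = dict(zip(reports.peptide, reports.condition_class))
    tally = hla_restriction.tally_by_locus(
        {p: c for p, c in calls.items() if p in cond_map}, cond_map
    )

    # cleavage motifs (peptides with reference-entry context)
    def _motif(row) -> str:
        ctx = [m.next_residue for m in row.mappings if not m.is_variant]
        if not ctx:
            return "none"
        return repertoire_stats.classify_motif(row.peptide, ctx)

    reports["motif_class"] = [
        _motif(row) for row in reports.itertuples(index=False)
    ]
    motif_tests = repertoire_stats.motif_enrichment_test(reports)

    # per-protein counts and abundance aggregation
    counts = repertoire_stats.count_by_protein(reports)
    occ_retained = occ[occ.peptide.isin(reports.peptide)].dropna(subset=["abundance"])
    granule_by_acc = dict(zip(annotations.accession, annotations.granule))
    granule_flags = {
        row.peptide: any(granule_by_acc.get(a, False) for a in row.accessions)
        for row in reports.itertuples(index=False)
    }
    abundance, ab_tests = repertoire_stats.aggregate_abundance(
        occ_retained, n_replicates=4, granule_flags=granule_flags
    )

    funnel_df = pd.DataFrame(funnel, columns=["stage", "n"])
    return PipelineResult(
        reports=reports, funnel=funnel_df, restriction_calls=calls,
        locus_tally=tally, protein_counts=counts, motif_tests=motif_tests,
        abundance=abundance, abundance_tests=ab_tests, fdr_threshold=threshold,
    )


def run_fixture(config: FixtureConfig | None = None, with_spectra: bool = True) -> tuple[Fixture, PipelineResult]:
    """Generate a fixture, build its database, and run the full pipeline."""
    fixture = make_fixture(config, with_spectra=with_spectra)
    db = build_database(fixture)
    result = run_pipeline(
        fixture.psms, db, fixture.annotations, fixture.ranks,
        ptm_spectra=fixture.ptm_spectra,
    )
    return fixture, result
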