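"""Plain-text readers and writers for the pipeline's tables.

Everything is TSV, FASTA or MGF so that fixtures and results stay
human-inspectable. The isoform table splits into a metadata TSV and a
long-format TPM TSV (isoform_id, group, sample_index, tpm).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import synthetic_data, variant_db


def write_annotations(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("pancreas_evidence", "endocrine_enriched", "granule"):
        df[col] = df[col].astype(bool)
    return df


def write_isoforms(isoforms: Sequence[variant_db.IsoformRecord], meta_path, tpm_path) -> None:
    meta, tpm_rows = [], []
    for iso in isoforms:
        fc, p = iso.de_stats if iso.de_stats is not None else (np.nan, np.nan)
        meta.append({
            "isoform_id": iso.isoform_id, "gene_id": iso.gene_id,
            "canonical_accession": iso.canonical_accession,
            "canonical_flag": iso.canonical_flag,
            "coding_sequence": iso.coding_sequence, "translation": iso.translation,
            "fold_change": fc, "adj_p": p,
        })
        for group, vec in iso.tpm.items():
            for i, v in enumerate(vec):
                tpm_rows.append({"isoform_id": iso.isoform_id, "group": group,
                                 "sample_index": i, "tpm": v})
    pd.DataFrame(meta).to_csv(meta_path, sep="\t", index=False)
    pd.DataFrame(tpm_rows).to_csv(tpm_path, sep="\t", index=False)


def read_isoforms(meta_path, tpm_path) -> list[variant_db.IsoformRecord]:
    meta = pd.read_csv(meta_path, sep="\t")
    tpm = pd.read_csv(tpm_path, sep="\t")
    grouped = {
        iso_id: {g: gg.sort_values("sample_index").tpm.to_numpy() for g, gg in grp.groupby("group")}
        for iso_id, grp in tpm.groupby("isoform_id")
    }
    out = []
    for row in meta.itertuples(index=False):
        de = None
        if not (pd.isna(row.fold_change) or pd.isna(row.adj_p)):
            de = (float(row.fold_change), float(row.adj_p))
        out.append(variant_db.IsoformRecord(
            isoform_id=row.isoform_id, gene_id=row.gene_id,
            canonical_accession=row.canonical_accession,
            canonical_flag=bool(row.canonical_flag),
            coding_sequence=row.coding_sequence, translation=row.translation,
            tpm=grouped.get(row.isoform_id, {}), de_stats=de,
        ))
    return out


def write_psms(psms: pd.DataFrame, path) -> None:
    psms.to_csv(path, sep="\t", index=False)


def read_psms(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=True)
    df["modifications"] = df["modifications"].fillna("")
    df["is_decoy"] = df["is_decoy"].astype(bool)
    return df


def read_ranks(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_fixture(fixture, outdir) -> None:
    """Write a whole synthetic study as plain-text files."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    variant_db.write_fasta(fixture.proteome, out / "proteome.fasta")
    write_annotations(fixture.annotations, out / "annotations.tsv")
    write_isoforms(fixture.isoforms, out / "isoforms.tsv", out / "tpm.tsv")
    write_psms(fixture.psms, out / "psms.tsv")
    fixture.ranks.to_csv(out / "ranks.tsv", sep="\t", index=False)
    fixture.peptide_truth.to_csv(out / "ground_truth_peptides.tsv", sep="\t", index=False)
    fixture.isoform_truth.to_csv(out / "ground_truth_isoforms.tsv", sep="\t", index=False)
    if fixture.ptm_spectra:
        synthetic_data.write_mgf([e["observed"] for e in fixture.ptm_spectra],
                                 out / "observed.mgf")
        synthetic_data.write_mgf([e["synthetic_modified"] for e in fixture.ptm_spectra],
                                 out / "synthetic_modified.mgf")
        synthetic_data.write_mgf([e["synthetic_native"] for e in fixture.ptm_spectra],
                                 out / "synthetic_native.mgf")


def write_result(result, outdir) -> None:
    """Write pipeline outputs (reports and statistics) as TSVs."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reports = result.reports.copy()
    reports["accessions"] = reports.accessions.map(";".join)
    reports["n_mappings"] = result.reports.mappings.map(len)
    reports = reports.drop(columns=["mappings", "splice_candidates", "modifications"])
    reports.to_csv(out / "peptide_reports.tsv", sep="\t", index=False)
    result.funnel.to_csv(out / "funnel.tsv", sep="\t", index=False)
    result.locus_tally.to_csv(out / "locus_tally.tsv", sep="\t", index=False)
    result.protein_counts.to_csv(out / "protein_counts.tsv", sep="\t", index=False)
    result.motif_tests.to_csv(out / "motif_tests.tsv", sep="\t", index=False)
    result.abundance.to_csv(out / "abundance.tsv", sep="\t", index=False)
    result.abundance_tests.to_csv(out / "abundance_tests.tsv", sep="\t", index=False)
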