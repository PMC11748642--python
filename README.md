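# isletpep

Analysis toolkit for the HLA class I immunopeptidome of pancreatic β
cells under inflammatory stress, built for the question of how type I
interferon reshapes the peptide repertoire that β cells display to
CD8⁺ T cells — in particular the preferential presentation of HLA-B
ligands under IFN-α.

It is aimed at computational immunologists working with eluted-ligand
mass-spectrometry data who need a reproducible, testable version of the
desk-side analysis that normally lives in one-off scripts: building a
variant-augmented search database from transcript isoforms, filtering
peptide-spectrum matches, validating post-translational modifications
(PTMs), interpreting non-templated peptides as proteasomal cis-spliced
products, and computing restriction and repertoire statistics.

## What it does

**Variant search database** (`isletpep.variant_db`). Transcript isoforms
quantified in islets, thymic mTECs, and 12 control tissues pass a
four-stage expression cascade (all inequalities strict):

1. TPM > 0.5 in ≥ 20% of islet samples,
2. median islet TPM > 5 (basal or IFN),
3. median mTEC TPM < 0.1 (either subset) or islet/mTEC fold > 100,
4. islet median > 10× the highest control-tissue median
   (neuroendocrine tissues are disallowed as controls).

Surviving isoform translations are globally aligned to their canonical
proteins (BLOSUM100, affine gaps) and maximal runs of non-canonical
residues — insertions, deletion junctions, frameshifted tails — are
appended to the reference FASTA with 13 residues of flanking context, so
every novel 8–14mer is searchable.

**PSM funnel** (`isletpep.psm_pipeline`). Peptide-level target–decoy FDR
(ratio estimator, 1% main level, 5% admitted for mRNA-variant matches),
the 8–14 aa HLA-I length window, per-condition classification
(basal / IFN / both), exact mapping onto the combined database, and a
β-cell-enriched-expression filter on source proteins.

**PTM arm** (`isletpep.ptm_analysis`). Per-PTM condition enrichment,
triage of candidates worth chemical synthesis (excludes artifact-prone
modifications and terminal positions), theoretical singly-charged b/y
ions, and a dual spectral comparison against synthetic modified and
native references yielding biological / artifactual / unvalidated
verdicts.

**Cis-splice search** (`isletpep.cis_splice`). Non-templated peptides
are explained as ligations of two non-contiguous fragments of one parent
protein, in forward or reverse order, with optional I/L equivalence
(indistinguishable by mass). Verified against an exhaustive brute-force
fragment-pair scan.

**Restriction and statistics** (`isletpep.hla_restriction`,
`isletpep.repertoire_stats`). Binder calls at percentile rank < 2 over a
seven-allele panel, single restriction when the second-best rank is
≥ 3-fold the best, per-locus tallies with Fisher exact tests, source-
protein log₂ fold changes (pseudocount 0.5), chymotrypsin-like cleavage
motifs (C-terminal Y/F/W or M/L, not followed by proline), abundance
aggregation with Wilcoxon comparisons, and repertoire overlaps.

**Assays** (`isletpep.assays`). Percent peptide-specific lysis from
dual-dye flow counts, and comparative-ΔCt (2^−ΔΔCt) relative expression.

**Synthetic studies** (`isletpep.synthetic_data`). Every input above can
be generated with planted ground truth — including a 5× IFN-conditional
HLA-B presentation weight — so the full pipeline is testable without any
external data. One seed fixes all outputs bit-for-bit.

## Worked example

```python
from isletpep import FixtureConfig, run_fixture

fixture, result = run_fixture(FixtureConfig(seed=1))
print(result.funnel.to_string(index=False))
print(result.locus_tally[["locus", "frac_basal", "frac_ifn", "fisher_p"]]
      .to_string(index=False))
```

```
                 stage   n
        input_peptides 554
          fdr_retained 554
       length_retained 527
cis_spliced_candidates   8
   unexplained_dropped   0
   enrichment_retained 454
                locus  frac_basal  frac_ifn      fisher_p
                    A    0.465812  0.378378  4.833716e-02
                    B    0.188034  0.402027  9.387453e-08
                    C    0.290598  0.195946  1.227042e-02
                    E    0.055556  0.023649  6.466464e-02
ambiguous-multi-locus    0.000000  0.000000  1.000000e+00
```

Reading the output: of 554 peptides entering the funnel, 454 survive to
the report stage; the planted IFN-conditional HLA-B weight surfaces as
an HLA-B binder share rising from ~19% of the basal-presented set to
~40% of the IFN-presented set, with a Fisher exact p ≈ 1e-7 — the same
qualitative signature seen in real IFN-α-treated β cells.

The same steps are scriptable from a shell:

```bash
isletpep fixtures make --seed 1 --out fx/
isletpep variantdb build --isoforms fx/isoforms.tsv --tpm fx/tpm.tsv \
    --ref fx/proteome.fasta --out fx/db.fasta
isletpep run --psm fx/psms.tsv --db fx/db.fasta \
    --annotations fx/annotations.tsv --ranks fx/ranks.tsv --out fx/results/
```

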