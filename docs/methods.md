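# Methods

## The analysis in one paragraph

β cells exposed to IFN-α up-regulate HLA class I and broaden the peptide
repertoire they present. The pipeline reconstructs that observation
computationally: peptide-spectrum matches (PSMs) from an
eluted-ligand search are filtered to a confident peptide set, each
peptide is explained against a search database consisting of the
reference proteome plus translated mRNA-isoform variants, peptides with
no templated explanation are tested as proteasomal cis-spliced products,
PTM assignments are validated spectrally, HLA restrictions are assigned
from predictor ranks, and the per-locus presentation balance between
untreated and IFN-α-treated conditions is compared with Fisher exact
tests.

## Expression filter cascade

Transcript isoforms carry TPM vectors for six islet samples per
condition (basal, IFN), five mTEC samples per HLA-II subset, and three
samples for each of 12 control tissues. The four filters are pure
functions applied in sequence; each returns survivors plus a complete
pass/fail log:

| stage | rule | default |
|---|---|---|
| expressed | TPM > 0.5 in ≥ 20% of pooled islet samples | 0.5 TPM, 20% |
| islet expression | median TPM > 5, basal **or** IFN | 5 TPM |
| mTEC escape | either mTEC median < 0.1, **or** islet/mTEC fold > 100 | 0.1 TPM, 100× |
| islet enrichment | islet median > 10× the control aggregate | 10× |

All inequalities are strict. Fold changes use a pseudocount ε = 0.01 TPM
in the denominator; without it a zero mTEC or control median makes the
ratio undefined, and 0.01 is an order of magnitude below the smallest
threshold in play, so it cannot flip a decision anywhere near a
boundary. The islet median is the larger of the two condition medians;
the mTEC median is the smaller of the two subset medians (the
permissive reading of "either"). The control aggregate is the **maximum**
control-tissue median — the conservative reading of "compared to 12
control tissues" — with a median-of-medians mode available
(`control_mode="median"`). Brain, testis, adrenal gland and thyroid are
rejected as control tissues because neuroendocrine expression overlaps
islet programs.

Differential-expression flags (fold change > 1.50, adjusted p < 0.05)
are evaluated from precomputed statistics; no model is fitted here.

## Alternative-sequence extraction

Isoform translations are globally aligned to the canonical protein with
the BLOSUM100 substitution matrix (shipped as a plain-text table) and
affine gap penalties (open 11, extend 1 — conventional protein-alignment
defaults). From the alignment we take maximal runs of isoform residues
that are inserted or substituted, plus internal deletion junctions, and
extend each by 13 residues (max peptide length − 1) of identical
context per side: this guarantees that every 8–14mer overlapping novel
sequence occurs in some emitted stretch. A stretch whose full sequence
still occurs in the canonical protein is dropped — this is exactly the
pure-truncation case, which creates no novel peptides. Variant FASTA
headers encode isoform, canonical accession, origin
(insertion / junction / frameshift-tail), the stretch span (1-based
inclusive) and the novel-core span within the stretch (0-based
half-open), and round-trip through `parse_variant_header`.

## FDR control

PSMs are collapsed to peptide level (best score per peptide) because the
error rate of interest is per reported peptide. The estimator is the
separate-search decoy/target ratio FDR(t) = D(t)/T(t) with no +1
correction; the retained set uses the lowest score threshold achieving
FDR ≤ α, with score ties kept (inclusive tie-breaking). Variant-matched
peptides may additionally enter at a relaxed 5% level, mirroring the
asymmetric cost of missing a genuinely novel sequence. The choice of a
separate-decoy (rather than concatenated-competition) estimator is an
assumption; the calibration test plants false targets and decoys from
one null distribution and checks that the realized false proportion
among retained peptides stays within 2× the nominal 1% level.

## Cis-splice enumeration

A peptide of length m is explained at every split point k
(min fragment ≤ k ≤ m − min fragment) by locating prefix and suffix in
the parent. Minimum fragment length is 2: single-residue fragments are
chemically implausible as ligation substrates and quadratically inflate
the candidate space. Fragments never overlap. A forward pair abutting
with gap 0 reconstructs a contiguous substring and is rejected as
templated; a reverse pair with gap 0 is a genuine rearrangement and is
kept. Only single parents are searched — cis-splicing is defined as
fusion of fragments from one protein; trans-splicing is out of scope.
I/L equivalence is applied only here (fragment masses cannot distinguish
them); candidates that needed any I↔L substitution are flagged.
Candidate ordering: best predictor rank of the peptide, then total
inter-fragment gap ascending, then parent accession — deterministic by
construction.

## PTM analysis

Modification mass shifts are frozen from the Unimod reference list into
`data/ptm_definitions.tsv` (oxidation +15.994915, sulphone +31.989829,
acetylation +42.010565, deamidation +0.984016, phosphorylation
+79.966331, cysteinylation +119.004099, glutathionylation +305.068156).
Sulphone is *not* flagged artifact-prone although it is chemically a
double oxidation: it survives deliberate synthesis and was retained as a
validated class, whereas single oxidation (M) arises spontaneously
during acquisition and is excluded from triage.

Per-PTM condition classes use distinct-peptide counts b (basal) and f
(IFN): IFN-enriched when f/(b+f) ≥ θ, basal-enriched when b/(b+f) ≥ θ,
else shared, with θ = 2/3. The trichotomy itself has no published
numeric rule; 2/3 makes a 2:1 imbalance the boundary and is
configurable.

Fragment ions are singly-protonated b/y series from standard
monoisotopic residue masses; a modification shifts every ion containing
its residue. Only charge 1 is modeled — sufficient for desk-scale
validation where the references are computed, not measured. Spectral
matching pairs peaks greedily by |Δm/z| within a Da tolerance (0.03 Da
default); `matched_fraction` is over reference peaks, and the cosine is
computed on square-root intensities with unpaired peaks contributing
zero. Match thresholds default to matched_fraction ≥ 0.6 and
cosine ≥ 0.7 — defaults, not published values. The verdict logic gives
the native reference precedence: a spectrum matching the native
synthetic peptide is artifactual regardless of the modified comparison,
because an experimentally introduced modification leaves the eluted
species native. An internal modified residue shifts exactly half of the
2(n−1) ions (n−i of the b series, i−1 of the y series), so a native
spectrum can match a modified reference at no more than 50% of peaks —
safely below the 0.6 threshold for any site.

## Restriction rules

Binders are alleles with percentile rank < 2 (strict). The single/dual
rule interprets "score difference ≥ 3-fold" as the rank ratio
second/best ≥ 3, matching rank semantics where lower is stronger; the
boundary (exactly 3) is inclusive and assigns a single allele. The rule
is scale-invariant in the ranks, which the tests verify. Dual
same-locus calls count once for their locus; dual cross-locus calls are
tallied under `ambiguous-multi-locus` and excluded from single-locus
fractions (fractional 0.5/0.5 counting would be the alternative; the
ambiguous class is reported so nothing is hidden). Locus tallies compare
the basal-presented set (classes basal ∪ both) against the IFN-presented
set (ifn ∪ both); a strict exclusive mode exists. The stringent HLA-E
set contains peptides whose *only* binder allele is E*01:01.

## Repertoire statistics

Per-protein counts use distinct peptides per condition set; a PTM
peptide with a biological verdict counts as its modified species, any
other PTM peptide collapses onto its native sequence; cis-spliced
candidates are excluded. log₂FC = log₂((n_ifn + 0.5)/(n_basal + 0.5));
the 0.5 pseudocount keeps zero counts finite and is symmetric.
Cleavage motifs classify the C-terminal residue (Y/F/W high-affinity,
M/L low-affinity) with the "not followed by proline" test passing if it
passes in any mapping; a protein-terminal context passes (nothing
follows). Abundance means treat a missing replicate as 0 over the
4 replicates — absence is non-detection in label-free data, not missing
at random. The condition comparison is a paired two-sided Wilcoxon
signed-rank on per-peptide means ("Wilcoxon test" alone is ambiguous;
signed-rank respects the pairing, and rank-sum is available); when every
paired difference is zero the test is degenerate and reported as p = 1
with an explicit flag rather than an error.

## Synthetic studies: what they emulate, and what they do not

The generator reproduces the *design* of the study: 4 biological
replicates × 2 conditions, 6 islet RNA-seq samples per condition, 5 mTEC
samples per subset, 12 control tissues, the seven-allele ECN90 panel,
and a planted 5× IFN-conditional weight on both HLA-B alleles. The
default peptide universe is 500 conventional peptides — the scale of the
real repertoire (~500–670 presented peptides per condition). Scores are
drawn from well-separated truncated normals for targets and decoys;
abundances are log-normal with multiplicative condition effects; spectra
are theoretical b/y ions with Bernoulli peak dropout and Gaussian m/z
jitter. For every downstream filter the fixture plants at least one
passing and one failing instance, and ground-truth tables record every
intended outcome.

Two constructions serve identifiability, not biology: planted insertion
cores and frameshift tails are drawn from letters absent in the local
canonical context, and junction boundaries are chosen so no flanking
residue recurs inside the deleted window. This makes the planted event
the unique optimal alignment, so "extraction recovers the plant" is a
well-defined check rather than a statement about co-optimal alignments.

What passing tests do **not** show: the generator has no chromatography,
charge states, isotope envelopes, shared peptides between proteins at
realistic rates, or search-engine score miscalibration. Real data adds
all of these; the tests establish correctness of the rules and
statistics, not field performance.

## Numerical choices and degenerate inputs

- Coordinates are 0-based half-open internally and 1-based inclusive in
  reports and FASTA headers.
- I and L are distinct everywhere except the cis-splice search and the
  optional I/L-equivalent overlap mode.
- FDR requires at least one decoy and one target; it raises otherwise.
- Empty spectra are rejected; noiseless generated spectra always retain
  at least one peak.
- Fisher exact tests use the two-sided hypergeometric formulation
  (verified against exhaustive summation); Wilcoxon exact p-values are
  verified against full sign-vector enumeration for n ≤ 12.
- The lysis formula errors on a zero unpulsed count (undefined survival
  ratio) and reports the raw percentage alongside a [0, 100]-clipped
  display value.

## Problem sizes

Default test and acceptance runs use the 500-peptide universe,
24 proteins of 90–160 residues, 16 isoforms, 200 planted-null FDR
fixtures of 10⁴ peptides, 500 random splice instances against parents of
≤ 40 residues, and 50 seeded end-to-end runs for the skew property. The
whole suite completes in well under a minute on one CPU.

## Known limitations

- Only singly-charged fragment ions; no PTM site-localization scoring.
- The separate-decoy FDR estimator is an assumption about the upstream
  search; a concatenated-competition variant would need its own
  calibration.
- Multi-mapping peptides pass the enrichment filter if *any* mapping
  qualifies (sensitivity-first); a strict all-mappings mode is not
  implemented.
- The learned re-scoring of splice candidates used downstream in real
  analyses is out of scope; ranking here uses predictor ranks and
  structural tie-breaks only.
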