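"""Construction of the augmented peptide-search database.

Transcript isoforms quantified in pancreatic islets (basal and
IFN-α-treated), thymic mTECs, and a panel of control tissues are pushed
through a four-stage expression filter cascade:

1. expressed        — TPM > 0.5 in at least 20% of islet samples;
2. islet expression — median TPM > 5 in islets under basal OR IFN
   conditions;
3. mTEC escape      — median TPM < 0.1 in either mTEC subset, or a
   > 100-fold islet/mTEC median ratio (low thymic expression means the
   transcript escapes central tolerance induction);
4. islet enrichment — > 10-fold islet median over the highest of 12
   control-tissue medians; neuroendocrine tissues (brain, testis,
   adrenal gland, thyroid) must not be used as controls.

Surviving isoform translations are globally aligned to their canonical
protein with the BLOSUM100 substitution matrix and affine gaps, and
maximal runs of non-canonical residues (insertions, deletion junctions,
frameshifted tails) are extracted with enough identical flanking context
that every 8–14mer spanning a novel junction is contained in some
stretch. Stretches are appended to the reference FASTA to form the
combined search database.

All thresholds are strict inequalities. Fold changes use a configurable
pseudocount (default 0.01 TPM) in the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NEUROENDOCRINE_TISSUES = frozenset({"brain", "testis", "adrenal gland", "thyroid"})

#: default fold-change pseudocount, in TPM
EPSILON = 0.01


@dataclass
class IsoformRecord:
    """A transcript isoform with its translation and TPM vectors.

    ``tpm`` maps sample-group names to TPM vectors. Groups
    ``islet_basal``, ``islet_ifn``, ``mtec_lo`` and ``mtec_hi`` are
    required by the filters; every other key is treated as a control
    tissue. ``de_stats`` optionally carries a precomputed linear-scale
    fold change and BH-adjusted p-value from a differential-expression
    fit (the fit itself is upstream of this package).
    """

    isoform_id: str
    gene_id: str
    canonical_accession: str
    canonical_flag: bool
    coding_sequence: str
    translation: str
    tpm: dict[str, np.ndarray] = field(default_factory=dict)
    de_stats: tuple[float, float] | None = None  # (fold_change, adj_p)

    def __post_init__(self) -> None:
        self.tpm = {k: np.asarray(v, dtype=float) for k, v in self.tpm.items()}
        for k, v in self.tpm.items():
            if (v < 0).any():
                raise ValueError(f"negative TPM in group {k!r} of {self.isoform_id}")

    def control_groups(self) -> list[str]:
        islet_mtec = {"islet_basal", "islet_ifn", "mtec_lo", "mtec_hi"}
        return [k for k in self.tpm if k not in islet_mtec]


@dataclass(frozen=True)
class AlternativeStretch:
    """A run of non-canonical residues in an isoform translation.

    ``aa_sequence`` is the stretch with identical flanking context;
    ``core_start``/``core_end`` delimit the novel residues within the
    stretch (0-based half-open; empty for a deletion junction).
    ``start``/``end`` locate the stretch within the isoform translation.
    """

    isoform_id: str
    aa_sequence: str
    origin: str  # insertion | junction | frameshift-tail
    start: int
    end: int
    core_start: int
    core_end: int
    flank_left: int
    flank_right: int

    @property
    def core(self) -> str:
        return self.aa_sequence[self.core_start:self.core_end]


# ---------------------------------------------------------------------------
# Filter cascade


def _log_frame(results: list[tuple[str, bool, str]]) -> pd.DataFrame:
    return pd.DataFrame(results, columns=["isoform_id", "passed", "detail"])


def filter_expressed(
    isoforms: Sequence[IsoformRecord], min_tpm: float = 0.5, min_fraction: float = 0.2
) -> tuple[list[IsoformRecord], pd.DataFrame]:
    """Keep isoforms with TPM > 0.5 in at least 20% of islet samples."""
    survivors, log = [], []
    for iso in isoforms:
        pooled = np.concatenate([iso.tpm.get("islet_basal", []), iso.tpm.get("islet_ifn", [])])
        if pooled.size == 0:
            raise ValueError(f"{iso.isoform_id}: empty islet TPM vectors")
        frac = float((pooled > min_tpm).mean())
        ok = frac >= min_fraction
        log.append((iso.isoform_id, ok, f"fraction_above={frac:.3f}"))
        if ok:
            survivors.append(iso)
    return survivors, _log_frame(log)


def filter_islet_expression(
    isoforms: Sequence[IsoformRecord], min_median: float = 5.0
) -> tuple[list[IsoformRecord], pd.DataFrame]:
    """Keep isoforms whose islet median TPM exceeds 5 in basal or IFN."""
    survivors, log = [], []
    for iso in isoforms:
        mb = float(np.median(iso.tpm["islet_basal"]))
        mf = float(np.median(iso.tpm["islet_ifn"]))
        ok = mb > min_median or mf > min_median
        log.append((iso.isoform_id, ok, f"median_basal={mb:.3g};median_ifn={mf:.3g}"))
        if ok:
            survivors.append(iso)
    return survivors, _log_frame(log)


def filter_mtec(
    isoforms: Sequence[IsoformRecord],
    max_median: float = 0.1,
    min_fold_decrease: float = 100.0,
    epsilon: float = EPSILON,
) -> tuple[list[IsoformRecord], pd.DataFrame]:
    """Keep isoforms silent in mTECs or strongly decreased vs islet.

    Pass when either mTEC subset has a median TPM < 0.1, or when the
    islet median (larger of basal/IFN) exceeds the smaller mTEC median
    more than 100-fold.
    """
    survivors, log = [], []
    for iso in isoforms:
        lo = float(np.median(iso.tpm["mtec_lo"]))
        hi = float(np.median(iso.tpm["mtec_hi"]))
        islet = max(float(np.median(iso.tpm["islet_basal"])), float(np.median(iso.tpm["islet_ifn"])))
        fold = islet / (min(lo, hi) + epsilon)
        ok = lo < max_median or hi < max_median or fold > min_fold_decrease
        log.append((iso.isoform_id, ok, f"mtec_lo={lo:.3g};mtec_hi={hi:.3g};fold={fold:.3g}"))
        if ok:
            survivors.append(iso)
    return survivors, _log_frame(log)


def filter_islet_enrichment(
    isoforms: Sequence[IsoformRecord],
    min_fold: float = 10.0,
    epsilon: float = EPSILON,
    control_mode: str = "max",
) -> tuple[list[IsoformRecord], pd.DataFrame]:
    """Keep isoforms > 10-fold enriched in islet over control tissues.

    ``control_mode`` selects the aggregate in the denominator: ``max``
    (islet median against the highest control-tissue median; the
    conservative default) or ``median`` (median of control medians).
    """
    survivors, log = [], []
    for iso in isoforms:
        controls = iso.control_groups()
        bad = NEUROENDOCRINE_TISSUES & {c.lower() for c in controls}
        if bad:
            raise ValueError(f"neuroendocrine tissue(s) used as control: {sorted(bad)}")
        if not controls:
            raise ValueError(f"{iso.isoform_id}: no control-tissue TPM groups")
        medians = [float(np.median(iso.tpm[c])) for c in controls]
        agg = max(medians) if control_mode == "max" else float(np.median(medians))
        islet = max(float(np.median(iso.tpm["islet_basal"])), float(np.median(iso.tpm["islet_ifn"])))
        fold = islet / (agg + epsilon)
        ok = fold > min_fold
        log.append((iso.isoform_id, ok, f"islet={islet:.3g};control_{control_mode}={agg:.3g};fold={fold:.3g}"))
        if ok:
            survivors.append(iso)
    return survivors, _log_frame(log)


def call_differential(
    isoforms: Sequence[IsoformRecord], min_fc: float = 1.50, max_adj_p: float = 0.05
) -> pd.DataFrame:
    """Flag isoforms as differentially expressed from precomputed stats.

    A transcript is DE when its linear fold change exceeds 1.50 and its
    adjusted p-value is below 0.05. No model is fitted here. Missing
    stats flag False with a warning detail.
    """
    rows = []
    for iso in isoforms:
        if iso.de_stats is None:
            rows.append((iso.isoform_id, False, "missing de_stats"))
            continue
        fc, p = iso.de_stats
        rows.append((iso.isoform_id, fc > min_fc and p < max_adj_p, f"fc={fc};adj_p={p}"))
    return pd.DataFrame(rows, columns=["isoform_id", "de", "detail"])


def run_filter_cascade(
    isoforms: Sequence[IsoformRecord], epsilon: float = EPSILON, control_mode: str = "max"
) -> tuple[list[IsoformRecord], pd.DataFrame]:
    """Apply the four expression filters in sequence.

    Returns survivors and a long log with one row per (isoform, stage)
    up to the stage where the isoform dropped out.
    """
    stages = [
        ("expressed", lambda xs: filter_expressed(xs)),
        ("islet_expression", lambda xs: filter_islet_expression(xs)),
        ("mtec", lambda xs: filter_mtec(xs, epsilon=epsilon)),
        ("islet_enrichment", lambda xs: filter_islet_enrichment(xs, epsilon=epsilon, control_mode=control_mode)),
    ]
    current = list(isoforms)
    logs = []
    for name, fn in stages:
        current, log = fn(current)
        log.insert(0, "stage", name)
        logs.append(log)
    return current, pd.concat(logs, ignore_index=True)


# ---------------------------------------------------------------------------
# Alignment and alternative-sequence extraction


def load_blosum100() -> substitution_matrices.Array:
    """The standard BLOSUM100 substitution matrix, shipped as a table."""
    with resources.files("isletpep.data").joinpath("blosum100.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0)
    alphabet = "".join(df.index)
    m = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            m[a, b] = float(df.loc[a, b])
    return m


_ALIGNER: Align.PairwiseAligner | None = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = load_blosum100()
        a.open_gap_score = -11.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def extract_alternative_sequences(
    canonical_aa: str,
    isoform_aa: str,
    isoform_id: str = "",
    min_peptide_len: int = 8,
    max_peptide_len: int = 14,
) -> list[AlternativeStretch]:
    """Alternative amino-acid stretches of an isoform vs its canonical protein.

    The two translations are globally aligned (BLOSUM100, affine gaps);
    maximal runs of isoform residues that are inserted or substituted —
    and internal deletion junctions — are reported, each extended by
    ``max_peptide_len - 1`` residues of identical context per side so
    that every 8–14mer overlapping novel sequence is contained in some
    stretch. Stretches whose full sequence still occurs in the canonical
    protein (e.g. a plain truncation) are dropped.
    """
    if not canonical_aa or not isoform_aa:
        raise ValueError("empty sequence")
    if canonical_aa == isoform_aa:
        return []
    flank = max_peptide_len - 1
    aln = _aligner().align(canonical_aa, isoform_aa)[0]
    can_idx, iso_idx = aln.indices  # -1 marks a gap in that sequence

    n_iso = len(isoform_aa)
    novel = np.zeros(n_iso, dtype=bool)  # inserted or substituted isoform residues
    junctions: list[int] = []  # isoform position following an internal deletion
    pending_deletion = False
    for ci, ii in zip(can_idx, iso_idx):
        if ii == -1:  # canonical residue deleted in isoform
            pending_deletion = True
            continue
        if pending_deletion:
            if 0 < ii < n_iso:
                junctions.append(int(ii))
            pending_deletion = False
        if ci == -1 or canonical_aa[ci] != isoform_aa[ii]:
            novel[ii] = True

    stretches: list[AlternativeStretch] = []

    # maximal novel runs
    runs = []
    i = 0
    while i < n_iso:
        if novel[i]:
            j = i
            while j < n_iso and novel[j]:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    for s, e in runs:
        left = min(flank, s)
        right = min(flank, n_iso - e)
        seq = isoform_aa[s - left:e + right]
        origin = "frameshift-tail" if e == n_iso else "insertion"
        stretches.append(
            AlternativeStretch(
                isoform_id=isoform_id, aa_sequence=seq, origin=origin,
                start=s - left, end=e + right,
                core_start=left, core_end=left + (e - s),
                flank_left=left, flank_right=right,
            )
        )

    # internal deletion junctions not already inside a novel run
    covered = [range(s, e) for s, e in runs]
    for p in junctions:
        if any(p in r or (p - 1) in r for r in covered):
            continue
        left = min(flank, p)
        right = min(flank, n_iso - p)
        seq = isoform_aa[p - left:p + right]
        stretches.append(
            AlternativeStretch(
                isoform_id=isoform_id, aa_sequence=seq, origin="junction",
                start=p - left, end=p + right,
                core_start=left, core_end=left,
                flank_left=left, flank_right=right,
            )
        )

    # a stretch still present verbatim in the canonical protein yields no
    # novel peptides (pure truncations end up here)
    out = [st for st in stretches if st.aa_sequence not in canonical_aa]
    out.sort(key=lambda st: st.start)
    return out


# ---------------------------------------------------------------------------
# FASTA assembly

VARIANT_TAG = "ALTSEQ"


def variant_header(stretch: AlternativeStretch, canonical_accession: str) -> str:
    """Header grammar: ``ALTSEQ|<isoform>|<canonical>|<origin>|<start>-<end>|core:<cs>-<ce>``.

    ``<start>-<end>`` is the 1-based inclusive span of the stretch
    within the isoform translation; ``core:<cs>-<ce>`` is the 0-based
    half-open novel-core span within the stretch (``cs == ce`` marks an
    empty junction core at that offset).
    """
    return (
        f"{VARIANT_TAG}|{stretch.isoform_id}|{canonical_accession}|{stretch.origin}"
        f"|{stretch.start + 1}-{stretch.end}|core:{stretch.core_start}-{stretch.core_end}"
    )


def parse_variant_header(header: str) -> dict:
    parts = header.split("|")
    if parts[0] != VARIANT_TAG or len(parts) != 6:
        raise ValueError(f"not a variant header: {header!r}")
    s, e = parts[4].split("-")
    cs, ce = parts[5].removeprefix("core:").split("-")
    return {
        "isoform_id": parts[1],
        "canonical_accession": parts[2],
        "origin": parts[3],
        "start": int(s) - 1,
        "end": int(e),
        "core_start": int(cs),
        "core_end": int(ce),
    }


def is_variant_entry(accession_or_header: str) -> bool:
    return accession_or_header.startswith(VARIANT_TAG + "|") or accession_or_header == VARIANT_TAG


def build_search_database(
    reference: Sequence[SeqRecord],
    stretches: Sequence[tuple[AlternativeStretch, str]],
    extra_entries: Sequence[SeqRecord] = (),
) -> list[SeqRecord]:
    """Reference proteins + one entry per alternative stretch + extras.

    ``stretches`` pairs each stretch with the canonical accession of its
    source gene (used downstream by the expression filter). Raises on
    duplicate accessions or non-amino-acid stretch sequences.
    """
    records: list[SeqRecord] = []
    seen: set[str] = set()
    for rec in reference:
        if rec.id in seen:
            raise ValueError(f"duplicate accession: {rec.id}")
        seen.add(rec.id)
        records.append(rec)
    valid = set("ACDEFGHIKLMNPQRSTVWY")
    for stretch, acc in stretches:
        if set(stretch.aa_sequence) - valid:
            raise ValueError(
                f"invalid residues in stretch from {stretch.isoform_id}: "
                f"{sorted(set(stretch.aa_sequence) - valid)}"
            )
        hid = variant_header(stretch, acc)
        if hid in seen:
            raise ValueError(f"duplicate accession: {hid}")
        seen.add(hid)
        records.append(SeqRecord(Seq(stretch.aa_sequence), id=hid, description=""))
    for rec in extra_entries:
        if rec.id in seen:
            raise ValueError(f"duplicate accession: {rec.id}")
        seen.add(rec.id)
        records.append(rec)
    return records


def write_fasta(records: Iterable[SeqRecord], path) -> None:
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list[SeqRecord]:
    return list(SeqIO.parse(path, "fasta"))
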