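"""Synthetic fixtures with planted ground truth for the whole pipeline.

Everything the analysis consumes can be generated here: a small
annotated proteome, transcript isoforms with planted expression-filter
outcomes and alternative amino-acid stretches, PSM tables across
4 biological replicates x 2 conditions (basal / IFN-α) with decoys, PTM
peptides, cis-spliced peptides and a condition-dependent HLA-B
presentation skew, predictor rank tables, and MGF peak lists for
spectral validation.

The defaults mirror the design of the study the pipeline targets: four
biological replicates per condition, six islet RNA-seq samples per
condition, five mTEC samples per subset, twelve non-neuroendocrine
control tissues, a seven-allele HLA panel, and a 5x IFN-conditional
presentation weight on the two HLA-B alleles. The generators plant, for
every downstream filter, at least one passing and one failing instance,
and record the intended outcome of each in ground-truth tables.

All randomness flows from one integer seed; outputs are bit-identical
across runs with the same configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mgf as _mgf

from . import ptm_analysis
from .ptm_analysis import SpectrumPeaks, precursor_mz, theoretical_fragments
from .variant_db import AlternativeStretch, IsoformRecord

AA = "ACDEFGHIKLMNPQRSTVWY"

#: control tissues used for the islet-enrichment filter (neuroendocrine
#: tissues are deliberately absent)
CONTROL_TISSUES = (
    "adipose tissue", "breast", "colon", "heart", "kidney", "liver",
    "lung", "lymph node", "ovary", "prostate", "skeletal muscle",
    "white blood cells",
)

ALLELES = ("A*02:01", "A*03:01", "B*40:01", "B*49:01", "C*03:04", "C*07:01", "E*01:01")

#: reverse-translation codon per amino acid (one representative codon)
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}

_LENGTH_WEIGHTS = {8: 0.10, 9: 0.35, 10: 0.25, 11: 0.15, 12: 0.08, 13: 0.05, 14: 0.02}


def _default_skew() -> dict[str, tuple[float, float]]:
    # (basal weight, IFN weight); HLA-B presentation is 5x under IFN
    return {
        "A*02:01": (0.28, 0.28),
        "A*03:01": (0.24, 0.24),
        "B*40:01": (0.05, 0.25),
        "B*49:01": (0.05, 0.25),
        "C*03:04": (0.12, 0.12),
        "C*07:01": (0.12, 0.12),
        "E*01:01": (0.02, 0.02),
    }


class FixtureConfigError(ValueError):
    pass


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study; the defaults ARE the study design."""

    seed: int = 0
    n_proteins: int = 24
    protein_length_range: tuple[int, int] = (90, 160)
    n_isoforms: int = 16
    n_replicates_per_condition: int = 4
    n_conventional_peptides: int = 500
    planted_hla_skew: dict[str, tuple[float, float]] = field(default_factory=_default_skew)
    fraction_decoy: float = 0.25
    n_ptm_peptides: int = 14
    n_splice_peptides: int = 8
    abundance_sigma: float = 0.5
    peak_dropout: float = 0.05
    mz_jitter_da: float = 0.005
    shared_fraction: float = 0.30  # peptides presented in both conditions
    replicate_detection_prob: float = 0.7
    fraction_nonenriched: float = 0.15  # peptides planted to fail the enrichment filter
    fraction_out_of_length: float = 0.05

    def validate(self) -> None:
        if self.n_proteins < 2:
            raise FixtureConfigError("n_proteins must be >= 2")
        if self.n_replicates_per_condition < 1:
            raise FixtureConfigError("n_replicates_per_condition must be >= 1")
        for name in ("fraction_decoy", "peak_dropout", "shared_fraction",
                     "fraction_nonenriched", "fraction_out_of_length",
                     "replicate_detection_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise FixtureConfigError(f"{name} must be in [0, 1]")
        lo, hi = self.protein_length_range
        if lo < 30 or hi < lo:
            raise FixtureConfigError("protein_length_range must be (lo, hi) with 30 <= lo <= hi")


# ---------------------------------------------------------------------------
# Proteome


def generate_proteome(config: FixtureConfig) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Random proteome plus an annotation table of boolean flags.

    Flags per accession: ``pancreas_evidence`` (seen in pancreas at RNA
    level or with high/medium protein-level evidence),
    ``endocrine_enriched`` (enriched in islet endocrine cells) and
    ``granule`` (secretory-granule protein). With ``n_proteins >= 8``
    every flag combination occurs at least once.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.protein_length_range
    records, rows = [], []
    combos = [(p, e, g) for p in (True, False) for e in (True, False) for g in (True, False)]
    for i in range(config.n_proteins):
        acc = f"BCP{i + 1:04d}"
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list(AA), size=length))
        if i < len(combos):
            pan, endo, gran = combos[i]
        else:
            # weight the remainder toward enriched granule proteins so that
            # most planted peptides have realistic beta-cell sources
            pan = bool(rng.random() < 0.9)
            endo = bool(rng.random() < 0.8)
            gran = bool(rng.random() < 0.5)
        records.append(SeqRecord(Seq(seq), id=acc, description=f"synthetic beta-cell protein {i + 1}"))
        rows.append({"accession": acc, "pancreas_evidence": pan,
                     "endocrine_enriched": endo, "granule": gran})
    ann = pd.DataFrame(rows)
    return records, ann


def _qualifying(ann: pd.DataFrame) -> list[str]:
    m = ann.pancreas_evidence & ann.endocrine_enriched
    return list(ann.loc[m, "accession"])


def _nonqualifying(ann: pd.DataFrame) -> list[str]:
    m = ~(ann.pancreas_evidence & ann.endocrine_enriched)
    return list(ann.loc[m, "accession"])


# ---------------------------------------------------------------------------
# Isoforms


_SCENARIOS = (
    "pass_insertion", "pass_junction", "pass_frameshift", "pass_identity",
    "fail_expressed", "fail_islet", "fail_mtec", "fail_enrichment",
)

_FLANK = 13  # max_peptide_len - 1


def _tpm(rng: np.random.Generator, level: float, n: int, jitter: float = 0.05) -> np.ndarray:
    if level == 0:
        return np.zeros(n)
    return level * np.exp(rng.normal(0.0, jitter, size=n))


def _reverse_translate(aa: str) -> str:
    return "".join(_CODON[a] for a in aa) + "TAA"


def _plant_alternative(
    rng: np.random.Generator, canonical: str, origin: str
) -> tuple[str, str, str, int]:
    """Return (isoform_aa, core, expected_stretch, stretch_start).

    Planted novel residues are drawn from letters absent in the local
    canonical context, and junction boundaries are constrained so that
    no residue flanking the deletion recurs inside the deleted window.
    Both constraints make the planted event the unique optimal global
    alignment, so extraction recovers it exactly.
    """
    L = len(canonical)
    if origin == "insertion":
        while True:
            u = int(rng.integers(20, L - 20))
            region = canonical[max(0, u - 25):u + 25]
            absent = [a for a in AA if a not in region]
            if len(absent) < 2:
                continue
            ins = "".join(rng.choice(absent, size=int(rng.integers(3, 6))))
            if ins in canonical:
                continue
            iso = canonical[:u] + ins + canonical[u:]
            start = u - _FLANK
            stretch = iso[start:u + len(ins) + _FLANK]
            if stretch in canonical:
                continue
            return iso, ins, stretch, start
    if origin == "junction":
        while True:
            u = int(rng.integers(20, L - 30))
            d = int(rng.integers(6, 11))
            window = canonical[u:u + d]
            if canonical[u - 1] in window or canonical[u + d] in window:
                continue
            iso = canonical[:u] + canonical[u + d:]
            start = u - _FLANK
            stretch = iso[start:u + _FLANK]
            if stretch in canonical:
                continue
            return iso, "", stretch, start
    if origin == "frameshift-tail":
        while True:
            k = int(rng.integers(8, 13))
            region = canonical[-(k + _FLANK + 10):]
            absent = [a for a in AA if a not in region]
            if not absent:
                continue
            tail = "".join(rng.choice(absent, size=k))
            if tail in canonical:
                continue
            iso = canonical[:L - k] + tail
            start = L - k - _FLANK
            stretch = iso[start:]
            if stretch in canonical:
                continue
            return iso, tail, stretch, start
    raise ValueError(f"unknown origin {origin!r}")


def generate_isoforms(
    proteome: Sequence[SeqRecord],
    annotations: pd.DataFrame,
    config: FixtureConfig,
) -> tuple[list[IsoformRecord], pd.DataFrame, list[tuple[AlternativeStretch, str]]]:
    """Isoforms with planted TPM filter outcomes and alternative stretches.

    Scenarios cycle through pass-all isoforms carrying each alternative
    origin (insertion, deletion junction, frameshifted tail), a pass-all
    isoform identical to its canonical protein, and one planted failure
    per expression filter. Returns the isoform records, a ground-truth
    table of intended per-filter outcomes, and the planted stretches of
    cascade-surviving isoforms (paired with canonical accessions).
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    qual = _qualifying(annotations)
    truth_rows = []
    isoforms: list[IsoformRecord] = []
    planted: list[tuple[AlternativeStretch, str]] = []
    by_acc = {r.id: str(r.seq) for r in proteome}

    for i in range(config.n_isoforms):
        scenario = _SCENARIOS[i % len(_SCENARIOS)]
        acc = qual[i % len(qual)]
        canonical = by_acc[acc]
        iso_id = f"ISO{i + 1:04d}"

        origin, core, stretch_seq, stretch_start = "", "", "", -1
        if scenario == "pass_insertion":
            iso_aa, core, stretch_seq, stretch_start = _plant_alternative(rng, canonical, "insertion")
            origin = "insertion"
        elif scenario == "pass_junction":
            iso_aa, core, stretch_seq, stretch_start = _plant_alternative(rng, canonical, "junction")
            origin = "junction"
        elif scenario == "pass_frameshift":
            iso_aa, core, stretch_seq, stretch_start = _plant_alternative(rng, canonical, "frameshift-tail")
            origin = "frameshift-tail"
        else:
            iso_aa = canonical

        n_islet, n_mtec, n_ctrl = 6, 5, 3
        levels = {"islet": 60.0, "mtec": 0.01, "ctrl": 0.8, "ctrl_high": None}
        flags = {"expressed": True, "islet": True, "mtec": True, "enrichment": True}
        const = False
        if scenario == "fail_expressed":
            # islet 0.2 also sinks the islet-median and enrichment folds
            levels.update(islet=0.2, mtec=0.01, ctrl=0.1)
            flags.update(expressed=False, islet=False, enrichment=False)
            const = True
        elif scenario == "fail_islet":
            levels.update(islet=2.0, mtec=0.01, ctrl=0.05)
            flags.update(islet=False)
        elif scenario == "fail_mtec":
            levels.update(islet=6.0, mtec=5.0, ctrl=0.05)
            flags.update(mtec=False)
            const = True
        elif scenario == "fail_enrichment":
            levels.update(islet=110.0, mtec=0.01, ctrl=1.0, ctrl_high=50.0)
            flags.update(enrichment=False)
            const = True

        def vec(level: float, n: int) -> np.ndarray:
            return np.full(n, level) if const else _tpm(rng, level, n)

        tpm = {
            "islet_basal": vec(levels["islet"], n_islet),
            "islet_ifn": vec(levels["islet"], n_islet),
            "mtec_lo": vec(levels["mtec"], n_mtec),
            "mtec_hi": vec(levels["mtec"], n_mtec),
        }
        for j, tissue in enumerate(CONTROL_TISSUES):
            lvl = levels["ctrl"]
            if levels["ctrl_high"] is not None and j == 0:
                lvl = levels["ctrl_high"]
            tpm[tissue] = vec(lvl, n_ctrl)

        de = (2.0, 0.01) if i % 3 == 0 else (1.2, 0.2) if i % 3 == 1 else None
        rec = IsoformRecord(
            isoform_id=iso_id, gene_id=f"GENE{acc[3:]}", canonical_accession=acc,
            canonical_flag=(iso_aa == canonical),
            coding_sequence=_reverse_translate(iso_aa), translation=iso_aa,
            tpm=tpm, de_stats=de,
        )
        isoforms.append(rec)
        survives = all(flags.values())
        truth_rows.append({
            "isoform_id": iso_id, "scenario": scenario, "canonical_accession": acc,
            "pass_expressed": flags["expressed"], "pass_islet": flags["islet"],
            "pass_mtec": flags["mtec"], "pass_enrichment": flags["enrichment"],
            "survives": survives, "alt_origin": origin, "alt_core": core,
            "alt_stretch": stretch_seq,
        })
        if survives and origin:
            cs = _FLANK
            ce = _FLANK + len(core)
            planted.append((
                AlternativeStretch(
                    isoform_id=iso_id, aa_sequence=stretch_seq, origin=origin,
                    start=stretch_start, end=stretch_start + len(stretch_seq),
                    core_start=cs, core_end=ce, flank_left=_FLANK,
                    flank_right=len(stretch_seq) - ce,
                ),
                acc,
            ))
    return isoforms, pd.DataFrame(truth_rows), planted


# ---------------------------------------------------------------------------
# PSM tables


def format_modifications(mods: Sequence[tuple]) -> str:
    return ";".join(f"{pos}:{name}" for pos, name in mods)


def parse_modifications(text: str) -> list[tuple]:
    if not text or (isinstance(text, float) and np.isnan(text)):
        return []
    out = []
    for item in str(text).split(";"):
        pos, name = item.split(":")
        out.append((pos if pos in ("N-term", "C-term") else int(pos), name))
    return out


def _choose_length(rng: np.random.Generator) -> int:
    ls = np.array(list(_LENGTH_WEIGHTS))
    ps = np.array(list(_LENGTH_WEIGHTS.values()))
    return int(rng.choice(ls, p=ps / ps.sum()))


def _sample_window(rng: np.random.Generator, seq: str, length: int) -> tuple[int, str]:
    start = int(rng.integers(0, len(seq) - length + 1))
    return start, seq[start:start + length]


def _condition_class(rng: np.random.Generator, w_basal: float, w_ifn: float, shared: float) -> str:
    probs = np.array([w_basal * (1 - shared), w_ifn * (1 - shared), shared * (w_basal + w_ifn) / 2])
    return str(rng.choice(["basal", "ifn", "both"], p=probs / probs.sum()))


def _replicate_hits(rng: np.random.Generator, n_rep: int, p: float) -> list[int]:
    hits = [r for r in range(1, n_rep + 1) if rng.random() < p]
    if not hits:
        hits = [int(rng.integers(1, n_rep + 1))]
    return hits


# planted PTM schedule: (ptm name, intended condition class of its
# peptides, spectral intent). Oxidation and the terminal deamidation row
# exercise the triage exclusions.
_PTM_SCHEDULE = (
    ("glutathionylation", "ifn", "biological"),
    ("glutathionylation", "ifn", "biological"),
    ("cysteinylation", "ifn", "biological"),
    ("phosphorylation", "ifn", "biological"),
    ("sulphone", "ifn", "biological"),
    ("deamidation", "basal", "biological"),
    ("deamidation", "basal", "artifact"),
    ("acetylation", "shared", "artifact"),
    ("glutathionylation", "ifn", "artifact"),
    ("cysteinylation", "ifn", "artifact"),
    ("oxidation", "ifn", "artifact"),
    ("oxidation", "basal", "artifact"),
)


def _find_ptm_window(
    rng: np.random.Generator, seq: str, residues: frozenset[str], length: int
) -> tuple[int, str, int] | None:
    """A window of ``length`` with a target residue at an internal position."""
    positions = [i for i, a in enumerate(seq) if a in residues]
    rng.shuffle(positions)
    for i in positions:
        lo = max(0, i - length + 2)
        hi = min(i - 1, len(seq) - length)
        if hi < lo:
            continue
        start = int(rng.integers(lo, hi + 1))
        pos_in_pep = i - start + 1  # 1-based, internal by construction
        if 2 <= pos_in_pep <= length - 1:
            return start, seq[start:start + length], pos_in_pep
    return None


def generate_psm_table(
    proteome: Sequence[SeqRecord],
    annotations: pd.DataFrame,
    variant_stretches: Sequence[tuple[AlternativeStretch, str]],
    config: FixtureConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """PSM rows across 2 conditions x n replicates, with ground truth.

    Plants conventional peptides with allele- and condition-dependent
    sampling weights, out-of-length peptides, mRNA-variant peptides
    spanning planted novel cores, PTM peptides (biological and artifact
    spectral intent), cis-spliced two-fragment peptides, and decoy
    peptides drawn from reversed proteins with a clearly lower score
    distribution.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    seqs = {r.id: str(r.seq) for r in proteome}
    ann = annotations.set_index("accession")
    qual = _qualifying(annotations)
    nonqual = _nonqualifying(annotations)
    skew = config.planted_hla_skew
    alleles = list(skew)
    w_b = np.array([skew[a][0] for a in alleles])
    w_f = np.array([skew[a][1] for a in alleles])
    w_mix = (w_b + w_f) / 2

    used: set[str] = set()
    truth_rows: list[dict] = []

    def _templated_anywhere(pep: str) -> bool:
        c = pep.replace("L", "I")
        return any(c in s.replace("L", "I") for s in seqs.values())

    def plant_peptide(category: str, **kw) -> dict:
        row = {
            "peptide": kw["peptide"], "category": category,
            "condition_class": kw.get("condition_class", "ifn"),
            "source_accession": kw.get("source_accession", ""),
            "start": kw.get("start", -1), "end": kw.get("end", -1),
            "allele": kw.get("allele", ""), "alleles": kw.get("alleles", kw.get("allele", "")),
            "enrichment_pass": kw.get("enrichment_pass", True),
            "in_length": 8 <= len(kw["peptide"]) <= 14,
            "ptm_name": kw.get("ptm_name", ""), "ptm_position": kw.get("ptm_position", 0),
            "ptm_intent": kw.get("ptm_intent", ""),
            "frag1_start": kw.get("frag1_start", -1), "frag1_end": kw.get("frag1_end", -1),
            "frag2_start": kw.get("frag2_start", -1), "frag2_end": kw.get("frag2_end", -1),
            "splice_order": kw.get("splice_order", ""),
        }
        truth_rows.append(row)
        used.add(kw["peptide"])
        return row

    def draw_allele() -> tuple[str, float, float]:
        i = int(rng.choice(len(alleles), p=w_mix / w_mix.sum()))
        a = alleles[i]
        tot = w_b[i] + w_f[i]
        return a, w_b[i] / tot, w_f[i] / tot

    # conventional peptides ------------------------------------------------
    n_conv = config.n_conventional_peptides
    n_nonenr = round(config.fraction_nonenriched * n_conv)
    for j in range(n_conv):
        enr = j >= n_nonenr if nonqual else True
        pool = qual if enr else nonqual
        for _ in range(200):
            acc = pool[int(rng.integers(len(pool)))]
            start, pep = _sample_window(rng, seqs[acc], _choose_length(rng))
            if pep not in used:
                break
        else:
            continue
        a, pb, pf = draw_allele()
        plant_peptide(
            "conventional", peptide=pep, source_accession=acc, start=start,
            end=start + len(pep), allele=a,
            condition_class=_condition_class(rng, pb, pf, config.shared_fraction),
            enrichment_pass=enr,
        )

    # out-of-length peptides ----------------------------------------------
    for j in range(round(config.fraction_out_of_length * n_conv)):
        length = int(rng.choice([6, 7, 15, 16]))
        for _ in range(200):
            acc = qual[int(rng.integers(len(qual)))]
            start, pep = _sample_window(rng, seqs[acc], length)
            if pep not in used:
                break
        a, pb, pf = draw_allele()
        plant_peptide(
            "conventional", peptide=pep, source_accession=acc, start=start,
            end=start + len(pep), allele=a,
            condition_class=_condition_class(rng, pb, pf, config.shared_fraction),
        )

    # mRNA-variant peptides -----------------------------------------------
    for stretch, acc in variant_stretches:
        s = stretch.aa_sequence
        cs, ce = stretch.core_start, stretch.core_end
        length = 10
        # window spanning the novel core (or strictly crossing the junction)
        mid = (cs + ce) // 2
        for off in range(6):
            start = max(0, min(mid - length // 2 + off, len(s) - length))
            pep = s[start:start + length]
            spans = (start < ce and start + length > cs) if ce > cs else (start < cs < start + length)
            if spans and pep not in used and not any(pep in t for t in seqs.values()):
                a, pb, pf = draw_allele()
                plant_peptide(
                    "variant", peptide=pep, source_accession=acc,
                    start=start, end=start + length, allele=a,
                    condition_class=_condition_class(rng, pb, pf, config.shared_fraction),
                )
                break

    # PTM peptides ---------------------------------------------------------
    defs = ptm_analysis.default_ptm_definitions()
    for j in range(config.n_ptm_peptides):
        name, cond, intent = _PTM_SCHEDULE[j % len(_PTM_SCHEDULE)]
        d = defs[name]
        found = None
        for _ in range(200):
            acc = qual[int(rng.integers(len(qual)))]
            hit = _find_ptm_window(rng, seqs[acc], d.target_residues, int(rng.integers(9, 12)))
            if hit and hit[1] not in used:
                found = (acc, *hit)
                break
        if found is None:
            continue
        acc, start, pep, pos = found
        cls = {"ifn": "ifn", "basal": "basal", "shared": ("basal" if j % 2 else "ifn")}[cond]
        a, _, _ = draw_allele()
        plant_peptide(
            "ptm-biological" if intent == "biological" else "ptm-artifact",
            peptide=pep, source_accession=acc, start=start, end=start + len(pep),
            allele=a, condition_class=cls, ptm_name=name, ptm_position=pos,
            ptm_intent=intent,
        )
    # one terminal-position modification row (triage must exclude it)
    if config.n_ptm_peptides:
        for _ in range(200):
            acc = qual[int(rng.integers(len(qual)))]
            start, pep = _sample_window(rng, seqs[acc], 9)
            if pep not in used and pep[-1] in "NQ":
                plant_peptide(
                    "ptm-artifact", peptide=pep, source_accession=acc, start=start,
                    end=start + 9, allele=alleles[0], condition_class="ifn",
                    ptm_name="deamidation", ptm_position=9, ptm_intent="artifact",
                )
                break

    # cis-spliced peptides -------------------------------------------------
    for j in range(config.n_splice_peptides):
        for _ in range(400):
            acc = qual[int(rng.integers(len(qual)))]
            s = seqs[acc]
            l1 = int(rng.integers(3, 7))
            l2 = int(rng.integers(max(3, 8 - l1), 7))  # total >= 8 aa
            order = "forward" if rng.random() < 0.5 else "reverse"
            s1 = int(rng.integers(0, len(s) - l1 - l2 - 2))
            if order == "forward":
                gap = int(rng.integers(2, 15))
                s2 = s1 + l1 + gap
                if s2 + l2 > len(s):
                    continue
            else:
                # frag1 occurs after frag2 in the parent
                s2 = s1 + l1 + int(rng.integers(1, 10))
                if s2 + l2 > len(s):
                    continue
                s1, s2 = s2, s1
                l1, l2 = l2, l1
            frag1 = (s1, s1 + l1)
            frag2 = (s2, s2 + l2)
            pep = s[frag1[0]:frag1[1]] + s[frag2[0]:frag2[1]]
            if pep in used or _templated_anywhere(pep):
                continue
            if any(pep in st.aa_sequence for st, _ in variant_stretches):
                continue
            cls = "ifn" if rng.random() < 0.75 else "basal"
            a, _, _ = draw_allele()
            plant_peptide(
                "cis-spliced", peptide=pep, source_accession=acc, allele=a,
                condition_class=cls, frag1_start=frag1[0], frag1_end=frag1[1],
                frag2_start=frag2[0], frag2_end=frag2[1], splice_order=order,
            )
            break

    # decoys ---------------------------------------------------------------
    n_decoy = round(config.fraction_decoy * n_conv)
    rev = {acc: s[::-1] for acc, s in seqs.items()}
    for j in range(n_decoy):
        for _ in range(200):
            acc = list(rev)[int(rng.integers(len(rev)))]
            start, pep = _sample_window(rng, rev[acc], int(rng.integers(8, 12)))
            if pep not in used and not _templated_anywhere(pep):
                break
        else:
            continue
        plant_peptide(
            "decoy", peptide=pep, source_accession=acc, start=start,
            end=start + len(pep), condition_class="ifn" if rng.random() < 0.5 else "basal",
            enrichment_pass=False,
        )

    truth = pd.DataFrame(truth_rows)

    # expand ground truth into PSM rows -----------------------------------
    n_rep = config.n_replicates_per_condition
    psm_rows: list[dict] = []
    counter = 0
    for row in truth.itertuples(index=False):
        conditions = {"basal": ["basal"], "ifn": ["ifn"], "both": ["basal", "ifn"]}[row.condition_class]
        is_decoy = row.category == "decoy"
        base_abund = float(np.exp(rng.normal(np.log(1e5), 1.0)))
        mods = ""
        if row.ptm_name:
            mods = format_modifications([(row.ptm_position, row.ptm_name)])
        for cond in conditions:
            for rep in _replicate_hits(rng, n_rep, config.replicate_detection_prob):
                counter += 1
                if is_decoy:
                    score = min(float(rng.normal(12.0, 3.0)), 21.0)
                else:
                    score = max(float(rng.normal(32.0, 4.0)), 23.0)
                abund = base_abund * float(np.exp(rng.normal(0.0, config.abundance_sigma)))
                psm_rows.append({
                    "peptide": row.peptide, "modifications": mods, "score": score,
                    "spectrum_id": f"sp{counter:06d}", "condition": cond,
                    "replicate": rep,
                    "abundance": abund if rng.random() > 0.1 else np.nan,
                    "is_decoy": is_decoy,
                })
    psms = pd.DataFrame(psm_rows)
    return psms, truth


def generate_null_psms(
    seed: int, n_true: int = 5000, n_false: int = 2500, n_decoy: int = 2500
) -> pd.DataFrame:
    """A planted-null PSM table for FDR calibration checks.

    True targets score high; false targets and decoys are exchangeable
    draws from one null distribution. The ``is_true`` column is ground
    truth, never visible to the FDR procedure.
    """
    rng = np.random.default_rng(seed)
    n = n_true + n_false + n_decoy

    # unique peptide strings: base-20 index encoding plus random residues
    idx = np.arange(n)
    letters = np.empty((n, 12), dtype="<U1")
    aa = np.array(list(AA))
    v = idx.copy()
    for k in range(6):
        letters[:, k] = aa[v % 20]
        v //= 20
    letters[:, 6:] = aa[rng.integers(0, 20, size=(n, 6))]
    peptides = ["".join(r) for r in letters]

    scores = np.concatenate([
        rng.normal(30.0, 3.0, n_true),
        rng.normal(15.0, 3.0, n_false),
        rng.normal(15.0, 3.0, n_decoy),
    ])
    is_decoy = np.r_[np.zeros(n_true + n_false, bool), np.ones(n_decoy, bool)]
    is_true = np.r_[np.ones(n_true, bool), np.zeros(n_false + n_decoy, bool)]
    return pd.DataFrame({
        "peptide": peptides, "modifications": "", "score": scores,
        "spectrum_id": [f"sp{i}" for i in idx], "condition": "basal",
        "replicate": 1, "abundance": np.nan, "is_decoy": is_decoy,
        "is_true": is_true,
    })


# ---------------------------------------------------------------------------
# Spectra


def generate_spectra(
    entries: Sequence[dict],
    config: FixtureConfig,
    rng: np.random.Generator | None = None,
    noiseless: bool = False,
) -> list[SpectrumPeaks]:
    """Peak lists from theoretical singly-charged b/y ions.

    Each entry needs ``spectrum_id``, ``peptide`` and ``modifications``
    (list of (position, name)). Peaks are dropped independently with
    probability ``peak_dropout`` and jittered with Gaussian noise of
    width ``mz_jitter_da`` unless ``noiseless``.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    out = []
    for e in entries:
        pep, mods = e["peptide"], list(e.get("modifications", []))
        if len(pep) < 2:
            raise ValueError("peptides must have length >= 2")
        ions = theoretical_fragments(pep, mods)
        peaks = []
        for _, mz in ions:
            inten = float(rng.uniform(200.0, 1000.0))
            if not noiseless and rng.random() < config.peak_dropout:
                continue
            jit = 0.0 if noiseless else float(rng.normal(0.0, config.mz_jitter_da))
            peaks.append((mz + jit, inten))
        if not peaks:  # never emit an empty spectrum
            _, mz = ions[0]
            peaks = [(mz, 500.0)]
        out.append(SpectrumPeaks(
            spectrum_id=e["spectrum_id"], precursor_mz=precursor_mz(pep, mods),
            charge=1, peaks=peaks,
        ))
    return out


def validation_spectra(
    truth: pd.DataFrame, config: FixtureConfig
) -> list[dict]:
    """Observed + synthetic reference spectra for every planted PTM peptide.

    For a ``biological`` intent the observed spectrum is generated from
    the modified peptide; for ``artifact`` intent from the native
    peptide (the modification was introduced experimentally, so the
    eluted species is native). Synthetic references are noiseless.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    out = []
    ptm = truth[truth.ptm_name != ""]
    for row in ptm.itertuples(index=False):
        mods = [(int(row.ptm_position), row.ptm_name)]
        obs_mods = mods if row.ptm_intent == "biological" else []
        obs = generate_spectra(
            [{"spectrum_id": f"obs|{row.peptide}", "peptide": row.peptide,
              "modifications": obs_mods}], config, rng)[0]
        ref_mod = generate_spectra(
            [{"spectrum_id": f"synmod|{row.peptide}", "peptide": row.peptide,
              "modifications": mods}], config, rng, noiseless=True)[0]
        ref_nat = generate_spectra(
            [{"spectrum_id": f"synnat|{row.peptide}", "peptide": row.peptide,
              "modifications": []}], config, rng, noiseless=True)[0]
        out.append({
            "peptide": row.peptide, "ptm_name": row.ptm_name,
            "intent": row.ptm_intent, "observed": obs,
            "synthetic_modified": ref_mod, "synthetic_native": ref_nat,
        })
    return out


def write_mgf(spectra: Sequence[SpectrumPeaks], path) -> None:
    records = []
    for sp in spectra:
        records.append({
            "m/z array": np.array([p[0] for p in sp.peaks]),
            "intensity array": np.array([p[1] for p in sp.peaks]),
            "params": {"title": sp.spectrum_id, "pepmass": sp.precursor_mz,
                       "charge": sp.charge},
        })
    _mgf.write(records, str(path), file_mode="w")


def read_mgf(path) -> list[SpectrumPeaks]:
    out = []
    with _mgf.MGF(str(path)) as reader:
        for rec in reader:
            out.append(SpectrumPeaks(
                spectrum_id=rec["params"]["title"],
                precursor_mz=float(rec["params"]["pepmass"][0]),
                charge=int(rec["params"].get("charge", [1])[0]),
                peaks=list(zip(rec["m/z array"].tolist(), rec["intensity array"].tolist())),
            ))
    return out


# ---------------------------------------------------------------------------
# Rank tables


def generate_rank_table(
    truth: pd.DataFrame,
    config: FixtureConfig,
    alleles: Sequence[str] = ALLELES,
    dual_fraction: float = 0.08,
) -> pd.DataFrame:
    """Long predictor-style rank table (peptide, allele, rank).

    The planted restricting allele receives a rank well under the
    binder cutoff; all other alleles receive ranks in (5, 60]. A small
    fraction of peptides get a second binder allele with a best/second
    ratio under 3, producing dual restriction calls.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 5]))
    rows = []
    peps = truth[truth.category != "decoy"]
    for row in peps.itertuples(index=False):
        planted = row.allele
        dual = bool(rng.random() < dual_fraction) and planted
        ranks = {}
        for a in alleles:
            ranks[a] = float(rng.uniform(5.0, 60.0))
        if planted:
            if dual:
                best = float(rng.uniform(0.15, 0.65))
                ranks[planted] = best
                # partner on the same locus when one exists
                partners = [a for a in alleles if a != planted and a[0] == planted[0]]
                partner = partners[0] if partners else [a for a in alleles if a != planted][0]
                ranks[partner] = best * float(rng.uniform(1.5, 2.9))
            else:
                ranks[planted] = float(rng.uniform(0.15, 1.2))
        for a in alleles:
            rows.append({"peptide": row.peptide, "allele": a, "rank": ranks[a]})
    return pd.DataFrame(rows)
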