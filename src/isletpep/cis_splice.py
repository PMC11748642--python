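"""Proteasomal cis-spliced peptide candidate enumeration.

A peptide that cannot be matched to any genome-templated sequence may be
the product of proteasome-catalyzed peptide splicing: two non-contiguous
fragments of a single parent protein ligated either in the order in
which they occur (forward) or in inverted order (reverse). This module
enumerates all two-fragment explanations of a peptide within a parent,
searches a whole proteome, and orders candidates.

Conventions:

- fragments are at least ``min_fragment_len`` residues (default 2; a
  single-residue fragment is chemically implausible and explodes the
  search space);
- fragments never overlap; a forward pair with gap 0 would reconstruct
  a contiguous (genome-templated) substring and is rejected, while a
  reverse pair with gap 0 is a genuine splice and is kept;
- isoleucine/leucine are indistinguishable by their residue mass, so
  matching can optionally treat I and L as equal; candidates that
  needed any I<->L substitution are flagged ``il_ambiguous``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.SeqRecord import SeqRecord


class TemplatedPeptideError(ValueError):
    """Raised when the peptide is a contiguous substring of the parent."""


@dataclass(frozen=True)
class SpliceCandidate:
    """A two-fragment explanation of a peptide within one parent protein.

    Fragment coordinates are 0-based half-open in the parent.
    ``order`` is ``forward`` when fragment1 precedes fragment2 in the
    parent and ``reverse`` otherwise. ``gap`` is the number of parent
    residues separating the fragments.
    """

    peptide: str
    parent_accession: str
    fragment1: tuple[int, int]
    fragment2: tuple[int, int]
    order: str
    il_ambiguous: bool = False

    @property
    def gap(self) -> int:
        if self.order == "forward":
            return self.fragment2[0] - self.fragment1[1]
        return self.fragment1[0] - self.fragment2[1]


def _canon(s: str, il_equivalent: bool) -> str:
    return s.replace("L", "I") if il_equivalent else s


def _occurrences(fragment: str, parent: str, il_equivalent: bool) -> list[int]:
    frag = _canon(fragment, il_equivalent)
    par = _canon(parent, il_equivalent)
    out = []
    start = par.find(frag)
    while start != -1:
        out.append(start)
        start = par.find(frag, start + 1)
    return out


def is_templated(peptide: str, parent: str, il_equivalent: bool = False) -> bool:
    return _canon(peptide, il_equivalent) in _canon(parent, il_equivalent)


def enumerate_candidates(
    peptide: str,
    parent_sequence: str,
    parent_accession: str = "",
    min_fragment_len: int = 2,
    il_equivalent: bool = False,
) -> list[SpliceCandidate]:
    """All two-fragment splice explanations of ``peptide`` in one parent.

    For every split point k the prefix ``peptide[:k]`` and suffix
    ``peptide[k:]`` are located in the parent; every non-overlapping
    occurrence pair satisfying the adjacency rules yields a candidate.
    Results are deduplicated and sorted by (k, fragment1 start,
    fragment2 start). Raises :class:`TemplatedPeptideError` when the
    peptide is a contiguous substring of the parent.
    """
    m = len(peptide)
    if m < 2 * min_fragment_len:
        raise ValueError(f"peptide shorter than two fragments of {min_fragment_len}")
    if is_templated(peptide, parent_sequence, il_equivalent):
        raise TemplatedPeptideError(f"{peptide!r} is genome-templated in this parent")

    out: list[SpliceCandidate] = []
    seen: set[tuple] = set()
    for k in range(min_fragment_len, m - min_fragment_len + 1):
        pre, suf = peptide[:k], peptide[k:]
        pre_occ = _occurrences(pre, parent_sequence, il_equivalent)
        if not pre_occ:
            continue
        suf_occ = _occurrences(suf, parent_sequence, il_equivalent)
        for s1 in pre_occ:
            e1 = s1 + k
            for s2 in suf_occ:
                e2 = s2 + (m - k)
                if e1 < s2:
                    order = "forward"  # strict gap >= 1: gap 0 is templated
                elif e2 <= s1:
                    order = "reverse"  # gap 0 allowed in reverse
                else:
                    continue
                key = (s1, e1, s2, e2)
                if key in seen:
                    continue
                seen.add(key)
                ambiguous = (
                    parent_sequence[s1:e1] + parent_sequence[s2:e2] != peptide
                    if il_equivalent
                    else False
                )
                out.append(
                    SpliceCandidate(
                        peptide=peptide,
                        parent_accession=parent_accession,
                        fragment1=(s1, e1),
                        fragment2=(s2, e2),
                        order=order,
                        il_ambiguous=ambiguous,
                    )
                )
    out.sort(key=lambda c: (c.fragment1[1] - c.fragment1[0], c.fragment1[0], c.fragment2[0]))
    return out


def search_proteome(
    peptide: str,
    proteome: Sequence[SeqRecord],
    annotations: pd.DataFrame | None = None,
    il_equivalent: bool = True,
    min_fragment_len: int = 2,
) -> list[SpliceCandidate]:
    """Splice candidates for a peptide across a whole proteome.

    Parents in which the peptide is genome-templated are skipped (such a
    peptide should have been routed as conventional upstream). When
    ``annotations`` is given (accession-indexed, boolean columns
    ``pancreas_evidence`` and ``endocrine_enriched``), only candidates
    whose parent passes the β-cell-enrichment rule are kept.
    """
    ann = None
    if annotations is not None:
        ann = annotations.set_index("accession") if "accession" in annotations.columns else annotations
    out: list[SpliceCandidate] = []
    for rec in proteome:
        seq = str(rec.seq)
        if ann is not None:
            row = ann.loc[rec.id]
            if not bool(row.pancreas_evidence and row.endocrine_enriched):
                continue
        if is_templated(peptide, seq, il_equivalent):
            continue
        out.extend(
            enumerate_candidates(
                peptide, seq, parent_accession=rec.id,
                min_fragment_len=min_fragment_len, il_equivalent=il_equivalent,
            )
        )
    return out


def rank_candidates(
    candidates: Sequence[SpliceCandidate],
    allele_ranks: Mapping[str, float] | None = None,
) -> list[SpliceCandidate]:
    """Deterministic ordering of splice candidates.

    Primary key is the peptide's best predictor rank (shared across its
    candidates; peptides lacking ranks sort last), then the
    inter-fragment gap ascending, then the parent accession.
    """
    def key(c: SpliceCandidate):
        best = float("inf")
        if allele_ranks is not None and c.peptide in allele_ranks:
            best = allele_ranks[c.peptide]
        return (best, c.gap, c.parent_accession)

    return sorted(candidates, key=key)
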