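"""Post-translational modification (PTM) analysis for HLA-I eluted ligands.

Covers four steps of the PTM arm of the pipeline:

1. per-PTM condition-enrichment classification (basal-enriched,
   IFN-enriched, or shared between conditions);
2. triage of PTM peptides worth chemical synthesis — modifications that
   arise spontaneously during synthesis or MS acquisition (oxidations,
   anything sitting on the vulnerable terminal residues) are excluded;
3. theoretical singly-charged b/y fragment ion computation for modified
   and native peptides;
4. spectral matching of an observed spectrum against synthetic modified
   and synthetic native references, yielding a biological / artifactual /
   unvalidated verdict.

Modification monoisotopic mass shifts are frozen from the Unimod
reference list into ``data/ptm_definitions.tsv`` (overridable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

PROTON = 1.00727646688
WATER = 18.0105646863

#: Standard monoisotopic residue masses for the 20 proteinogenic amino acids.
AA_MONO: Mapping[str, float] = {aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"}

TermPos = int | str  # 1-based residue index, or "N-term"/"C-term"


@dataclass(frozen=True)
class PtmDefinition:
    """One modification type: mass shift, residue specificity, triage flags."""

    name: str
    mass_delta: float
    target_residues: frozenset[str]
    terminal_only: bool = False
    synthesizable: bool = True
    artifact_prone: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.mass_delta):
            raise ValueError(f"non-finite mass delta for PTM {self.name!r}")
        if not self.target_residues and not self.terminal_only:
            raise ValueError(f"PTM {self.name!r} has no target residues and is not terminal-only")


def load_ptm_definitions(path=None) -> dict[str, PtmDefinition]:
    """Load the shipped (or a user-supplied) PTM definition table."""
    if path is None:
        with resources.files("isletpep.data").joinpath("ptm_definitions.tsv").open() as fh:
            df = pd.read_csv(fh, sep="\t", keep_default_na=False)
    else:
        df = pd.read_csv(path, sep="\t", keep_default_na=False)
    defs = {}
    for row in df.itertuples(index=False):
        defs[row.name] = PtmDefinition(
            name=row.name,
            mass_delta=float(row.mass_delta),
            target_residues=frozenset(str(row.target_residues)),
            terminal_only=str(row.terminal_only) == "True",
            synthesizable=str(row.synthesizable) == "True",
            artifact_prone=str(row.artifact_prone) == "True",
        )
    return defs


_DEFAULT_DEFS: dict[str, PtmDefinition] | None = None


def default_ptm_definitions() -> dict[str, PtmDefinition]:
    global _DEFAULT_DEFS
    if _DEFAULT_DEFS is None:
        _DEFAULT_DEFS = load_ptm_definitions()
    return _DEFAULT_DEFS


class UnknownModificationError(KeyError):
    pass


def _resolve(name: str, definitions: Mapping[str, PtmDefinition] | None) -> PtmDefinition:
    defs = definitions if definitions is not None else default_ptm_definitions()
    try:
        return defs[name]
    except KeyError:
        raise UnknownModificationError(f"unknown modification: {name!r}") from None


# ---------------------------------------------------------------------------
# Fragment ions


def theoretical_fragments(
    peptide: str,
    modifications: Sequence[tuple[TermPos, str]] = (),
    charge: int = 1,
    definitions: Mapping[str, PtmDefinition] | None = None,
) -> list[tuple[str, float]]:
    """Singly-protonated b/y ion m/z values for a (modified) peptide.

    Returns ``[("b1", mz), ..., ("y1", mz), ...]`` for b1..b(n-1) and
    y1..y(n-1). A modification at residue *i* shifts every ion containing
    that residue; N-/C-terminal modifications shift the whole b or y
    series respectively (and the complementary largest ions).
    Only ``charge == 1`` is modeled.
    """
    n = len(peptide)
    if n < 2:
        raise ValueError("peptide must have length >= 2")
    if charge != 1:
        raise ValueError("only singly-charged fragment ions are modeled")
    bad = set(peptide) - set(AA_MONO)
    if bad:
        raise ValueError(f"residues outside the standard alphabet: {sorted(bad)}")

    # per-residue mass shifts; terminal mods attach to the first/last residue
    shifts = np.zeros(n)
    for pos, name in modifications:
        d = _resolve(name, definitions)
        if pos == "N-term":
            shifts[0] += d.mass_delta
        elif pos == "C-term":
            shifts[-1] += d.mass_delta
        else:
            i = int(pos)
            if not 1 <= i <= n:
                raise ValueError(f"modification position {i} outside peptide of length {n}")
            shifts[i - 1] += d.mass_delta

    res = np.array([AA_MONO[a] for a in peptide]) + shifts
    b_cum = np.cumsum(res[:-1])
    y_cum = np.cumsum(res[::-1][:-1])
    ions = [(f"b{k + 1}", m + PROTON) for k, m in enumerate(b_cum)]
    ions += [(f"y{k + 1}", m + WATER + PROTON) for k, m in enumerate(y_cum)]
    return ions


def precursor_mz(
    peptide: str,
    modifications: Sequence[tuple[TermPos, str]] = (),
    charge: int = 1,
    definitions: Mapping[str, PtmDefinition] | None = None,
) -> float:
    """[M + z·H]^z+ m/z of the (modified) peptide."""
    neutral = sum(AA_MONO[a] for a in peptide) + WATER
    for _, name in modifications:
        neutral += _resolve(name, definitions).mass_delta
    return (neutral + charge * PROTON) / charge


# ---------------------------------------------------------------------------
# Spectra


@dataclass
class SpectrumPeaks:
    """A peak list with precursor information; peaks sorted by m/z."""

    spectrum_id: str
    precursor_mz: float
    charge: int
    peaks: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks)
        if any(mz <= 0 for mz, _ in self.peaks):
            raise ValueError("peak m/z values must be positive")

    @property
    def mz(self) -> np.ndarray:
        return np.array([p[0] for p in self.peaks])

    @property
    def intensity(self) -> np.ndarray:
        return np.array([p[1] for p in self.peaks])


def match_spectra(
    observed: SpectrumPeaks,
    reference: SpectrumPeaks,
    fragment_tol_da: float = 0.03,
) -> tuple[float, float]:
    """Greedy nearest-peak pairing within a Da tolerance.

    Returns ``(matched_fraction, cosine)``: the fraction of reference
    peaks paired with an observed peak, and the cosine similarity on
    square-root intensities where unpaired peaks contribute zero.
    """
    if fragment_tol_da <= 0:
        raise ValueError("fragment_tol_da must be positive")
    if not observed.peaks or not reference.peaks:
        raise ValueError("empty peak list")

    omz, oint = observed.mz, observed.intensity
    rmz, rint = reference.mz, reference.intensity

    # all candidate pairs within tolerance, greedily matched by |Δm/z|
    cand = []
    j0 = 0
    for i, m in enumerate(rmz):
        while j0 < len(omz) and omz[j0] < m - fragment_tol_da:
            j0 += 1
        j = j0
        while j < len(omz) and omz[j] <= m + fragment_tol_da:
            cand.append((abs(omz[j] - m), i, j))
            j += 1
    cand.sort()
    used_r: set[int] = set()
    used_o: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i in used_r or j in used_o:
            continue
        used_r.add(i)
        used_o.add(j)
        pairs.append((i, j))

    matched_fraction = len(pairs) / len(rmz)
    num = sum(math.sqrt(rint[i] * oint[j]) for i, j in pairs)
    den = math.sqrt(rint.sum()) * math.sqrt(oint.sum())
    cosine = num / den if den > 0 else 0.0
    return matched_fraction, cosine


@dataclass(frozen=True)
class MatchThresholds:
    """Minimum metrics for declaring two spectra a match."""

    matched_fraction: float = 0.6
    cosine: float = 0.7


def validate_ptm(
    observed: SpectrumPeaks,
    synthetic_modified: SpectrumPeaks,
    synthetic_native: SpectrumPeaks,
    thresholds: MatchThresholds = MatchThresholds(),
    fragment_tol_da: float = 0.03,
) -> str:
    """Verdict on a PTM assignment by dual spectral comparison.

    ``biological`` — the observed spectrum matches the synthetic modified
    peptide and not the native one; ``artifactual`` — it matches the
    native peptide (the modification was introduced experimentally);
    ``unvalidated`` — neither reference is matched.
    """
    mf_m, cos_m = match_spectra(observed, synthetic_modified, fragment_tol_da)
    mf_n, cos_n = match_spectra(observed, synthetic_native, fragment_tol_da)
    hit_mod = mf_m >= thresholds.matched_fraction and cos_m >= thresholds.cosine
    hit_nat = mf_n >= thresholds.matched_fraction and cos_n >= thresholds.cosine
    if hit_nat:
        return "artifactual"
    if hit_mod:
        return "biological"
    return "unvalidated"


# ---------------------------------------------------------------------------
# Condition enrichment and triage


def classify_ptm_enrichment(
    ptm_peptides: pd.DataFrame,
    theta: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Per-PTM condition class from distinct-peptide counts.

    ``ptm_peptides`` needs columns ``ptm_name``, ``peptide``,
    ``condition`` (values ``basal``/``ifn``). With b and f the distinct
    peptide counts per condition, a PTM is ``ifn-enriched`` when
    f/(b+f) >= theta, ``basal-enriched`` when b/(b+f) >= theta, else
    ``shared``.
    """
    rows = []
    for name, grp in ptm_peptides.groupby("ptm_name", sort=True):
        b = grp.loc[grp.condition == "basal", "peptide"].nunique()
        f = grp.loc[grp.condition == "ifn", "peptide"].nunique()
        if b + f == 0:
            raise ValueError(f"PTM {name!r} has no peptide occurrences")
        if f / (b + f) >= theta:
            cls = "ifn-enriched"
        elif b / (b + f) >= theta:
            cls = "basal-enriched"
        else:
            cls = "shared"
        rows.append({"ptm_name": name, "n_basal": b, "n_ifn": f, "ptm_class": cls})
    return pd.DataFrame(rows)


def triage_candidates(
    ptm_peptides: pd.DataFrame,
    definitions: Mapping[str, PtmDefinition] | None = None,
    theta: float = 2.0 / 3.0,
) -> pd.DataFrame:
    """Select PTM peptides suitable for synthetic-peptide validation.

    A row is retained when its PTM is condition-enriched (either
    direction), not artifact-prone, chemically synthesizable, and the
    modified position is internal (neither the first nor the last
    residue, nor a terminus).

    ``ptm_peptides`` needs columns ``peptide``, ``ptm_name``,
    ``ptm_position`` (1-based int or ``N-term``/``C-term``) and
    ``condition``. Returns the input with ``ptm_class`` and ``retained``
    columns added.
    """
    classes = classify_ptm_enrichment(ptm_peptides, theta=theta)
    out = ptm_peptides.merge(classes[["ptm_name", "ptm_class"]], on="ptm_name", how="left")
    retained = []
    for row in out.itertuples(index=False):
        d = _resolve(row.ptm_name, definitions)
        pos = row.ptm_position
        if pos in ("N-term", "C-term"):
            terminal = True
        else:
            terminal = int(pos) in (1, len(row.peptide))
        keep = (
            row.ptm_class in ("basal-enriched", "ifn-enriched")
            and not d.artifact_prone
            and d.synthesizable
            and not terminal
        )
        retained.append(keep)
    out["retained"] = retained
    return out
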