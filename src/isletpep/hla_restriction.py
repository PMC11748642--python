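"""HLA-I binder calls and restriction assignment from predictor ranks.

Binding predictions arrive as percentile ranks (lower = stronger
binding) per peptide and allele; the panel is the set of alleles
expressed by the presenting cell (for the ECN90 β-cell line:
A*02:01/03:01, B*40:01/49:01, C*03:04/07:01, E*01:01). A peptide is a
binder of every allele with rank < 2. A single restriction is assigned
when the second-best binder's rank is at least 3-fold the best one's;
otherwise the two best alleles are both assigned. Locus-level tallies
(A/B/C/E) compare the basal-presented and IFN-presented peptide sets
with two-sided Fisher exact tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from scipy import stats

ECN90_ALLELES = (
    "A*02:01", "A*03:01", "B*40:01", "B*49:01", "C*03:04", "C*07:01", "E*01:01",
)

LOCI = ("A", "B", "C", "E")


@dataclass(frozen=True)
class RestrictionCall:
    peptide: str
    assigned_alleles: tuple[str, ...]
    best_rank: float
    second_rank: float | None
    locus_class: str  # A | B | C | E | ambiguous-multi-locus


def locus_of(allele: str) -> str:
    return allele[0]


def call_binders(
    rows: pd.DataFrame,
    cutoff: float = 2.0,
    alleles: Sequence[str] | None = None,
) -> dict[str, dict[str, float]]:
    """Binder alleles (rank < cutoff) per peptide.

    ``rows`` is a long table (peptide, allele, rank). When ``alleles``
    is given, every peptide must carry a rank for each panel allele.
    Peptides with no binder allele map to an empty dict.
    """
    for col in ("peptide", "allele", "rank"):
        if col not in rows.columns:
            raise KeyError(f"missing column {col!r} in rank table")
    if (rows["rank"] <= 0).any():
        raise ValueError("ranks must be positive")
    out: dict[str, dict[str, float]] = {}
    for pep, grp in rows.groupby("peptide", sort=False):
        have = set(grp.allele)
        if alleles is not None and not set(alleles) <= have:
            missing = sorted(set(alleles) - have)
            raise ValueError(f"peptide {pep!r} lacks ranks for alleles {missing}")
        out[pep] = {
            a: float(r) for a, r in zip(grp.allele, grp["rank"]) if r < cutoff
        }
    return out


def assign_restriction(binder_ranks: Mapping[str, float], fold: float = 3.0) -> RestrictionCall:
    """Restriction call from one peptide's binder ranks.

    Single assignment when second_rank / best_rank >= fold (inclusive),
    otherwise the two best alleles are assigned. The locus class is the
    shared locus letter, or ``ambiguous-multi-locus`` for a cross-locus
    dual call.
    """
    if not binder_ranks:
        raise ValueError("assign_restriction requires at least one binder allele")
    ordered = sorted(binder_ranks.items(), key=lambda kv: (kv[1], kv[0]))
    best_allele, best_rank = ordered[0]
    peptide = ""  # filled by caller when known
    if len(ordered) == 1:
        return RestrictionCall(peptide, (best_allele,), best_rank, None, locus_of(best_allele))
    second_allele, second_rank = ordered[1]
    if second_rank / best_rank >= fold:
        assigned = (best_allele,)
    else:
        assigned = (best_allele, second_allele)
    loci = {locus_of(a) for a in assigned}
    locus = loci.pop() if len(loci) == 1 else "ambiguous-multi-locus"
    return RestrictionCall(peptide, assigned, best_rank, second_rank, locus)


def call_restrictions(
    rows: pd.DataFrame,
    cutoff: float = 2.0,
    fold: float = 3.0,
    alleles: Sequence[str] | None = None,
) -> dict[str, RestrictionCall]:
    """Binder calls + restriction assignment for every binding peptide."""
    binders = call_binders(rows, cutoff=cutoff, alleles=alleles)
    out = {}
    for pep, ranks in binders.items():
        if not ranks:
            continue
        call = assign_restriction(ranks, fold=fold)
        out[pep] = RestrictionCall(pep, call.assigned_alleles, call.best_rank, call.second_rank, call.locus_class)
    return out


def stringent_hla_e_set(
    rows: pd.DataFrame, cutoff: float = 2.0, allele: str = "E*01:01"
) -> set[str]:
    """Peptides whose ONLY binder allele is HLA-E (no alternative restriction)."""
    binders = call_binders(rows, cutoff=cutoff)
    return {pep for pep, ranks in binders.items() if set(ranks) == {allele}}


def tally_by_locus(
    calls: Mapping[str, RestrictionCall],
    condition_classes: Mapping[str, str],
    inclusive: bool = True,
) -> pd.DataFrame:
    """Per-locus peptide counts in basal vs IFN sets, with Fisher tests.

    The basal-presented set contains peptides of class ``basal`` or
    ``both``; the IFN-presented set ``ifn`` or ``both`` (set
    ``inclusive=False`` for strictly exclusive sets). A dual same-locus
    call counts once for its locus; cross-locus dual calls are tallied
    under ``ambiguous-multi-locus`` and excluded from single-locus
    fractions. Each locus gets a two-sided Fisher exact p on the 2x2
    (locus vs other) x (basal vs ifn) table.
    """
    sets = {"basal": [], "ifn": []}
    for pep, call in calls.items():
        cls = condition_classes.get(pep)
        if cls is None:
            raise KeyError(f"no condition class for peptide {pep!r}")
        if inclusive:
            in_basal = cls in ("basal", "both")
            in_ifn = cls in ("ifn", "both")
        else:
            in_basal = cls == "basal"
            in_ifn = cls == "ifn"
        if in_basal:
            sets["basal"].append(call.locus_class)
        if in_ifn:
            sets["ifn"].append(call.locus_class)

    n_basal, n_ifn = len(sets["basal"]), len(sets["ifn"])
    rows = []
    for locus in list(LOCI) + ["ambiguous-multi-locus"]:
        b = sum(1 for x in sets["basal"] if x == locus)
        f = sum(1 for x in sets["ifn"] if x == locus)
        table = [[b, n_basal - b], [f, n_ifn - f]]
        p = float(stats.fisher_exact(table, alternative="two-sided")[1]) if n_basal and n_ifn else float("nan")
        rows.append({
            "locus": locus,
            "n_basal": b,
            "n_ifn": f,
            "frac_basal": b / n_basal if n_basal else float("nan"),
            "frac_ifn": f / n_ifn if n_ifn else float("nan"),
            "fisher_p": p,
        })
    df = pd.DataFrame(rows)
    df.attrs["n_basal_total"] = n_basal
    df.attrs["n_ifn_total"] = n_ifn
    return df
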