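"""Closed-form assay computations.

Two small calculators used alongside the immunopeptidome analysis:

- percent peptide-specific lysis from dual-dye flow-cytometry counts of
  surviving antigen-pulsed (CFSE+) vs unpulsed (CTV+) target cells,
  normalized to effector-free control wells;
- comparative ΔCt relative expression (2^-ΔΔCt) against one or more
  housekeeping genes and a reference sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class LysisWell:
    """Surviving (Live/Dead-negative) cell counts in one well."""

    live_pulsed_count: int  # CFSE-labeled, peptide-pulsed targets
    live_unpulsed_count: int  # CTV-labeled, unpulsed targets

    def ratio(self) -> float:
        if self.live_unpulsed_count <= 0:
            raise ValueError("zero unpulsed count: survival ratio undefined")
        return self.live_pulsed_count / self.live_unpulsed_count


def specific_lysis(
    test_wells: Sequence[LysisWell],
    control_wells: Sequence[LysisWell],
) -> dict[str, float]:
    """Percent peptide-specific lysis.

    lysis% = (1 - (pulsed/unpulsed)_test / (pulsed/unpulsed)_control) x 100,
    with well ratios averaged per class. Returns the raw value and a
    [0, 100]-clipped display value (sampling noise can push the raw
    value slightly negative).
    """
    if not test_wells or not control_wells:
        raise ValueError("both test and control wells are required")
    r_test = float(np.mean([w.ratio() for w in test_wells]))
    r_ctrl = float(np.mean([w.ratio() for w in control_wells]))
    if r_ctrl <= 0:
        raise ValueError("control survival ratio must be positive")
    raw = (1.0 - r_test / r_ctrl) * 100.0
    return {"lysis_percent": raw, "lysis_percent_clipped": float(np.clip(raw, 0.0, 100.0))}


def relative_expression(
    ct_records: pd.DataFrame,
    target_gene: str,
    housekeeping_genes: Sequence[str],
    reference_sample: str,
) -> pd.DataFrame:
    """Comparative-ΔCt fold change of a target gene per sample.

    ``ct_records`` is long: ``sample``, ``gene``, ``ct``. For each
    sample, ΔCt = Ct(target) - mean Ct over the housekeeping genes;
    ΔΔCt subtracts the reference sample's ΔCt; fold = 2^-ΔΔCt. The
    reference sample's fold is exactly 1 by construction.
    """
    if not housekeeping_genes:
        raise ValueError("at least one housekeeping gene is required")
    piv = ct_records.pivot_table(index="sample", columns="gene", values="ct")
    if target_gene not in piv.columns:
        raise KeyError(f"no Ct values for target gene {target_gene!r}")
    for hk in housekeeping_genes:
        if hk not in piv.columns or piv[hk].isna().any():
            raise KeyError(f"missing housekeeping Ct for gene {hk!r}")
    if reference_sample not in piv.index:
        raise KeyError(f"reference sample {reference_sample!r} absent")
    hk_mean = piv[list(housekeeping_genes)].mean(axis=1)
    dct = piv[target_gene] - hk_mean
    ddct = dct - dct.loc[reference_sample]
    out = pd.DataFrame({
        "sample": piv.index,
        "delta_ct": dct.to_numpy(),
        "delta_delta_ct": ddct.to_numpy(),
        "fold_change": np.power(2.0, -ddct.to_numpy()),
    })
    return out.reset_index(drop=True)
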