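"""Normalized spectral abundance factors (NSAF).

NSAF expresses a protein's share of a purified complex from spectral
counting: the spectral count of protein *i* is divided by its length
(longer proteins yield more peptides per mole) and normalized over all
proteins in the sample,

    NSAF_i = (SpC_i / L_i) / sum_j (SpC_j / L_j)

so the values of a sample sum to 1.  Whether the count column holds
unique or total spectral counts is the caller's choice; the computation
is identical.
"""

from __future__ import annotations

import pandas as pd

from .errors import ExonRnpError


def nsaf(counts: pd.DataFrame) -> pd.DataFrame:
    """Append an ``nsaf`` column to a (protein, spc, length) table.

    Proteins with zero counts are retained with NSAF 0 so that tables
    from different complexes stay aligned row-for-row.
    """
    if counts.empty:
        raise ExonRnpError("no spectral count records")
    if (counts["length"] < 1).any():
        bad = counts.loc[counts["length"] < 1, "protein"].iloc[0]
        raise ValueError(f"protein length must be >= 1 (offending protein: {bad})")
    if (counts["spc"] < 0).any():
        bad = counts.loc[counts["spc"] < 0, "protein"].iloc[0]
        raise ValueError(f"spectral counts must be >= 0 (offending protein: {bad})")

    saf = counts["spc"] / counts["length"]
    total = saf.sum()
    if total <= 0:
        raise ExonRnpError("no spectra: all spectral counts are zero")
    out = counts.copy()
    out["nsaf"] = saf / total
    return out
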