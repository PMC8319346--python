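"""emPAI summarization of shotgun proteomics tables.

The exponentially modified protein abundance index (emPAI) is roughly
proportional to a protein's molar amount in the sample, so molar
percentages follow directly: pct_i = emPAI_i / sum_j emPAI_j * 100.
The tailocin fraction of a partially purified sample is the summed
molar percentage of the proteins mapped to the tailocin gene cluster
(the ``is_tailocin`` flag is input metadata, assigned upstream).
"""

from __future__ import annotations

import pandas as pd

from .errors import FormatError

__all__ = ["molar_percent", "tailocin_fraction", "empai_summary"]


def molar_percent(records: pd.DataFrame) -> pd.Series:
    """Per-protein molar percentage for one sample's emPAI records.

    ``records`` needs columns ``protein`` and ``empai``; all emPAI
    values must be strictly positive (zeros would mean undetected
    proteins, which these tables do not list — reject rather than drop
    silently).
    """
    if records.empty:
        raise FormatError("emPAI table is empty")
    values = pd.to_numeric(records["empai"])
    bad = values <= 0
    if bad.any():
        prot = records.loc[bad.idxmax(), "protein"]
        raise FormatError(f"non-positive emPAI value for protein {prot!r}")
    pct = values / values.sum() * 100.0
    pct.index = pd.Index(records["protein"], name="protein")
    pct.name = "molar_percent"
    return pct


def tailocin_fraction(records: pd.DataFrame) -> float:
    """Summed molar percentage of tailocin-flagged proteins (0-100)."""
    pct = molar_percent(records)
    mask = records["is_tailocin"].astype(bool).to_numpy()
    return float(pct.to_numpy()[mask].sum())


def empai_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample protein counts and tailocin molar fraction."""
    rows = []
    for sample, d in table.groupby("sample"):
        rows.append(
            {
                "sample": sample,
                "n_proteins": len(d),
                "tailocin_fraction_pct": tailocin_fraction(d),
            }
        )
    return pd.DataFrame(rows)
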