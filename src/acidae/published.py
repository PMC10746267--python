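"""Worked-example reference data: E. coli mild-acid-stress top tables.

The module ships the printed top-20 table of genes with *decreased*
ribosome-footprint (RPF) levels at pH 5.8 vs pH 7.6 — per-gene Ribo-Seq
and RNA-Seq log2 fold changes, BH-adjusted p-values and annotated cellular
location (C cytosol, IM inner membrane, OM outer membrane, P periplasm).
It is used as a small real-data worked example for the regulatory
classification and for the observation that membrane and periplasmic
proteins dominate the down-regulated response to mild acid stress.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["top20_down_ph58", "membrane_or_periplasmic"]

# gene, lfc_ribo, padj_ribo, lfc_rna, padj_rna, cellular location
_TOP20_DOWN_PH58 = [
    ("yjcH", -5.59, 3e-27, -3.14, 1e-8, "IM"),
    ("actP", -4.63, 2e-47, -3.58, 1e-11, "IM"),
    ("lamB", -4.32, 3e-6, -2.27, 6e-6, "OM"),
    ("dppD", -4.23, 5e-33, -3.79, 9e-15, "IM"),
    ("acs", -4.06, 3e-20, -2.60, 3e-6, "C"),
    ("malK", -3.96, 2e-18, -2.64, 2e-10, "IM"),
    ("dppC", -3.83, 1e-28, -3.78, 5e-13, "IM"),
    ("malG", -3.82, 5e-20, -2.52, 4e-7, "IM"),
    ("dppF", -3.75, 4e-34, -3.93, 4e-18, "IM"),
    ("dppB", -3.74, 1e-31, -3.74, 1e-16, "IM"),
    ("malM", -3.69, 7e-5, -2.06, 2e-6, "P"),
    ("melB", -3.60, 6e-28, -1.24, 0.03, "IM"),
    ("ydcT", -3.59, 2e-27, -3.61, 1e-10, "IM"),
    ("ydcS", -3.57, 1e-31, -4.05, 9e-15, "IM,P"),
    ("gabP", -3.56, 5e-19, -2.76, 9e-8, "IM"),
    ("ydcV", -3.48, 1e-23, -3.39, 1e-8, "IM"),
    ("ydhY", -3.44, 5e-16, -0.40, 0.23, "IM"),
    ("gudP", -3.42, 5e-21, -3.50, 4e-7, "IM"),
    ("astE", -3.34, 2e-15, -3.47, 1e-5, "C"),
    ("malE", -3.32, 1e-12, -2.52, 1e-9, "IM,P"),
]


def top20_down_ph58() -> pd.DataFrame:
    """The printed top-20 decreased-RPF table (pH 5.8 vs 7.6)."""
    return pd.DataFrame(
        _TOP20_DOWN_PH58,
        columns=["gene", "lfc_ribo", "padj_ribo", "lfc_rna", "padj_rna", "location"],
    )


def membrane_or_periplasmic(location: str) -> bool:
    """True if any annotated compartment is membrane or periplasm."""
    return any(part in ("IM", "OM", "P") for part in location.split(","))
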