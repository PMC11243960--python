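"""Packaged worked-example datasets.

Small published summary tables from a UV-B stress study of the alpine shrub
*Rhododendron chrysanthum* (groups: A control, B UV-B, C UV-B+ABA, D ABA),
shipped as plain TSV so the screening and correlation rules can be exercised
on real numbers:

* :func:`load_calvin_cycle_degs` — differentially expressed genes of the
  Calvin-cycle pathway for the A-vs-B comparison, with Q-values, log2 fold
  changes (B over A) and EC-number annotations;
* :func:`load_g2like_tf_members` — G2-like (GLK) transcription-factor family
  members with per-comparison log2 fold changes and Q-values;
* :func:`load_tf_calvin_correlations` — Pearson correlations between the two
  recurrent G2-like members and Calvin-cycle genes.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

_FIXTURES = resources.files("fluoromics") / "fixtures"


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_FIXTURES / name) as path:
        return pd.read_csv(path, sep="\t")


def load_calvin_cycle_degs() -> pd.DataFrame:
    """Calvin-cycle DEG table (A vs B): gene, Q-value, log2FC, p, EC number."""
    return _read("calvin_cycle_degs.tsv")


def load_g2like_tf_members(long: bool = False) -> pd.DataFrame:
    """G2-like TF family table across the AvsB, DvsC and AvsC comparisons.

    The published table lists one gene twice; the wide form preserves the
    duplication as printed.  With ``long=True`` the table is melted to one
    row per (gene, comparison) with columns log2fc/qvalue/fc, de-duplicated
    on (gene, comparison).
    """
    wide = _read("g2like_tf_members.tsv")
    if not long:
        return wide
    frames = []
    for comparison, (lfc_col, q_col) in {
        "AvsB": ("log2fc_BvsA", "qvalue_AvsB"),
        "DvsC": ("log2fc_CvsD", "qvalue_DvsC"),
        "AvsC": ("log2fc_CvsA", "qvalue_AvsC"),
    }.items():
        sub = wide[["gene_id", lfc_col, q_col]].dropna()
        sub = sub.rename(columns={lfc_col: "log2fc", q_col: "qvalue"})
        sub["comparison"] = comparison
        frames.append(sub)
    out = pd.concat(frames, ignore_index=True)
    out = out.drop_duplicates(subset=["gene_id", "comparison"])
    out["fc"] = np.exp2(out["log2fc"])
    return out[["gene_id", "comparison", "log2fc", "fc", "qvalue"]]


def load_tf_calvin_correlations() -> pd.DataFrame:
    """TF–gene Pearson correlation table: tf, gene, PCC, p-value."""
    return _read("tf_calvin_correlations.tsv")
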