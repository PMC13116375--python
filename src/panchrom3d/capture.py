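"""Capture Hi-C differential interaction calling.

Consumes CHiCAGO-style interaction confidence scores (one per condition) and
applies the high-confidence rule (score >= 3) and the MT-vs-WT differential
rule: significant in one condition, non-significant in the other, and a
score difference above 3.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SIG_THRESHOLD = 3.0
DIFF_DELTA = 3.0


def call_significant(scores, threshold: float = SIG_THRESHOLD) -> np.ndarray:
    """High-confidence mask: score >= threshold (inclusive)."""
    return np.asarray(scores, dtype=float) >= threshold


def differential_interactions(
    table: pd.DataFrame,
    wt_col: str = "score_wt",
    mt_col: str = "score_mt",
    sig: float = SIG_THRESHOLD,
    delta: float = DIFF_DELTA,
) -> pd.DataFrame:
    """Label each row MT_enhanced / WT_enhanced / none.

    MT_enhanced iff MT >= sig AND WT < sig AND MT - WT > delta; WT_enhanced
    is the mirror image.  The two labels are mutually exclusive by
    construction.
    """
    wt = table[wt_col].to_numpy(dtype=float)
    mt = table[mt_col].to_numpy(dtype=float)
    if (wt < 0).any() or (mt < 0).any():
        raise ValueError("interaction scores must be non-negative")
    mt_enh = (mt >= sig) & (wt < sig) & (mt - wt > delta)
    wt_enh = (wt >= sig) & (mt < sig) & (wt - mt > delta)
    out = table.copy()
    out["label"] = np.where(mt_enh, "MT_enhanced",
                            np.where(wt_enh, "WT_enhanced", "none"))
    return out
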