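"""Transmembrane-domain consensus and localization-category summaries.

A protein counts as a membrane protein iff *any* of the four prediction
programs (two alpha-helix topology, two beta-barrel) reports at least one
transmembrane domain. Raw predictor outputs are consumed as pre-parsed
integer count tables; proteins absent from the table count as 0 TMDs.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import UsageError
from .io import AnnotationMap, TMTable, TM_PROGRAMS

logger = logging.getLogger(__name__)


def tm_consensus(tm: TMTable) -> tuple[pd.DataFrame, float]:
    """Per-protein membrane call and the overall membrane fraction.

    Returns a frame with per-program counts, ``max_tmd`` and
    ``is_membrane`` (max_tmd >= 1), plus membrane proteins / total.
    """
    df = tm.data.copy()
    counts = df[list(TM_PROGRAMS)].to_numpy()
    df["max_tmd"] = counts.max(axis=1) if len(df) else np.array([], dtype=int)
    df["is_membrane"] = df["max_tmd"] >= 1
    fraction = float(df["is_membrane"].mean()) if len(df) else float("nan")
    return df, fraction


def tmd_histogram(tm: TMTable, program: str) -> pd.Series:
    """Histogram of predicted TMD counts for one program, over 0..max.
    Bin counts sum to the number of proteins."""
    if program not in TM_PROGRAMS:
        raise UsageError(
            f"unknown program {program!r}; expected one of {TM_PROGRAMS}")
    counts = tm.data[program]
    if counts.empty:
        return pd.Series(dtype=int, name=program)
    hist = counts.value_counts().reindex(
        range(0, int(counts.max()) + 1), fill_value=0).sort_index()
    hist.index.name = "n_tmd"
    hist.name = program
    return hist


def category_summary(annotation: AnnotationMap,
                     mode: str = "hcm") -> pd.Series:
    """Percentage of proteins per localization category.

    ``mode`` selects the high-confidence-marker column ("hcm") or the
    consensus-predictor column ("consensus"). Proteins without a category
    fall in "unassigned"; in consensus mode a protein predicted in several
    locations is counted once under "multiple". Percentages sum to 100.
    """
    if mode not in ("hcm", "consensus"):
        raise UsageError("mode must be 'hcm' or 'consensus'")
    df = annotation.data
    labels = []
    for value in df[mode]:
        cats = [c for c in str(value).split(";") if c]
        if not cats:
            labels.append("unassigned")
        elif len(cats) > 1:
            labels.append("multiple")
        else:
            labels.append(cats[0])
    ser = pd.Series(labels, name=mode)
    pct = ser.value_counts().sort_index() / len(ser) * 100.0
    pct.index.name = "category"
    return pct
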