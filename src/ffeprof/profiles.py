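"""Compartment consensus profiles from marker proteins.

A compartment's consensus is the element-wise median of its detected
markers' unit-sum profiles, renormalized to unit sum. The median is robust
to the isoform-specific outliers curated marker lists are known to contain
(e.g. V-ATPase subunits whose cathodic population dominates).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import MarkerSet
from .preprocess import WesternSet, unit_normalize

logger = logging.getLogger(__name__)


@dataclass
class CompartmentProfile:
    name: str
    consensus: np.ndarray      # unit-sum over the analysis window
    samples: np.ndarray
    n_markers: int
    marker_ids: list[str] = field(default_factory=list)
    coherence: float | None = None  # median pairwise Pearson r among markers


def _detected_marker_profiles(
    westerns: WesternSet, markers: MarkerSet
) -> dict[str, pd.DataFrame]:
    """Unit-normalized profiles of markers present (non-zero) in the run,
    grouped by compartment. Absent markers are skipped, not imputed."""
    out: dict[str, pd.DataFrame] = {}
    for comp, ids in markers.by_compartment().items():
        rows = {}
        for pid in ids:
            if pid not in westerns:
                logger.warning("marker %s not detected in run; skipped", pid)
                continue
            prof, all_zero = unit_normalize(westerns.profiles.loc[pid].to_numpy())
            if all_zero:
                logger.warning("marker %s has an all-zero profile; skipped", pid)
                continue
            rows[pid] = prof
        if rows:
            out[comp] = pd.DataFrame.from_dict(
                rows, orient="index", columns=westerns.samples)
        else:
            logger.warning("compartment %s: no detected markers; omitted", comp)
    return out


def build_consensus(westerns: WesternSet,
                    markers: MarkerSet) -> dict[str, CompartmentProfile]:
    """Element-wise median of unit-normalized marker profiles per
    compartment, renormalized to unit sum."""
    if len(markers) == 0:
        raise ConfigError("marker set is empty")
    grouped = _detected_marker_profiles(westerns, markers)
    out: dict[str, CompartmentProfile] = {}
    for comp, profs in grouped.items():
        median = profs.median(axis=0).to_numpy()
        consensus, _ = unit_normalize(median)
        out[comp] = CompartmentProfile(
            name=comp,
            consensus=consensus,
            samples=westerns.samples,
            n_markers=len(profs),
            marker_ids=list(profs.index),
        )
    return out


def marker_coherence(westerns: WesternSet, markers: MarkerSet,
                     floor: float = 0.5) -> pd.DataFrame:
    """Per-compartment marker agreement report.

    For each compartment with >= 2 detected markers: the median and minimum
    pairwise Pearson correlation among marker profiles, and markers whose
    median correlation to the others falls below ``floor`` listed as
    outliers. Single-marker compartments report NaN (not applicable).
    """
    grouped = _detected_marker_profiles(westerns, markers)
    rows = []
    for comp, profs in grouped.items():
        ids = list(profs.index)
        if len(ids) < 2:
            rows.append({"compartment": comp, "n_markers": len(ids),
                         "median_r": np.nan, "min_r": np.nan,
                         "outliers": ""})
            continue
        mat = profs.to_numpy()
        corr = np.corrcoef(mat)
        pair_r = [corr[i, j]
                  for i, j in itertools.combinations(range(len(ids)), 2)]
        per_marker = [
            float(np.median(np.delete(corr[i], i))) for i in range(len(ids))
        ]
        outliers = [pid for pid, r in zip(ids, per_marker) if r < floor]
        for pid in outliers:
            logger.warning("marker %s is an outlier in %s "
                           "(median r to peers < %.2f)", pid, comp, floor)
        rows.append({
            "compartment": comp,
            "n_markers": len(ids),
            "median_r": float(np.median(pair_r)),
            "min_r": float(np.min(pair_r)),
            "outliers": ";".join(outliers),
        })
    report = pd.DataFrame(
        rows, columns=["compartment", "n_markers", "median_r", "min_r",
                       "outliers"])
    return report.sort_values("compartment").reset_index(drop=True)


def build_consensus_robust(westerns: WesternSet, markers: MarkerSet,
                           floor: float = 0.5) -> dict[str, CompartmentProfile]:
    """Consensus with below-floor outlier markers excluded first (opt-in;
    the default consensus uses curated lists as-is)."""
    report = marker_coherence(westerns, markers, floor=floor)
    drop = set()
    for outliers in report["outliers"]:
        drop.update(x for x in str(outliers).split(";") if x)
    kept = markers.data[~markers.data["protein_id"].isin(drop)]
    return build_consensus(westerns, MarkerSet(kept.reset_index(drop=True)))


def consensus_to_frame(
    consensus: dict[str, CompartmentProfile]) -> pd.DataFrame:
    """Consensus profiles as a compartment x sample table (for TSV export)."""
    return pd.DataFrame(
        {comp: prof.consensus for comp, prof in consensus.items()},
        index=next(iter(consensus.values())).samples,
    ).T.rename_axis("compartment").reset_index()
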