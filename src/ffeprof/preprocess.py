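"""From 96 raw fractions to per-protein "digital western" profiles.

The chain mirrors the wet-lab processing: adjacent fractions are physically
combined (summed) into 48 pooled samples, the analysis window is the
largest contiguous run of pooled samples with positive OD280, peak areas
are normalized per sample to OD280 (a protein-amount proxy), replicates
are averaged, and profiles are scaled to unit sum so that only shape, not
magnitude, is compared downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import EmptyWindowError, FfeprofError, UsageError
from .io import FractionationRun, QuantMatrix

logger = logging.getLogger(__name__)


@dataclass
class DigitalWestern:
    """One protein's replicate-averaged, OD-normalized, unit-sum profile
    over the analysis window, plus per-sample replicate dispersion (SD)."""

    protein_id: str
    samples: np.ndarray   # pooled sample indices, contiguous, 1-based
    profile: np.ndarray   # unit-sum unless all-zero
    dispersion: np.ndarray
    all_zero: bool = False


class WesternSet:
    """Digital westerns for a whole run, profile matrix oriented
    proteins x window samples."""

    def __init__(self, profiles: pd.DataFrame, dispersion: pd.DataFrame,
                 window: tuple[int, int]):
        self.profiles = profiles
        self.dispersion = dispersion
        self.window = window

    @property
    def samples(self) -> np.ndarray:
        return self.profiles.columns.to_numpy()

    @property
    def proteins(self) -> list[str]:
        return list(self.profiles.index)

    def __getitem__(self, protein_id: str) -> DigitalWestern:
        prof = self.profiles.loc[protein_id].to_numpy()
        return DigitalWestern(
            protein_id=protein_id,
            samples=self.samples,
            profile=prof,
            dispersion=self.dispersion.loc[protein_id].to_numpy(),
            all_zero=bool(not prof.any()),
        )

    def __contains__(self, protein_id: str) -> bool:
        return protein_id in self.profiles.index

    def __len__(self) -> int:
        return len(self.profiles)


def pool_fractions(matrix: QuantMatrix, k: int = 2) -> QuantMatrix:
    """Combine adjacent fractions by summation: pooled sample ``s``
    aggregates fractions ``k(s-1)+1 .. ks``. Total per-protein signal is
    conserved exactly."""
    if matrix.level != "fraction":
        raise UsageError("pool_fractions requires a fraction-level matrix")
    n = int(matrix.samples.max())
    if n % k:
        raise UsageError(f"pooling width {k} does not divide {n} fractions")
    df = matrix.data.copy()
    df["sample"] = (df["sample"] - 1) // k + 1
    pooled = (
        df.groupby(["protein_id", "sample", "replicate"], sort=True,
                   as_index=False)["peak_area"].sum()
    )
    return QuantMatrix(pooled, level="pooled")


def pool_od280(run: FractionationRun, k: int = 2) -> pd.Series:
    """Pool the OD280 trace with the same geometry (sum of member
    fractions); index is the pooled sample, 1-based."""
    od = run.od280
    pooled_index = (od.index.to_numpy() - 1) // k + 1
    pooled = od.groupby(pooled_index).sum()
    pooled.index.name = "sample"
    pooled.name = "od280"
    return pooled


def select_analysis_window(pooled_od: pd.Series,
                           threshold: float = 0.0) -> tuple[int, int]:
    """Largest contiguous run of pooled samples with OD strictly greater
    than ``threshold``, as an inclusive (lo, hi) range. Ties go to the
    most anodic (lowest-index) run."""
    positive = (pooled_od.to_numpy() > threshold)
    samples = pooled_od.index.to_numpy()
    best: tuple[int, int] | None = None
    start = None
    for i, flag in enumerate([*positive, False]):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if best is None or (i - start) > (best[1] - best[0] + 1):
                best = (int(samples[start]), int(samples[i - 1]))
            start = None
    if best is None:
        raise EmptyWindowError("no pooled sample has positive OD280")
    return best


def normalize_to_od280(matrix: QuantMatrix, pooled_od: pd.Series,
                       window: tuple[int, int]) -> QuantMatrix:
    """Divide each (protein, sample, replicate) peak area by that sample's
    pooled OD280; samples outside the window are dropped."""
    if matrix.level != "pooled":
        raise UsageError("normalize_to_od280 requires a pooled-level matrix")
    lo, hi = window
    od = pooled_od.loc[lo:hi]
    if (od.to_numpy() <= 0).any():
        raise FfeprofError("OD280 must be positive inside the window")
    df = matrix.data[matrix.data["sample"].between(lo, hi)].copy()
    df["peak_area"] = df["peak_area"] / df["sample"].map(od).to_numpy()
    return QuantMatrix(df.reset_index(drop=True), level="pooled")


def average_replicates(
    matrix: QuantMatrix,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Arithmetic mean and SD over replicates per (protein, sample).

    Zero (non-detected) cells are included in the mean; replicates in which
    a protein was entirely undetected are counted, not dropped, with a
    low-coverage warning logged.
    """
    wide = matrix.pivot()  # (protein, replicate) x sample
    by_protein = wide.groupby(level="protein_id", sort=True)
    mean = by_protein.mean()
    sd = by_protein.std(ddof=0)
    empty_reps = wide.index[(wide.to_numpy() == 0).all(axis=1)]
    for pid, rep in empty_reps:
        logger.warning(
            "protein %s: replicate %s entirely undetected "
            "(averaged including zeros)", pid, rep)
    return mean, sd


def unit_normalize(profile: np.ndarray) -> tuple[np.ndarray, bool]:
    """Scale a profile to unit sum. All-zero input passes through
    unchanged, flagged True."""
    profile = np.asarray(profile, dtype=float)
    total = profile.sum()
    if total == 0:
        return profile.copy(), True
    return profile / total, False


def build_westerns(matrix: QuantMatrix, run: FractionationRun | None = None,
                   k: int = 2,
                   window: tuple[int, int] | None = None) -> WesternSet:
    """Full chain: pool -> window -> OD-normalize -> average -> unit-sum.

    ``matrix`` may be fraction- or pooled-level. The window is recomputed
    from the OD trace when one is provided, unless explicitly overridden;
    with neither, the default window (pooled samples 8..35) is used without
    OD normalization.
    """
    if matrix.level == "fraction":
        matrix = pool_fractions(matrix, k)
    if run is not None:
        pooled_od = pool_od280(run, k)
        if window is None:
            window = select_analysis_window(pooled_od)
        matrix = normalize_to_od280(matrix, pooled_od, window)
    else:
        if window is None:
            window = (8, 35)
        df = matrix.data[matrix.data["sample"].between(*window)]
        matrix = QuantMatrix(df.reset_index(drop=True), level="pooled")
    mean, sd = average_replicates(matrix)
    lo, hi = window
    mean = mean.reindex(columns=np.arange(lo, hi + 1), fill_value=0.0)
    sd = sd.reindex(columns=np.arange(lo, hi + 1), fill_value=0.0)
    totals = mean.sum(axis=1)
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("%d all-zero profiles left unnormalized", n_zero)
    scale = totals.replace(0, 1.0)
    profiles = mean.div(scale, axis=0)
    dispersion = sd.div(scale, axis=0)
    return WesternSet(profiles, dispersion, window)
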