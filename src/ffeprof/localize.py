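"""Compartment assignment, population detection, and discordance flags.

Each protein's digital western is compared to every compartment consensus
by Pearson correlation (profiles are unit-sum, so the comparison is purely
of shape). Assignment requires both a minimum correlation and a minimum
margin over the runner-up; exact ties are never broken arbitrarily.

A profile's *populations* are contiguous peaks of abundance mass along the
fraction axis, found on a lightly smoothed profile by topographic
prominence and quantified by the raw mass of each peak's watershed basin.
Two populations mapping to different compartments' characteristic windows
flag candidate dual localization; disagreement between the profile-based
assignment and prior annotation flags discordance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import find_peaks

from .errors import UsageError
from .io import AnnotationMap
from .preprocess import WesternSet
from .profiles import CompartmentProfile

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class Population:
    """One abundance population: its peak sample (argmax of the raw
    profile within the basin), the profile mass in the basin, and the
    compartment window the peak maps to (None if it maps nowhere)."""

    peak_sample: int
    mass: float
    compartment: str | None = None


@dataclass
class LocalizationCall:
    protein_id: str
    scores: dict[str, float | None]
    assigned: str = UNASSIGNED
    margin: float | None = None
    tie: bool = False
    populations: list[Population] = field(default_factory=list)
    dual_flag: bool = False
    discordance_flag: bool = False
    unannotated: bool = False


# ---------------------------------------------------------------------------
# scoring and assignment
# ---------------------------------------------------------------------------

def score_protein(
    profile: np.ndarray,
    consensus: dict[str, CompartmentProfile],
) -> dict[str, float | None]:
    """Pearson correlation of a unit-sum profile against each compartment
    consensus. Scores are undefined (None) for a constant or all-zero
    profile, or against a constant consensus."""
    profile = np.asarray(profile, dtype=float)
    out: dict[str, float | None] = {}
    p_sd = profile.std()
    for comp, cp in consensus.items():
        if len(cp.consensus) != len(profile):
            raise UsageError(
                f"profile length {len(profile)} does not match consensus "
                f"window of {comp} ({len(cp.consensus)})"
            )
        c_sd = cp.consensus.std()
        if p_sd == 0 or c_sd == 0:
            out[comp] = None
            continue
        out[comp] = float(np.corrcoef(profile, cp.consensus)[0, 1])
    return out


def assign(scores: dict[str, float | None], r_min: float = 0.8,
           margin_min: float = 0.1) -> tuple[str, float | None, bool]:
    """Assign the argmax compartment iff best r >= r_min and the margin
    over the runner-up >= margin_min; exact top ties -> unassigned with the
    tie flag. Returns (compartment-or-'unassigned', margin, tie)."""
    valid = {c: r for c, r in scores.items() if r is not None}
    if not valid:
        return UNASSIGNED, None, False
    ranked = sorted(valid.items(), key=lambda kv: -kv[1])
    best_comp, best_r = ranked[0]
    if len(ranked) == 1:
        return (best_comp if best_r >= r_min else UNASSIGNED), None, False
    second_r = ranked[1][1]
    margin = best_r - second_r
    if margin == 0.0:
        return UNASSIGNED, 0.0, True
    if best_r >= r_min and margin >= margin_min:
        return best_comp, margin, False
    return UNASSIGNED, margin, False


# ---------------------------------------------------------------------------
# population detection
# ---------------------------------------------------------------------------

def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    """Centered moving average with zero padding at the edges."""
    if width <= 1:
        return x.astype(float)
    half = width // 2
    padded = np.concatenate([np.zeros(half), x, np.zeros(half)])
    kernel = np.ones(width) / width
    return np.convolve(padded, kernel, mode="valid")


def detect_populations(profile: np.ndarray,
                       samples: np.ndarray | None = None,
                       smooth_width: int = 3,
                       prominence_frac: float = 0.10,
                       mass_min: float = 0.15) -> list[Population]:
    """Find abundance populations in a unit-sum profile.

    The profile is smoothed by a centered moving average (zero-padded, odd
    ``smooth_width``); local maxima of the smoothed profile with topographic
    prominence >= ``prominence_frac`` x its global maximum are retained
    (edges may host peaks). Basin boundaries between adjacent retained peaks
    sit at the smoothed minimum between them; the boundary sample's raw mass
    is split evenly between the two basins (keeping the output invariant
    under profile reversal). Each population's mass is the raw profile mass
    over its basin and its peak sample is the raw argmax within the basin.
    Populations with mass below ``mass_min`` are discarded. Output is sorted
    by sample index.
    """
    raw = np.asarray(profile, dtype=float)
    n = len(raw)
    if samples is None:
        samples = np.arange(1, n + 1)
    if n == 0 or raw.sum() <= 0:
        return []
    sm = _moving_average(raw, smooth_width)
    # pad with -1 so boundary samples can be detected as peaks
    padded = np.concatenate([[-1.0], sm, [-1.0]])
    peaks, _ = find_peaks(padded, prominence=prominence_frac * sm.max())
    idx = peaks - 1
    if len(idx) == 0:
        return []
    interior = [a + int(np.argmin(sm[a:b + 1]))
                for a, b in zip(idx[:-1], idx[1:])]
    pops = []
    for j in range(len(idx)):
        lo = interior[j - 1] if j > 0 else 0
        hi = interior[j] if j < len(idx) - 1 else n - 1
        mass = float(raw[lo:hi + 1].sum())
        if j > 0:
            mass -= raw[lo] / 2.0
        if j < len(idx) - 1:
            mass -= raw[hi] / 2.0
        if mass < mass_min:
            continue
        # interior boundary samples are smoothed minima, not peaks:
        # exclude them from the argmax search
        a = lo + 1 if j > 0 else lo
        b = hi - 1 if j < len(idx) - 1 else hi
        peak_pos = a + int(np.argmax(raw[a:b + 1]))
        pops.append(Population(int(samples[peak_pos]), mass))
    return sorted(pops, key=lambda p: p.peak_sample)


# ---------------------------------------------------------------------------
# dual localization and discordance
# ---------------------------------------------------------------------------

def compartment_windows(
    consensus: dict[str, CompartmentProfile],
) -> dict[str, list[tuple[int, int]]]:
    """Characteristic windows per compartment: the contiguous sample runs
    where the consensus exceeds half its own maximum. A bimodal consensus
    yields two windows."""
    out: dict[str, list[tuple[int, int]]] = {}
    for comp, cp in consensus.items():
        above = cp.consensus > 0.5 * cp.consensus.max()
        runs: list[tuple[int, int]] = []
        start = None
        for i, flag in enumerate([*above, False]):
            if flag and start is None:
                start = i
            elif not flag and start is not None:
                runs.append((int(cp.samples[start]), int(cp.samples[i - 1])))
                start = None
        out[comp] = runs
    return out


def _in_windows(sample: int, runs: list[tuple[int, int]]) -> bool:
    return any(lo <= sample <= hi for lo, hi in runs)


def flag_dual(
    populations: list[Population],
    windows: dict[str, list[tuple[int, int]]],
    consensus: dict[str, CompartmentProfile] | None = None,
    assigned: str | None = None,
) -> tuple[bool, list[Population]]:
    """Map each population to a compartment window and flag dual
    localization iff >= 2 populations map to different compartments.

    A population maps to the assigned compartment whenever that
    compartment's own windows contain its peak (a bimodal compartment's
    second population is not evidence of dual localization); otherwise to
    the in-window compartment with the highest consensus value at the peak
    sample (or None if no window contains it).
    """
    mapped: list[Population] = []
    for pop in populations:
        if (assigned and assigned in windows
                and _in_windows(pop.peak_sample, windows[assigned])):
            mapped.append(replace(pop, compartment=assigned))
            continue
        candidates = [c for c, runs in windows.items()
                      if _in_windows(pop.peak_sample, runs)]
        if not candidates:
            mapped.append(replace(pop, compartment=None))
            continue
        if consensus is not None:
            def value_at(comp: str) -> float:
                cp = consensus[comp]
                pos = np.where(cp.samples == pop.peak_sample)[0]
                return float(cp.consensus[pos[0]]) if len(pos) else -np.inf
            best = max(candidates, key=value_at)
        else:
            best = candidates[0]
        mapped.append(replace(pop, compartment=best))
    distinct = {p.compartment for p in mapped if p.compartment is not None}
    return len(distinct) >= 2, mapped


def flag_discordant(assigned: str, protein_id: str,
                    annotation: AnnotationMap | None) -> tuple[bool, bool]:
    """Discordance iff the profile assignment differs from the prior
    annotation (high-confidence marker preferred over consensus
    prediction). Unassigned or unannotated proteins are never flagged.
    Returns (discordant, unannotated)."""
    if assigned == UNASSIGNED:
        return False, annotation is None or protein_id not in annotation
    if annotation is None or protein_id not in annotation:
        return False, True
    prior = annotation.compartments_of(protein_id)
    if not prior:
        return False, True
    return assigned not in prior, False


# ---------------------------------------------------------------------------
# full pipeline over a run
# ---------------------------------------------------------------------------

def localize_all(westerns: WesternSet,
                 consensus: dict[str, CompartmentProfile],
                 annotation: AnnotationMap | None = None,
                 r_min: float = 0.8, margin_min: float = 0.1,
                 smooth_width: int = 3, prominence_frac: float = 0.10,
                 mass_min: float = 0.15) -> list[LocalizationCall]:
    """Score, assign, detect populations, and flag every protein in a run."""
    windows = compartment_windows(consensus)
    calls = []
    for pid in westerns.proteins:
        profile = westerns.profiles.loc[pid].to_numpy()
        scores = score_protein(profile, consensus)
        assigned, margin, tie = assign(scores, r_min, margin_min)
        pops = detect_populations(profile, samples=westerns.samples,
                                  smooth_width=smooth_width,
                                  prominence_frac=prominence_frac,
                                  mass_min=mass_min)
        dual, mapped = flag_dual(
            pops, windows, consensus=consensus,
            assigned=assigned if assigned != UNASSIGNED else None)
        discordant, unannotated = flag_discordant(assigned, pid, annotation)
        calls.append(LocalizationCall(
            protein_id=pid, scores=scores, assigned=assigned, margin=margin,
            tie=tie, populations=mapped, dual_flag=dual,
            discordance_flag=discordant, unannotated=unannotated))
    return calls


def evaluate(calls: list[LocalizationCall], truth,
             template_peak_counts: dict[str, int] | None = None,
             separation: int = 5) -> dict:
    """Recovery metrics against simulation ground truth.

    assignment_accuracy and false_dual_rate are computed over singleton
    proteins; dual_sensitivity over *well-separated* planted duals — those
    whose secondary compartment has a template peak at least ``separation``
    samples from every peak of the primary compartment, i.e. the duals for
    which a geometrically distinct second population exists at all.
    population-count accuracy compares detected population counts on
    singletons with their template's peak count.
    """
    by_id = {c.protein_id: c for c in calls}
    truth_df = truth.data
    singles = truth_df[truth_df["secondary"] == ""]
    n_correct = sum(
        by_id[pid].assigned == comp
        for pid, comp in zip(singles["protein_id"], singles["primary"])
        if pid in by_id
    )
    n_singles = int(singles["protein_id"].isin(by_id).sum())
    false_dual = sum(
        by_id[pid].dual_flag for pid in singles["protein_id"] if pid in by_id
    )

    metrics: dict = {
        "n_proteins": len(calls),
        "n_singletons": n_singles,
        "assignment_accuracy": n_correct / n_singles if n_singles else None,
        "false_dual_rate": false_dual / n_singles if n_singles else None,
        "unassigned_rate": (
            sum(c.assigned == UNASSIGNED for c in calls) / len(calls)
            if calls else None
        ),
    }

    if template_peak_counts is not None:
        ok = tot = 0
        for pid, comp in zip(singles["protein_id"], singles["primary"]):
            if pid in by_id and comp in template_peak_counts:
                tot += 1
                ok += len(by_id[pid].populations) == template_peak_counts[comp]
        metrics["population_count_accuracy"] = ok / tot if tot else None

    duals = truth_df[truth_df["secondary"] != ""]
    if len(duals) and hasattr(truth, "well_separated"):
        duals = truth.well_separated(separation)
    detected = sum(
        by_id[pid].dual_flag for pid in duals["protein_id"] if pid in by_id
    )
    n_duals = int(duals["protein_id"].isin(by_id).sum())
    metrics["n_well_separated_duals"] = n_duals
    metrics["dual_sensitivity"] = detected / n_duals if n_duals else None
    return metrics
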