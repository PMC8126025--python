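"""Scoring, assignment, population detection, dual/discordance flags."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ffeprof import (
    AnnotationMap,
    CompartmentProfile,
    UsageError,
    assign,
    compartment_windows,
    detect_populations,
    flag_discordant,
    flag_dual,
    score_protein,
    template_profile,
)
from ffeprof.localize import Population, UNASSIGNED
from ffeprof.simulate import CompartmentTemplate, GaussianPeak


def make_consensus(vectors: dict[str, list[float]]) -> dict:
    out = {}
    for name, vec in vectors.items():
        arr = np.asarray(vec, dtype=float)
        out[name] = CompartmentProfile(
            name=name, consensus=arr / arr.sum(),
            samples=np.arange(1, len(arr) + 1), n_markers=1)
    return out


# ---------------------------------------------------------------------------
# independent oracle for population detection
# ---------------------------------------------------------------------------

def oracle_populations(raw, smooth_width=3, prominence_frac=0.10,
                       mass_min=0.15, samples=None):
    """Exhaustive re-derivation: naive smoothing loop, local-maxima scan
    with virtual -1 boundaries, textbook topographic prominence by walking
    outward, basin boundaries at the minimum between peaks with the
    boundary sample's mass shared between the adjacent basins."""
    raw = np.asarray(raw, dtype=float)
    n = len(raw)
    if samples is None:
        samples = np.arange(1, n + 1)
    if n == 0 or raw.sum() <= 0:
        return []
    half = smooth_width // 2
    sm = np.array([
        sum(raw[j] for j in range(i - half, i + half + 1) if 0 <= j < n)
        / smooth_width
        for i in range(n)
    ])
    ext = np.concatenate([[-1.0], sm, [-1.0]])

    def prominence(p):  # p indexes ext
        h = ext[p]
        bases = []
        for step in (-1, 1):
            j = p + step
            m = h
            while 0 <= j < len(ext) and ext[j] <= h:
                m = min(m, ext[j])
                j += step
            bases.append(m)
        return h - max(bases)

    peaks = [i for i in range(n)
             if ext[i + 1] > ext[i] and ext[i + 1] > ext[i + 2]]
    thresh = prominence_frac * sm.max()
    peaks = [i for i in peaks if prominence(i + 1) >= thresh]
    if not peaks:
        return []
    cuts = [a + int(np.argmin(sm[a:b + 1]))
            for a, b in zip(peaks[:-1], peaks[1:])]
    pops = []
    for j in range(len(peaks)):
        lo = cuts[j - 1] if j > 0 else 0
        hi = cuts[j] if j < len(peaks) - 1 else n - 1
        mass = raw[lo:hi + 1].sum()
        if j > 0:
            mass -= raw[lo] / 2.0
        if j < len(peaks) - 1:
            mass -= raw[hi] / 2.0
        if mass < mass_min:
            continue
        a = lo + 1 if j > 0 else lo
        b = hi - 1 if j < len(peaks) - 1 else hi
        pk = a + int(np.argmax(raw[a:b + 1]))
        pops.append((int(samples[pk]), float(mass)))
    return sorted(pops)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

class TestScoreProtein:
    def test_self_correlation_is_one(self):
        cons = make_consensus({"PM": [1, 2, 5, 2, 1]})
        scores = score_protein(cons["PM"].consensus, cons)
        assert scores["PM"] == pytest.approx(1.0)

    def test_scale_invariance(self):
        cons = make_consensus({"PM": [1, 2, 5, 2, 1], "TP": [5, 3, 1, 1, 1]})
        profile = np.array([0.5, 1.0, 2.0, 1.5, 0.3])
        s1 = score_protein(profile / profile.sum(), cons)
        s2 = score_protein(2.0 * profile / profile.sum(), cons)
        for comp in cons:
            assert s1[comp] == pytest.approx(s2[comp], abs=1e-12)

    def test_matches_textbook_pearson_formula(self):
        x = np.array([0.1, 0.3, 0.2, 0.25, 0.15])
        y = np.array([0.05, 0.4, 0.3, 0.2, 0.05])
        cons = make_consensus({"C": y})
        score = score_protein(x, cons)["C"]
        yn = y / y.sum()
        xc, yc = x - x.mean(), yn - yn.mean()
        expected = (xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
        assert score == pytest.approx(expected, abs=1e-12)

    def test_all_zero_profile_undefined(self):
        cons = make_consensus({"PM": [1, 2, 5, 2, 1]})
        scores = score_protein(np.zeros(5), cons)
        assert scores["PM"] is None
        assert assign(scores)[0] == UNASSIGNED

    def test_window_mismatch_rejected(self):
        cons = make_consensus({"PM": [1, 2, 5, 2, 1]})
        with pytest.raises(UsageError):
            score_protein(np.ones(4) / 4, cons)


class TestAssign:
    def test_clear_winner(self):
        assert assign({"PM": 0.95, "ER": 0.40})[0] == "PM"

    def test_margin_too_small(self):
        assert assign({"PM": 0.85, "TGN": 0.82})[0] == UNASSIGNED

    def test_exact_tie_flagged(self):
        comp, margin, tie = assign({"PM": 0.9, "TP": 0.9})
        assert comp == UNASSIGNED and tie

    def test_grid_sweep_matches_rule_evaluator(self):
        # independent literal transcription of the assignment rule
        def oracle(scores, r_min=0.8, margin_min=0.1):
            ranked = sorted(scores.items(), key=lambda kv: -kv[1])
            best, second = ranked[0], ranked[1]
            if best[1] == second[1]:
                return UNASSIGNED
            if best[1] >= r_min and best[1] - second[1] >= margin_min:
                return best[0]
            return UNASSIGNED

        grid = np.round(np.arange(0.0, 1.0001, 0.05), 2)
        for a, b, c in itertools.product(grid, repeat=3):
            scores = {"TP": float(a), "GA": float(b), "PM": float(c)}
            assert assign(scores)[0] == oracle(scores), scores


class TestDetectPopulations:
    def test_unimodal_template_single_population(self):
        t = CompartmentTemplate("PM", (GaussianPeak(25, 1.5, 1.0),))
        prof = template_profile(t)[7:35]  # samples 8..35
        pops = detect_populations(prof, samples=np.arange(8, 36))
        assert len(pops) == 1
        assert pops[0].peak_sample == 25

    def test_tonoplast_template_two_populations(self):
        t = CompartmentTemplate("TP", (GaussianPeak(16, 1.6, 0.75),
                                       GaussianPeak(24, 0.7, 0.25)))
        prof = template_profile(t)[7:35]
        pops = detect_populations(prof, samples=np.arange(8, 36))
        assert len(pops) == 2
        assert 13 <= pops[0].peak_sample <= 19
        assert pops[1].peak_sample == 24

    def test_planted_60_40_mixture_masses(self):
        t = CompartmentTemplate("mix", (GaussianPeak(16, 1.0, 0.6),
                                        GaussianPeak(24, 1.0, 0.4)))
        prof = template_profile(t)[7:35]
        prof = prof / prof.sum()
        pops = detect_populations(prof, samples=np.arange(8, 36))
        assert [p.peak_sample for p in pops] == [16, 24]
        assert pops[0].mass == pytest.approx(0.6, abs=0.05)
        assert pops[1].mass == pytest.approx(0.4, abs=0.05)
        oracle = oracle_populations(prof, samples=np.arange(8, 36))
        assert [(p.peak_sample, p.mass) for p in pops] == pytest.approx(oracle)

    def test_matches_brute_force_oracle_on_random_profiles(self):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            raw = rng.random(28) ** rng.integers(1, 4)
            raw = raw / raw.sum()
            got = [(p.peak_sample, p.mass)
                   for p in detect_populations(raw)]
            expected = oracle_populations(raw)
            assert len(got) == len(expected)
            for (gs, gm), (es, em) in zip(got, expected):
                assert gs == es
                assert gm == pytest.approx(em, abs=1e-12)

    def test_reversal_symmetry(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            raw = rng.random(28)
            raw = raw / raw.sum()
            fwd = detect_populations(raw)
            rev = detect_populations(raw[::-1])
            assert sorted(29 - p.peak_sample for p in rev) == \
                [p.peak_sample for p in fwd]
            assert sorted(p.mass for p in rev) == pytest.approx(
                sorted(p.mass for p in fwd))

    def test_empty_and_zero_profiles(self):
        assert detect_populations(np.zeros(10)) == []
        assert detect_populations(np.array([])) == []


class TestFlagDual:
    WINDOWS = {"TP": [(13, 19), (24, 24)], "GA": [(23, 24)],
               "PM": [(24, 30)]}

    def test_both_peaks_inside_pm_window_not_dual(self):
        pops = [Population(25, 0.6), Population(27, 0.4)]
        dual, mapped = flag_dual(pops, {"PM": [(24, 30)]})
        assert not dual
        assert all(p.compartment == "PM" for p in mapped)

    def test_tp_and_ga_windows_dual(self):
        pops = [Population(16, 0.6), Population(23, 0.4)]
        dual, mapped = flag_dual(pops, self.WINDOWS)
        assert dual
        assert [p.compartment for p in mapped] == ["TP", "GA"]

    def test_single_population_never_dual(self):
        dual, _ = flag_dual([Population(16, 1.0)], self.WINDOWS)
        assert not dual

    def test_assigned_compartments_own_windows_not_dual(self):
        # a bimodal compartment's second population is not dual evidence
        pops = [Population(16, 0.75), Population(24, 0.25)]
        dual, mapped = flag_dual(pops, self.WINDOWS, assigned="TP")
        assert not dual
        assert all(p.compartment == "TP" for p in mapped)

    def test_peak_outside_all_windows_maps_to_none(self):
        dual, mapped = flag_dual(
            [Population(10, 0.5), Population(16, 0.5)], self.WINDOWS)
        assert mapped[0].compartment is None
        assert not dual


class TestFlagDiscordant:
    ANN = AnnotationMap(pd.DataFrame({
        "protein_id": ["NHX7", "AHA2"], "agi": ["At2g01980", ""],
        "hcm": ["PM", "PM"], "consensus": ["PM", ""]}))

    def test_pm_annotation_tp_assignment_flagged(self):
        flagged, unannotated = flag_discordant("TP", "NHX7", self.ANN)
        assert flagged and not unannotated

    def test_matching_assignment_not_flagged(self):
        flagged, _ = flag_discordant("PM", "AHA2", self.ANN)
        assert not flagged

    def test_unannotated_not_flagged(self):
        flagged, unannotated = flag_discordant("TP", "UNKNOWN", self.ANN)
        assert not flagged and unannotated

    def test_unassigned_never_flagged(self):
        flagged, _ = flag_discordant(UNASSIGNED, "NHX7", self.ANN)
        assert not flagged


class TestCompartmentWindows:
    def test_windows_are_half_max_runs(self):
        cons = make_consensus({"X": [0.1, 0.2, 1.0, 0.9, 0.2, 0.6, 0.1]})
        wins = compartment_windows(cons)
        assert wins["X"] == [(3, 4), (6, 6)]
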