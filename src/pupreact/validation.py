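"""Synthetic-benchmark suite: end-to-end recovery and exactness checks.

Each routine here regenerates its own inputs from a seed, runs the package
end to end, and measures agreement with ground truth or with an
independent oracle (exact rational arithmetic, full hypergeometric
enumeration, or a literal reimplementation of a scoring rule).  The
oracles are deliberately separate code paths from the implementations they
check.
"""

from __future__ import annotations

import warnings
from fractions import Fraction
from math import comb

import numpy as np

from . import tracking
from .arena import ArenaGeometry, Trajectory, center_time_fraction, \
    chamber_preference, object_preference, open_arm_fraction
from .ppi import airpuff_alone_response, percent_ppi
from .puncta import analyze_stack
from .reactivity import (OptoSession, PuffSession, PuffTrial,
                         apply_trial_exclusion, classify_habituation,
                         genotype_difference_sign, habituation_sensitivity,
                         repeated_mean, score_opto_session)
from .stats import ContingencyTable2x2, compare_habituation_fractions, \
    fisher_exact_one_sided
from .synthetic import CohortSpec, StackSpec, generate_cohort, \
    generate_confocal_stack, generate_puff_video


# --------------------------------------------------------------------------
# habituation classifier vs brute-force oracle
# --------------------------------------------------------------------------

def _oracle_classify(peaks, baselines, threshold=2.0, theta_incl=0.20,
                     theta_hab=0.25):
    """Literal reimplementation of the habituation rule, plain loops.

    Returns (category, habituated) where category is one of
    'first_excluded', 'not_included', 'insufficient', 'degenerate',
    'classified'.
    """
    excluded = [b > threshold for b in baselines]
    if excluded[0]:
        return "first_excluded", None
    if not peaks[0] > (1 + theta_incl) * baselines[0]:
        return "not_included", None
    first, last = [], []
    for k in range(3):
        if not excluded[k]:
            first.append(peaks[k])
    n = len(peaks)
    for k in range(n - 3, n):
        if not excluded[k]:
            last.append(peaks[k])
    if len(first) < 2 or len(last) < 2:
        return "insufficient", None
    m1 = sum(first) / len(first)
    m2 = sum(last) / len(last)
    if m1 <= 0:
        return "degenerate", None
    H = 1 - m2 / m1
    return "classified", H > theta_hab


def _random_session(rng) -> PuffSession:
    peaks = rng.uniform(0, 20, 10)
    if rng.random() < 0.1:
        peaks[0] = 0.0                      # occasional non-responder
    baselines = rng.uniform(0, 4, 10)       # some exceed the 2-px threshold
    rep = [PuffTrial(intensity=1.0, peak=float(p), baseline_movement=float(b))
           for p, b in zip(peaks, baselines)]
    return PuffSession(animal_id="r", genotype="control", ramp_trials=[],
                       repeated_trials=rep)


def habituation_oracle_agreement(n_sessions: int = 1000,
                                 seed: int = 0) -> dict:
    """Fraction of randomized sessions where classifier and oracle agree."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_sessions):
        s = _random_session(rng)
        peaks = [t.peak for t in s.repeated_trials]
        baselines = [t.baseline_movement for t in s.repeated_trials]
        want = _oracle_classify(peaks, baselines)

        r = classify_habituation(apply_trial_exclusion(s))
        if not r.included and r.reason and "not classifiable" in r.reason:
            got = ("first_excluded", None)
        elif not r.included:
            got = ("not_included", None)
        elif r.habituated is None and "insufficient" in (r.reason or ""):
            got = ("insufficient", None)
        elif r.habituated is None:
            got = ("degenerate", None)
        else:
            got = ("classified", r.habituated)
        agree += got == want
    return {"agreement": agree / n_sessions, "n": n_sessions}


# --------------------------------------------------------------------------
# formula exactness vs rational arithmetic
# --------------------------------------------------------------------------

def formula_exactness(n: int = 500, seed: int = 0) -> dict:
    """Max |implementation - exact rational evaluation| per formula.

    Inputs are random rationals on each assay's realistic scale (tens to
    hundreds of mV for startle responses, tens of px for displacements,
    dwell counts for the arenas), so the absolute comparison is meaningful
    at float64 resolution.
    """
    rng = np.random.default_rng(seed)
    errs = {k: 0.0 for k in ("percent_ppi", "airpuff_alone",
                             "open_arm_fraction", "chamber_preference",
                             "object_preference", "repeated_mean",
                             "opto_mean")}

    def upd(key, got, exact):
        errs[key] = max(errs[key], abs(got - float(exact)))

    epm = ArenaGeometry(kind="epm")
    tc = ArenaGeometry(kind="three_chamber", mouse_side="left")
    nort = ArenaGeometry(kind="nort", objects={"L": (13.0, 20.0),
                                               "R": (27.0, 20.0)},
                         novel_object="L")
    cap = Fraction(106383, 1000)

    for _ in range(n):
        # accelerometer responses: P (pulse alone) 10-400 mV, S up to ~4P
        P = Fraction(int(rng.integers(40, 1600)), 4)
        S = Fraction(int(rng.integers(1, 1600)), 4)
        upd("percent_ppi", percent_ppi(float(S), float(P)),
            (1 - S / P) * 100)

        A = Fraction(int(rng.integers(0, 400)), 4)
        B = Fraction(int(rng.integers(0, 400)), 4)
        upd("airpuff_alone", airpuff_alone_response(float(A), float(B),
                                                    float(P)), A / P - B / P)

        no, nc = int(rng.integers(1, 40)), int(rng.integers(1, 40))
        pts = [[10.0, 0.0]] * no + [[0.0, 10.0]] * nc
        traj = _traj(pts, epm)
        upd("open_arm_fraction", open_arm_fraction(traj),
            Fraction(no, no + nc))

        nm, nb = int(rng.integers(1, 40)), int(rng.integers(1, 40))
        pts = [[10.0, 20.0]] * nm + [[50.0, 20.0]] * nb
        upd("chamber_preference", chamber_preference(_traj(pts, tc)),
            Fraction(nm, nm + nb))

        nn, nf = int(rng.integers(1, 40)), int(rng.integers(1, 40))
        pts = [[13.0, 20.0]] * nn + [[27.0, 20.0]] * nf
        t = _traj(pts, nort)
        upd("object_preference", object_preference(t, t),
            Fraction(nn, nn + nf))

        peaks = [Fraction(int(rng.integers(1, 400)), 4) for _ in range(10)]
        sess = PuffSession(animal_id="f", genotype="control", ramp_trials=[],
                           repeated_trials=[
                               PuffTrial(intensity=1.0, peak=float(p),
                                         baseline_movement=0.0)
                               for p in peaks])
        upd("repeated_mean", repeated_mean(sess), sum(peaks) / 10)

        opeaks = [Fraction(int(rng.integers(1, 400)), 4) for _ in range(5)]
        fell = [bool(rng.random() < 0.3) for _ in range(5)]
        opeaks = [min(p, cap) for p in opeaks]
        got = score_opto_session(OptoSession(peaks=[float(p) for p in opeaks],
                                             fell_over=fell))
        exact = sum(cap if f else p for p, f in zip(opeaks, fell)) / 5
        upd("opto_mean", got, exact)
    errs["n_per_formula"] = n
    return errs


def _traj(points, arena):
    pts = np.asarray(points, float)
    return Trajectory(t=np.arange(len(pts)) / 30.0, x=pts[:, 0], y=pts[:, 1],
                      frame_rate=30.0, arena=arena)


# --------------------------------------------------------------------------
# Fisher's exact vs full enumeration
# --------------------------------------------------------------------------

def _fisher_oracle(a, b, c, d) -> Fraction:
    n1, n2, K = a + c, b + d, a + b
    hi = min(K, n1)
    num = sum(comb(n1, k) * comb(n2, K - k) for k in range(a, hi + 1))
    return Fraction(num, comb(n1 + n2, K))


def fisher_enumeration_check(max_margin: int = 30) -> dict:
    """Compare against exact enumeration for all tables with margins <= m.

    Also verifies directional monotonicity: moving one mutant animal from
    habituated to non-habituated never increases the one-sided p.
    """
    max_err = 0.0
    n_tables = 0
    violations = 0
    for n1 in range(max_margin + 1):
        for n2 in range(max_margin + 1):
            if n1 + n2 == 0:
                continue
            for a in range(n1 + 1):
                c = n1 - a
                for b in range(n2 + 1):
                    d = n2 - b
                    if a + b > max_margin or c + d > max_margin:
                        continue
                    t = ContingencyTable2x2(a, b, c, d)
                    p = fisher_exact_one_sided(t, "mutant_lower")
                    exact = _fisher_oracle(a, b, c, d)
                    max_err = max(max_err, abs(p - float(exact)))
                    n_tables += 1
                    if b > 0 and c + d + 1 <= max_margin:
                        t2 = ContingencyTable2x2(a, b - 1, c, d + 1)
                        if fisher_exact_one_sided(t2, "mutant_lower") \
                                > p + 1e-12:
                            violations += 1
    return {"max_abs_error": max_err, "n_tables": n_tables,
            "monotonicity_violations": violations}


# --------------------------------------------------------------------------
# tracking recovery
# --------------------------------------------------------------------------

def tracking_recovery(n_videos: int = 100, seed: int = 0) -> dict:
    """Recover planted peak displacements (2-50 px) from rendered videos."""
    rng = np.random.default_rng(seed)
    amplitudes = rng.uniform(2.0, 50.0, n_videos)
    ok = 0
    errors = []
    for i, amp in enumerate(amplitudes):
        spec = CohortSpec(seed=int(rng.integers(0, 2 ** 31)))
        stack, truth, info = generate_puff_video(spec, "control", i,
                                                 amplitude=float(amp))
        with warnings.catch_warnings():
            # texture occasionally supports fewer than the 20 requested
            # features; a dozen points is ample for a rigid blob
            warnings.simplefilter("ignore", UserWarning)
            pts = tracking.seed_points(stack.frames[0], info["roi"], 20)
        traj = tracking.track_points(stack, pts)
        trace = tracking.displacement_trace(traj, (5, 15), spec.fps, 15)
        peak = tracking.peak_in_window(trace)
        true_peak = tracking.peak_in_window(truth)
        err = abs(peak - true_peak)
        errors.append(err)
        ok += err <= max(0.5, 0.05 * true_peak)
    return {"n_within_tolerance": ok, "n": n_videos,
            "recovery_rate": ok / n_videos,
            "median_abs_error_px": float(np.median(errors))}


# --------------------------------------------------------------------------
# puncta proximity recovery
# --------------------------------------------------------------------------

def puncta_recovery(seed: int = 0, fractions=(0.0, 0.25, 0.5, 0.75, 1.0),
                    n_stacks: int = 3) -> dict:
    """Planted-fraction recovery, noiseless and at default noise, plus the
    dense-background overestimation stress test."""
    err_clean, err_noisy, stress_margins = [], [], []
    base = np.random.default_rng(seed).integers(0, 2 ** 30)
    for f in fractions:
        for k in range(n_stacks):
            s = int(base) + 97 * k
            clean = StackSpec(coloc_fraction=f, seed=s, poisson_scale=0.0,
                              gaussian_sd=0.0)
            stack, labels = generate_confocal_stack(clean)
            rho = analyze_stack(stack, "VGLUT1").proximity
            err_clean.append(abs(rho - labels["coloc_fraction_planted"]))

            noisy = StackSpec(coloc_fraction=f, seed=s)
            stack, labels = generate_confocal_stack(noisy)
            rho = analyze_stack(stack, "VGLUT1").proximity
            err_noisy.append(abs(rho - labels["coloc_fraction_planted"]))
        # dense background collapsing into the optical section: the
        # measured proximity bounds the true fraction from above
        stress = StackSpec(coloc_fraction=f, seed=int(base) + 1,
                           background_puncta_density=0.5,
                           background_avoids_terminals=False)
        stack, labels = generate_confocal_stack(stress)
        rho = analyze_stack(stack, "VGLUT1").proximity
        stress_margins.append(rho - labels["coloc_fraction_planted"])
    return {"max_abs_error_noiseless": float(np.max(err_clean)),
            "max_abs_error_noisy": float(np.max(err_noisy)),
            "min_stress_margin": float(np.min(stress_margins)),
            "n_stacks": len(err_clean)}


# --------------------------------------------------------------------------
# cohort-level power, null behavior, cutoff concordance
# --------------------------------------------------------------------------

def _cohort_p(seed: int, p_ctrl: float, p_mut: float) -> float:
    spec = CohortSpec(seed=seed,
                      habituation_prob={"control": p_ctrl, "mutant": p_mut})
    sessions, _ = generate_cohort(spec)
    results = [classify_habituation(apply_trial_exclusion(s))
               for s in sessions]
    _, p = compare_habituation_fractions(results, "control", "mutant")
    return p


def cohort_power(root_seed: int, n_cohorts: int = 500, p_ctrl: float = 0.8,
                 p_mut: float = 0.3, alpha: float = 0.05) -> float:
    """Fraction of simulated cohorts (n = 16 vs 10) rejecting at alpha."""
    rej = sum(_cohort_p(root_seed * 1_000_003 + c, p_ctrl, p_mut) < alpha
              for c in range(n_cohorts))
    return rej / n_cohorts


def null_rejection_rate(root_seed: int, n_cohorts: int = 1000,
                        p: float = 0.8, alpha: float = 0.05) -> float:
    """Rejection rate when both genotypes share habituation probability."""
    rej = sum(_cohort_p(root_seed * 2_000_003 + c, p, p) < alpha
              for c in range(n_cohorts))
    return rej / n_cohorts


def cutoff_concordance(root_seed: int, n_cohorts: int = 500,
                       p_ctrl: float = 0.8, p_mut: float = 0.3) -> float:
    """Fraction of cohorts where the genotype-difference sign is identical
    at the 20/25/30/40% habituation cutoffs (ties in between count as
    discordant only if strict signs disagree)."""
    concordant = 0
    for c in range(n_cohorts):
        spec = CohortSpec(seed=root_seed * 3_000_017 + c,
                          habituation_prob={"control": p_ctrl,
                                            "mutant": p_mut})
        sessions, _ = generate_cohort(spec)
        sessions = [apply_trial_exclusion(s) for s in sessions]
        table = habituation_sensitivity(sessions)
        signs = set(genotype_difference_sign(table, "control",
                                             "mutant").values())
        strict = signs - {0}
        concordant += len(strict) <= 1
    return concordant / n_cohorts


# --------------------------------------------------------------------------
# arena exactness
# --------------------------------------------------------------------------

def arena_exact_cases() -> dict:
    """The four constructed-trajectory checks with exact expected values."""
    of = ArenaGeometry(kind="open_field")
    all_center = _traj([[20.0, 20.0]] * 60, of)
    wall = _traj([[x, 2.0] for x in np.linspace(2, 38, 60)], of)
    boundary = _traj([[5.0, 20.0]] * 60, of)
    epm = ArenaGeometry(kind="epm")
    equal = _traj([[10.0, 0.0]] * 30 + [[0.0, 10.0]] * 30, epm)
    return {"all_center": center_time_fraction(all_center),
            "wall_following": center_time_fraction(wall),
            "boundary_exact_5cm": center_time_fraction(boundary),
            "equal_dwell_symmetric": open_arm_fraction(equal)}
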