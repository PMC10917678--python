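"""Neonatal air-puff reactivity endpoints.

A testing session delivers an intensity ramp (0.10, 0.25, 0.50, 0.75,
1.0 psi; 50 ms each) followed by ten consecutive 1.0-psi stimuli — 14
trials per animal.  This module turns per-trial peak displacements into
the assay's endpoints: the intensity--response table, the mean response to
the repeated stimulus, and the habituation classification (a >25% drop
between the mean of the first three and last three repeated trials), with
the trial- and animal-level inclusion rules applied first.  It also scores
the embryonic/neonatal optogenetic assay (mean of five peak displacements,
fall-overs capped at 106.383 px).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

FALL_OVER_CAP_PX = 106.383


@dataclass
class PuffTrial:
    """One air-puff presentation."""

    intensity: float                 # psi
    peak: float                      # px
    baseline_movement: float         # px, max over the 10 pre-stimulus frames
    fell_over: bool = False
    excluded: bool = False
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if self.peak < 0:
            raise ValueError("peak displacement must be nonnegative")
        if self.excluded and not self.exclusion_reason:
            raise ValueError("excluded trials must carry a reason")


@dataclass
class PuffSession:
    """One animal's ordered trials with the scoring thresholds.

    ``theta_hab`` is the habituation cutoff (default 0.25: a >25%
    first-to-last block reduction counts as habituation), ``theta_incl``
    the inclusion margin (default 0.20: the first repeated-trial response
    must exceed that trial's baseline movement by >20%), and
    ``movement_threshold`` the baseline-movement level (px) above which a
    trial is discarded.
    """

    animal_id: str
    genotype: str
    ramp_trials: list[PuffTrial]
    repeated_trials: list[PuffTrial]
    theta_hab: float = 0.25
    theta_incl: float = 0.20
    movement_threshold: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.theta_hab < 1 and 0 < self.theta_incl < 1):
            raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class HabituationResult:
    animal_id: str
    genotype: str
    included: bool
    H: float | None = None           # 1 - mean(last block)/mean(first block)
    habituated: bool | None = None
    first_block_mean: float | None = None
    last_block_mean: float | None = None
    reason: str | None = None


@dataclass
class OptoSession:
    """Five optical-stimulus trials for one paw site of one animal."""

    peaks: list[float]
    fell_over: list[bool] = field(default_factory=list)
    cap: float = FALL_OVER_CAP_PX
    site: str = "forepaw"
    age: str = "P0"

    def __post_init__(self) -> None:
        if not self.fell_over:
            self.fell_over = [False] * len(self.peaks)
        if len(self.peaks) != len(self.fell_over):
            raise ValueError("peaks and fell_over must have equal length")
        for p, f in zip(self.peaks, self.fell_over):
            if not f and p > self.cap:
                raise ValueError("capped peaks must not exceed the cap")


def apply_trial_exclusion(session: PuffSession) -> PuffSession:
    """Discard trials with baseline movement above the threshold.

    Trials in which the animal moved during the 10-frame pre-stimulus
    baseline period (strictly above ``movement_threshold``) are flagged
    excluded with reason ``"baseline_movement"``; all other flags are left
    untouched.  Returns a new session.
    """
    def mark(t: PuffTrial) -> PuffTrial:
        if t.baseline_movement > session.movement_threshold:
            return replace(t, excluded=True, exclusion_reason="baseline_movement")
        return replace(t)

    return replace(session,
                   ramp_trials=[mark(t) for t in session.ramp_trials],
                   repeated_trials=[mark(t) for t in session.repeated_trials])


def intensity_response(session: PuffSession) -> pd.DataFrame:
    """Long-format intensity--response table for one session.

    One row per ramp intensity; excluded trials appear with a missing
    peak so that repeated-measures models downstream can handle the gap.
    """
    rows = [{"animal_id": session.animal_id,
             "genotype": session.genotype,
             "intensity_psi": t.intensity,
             "peak_px": np.nan if t.excluded else t.peak}
            for t in session.ramp_trials]
    return pd.DataFrame(rows)


def repeated_mean(session: PuffSession) -> float:
    """Arithmetic mean peak over non-excluded repeated (1.0-psi) trials."""
    peaks = [t.peak for t in session.repeated_trials if not t.excluded]
    if not peaks:
        raise ValueError("all repeated trials excluded")
    return float(np.mean(peaks))


def habituation_inclusion(session: PuffSession, *, rule: str = "margin") -> bool:
    """Animal-level inclusion for the habituation analysis.

    Only animals that responded to the first 1.0-psi presentation are
    classifiable.  Under the default ``"margin"`` rule the first-trial
    peak must exceed that trial's baseline movement by more than the
    inclusion margin (peak > (1 + theta_incl) * baseline, strict).  The
    ``"literal"`` rule reads the criterion as peak > theta_incl * baseline.
    """
    if not session.repeated_trials:
        raise ValueError("session has no repeated trials")
    first = session.repeated_trials[0]
    if first.excluded:
        raise ValueError("first repeated trial excluded; animal not classifiable")
    if rule == "margin":
        return first.peak > (1.0 + session.theta_incl) * first.baseline_movement
    if rule == "literal":
        return first.peak > session.theta_incl * first.baseline_movement
    raise ValueError(f"unknown inclusion rule {rule!r}")


def classify_habituation(session: PuffSession, *,
                         cutoff: float | None = None,
                         rule: str = "margin",
                         min_block_trials: int = 2,
                         block_size: int = 3) -> HabituationResult:
    """Classify one animal as habituating or not.

    H = 1 - mean(last block)/mean(first block) over the repeated 1.0-psi
    trials, blocks being the first and last ``block_size`` presentations;
    the animal habituated iff H strictly exceeds the cutoff (default the
    session's theta_hab, 0.25).  Excluded trials are dropped within each
    block and at least ``min_block_trials`` survivors are required per
    block.  Animals failing the first-trial inclusion rule are returned
    with ``included=False`` and no classification.
    """
    cutoff = session.theta_hab if cutoff is None else cutoff
    base = dict(animal_id=session.animal_id, genotype=session.genotype)
    try:
        included = habituation_inclusion(session, rule=rule)
    except ValueError as err:
        return HabituationResult(included=False, reason=str(err), **base)
    if not included:
        return HabituationResult(included=False,
                                 reason="first-trial response below inclusion margin",
                                 **base)
    trials = session.repeated_trials
    first = [t.peak for t in trials[:block_size] if not t.excluded]
    last = [t.peak for t in trials[-block_size:] if not t.excluded]
    if len(first) < min_block_trials or len(last) < min_block_trials:
        return HabituationResult(included=True, reason="insufficient trials per block",
                                 **base)
    m_first = float(np.mean(first))
    m_last = float(np.mean(last))
    if m_first <= 0:
        return HabituationResult(included=True, reason="zero first-block mean",
                                 first_block_mean=m_first, last_block_mean=m_last,
                                 **base)
    H = 1.0 - m_last / m_first
    return HabituationResult(included=True, H=H, habituated=H > cutoff,
                             first_block_mean=m_first, last_block_mean=m_last,
                             **base)


def habituation_sensitivity(sessions: list[PuffSession],
                            cutoffs: tuple[float, ...] = (0.20, 0.25, 0.30, 0.40),
                            *, rule: str = "margin") -> pd.DataFrame:
    """Habituating fraction per genotype at alternative cutoffs.

    The primary 25% cutoff is bracketed by 20/30/40% re-analyses to check
    that the direction of the genotype difference is cutoff-independent.
    Returns a tidy table (cutoff, genotype, n, n_habituated, fraction);
    unclassifiable animals are dropped.
    """
    results = [classify_habituation(s, rule=rule) for s in sessions]
    usable = [r for r in results if r.included and r.H is not None]
    genotypes = sorted({r.genotype for r in usable})
    if not genotypes:
        raise ValueError("no classifiable animals in cohort")
    rows = []
    for cutoff in cutoffs:
        for g in genotypes:
            hs = [r.H for r in usable if r.genotype == g]
            if not hs:
                raise ValueError(f"no classifiable animals for genotype {g!r}")
            n_hab = sum(h > cutoff for h in hs)
            rows.append({"cutoff": cutoff, "genotype": g, "n": len(hs),
                         "n_habituated": n_hab, "fraction": n_hab / len(hs)})
    return pd.DataFrame(rows)


def genotype_difference_sign(table: pd.DataFrame, control: str,
                             mutant: str) -> dict[float, int]:
    """Sign of (control - mutant) habituating fraction at each cutoff."""
    out: dict[float, int] = {}
    for cutoff, sub in table.groupby("cutoff"):
        fc = float(sub.loc[sub.genotype == control, "fraction"].iloc[0])
        fm = float(sub.loc[sub.genotype == mutant, "fraction"].iloc[0])
        out[float(cutoff)] = int(np.sign(fc - fm))
    return out


def score_opto_session(session: OptoSession) -> float:
    """Mean peak displacement over the five optical stimuli.

    Fall-over trials are substituted with the cap (106.383 px) before
    averaging.
    """
    if len(session.peaks) != 5:
        raise ValueError(f"expected exactly 5 trials, got {len(session.peaks)}")
    vals = [session.cap if f else p
            for p, f in zip(session.peaks, session.fell_over)]
    return float(np.mean(vals))
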