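"""Tactile prepulse inhibition (PPI) of the acoustic startle reflex.

Adult mice in a startle enclosure receive a 125-dB acoustic pulse either
alone or preceded by a light air puff (0.9 psi, 50 ms) at various
interstimulus intervals; the accelerometer response is the maximum output
in the 100-ms window after the stimulus ends.  Sessions are arranged in
blocks: (1) pulse-alone acclimation trials, (2) prepulse-alone trials, and
(3) a pseudorandomized mixed block of prepulse+pulse, pulse-alone (the
denominator of %PPI) and no-stimulation trials.  Reported %PPI comes from
the 250-ms interstimulus-interval trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRIAL_TYPES = ("pulse_alone", "prepulse_pulse", "prepulse_alone", "no_stim")
REPORTED_ISI_MS = 250


@dataclass
class StartleTrial:
    trial_type: str
    response: float                  # mV, max accelerometer output
    isi_ms: float | None = None      # prepulse->pulse interval
    block: str = "mixed"             # "pulse_alone", "prepulse_alone" or "mixed"

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial type {self.trial_type!r}")
        if self.response < 0:
            raise ValueError("accelerometer response must be nonnegative")


@dataclass
class StartleSession:
    animal_id: str
    genotype: str
    trials: list[StartleTrial]
    enclosure_cm: float | None = None


@dataclass
class PPIResult:
    animal_id: str
    genotype: str
    percent_ppi: float
    airpuff_alone: float
    included: bool
    startle_mean: float              # S: prepulse+pulse (250-ms ISI) mean, mV
    pulse_alone_mean: float          # P: mixed-block pulse-alone mean, mV
    prepulse_alone_mean: float       # A
    no_stim_mean: float              # B


def percent_ppi(startle: float, pulse_alone: float) -> float:
    """%PPI = [1 - (startle response / pulse-alone response)] x 100.

    ``startle`` is the mean response to prepulse+pulse trials (S) and
    ``pulse_alone`` the mean response to the pulse alone (P).  Negative
    values (facilitation) are reported as-is.
    """
    if pulse_alone <= 0:
        raise ValueError("pulse-alone response must be positive")
    return (1.0 - startle / pulse_alone) * 100.0


def airpuff_alone_response(prepulse_alone: float, no_stim: float,
                           pulse_alone: float) -> float:
    """Air-puff-alone reactivity as a fraction of the startle response.

    (prepulse alone / pulse alone) - (no stimulation / pulse alone);
    negative values are reported as-is.
    """
    if pulse_alone <= 0:
        raise ValueError("pulse-alone response must be positive")
    return prepulse_alone / pulse_alone - no_stim / pulse_alone


def include_session(session: StartleSession) -> bool:
    """Inclusion rule: baseline movement must not dominate the startle.

    Animals whose no-stimulation block mean exceeds 25% of their
    pulse-alone (acoustic startle) mean are excluded — they startled too
    weakly for %PPI to be meaningful.  Exactly 25% is still included.
    """
    B = _block_mean(session, "no_stim")
    P = _block_mean(session, "pulse_alone", block="mixed")
    return B <= 0.25 * P


def _block_mean(session: StartleSession, trial_type: str,
                block: str | None = None,
                isi_ms: float | None = None) -> float:
    vals = [t.response for t in session.trials
            if t.trial_type == trial_type
            and (block is None or t.block == block)
            and (isi_ms is None or t.isi_ms == isi_ms)]
    if not vals:
        raise ValueError(
            f"no trials of type {trial_type!r}"
            + (f" at {isi_ms}-ms ISI" if isi_ms is not None else ""))
    return float(np.mean(vals))


def summarize_session(session: StartleSession,
                      isi_ms: float = REPORTED_ISI_MS) -> PPIResult:
    """Score one session: %PPI, air-puff-alone response, inclusion flag.

    The %PPI numerator uses prepulse+pulse trials at the reported ISI
    (250 ms by default); the denominator uses pulse-alone trials from the
    pseudorandomized mixed block.  Metrics are reported even for sessions
    failing the inclusion rule, with ``included=False``.
    """
    S = _block_mean(session, "prepulse_pulse", isi_ms=isi_ms)
    P = _block_mean(session, "pulse_alone", block="mixed")
    A = _block_mean(session, "prepulse_alone")
    B = _block_mean(session, "no_stim")
    return PPIResult(animal_id=session.animal_id, genotype=session.genotype,
                     percent_ppi=percent_ppi(S, P),
                     airpuff_alone=airpuff_alone_response(A, B, P),
                     included=B <= 0.25 * P,
                     startle_mean=S, pulse_alone_mean=P,
                     prepulse_alone_mean=A, no_stim_mean=B)
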