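"""Cohort-level statistics: exact tests, test routing, event summaries.

Habituation is a binary per-animal outcome, so genotype comparisons of
habituating fractions use a one-sided Fisher's exact test.  Continuous
group comparisons are routed by normality (Shapiro--Wilk per group) and
equal-variance (Bartlett) gates to Student's t, Welch's t or
Mann--Whitney U, executed by scipy.  Electrophysiological event lists
(miniature PSCs) are summarized to frequency and mean amplitude with the
100-events-per-cell sufficiency flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .reactivity import HabituationResult

GATE_ALPHA = 0.05
MIN_EVENTS_PER_CELL = 100


@dataclass
class ContingencyTable2x2:
    """Counts: rows habituated/not, columns control/mutant."""

    hab_control: int
    hab_mutant: int
    nohab_control: int
    nohab_mutant: int

    def __post_init__(self) -> None:
        counts = (self.hab_control, self.hab_mutant,
                  self.nohab_control, self.nohab_mutant)
        if any(c < 0 or c != int(c) for c in counts):
            raise ValueError("counts must be nonnegative integers")
        if sum(counts) == 0:
            raise ValueError("empty table")

    @property
    def n_control(self) -> int:
        return self.hab_control + self.nohab_control

    @property
    def n_mutant(self) -> int:
        return self.hab_mutant + self.nohab_mutant


@dataclass
class TestRoute:
    test: str                        # student_t | welch_t | mann_whitney
    tails: str                       # "two" | "one"
    normal_a: bool
    normal_b: bool
    equal_variance: bool | None
    statistic: float
    pvalue: float


@dataclass
class EventListSummary:
    n_events: int
    duration_s: float
    frequency_hz: float
    mean_amplitude_pa: float
    sufficient: bool                 # n >= 100 events analyzed for this cell


def fisher_exact_one_sided(table: ContingencyTable2x2,
                           direction: str = "mutant_lower") -> float:
    """One-sided Fisher's exact test on a habituation 2x2 table.

    Conditional on the margins, the number of habituated controls follows
    a hypergeometric law; the p-value is the exact tail probability of
    tables at least as extreme in the stated direction.
    ``direction="mutant_lower"`` tests whether mutants habituate less than
    controls (evidence = many habituated controls), ``"control_lower"``
    the reverse.
    """
    a = table.hab_control
    N = (table.hab_control + table.hab_mutant
         + table.nohab_control + table.nohab_mutant)
    K = table.hab_control + table.hab_mutant       # total habituated
    n = table.n_control
    if direction == "mutant_lower":
        return float(sps.hypergeom.sf(a - 1, N, K, n))
    if direction == "control_lower":
        return float(sps.hypergeom.cdf(a, N, K, n))
    raise ValueError(f"unknown direction {direction!r}")


def route_group_test(group_a: np.ndarray, group_b: np.ndarray, *,
                     tails: str = "two", alternative: str = "two-sided",
                     gate_alpha: float = GATE_ALPHA) -> TestRoute:
    """Gate-and-route a two-group comparison.

    Both groups are tested for normality (Shapiro--Wilk) and, if both
    pass, for equal variance (Bartlett), each at alpha = 0.05.  Route:
    Student's t if normal with equal variances, Welch's t if normal with
    unequal variances, Mann--Whitney U otherwise.  One-tailed use requires
    ``alternative`` ("less"/"greater", direction of group_a vs group_b).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if tails not in ("one", "two"):
        raise ValueError("tails must be 'one' or 'two'")
    if tails == "two" and alternative != "two-sided":
        raise ValueError("two-tailed test requires alternative='two-sided'")
    if tails == "one" and alternative not in ("less", "greater"):
        raise ValueError("one-tailed test requires alternative 'less'/'greater'")
    normal_a = sps.shapiro(a).pvalue > gate_alpha
    normal_b = sps.shapiro(b).pvalue > gate_alpha
    equal_var: bool | None = None
    if normal_a and normal_b:
        equal_var = sps.bartlett(a, b).pvalue > gate_alpha
        res = sps.ttest_ind(a, b, equal_var=equal_var, alternative=alternative)
        test = "student_t" if equal_var else "welch_t"
    else:
        res = sps.mannwhitneyu(a, b, alternative=alternative)
        test = "mann_whitney"
    return TestRoute(test=test, tails=tails, normal_a=normal_a,
                     normal_b=normal_b, equal_variance=equal_var,
                     statistic=float(res.statistic), pvalue=float(res.pvalue))


def habituation_table(results: list[HabituationResult], control: str,
                      mutant: str) -> ContingencyTable2x2:
    """Build the habituated/not x control/mutant table from classifications.

    Only included, classifiable animals enter the table.
    """
    usable = [r for r in results if r.included and r.habituated is not None]
    def count(genotype: str, habituated: bool) -> int:
        return sum(r.genotype == genotype and r.habituated == habituated
                   for r in usable)
    table = ContingencyTable2x2(
        hab_control=count(control, True), hab_mutant=count(mutant, True),
        nohab_control=count(control, False), nohab_mutant=count(mutant, False))
    if table.n_control == 0 or table.n_mutant == 0:
        raise ValueError("a genotype group is empty after inclusion filtering")
    return table


def compare_habituation_fractions(results: list[HabituationResult],
                                  control: str, mutant: str,
                                  direction: str = "mutant_lower",
                                  ) -> tuple[ContingencyTable2x2, float]:
    """One-sided Fisher comparison of habituating fractions by genotype."""
    table = habituation_table(results, control, mutant)
    return table, fisher_exact_one_sided(table, direction)


def summarize_event_list(times_s: np.ndarray, amplitudes_pa: np.ndarray,
                         duration_s: float) -> EventListSummary:
    """Frequency / mean amplitude summary of a miniature-PSC event list."""
    times = np.asarray(times_s, dtype=float)
    amps = np.asarray(amplitudes_pa, dtype=float)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if times.size and (times.min() < 0 or times.max() > duration_s):
        raise ValueError("event times must lie within [0, duration]")
    if times.shape != amps.shape:
        raise ValueError("times and amplitudes must have equal length")
    n = times.size
    return EventListSummary(
        n_events=n, duration_s=float(duration_s),
        frequency_hz=n / duration_s,
        mean_amplitude_pa=float(np.mean(amps)) if n else float("nan"),
        sufficient=n >= MIN_EVENTS_PER_CELL)
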