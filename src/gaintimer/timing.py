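"""Order inference, timing solve, and result flags.

The observed multiplicity spectrum of a segment determines which candidate
histories are possible: an order is consistent when every observed
multiplicity class is among the classes it predicts.  Among consistent
candidates the one with the fewest events is selected (parsimony).  The
timing system is then solved exactly: with the substitution ``u_i = m t_i``
the ledger rows ``n_k = c_k0 m + sum_i c_ki u_i`` form a square linear system
in ``(m, u_1..u_K)``, and ``t_i = u_i / m``.

Estimates are deliberately not clamped to [0, 1] and events are not reordered:
a time above 1 indicates an event late in the tumour's history (few or no
multiplicity-1 mutations) and is surfaced through a flag rather than hidden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .copy_history import (
    DurationLedger,
    EventOrder,
    build_duration_ledger,
    enumerate_event_orders,
    expected_multiplicity_states,
)
from .errors import (
    DegenerateSystemError,
    NonPositiveRateError,
    TooFewMutationsError,
)

#: Fewer mutations than this triggers a refusal to time the segment.
MIN_MUTATIONS = 3

#: Fewer timing mutations than this raises the FEW_MUTATIONS flag.
FEW_MUTATIONS_THRESHOLD = 10

FLAG_TIME_EXCEEDS_ONE = "TIME_EXCEEDS_ONE"
FLAG_NEGATIVE_TIME = "NEGATIVE_TIME"
FLAG_NON_MONOTONIC_ORDER = "NON_MONOTONIC_ORDER"
FLAG_FEW_MUTATIONS = "FEW_MUTATIONS"
FLAG_MISSING_EXPECTED_STATE = "MISSING_EXPECTED_STATE"
FLAG_INCONSISTENT_SPECTRUM = "INCONSISTENT_SPECTRUM"

FLAG_VOCABULARY = frozenset(
    {
        FLAG_TIME_EXCEEDS_ONE,
        FLAG_NEGATIVE_TIME,
        FLAG_NON_MONOTONIC_ORDER,
        FLAG_FEW_MUTATIONS,
        FLAG_MISSING_EXPECTED_STATE,
        FLAG_INCONSISTENT_SPECTRUM,
    }
)


class MultiplicitySpectrum(dict):
    """Mapping multiplicity class -> mutation count.

    A thin dict subclass so spectra can be built from any mapping or from a
    sequence of per-mutation multiplicities.
    """

    @classmethod
    def from_multiplicities(cls, multiplicities: Iterable[int]) -> "MultiplicitySpectrum":
        spectrum = cls()
        for k in multiplicities:
            spectrum[int(k)] = spectrum.get(int(k), 0) + 1
        return spectrum

    @property
    def total(self) -> int:
        return sum(self.values())

    def observed_classes(self) -> set[int]:
        return {k for k, n in self.items() if n > 0}

    def count_vector(self, classes: Iterable[int]) -> np.ndarray:
        """Counts aligned to ``classes``; classes not observed enter as 0."""
        return np.array([self.get(k, 0) for k in classes], dtype=float)


@dataclass
class TimingResult:
    """Timing of one segment: inferred order, event times, bootstrap summary."""

    order: EventOrder
    t_point: np.ndarray
    m_hat: float
    t_boot_mean: np.ndarray | None = None
    ci_low: np.ndarray | None = None
    ci_high: np.ndarray | None = None
    n_mutations_order: int = 0
    n_mutations_timing: int = 0
    n_bootstrap_failures: int = 0
    flags: set[str] = field(default_factory=set)

    @property
    def event_labels(self) -> tuple[str, ...]:
        return self.order.events


def infer_order(
    spectrum: Mapping[int, int], major: int, minor: int, wgd_flag: bool
) -> tuple[EventOrder, bool]:
    """Most parsimonious event order consistent with the observed spectrum.

    An order is consistent when its expected multiplicity set contains every
    observed class with a nonzero count.  Candidates are examined fewest
    events first, so the first consistent one wins.  If no candidate is
    consistent the one covering the most observed classes is returned and the
    second element of the result is False (callers raise the
    INCONSISTENT_SPECTRUM flag).
    """
    observed = {k for k, n in spectrum.items() if n > 0}
    if not observed:
        raise TooFewMutationsError("empty multiplicity spectrum")
    candidates = enumerate_event_orders(major, minor, wgd_flag)
    best, best_overlap = None, -1
    for order in candidates:
        expected = expected_multiplicity_states(order, minor)
        if observed <= expected:
            return order, True
        overlap = len(observed & expected)
        if overlap > best_overlap:
            best, best_overlap = order, overlap
    return best, False


def solve_times(
    ledger: DurationLedger, spectrum: Mapping[int, int]
) -> tuple[float, np.ndarray]:
    """Solve the timing system exactly for (m_hat, event times).

    Observed classes absent from the spectrum enter as zero counts; the
    system stays square.  Estimates are not clamped to [0, 1].
    """
    classes = ledger.multiplicity_classes
    counts = np.array([spectrum.get(k, 0) for k in classes], dtype=float)
    design = ledger.coefficient_matrix()  # columns: m, u_1..u_K
    try:
        solution = np.linalg.solve(design, counts)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSystemError(
            f"singular timing system for order {ledger.order}"
        ) from exc
    m_hat = solution[0]
    if m_hat <= 0:
        raise NonPositiveRateError(
            f"solved mutation-rate scale m_hat = {m_hat:.4g} is not positive; "
            "the spectrum is incompatible with the assumed history"
        )
    return float(m_hat), solution[1:] / m_hat


def assign_flags(
    t_point: np.ndarray,
    expected_states: set[int],
    spectrum: Mapping[int, int],
    n_mutations_timing: int,
    consistent: bool = True,
    threshold: int = FEW_MUTATIONS_THRESHOLD,
) -> set[str]:
    """Quality flags for a timing result (anomalies surface, never corrected)."""
    flags: set[str] = set()
    t = np.asarray(t_point, dtype=float)
    if np.any(t > 1):
        flags.add(FLAG_TIME_EXCEEDS_ONE)
    if np.any(t < 0):
        flags.add(FLAG_NEGATIVE_TIME)
    if np.any(np.diff(t) < 0):
        flags.add(FLAG_NON_MONOTONIC_ORDER)
    if n_mutations_timing < threshold:
        flags.add(FLAG_FEW_MUTATIONS)
    if any(spectrum.get(k, 0) == 0 for k in expected_states):
        flags.add(FLAG_MISSING_EXPECTED_STATE)
    if not consistent:
        flags.add(FLAG_INCONSISTENT_SPECTRUM)
    return flags


def time_spectrum(
    order_spectrum: Mapping[int, int],
    timing_spectrum: Mapping[int, int],
    major: int,
    minor: int,
    wgd_flag: bool,
    bootstraps: int = 500,
    seed: int | None = None,
    few_mutations_threshold: int = FEW_MUTATIONS_THRESHOLD,
) -> TimingResult:
    """Infer the order from ``order_spectrum``, time it on ``timing_spectrum``.

    The two spectra implement the two-stage mode: all mutations inform the
    order (non-clock-like mutations still reveal which multiplicity states
    exist) while timing may be restricted to clock-like mutations.  With a
    single spectrum pass the same mapping twice.
    """
    from .bootstrap import bootstrap_times  # local import: avoid cycle

    n_order = sum(order_spectrum.values())
    n_timing = sum(timing_spectrum.values())
    if n_order < MIN_MUTATIONS:
        raise TooFewMutationsError(
            f"segment has {n_order} mutations; minimum is {MIN_MUTATIONS}"
        )
    if n_timing < 1:
        raise TooFewMutationsError("no mutations left for timing after filtering")

    order, consistent = infer_order(order_spectrum, major, minor, wgd_flag)
    ledger = build_duration_ledger(order, minor)
    m_hat, t_point = solve_times(ledger, timing_spectrum)

    boot_mean, ci_low, ci_high, n_failures = bootstrap_times(
        timing_spectrum, ledger, B=bootstraps, seed=seed
    )
    flags = assign_flags(
        t_point,
        expected_multiplicity_states(order, minor),
        timing_spectrum,
        n_timing,
        consistent=consistent,
        threshold=few_mutations_threshold,
    )
    return TimingResult(
        order=order,
        t_point=t_point,
        m_hat=m_hat,
        t_boot_mean=boot_mean,
        ci_low=ci_low,
        ci_high=ci_high,
        n_mutations_order=n_order,
        n_mutations_timing=n_timing,
        n_bootstrap_failures=n_failures,
        flags=flags,
    )


def time_segment(
    mutations,
    segment,
    mutation_mode: str = "all",
    bootstraps: int = 500,
    seed: int | None = None,
    reference=None,
    few_mutations_threshold: int = FEW_MUTATIONS_THRESHOLD,
) -> TimingResult:
    """Time all gain/WGD events of one amplified segment.

    Orchestrates the full pipeline: select the mutations overlapping the
    segment, assign integer multiplicities (precomputed values take
    precedence), infer the event order from *all* of them, restrict to
    clock-like mutations per ``mutation_mode`` ("all", "sbs", "ct_cpg") for
    the timing solve, bootstrap, and flag.  The segment's highest-major state
    defines the candidate orders; a lower coexisting state is ancestral.
    """
    # local imports keep the module dependency graph acyclic
    from .clocklike import filter_mutations
    from .multiplicity import assign_multiplicities, build_spectrum

    overlapping = [m for m in mutations if segment.contains(m.chrom, m.pos)]
    if len(overlapping) < MIN_MUTATIONS:
        raise TooFewMutationsError(
            f"segment {segment.chrom}:{segment.start}-{segment.end} has "
            f"{len(overlapping)} mutations; minimum is {MIN_MUTATIONS}"
        )
    assigned = assign_multiplicities(overlapping, segment)
    major, minor, _ = segment.top_state
    order_spectrum = build_spectrum(assigned)
    timing_set = filter_mutations(assigned, mode=mutation_mode, reference=reference)
    timing_spectrum = build_spectrum(timing_set)
    return time_spectrum(
        order_spectrum,
        timing_spectrum,
        major,
        minor,
        segment.wgd_flag,
        bootstraps=bootstraps,
        seed=seed,
        few_mutations_threshold=few_mutations_threshold,
    )
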