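"""Candidate event histories for amplified segments and their timing systems.

An amplified allele-specific copy number state (major + minor) can be reached
through different sequences of single-copy gains (``G``) and at most one whole
genome duplication (``W``).  Only histories in which the *same* chromosome
copy is gained at every step admit a uniquely solvable timing system, so the
enumeration here is restricted to orders of the form ``G^a W G^b`` (WGD
samples) or ``G^k`` (non-WGD samples).

For each order this module constructs the *duration ledger*: the linear
expressions, in the per-copy mutation rate ``m`` and the event times
``t_1 < ... < t_K`` (on a [0, 1] mutational-time scale where 1 is sampling),
for the expected number of mutations at each multiplicity.  A mutation that
lands on a chromosome copy is inherited by every descendant of that copy, so
its final multiplicity equals the number of surviving copies descended from
the (copy, time) point at which it arose.  The ledger is therefore built by
forward simulation of the copy forest: every copy-lineage interval between
consecutive events contributes its duration to the multiplicity class equal
to the number of final copies descended from it.

For the canonical single-gain state (2+1) this reproduces the classical
identities n1 = m(3 - 2 t1), n2 = m t1, hence t1 = 3 n2 / (n1 + 2 n2).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import UnsupportedStateError, UntimeableStateError

MAJOR_MIN = 2
MAJOR_MAX = 10
MAX_EVENTS = 9


@dataclass(frozen=True)
class EventOrder:
    """A hypothesized history of a segment: a sequence over {G, W}.

    ``G`` is a single-copy gain of the same chromosome copy; ``W`` is a whole
    genome duplication.  At most one ``W`` may appear.
    """

    events: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.events:
            raise ValueError("an event order must contain at least one event")
        if any(e not in ("G", "W") for e in self.events):
            raise ValueError(f"events must be 'G' or 'W', got {self.events!r}")
        if self.events.count("W") > 1:
            raise ValueError("WGD occurs at most once in a history")
        if len(self.events) > MAX_EVENTS:
            raise ValueError(f"at most {MAX_EVENTS} events are supported")

    @classmethod
    def from_string(cls, s: str) -> "EventOrder":
        return cls(tuple(s.strip().upper()))

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def has_wgd(self) -> bool:
        return "W" in self.events

    @property
    def pre_wgd_gains(self) -> int:
        """Number of gains before the WGD (0 if no WGD)."""
        return self.events.index("W") if self.has_wgd else 0

    @property
    def post_wgd_gains(self) -> int:
        if not self.has_wgd:
            return 0
        return self.n_events - self.events.index("W") - 1

    @property
    def final_major(self) -> int:
        """Major copy number implied by the history (starting from one copy)."""
        if self.has_wgd:
            return 2 * (1 + self.pre_wgd_gains) + self.post_wgd_gains
        return 1 + self.n_events

    def __str__(self) -> str:
        return "".join(self.events)


def _validate_state(major: int, minor: int, wgd_flag: bool) -> None:
    if major != int(major) or not (MAJOR_MIN <= major <= MAJOR_MAX):
        raise UnsupportedStateError(
            f"major copy number {major} outside supported range "
            f"[{MAJOR_MIN}, {MAJOR_MAX}]"
        )
    if minor not in (0, 1, 2):
        raise UnsupportedStateError(f"minor copy number {minor} not in {{0, 1, 2}}")
    if minor == 2 and not wgd_flag:
        raise UntimeableStateError(
            "minor copy number 2 without WGD precludes timing: the allelic "
            "origin of each mutation cannot be determined"
        )


def enumerate_event_orders(major: int, minor: int, wgd_flag: bool) -> list[EventOrder]:
    """All timeable event orders reaching ``major`` copies, fewest events first.

    WGD samples receive every order ``G^a W G^b`` with ``2(1+a) + b == major``;
    non-WGD samples the single order ``G^(major-1)``.  Histories that gain
    different chromosome copies yield timing systems with no unique solution
    and are excluded.
    """
    _validate_state(major, minor, wgd_flag)
    if not wgd_flag:
        return [EventOrder(("G",) * (major - 1))]
    orders = []
    # n_events = major - 1 - a, so larger a means fewer events.
    for a in range((major - MAJOR_MIN) // 2, -1, -1):
        b = major - 2 * (1 + a)
        orders.append(EventOrder(("G",) * a + ("W",) + ("G",) * b))
    return orders


class _Copy:
    """One chromosome copy lineage in the forward simulation."""

    __slots__ = ("children",)

    def __init__(self) -> None:
        # (event index at which the child was spawned, child node)
        self.children: list[tuple[int, "_Copy"]] = []

    def descendants(self, from_event: int) -> int:
        """Final copies descended from this lineage as of just before
        ``from_event`` (events are 1-indexed; K+1 means 'after all events')."""
        n = 1
        for spawn, child in self.children:
            if spawn >= from_event:
                n += child.descendants(spawn + 1)
        return n


@dataclass(frozen=True)
class DurationLedger:
    """Design matrix of the timing system for one (order, minor) combination.

    For each multiplicity class ``k`` the expected mutation count is
    ``n_k = m * (c_k0 + sum_i c_ki * t_i)``.  Coefficient vectors have length
    ``n_events + 1``: index 0 is the constant term, index i the coefficient
    on ``t_i``.
    """

    order: EventOrder
    minor: int
    multiplicity_classes: tuple[int, ...]
    coefficients: tuple[tuple[float, ...], ...] = field(repr=False)
    total_final_copies: int

    @property
    def n_events(self) -> int:
        return self.order.n_events

    def coefficient_matrix(self) -> np.ndarray:
        """(n_classes, n_events + 1) array; column 0 is the constant term."""
        return np.array(self.coefficients, dtype=float)

    def expected_counts(self, m: float, times: np.ndarray) -> np.ndarray:
        """Expected mutation count per class at rate ``m`` and event times
        ``times`` (length n_events), ordered as ``multiplicity_classes``."""
        t = np.asarray(times, dtype=float)
        if t.shape != (self.n_events,):
            raise ValueError(f"expected {self.n_events} event times, got {t.shape}")
        coeffs = self.coefficient_matrix()
        return m * (coeffs[:, 0] + coeffs[:, 1:] @ t)

    def class_probabilities(self, times: np.ndarray) -> np.ndarray:
        """Probability that a clock-like mutation falls in each class."""
        counts = self.expected_counts(1.0, times)
        return counts / counts.sum()


def _simulate_forest(order: EventOrder) -> tuple[_Copy, list[list[_Copy]]]:
    """Run the major-allele copy forest forward through ``order``.

    Returns the root (the repeatedly gained chromosome copy) and, for each
    inter-event interval 0..K, the list of copies live during that interval.
    """
    root = _Copy()
    live = [root]
    live_per_interval = [list(live)]
    for idx, event in enumerate(order.events, start=1):
        if event == "W":
            new = []
            for copy in live:
                child = _Copy()
                copy.children.append((idx, child))
                new.append(child)
            live.extend(new)
        else:  # G: the same chromosome copy is gained every time
            child = _Copy()
            root.children.append((idx, child))
            live.append(child)
        live_per_interval.append(list(live))
    return root, live_per_interval


@lru_cache(maxsize=None)
def build_duration_ledger(order: EventOrder, minor: int) -> DurationLedger:
    """Construct the duration ledger for ``order`` with ``minor`` minor copies.

    The minor allele is handled outside the forest: with ``minor == 2`` (only
    possible with WGD) its single pre-WGD copy contributes the interval up to
    the WGD at class 2 and both copies contribute afterwards at class 1; with
    ``minor == 1`` one surviving copy contributes duration 1 at class 1 (any
    loss is assumed to have removed the WGD duplicate symmetrically); with
    ``minor == 0`` nothing.
    """
    if minor not in (0, 1, 2):
        raise UnsupportedStateError(f"minor copy number {minor} not in {{0, 1, 2}}")
    if minor == 2 and not order.has_wgd:
        raise UntimeableStateError("minor copy number 2 requires a WGD history")

    k_events = order.n_events
    # coefficient vectors per class: [const, t_1, ..., t_K]
    rows: dict[int, np.ndarray] = {}

    def add_interval(klass: int, i: int) -> None:
        """Add the duration t_{i+1} - t_i of interval i (t_0 = 0, t_{K+1} = 1)."""
        row = rows.setdefault(klass, np.zeros(k_events + 1))
        if i + 1 <= k_events:
            row[i + 1] += 1.0
        else:
            row[0] += 1.0
        if i >= 1:
            row[i] -= 1.0

    _, live_per_interval = _simulate_forest(order)
    for i, live in enumerate(live_per_interval):
        for copy in live:
            add_interval(copy.descendants(i + 1), i)

    if minor == 1:
        row = rows.setdefault(1, np.zeros(k_events + 1))
        row[0] += 1.0
    elif minor == 2:
        wgd_idx = order.events.index("W") + 1  # 1-indexed event position
        for i in range(wgd_idx):
            add_interval(2, i)
        for i in range(wgd_idx, k_events + 1):
            add_interval(1, i)
            add_interval(1, i)

    classes = tuple(sorted(rows))
    return DurationLedger(
        order=order,
        minor=minor,
        multiplicity_classes=classes,
        coefficients=tuple(tuple(rows[k]) for k in classes),
        total_final_copies=order.final_major + minor,
    )


def expected_multiplicity_states(order: EventOrder, minor: int) -> set[int]:
    """Multiplicity classes with nonzero duration for generic event times.

    Always contains 1 and the final major copy number.
    """
    return set(build_duration_ledger(order, minor).multiplicity_classes)
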