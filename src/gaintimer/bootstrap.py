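"""Bootstrap confidence intervals for event times.

Mutations (with their multiplicities) are resampled with replacement, the
timing system is re-solved on each resample, and per-event means and 2.5/97.5
percentile bounds are reported.  Resampling n mutations with replacement and
retaining only their multiplicities is exactly a multinomial draw over the
observed spectrum, so all B resamples are drawn and solved in one vectorised
pass.

The event order is fixed (inferred once from the full data) and is not
re-inferred per resample; read-depth uncertainty in the multiplicity
assignments is not propagated.  The upper bound is not truncated at 1: times
above 1 are informative and must stay inside their intervals.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .copy_history import DurationLedger
from .errors import InvalidParameterError, TooFewMutationsError

DEFAULT_BOOTSTRAPS = 500


def bootstrap_times(
    spectrum: Mapping[int, int],
    ledger: DurationLedger,
    B: int = DEFAULT_BOOTSTRAPS,
    seed: int | np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Bootstrap means and 95% CIs for each event time.

    Returns ``(mean, ci_low, ci_high, n_failures)`` where each array has one
    entry per event.  Resamples for which the solver fails (non-positive
    mutation-rate scale) are counted in ``n_failures`` and excluded from the
    summaries.
    """
    if B < 2:
        raise InvalidParameterError(f"bootstrap count B={B} must be at least 2")
    classes = ledger.multiplicity_classes
    counts = np.array([spectrum.get(k, 0) for k in classes], dtype=float)
    n = int(counts.sum())
    if n < 1:
        raise TooFewMutationsError("cannot bootstrap an empty spectrum")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    resampled = rng.multinomial(n, counts / n, size=B).astype(float)  # (B, classes)

    design = ledger.coefficient_matrix()  # (classes, K+1), square
    solutions = np.linalg.solve(design, resampled.T).T  # (B, K+1)
    m = solutions[:, 0]
    ok = m > 0
    n_failures = int(B - ok.sum())
    if not np.any(ok):
        raise TooFewMutationsError("all bootstrap resamples failed to solve")
    times = solutions[ok, 1:] / m[ok, None]  # (B_ok, K)

    mean = times.mean(axis=0)
    ci_low = np.percentile(times, 2.5, axis=0)
    ci_high = np.percentile(times, 97.5, axis=0)
    return mean, ci_low, ci_high, n_failures
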