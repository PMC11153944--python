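"""Mutation records, segment states, and multiplicity assignment.

Multiplicity — the number of chromosome copies carrying a mutation — is
assigned per mutation by binomial maximum likelihood: the expected variant
allele fraction of a mutation present on ``k`` copies in a tumour of purity
``rho`` at a locus of tumour total copy number ``C`` (normal cells diploid) is

    VAF(k) = k * rho / (rho * C + 2 * (1 - rho))

and the assigned multiplicity maximises the binomial likelihood of the
observed alt read count given the sequencing depth.  When the top copy number
state at the locus is subclonal, candidate multiplicities become fractional
expectations across states weighted by their cell fractions; the winning
candidate is rounded *up* to the next integer, so the final (possibly still
subclonal) gain remains timeable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InvalidParameterError, ValidationError
from .timing import MultiplicitySpectrum


@dataclass
class MutationRecord:
    """One somatic SNV with read counts and optional annotations."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    alt_count: int | None = None
    depth: int | None = None
    context: str | None = None  # 3-mer centred on pos, reference strand
    signature: str | None = None  # e.g. "SBS1"
    multiplicity: float | None = None  # precomputed, possibly fractional
    is_clocklike: bool | None = None  # set by the simulator

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(f"{self.chrom}:{self.pos}: ref equals alt")
        if self.alt_count is not None and self.depth is not None:
            if not (0 <= self.alt_count <= self.depth):
                raise ValidationError(
                    f"{self.chrom}:{self.pos}: alt_count {self.alt_count} "
                    f"outside [0, depth={self.depth}]"
                )


@dataclass
class SegmentState:
    """Allele-specific copy number of one segment, with sample context.

    ``states`` holds one clonal state or a clonal + subclonal pair as
    ``(major, minor, fraction)`` tuples with fractions summing to <= 1.
    Coordinates are 1-based inclusive.
    """

    chrom: str
    start: int
    end: int
    states: list[tuple[int, int, float]]
    purity: float = 1.0
    wgd_flag: bool = False

    def __post_init__(self) -> None:
        if not self.states:
            raise ValidationError("segment needs at least one copy number state")
        for major, minor, frac in self.states:
            if major < minor or minor < 0:
                raise ValidationError(
                    f"invalid state {major}+{minor} on {self.chrom}:{self.start}"
                )
            if not (0 < frac <= 1 + 1e-9):
                raise ValidationError(f"state fraction {frac} outside (0, 1]")
        if not (0 < self.purity <= 1):
            raise InvalidParameterError(f"purity {self.purity} outside (0, 1]")

    @property
    def top_state(self) -> tuple[int, int, float]:
        """The state with the highest major copy number (defines the order;
        a lower coexisting state is considered ancestral)."""
        return max(self.states, key=lambda s: s[0])

    @property
    def is_subclonal_top(self) -> bool:
        return len(self.states) > 1

    @property
    def mean_total_cn(self) -> float:
        """Cell-fraction-weighted tumour total copy number at the locus."""
        return sum(f * (ma + mi) for ma, mi, f in self.states)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


def expected_vaf(k: float, purity: float, total_cn: float) -> float:
    """Expected variant allele fraction of a mutation on ``k`` tumour copies."""
    if not (0 < purity <= 1):
        raise InvalidParameterError(f"purity {purity} outside (0, 1]")
    if k > total_cn or k < 1:
        raise InvalidParameterError(
            f"multiplicity {k} outside [1, total copy number {total_cn}]"
        )
    return k * purity / (purity * total_cn + 2.0 * (1.0 - purity))


def _candidate_multiplicities(segment: SegmentState) -> list[float]:
    """Candidate multiplicities 1..major of the top state.

    With a subclonal top state, a mutation at nominal multiplicity ``k`` is
    carried at ``min(k, major_s)`` copies in cells of each state ``s``, so
    the candidate becomes the fraction-weighted expectation — generally
    non-integer above the ancestral major.
    """
    top_major = segment.top_state[0]
    if not segment.is_subclonal_top:
        return [float(k) for k in range(1, top_major + 1)]
    return [
        sum(f * min(k, ma) for ma, mi, f in segment.states)
        for k in range(1, top_major + 1)
    ]


def assign_multiplicity(record: MutationRecord, segment: SegmentState) -> int:
    """Integer multiplicity of ``record`` by binomial maximum likelihood.

    A precomputed multiplicity on the record takes precedence (compatibility
    with upstream subclonal-clustering output); fractional values are rounded
    up with the ceiling function.  The result is capped at the top major copy
    number.
    """
    top_major = segment.top_state[0]
    if record.multiplicity is not None:
        if record.multiplicity < 0 or math.isnan(record.multiplicity):
            raise ValidationError(
                f"{record.chrom}:{record.pos}: invalid precomputed "
                f"multiplicity {record.multiplicity}"
            )
        return min(max(1, math.ceil(record.multiplicity)), top_major)
    if record.depth is None or record.alt_count is None:
        raise ValidationError(
            f"{record.chrom}:{record.pos}: read counts required when no "
            "precomputed multiplicity is supplied"
        )
    if record.depth == 0:
        raise ValidationError(f"{record.chrom}:{record.pos}: zero depth is uninformative")

    total_cn = segment.mean_total_cn
    candidates = _candidate_multiplicities(segment)
    vafs = np.array([expected_vaf(k, segment.purity, total_cn) for k in candidates])
    vafs = np.clip(vafs, 1e-12, 1 - 1e-12)
    loglik = record.alt_count * np.log(vafs) + (record.depth - record.alt_count) * np.log1p(-vafs)
    best = candidates[int(np.argmax(loglik))]
    return min(max(1, math.ceil(best - 1e-9)), top_major)


def assign_multiplicities(
    mutations: list[MutationRecord], segment: SegmentState
) -> list[MutationRecord]:
    """Assigned copies of ``mutations`` with integer multiplicities.

    Duplicate records at the same genomic position are rejected: the model
    assumes each site is mutated at most once.
    """
    seen: set[tuple[str, int]] = set()
    out = []
    for rec in mutations:
        key = (rec.chrom, rec.pos)
        if key in seen:
            raise ValidationError(
                f"{rec.chrom}:{rec.pos}: duplicate mutation record; each site "
                "may be mutated only once"
            )
        seen.add(key)
        out.append(replace(rec, multiplicity=float(assign_multiplicity(rec, segment))))
    return out


def build_spectrum(mutations: list[MutationRecord]) -> MultiplicitySpectrum:
    """Count mutations per integer multiplicity class."""
    for rec in mutations:
        if rec.multiplicity is None:
            raise ValidationError(
                f"{rec.chrom}:{rec.pos}: record lacks an assigned multiplicity"
            )
    return MultiplicitySpectrum.from_multiplicities(
        int(round(rec.multiplicity)) for rec in mutations
    )
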