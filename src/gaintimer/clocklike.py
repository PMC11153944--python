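"""Clock-like mutation selection.

Timing in mutational time only corresponds to chronological time if the
mutations used accrue at a constant rate.  Two proxies are supported:
mutations attributed to the clock-like single-base-substitution signatures
SBS1/SBS5, and C>T mutations at CpG dinucleotides (the dominant SBS1
channel).  CpG detection is strand-symmetric: a G>A with a 5' C is the same
event read from the other strand.  Users may bypass filtering (`mode="all"`)
at their own risk.
"""

from __future__ import annotations

from typing import Sequence

from .errors import ContextUnavailableError, MissingAnnotationError
from .multiplicity import MutationRecord

CLOCKLIKE_SIGNATURES = frozenset({"SBS1", "SBS5"})
MODES = ("all", "sbs", "ct_cpg")

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def get_context(record: MutationRecord, reference=None) -> str:
    """3-mer reference context centred on the mutated base.

    Uses the record's annotation when present, otherwise an indexed FASTA
    (any object supporting ``fetch(chrom, start, end)`` with 0-based
    half-open coordinates, e.g. ``pysam.FastaFile`` or ``pyfaidx.Fasta``).
    """
    if record.context is not None:
        return record.context.upper()
    if reference is None:
        raise ContextUnavailableError(
            f"{record.chrom}:{record.pos}: no context annotation and no "
            "reference FASTA supplied"
        )
    if hasattr(reference, "fetch"):  # pysam-style
        seq = reference.fetch(record.chrom, record.pos - 2, record.pos + 1)
    else:  # pyfaidx-style mapping
        seq = str(reference[record.chrom][record.pos - 2 : record.pos + 1])
    if len(seq) != 3:
        raise ContextUnavailableError(
            f"{record.chrom}:{record.pos}: context lookup returned {seq!r}"
        )
    return seq.upper()


def is_ct_cpg(record: MutationRecord, reference=None) -> bool:
    """True iff the mutation is a C>T at a CpG site (strand-symmetric)."""
    context = get_context(record, reference)
    ref, alt = record.ref.upper(), record.alt.upper()
    if ref == "C" and alt == "T":
        return context[2] == "G"
    if ref == "G" and alt == "A":
        # reverse complement: C>T at CpG on the other strand
        return context[0] == "C"
    return False


def filter_mutations(
    mutations: Sequence[MutationRecord], mode: str = "all", reference=None
) -> list[MutationRecord]:
    """Subset of ``mutations`` usable as a molecular clock under ``mode``."""
    if mode not in MODES:
        raise ValueError(f"mode {mode!r} not in {MODES}")
    if mode == "all":
        return list(mutations)
    if mode == "sbs":
        if any(rec.signature is None for rec in mutations):
            raise MissingAnnotationError(
                "mode='sbs' requires a signature annotation on every mutation"
            )
        return [rec for rec in mutations if rec.signature in CLOCKLIKE_SIGNATURES]
    return [rec for rec in mutations if is_ct_cpg(rec, reference)]
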