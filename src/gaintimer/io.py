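"""Readers and writers for mutation tables, segment tables, and results.

Coordinates are 1-based and inclusive throughout (the VCF / Battenberg
convention).  Mutation tables are tab-separated with columns ``chr`` (or
``chrom``), ``pos``, ``ref``, ``alt`` and optionally ``alt_count``, ``depth``,
``context``, ``signature``, ``multiplicity``; read counts are required unless
a precomputed multiplicity is present.  Segment tables follow Battenberg
naming: ``chr``, ``startpos``, ``endpos``, ``nMaj1_A``, ``nMin1_A``,
``frac1_A`` and optionally a second subclonal state ``nMaj2_A``, ``nMin2_A``,
``frac2_A``.  VCF input is supported through cyvcf2, taking alt/depth from
the first sample's AD and DP genotype fields.
"""

from __future__ import annotations

import math
import re
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import ValidationError
from .multiplicity import MutationRecord, SegmentState
from .timing import TimingResult

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_region(region: str) -> tuple[str, int, int]:
    """Parse ``chrom:start-end`` (1-based inclusive)."""
    m = _REGION_RE.match(region.strip())
    if not m:
        raise ValidationError(f"region {region!r} is not of the form chrom:start-end")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start > end:
        raise ValidationError(f"region {region!r} has start > end")
    return chrom, start, end


def _optional(row, column):
    if column not in row or pd.isna(row[column]):
        return None
    return row[column]


def read_mutations(path, format: str | None = None) -> list[MutationRecord]:
    """Load mutation records from a TSV table or a VCF."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() in (".vcf", ".gz") else "tsv"
    if format == "vcf":
        return _read_mutations_vcf(path)
    if format != "tsv":
        raise ValidationError(f"unknown mutation format {format!r}")
    return _read_mutations_tsv(path)


def _read_mutations_tsv(path: Path) -> list[MutationRecord]:
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"chr": str, "chrom": str})
    chrom_col = "chr" if "chr" in table.columns else "chrom"
    required = {chrom_col, "pos", "ref", "alt"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    records = []
    for idx, row in table.iterrows():
        line = idx + 2  # 1-based, after the header
        try:
            alt_count = _optional(row, "alt_count")
            depth = _optional(row, "depth")
            multiplicity = _optional(row, "multiplicity")
            if multiplicity is None and (alt_count is None or depth is None):
                raise ValidationError(
                    "needs alt_count and depth (or a precomputed multiplicity)"
                )
            records.append(
                MutationRecord(
                    chrom=str(row[chrom_col]),
                    pos=int(row["pos"]),
                    ref=str(row["ref"]).upper(),
                    alt=str(row["alt"]).upper(),
                    alt_count=None if alt_count is None else int(alt_count),
                    depth=None if depth is None else int(depth),
                    context=_optional(row, "context"),
                    signature=_optional(row, "signature"),
                    multiplicity=None if multiplicity is None else float(multiplicity),
                )
            )
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {line}: {exc}") from exc
    return records


def _read_mutations_vcf(path: Path) -> list[MutationRecord]:
    from cyvcf2 import VCF

    records = []
    for variant in VCF(str(path)):
        if len(variant.ALT) != 1 or len(variant.REF) != 1 or len(variant.ALT[0]) != 1:
            continue  # SNVs only
        depth = alt_count = None
        try:
            ad = variant.format("AD")
            if ad is not None:
                alt_count = int(ad[0][1])
        except (KeyError, IndexError, TypeError):
            pass
        try:
            dp = variant.format("DP")
            if dp is not None:
                depth = int(dp[0][0] if hasattr(dp[0], "__len__") else dp[0])
        except (KeyError, IndexError, TypeError):
            pass
        if depth is None and alt_count is not None:
            ad = variant.format("AD")
            depth = int(ad[0][0]) + int(ad[0][1])
        records.append(
            MutationRecord(
                chrom=variant.CHROM,
                pos=variant.POS,
                ref=variant.REF,
                alt=variant.ALT[0],
                alt_count=alt_count,
                depth=depth,
            )
        )
    return records


def read_segments(path, purity: float = 1.0, wgd_flag: bool = False) -> list[SegmentState]:
    """Load a Battenberg-style allele-specific copy number table."""
    table = pd.read_csv(path, sep="\t", comment="#", dtype={"chr": str, "chrom": str})
    chrom_col = "chr" if "chr" in table.columns else "chrom"
    required = {chrom_col, "startpos", "endpos", "nMaj1_A", "nMin1_A", "frac1_A"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"{path}: missing required columns {sorted(missing)}")
    segments = []
    for idx, row in table.iterrows():
        line = idx + 2
        try:
            states = [(int(row["nMaj1_A"]), int(row["nMin1_A"]), float(row["frac1_A"]))]
            maj2 = _optional(row, "nMaj2_A")
            if maj2 is not None and not (
                isinstance(maj2, float) and math.isnan(maj2)
            ):
                states.append(
                    (int(maj2), int(row["nMin2_A"]), float(row["frac2_A"]))
                )
            segments.append(
                SegmentState(
                    chrom=str(row[chrom_col]),
                    start=int(row["startpos"]),
                    end=int(row["endpos"]),
                    states=states,
                    purity=purity,
                    wgd_flag=wgd_flag,
                )
            )
        except (ValueError, TypeError, ValidationError) as exc:
            raise ValidationError(f"{path}: line {line}: {exc}") from exc
    _check_overlaps(segments, path)
    return segments


def _check_overlaps(segments: list[SegmentState], path) -> None:
    by_chrom: dict[str, list[SegmentState]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValidationError(
                    f"{path}: overlapping segments on {chrom}: "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )


RESULT_COLUMNS = [
    "sample",
    "chrom",
    "start",
    "end",
    "major",
    "minor",
    "order",
    "event_index",
    "event_type",
    "t_point",
    "t_boot_mean",
    "ci_low",
    "ci_high",
    "n_mutations_order",
    "n_mutations_timing",
    "flags",
]


def results_table(
    items: Iterable[tuple[SegmentState, TimingResult]], sample: str = "sample"
) -> pd.DataFrame:
    """One row per (segment, event)."""
    rows = []
    for segment, result in items:
        major, minor, _ = segment.top_state
        for i, label in enumerate(result.event_labels):
            rows.append(
                {
                    "sample": sample,
                    "chrom": segment.chrom,
                    "start": segment.start,
                    "end": segment.end,
                    "major": major,
                    "minor": minor,
                    "order": str(result.order),
                    "event_index": i + 1,
                    "event_type": label,
                    "t_point": result.t_point[i],
                    "t_boot_mean": None
                    if result.t_boot_mean is None
                    else result.t_boot_mean[i],
                    "ci_low": None if result.ci_low is None else result.ci_low[i],
                    "ci_high": None if result.ci_high is None else result.ci_high[i],
                    "n_mutations_order": result.n_mutations_order,
                    "n_mutations_timing": result.n_mutations_timing,
                    "flags": ";".join(sorted(result.flags)),
                }
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(
    items: Iterable[tuple[SegmentState, TimingResult]],
    path,
    sample: str = "sample",
    seed: int | None = None,
    mode: str = "all",
    bootstraps: int | None = None,
) -> None:
    """Write the results TSV with a commented provenance header."""
    from . import __version__

    table = results_table(items, sample=sample)
    with open(path, "w") as fh:
        fh.write(f"# gaintimer {__version__}\n")
        fh.write(f"# seed: {seed}\n# mutation_mode: {mode}\n# bootstraps: {bootstraps}\n")
        table.to_csv(fh, sep="\t", index=False)
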