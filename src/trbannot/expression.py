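"""TRBC read assignment, RPKM and the TRBC1/TRBC2 expression ratio.

Reads are aligned to every reference on both strands; the best alignment
wins if its edit distance (substitutions and indels both count as
mismatches) is at most ``max_mismatches``, reads tying between different
references are discarded as ambiguous, and counts are converted to RPKM
using total input reads as library depth:

    RPKM = count x 10^9 / (total_input_reads x reference_length)

The reported ratio rounds half away from zero to one decimal; the raw
value is retained. A SAM/BAM path (primary alignments filtered on the NM
tag) is provided for externally mapped data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import edlib

from .seq_io import revcomp

__all__ = [
    "ExpressionResult",
    "assign_reads",
    "rpkm",
    "c_ratio",
    "quantify",
    "count_sam",
]


@dataclass
class ExpressionResult:
    counts: dict[str, int]
    reference_lengths: dict[str, int]
    total_input_reads: int
    rpkm: dict[str, float] = field(default_factory=dict)
    ratio_c1_c2: float | None = None
    ratio_c1_c2_rounded: float | None = None
    ratio_undefined: bool = False
    discarded: dict[str, int] = field(default_factory=dict)

    @property
    def reads_processed(self) -> int:
        return sum(self.counts.values()) + sum(self.discarded.values())

    def to_row(self, dataset: str = "") -> dict:
        keys = sorted(self.counts)
        row = {"dataset": dataset, "input_reads": self.total_input_reads}
        for k in keys:
            row[f"rpkm_{k}"] = self.rpkm.get(k)
        row["ratio"] = self.ratio_c1_c2_rounded
        return row


def assign_reads(
    reads,
    c_refs: dict[str, str],
    max_mismatches: int = 2,
) -> tuple[dict[str, int], dict[str, int]]:
    """Assign each read to its best reference under the mismatch cap.

    ``reads`` yields (id, sequence[, quality]) tuples. Each read is
    locally aligned (infix semiglobal) to every reference on both
    strands; indels count toward the mismatch total. Returns
    (counts per reference, discards by reason).
    """
    if not c_refs:
        raise ValueError("empty reference set")
    refs = {k: v.upper() for k, v in c_refs.items()}
    counts = {k: 0 for k in refs}
    discarded = {"too_many_mismatches": 0, "ambiguous_tie": 0, "unmapped": 0}
    for rec in reads:
        seq = rec[1].upper()
        best_d = None
        best_refs: set[str] = set()
        for name, ref in refs.items():
            for query in (seq, revcomp(seq)):
                res = edlib.align(query, ref, mode="HW", task="distance", k=max_mismatches)
                d = res["editDistance"]
                if d < 0:
                    continue
                if best_d is None or d < best_d:
                    best_d, best_refs = d, {name}
                elif d == best_d:
                    best_refs.add(name)
        if best_d is None:
            discarded["too_many_mismatches"] += 1
        elif len(best_refs) > 1:
            discarded["ambiguous_tie"] += 1
        else:
            counts[best_refs.pop()] += 1
    return counts, discarded


def rpkm(count: int, total_input_reads: int, reference_length: int) -> float:
    """Reads per kilobase of reference per million input reads."""
    if total_input_reads <= 0:
        raise ValueError("total_input_reads must be > 0")
    if reference_length <= 0:
        raise ValueError("reference_length must be > 0")
    return count * 1e9 / (total_input_reads * reference_length)


def c_ratio(rpkm_c1: float, rpkm_c2: float) -> tuple[float, float]:
    """TRBC1/TRBC2 ratio; returns (raw, rounded-to-1-decimal).

    Rounding is half away from zero, matching conventional table
    formatting. Raises on a zero denominator (flag upstream instead).
    """
    if rpkm_c2 <= 0:
        raise ValueError("rpkm_c2 must be > 0 (ratio undefined)")
    raw = rpkm_c1 / rpkm_c2
    sign = -1.0 if raw < 0 else 1.0
    rounded = float(
        Decimal(repr(abs(raw))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )
    return raw, sign * rounded


def quantify(
    reads,
    c_refs: dict[str, str],
    total_input_reads: int | None = None,
    max_mismatches: int = 2,
    c1: str = "TRBC1",
    c2: str = "TRBC2",
) -> ExpressionResult:
    """Full pipeline: assign, count, RPKM, TRBC1/TRBC2 ratio."""
    counts, discarded = assign_reads(reads, c_refs, max_mismatches)
    total = total_input_reads
    if total is None:
        total = sum(counts.values()) + sum(discarded.values())
    lengths = {k: len(v) for k, v in c_refs.items()}
    result = ExpressionResult(counts, lengths, total, discarded=discarded)
    result.rpkm = {k: rpkm(counts[k], total, lengths[k]) for k in c_refs}
    if c1 in result.rpkm and c2 in result.rpkm:
        if result.rpkm[c2] <= 0:
            result.ratio_undefined = True
        else:
            result.ratio_c1_c2, result.ratio_c1_c2_rounded = c_ratio(
                result.rpkm[c1], result.rpkm[c2]
            )
    return result


def count_sam(path, max_mismatches: int = 2) -> dict[str, int]:
    """Count primary alignments per reference in a SAM/BAM file, keeping
    records whose NM tag (edit distance) is <= ``max_mismatches``."""
    import pysam

    counts: dict[str, int] = {}
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        for name in fh.references:
            counts[name] = 0
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            nm = rec.get_tag("NM") if rec.has_tag("NM") else 0
            if nm <= max_mismatches:
                counts[rec.reference_name] += 1
    return counts
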