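"""Sequence and annotation IO with strand-aware coordinate arithmetic.

All internal coordinates are 0-based half-open on the forward strand of a
contig. External formats use their own conventions: GFF3 is 1-based
inclusive, BED is 0-based half-open. Conversion helpers are provided so the
two never mix silently.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "GenomicSequence",
    "Interval",
    "GffFeature",
    "load_fasta",
    "write_fasta",
    "load_fastq",
    "extract",
    "revcomp",
    "translate",
    "read_gff3",
    "write_gff3",
    "to_external",
    "from_external",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence over {A, C, G, T, N}, uppercased on load."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - set("ACGTN")
        if bad:
            raise ValueError(f"sequence {self.id!r}: non-DNA residues {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """Strand-aware region: 0-based half-open [start, end) on ``contig``."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def shift(self, offset: int) -> "Interval":
        return Interval(self.contig, self.start + offset, self.end + offset, self.strand)

    def opposite(self) -> "Interval":
        return Interval(self.contig, self.start, self.end, "-" if self.strand == "+" else "+")

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


def to_external(iv: Interval) -> tuple[str, int, int, str]:
    """Internal 0-based half-open -> external 1-based inclusive (GFF3 style)."""
    return (iv.contig, iv.start + 1, iv.end, iv.strand)


def from_external(contig: str, start1: int, end1: int, strand: str = "+") -> Interval:
    """External 1-based inclusive -> internal 0-based half-open."""
    return Interval(contig, start1 - 1, end1, strand)


def revcomp(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def load_fasta(path) -> dict[str, GenomicSequence]:
    """Load a multi-FASTA into an id-keyed, order-preserving dict.

    Raises on duplicate ids, empty records and empty files.
    """
    records: dict[str, GenomicSequence] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        if len(rec.seq) == 0:
            raise ValueError(f"empty FASTA record {rec.id!r} in {path}")
        records[rec.id] = GenomicSequence(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs, path, width: int = 60) -> None:
    """Write GenomicSequences (iterable or id-keyed dict) as wrapped FASTA."""
    if isinstance(seqs, dict):
        seqs = seqs.values()
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i : i + width] + "\n")


def load_fastq(path):
    """Yield (id, sequence, quality-string) from a Sanger FASTQ file."""
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        yield rec.id, str(rec.seq).upper(), qual


def extract(seq: GenomicSequence, iv: Interval) -> str:
    """Extract ``iv`` from ``seq``; reverse strand returns the reverse complement."""
    if iv.contig != seq.id:
        raise ValueError(f"interval contig {iv.contig!r} != sequence id {seq.id!r}")
    if iv.end > len(seq):
        raise ValueError(
            f"interval [{iv.start}, {iv.end}) out of bounds for {seq.id!r} (length {len(seq)})"
        )
    sub = seq.residues[iv.start : iv.end]
    return revcomp(sub) if iv.strand == "-" else sub


def translate(dna: str, frame: int = 0) -> str:
    """Translate ``dna`` in ``frame`` with the standard code.

    Stops render as '*'; codons containing non-ACGT residues render as 'X';
    a trailing partial codon is dropped.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    s = dna.upper()[frame:]
    s = s[: len(s) - len(s) % 3]
    if not s:
        return ""
    # Seq.translate maps ambiguous codons to X and stops to * already.
    return str(Seq(s).translate())


# ---------------------------------------------------------------------------
# GFF3

_GFF_ESCAPES = {";": "%3B", "=": "%3D", ",": "%2C", "&": "%26", "\t": "%09"}


def _attr_escape(v: str) -> str:
    v = v.replace("%", "%25")
    for k, r in _GFF_ESCAPES.items():
        v = v.replace(k, r)
    return v


def _attr_unescape(v: str) -> str:
    for k, r in _GFF_ESCAPES.items():
        v = v.replace(r, k)
    return v.replace("%25", "%")


@dataclass
class GffFeature:
    """One GFF3 feature line; ``iv`` is internal-coordinate."""

    iv: Interval
    ftype: str
    source: str = "trbannot"
    score: str = "."
    phase: str = "."
    attributes: dict[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        contig, start1, end1, strand = to_external(self.iv)
        attrs = ";".join(
            f"{k}={_attr_escape(str(v))}" for k, v in self.attributes.items()
        ) or "."
        return "\t".join(
            [contig, self.source, self.ftype, str(start1), str(end1),
             self.score, strand, self.phase, attrs]
        )


def write_gff3(features, path) -> None:
    out = io.StringIO()
    out.write("##gff-version 3\n")
    for f in features:
        out.write(f.to_line() + "\n")
    with open(path, "w") as fh:
        fh.write(out.getvalue())


def read_gff3(path) -> list[GffFeature]:
    feats: list[GffFeature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            contig, source, ftype, start1, end1, score, strand, phase, attr = line.split("\t")
            attributes = {}
            if attr != ".":
                for pair in attr.split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attributes[k] = _attr_unescape(v)
            feats.append(
                GffFeature(
                    iv=from_external(contig, int(start1), int(end1), strand),
                    ftype=ftype,
                    source=source,
                    score=score,
                    phase=phase,
                    attributes=attributes,
                )
            )
    return feats


def write_bed6(features, path) -> None:
    """Optional BED6 export (0-based half-open, as BED specifies)."""
    with open(path, "w") as fh:
        for f in features:
            name = f.attributes.get("Name", f.ftype)
            fh.write(
                f"{f.iv.contig}\t{f.iv.start}\t{f.iv.end}\t{name}\t0\t{f.iv.strand}\n"
            )
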