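"""Recombination-signal (RS) and splice-signal detection.

An RS is a heptamer/spacer/nonamer motif abutting the coding end of a V, D
or J gene; the spacer is nominally 12 or 23 bp and recombination obeys the
12/23 rule. The scanner matches both literal layouts of the motif on the
forward sequence:

* ``CACAGTG .. spacer .. ACAAAAACC``  -> orientation ``gene-3prime``
  (the RS a forward-strand gene carries at its 3' coding end), and
* ``GGTTTTTGT .. spacer .. CACTGTG``  -> orientation ``gene-5prime``
  (the reverse-complement layout a forward-strand J or D gene carries
  5' of its coding start).

A ``gene-3prime`` hit read from the reverse strand is a ``gene-5prime``
RS of a reverse-strand gene, and vice versa; callers reinterpret via
:meth:`RSHit.orientation_for`. Coordinates are always forward-strand.

Scoring is mismatch-count only (heptamer + nonamer mismatches); a PWM hook
is deliberately not enabled by default so that hit sets are reproducible
and checkable against exhaustive scans.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seq_io import GenomicSequence, Interval, revcomp

__all__ = [
    "RS_HEPTAMER",
    "RS_NONAMER",
    "DONOR_CONSENSUS",
    "RSHit",
    "SpliceSite",
    "scan_rs",
    "pair_rs_12_23",
    "scan_splice",
]

RS_HEPTAMER = "CACAGTG"
RS_NONAMER = "ACAAAAACC"
DONOR_CONSENSUS = "GTAAGT"
_PYRIMIDINES = set("CT")


@dataclass(frozen=True)
class RSHit:
    """One heptamer-spacer-nonamer match.

    ``strand`` is the strand of the gene this RS would serve under the
    forward-frame reading; ``orientation`` says on which side of that gene
    the RS sits. ``heptamer``/``nonamer`` are forward-strand intervals.
    """

    heptamer: Interval
    nonamer: Interval
    spacer_length: int
    spacer_class: int
    orientation: str  # gene-3prime | gene-5prime
    heptamer_mismatches: int
    nonamer_mismatches: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.spacer_class not in (12, 23):
            raise ValueError(f"spacer_class must be 12 or 23, got {self.spacer_class}")
        if abs(self.spacer_length - self.spacer_class) > 1:
            raise ValueError(
                f"spacer_length {self.spacer_length} incompatible with class {self.spacer_class}"
            )
        if self.orientation not in ("gene-3prime", "gene-5prime"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        if self.heptamer.overlaps(self.nonamer):
            raise ValueError("heptamer and nonamer overlap")

    @property
    def score(self) -> int:
        return self.heptamer_mismatches + self.nonamer_mismatches

    @property
    def start(self) -> int:
        return min(self.heptamer.start, self.nonamer.start)

    @property
    def end(self) -> int:
        return max(self.heptamer.end, self.nonamer.end)

    def orientation_for(self, gene_strand: str) -> str:
        """Orientation of this hit relative to a gene on ``gene_strand``."""
        if gene_strand == self.strand:
            return self.orientation
        return "gene-5prime" if self.orientation == "gene-3prime" else "gene-3prime"

    def coding_edge(self, gene_strand: str) -> int:
        """Forward coordinate where the abutting coding region ends/starts."""
        if self.orientation_for(gene_strand) == "gene-3prime":
            # coding is on the heptamer's outer side
            return self.heptamer.start if self.heptamer.start < self.nonamer.start else self.heptamer.end
        return self.heptamer.end if self.heptamer.start < self.nonamer.start else self.heptamer.start


@dataclass
class SpliceSite:
    """A donor (GT..) or acceptor (..AG) splice signal.

    ``frame`` is the splicing frame relative to the upstream exon: 0 means
    the junction falls between codons, 1/2 that the codon is split after
    1 or 2 bases.
    """

    kind: str  # donor | acceptor
    position: Interval
    motif: str
    score: int = 0
    frame: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("donor", "acceptor"):
            raise ValueError(f"bad splice kind {self.kind!r}")
        if self.frame not in (0, 1, 2):
            raise ValueError(f"bad splicing frame {self.frame}")


def _as_str(seq) -> tuple[str, str]:
    if isinstance(seq, GenomicSequence):
        return seq.residues, seq.id
    return seq.upper(), "seq"


def _mismatches(s: str, i: int, motif: str) -> int:
    return sum(1 for k, m in enumerate(motif) if s[i + k] != m)


def _mismatch_profile(arr: np.ndarray, motif: str) -> np.ndarray:
    """Vector of mismatch counts of ``motif`` at every start position."""
    n, m = len(arr), len(motif)
    if n < m:
        return np.zeros(0, dtype=np.int8)
    out = np.zeros(n - m + 1, dtype=np.int8)
    mot = np.frombuffer(motif.encode(), dtype="S1")
    for k in range(m):
        out += arr[k : n - m + 1 + k] != mot[k]
    return out


def scan_rs(
    seq,
    spacer_class: int,
    max_heptamer_mm: int = 2,
    max_nonamer_mm: int = 3,
    spacer_slack: int = 1,
    require_cac: bool = True,
) -> list[RSHit]:
    """Exhaustively scan for RS motifs of one spacer class, both layouts.

    A window is a hit when the heptamer matches ``CACAGTG`` within
    ``max_heptamer_mm`` (with the recombinationally critical CAC core
    exact when ``require_cac``) and the nonamer matches ``ACAAAAACC``
    within ``max_nonamer_mm``, at spacer ``spacer_class`` +/-
    ``spacer_slack``. Hits are sorted by position, then score.
    """
    if spacer_class not in (12, 23):
        raise ValueError(f"spacer_class must be 12 or 23, got {spacer_class}")
    s, contig = _as_str(seq)
    n = len(s)
    min_len = 7 + spacer_class - spacer_slack + 9
    hits: list[RSHit] = []
    if n < min_len:
        return hits

    arr = np.frombuffer(s.encode(), dtype="S1")
    spacers = range(spacer_class - spacer_slack, spacer_class + spacer_slack + 1)

    hep_fwd = _mismatch_profile(arr, RS_HEPTAMER)
    non_fwd = _mismatch_profile(arr, RS_NONAMER)
    hep_rc = _mismatch_profile(arr, revcomp(RS_HEPTAMER))
    non_rc = _mismatch_profile(arr, revcomp(RS_NONAMER))
    if require_cac:
        cac_fwd = _mismatch_profile(arr, "CAC") == 0
        gtg = _mismatch_profile(arr, "GTG") == 0  # revcomp(CAC)
    hep_ok_f = hep_fwd <= max_heptamer_mm
    hep_ok_r = hep_rc <= max_heptamer_mm
    if require_cac:
        hep_ok_f &= cac_fwd[: len(hep_ok_f)]
        # CAC core maps to the last 3 bases of the reverse-complement heptamer
        hep_ok_r &= gtg[4 : 4 + len(hep_ok_r)]

    for sp in spacers:
        # forward layout: heptamer at i, nonamer at i+7+sp -> gene-3prime
        j0 = 7 + sp
        lim = min(len(hep_ok_f), len(non_fwd) - j0)
        if lim > 0:
            ok = hep_ok_f[:lim] & (non_fwd[j0 : j0 + lim] <= max_nonamer_mm)
            for i in np.nonzero(ok)[0]:
                i = int(i)
                hits.append(
                    RSHit(
                        heptamer=Interval(contig, i, i + 7),
                        nonamer=Interval(contig, i + j0, i + j0 + 9),
                        spacer_length=sp,
                        spacer_class=spacer_class,
                        orientation="gene-3prime",
                        heptamer_mismatches=int(hep_fwd[i]),
                        nonamer_mismatches=int(non_fwd[i + j0]),
                    )
                )
        # reverse-complement layout: nonamer' at i-sp-9, heptamer' at i -> gene-5prime
        off = sp + 9
        lim = len(hep_ok_r)
        if lim > off:
            ok = hep_ok_r[off:lim] & (non_rc[: lim - off] <= max_nonamer_mm)
            for k in np.nonzero(ok)[0]:
                i = int(k) + off
                hits.append(
                    RSHit(
                        heptamer=Interval(contig, i, i + 7),
                        nonamer=Interval(contig, i - off, i - off + 9),
                        spacer_length=sp,
                        spacer_class=spacer_class,
                        orientation="gene-5prime",
                        heptamer_mismatches=int(hep_rc[i]),
                        nonamer_mismatches=int(non_rc[i - off]),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.score, h.orientation))
    return hits


def pair_rs_12_23(hits: list[RSHit], min_gap: int = 8, max_gap: int = 25) -> list[tuple[RSHit, RSHit]]:
    """Pair 12- and 23-class hits flanking a candidate D-REGION.

    Valid geometry (forward frame): a ``gene-5prime`` hit whose heptamer's
    inner edge faces the heptamer of a downstream ``gene-3prime`` hit, with
    ``min_gap``..``max_gap`` bases between heptamers (the D-REGION window).
    The 12/23 rule admits either arrangement of classes (a forward D has
    5'RS class 12, a reverse D has 5'RS class 23 when read forward). Hits
    pair greedily, closest pair first, each hit used once. Hits must share
    a contig and a strand; returned as ``(12-class hit, 23-class hit)``.
    """
    five = [h for h in hits if h.orientation == "gene-5prime"]
    three = [h for h in hits if h.orientation == "gene-3prime"]
    candidates = []
    for a in five:
        for b in three:
            if a.heptamer.contig != b.heptamer.contig or a.strand != b.strand:
                continue
            if {a.spacer_class, b.spacer_class} != {12, 23}:
                continue
            gap = b.heptamer.start - a.heptamer.end
            if min_gap <= gap <= max_gap:
                candidates.append((gap, a.score + b.score, a, b))
    candidates.sort(key=lambda c: (c[0], c[1], c[2].start))
    used: set[int] = set()
    pairs: list[tuple[RSHit, RSHit]] = []
    for _, _, a, b in candidates:
        if id(a) in used or id(b) in used:
            continue
        used.add(id(a))
        used.add(id(b))
        twelve, twenty3 = (a, b) if a.spacer_class == 12 else (b, a)
        pairs.append((twelve, twenty3))
    pairs.sort(key=lambda p: min(p[0].start, p[1].start))
    return pairs


def scan_splice(seq, kind: str, window: Interval) -> list[SpliceSite]:
    """Scan ``window`` for splice signals of ``kind`` on the window strand.

    Donors are GT dinucleotides, scored by agreement with the full
    ``GTAAGT`` hexamer; acceptors are AG dinucleotides preceded by a
    pyrimidine-rich tract (>=5 pyrimidines in the 8 preceding bases; the
    tract definition is a configurable heuristic, the motif itself being
    the only universal signal). Sorted by score (desc), then position.
    """
    if kind not in ("donor", "acceptor"):
        raise ValueError(f"bad splice kind {kind!r}")
    s, contig = _as_str(seq)
    if window.end > len(s):
        raise ValueError(f"window [{window.start},{window.end}) outside sequence")
    sub = s[window.start : window.end]
    if window.strand == "-":
        sub = revcomp(sub)

    sites: list[SpliceSite] = []
    L = len(sub)

    def to_fwd(i: int, length: int) -> Interval:
        # map window-local [i, i+length) back to forward coordinates
        if window.strand == "+":
            return Interval(contig, window.start + i, window.start + i + length, "+")
        return Interval(contig, window.end - i - length, window.end - i, "-")

    if kind == "donor":
        for i in range(L - 1):
            if sub[i : i + 2] != "GT":
                continue
            hexamer = sub[i : i + 6]
            score = sum(1 for k, m in enumerate(DONOR_CONSENSUS) if k < len(hexamer) and hexamer[k] == m)
            sites.append(SpliceSite("donor", to_fwd(i, len(hexamer)), hexamer, score=score))
    else:
        for i in range(L - 1):
            if sub[i : i + 2] != "AG":
                continue
            tract = sub[max(0, i - 8) : i]
            pyr = sum(1 for c in tract if c in _PYRIMIDINES)
            if pyr >= 5:
                sites.append(SpliceSite("acceptor", to_fwd(i, 2), sub[i : i + 2], score=pyr))
    sites.sort(key=lambda x: (-x.score, x.position.start))
    return sites
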