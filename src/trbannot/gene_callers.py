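"""Call C, J, D and V genes and assemble them into oriented V-D-J-C loci.

Calling is similarity-seeded: reference coding sequences locate candidate
regions (k-mer seeds grouped on diagonals, per-segment identity), a
spliced-alignment refinement places exon boundaries on GT..AG signals, and
RS motif evidence fixes coding ends and licenses the call. D and J genes
are motif-called inside the region between the V cluster and the C gene.

All genomic coordinates are forward-strand 0-based half-open; per-gene
exon lists are ordered 5'->3' along the gene.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib

from .functionality import NumberingProfile, RSEvidence
from .motif_scan import (
    DONOR_CONSENSUS,
    RSHit,
    SpliceSite,
    pair_rs_12_23,
    scan_rs,
)
from .seq_io import GenomicSequence, Interval, extract, revcomp, translate

__all__ = [
    "SeedHit",
    "ReferenceLibrary",
    "VGene",
    "DGene",
    "JGene",
    "CGene",
    "Locus",
    "LocusStructure",
    "similarity_search",
    "load_hit_table",
    "call_c_genes",
    "call_j_genes",
    "call_d_genes",
    "call_v_genes",
    "assemble_loci",
    "detect_duplication_pattern",
]

# mismatch-threshold tiers for RS evidence (see functionality docs)
STRICT_RS = dict(max_heptamer_mm=2, max_nonamer_mm=3, spacer_slack=1)
RELAXED_RS = dict(max_heptamer_mm=3, max_nonamer_mm=5, spacer_slack=1, require_cac=True)


@dataclass(frozen=True)
class SeedHit:
    """One ungapped similarity segment of a reference against the genome."""

    query_id: str
    iv: Interval
    q_start: int
    q_end: int
    identity: float
    coverage: float


@dataclass
class ReferenceLibrary:
    """Reference sequences that seed discovery and transfer annotations.

    ``v_refs`` maps subgroup exemplar name -> coding sequence (L-PART1 +
    V-EXON concatenated); ``c_refs`` maps C subgroup name -> spliced CDS.
    ``c_anchors`` maps C-domain numbering position -> amino-acid index in
    the C reference protein.
    """

    v_refs: dict[str, str]
    c_refs: dict[str, str]
    v_leader_len: int = 49
    c_anchors: dict[int, int] = field(
        default_factory=lambda: {23: 22, 41: 40, 89: 88, 104: 103}
    )
    c_regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "C-DOMAIN": (0, 127),
            "CO": (127, 147),
            "TM": (147, 163),
            "CY": (163, 169),
        }
    )
    numbering_profile: NumberingProfile | None = None


# ---------------------------------------------------------------------------
# gene containers


@dataclass
class VGene:
    gene_type = "V"
    contig: str
    strand: str
    l_part1: Interval | None
    v_exons: list[Interval]
    v_rs: RSHit | None
    rs_evidence: RSEvidence
    coding: str
    splice_defects: list[str] = field(default_factory=list)
    anchors: dict[int, str | None] | None = None
    functionality: str | None = None
    functionality_reasons: list[str] = field(default_factory=list)
    subgroup: str | None = None
    name: str | None = None
    ref_id: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def protein(self) -> str:
        return translate(self.coding)

    @property
    def exons(self) -> list[Interval]:
        return ([self.l_part1] if self.l_part1 else []) + self.v_exons

    @property
    def span(self) -> Interval:
        parts = [iv for iv in self.exons]
        if self.v_rs:
            parts += [self.v_rs.heptamer, self.v_rs.nonamer]
        return Interval(
            self.contig, min(p.start for p in parts), max(p.end for p in parts), self.strand
        )

    @property
    def coding_start_fwd(self) -> int:
        return min(e.start for e in self.exons)


@dataclass
class DGene:
    gene_type = "D"
    contig: str
    strand: str
    five_prime_rs: RSHit
    d_region: Interval
    three_prime_rs: RSHit
    functionality: str | None = None
    functionality_reasons: list[str] = field(default_factory=list)
    name: str | None = None

    @property
    def coding(self) -> str:
        return self._coding

    @coding.setter
    def coding(self, value: str) -> None:
        self._coding = value

    @property
    def span(self) -> Interval:
        lo = min(self.five_prime_rs.start, self.three_prime_rs.start, self.d_region.start)
        hi = max(self.five_prime_rs.end, self.three_prime_rs.end, self.d_region.end)
        return Interval(self.contig, lo, hi, self.strand)


@dataclass
class JGene:
    gene_type = "J"
    contig: str
    strand: str
    j_rs: RSHit
    j_region: Interval
    donor: SpliceSite | None
    coding: str
    fgxg_position: int | None = None
    fgxg_frame: int | None = None
    donor_defective: bool = False
    functionality: str | None = None
    functionality_reasons: list[str] = field(default_factory=list)
    name: str | None = None
    expected_length_mod3 = None  # germline J frame is set by rearrangement

    @property
    def span(self) -> Interval:
        lo = min(self.j_rs.start, self.j_region.start)
        hi = max(self.j_rs.end, self.j_region.end)
        if self.donor is not None:
            hi = max(hi, self.donor.position.end)
            lo = min(lo, self.donor.position.start)
        return Interval(self.contig, lo, hi, self.strand)


@dataclass
class CGene:
    gene_type = "C"
    contig: str
    strand: str
    exons: list[Interval]
    coding: str
    conserved_positions: dict[int, str | None] | None = None
    regions: dict[str, tuple[int, int]] | None = None
    splice_defects: list[str] = field(default_factory=list)
    subgroup: str | None = None
    functionality: str | None = None
    functionality_reasons: list[str] = field(default_factory=list)
    name: str | None = None
    ref_id: str | None = None
    flags: list[str] = field(default_factory=list)

    @property
    def protein(self) -> str:
        return translate(self.coding).rstrip("*")

    @property
    def span(self) -> Interval:
        return Interval(
            self.contig,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


@dataclass
class Locus:
    name: str | None
    contig: str
    orientation: str
    v_genes: list[VGene]
    d_gene: DGene | None
    j_genes: list[JGene]
    c_gene: CGene

    @property
    def genes(self) -> list:
        return list(self.v_genes) + ([self.d_gene] if self.d_gene else []) + list(self.j_genes) + [self.c_gene]

    @property
    def complete(self) -> bool:
        return bool(self.v_genes) and self.d_gene is not None and bool(self.j_genes)

    @property
    def span(self) -> Interval:
        spans = [g.span for g in self.genes]
        return Interval(
            self.contig, min(s.start for s in spans), max(s.end for s in spans), self.orientation
        )


@dataclass
class LocusStructure:
    contig: str
    loci: list[Locus]
    orphans: list[VGene]
    pattern: str  # head_to_head_pair | single | remnant | tandem_DJC_duplication
    notes: str = ""


# ---------------------------------------------------------------------------
# similarity search


def _kmer_index(s: str, k: int) -> dict[str, list[int]]:
    idx: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        idx[s[i : i + k]].append(i)
    return idx


def _segments_from_matches(matches: list[tuple[int, int, int]], k: int, max_gap: int = 40):
    """Group (diag, q, g) seed matches into ungapped segments per diagonal."""
    matches.sort()
    segs = []
    cur = None
    for diag, q, g in matches:
        if cur is not None and diag == cur[0] and q - cur[2] <= max_gap:
            cur[2] = q
        else:
            if cur is not None:
                segs.append(cur)
            cur = [diag, q, q]
        if cur[2] < q:
            cur[2] = q
    if cur is not None:
        segs.append(cur)
    # (q_start, q_end, g_start, g_end)
    return [(q0, q1 + k, q0 + d, q1 + k + d) for d, q0, q1 in segs]


def _extend_ungapped(q: str, t: str, qs: int, qe: int, ts: int, te: int, max_ext: int = 40):
    """Extend an ungapped segment outward, keeping the best-scoring ends."""
    # left
    best, score, off, qs_ext = 0, 0, 0, 0
    while off < max_ext and qs - off > 0 and ts - off > 0:
        off += 1
        score += 1 if q[qs - off] == t[ts - off] else -2
        if score > best:
            best, qs_ext = score, off
    qs, ts = qs - qs_ext, ts - qs_ext
    best, score, off = 0, 0, 0
    qe_ext = 0
    while off < max_ext and qe + off < len(q) and te + off < len(t):
        score += 1 if q[qe + off] == t[te + off] else -2
        off += 1
        if score > best:
            best, qe_ext = score, off
    qe_ext = qe_ext if best > 0 else 0
    return qs, qe + qe_ext, ts, te + qe_ext


def similarity_search(
    query_refs: dict[str, str],
    genome: dict[str, GenomicSequence],
    min_identity: float = 70.0,
    min_cov: float = 50.0,
    k: int = 12,
) -> list[SeedHit]:
    """k-mer seeded ungapped-segment search of references against a genome.

    Each hit is one ungapped similarity segment (an exon typically yields
    one segment; introns and indels break segments). Identity is the
    match fraction over the segment; coverage the query fraction the
    segment spans. Overlapping same-strand segments of one query merge.
    Ordering is deterministic: (contig, start, query, strand).
    """
    if not query_refs:
        raise ValueError("empty reference set")
    hits: list[SeedHit] = []
    for contig, gseq in genome.items():
        s = gseq.residues
        if len(s) < k:
            continue
        index = _kmer_index(s, k)
        for qid, qseq0 in query_refs.items():
            for strand in "+-":
                qseq = qseq0.upper() if strand == "+" else revcomp(qseq0.upper())
                if len(qseq) < k:
                    continue
                matches = []
                for qi in range(len(qseq) - k + 1):
                    for gi in index.get(qseq[qi : qi + k], ()):
                        matches.append((gi - qi, qi, gi))
                if not matches:
                    continue
                segs = _segments_from_matches(matches, k)
                merged: list[list[int]] = []
                for qs, qe, gs, ge in sorted(segs, key=lambda x: x[2]):
                    qs, qe, gs, ge = _extend_ungapped(qseq, s, qs, qe, gs, ge)
                    if merged and gs <= merged[-1][3] and qs <= merged[-1][1]:
                        m = merged[-1]
                        m[1], m[3] = max(m[1], qe), max(m[3], ge)
                        m[0], m[2] = min(m[0], qs), min(m[2], gs)
                    else:
                        merged.append([qs, qe, gs, ge])
                for qs, qe, gs, ge in merged:
                    span = min(qe - qs, ge - gs)
                    matches_n = sum(
                        1 for a, b in zip(qseq[qs : qs + span], s[gs : gs + span]) if a == b
                    )
                    identity = 100.0 * matches_n / span if span else 0.0
                    coverage = 100.0 * span / len(qseq)
                    if identity >= min_identity and coverage >= min_cov:
                        if strand == "+":
                            q_lo, q_hi = qs, qe
                        else:  # report query coordinates on the original ref
                            q_lo, q_hi = len(qseq) - qe, len(qseq) - qs
                        hits.append(
                            SeedHit(qid, Interval(contig, gs, ge, strand), q_lo, q_hi, identity, coverage)
                        )
    hits.sort(key=lambda h: (h.iv.contig, h.iv.start, h.query_id, h.iv.strand))
    return hits


def load_hit_table(path) -> list[SeedHit]:
    """Import a 12-column tab-separated local-alignment hit table.

    Columns: query, subject, %identity, length, mismatches, gapopens,
    qstart, qend, sstart, send, evalue, bitscore (1-based inclusive
    coordinates; subject start > end encodes the reverse strand).
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"expected 12 columns, got {len(f)}: {line!r}")
            qid, sid = f[0], f[1]
            ident = float(f[2])
            qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            strand = "+" if ss <= se else "-"
            if strand == "-":
                ss, se = se, ss
            hits.append(
                SeedHit(
                    qid,
                    Interval(sid, ss - 1, se, strand),
                    qs - 1,
                    qe,
                    ident,
                    100.0 * (abs(qe - qs) + 1) / max(qe, qs),
                )
            )
    hits.sort(key=lambda h: (h.iv.contig, h.iv.start, h.query_id, h.iv.strand))
    return hits


# ---------------------------------------------------------------------------
# spliced alignment of a coding reference onto a genomic window


def _hamming(a: str, b: str) -> int:
    return sum(1 for x, y in zip(a, b) if x != y) + abs(len(a) - len(b))


@dataclass
class _Junction:
    q_boundary: int
    donor_pos: int       # window coord right after upstream exon
    acceptor_pos: int    # window coord where downstream exon starts
    donor_motif: str
    acceptor_motif: str
    defective: bool
    frame: int


def _chain_segments(ref: str, win: str, k: int = 11):
    matches = []
    index = _kmer_index(win, k) if len(win) >= k else {}
    for qi in range(max(0, len(ref) - k + 1)):
        for gi in index.get(ref[qi : qi + k], ()):
            matches.append((gi - qi, qi, gi))
    segs = _segments_from_matches(matches, k)
    segs.sort(key=lambda x: (x[0], x[2]))
    # chain by DP: maximize covered query length with consistent order
    segs.sort(key=lambda x: x[0])
    n = len(segs)
    best_score = [0.0] * n
    prev = [-1] * n
    for i, (qs, qe, ts, te) in enumerate(segs):
        best_score[i] = qe - qs
        for j in range(i):
            qj = segs[j]
            if qj[1] <= qs + 5 and qj[3] <= ts + 5 and best_score[j] + (qe - qs) > best_score[i]:
                best_score[i] = best_score[j] + (qe - qs)
                prev[i] = j
    if not segs:
        return []
    i = max(range(n), key=lambda x: best_score[x])
    chain = []
    while i >= 0:
        chain.append(list(segs[i]))
        i = prev[i]
    chain.reverse()
    return chain


def spliced_align(
    ref: str,
    win: str,
    min_intron: int = 30,
    max_shift: int = 6,
    k: int = 11,
) -> tuple[list[tuple[int, int, int, int]], list[_Junction]]:
    """Align a spliced coding reference to a genomic window.

    Returns exon segments as (q_start, q_end, t_start, t_end) plus one
    junction record per intron. Junction placement maximizes local
    sequence agreement with the reference, preferring GT..AG boundaries;
    a junction with no GT/AG solution keeps the best-agreement boundary
    and is flagged defective. Segment pairs whose query and target gaps
    agree (an indel, not an intron) are merged.
    """
    chain = _chain_segments(ref, win, k)
    if not chain:
        return [], []
    # pass 1: merge indel-separated segments (near-identical diagonals)
    pass1 = [chain[0]]
    for seg in chain[1:]:
        p = pass1[-1]
        t_gap = seg[2] - p[3]
        q_gap = seg[0] - p[1]
        if t_gap < min_intron or abs(t_gap - q_gap) <= 5:
            p[1], p[3] = max(p[1], seg[1]), max(p[3], seg[3])
        else:
            pass1.append(seg)
    # pass 2: resolve candidate introns. A real intron leaves ~75%
    # mismatches when the reference is forced across the gap ungapped;
    # clearly sub-random density means the downstream segment was a
    # chance seed match, not a separate exon. Segments too short to
    # carry intron evidence on their own are dropped.
    merged = [pass1[0]]
    for seg in pass1[1:]:
        p = merged[-1]
        span = seg[1] - p[1]
        alt = win[p[3] : p[3] + span]
        refseg = ref[p[1] : seg[1]]
        if span > 0 and len(alt) == span:
            frac = sum(1 for x, y in zip(refseg, alt) if x != y) / span
            if frac < 0.35:
                p[1] = seg[1]
                p[3] = p[3] + span
                continue
        merged.append(seg)
    # extend outer ends to cover the full query, ungapped
    first, last = merged[0], merged[-1]
    ext = min(first[0], first[2])
    first[0] -= ext
    first[2] -= ext
    ext = min(len(ref) - last[1], len(win) - last[3])
    last[1] += ext
    last[3] += ext

    junctions: list[_Junction] = []
    exons: list[tuple[int, int, int, int]] = []
    m = 6
    for i, seg in enumerate(merged):
        if i == 0:
            exons.append(tuple(seg))
            continue
        pqs, pqe, pts, pte = exons[-1]
        qs, qe, ts, te = seg
        best = None
        lo = max(1, min(pqe, qs) - max_shift)
        hi = min(len(ref) - 1, max(pqe, qs) + max_shift)
        for q_star in range(lo, hi + 1):
            d = pte + (q_star - pqe)
            a = ts - (qs - q_star)
            if d < 0 or a - 2 < 0 or a > len(win) or d + 2 > len(win):
                continue
            if a - d < min_intron:
                continue
            donor_ok = win[d : d + 2] == "GT"
            acc_ok = win[a - 2 : a] == "AG"
            score = _hamming(ref[max(0, q_star - m) : q_star], win[max(0, d - m) : d])
            score += _hamming(ref[q_star : q_star + m], win[a : a + m])
            penalty = score + 2 * (not donor_ok) + 2 * (not acc_ok)
            hex_bonus = 0 if win[d : d + 6] == DONOR_CONSENSUS else 1
            key = (penalty, hex_bonus, abs(q_star - pqe), q_star)
            if best is None or key < best[0]:
                best = (key, q_star, d, a, donor_ok and acc_ok)
        if best is None:
            # no geometric solution; keep raw segment boundaries, flagged
            junctions.append(
                _Junction(pqe, pte, ts, win[pte : pte + 6], win[ts - 2 : ts], True, pqe % 3)
            )
            exons.append(tuple(seg))
            continue
        key, q_star, d, a, ok = best
        if key[0] > 4:
            # badly-fitting junction: if the reference also bridges the
            # gap ungapped at sub-random mismatch density, this is a
            # chance seed match, not an intron - collapse it
            span = qe - pqe
            alt = win[pte : pte + span]
            if span > 0 and len(alt) == span:
                frac = sum(1 for x, y in zip(ref[pqe:qe], alt) if x != y) / span
                if frac < 0.5:
                    exons[-1] = (pqs, qe, pts, pte + span)
                    continue
        exons[-1] = (pqs, q_star, pts, d)
        exons.append((q_star, qe, a, te))
        junctions.append(
            _Junction(q_star, d, a, win[d : d + 6], win[a - 2 : a], not ok, q_star % 3)
        )
    return exons, junctions


# ---------------------------------------------------------------------------
# coordinate helpers


def _win_to_fwd(contig: str, win_iv: Interval, a: int, b: int, strand: str) -> Interval:
    """Map window-frame [a, b) (gene orientation) to forward coordinates."""
    if strand == "+":
        return Interval(contig, win_iv.start + a, win_iv.start + b, "+")
    return Interval(contig, win_iv.end - b, win_iv.end - a, "-")


def _shift_rs(hit: RSHit, win_iv: Interval, strand: str, contig: str) -> RSHit:
    """Map an RSHit found in an oriented window back to forward coordinates."""

    def mapiv(iv: Interval) -> Interval:
        return _win_to_fwd(contig, win_iv, iv.start, iv.end, strand)

    return RSHit(
        heptamer=mapiv(hit.heptamer),
        nonamer=mapiv(hit.nonamer),
        spacer_length=hit.spacer_length,
        spacer_class=hit.spacer_class,
        orientation=hit.orientation,
        heptamer_mismatches=hit.heptamer_mismatches,
        nonamer_mismatches=hit.nonamer_mismatches,
        strand=strand,
    )


def _oriented_window(gseq: GenomicSequence, lo: int, hi: int, strand: str) -> tuple[str, Interval]:
    lo = max(0, lo)
    hi = min(len(gseq), hi)
    iv = Interval(gseq.id, lo, hi, strand)
    return extract(gseq, iv), iv


# ---------------------------------------------------------------------------
# candidate grouping


def _group_candidates(hits: list[SeedHit], gap: int = 300):
    """Group seed hits into per-gene candidates by contig/strand/proximity."""
    groups: list[list[SeedHit]] = []
    for key in sorted({(h.iv.contig, h.iv.strand) for h in hits}):
        sub = sorted(
            (h for h in hits if (h.iv.contig, h.iv.strand) == key),
            key=lambda h: h.iv.start,
        )
        cur: list[SeedHit] = []
        end = -1
        for h in sub:
            if cur and h.iv.start - end > gap:
                groups.append(cur)
                cur = []
                end = -1
            cur.append(h)
            end = max(end, h.iv.end)
        if cur:
            groups.append(cur)
    return groups


def _best_ref(group: list[SeedHit]) -> str:
    weight: dict[str, float] = defaultdict(float)
    for h in group:
        weight[h.query_id] += (h.q_end - h.q_start) * h.identity
    return max(sorted(weight), key=lambda q: weight[q])


# ---------------------------------------------------------------------------
# C genes


def call_c_genes(
    genome: dict[str, GenomicSequence],
    reflib: ReferenceLibrary,
    min_identity: float = 70.0,
    margin: int = 500,
) -> list[CGene]:
    """Call constant genes: 4 exons bounded by splice signals, frame 1,1,0.

    Exon boundaries are chosen to satisfy donor/acceptor motifs and
    maximize agreement with the reference CDS; the translated product is
    annotated with the conserved C-domain positions (23, 41, 89, 104).
    """
    if not reflib.c_refs:
        raise ValueError("empty reference set")
    hits = similarity_search(reflib.c_refs, genome, min_identity=min_identity, min_cov=8.0)
    genes: list[CGene] = []
    for group in _group_candidates(hits):
        contig = group[0].iv.contig
        strand = group[0].iv.strand
        gseq = genome[contig]
        ref_id = _best_ref(group)
        ref = reflib.c_refs[ref_id]
        lo = min(h.iv.start for h in group) - margin
        hi = max(h.iv.end for h in group) + margin
        win, win_iv = _oriented_window(gseq, lo, hi, strand)
        exon_segs, junctions = spliced_align(ref, win)
        if not exon_segs:
            continue
        exons = [
            _win_to_fwd(contig, win_iv, ts, te, strand) for _, _, ts, te in exon_segs
        ]
        if strand == "-":
            pass  # list order stays 5'->3' of gene; intervals already mapped
        coding = "".join(win[ts:te] for _, _, ts, te in exon_segs)
        flags = []
        frames = [j.frame for j in junctions]
        if len(exon_segs) != 4 or frames != [1, 1, 0]:
            flags.append("incomplete_exon_structure")
        splice_defects = [
            f"junction_{i+1}" for i, j in enumerate(junctions) if j.defective
        ]
        gene = CGene(
            contig=contig,
            strand=strand,
            exons=exons,
            coding=coding,
            splice_defects=splice_defects,
            ref_id=ref_id,
            flags=flags,
        )
        gene.regions = dict(reflib.c_regions)
        gene.conserved_positions = _transfer_c_anchors(gene.protein, ref, reflib.c_anchors)
        genes.append(gene)
    return _dedupe_overlapping(genes)


def _transfer_c_anchors(protein: str, ref_cds: str, anchor_map: dict[int, int]):
    ref_protein = translate(ref_cds).rstrip("*")
    if not protein:
        return {pos: None for pos in anchor_map}
    res = edlib.align(protein, ref_protein, task="path", mode="NW")
    qi = ri = 0
    ref_to_q: dict[int, int | None] = {}
    for n, op in _iter_cigar(res["cigar"]):
        for _ in range(n):
            if op in ("=", "X", "M"):
                ref_to_q[ri] = qi
                qi += 1
                ri += 1
            elif op == "I":  # insertion in query
                qi += 1
            else:  # deletion: ref position unmatched
                ref_to_q[ri] = None
                ri += 1
    out = {}
    for pos, ref_idx in anchor_map.items():
        q_idx = ref_to_q.get(ref_idx)
        out[pos] = protein[q_idx] if q_idx is not None and q_idx < len(protein) else None
    return out


def _iter_cigar(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


# ---------------------------------------------------------------------------
# J genes


def call_j_genes(
    genome: dict[str, GenomicSequence],
    region: Interval,
    strand: str,
    min_j: int = 21,
    max_j: int = 72,
) -> list[JGene]:
    """Call J genes inside ``region``: a 12-spacer RS followed by an open
    J-REGION ending at a donor splice (GTAAGT class).

    The J-REGION starts at the base after the RS heptamer; the donor is
    the best GTAAGT-scoring hexamer ``min_j``..``max_j`` bases downstream
    (ties: leftmost). A donor that is GT-led but not the full conserved
    hexamer is flagged defective. FGXG is located by scanning all frames.
    """
    gseq = genome[region.contig]
    win, win_iv = _oriented_window(gseq, region.start, region.end, strand)
    hits = [
        h
        for h in scan_rs(win, 12, **STRICT_RS)
        if h.orientation == "gene-5prime"
    ]
    genes: list[JGene] = []
    called_starts: set[int] = set()
    for h in sorted(hits, key=lambda h: (h.score, h.start)):
        start = h.heptamer.end
        if start in called_starts:
            continue  # duplicate hit from spacer slack
        best = None
        for p in range(start + min_j, min(start + max_j, len(win) - 1)):
            hexamer = win[p : p + 6]
            if not hexamer.startswith("G"):
                continue
            score = sum(1 for a, b in zip(hexamer, DONOR_CONSENSUS) if a == b)
            if best is None or score > best[0]:
                best = (score, p, hexamer)
        if best is None or best[0] < 4:
            continue
        score, p, hexamer = best
        called_starts.add(start)
        coding = win[start:p]
        fgxg_pos = fgxg_frame = None
        for frame in range(3):
            prot = translate(coding, frame)
            idx = _find_fgxg(prot)
            if idx is not None:
                fgxg_pos, fgxg_frame = idx, frame
                break
        donor_iv = _win_to_fwd(region.contig, win_iv, p, p + len(hexamer), strand)
        genes.append(
            JGene(
                contig=region.contig,
                strand=strand,
                j_rs=_shift_rs(h, win_iv, strand, region.contig),
                j_region=_win_to_fwd(region.contig, win_iv, start, p, strand),
                donor=SpliceSite("donor", donor_iv, hexamer, score=score),
                coding=coding,
                fgxg_position=fgxg_pos,
                fgxg_frame=fgxg_frame,
                donor_defective=hexamer != DONOR_CONSENSUS,
            )
        )
    genes.sort(key=lambda g: g.j_region.start if strand == "+" else -g.j_region.start)
    return genes


def _find_fgxg(protein: str) -> int | None:
    for i in range(len(protein) - 3):
        if (
            protein[i] == "F"
            and protein[i + 1] == "G"
            and protein[i + 3] == "G"
            and protein[i + 2] not in "*X"
        ):
            return i
    return None


# ---------------------------------------------------------------------------
# D genes


def call_d_genes(
    genome: dict[str, GenomicSequence],
    region: Interval,
    strand: str,
) -> list[DGene]:
    """Call D genes: one per valid 12/23-paired RS with D-REGION 8-25 bp."""
    gseq = genome[region.contig]
    win, win_iv = _oriented_window(gseq, region.start, region.end, strand)
    hits = scan_rs(win, 12, **STRICT_RS) + scan_rs(win, 23, **STRICT_RS)
    genes: list[DGene] = []
    seen_regions: set[tuple[int, int]] = set()
    for twelve, twenty3 in pair_rs_12_23(hits):
        five, three = (
            (twelve, twenty3)
            if twelve.orientation == "gene-5prime"
            else (twenty3, twelve)
        )
        d_lo, d_hi = five.heptamer.end, three.heptamer.start
        if (d_lo, d_hi) in seen_regions or any(
            a < d_hi and d_lo < b for a, b in seen_regions
        ):
            continue  # near-duplicate pair from spacer slack
        seen_regions.add((d_lo, d_hi))
        d_iv = _win_to_fwd(region.contig, win_iv, d_lo, d_hi, strand)
        gene = DGene(
            contig=region.contig,
            strand=strand,
            five_prime_rs=_shift_rs(five, win_iv, strand, region.contig),
            d_region=d_iv,
            three_prime_rs=_shift_rs(three, win_iv, strand, region.contig),
        )
        gene.coding = win[d_lo:d_hi]
        genes.append(gene)
    genes.sort(key=lambda g: g.d_region.start)
    return genes


# ---------------------------------------------------------------------------
# V genes


def call_v_genes(
    genome: dict[str, GenomicSequence],
    reflib: ReferenceLibrary,
    allow_spliced_vexon: bool = True,
    min_identity: float = 70.0,
    rs_slack: int = 3,
    rs_window: int = 40,
    margin: int = 600,
) -> list[VGene]:
    """Call V genes from similarity clusters plus RS and splice evidence.

    Per candidate: the leader (L-PART1) and V-EXON(s) are placed by
    spliced alignment to the best reference; the coding 3' end is fixed
    by a 23-spacer RS whose heptamer begins within ``rs_slack`` bases of
    the aligned end. When the strict-threshold RS is absent the window
    +/- ``rs_window`` is rescanned at relaxed thresholds; candidates with
    neither RS nor strong similarity are dropped.
    """
    if not reflib.v_refs:
        raise ValueError("empty reference set")
    hits = similarity_search(reflib.v_refs, genome, min_identity=min_identity, min_cov=8.0)
    genes: list[VGene] = []
    for group in _group_candidates(hits):
        contig = group[0].iv.contig
        strand = group[0].iv.strand
        gseq = genome[contig]
        ref_id = _best_ref(group)
        ref = reflib.v_refs[ref_id]
        leader_len = reflib.v_leader_len
        lo = min(h.iv.start for h in group) - margin
        hi = max(h.iv.end for h in group) + margin
        win, win_iv = _oriented_window(gseq, lo, hi, strand)
        exon_segs, junctions = spliced_align(ref, win)
        if not exon_segs:
            continue
        n_introns = len(exon_segs) - 1
        if n_introns > 1 and not allow_spliced_vexon:
            # collapse to the leader intron only; remaining structure flagged
            keep = exon_segs[:2]
            exon_segs, junctions = keep, junctions[:1]
        flags = []
        # leader boundary should coincide with the first junction
        if n_introns == 0:
            flags.append("no_leader_intron")
        elif abs(junctions[0].q_boundary - leader_len) > 6:
            flags.append("unexpected_leader_boundary")
        if n_introns > 1:
            flags.append("spliced_v_exon")

        v_end_win = exon_segs[-1][3]
        # RS at the coding 3' end
        rs_lo = max(0, v_end_win - rs_window)
        rs_hi = min(len(win), v_end_win + rs_window + 45)
        sub = win[rs_lo:rs_hi]
        strict = [
            h
            for h in scan_rs(sub, 23, **STRICT_RS)
            if h.orientation == "gene-3prime"
            and abs((rs_lo + h.heptamer.start) - v_end_win) <= rs_slack
        ]
        relaxed_hits = []
        if not strict:
            relaxed_hits = [
                h
                for h in scan_rs(sub, 23, **RELAXED_RS)
                if h.orientation == "gene-3prime"
                and abs((rs_lo + h.heptamer.start) - v_end_win) <= rs_window
            ]
        strict_hit = relaxed_hit = None
        if strict:
            strict.sort(key=lambda h: (h.score, abs((rs_lo + h.heptamer.start) - v_end_win)))
            h = strict[0]
            v_end_win = rs_lo + h.heptamer.start
            strict_hit = _shift_rs(
                _offset_rs(h, rs_lo), win_iv, strand, contig
            )
        elif relaxed_hits:
            relaxed_hits.sort(key=lambda h: (h.score, abs((rs_lo + h.heptamer.start) - v_end_win)))
            relaxed_hit = _shift_rs(_offset_rs(relaxed_hits[0], rs_lo), win_iv, strand, contig)

        # rebuild final exon with the RS-fixed end
        exon_segs = list(exon_segs)
        q0, q1, t0, t1 = exon_segs[-1]
        exon_segs[-1] = (q0, q1 + (v_end_win - t1), t0, v_end_win)

        coding = "".join(win[ts:te] for _, _, ts, te in exon_segs)
        ivs = [_win_to_fwd(contig, win_iv, ts, te, strand) for _, _, ts, te in exon_segs]
        l_part1 = ivs[0] if len(ivs) > 1 else None
        v_exons = ivs[1:] if len(ivs) > 1 else ivs
        splice_defects = [f"junction_{i+1}" for i, j in enumerate(junctions) if j.defective]
        if strict_hit is None and relaxed_hit is None:
            # RS absent: require solid similarity to keep the candidate
            best_id = max(h.identity for h in group)
            if best_id < min_identity:
                continue
        genes.append(
            VGene(
                contig=contig,
                strand=strand,
                l_part1=l_part1,
                v_exons=v_exons,
                v_rs=strict_hit,
                rs_evidence=RSEvidence(strict=strict_hit, relaxed=relaxed_hit),
                coding=coding,
                splice_defects=splice_defects,
                ref_id=ref_id,
                flags=flags,
            )
        )
    return _dedupe_overlapping(genes)


def _dedupe_overlapping(genes: list) -> list:
    """Drop calls whose span overlaps an already-kept same-strand call.

    Neighbouring seed groups can converge onto the same gene when a
    divergent exon chunk carries no exact seed; calls are ranked best
    first (RS evidence, then coding length) before filtering.
    """
    ranked = sorted(
        genes,
        key=lambda g: (
            getattr(g, "v_rs", None) is None,
            -len(getattr(g, "coding", "")),
            g.span.start,
        ),
    )
    kept: list = []
    for g in ranked:
        if any(
            k.contig == g.contig and k.strand == g.strand and k.span.overlaps(g.span)
            for k in kept
        ):
            continue
        kept.append(g)
    kept.sort(key=lambda g: (g.contig, g.span.start))
    return kept


def _offset_rs(hit: RSHit, offset: int) -> RSHit:
    return RSHit(
        heptamer=hit.heptamer.shift(offset),
        nonamer=hit.nonamer.shift(offset),
        spacer_length=hit.spacer_length,
        spacer_class=hit.spacer_class,
        orientation=hit.orientation,
        heptamer_mismatches=hit.heptamer_mismatches,
        nonamer_mismatches=hit.nonamer_mismatches,
        strand=hit.strand,
    )


# ---------------------------------------------------------------------------
# locus assembly


def assemble_loci(
    v_genes: list[VGene],
    d_genes: list[DGene],
    j_genes: list[JGene],
    c_genes: list[CGene],
) -> tuple[list[Locus], list[VGene]]:
    """Assemble called genes into loci; returns (loci, orphan V genes).

    Each C gene seeds a locus. The nearest upstream (gene-frame) D on the
    same strand joins it, J genes between D and C join it, and V genes on
    the same strand upstream of the D join the locus whose D is nearest,
    provided no C gene intervenes.
    """
    loci: list[Locus] = []
    used_d: set[int] = set()
    for c in sorted(c_genes, key=lambda g: (g.contig, g.span.start)):
        sign = 1 if c.strand == "+" else -1
        cand_d = [
            d
            for d in d_genes
            if d.contig == c.contig
            and d.strand == c.strand
            and id(d) not in used_d
            and sign * (c.span.start - d.span.start) > 0
        ]
        cand_d.sort(key=lambda d: abs(d.span.start - c.span.start))
        d = cand_d[0] if cand_d else None
        if d is not None:
            used_d.add(id(d))
            lo = min(d.span.end, c.span.start) if c.strand == "+" else min(c.span.end, d.span.start)
            hi = max(d.span.end, c.span.start) if c.strand == "+" else max(c.span.end, d.span.start)
            js = [
                j
                for j in j_genes
                if j.contig == c.contig
                and j.strand == c.strand
                and lo <= j.span.start
                and j.span.end <= hi
            ]
        else:
            js = []
        js.sort(key=lambda j: sign * j.span.start)
        loci.append(Locus(None, c.contig, c.strand, [], d, js, c))

    orphans: list[VGene] = []
    c_positions = [(c.contig, c.span.start) for c in c_genes]
    for v in v_genes:
        sign = 1 if v.strand == "+" else -1
        best = None
        for locus in loci:
            if locus.contig != v.contig or locus.orientation != v.strand or locus.d_gene is None:
                continue
            dist = sign * (locus.d_gene.span.start - v.span.start)
            if dist <= 0:
                continue
            lo, hi = sorted((v.span.start, locus.d_gene.span.start))
            if any(
                ctg == v.contig and lo < pos < hi for ctg, pos in c_positions
            ):
                continue
            if best is None or dist < best[0]:
                best = (dist, locus)
        if best is None:
            orphans.append(v)
        else:
            best[1].v_genes.append(v)
    for locus in loci:
        sign = 1 if locus.orientation == "+" else -1
        locus.v_genes.sort(key=lambda v: sign * v.span.start)
    return loci, orphans


def detect_duplication_pattern(loci: list[Locus], orphans: list[VGene]) -> LocusStructure:
    """Classify the locus-level duplication pattern on one contig."""
    if not loci and not orphans:
        raise ValueError("no loci or orphans to classify")
    contig = (loci[0].contig if loci else orphans[0].contig)
    complete = [l for l in loci if l.complete]
    v_less = [l for l in loci if not l.v_genes]
    notes = []
    if v_less and complete:
        pattern = "tandem_DJC_duplication"
        notes.append(f"{len(v_less)} D-J-C cluster(s) without upstream V genes")
    elif (
        len(complete) == 2
        and complete[0].orientation != complete[1].orientation
        and _v_between(complete)
    ):
        pattern = "head_to_head_pair"
        notes.append("two opposite-orientation loci with V genes between the C genes")
    elif orphans and len(complete) >= 1 and any(
        o.strand != complete[0].orientation for o in orphans
    ):
        pattern = "remnant"
        notes.append(f"{len(orphans)} inverted orphan V gene(s) near a single locus")
    elif len(loci) == 1:
        pattern = "single"
    else:
        pattern = "single"
        notes.append(f"{len(loci)} loci with no recognized duplication pattern")
    return LocusStructure(contig, loci, orphans, pattern, "; ".join(notes))


def _v_between(pair: list[Locus]) -> bool:
    c_pos = sorted(l.c_gene.span.start for l in pair)
    vs = [v.span.start for l in pair for v in l.v_genes]
    return bool(vs) and all(c_pos[0] <= p <= c_pos[1] for p in vs)
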