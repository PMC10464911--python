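"""Ground-truthed synthetic TRB locus generator.

Builds chromosome-scale sequences containing V-D-J-C loci with planted
recombination signals, splice signals, subgroup structure and labeled
functional / ORF / pseudogene variants, plus simulated RNA-seq reads from
the two C-gene transcripts at a known mixing ratio. Every planted feature
is recorded with exact coordinates so annotation output can be scored
against truth.

Gene architecture (gene-strand frame):

* V: L-PART1 (49 bp, ends in splicing frame 1) - intron - V-EXON (323 bp
  = split codon + L-PART2 + 104-codon V-REGION ending at 2nd-CYS) -
  23-spacer RS. A TRBV6-style variant splits the V-EXON with two
  further frame-0 introns (4 exons in total).
* J: 12-spacer RS (reverse layout) - 48 bp J-REGION carrying FGXG -
  GTAAGT donor.
* D: 12-spacer RS (reverse layout) - 12 bp G-rich D-REGION - 23-spacer RS.
* C: four exons (286, 108, 71, 45 bp; splicing frames 1, 1, 0) encoding
  169 residues + stop, with CYS-23, TRP-41, hydrophobic-89 and CYS-104.

Divergence is modeled as i.i.d. substitutions; coding indels occur only
through the explicit frameshift operation, so truth coordinates stay
exact. Intergenic sequence is uniform random, rejection-sampled so that
it contains no chance RS motif at calling thresholds and no GTAAGT
hexamer (synthetic intergenic DNA carries no cryptic signals; real
genomes do, which is a stated limitation, not an accident).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .functionality import NumberingProfile
from .gene_callers import RELAXED_RS, STRICT_RS, ReferenceLibrary
from .motif_scan import DONOR_CONSENSUS, RS_HEPTAMER, RS_NONAMER, scan_rs
from .seq_io import GenomicSequence, GffFeature, Interval, revcomp, translate

__all__ = [
    "LocusSpec",
    "ReadSimConfig",
    "SynthConfig",
    "TruthFeature",
    "TruthSet",
    "VRecord",
    "MUTATION_OPS",
    "default_config",
    "generate_locus_genome",
    "apply_mutation",
    "simulate_reads",
    "generate_subgroup_members",
    "evaluate_against_truth",
]

# --- gene geometry constants -------------------------------------------------

V_LEADER_LEN = 49          # L-PART1, splicing frame 1
V_EXON_LEN = 323
V_CODING_LEN = V_LEADER_LEN + V_EXON_LEN  # 372 = 124 codons
V_REGION_START = 60        # leader (L-PART1 + split codon + L-PART2) = 20 codons
V_ANCHOR_CODONS = {23: 42, 41: 60, 104: 123}   # numbering pos -> codon index
TRBV6_EXTRA_SPLITS = (159, 279)                # frame-0 splits of the V-EXON

J_REGION_LEN = 48
J_FGXG_CODON = 9           # F at codon 9 (0-based) of the frame-0 translation

D_REGION_SEQ = "GGGACAGGGGGC"  # G-rich, open in all three frames

C_EXON_LENS = (286, 108, 71, 45)   # splicing frames 1, 1, 0
C_CODING_LEN = sum(C_EXON_LENS)    # 510 = 169 codons + stop
C_ANCHOR_CODONS = {23: 22, 41: 40, 89: 88, 104: 103}

RS_23 = 23
RS_12 = 12

MUTATION_OPS = (
    "none",
    "stop",
    "frameshift",
    "ablate_rs",
    "degrade_rs",
    "break_donor",
    "break_acceptor",
    "anchor_change",
)

_OP_LABEL = {
    "none": "F",
    "stop": "P",
    "frameshift": "P",
    "ablate_rs": "P",
    "degrade_rs": "ORF",
    "break_donor": "ORF",
    "break_acceptor": "ORF",
    "anchor_change": "ORF",
}

_ABLATED_HEPTAMER = "GGTCTAG"    # >=6 mismatches from the consensus, no CAC
_ABLATED_NONAMER = "TGCGTTGGA"
_DEGRADED_HEPTAMER = "CACCAGG"   # CAC intact, 3 mismatches: strict fails, relaxed finds

_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if translate(a + b + c) != "*"
)
_CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _c in _SENSE_CODONS:
    _CODONS_BY_AA.setdefault(translate(_c), tuple())
for _c in _SENSE_CODONS:
    _CODONS_BY_AA[translate(_c)] = _CODONS_BY_AA[translate(_c)] + (_c,)


# --- configuration -----------------------------------------------------------


@dataclass
class LocusSpec:
    """One V-D-J-C locus: V composition, J count, orientation, spacing."""

    n_v_per_subgroup: dict[str, int]
    n_j: int = 10
    orientation: str = "+"
    intergenic_mean: int = 800
    include_trbv6: bool = False
    c_subgroup: str = "C1"
    v_mutations: dict[int, str] = field(default_factory=dict)

    @property
    def n_v(self) -> int:
        return sum(self.n_v_per_subgroup.values()) + (1 if self.include_trbv6 else 0)


@dataclass
class ReadSimConfig:
    read_length: int = 75
    n_reads: int = 20000
    error_rate: float = 0.0
    c1_c2_ratio: float = 3.0


@dataclass
class SynthConfig:
    seed: int = 0
    loci: list[LocusSpec] = field(default_factory=list)
    head_to_head: bool = True
    tandem_djc: bool = False
    remnant_v: int = 0
    within_divergence: float = 0.10
    between_divergence: float = 0.35
    c_within_divergence: float = 0.01
    c_between_divergence: float = 0.13
    read_sim: ReadSimConfig = field(default_factory=ReadSimConfig)

    def __post_init__(self) -> None:
        if self.within_divergence >= self.between_divergence:
            raise ValueError("within-subgroup divergence must be < between-subgroup divergence")
        if self.c_within_divergence >= self.c_between_divergence:
            raise ValueError("c_within_divergence must be < c_between_divergence")
        for spec in self.loci:
            if spec.orientation not in "+-":
                raise ValueError(f"bad locus orientation {spec.orientation!r}")


def default_config(seed: int = 0) -> SynthConfig:
    """Trout-like two-contig default: a head-to-head pair plus a single
    locus with a two-gene inverted remnant, ~200 kb in total."""
    return SynthConfig(
        seed=seed,
        loci=[
            LocusSpec(
                {"1": 4, "2": 7, "3": 6, "4": 5, "5": 7, "8": 1, "12": 1, "13": 3},
                n_j=10,
                orientation="-",
                intergenic_mean=1100,
                include_trbv6=True,
            ),
            LocusSpec(
                {"1": 14, "2": 16, "3": 16, "5": 2, "9": 1, "10": 2, "13": 14},
                n_j=10,
                orientation="+",
                intergenic_mean=1100,
            ),
            LocusSpec(
                {"3": 5, "4": 2, "5": 2, "7": 1, "10": 5, "11": 4},
                n_j=4,
                orientation="+",
                c_subgroup="C2",
            ),
        ],
        head_to_head=True,
        remnant_v=2,
    )


# --- truth containers --------------------------------------------------------


@dataclass
class TruthFeature:
    gene_type: str
    gene_id: str
    contig: str
    strand: str
    locus: str
    subgroup: str | None
    functionality: str
    mutation: str
    exons: list[tuple[int, int]]
    rs: list[tuple[int, int]]
    span: tuple[int, int]
    coding: str


@dataclass
class TruthSet:
    genome: dict[str, GenomicSequence]
    features: list[TruthFeature]
    transcripts: dict[str, str]
    config: SynthConfig
    _templates: "_Templates" = None

    def reference_library(self) -> ReferenceLibrary:
        t = self._templates
        return ReferenceLibrary(
            v_refs=dict(t.v_ancestors),
            c_refs={"C1": t.c_templates["C1"], "C2": t.c_templates["C2"]},
            v_leader_len=V_LEADER_LEN,
            numbering_profile=NumberingProfile.sequential(
                translate(t.v_root[V_REGION_START:])
            ),
        )

    def features_of(self, gene_type: str) -> list[TruthFeature]:
        return [f for f in self.features if f.gene_type == gene_type]

    def truth_gff(self) -> list[GffFeature]:
        feats = []
        for f in self.features:
            attrs = {
                "ID": f.gene_id,
                "locus": f.locus,
                "functionality": f.functionality,
                "mutation": f.mutation,
            }
            if f.subgroup:
                attrs["subgroup"] = f.subgroup
            feats.append(
                GffFeature(
                    Interval(f.contig, f.span[0], f.span[1], f.strand),
                    f"{f.gene_type}_gene_segment",
                    attributes=attrs,
                )
            )
            for i, (a, b) in enumerate(f.exons):
                feats.append(
                    GffFeature(
                        Interval(f.contig, a, b, f.strand),
                        "exon",
                        attributes={"Parent": f.gene_id, "rank": str(i + 1)},
                    )
                )
        return feats


# --- random-sequence helpers -------------------------------------------------

_BASES = np.array(list("ACGT"))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n)) if n > 0 else ""


def _has_rs(s: str, **thresholds) -> bool:
    return bool(len(s) >= 27 and (scan_rs(s, 12, **thresholds) or scan_rs(s, 23, **thresholds)))


def _clean_random(rng: np.random.Generator, n: int, forbid_donor: bool = True) -> str:
    """Uniform random DNA free of chance RS motifs (and GTAAGT)."""
    for _ in range(200):
        s = _rand_dna(rng, n)
        if forbid_donor and DONOR_CONSENSUS in s:
            continue
        if _has_rs(s, **STRICT_RS):
            continue
        return s
    raise RuntimeError("could not draw a clean random segment")


def _random_coding(rng: np.random.Generator, n_codons: int) -> str:
    idx = rng.integers(0, len(_SENSE_CODONS), size=n_codons)
    return "".join(_SENSE_CODONS[i] for i in idx)


def _substitute(chars: list[str], p: int, rng: np.random.Generator, frame_offset: int = 0) -> None:
    """Substitute position ``p`` without creating an in-frame stop codon."""
    old = chars[p]
    options = [b for b in "ACGT" if b != old]
    for b in rng.permutation(options):
        chars[p] = b
        c0 = p - (p - frame_offset) % 3
        codon = "".join(chars[c0 : c0 + 3])
        if len(codon) < 3 or translate(codon) != "*":
            return
    chars[p] = old


def _mutate_coding(
    coding: str,
    rate: float,
    rng: np.random.Generator,
    protected: frozenset[int],
) -> str:
    chars = list(coding)
    hits = np.nonzero(rng.random(len(chars)) < rate)[0]
    for p in hits:
        p = int(p)
        if p in protected:
            continue
        _substitute(chars, p, rng)
    out = "".join(chars)
    # substitutions must not spawn chance RS motifs inside coding
    for _ in range(30):
        found = scan_rs(out, 12, **STRICT_RS) + scan_rs(out, 23, **STRICT_RS)
        if not found:
            break
        h = found[0]
        cand = [
            p
            for p in list(range(h.heptamer.start, h.heptamer.end))
            + list(range(h.nonamer.start, h.nonamer.end))
            if p not in protected
        ]
        if not cand:
            break
        chars = list(out)
        _substitute(chars, cand[int(rng.integers(len(cand)))], rng)
        out = "".join(chars)
    return out


def _sanitize_coding_template(coding: str, rng: np.random.Generator, protected: frozenset[int]) -> str:
    return _mutate_coding(coding, 0.0, rng, protected)


# --- templates ---------------------------------------------------------------


def _v_protected(boundaries: tuple[int, ...]) -> frozenset[int]:
    prot: set[int] = set(range(0, 6)) | set(range(V_CODING_LEN - 6, V_CODING_LEN))
    for b in boundaries:
        prot |= set(range(b - 6, b + 8))
    for codon in V_ANCHOR_CODONS.values():
        prot |= {codon * 3, codon * 3 + 1, codon * 3 + 2}
    return frozenset(p for p in prot if 0 <= p < V_CODING_LEN)


def _c_protected() -> frozenset[int]:
    prot: set[int] = set(range(0, 6)) | set(range(C_CODING_LEN - 6, C_CODING_LEN))
    b = 0
    for ln in C_EXON_LENS[:-1]:
        b += ln
        prot |= set(range(b - 6, b + 8))
    for codon in C_ANCHOR_CODONS.values():
        prot |= {codon * 3, codon * 3 + 1, codon * 3 + 2}
    return frozenset(p for p in prot if 0 <= p < C_CODING_LEN)


class _Templates:
    """Root/ancestor sequences shared by every genome from one config."""

    def __init__(self, config: SynthConfig, rng: np.random.Generator):
        subgroups = sorted(
            {sg for spec in config.loci for sg in spec.n_v_per_subgroup},
            key=lambda x: (len(x), x),
        )
        if any(spec.include_trbv6 for spec in config.loci):
            subgroups = [s for s in subgroups if s != "6"] + ["6"]
        self.v_protected = _v_protected((V_LEADER_LEN,))
        self.v6_protected = _v_protected((V_LEADER_LEN,) + TRBV6_EXTRA_SPLITS)

        self.v_root = self._make_v_root(rng)
        self.v_ancestors: dict[str, str] = {}
        for sg in subgroups:
            prot = self.v6_protected if sg == "6" else self.v_protected
            self.v_ancestors[sg] = _mutate_coding(
                self.v_root, config.between_divergence, rng, prot
            )
        self.j_templates = [self._make_j(rng) for _ in range(12)]
        self.c_protected = _c_protected()
        c1 = self._make_c(rng)
        c2 = _mutate_coding(c1, config.c_between_divergence, rng, self.c_protected)
        self.c_templates = {"C1": c1, "C2": c2}
        self.config = config

    def _make_v_root(self, rng) -> str:
        for _ in range(50):
            coding = list(_random_coding(rng, V_CODING_LEN // 3))
            s = "".join(coding)
            s = "ATG" + s[3:]
            chars = list(s)
            for pos, codon_idx in V_ANCHOR_CODONS.items():
                aa = "W" if pos == 41 else "C"
                codon = "TGG" if aa == "W" else "TGC"
                chars[codon_idx * 3 : codon_idx * 3 + 3] = codon
            s = "".join(chars)
            if not _has_rs(s, **STRICT_RS) and DONOR_CONSENSUS not in s:
                return s
        raise RuntimeError("failed to build V root template")

    def _make_j(self, rng) -> str:
        for _ in range(50):
            s = _random_coding(rng, J_REGION_LEN // 3)
            codons = [s[i : i + 3] for i in range(0, len(s), 3)]
            codons[J_FGXG_CODON] = "TTC"       # F
            codons[J_FGXG_CODON + 1] = "GGA"   # G
            codons[J_FGXG_CODON + 3] = "GGT"   # G
            out = "".join(codons)
            if _has_rs(out, **STRICT_RS):
                continue
            if DONOR_CONSENSUS in (out + DONOR_CONSENSUS)[:-6]:
                continue
            return out
        raise RuntimeError("failed to build J template")

    def _make_c(self, rng) -> str:
        hydro = "GTG"  # Val at position 89
        for _ in range(50):
            s = list(_random_coding(rng, C_CODING_LEN // 3 - 1))
            chars = list("".join(s) + "TAA")
            for pos, codon_idx in C_ANCHOR_CODONS.items():
                codon = {23: "TGC", 41: "TGG", 89: hydro, 104: "TGC"}[pos]
                chars[codon_idx * 3 : codon_idx * 3 + 3] = codon
            out = "".join(chars)
            if not _has_rs(out, **STRICT_RS) and DONOR_CONSENSUS not in out:
                return out
        raise RuntimeError("failed to build C template")

    def v_member(self, sg: str, rng) -> "VRecord":
        boundaries = (V_LEADER_LEN,) + (TRBV6_EXTRA_SPLITS if sg == "6" else ())
        prot = self.v6_protected if sg == "6" else self.v_protected
        # leaders are conserved within a subgroup; only the V-EXON diverges
        prot = frozenset(prot | set(range(0, V_LEADER_LEN + 8)))
        coding = _mutate_coding(
            self.v_ancestors[sg], self.config.within_divergence, rng, prot
        )
        return VRecord(coding=coding, boundaries=boundaries, subgroup=sg)

    def j_member(self, idx: int, rng) -> str:
        s = list(self.j_templates[idx % len(self.j_templates)])
        n_sub = int(rng.integers(0, 3))
        fgxg = set()
        for c in (J_FGXG_CODON, J_FGXG_CODON + 1, J_FGXG_CODON + 3):
            fgxg |= {c * 3, c * 3 + 1, c * 3 + 2}
        for _ in range(n_sub):
            p = int(rng.integers(0, len(s)))
            if p in fgxg:
                continue
            _substitute(s, p, rng)
        return "".join(s)

    def c_member(self, subgroup: str, rng) -> str:
        return _mutate_coding(
            self.c_templates[subgroup], self.config.c_within_divergence, rng, self.c_protected
        )


# --- gene records and mutation ops ------------------------------------------


@dataclass
class VRecord:
    """A V gene before genome layout; coordinates are coding-local."""

    coding: str
    boundaries: tuple[int, ...]
    subgroup: str
    heptamer: str = RS_HEPTAMER
    nonamer: str = RS_NONAMER
    donor_broken: bool = False
    acceptor_broken: bool = False
    label: str = "F"
    op: str = "none"


def apply_mutation(gene_record, op: str, seed) -> tuple[object, str]:
    """Apply one labeled mutation operation; returns (record, expected label).

    Supported on V records: none, stop (earliest V-REGION codon -> TAA),
    frameshift (1-base deletion mid V-REGION), ablate_rs (heptamer and
    nonamer randomized beyond recognition), degrade_rs (3 heptamer
    mismatches), break_donor (GT -> AT), break_acceptor (AG -> AC),
    anchor_change (2nd-CYS -> GLY).
    """
    if op not in MUTATION_OPS:
        raise ValueError(f"unknown mutation op {op!r}")
    if not isinstance(gene_record, VRecord):
        raise ValueError(f"op {op!r} not applicable to {type(gene_record).__name__}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rec = copy.deepcopy(gene_record)
    rec.op = op
    rec.label = _OP_LABEL[op]
    prot = _v_protected(rec.boundaries)
    if op == "stop":
        anchor_codons = set(V_ANCHOR_CODONS.values())
        for codon_idx in range(V_REGION_START // 3, len(rec.coding) // 3):
            p = codon_idx * 3
            if codon_idx in anchor_codons or any(q in prot for q in (p, p + 1, p + 2)):
                continue
            rec.coding = rec.coding[:p] + "TAA" + rec.coding[p + 3 :]
            break
    elif op == "frameshift":
        p = len(rec.coding) // 2
        while p in prot:
            p += 1
        rec.coding = rec.coding[:p] + rec.coding[p + 1 :]
    elif op == "ablate_rs":
        rec.heptamer = _ABLATED_HEPTAMER
        rec.nonamer = _ABLATED_NONAMER
    elif op == "degrade_rs":
        rec.heptamer = _DEGRADED_HEPTAMER
    elif op == "break_donor":
        rec.donor_broken = True
    elif op == "break_acceptor":
        rec.acceptor_broken = True
    elif op == "anchor_change":
        idx = V_ANCHOR_CODONS[104] * 3
        rec.coding = rec.coding[:idx] + "GGA" + rec.coding[idx + 3 :]
    return rec, rec.label


# --- block assembly ----------------------------------------------------------


@dataclass
class _Block:
    """A sequence fragment with truth annotations in local coordinates."""

    seq: str = ""
    features: list[TruthFeature] = field(default_factory=list)
    mutable: list[tuple[int, int]] = field(default_factory=list)
    planted_rs: list[tuple[int, int]] = field(default_factory=list)
    relaxed_clean: list[tuple[int, int]] = field(default_factory=list)

    def append(self, other: "_Block") -> None:
        off = len(self.seq)
        self.seq += other.seq
        for f in other.features:
            self.features.append(_shift_feature(f, off))
        self.mutable += [(a + off, b + off) for a, b in other.mutable]
        self.planted_rs += [(a + off, b + off) for a, b in other.planted_rs]
        self.relaxed_clean += [(a + off, b + off) for a, b in other.relaxed_clean]

    def add_seq(self, seq: str, mutable: bool = False) -> tuple[int, int]:
        a = len(self.seq)
        self.seq += seq
        if mutable and seq:
            self.mutable.append((a, a + len(seq)))
        return a, a + len(seq)

    def flip(self) -> "_Block":
        L = len(self.seq)
        out = _Block(seq=revcomp(self.seq))
        for f in self.features:
            out.features.append(_flip_feature(f, L))
        out.mutable = [(L - b, L - a) for a, b in self.mutable]
        out.planted_rs = [(L - b, L - a) for a, b in self.planted_rs]
        out.relaxed_clean = [(L - b, L - a) for a, b in self.relaxed_clean]
        return out


def _shift_feature(f: TruthFeature, off: int) -> TruthFeature:
    return replace(
        f,
        exons=[(a + off, b + off) for a, b in f.exons],
        rs=[(a + off, b + off) for a, b in f.rs],
        span=(f.span[0] + off, f.span[1] + off),
    )


def _flip_feature(f: TruthFeature, L: int) -> TruthFeature:
    return replace(
        f,
        strand="-" if f.strand == "+" else "+",
        exons=[(L - b, L - a) for a, b in f.exons],
        rs=[(L - b, L - a) for a, b in f.rs],
        span=(L - f.span[1], L - f.span[0]),
    )


def _intron_block(block: _Block, rng, length: int, donor_broken=False, acceptor_broken=False):
    donor = "AT" + DONOR_CONSENSUS[2:] if donor_broken else DONOR_CONSENSUS
    acceptor = "TCTTTCCT" + ("AC" if acceptor_broken else "AG")
    filler = _clean_random(rng, max(0, length - len(donor) - len(acceptor)))
    block.add_seq(donor)
    block.add_seq(filler, mutable=True)
    block.add_seq(acceptor)


def _rs_block(block: _Block, rng, spacer_class: int, orientation: str, heptamer: str, nonamer: str):
    """Plant an RS; returns the (start, end) span of the whole element."""
    spacer = _clean_random(rng, spacer_class, forbid_donor=False)
    if orientation == "gene-3prime":
        a, _ = block.add_seq(heptamer)
        block.add_seq(spacer, mutable=True)
        _, b = block.add_seq(nonamer)
    else:
        a, _ = block.add_seq(revcomp(nonamer))
        block.add_seq(spacer, mutable=True)
        _, b = block.add_seq(revcomp(heptamer))
    block.planted_rs.append((a, b))
    return a, b


def _v_block(rec: VRecord, rng, gene_id: str, locus: str) -> _Block:
    block = _Block()
    bounds = [0] + sorted(rec.boundaries) + [len(rec.coding)]
    bounds = sorted(set(min(b, len(rec.coding)) for b in bounds))
    exons = []
    for i in range(len(bounds) - 1):
        a, b = block.add_seq(rec.coding[bounds[i] : bounds[i + 1]])
        exons.append((a, b))
        if i < len(bounds) - 2:
            _intron_block(
                block,
                rng,
                int(rng.integers(90, 220)),
                donor_broken=rec.donor_broken and i == 0,
                acceptor_broken=rec.acceptor_broken and i == 0,
            )
    rs_a, rs_b = _rs_block(block, rng, RS_23, "gene-3prime", rec.heptamer, rec.nonamer)
    if rec.op == "ablate_rs":
        # an ablated RS is not an RS: without this the sanitizer would
        # skip chance relaxed-threshold motifs inside its footprint
        block.planted_rs.pop()
        block.mutable.append((rs_a, rs_b))
        # the entire RS neighbourhood must stay clean even at relaxed
        # thresholds, else "missing RS" cannot be certified
        a = max(0, exons[-1][1] - 45)
        block.relaxed_clean.append((a, len(block.seq)))
    feat = TruthFeature(
        gene_type="V",
        gene_id=gene_id,
        contig="",
        strand="+",
        locus=locus,
        subgroup=rec.subgroup,
        functionality=rec.label,
        mutation=rec.op,
        exons=exons,
        rs=[(rs_a, rs_b)],
        span=(0, len(block.seq)),
        coding=rec.coding,
    )
    block.features.append(feat)
    return block


def _sanitize_j_block(block: _Block, rng, rs_a: int, rs_b: int, a: int, b: int) -> None:
    """Remove stray donors and chance RS motifs from one J block.

    The planted 12-RS heptamer ends at the coding start; any other motif
    (either class) inside the block is a calling hazard: a stray GTAAGT
    truncates the J-REGION, a chance RS can seed a spurious D pairing.
    Coding positions are substituted frame-aware, sparing the FGXG codons.
    """
    hep_lo = rs_b - 7
    fgxg_codons = {J_FGXG_CODON, J_FGXG_CODON + 1, J_FGXG_CODON + 3}
    protected = set(range(hep_lo, rs_b)) | set(range(rs_a, rs_a + 9))
    protected |= set(range(b, b + 6))  # the real donor
    for c in fgxg_codons:
        protected |= {a + c * 3, a + c * 3 + 1, a + c * 3 + 2}
    for _ in range(40):
        seq = block.seq
        targets: set[int] = set()
        idx = seq.find(DONOR_CONSENSUS)
        if 0 <= idx < b:
            targets.add(idx + 2)
        for cls in (12, 23):
            for h in scan_rs(seq, cls, **STRICT_RS):
                if (
                    cls == 12
                    and h.orientation == "gene-5prime"
                    and h.heptamer.start == hep_lo
                ):
                    continue
                span = list(range(h.heptamer.start, h.heptamer.end)) + list(
                    range(h.nonamer.start, h.nonamer.end)
                )
                targets.update(p for p in span if p not in protected)
        targets = {p for p in targets if p < len(seq)}
        if not targets:
            break
        chars = list(seq)
        for p in sorted(targets):
            if a <= p < b:
                _substitute(chars, p, rng, frame_offset=a)
            else:
                old = chars[p]
                chars[p] = str(rng.choice([x for x in "ACGT" if x != old]))
        block.seq = "".join(chars)


def _j_block(region: str, rng, gene_id: str, locus: str) -> _Block:
    block = _Block()
    rs_a, rs_b = _rs_block(block, rng, RS_12, "gene-5prime", RS_HEPTAMER, RS_NONAMER)
    a, b = block.add_seq(region)
    block.add_seq(DONOR_CONSENSUS)
    _sanitize_j_block(block, rng, rs_a, rs_b, a, b)
    region = block.seq[a:b]
    feat = TruthFeature(
        gene_type="J",
        gene_id=gene_id,
        contig="",
        strand="+",
        locus=locus,
        subgroup=None,
        functionality="F",
        mutation="none",
        exons=[(a, b)],
        rs=[(rs_a, rs_b)],
        span=(rs_a, len(block.seq)),
        coding=region,
    )
    block.features.append(feat)
    return block


def _d_block(rng, gene_id: str, locus: str) -> _Block:
    block = _Block()
    rs1 = _rs_block(block, rng, RS_12, "gene-5prime", RS_HEPTAMER, RS_NONAMER)
    a, b = block.add_seq(D_REGION_SEQ)
    rs2 = _rs_block(block, rng, RS_23, "gene-3prime", RS_HEPTAMER, RS_NONAMER)
    feat = TruthFeature(
        gene_type="D",
        gene_id=gene_id,
        contig="",
        strand="+",
        locus=locus,
        subgroup=None,
        functionality="F",
        mutation="none",
        exons=[(a, b)],
        rs=[rs1, rs2],
        span=(0, len(block.seq)),
        coding=D_REGION_SEQ,
    )
    block.features.append(feat)
    return block


def _c_block(cds: str, subgroup: str, rng, gene_id: str, locus: str) -> _Block:
    block = _Block()
    exons = []
    pos = 0
    for i, ln in enumerate(C_EXON_LENS):
        a, b = block.add_seq(cds[pos : pos + ln])
        exons.append((a, b))
        pos += ln
        if i < len(C_EXON_LENS) - 1:
            _intron_block(block, rng, int(rng.integers(90, 220)))
    feat = TruthFeature(
        gene_type="C",
        gene_id=gene_id,
        contig="",
        strand="+",
        locus=locus,
        subgroup=subgroup,
        functionality="F",
        mutation="none",
        exons=exons,
        rs=[],
        span=(0, len(block.seq)),
        coding=cds,
    )
    block.features.append(feat)
    return block


def _intergenic(rng, mean: int) -> str:
    lo = max(450, mean - mean // 3)
    hi = mean + mean // 3
    return _clean_random(rng, int(rng.integers(lo, max(hi, lo + 1))))


def _locus_block(
    spec: LocusSpec, templates: _Templates, rng, locus_name: str
) -> _Block:
    block = _Block()
    members: list[VRecord] = []
    for sg in sorted(spec.n_v_per_subgroup, key=lambda x: (len(x), x)):
        for _ in range(spec.n_v_per_subgroup[sg]):
            members.append(templates.v_member(sg, rng))
    if spec.include_trbv6:
        members.append(templates.v_member("6", rng))
    order = rng.permutation(len(members))
    members = [members[i] for i in order]
    for idx, op in sorted(spec.v_mutations.items()):
        if idx >= len(members):
            raise ValueError(f"v_mutations index {idx} out of range")
        members[idx], _ = apply_mutation(members[idx], op, rng)
    for i, rec in enumerate(members):
        block.add_seq(_intergenic(rng, spec.intergenic_mean), mutable=True)
        block.append(_v_block(rec, rng, f"{locus_name}_V{i+1:03d}", locus_name))
    block.add_seq(_intergenic(rng, spec.intergenic_mean), mutable=True)
    block.append(_d_block(rng, f"{locus_name}_D", locus_name))
    for j in range(spec.n_j):
        block.add_seq(_clean_random(rng, int(rng.integers(90, 170))), mutable=True)
        block.append(
            _j_block(templates.j_member(j, rng), rng, f"{locus_name}_J{j+1}", locus_name)
        )
    block.add_seq(_clean_random(rng, int(rng.integers(500, 800))), mutable=True)
    block.append(
        _c_block(
            templates.c_member(spec.c_subgroup, rng),
            spec.c_subgroup,
            rng,
            f"{locus_name}_C",
            locus_name,
        )
    )
    if spec.orientation == "-":
        return block.flip()
    return block


# --- contig sanitation -------------------------------------------------------


def _overlaps(a0, a1, spans) -> bool:
    return any(a0 < b and a < a1 for a, b in spans)


def _sanitize_contig(block: _Block, rng) -> None:
    """Remove chance RS motifs from mutable spans of an assembled contig."""
    mask = np.zeros(len(block.seq), dtype=bool)
    for a, b in block.mutable:
        mask[a:b] = True
    chars = list(block.seq)
    for _ in range(60):
        s = "".join(chars)
        targets: set[int] = set()
        for cls in (12, 23):
            for h in scan_rs(s, cls, **STRICT_RS):
                # exempt only hits sitting fully inside one planted RS;
                # a partial overlap is a chance motif, not the plant
                if any(a <= h.start and h.end <= b for a, b in block.planted_rs):
                    continue
                targets.update(
                    p
                    for p in list(range(h.heptamer.start, h.heptamer.end))
                    + list(range(h.nonamer.start, h.nonamer.end))
                    if mask[p]
                )
        for a, b in block.relaxed_clean:
            # the classifier's relaxed rescan reaches ~80 bp past the
            # coding end (heptamer slack + spacer + nonamer), so the
            # clean guarantee must extend at least that far
            sub = s[max(0, a - 80) : b + 80]
            off = max(0, a - 80)
            for cls in (12, 23):
                for h in scan_rs(sub, cls, **RELAXED_RS):
                    h0, h1 = h.start + off, h.end + off
                    if _overlaps(h0, h1, block.planted_rs):
                        continue
                    span = list(range(h.heptamer.start + off, h.heptamer.end + off))
                    cand = [p for p in span if mask[p]] or [
                        p for p in span if a <= p < b
                    ]
                    targets.update(cand)
        if not targets:
            break
        for p in targets:
            old = chars[p]
            chars[p] = str(rng.choice([b for b in "ACGT" if b != old]))
    block.seq = "".join(chars)


# --- genome generation -------------------------------------------------------


def generate_locus_genome(config: SynthConfig) -> TruthSet:
    """Generate a ground-truthed genome per ``config`` (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    templates = _Templates(config, rng)

    contig_plan: list[tuple[str, list[tuple[LocusSpec, str]]]] = []
    loci = list(config.loci)
    names = [f"TRB{i+1}" for i in range(len(loci))]
    if config.tandem_djc:
        if len(loci) < 3:
            raise ValueError("tandem_djc layout needs three locus specs")
        contig_plan.append(("contig_1", list(zip(loci[:3], names[:3]))))
        rest = list(zip(loci[3:], names[3:]))
    elif config.head_to_head and len(loci) >= 2:
        contig_plan.append(("contig_1", list(zip(loci[:2], names[:2]))))
        rest = list(zip(loci[2:], names[2:]))
    else:
        rest = list(zip(loci, names))
    for i, (spec, name) in enumerate(rest):
        contig_plan.append((f"contig_{len(contig_plan)+1}", [(spec, name)]))

    genome: dict[str, GenomicSequence] = {}
    features: list[TruthFeature] = []
    for ci, (contig_name, specs) in enumerate(contig_plan):
        contig = _Block()
        contig.add_seq(_clean_random(rng, 600), mutable=True)
        for spec, lname in specs:
            contig.append(_locus_block(spec, templates, rng, lname))
            contig.add_seq(_clean_random(rng, 1200), mutable=True)
        if ci == len(contig_plan) - 1 and config.remnant_v > 0:
            # inverted orphan V genes: the remnant of a lost locus
            remnant_name = f"TRB{len(loci)+1}"
            main_orient = specs[-1][0].orientation
            flip_to = "-" if main_orient == "+" else "+"
            for r in range(config.remnant_v):
                sg = sorted(specs[-1][0].n_v_per_subgroup)[0]
                vb = _v_block(
                    templates.v_member(sg, rng), rng, f"{remnant_name}_V{r+1:03d}", remnant_name
                )
                if flip_to == "-":
                    vb = vb.flip()
                contig.append(vb)
                contig.add_seq(_clean_random(rng, 800), mutable=True)
        _sanitize_contig(contig, rng)
        genome[contig_name] = GenomicSequence(contig_name, contig.seq)
        for f in contig.features:
            features.append(replace(f, contig=contig_name))

    transcripts = {"TRBC1": templates.c_templates["C1"], "TRBC2": templates.c_templates["C2"]}
    return TruthSet(genome, features, transcripts, config, templates)


# --- read simulation ---------------------------------------------------------


def simulate_reads(
    transcripts: dict[str, str],
    config: ReadSimConfig,
    seed: int = 0,
    ratio_keys: tuple[str, str] = ("TRBC1", "TRBC2"),
) -> tuple[list[tuple[str, str, str]], dict[str, str]]:
    """Simulate reads from two transcripts at a known RPKM ratio.

    Read counts are allocated proportionally to target RPKM x length
    (largest-remainder rounding, so small runs are exact), positions are
    uniform, strands random, substitution errors i.i.d. at ``error_rate``.
    Returns (reads, truth) where truth maps read id -> source transcript.
    """
    if len(transcripts) < 2:
        raise ValueError("ratio simulation needs at least two transcripts")
    rng = np.random.default_rng(seed)
    k1, k2 = ratio_keys
    for key in (k1, k2):
        if config.read_length > len(transcripts[key]):
            raise ValueError(
                f"read_length {config.read_length} exceeds transcript {key} length"
            )
    weights = {
        k1: config.c1_c2_ratio * len(transcripts[k1]),
        k2: 1.0 * len(transcripts[k2]),
    }
    total_w = sum(weights.values())
    counts = {}
    shares = {k: config.n_reads * w / total_w for k, w in weights.items()}
    floors = {k: int(np.floor(v)) for k, v in shares.items()}
    remainder = config.n_reads - sum(floors.values())
    by_frac = sorted(shares, key=lambda k: (shares[k] - floors[k], k), reverse=True)
    for i, k in enumerate(by_frac):
        counts[k] = floors[k] + (1 if i < remainder else 0)

    reads: list[tuple[str, str, str]] = []
    truth: dict[str, str] = {}
    qual = "I" * config.read_length
    n = 0
    for key in (k1, k2):
        tseq = transcripts[key]
        max_start = len(tseq) - config.read_length
        starts = rng.integers(0, max_start + 1, size=counts[key])
        flips = rng.random(counts[key]) < 0.5
        for s0, flip in zip(starts, flips):
            seq = tseq[int(s0) : int(s0) + config.read_length]
            if flip:
                seq = revcomp(seq)
            if config.error_rate > 0:
                errs = np.nonzero(rng.random(len(seq)) < config.error_rate)[0]
                if len(errs):
                    chars = list(seq)
                    for p in errs:
                        p = int(p)
                        chars[p] = str(
                            rng.choice([b for b in "ACGT" if b != chars[p]])
                        )
                    seq = "".join(chars)
            rid = f"read_{n:07d}"
            n += 1
            reads.append((rid, seq, qual))
            truth[rid] = key
    return reads, truth


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


# --- desk-scale helpers ------------------------------------------------------


def generate_subgroup_members(
    n_subgroups: int = 13,
    members_per_subgroup: int = 4,
    within_divergence: float = 0.10,
    between_divergence: float = 0.35,
    seed: int = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """V-REGION member sequences with known subgroup labels (for
    clustering studies); returns (id -> sequence, id -> subgroup)."""
    spec = LocusSpec({str(i + 1): members_per_subgroup for i in range(n_subgroups)})
    config = SynthConfig(
        seed=seed,
        loci=[spec],
        head_to_head=False,
        within_divergence=within_divergence,
        between_divergence=between_divergence,
    )
    rng = np.random.default_rng(seed)
    templates = _Templates(config, rng)
    seqs: dict[str, str] = {}
    labels: dict[str, str] = {}
    for sg in sorted(spec.n_v_per_subgroup, key=lambda x: (len(x), x)):
        for m in range(members_per_subgroup):
            rec = templates.v_member(sg, rng)
            gid = f"SG{sg}_M{m+1}"
            seqs[gid] = rec.coding[V_REGION_START:]
            labels[gid] = sg
    return seqs, labels


def evaluate_against_truth(result, truth: TruthSet) -> dict[str, dict[str, float]]:
    """Exact-coordinate precision/recall of an annotation vs planted truth.

    A call matches a truth feature when contig, strand and every exon
    boundary agree exactly (for D, the D-REGION; for J, the J-REGION).
    """

    def truth_keys(gene_type):
        return {
            (f.contig, f.strand, tuple(sorted(f.exons))) for f in truth.features_of(gene_type)
        }

    def call_keys(genes):
        out = []
        for g in genes:
            if g.gene_type == "D":
                exons = [(g.d_region.start, g.d_region.end)]
            elif g.gene_type == "J":
                exons = [(g.j_region.start, g.j_region.end)]
            else:
                exons = [(e.start, e.end) for e in g.exons]
            out.append((g.contig, g.strand, tuple(sorted(exons))))
        return out

    report = {}
    for gene_type, genes in (
        ("V", result.v_genes),
        ("D", result.d_genes),
        ("J", result.j_genes),
        ("C", result.c_genes),
    ):
        t = truth_keys(gene_type)
        calls = call_keys(genes)
        tp = sum(1 for key in calls if key in t)
        precision = tp / len(calls) if calls else 0.0
        recall = len(t & set(calls)) / len(t) if t else 1.0
        report[gene_type] = {
            "n_truth": len(t),
            "n_called": len(calls),
            "precision": precision,
            "recall": recall,
        }
    return report
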