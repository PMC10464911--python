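"""Position numbering and F/ORF/P functionality classification.

A germline V, D, J or C gene is classified as

* ``F`` (functional): open reading frame, intact recombination signal and
  splice sites, conserved anchor residues present;
* ``ORF``: reading frame intact but the RS or a splice site is defective,
  or an anchor residue changed (operationalized folding defect);
* ``P`` (pseudogene): stop codon, frameshift, or no RS at all.

Anchor residues follow the standard unique numbering of the V and C
domains: 1st-CYS at position 23, CONSERVED-TRP at 41, 2nd-CYS at 104 and,
for the C domain, a hydrophobic residue at 89. Numbering is transferred
from a curated reference profile by global alignment rather than by a full
gap-insertion numbering algorithm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "NumberingProfile",
    "NumberingMap",
    "FunctionalityCall",
    "RSEvidence",
    "number_v_domain",
    "classify_functionality",
    "HYDROPHOBIC_89",
]

#: residues accepted as "hydrophobic" at C-domain position 89
HYDROPHOBIC_89 = set("AVLIMFWCY")

V_ANCHOR_EXPECT = {23: "C", 41: "W", 104: "C"}

P_REASONS = {"stop_codon", "frameshift", "missing_rs"}
ORF_REASONS = {"defective_rs", "defective_splice", "anchor_change", "contains_N"}


@dataclass(frozen=True)
class NumberingProfile:
    """A curated domain sequence with known position assignments.

    ``positions[i]`` is the numbering position of profile residue ``i``.
    """

    protein: str
    positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.protein) != len(self.positions):
            raise ValueError("profile protein and position map differ in length")
        if list(self.positions) != sorted(set(self.positions)):
            raise ValueError("profile positions must be strictly increasing")

    @classmethod
    def sequential(cls, protein: str, start: int = 1) -> "NumberingProfile":
        return cls(protein, tuple(range(start, start + len(protein))))


@dataclass
class NumberingMap:
    """Numbering positions mapped onto a query sequence.

    ``query_positions[pos]`` is the 0-based query residue index carrying
    numbering position ``pos``, or None where the query has a gap.
    """

    query_positions: dict[int, int | None]
    anchor_residues: dict[int, str | None]
    identity: float

    def residue_at(self, pos: int, query: str) -> str | None:
        qi = self.query_positions.get(pos)
        return query[qi] if qi is not None else None


@dataclass
class FunctionalityCall:
    label: str  # F | ORF | P
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in ("F", "ORF", "P"):
            raise ValueError(f"bad functionality label {self.label!r}")


@dataclass
class RSEvidence:
    """RS search outcome at the two mismatch-threshold tiers.

    ``strict`` holds a hit found at the functional thresholds
    (heptamer mm <= 2, nonamer mm <= 3); ``relaxed`` a hit found only at
    the widened thresholds (<= 3, <= 5) within the search window around
    the coding end. Both None means no RS even relaxed.
    """

    strict: object | None = None
    relaxed: object | None = None


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -11
        a.extend_gap_score = -1
        a.mode = "global"
        _aligner = a
    return _aligner


def number_v_domain(protein: str, reference_profile: NumberingProfile) -> NumberingMap:
    """Transfer numbering from ``reference_profile`` onto ``protein``.

    The query is globally aligned to the profile (BLOSUM62, affine gaps)
    and position labels are carried through aligned columns. Insertions
    relative to the profile receive no position (they fall in CDR loops by
    construction of the profile). Deterministic for fixed gap parameters.

    Raises ValueError("unalignable") when alignment identity < 30%.
    """
    if not protein:
        raise ValueError("unalignable: empty query")
    clean = protein.replace("*", "X")
    aln = _get_aligner().align(clean, reference_profile.protein)[0]
    q_aln, p_aln = aln[0], aln[1]
    matches = sum(1 for a, b in zip(q_aln, p_aln) if a == b and a != "-")
    columns = sum(1 for a, b in zip(q_aln, p_aln) if a != "-" and b != "-")
    identity = 100.0 * matches / columns if columns else 0.0
    if identity < 30.0:
        raise ValueError(f"unalignable: identity {identity:.1f}% < 30%")

    query_positions: dict[int, int | None] = {}
    qi = pi = 0
    for a, b in zip(q_aln, p_aln):
        if b != "-":
            pos = reference_profile.positions[pi]
            query_positions[pos] = qi if a != "-" else None
            pi += 1
        if a != "-":
            qi += 1
    anchors = {}
    for pos in (23, 41, 104):
        idx = query_positions.get(pos)
        anchors[pos] = protein[idx] if idx is not None else None
    return NumberingMap(query_positions, anchors, identity)


def _rs_reasons(rs_evidence) -> list[str]:
    reasons = []
    if rs_evidence is None:
        return reasons
    items = rs_evidence if isinstance(rs_evidence, (list, tuple)) else [rs_evidence]
    for ev in items:
        if ev.strict is not None:
            continue
        if ev.relaxed is not None:
            reasons.append("defective_rs")
        else:
            reasons.append("missing_rs")
    return reasons


def classify_functionality(
    gene,
    rs_evidence=None,
    splice_evidence=None,
    numbering: NumberingMap | None = None,
) -> FunctionalityCall:
    """Classify a called gene as F, ORF or P with machine-readable reasons.

    ``gene`` is any called gene object exposing ``coding`` (the spliced
    coding nucleotides) and, per type, ``protein`` / ``fgxg_position``.
    ``rs_evidence`` is an :class:`RSEvidence` (or list, for D genes with
    two signals); ``splice_evidence`` a list of defective-junction flags
    (truthy entries count as defects); ``numbering`` the V-domain map for
    V genes.

    Precedence: any of stop codon / frameshift / missing RS forces P;
    otherwise any of defective RS / defective splice / anchor change (or
    an N in the coding span, which prevents certifying functionality)
    yields ORF; otherwise F.
    """
    reasons: list[str] = []
    coding = getattr(gene, "coding", None) or ""
    gtype = getattr(gene, "gene_type", "V")

    if "N" in coding:
        reasons.append("contains_N")

    if gtype == "D":
        # D region must be productively readable in at least one frame
        from .seq_io import translate

        open_frames = [f for f in range(3) if "*" not in translate(coding, f)]
        if not open_frames:
            reasons.append("stop_codon")
    else:
        protein = getattr(gene, "protein", None)
        if protein is None:
            from .seq_io import translate

            protein = translate(coding)
        if "*" in protein.rstrip("*"):
            reasons.append("stop_codon")
        expected_mod = getattr(gene, "expected_length_mod3", 0 if gtype in ("V", "C") else None)
        if expected_mod is not None and len(coding) % 3 != expected_mod:
            reasons.append("frameshift")

    reasons.extend(_rs_reasons(rs_evidence))

    if splice_evidence:
        if any(bool(x) for x in splice_evidence):
            reasons.append("defective_splice")

    if gtype == "V" and numbering is not None:
        for pos, expect in V_ANCHOR_EXPECT.items():
            if numbering.anchor_residues.get(pos) != expect:
                reasons.append("anchor_change")
                break
    elif gtype == "J":
        if getattr(gene, "fgxg_position", None) is None:
            reasons.append("anchor_change")
    elif gtype == "C":
        cp = getattr(gene, "conserved_positions", None)
        if cp is not None:
            bad = (
                cp.get(23) != "C"
                or cp.get(41) != "W"
                or cp.get(104) != "C"
                or (cp.get(89) not in HYDROPHOBIC_89)
            )
            if bad:
                reasons.append("anchor_change")

    reasons = list(dict.fromkeys(reasons))  # dedupe, keep order
    if set(reasons) & P_REASONS:
        label = "P"
    elif set(reasons) & ORF_REASONS:
        label = "ORF"
    else:
        label = "F"
    return FunctionalityCall(label, reasons)
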