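"""V-gene subgroup clustering and positional nomenclature.

A subgroup is a set of genes sharing more than 75% nucleotide identity
(strictly greater; identity exactly 75 does not link). Clustering is
single linkage — the subgroup definition is a connectivity criterion —
with complete linkage available via ``linkage=``. Names follow the
positional scheme TRB{locus}{type}{subgroup}-{rank}: e.g. TRB2V13-4 is
the 4th subgroup-13 V gene (5'->3') of locus TRB2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

__all__ = [
    "IdentityMatrix",
    "SubgroupAssignment",
    "GeneName",
    "pairwise_identity",
    "sequence_identity",
    "cluster_subgroups",
    "map_to_reference_subgroups",
    "assign_names",
]


@dataclass
class IdentityMatrix:
    ids: list[str]
    values: np.ndarray  # percent identity, symmetric, diagonal 100

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("identity matrix shape mismatch")
        if not np.allclose(v, v.T):
            raise ValueError("identity matrix not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


@dataclass
class SubgroupAssignment:
    assignment: dict[str, str]           # gene id -> subgroup label
    novel: dict[str, bool] = field(default_factory=dict)

    def members(self, label: str) -> list[str]:
        return [g for g, l in self.assignment.items() if l == label]


@dataclass(frozen=True)
class GeneName:
    locus_number: int
    gene_type: str  # V D J C
    subgroup: int | None = None
    rank: int | None = None

    def render(self) -> str:
        t = self.gene_type
        if t in ("V", "C"):
            return f"TRB{self.locus_number}{t}{self.subgroup}-{self.rank}"
        if t == "J":
            return f"TRB{self.locus_number}J{self.rank}"
        return f"TRB{self.locus_number}D"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.render()


_aligner = None


def _get_aligner() -> Align.PairwiseAligner:
    global _aligner
    if _aligner is None:
        a = Align.PairwiseAligner()
        a.match_score = 1
        a.mismatch_score = -1
        a.open_gap_score = -4
        a.extend_gap_score = -1
        a.mode = "global"
        _aligner = a
    return _aligner


def sequence_identity(a: str, b: str) -> float:
    """Percent identity over the global alignment of two sequences.

    Identity = matches / aligned columns, excluding terminal-gap columns
    (overhangs contribute neither matches nor columns).
    """
    if not a or not b:
        raise ValueError("empty sequence")
    aln = _get_aligner().align(a.upper(), b.upper())[0]
    sa, sb = aln[0], aln[1]
    # trim terminal gap columns of either sequence
    lo = 0
    hi = len(sa)
    for s in (sa, sb):
        i = 0
        while i < len(s) and s[i] == "-":
            i += 1
        lo = max(lo, i)
        j = len(s)
        while j > 0 and s[j - 1] == "-":
            j -= 1
        hi = min(hi, j)
    if hi <= lo:
        return 0.0
    matches = sum(1 for x, y in zip(sa[lo:hi], sb[lo:hi]) if x == y and x != "-")
    return 100.0 * matches / (hi - lo)


def pairwise_identity(sequences: dict[str, str]) -> IdentityMatrix:
    """All-against-all percent nucleotide identity (global alignment)."""
    ids = list(sequences)
    for gid in ids:
        if not sequences[gid]:
            raise ValueError(f"empty sequence for {gid!r}")
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            ident = sequence_identity(sequences[ids[i]], sequences[ids[j]])
            m[i, j] = m[j, i] = ident
    return IdentityMatrix(ids, m)


def cluster_subgroups(
    matrix: IdentityMatrix,
    threshold: float = 75.0,
    linkage: str = "single",
) -> SubgroupAssignment:
    """Cluster genes at identity strictly greater than ``threshold``.

    Single linkage is connected components over >threshold edges;
    complete linkage requires every within-cluster pair to exceed it
    (agglomerative, deterministic order). Labels are integers ordered by
    cluster size then first member position in the input.
    """
    ids = matrix.ids
    n = len(ids)
    if linkage == "single":
        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if matrix.values[i, j] > threshold:
                    parent[find(i)] = find(j)
        comp: dict[int, list[int]] = {}
        for i in range(n):
            comp.setdefault(find(i), []).append(i)
        clusters = list(comp.values())
    elif linkage == "complete":
        clusters = [[i] for i in range(n)]
        merged = True
        while merged:
            merged = False
            best = None
            for a in range(len(clusters)):
                for b in range(a + 1, len(clusters)):
                    worst = min(
                        matrix.values[i, j] for i in clusters[a] for j in clusters[b]
                    )
                    if worst > threshold and (best is None or worst > best[0]):
                        best = (worst, a, b)
            if best is not None:
                _, a, b = best
                clusters[a] = sorted(clusters[a] + clusters[b])
                del clusters[b]
                merged = True
    else:
        raise ValueError(f"unknown linkage {linkage!r}")

    clusters.sort(key=lambda c: (-len(c), min(c)))
    assignment = {}
    for label, members in enumerate(clusters, start=1):
        for i in members:
            assignment[ids[i]] = str(label)
    return SubgroupAssignment(assignment, {str(l): True for l in range(1, len(clusters) + 1)})


def map_to_reference_subgroups(
    assignment: SubgroupAssignment,
    sequences: dict[str, str],
    ref_subgroup_library: dict[str, str],
    threshold: float = 75.0,
) -> SubgroupAssignment:
    """Relabel clusters by their best reference exemplar (> threshold).

    ``ref_subgroup_library`` maps subgroup label (e.g. "13") -> exemplar
    sequence. Clusters beating no exemplar are labeled novel with the
    next free integer.
    """
    labels = sorted(set(assignment.assignment.values()), key=lambda x: (len(x), x))
    used_ints = set()
    for label in ref_subgroup_library:
        try:
            used_ints.add(int(label))
        except ValueError:
            pass
    out: dict[str, str] = {}
    novel: dict[str, bool] = {}
    next_free = max(used_ints, default=0) + 1
    for label in labels:
        members = assignment.members(label)
        best = None
        for ref_label, ref_seq in sorted(ref_subgroup_library.items()):
            for g in members:
                ident = sequence_identity(sequences[g], ref_seq)
                if best is None or ident > best[0]:
                    best = (ident, ref_label)
        if best is not None and best[0] > threshold:
            new_label, is_novel = best[1], False
        else:
            new_label, is_novel = str(next_free), True
            next_free += 1
        for g in members:
            out[g] = new_label
        novel[new_label] = is_novel
    return SubgroupAssignment(out, novel)


def assign_names(
    loci: list,
    assignment: SubgroupAssignment | None = None,
    orphans: list | None = None,
    orphan_locus_number: int | None = None,
    c_subgroups: dict[int, str] | None = None,
) -> dict[int, GeneName]:
    """Assign positional names to every gene of assembled loci.

    Returns a map from ``id(gene)`` -> :class:`GeneName` and sets each
    gene's ``name``. V ranks run 5'->3' along the locus transcriptional
    orientation within (locus, subgroup); J genes are numbered
    positionally; C genes are ranked across loci within their C subgroup.
    Loci must already be ordered/numbered (list position = locus number).
    """
    names: dict[int, GeneName] = {}
    c_sub_rank: dict[str, int] = {}
    for locus_number, locus in enumerate(loci, start=1):
        if locus.name is None:
            locus.name = f"TRB{locus_number}"
        counters: dict[str, int] = {}
        for v in locus.v_genes:
            if assignment is not None:
                sg = assignment.assignment.get(_gene_key(v))
                if sg is None:
                    raise ValueError(f"V gene {_gene_key(v)} has no subgroup assignment")
                v.subgroup = sg
            sg = v.subgroup
            if sg is None:
                raise ValueError(f"V gene {_gene_key(v)} has no subgroup")
            counters[sg] = counters.get(sg, 0) + 1
            name = GeneName(locus_number, "V", int(sg), counters[sg])
            names[id(v)] = name
            v.name = name.render()
        if locus.d_gene is not None:
            name = GeneName(locus_number, "D")
            names[id(locus.d_gene)] = name
            locus.d_gene.name = name.render()
        for rank, j in enumerate(locus.j_genes, start=1):
            name = GeneName(locus_number, "J", rank=rank)
            names[id(j)] = name
            j.name = name.render()
        c = locus.c_gene
        c_sub = (c_subgroups or {}).get(locus_number) or c.subgroup or "1"
        c_sub = str(c_sub).lstrip("C") or "1"
        c_sub_rank[c_sub] = c_sub_rank.get(c_sub, 0) + 1
        name = GeneName(locus_number, "C", int(c_sub), c_sub_rank[c_sub])
        names[id(c)] = name
        c.name = name.render()

    if orphans:
        n = orphan_locus_number or len(loci) + 1
        counters = {}
        # rank 5'->3' along each orphan's own transcriptional orientation
        for v in sorted(
            orphans,
            key=lambda g: (
                g.contig,
                g.span.start if g.strand == "+" else -g.span.start,
            ),
        ):
            sg = None
            if assignment is not None:
                sg = assignment.assignment.get(_gene_key(v))
            sg = sg or v.subgroup
            if sg is None:
                raise ValueError(f"orphan V gene {_gene_key(v)} has no subgroup")
            v.subgroup = sg
            counters[sg] = counters.get(sg, 0) + 1
            name = GeneName(n, "V", int(sg), counters[sg])
            names[id(v)] = name
            v.name = name.render()
    return names


def _gene_key(gene) -> str:
    return f"{gene.contig}:{gene.span.start}-{gene.span.end}({gene.strand})"
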