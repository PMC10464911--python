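"""Comparative summaries: subgroup-by-locus count matrix, C-subgroup
classification and the locus-architecture report."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import bootstrap_supports
from .subgroups import IdentityMatrix, cluster_subgroups, sequence_identity

__all__ = [
    "CSubgroupReport",
    "subgroup_count_table",
    "classify_c_subgroups",
    "locus_architecture_report",
]

FUNCTIONALITY_CLASSES = ("F", "ORF", "P")


def subgroup_count_table(v_genes, remnant_merge: bool = False) -> pd.DataFrame:
    """Count V genes per (subgroup, locus, functionality class).

    ``v_genes`` is an iterable of called V genes with ``name``,
    ``subgroup`` and ``functionality`` set; the locus is read from the
    name prefix (TRB{n}). Rows are subgroups, columns a (locus, class)
    MultiIndex plus margins. ``remnant_merge`` folds genes of the highest
    locus number (a remnant) into the preceding locus.
    """
    rows = []
    for g in v_genes:
        if g.name is None:
            raise ValueError(f"unnamed V gene at {g.contig}:{g.span.start}")
        if g.subgroup is None:
            raise ValueError(f"V gene {g.name} has no subgroup")
        locus = g.name.split("V")[0]
        rows.append(
            {"subgroup": str(g.subgroup), "locus": locus, "functionality": g.functionality or "F"}
        )
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame()
    if remnant_merge:
        loci = sorted(df["locus"].unique())
        if len(loci) > 1:
            df.loc[df["locus"] == loci[-1], "locus"] = loci[-2]
    table = (
        df.groupby(["subgroup", "locus", "functionality"])
        .size()
        .unstack(["locus", "functionality"], fill_value=0)
    )
    # stable ordering: loci alphabetical, classes F, ORF, P
    loci = sorted({c[0] for c in table.columns})
    cols = [
        (l, f) for l in loci for f in FUNCTIONALITY_CLASSES if (l, f) in table.columns
    ]
    table = table[cols]
    table = table.reindex(sorted(table.index, key=lambda s: (len(s), s)))
    table[("total", "")] = table.sum(axis=1)
    table.loc["total"] = table.sum(axis=0)
    return table


@dataclass
class CSubgroupReport:
    c_ids: list[str]
    identity: IdentityMatrix
    assignment: dict[str, str]           # gene id -> C1/C2/...
    support: float | None = None         # bootstrap % of the separating split
    excluded: list[str] = field(default_factory=list)


def classify_c_subgroups(
    c_proteins: dict[str, str],
    exemplars: dict[str, str] | None = None,
    threshold: float = 85.0,
    n_bootstrap: int = 200,
    seed: int = 0,
) -> CSubgroupReport:
    """Cluster C genes by amino-acid identity and label C1/C2.

    Single linkage at ``threshold`` percent amino-acid identity
    (within-subgroup salmonid C genes sit near 99%, between-subgroup
    near 70%). Clusters are labeled by their best exemplar when
    ``exemplars`` maps subgroup name -> protein. With >= 4 genes the
    bootstrap support of the bipartition separating the two largest
    clusters is attached (Poisson distances on a master-projected
    alignment).
    """
    proteins = {k: v for k, v in c_proteins.items() if v}
    excluded = [k for k in c_proteins if not c_proteins[k]]
    ids = list(proteins)
    if len(ids) < 2:
        raise ValueError("need at least 2 translatable C genes")
    n = len(ids)
    m = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            m[i, j] = m[j, i] = sequence_identity(proteins[ids[i]], proteins[ids[j]])
    identity = IdentityMatrix(ids, m)
    clustering = cluster_subgroups(identity, threshold=threshold)

    labels = sorted(set(clustering.assignment.values()), key=int)
    relabel = {}
    if exemplars:
        for lab in labels:
            members = clustering.members(lab)
            best = None
            for ex_name, ex_seq in sorted(exemplars.items()):
                ident = max(sequence_identity(proteins[g], ex_seq) for g in members)
                if best is None or ident > best[0]:
                    best = (ident, ex_name)
            relabel[lab] = best[1]
    else:
        relabel = {lab: f"C{lab}" for lab in labels}
    assignment = {g: relabel[l] for g, l in clustering.assignment.items()}

    support = None
    if n >= 4 and len(set(assignment.values())) >= 2:
        aln = _project_alignment(proteins)
        tree = bootstrap_supports(aln, n_replicates=n_bootstrap, seed=seed, model="poisson")
        groups = {}
        for g, l in assignment.items():
            groups.setdefault(l, set()).add(g)
        two = sorted(groups.values(), key=len, reverse=True)[:2]
        all_ids = frozenset(ids)
        anchor = min(all_ids)
        for side in two:
            side = frozenset(side)
            canonical = side if anchor not in side else all_ids - side
            if canonical in tree.supports:
                support = tree.supports[canonical]
                break
    return CSubgroupReport(ids, identity, assignment, support, excluded)


def _project_alignment(proteins: dict[str, str]) -> dict[str, str]:
    """Project every sequence onto the columns of the first (master)
    sequence via pairwise alignment; insertions are dropped. A light
    stand-in for a proper multiple alignment, adequate for same-length
    homologous proteins."""
    from Bio import Align

    ids = list(proteins)
    master = proteins[ids[0]]
    a = Align.PairwiseAligner()
    a.match_score, a.mismatch_score = 1, -1
    a.open_gap_score, a.extend_gap_score = -4, -1
    a.mode = "global"
    out = {ids[0]: master}
    for gid in ids[1:]:
        aln = a.align(proteins[gid], master)[0]
        q_aln, m_aln = aln[0], aln[1]
        row = []
        for qc, mc in zip(q_aln, m_aln):
            if mc != "-":
                row.append(qc if qc != "-" else "-")
        out[gid] = "".join(row)
    return out


def locus_architecture_report(structures) -> pd.DataFrame:
    """Tabulate per-contig locus architecture (gene-class strings,
    orientations, duplication pattern, V counts)."""
    rows = []
    for st in structures:
        descriptions = []
        for locus in sorted(st.loci, key=lambda l: l.span.start):
            arrow = "->" if locus.orientation == "+" else "<-"
            parts = []
            if locus.v_genes:
                parts.append(f"V({len(locus.v_genes)})")
            if locus.d_gene is not None:
                parts.append("D")
            if locus.j_genes:
                parts.append(f"J({len(locus.j_genes)})")
            parts.append("C")
            if locus.orientation == "-":
                parts = parts[::-1]
            descriptions.append("-".join(parts) + arrow)
        if st.orphans:
            descriptions.append(f"orphanV({len(st.orphans)})")
        rows.append(
            {
                "contig": st.contig,
                "architecture": " | ".join(descriptions),
                "pattern": st.pattern,
                "n_loci": len(st.loci),
                "n_v": sum(len(l.v_genes) for l in st.loci),
                "n_orphan_v": len(st.orphans),
                "notes": st.notes,
            }
        )
    return pd.DataFrame(rows)
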