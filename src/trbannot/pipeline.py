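"""End-to-end annotation: callers -> loci -> functionality -> names.

This is the glue the CLI and the tests drive; every step is also
available individually through the per-stage modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import functionality as fn
from .gene_callers import (
    CGene,
    DGene,
    JGene,
    Locus,
    LocusStructure,
    ReferenceLibrary,
    VGene,
    assemble_loci,
    call_c_genes,
    call_d_genes,
    call_j_genes,
    call_v_genes,
    detect_duplication_pattern,
)
from .seq_io import GenomicSequence, GffFeature, Interval, translate
from .subgroups import (
    SubgroupAssignment,
    assign_names,
    cluster_subgroups,
    map_to_reference_subgroups,
    pairwise_identity,
    _gene_key,
)

__all__ = ["AnnotationResult", "annotate_genome", "annotation_to_gff"]

V_REGION_NT_OFFSET = 60  # leader codons (L-PART1 + split codon + L-PART2)


@dataclass
class AnnotationResult:
    genome: dict[str, GenomicSequence]
    v_genes: list[VGene]
    d_genes: list[DGene]
    j_genes: list[JGene]
    c_genes: list[CGene]
    loci: list[Locus]
    orphans: list[VGene]
    structures: list[LocusStructure]
    subgroup_assignment: SubgroupAssignment | None = None
    names: dict = field(default_factory=dict)

    @property
    def all_genes(self) -> list:
        return self.v_genes + self.d_genes + self.j_genes + self.c_genes


def _dj_region(c: CGene, v_genes, c_genes, cap: int = 25000) -> Interval | None:
    """Gene-frame-upstream window of a C gene, bounded by the nearest
    same-strand V gene or any other C gene."""
    contig_len = None
    if c.strand == "+":
        hi = c.span.start
        lo = max(0, hi - cap)
        for v in v_genes:
            if v.contig == c.contig and v.strand == "+" and v.span.end <= hi:
                lo = max(lo, v.span.end)
        for c2 in c_genes:
            if c2 is not c and c2.contig == c.contig and c2.span.end <= hi:
                lo = max(lo, c2.span.end)
        if hi - lo < 50:
            return None
        return Interval(c.contig, lo, hi, "+")
    lo = c.span.end
    hi = lo + cap
    for v in v_genes:
        if v.contig == c.contig and v.strand == "-" and v.span.start >= lo:
            hi = min(hi, v.span.start)
    for c2 in c_genes:
        if c2 is not c and c2.contig == c.contig and c2.span.start >= lo:
            hi = min(hi, c2.span.start)
    if hi - lo < 50:
        return None
    return Interval(c.contig, lo, hi, "-")


def annotate_genome(
    genome: dict[str, GenomicSequence],
    reflib: ReferenceLibrary,
    allow_spliced_vexon: bool = True,
    classify: bool = True,
    name_genes: bool = True,
    region_cap: int = 25000,
) -> AnnotationResult:
    """Annotate all TRB genes in ``genome`` using ``reflib``.

    Calls C and V genes by similarity + motif evidence, D and J genes in
    the region between each C gene and its V cluster, assembles loci,
    classifies functionality, clusters V subgroups against the reference
    exemplars and assigns positional names.
    """
    c_genes = call_c_genes(genome, reflib)
    v_genes = call_v_genes(genome, reflib, allow_spliced_vexon=allow_spliced_vexon)
    d_genes: list[DGene] = []
    j_genes: list[JGene] = []
    for c in c_genes:
        region = _dj_region(c, v_genes, c_genes, cap=region_cap)
        if region is None:
            continue
        ds = call_d_genes(genome, region, c.strand)
        d_genes.extend(ds)
        if ds:
            d = ds[0] if c.strand == "+" else ds[-1]
            if c.strand == "+":
                j_region = Interval(c.contig, d.span.end, region.end, "+")
            else:
                j_region = Interval(c.contig, region.start, d.span.start, "-")
        else:
            j_region = region
        if len(j_region) >= 50:
            j_genes.extend(call_j_genes(genome, j_region, c.strand))

    loci, orphans = assemble_loci(v_genes, d_genes, j_genes, c_genes)
    # locus numbering: contig order of appearance, then C position
    contig_order = {name: i for i, name in enumerate(genome)}
    loci.sort(key=lambda l: (contig_order.get(l.contig, 99), l.c_gene.span.start))
    structures = []
    for contig in sorted({l.contig for l in loci} | {o.contig for o in orphans},
                         key=lambda c: contig_order.get(c, 99)):
        cl = [l for l in loci if l.contig == contig]
        co = [o for o in orphans if o.contig == contig]
        if cl or co:
            structures.append(detect_duplication_pattern(cl, co))

    if classify:
        _classify_all(v_genes, d_genes, j_genes, c_genes, reflib)

    assignment = None
    names = {}
    if name_genes and v_genes:
        v_seqs = {
            _gene_key(v): v.coding[V_REGION_NT_OFFSET:]
            for v in v_genes
            if len(v.coding) > V_REGION_NT_OFFSET
        }
        if len(v_seqs) >= 2:
            matrix = pairwise_identity(v_seqs)
            clusters = cluster_subgroups(matrix)
            refs = {
                name: seq[V_REGION_NT_OFFSET:]
                for name, seq in reflib.v_refs.items()
            }
            assignment = map_to_reference_subgroups(clusters, v_seqs, refs)
        elif len(v_seqs) == 1:
            assignment = SubgroupAssignment({next(iter(v_seqs)): "1"})
        # C subgroup labels from reference identity
        for c in c_genes:
            c.subgroup = (c.ref_id or "C1").lstrip("C")
        names = assign_names(loci, assignment, orphans=orphans)
    return AnnotationResult(
        genome, v_genes, d_genes, j_genes, c_genes, loci, orphans, structures,
        assignment, names,
    )


def _classify_all(v_genes, d_genes, j_genes, c_genes, reflib: ReferenceLibrary) -> None:
    for v in v_genes:
        # number against the gene's own subgroup exemplar when known;
        # a generic profile can fall below alignability at high divergence
        profile = None
        if v.ref_id and v.ref_id in reflib.v_refs:
            ref_vregion = translate(reflib.v_refs[v.ref_id][V_REGION_NT_OFFSET:])
            if ref_vregion:
                profile = fn.NumberingProfile.sequential(ref_vregion)
        if profile is None:
            profile = reflib.numbering_profile
        numbering = None
        if profile is not None and len(v.coding) > V_REGION_NT_OFFSET:
            v_prot = translate(v.coding[V_REGION_NT_OFFSET:])
            try:
                numbering = fn.number_v_domain(v_prot, profile)
            except ValueError:
                numbering = None
        if numbering is not None:
            v.anchors = numbering.anchor_residues
        call = fn.classify_functionality(
            v, v.rs_evidence, v.splice_defects, numbering
        )
        v.functionality, v.functionality_reasons = call.label, call.reasons
    for d in d_genes:
        call = fn.classify_functionality(
            d,
            [fn.RSEvidence(strict=d.five_prime_rs), fn.RSEvidence(strict=d.three_prime_rs)],
        )
        d.functionality, d.functionality_reasons = call.label, call.reasons
    for j in j_genes:
        call = fn.classify_functionality(
            j, fn.RSEvidence(strict=j.j_rs), [j.donor_defective]
        )
        j.functionality, j.functionality_reasons = call.label, call.reasons
    for c in c_genes:
        defects = list(c.splice_defects) + (
            ["incomplete_exon_structure"] if "incomplete_exon_structure" in c.flags else []
        )
        call = fn.classify_functionality(c, None, defects)
        c.functionality, c.functionality_reasons = call.label, call.reasons


def annotation_to_gff(result: AnnotationResult) -> list[GffFeature]:
    """Export the annotation as GFF3 features (genes + exon children)."""
    type_map = {"V": "V_gene_segment", "D": "D_gene_segment",
                "J": "J_gene_segment", "C": "C_gene_segment"}
    feats: list[GffFeature] = []
    counter = 0
    for g in result.all_genes:
        counter += 1
        gid = g.name or f"{g.gene_type}_{counter:04d}"
        attrs = {"ID": gid}
        if g.functionality:
            attrs["functionality"] = g.functionality
        if g.functionality_reasons:
            attrs["reasons"] = ",".join(g.functionality_reasons)
        sub = getattr(g, "subgroup", None)
        if sub:
            attrs["subgroup"] = str(sub)
        rs_parts = []
        for attr in ("v_rs", "j_rs", "five_prime_rs", "three_prime_rs"):
            hit = getattr(g, attr, None)
            if hit is not None:
                rs_parts.append(f"{hit.start + 1}-{hit.end}")
        if rs_parts:
            attrs["rs_coordinates"] = ",".join(rs_parts)
        flags = getattr(g, "flags", None)
        if flags:
            attrs["flags"] = ",".join(flags)
        feats.append(GffFeature(g.span, type_map[g.gene_type], attributes=attrs))
        if g.gene_type == "D":
            exons = [g.d_region]
        elif g.gene_type == "J":
            exons = [g.j_region]
        else:
            exons = g.exons
        for i, e in enumerate(exons):
            feats.append(
                GffFeature(e, "exon", attributes={"Parent": gid, "rank": str(i + 1)})
            )
    return feats
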