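"""Gene callers: similarity search, per-type calling, locus assembly."""

import numpy as np
import pytest

from trbannot.gene_callers import (
    ReferenceLibrary,
    assemble_loci,
    call_c_genes,
    call_j_genes,
    call_v_genes,
    detect_duplication_pattern,
    load_hit_table,
    similarity_search,
)
from trbannot.pipeline import annotate_genome
from trbannot.seq_io import GenomicSequence, Interval, revcomp
from trbannot.synth import (
    LocusSpec,
    SynthConfig,
    evaluate_against_truth,
    generate_locus_genome,
)


def _rand(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestSimilaritySearch:
    def test_exact_copy_full_identity(self):
        rng = np.random.default_rng(0)
        ref = _rand(rng, 300)
        genome = {"g": GenomicSequence("g", _rand(rng, 400) + ref + _rand(rng, 400))}
        hits = similarity_search({"q": ref}, genome)
        assert len(hits) == 1
        h = hits[0]
        assert (h.iv.start, h.iv.end) == (400, 700)
        assert h.identity == 100.0
        assert h.coverage == 100.0

    def test_point_mutated_copy_matches_ungapped_oracle(self):
        rng = np.random.default_rng(1)
        ref = _rand(rng, 300)
        copy = list(ref)
        mut_pos = rng.choice(300, size=15, replace=False)  # 5% point mutations
        for p in mut_pos:
            copy[p] = str(rng.choice([b for b in "ACGT" if b != copy[p]]))
        copy = "".join(copy)
        genome = {"g": GenomicSequence("g", _rand(rng, 200) + copy + _rand(rng, 200))}
        hits = similarity_search({"q": ref}, genome)
        assert len(hits) == 1
        h = hits[0]
        # oracle: substitutions only, so the optimal alignment is ungapped
        span = genome["g"].residues[h.iv.start : h.iv.end]
        matches = sum(1 for a, b in zip(ref[h.q_start : h.q_end], span) if a == b)
        assert h.identity == pytest.approx(100.0 * matches / len(span))
        assert h.identity == pytest.approx(100.0 * (300 - 15) / 300, abs=2.0)

    def test_random_genome_no_hit(self):
        rng = np.random.default_rng(2)
        ref = _rand(rng, 300)
        genome = {"g": GenomicSequence("g", _rand(rng, 5000))}
        assert similarity_search({"q": ref}, genome, min_identity=80.0) == []

    def test_empty_refs_rejected(self):
        with pytest.raises(ValueError):
            similarity_search({}, {"g": GenomicSequence("g", "ACGT" * 10)})

    def test_reverse_strand_hit(self):
        rng = np.random.default_rng(3)
        ref = _rand(rng, 200)
        genome = {"g": GenomicSequence("g", _rand(rng, 300) + revcomp(ref) + _rand(rng, 300))}
        hits = similarity_search({"q": ref}, genome)
        assert len(hits) == 1
        assert hits[0].iv.strand == "-"
        assert (hits[0].iv.start, hits[0].iv.end) == (300, 500)


class TestHitTable:
    def test_import_converts_coordinates_and_strand(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text(
            "q1\tchr1\t98.5\t300\t4\t0\t1\t300\t1001\t1300\t1e-50\t550\n"
            "q2\tchr1\t91.0\t200\t18\t0\t1\t200\t2400\t2201\t1e-20\t210\n"
        )
        hits = load_hit_table(p)
        assert len(hits) == 2
        fwd = next(h for h in hits if h.query_id == "q1")
        assert (fwd.iv.start, fwd.iv.end, fwd.iv.strand) == (1000, 1300, "+")
        rev = next(h for h in hits if h.query_id == "q2")
        assert (rev.iv.start, rev.iv.end, rev.iv.strand) == (2200, 2400, "-")

    def test_wrong_column_count_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("a\tb\tc\n")
        with pytest.raises(ValueError, match="12 columns"):
            load_hit_table(p)


class TestCallersOnTruth:
    def test_all_gene_classes_exact_on_clean_locus(self, small_truth, small_result):
        report = evaluate_against_truth(small_result, small_truth)
        for cls in "VDJC":
            assert report[cls]["precision"] == 1.0, report
            assert report[cls]["recall"] == 1.0, report

    def test_c_gene_conserved_positions(self, small_result):
        (c,) = small_result.c_genes
        assert c.conserved_positions[23] == "C"
        assert c.conserved_positions[104] == "C"
        assert c.conserved_positions[41] == "W"
        assert len(c.exons) == 4

    def test_functional_j_has_fgxg_and_canonical_donor(self, small_result):
        for j in small_result.j_genes:
            assert j.fgxg_position is not None
            assert j.donor.motif == "GTAAGT"
            prot = j.coding  # translated downstream; spot-check the motif
            assert j.functionality == "F"

    def test_every_d_has_both_rs_classes(self, small_result):
        for d in small_result.d_genes:
            assert d.five_prime_rs.spacer_class == 12
            assert d.three_prime_rs.spacer_class == 23
            assert 8 <= len(d.d_region) <= 25

    def test_every_functional_v_has_23_rs(self, small_result):
        for v in small_result.v_genes:
            if v.functionality == "F":
                assert v.v_rs is not None
                assert v.v_rs.spacer_class == 23

    def test_strand_covariance(self, small_truth):
        """Annotating the reverse-complemented contig mirrors the calls."""
        reflib = small_truth.reference_library()
        fwd = annotate_genome(small_truth.genome, reflib, name_genes=False)
        flipped = {
            k: GenomicSequence(k, revcomp(v.residues)) for k, v in small_truth.genome.items()
        }
        rev = annotate_genome(flipped, reflib, name_genes=False)
        L = len(next(iter(small_truth.genome.values())))

        def keyset(genes):
            return sorted(
                (g.strand, g.span.start, g.span.end, g.functionality) for g in genes
            )

        def mirrored(genes):
            return sorted(
                (
                    "+" if g.strand == "-" else "-",
                    L - g.span.end,
                    L - g.span.start,
                    g.functionality,
                )
                for g in genes
            )

        assert keyset(fwd.v_genes) == mirrored(rev.v_genes)
        assert keyset(fwd.j_genes) == mirrored(rev.j_genes)
        assert keyset(fwd.c_genes) == mirrored(rev.c_genes)


class TestJDonorDefect:
    def test_mutated_donor_called_with_defect_flag(self):
        """A J whose GTAAGT donor is degraded still gets called, flagged."""
        from trbannot.motif_scan import RS_HEPTAMER, RS_NONAMER

        rng = np.random.default_rng(7)
        j_region = (
            "GTG" * 3 + "TTC" + "GGA" + "ACA" + "GGT" + "GAA" * 4
        )  # 48 bp, FGXG at codons 3-6
        unit = revcomp(RS_NONAMER) + _rand(rng, 12) + revcomp(RS_HEPTAMER) + j_region + "GTAACT"
        s = "CATCAT" * 20 + unit + "CATCAT" * 20
        genome = {"r": GenomicSequence("r", s)}
        genes = call_j_genes(genome, Interval("r", 0, len(s)), "+")
        assert len(genes) == 1
        assert genes[0].donor_defective
        assert genes[0].donor.motif == "GTAACT"


@pytest.fixture(scope="module")
def trbv6_truth():
    cfg = SynthConfig(
        seed=5,
        head_to_head=False,
        loci=[LocusSpec({"1": 2}, n_j=3, orientation="+", include_trbv6=True)],
    )
    return generate_locus_genome(cfg)


class TestSplicedVExon:
    def test_four_exon_v_recovered_when_enabled(self, trbv6_truth):
        res = annotate_genome(
            trbv6_truth.genome, trbv6_truth.reference_library(), name_genes=False
        )
        spliced = [v for v in res.v_genes if len(v.exons) == 4]
        assert len(spliced) == 1
        assert "spliced_v_exon" in spliced[0].flags
        assert spliced[0].functionality == "F"
        report = evaluate_against_truth(res, trbv6_truth)
        assert report["V"]["precision"] == report["V"]["recall"] == 1.0

    def test_flagged_incomplete_when_disabled(self, trbv6_truth):
        res = annotate_genome(
            trbv6_truth.genome,
            trbv6_truth.reference_library(),
            allow_spliced_vexon=False,
            name_genes=False,
        )
        assert not any(len(v.exons) > 2 for v in res.v_genes)
        flagged = [v for v in res.v_genes if "spliced_v_exon" in v.flags]
        assert len(flagged) == 1
        assert flagged[0].functionality != "F"


class TestLocusAssembly:
    def test_single_locus_membership_and_order(self, small_result):
        (locus,) = small_result.loci
        assert locus.complete
        assert len(locus.v_genes) == 5
        assert len(locus.j_genes) == 4
        # 5'->3' ordering along the + strand
        starts = [v.span.start for v in locus.v_genes]
        assert starts == sorted(starts)
        assert locus.v_genes[-1].span.end < locus.d_gene.span.start
        assert locus.d_gene.span.end < locus.j_genes[0].span.start
        assert locus.j_genes[-1].span.end < locus.c_gene.span.start

    def test_head_to_head_and_remnant_detection(self, full_result):
        patterns = {s.contig: s.pattern for s in full_result.structures}
        assert patterns["contig_1"] == "head_to_head_pair"
        assert patterns["contig_2"] == "remnant"
        remnant = next(s for s in full_result.structures if s.pattern == "remnant")
        assert len(remnant.orphans) == 2
        assert all(o.strand != remnant.loci[0].orientation for o in remnant.orphans)

    def test_tandem_djc_detection(self):
        cfg = SynthConfig(
            seed=4,
            tandem_djc=True,
            head_to_head=False,
            loci=[
                LocusSpec({}, n_j=3, orientation="-"),
                LocusSpec({"1": 3}, n_j=3, orientation="-"),
                LocusSpec({"1": 2, "2": 2}, n_j=3, orientation="+"),
            ],
        )
        truth = generate_locus_genome(cfg)
        res = annotate_genome(truth.genome, truth.reference_library(), name_genes=False)
        (structure,) = res.structures
        assert structure.pattern == "tandem_DJC_duplication"
        report = evaluate_against_truth(res, truth)
        assert all(report[c]["precision"] == report[c]["recall"] == 1.0 for c in "VDJC")

    def test_no_gene_in_two_loci(self, full_result):
        seen = set()
        for locus in full_result.loci:
            for g in locus.genes:
                assert id(g) not in seen
                seen.add(id(g))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            detect_duplication_pattern([], [])
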