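"""Identity computation, >75% clustering, reference mapping and naming."""

import numpy as np
import pytest

from trbannot.subgroups import (
    GeneName,
    IdentityMatrix,
    cluster_subgroups,
    map_to_reference_subgroups,
    pairwise_identity,
    sequence_identity,
)
from trbannot.synth import generate_subgroup_members


def _nw_identity_oracle(a, b, match=1, mismatch=-1, gap_open=-4, gap_extend=-1):
    """Independent affine-gap global DP, tracking the aligned strings."""
    n, m = len(a), len(b)
    NEG = -10**9
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a
    M[0][0] = 0
    for i in range(1, n + 1):
        X[i][0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend)
    # traceback from the best terminal state
    i, j = n, m
    state = max(("M", M[n][m]), ("X", X[n][m]), ("Y", Y[n][m]), key=lambda t: t[1])[0]
    cols = []
    while i > 0 or j > 0:
        if state == "M":
            cols.append((a[i - 1], b[j - 1]))
            prev = max(
                ("M", M[i - 1][j - 1]), ("X", X[i - 1][j - 1]), ("Y", Y[i - 1][j - 1]),
                key=lambda t: t[1],
            )[0]
            i, j = i - 1, j - 1
            state = prev
        elif state == "X":
            cols.append((a[i - 1], "-"))
            state = "M" if M[i - 1][j] + gap_open >= X[i - 1][j] + gap_extend else "X"
            i -= 1
        else:
            cols.append((b[j - 1], None))
            cols[-1] = ("-", b[j - 1])
            state = "M" if M[i][j - 1] + gap_open >= Y[i][j - 1] + gap_extend else "Y"
            j -= 1
    cols.reverse()
    lo, hi = 0, len(cols)
    while lo < hi and "-" in cols[lo]:
        lo += 1
    while hi > lo and "-" in cols[hi - 1]:
        hi -= 1
    core = cols[lo:hi]
    matches = sum(1 for x, y in core if x == y and x != "-")
    return 100.0 * matches / len(core) if core else 0.0


class TestIdentity:
    def test_identical_sequences(self):
        s = "ACGT" * 75
        assert sequence_identity(s, s) == 100.0

    def test_three_of_four(self):
        assert sequence_identity("ACGT", "ACGA") == 75.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            sequence_identity("", "ACGT")
        with pytest.raises(ValueError, match="x1"):
            pairwise_identity({"x1": "", "x2": "ACGT"})

    def test_matrix_symmetric_diagonal_100(self):
        rng = np.random.default_rng(0)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=60)) for i in range(5)}
        m = pairwise_identity(seqs)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 100.0)

    def test_substitution_only_pairs_match_dp_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=50))
            b = list(a)
            for p in rng.choice(50, size=int(rng.integers(1, 10)), replace=False):
                b[p] = str(rng.choice([x for x in "ACGT" if x != b[p]]))
            b = "".join(b)
            assert sequence_identity(a, b) == pytest.approx(_nw_identity_oracle(a, b))


class TestClustering:
    def _matrix(self, entries, n):
        ids = [f"g{i}" for i in range(n)]
        m = np.full((n, n), 50.0)
        np.fill_diagonal(m, 100.0)
        for (i, j), v in entries.items():
            m[i, j] = m[j, i] = v
        return IdentityMatrix(ids, m)

    def test_single_linkage_is_transitive_closure(self):
        # AB 90, BC 80, AC 60 -> one subgroup
        m = self._matrix({(0, 1): 90, (1, 2): 80, (0, 2): 60}, 3)
        asn = cluster_subgroups(m)
        assert len(set(asn.assignment.values())) == 1

    def test_all_distant_all_singletons(self):
        m = self._matrix({}, 4)
        asn = cluster_subgroups(m)
        assert len(set(asn.assignment.values())) == 4

    def test_exactly_75_is_not_linked(self):
        m = self._matrix({(0, 1): 75.0}, 2)
        asn = cluster_subgroups(m)
        assert asn.assignment["g0"] != asn.assignment["g1"]
        m2 = self._matrix({(0, 1): 75.0 + 1e-9}, 2)
        asn2 = cluster_subgroups(m2)
        assert asn2.assignment["g0"] == asn2.assignment["g1"]

    def test_input_order_invariance(self):
        rng = np.random.default_rng(2)
        seqs, _ = generate_subgroup_members(n_subgroups=3, members_per_subgroup=3, seed=3)
        m1 = pairwise_identity(seqs)
        shuffled_ids = list(seqs)
        rng.shuffle(shuffled_ids)
        m2 = pairwise_identity({k: seqs[k] for k in shuffled_ids})
        a1 = cluster_subgroups(m1).assignment
        a2 = cluster_subgroups(m2).assignment
        partition1 = {frozenset(g for g in a1 if a1[g] == l) for l in set(a1.values())}
        partition2 = {frozenset(g for g in a2 if a2[g] == l) for l in set(a2.values())}
        assert partition1 == partition2

    def test_complete_linkage_is_stricter(self):
        m = self._matrix({(0, 1): 90, (1, 2): 80, (0, 2): 60}, 3)
        single = cluster_subgroups(m, linkage="single")
        complete = cluster_subgroups(m, linkage="complete")
        assert len(set(single.assignment.values())) <= len(set(complete.assignment.values()))


class TestReferenceMapping:
    def test_cluster_maps_to_best_exemplar(self):
        seqs, labels = generate_subgroup_members(n_subgroups=3, members_per_subgroup=4, seed=4)
        m = pairwise_identity(seqs)
        asn = cluster_subgroups(m)
        # exemplar = first member of each generating subgroup
        refs = {}
        for gid, sg in labels.items():
            refs.setdefault(sg, seqs[gid])
        mapped = map_to_reference_subgroups(asn, seqs, refs)
        assert all(mapped.assignment[g] == labels[g] for g in seqs)
        assert not any(mapped.novel[l] for l in set(mapped.assignment.values()))

    def test_unmatched_cluster_labeled_novel(self):
        rng = np.random.default_rng(5)
        seqs = {
            "a": "".join(rng.choice(list("ACGT"), size=120)),
            "b": "".join(rng.choice(list("ACGT"), size=120)),
        }
        m = pairwise_identity(seqs)
        asn = cluster_subgroups(m)
        refs = {"7": "".join(rng.choice(list("ACGT"), size=120))}
        mapped = map_to_reference_subgroups(asn, seqs, refs)
        for label in set(mapped.assignment.values()):
            assert mapped.novel[label]
            assert int(label) > 7


class TestNaming:
    def test_worked_example_trb2v13_4(self, full_result):
        """The 4th subgroup-13 V gene of locus TRB2 renders TRB2V13-4."""
        trb2 = next(l for l in full_result.loci if l.name == "TRB2")
        sg13 = [v for v in trb2.v_genes if v.subgroup == "13"]
        assert len(sg13) >= 4
        assert sg13[3].name == "TRB2V13-4"
        # ranks are consecutive from 1 in 5'->3' order
        assert [v.name for v in sg13[:4]] == [f"TRB2V13-{i}" for i in range(1, 5)]

    def test_c_gene_names_rank_within_subgroup(self, full_result):
        c_names = sorted(c.name for c in full_result.c_genes)
        assert c_names == ["TRB1C1-1", "TRB2C1-2", "TRB3C2-1"]

    def test_rank_bijection_within_locus_subgroup(self, full_result):
        for locus in full_result.loci:
            by_sg = {}
            for v in locus.v_genes:
                by_sg.setdefault(v.subgroup, []).append(v)
            for sg, genes in by_sg.items():
                ranks = sorted(int(g.name.rsplit("-", 1)[1]) for g in genes)
                assert ranks == list(range(1, len(genes) + 1))

    def test_ranks_invariant_under_contig_reversal(self, full_truth, full_result):
        """Subgroup and rank follow transcriptional, not assembly,
        orientation; locus numbers are positional by design and may swap."""
        from trbannot.pipeline import annotate_genome
        from trbannot.seq_io import GenomicSequence, revcomp

        flipped = {
            k: GenomicSequence(k, revcomp(v.residues))
            for k, v in full_truth.genome.items()
        }
        rev = annotate_genome(flipped, full_truth.reference_library())
        lens = {k: len(v) for k, v in full_truth.genome.items()}
        fwd_map = {
            (v.contig, v.span.start, v.span.end): v.name for v in full_result.v_genes
        }
        assert len(rev.v_genes) == len(full_result.v_genes)
        for v in rev.v_genes:
            L = lens[v.contig]
            fwd_name = fwd_map[(v.contig, L - v.span.end, L - v.span.start)]
            # the V{subgroup}-{rank} part is orientation-independent
            assert fwd_name.split("V", 1)[1] == v.name.split("V", 1)[1]

    def test_render_forms(self):
        assert GeneName(2, "V", 13, 4).render() == "TRB2V13-4"
        assert GeneName(1, "J", rank=7).render() == "TRB1J7"
        assert GeneName(3, "D").render() == "TRB3D"
        assert GeneName(1, "C", 1, 1).render() == "TRB1C1-1"
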