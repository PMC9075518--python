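"""Anchored alignment, p-distances, neighbor joining, bootstrap."""

import random

import dendropy
import numpy as np
import pytest

from shsp.align import AnchoredAlignment, align_cores
from shsp.detect import detect_acds
from shsp.seqio import ProteinRecord
from shsp.templates import build_template
from shsp.tree import (
    bootstrap_supports,
    neighbor_joining,
    p_distance_matrix,
    tree_path_distances,
)


class TestAlignCores:
    def test_self_alignment_identical_rows(self, model):
        core = build_template("B2").core_seqs[0]
        msa = align_cores([("a", core), ("b", core)], model)
        assert msa.rows[0] == msa.rows[1]
        assert "-" not in msa.rows[0]

    def test_ungapping_recovers_inputs(self, model, small_repertoire):
        _, rep = small_repertoire
        cores = []
        for p in rep.proteins:
            hits, arch = detect_acds(p, model)
            if arch.label == "monomeric":
                cores.append((p.id, p.seq[hits[0].start : hits[0].end]))
        msa = align_cores(cores, model)
        orig = dict(cores)
        for i, cid in enumerate(msa.ids):
            assert msa.ungapped(i) == orig[cid]

    def test_l57_deletion_gaps_confined_to_l57_columns(self, model):
        t = build_template("B1")
        core = t.core_seqs[0]
        s, e = t.segments[0]["L57"]
        cs = t.cores[0][0]
        a, b = s - cs, e - cs  # L57 in core coordinates
        # delete two non-motif L57 residues (keep the fixed KK / EE blocks)
        deleted = core[:a + 2] + core[a + 4 : b] + core[b:]
        msa = align_cores([("full", core), ("del", deleted)], model)
        row = msa.rows[msa.ids.index("del")]
        gap_cols = {j for j, ch in enumerate(row) if ch == "-"}
        assert gap_cols, "deletion must appear as gaps"
        assert {msa.column_labels[j] for j in gap_cols} == {"L57"}

    def test_a1_b1_alignment_width(self, model):
        cores = [
            ("a1", build_template("A1").core_seqs[0]),
            ("b1", build_template("B1").core_seqs[0]),
        ]
        msa = align_cores(cores, model)
        assert 60 <= msa.n_columns <= 96

    def test_unalignable_core_excluded_with_warning(self, model):
        good = build_template("B2").core_seqs[0]
        with pytest.warns(UserWarning, match="unalignable"):
            msa = align_cores(
                [("g1", good), ("g2", good), ("junk", "A" * 70)], model
            )
        assert "junk" not in msa.ids

    def test_column_labels_non_decreasing(self, model):
        from shsp.templates import SEGMENT_ORDER

        cores = [(lab, build_template(lab).core_seqs[0]) for lab in ("A1", "B3")]
        msa = align_cores(cores, model)
        order = {s: i for i, s in enumerate(SEGMENT_ORDER)}
        ranks = [order[l] for l in msa.column_labels]
        assert ranks == sorted(ranks)


class TestPDistance:
    def _msa(self, rows):
        ids = [f"s{i}" for i in range(len(rows))]
        return AnchoredAlignment(ids=ids, rows=rows,
                                 column_labels=["b3"] * len(rows[0]))

    def test_identical_rows_zero(self):
        d = p_distance_matrix(self._msa(["ACDE", "ACDE"]))
        assert d[0, 1] == 0.0

    def test_counted_mismatch_fraction(self):
        row1 = "A" * 80
        row2 = "C" * 5 + "A" * 75
        d = p_distance_matrix(self._msa([row1, row2]))
        assert d[0, 1] == pytest.approx(5 / 80)

    def test_gapped_columns_excluded_pairwise(self):
        d = p_distance_matrix(self._msa(["AC-E", "ACDE", "GCDE"]))
        assert d[0, 1] == 0.0          # gap column dropped for this pair
        assert d[1, 2] == pytest.approx(1 / 4)
        assert d[0, 2] == pytest.approx(1 / 3)

    def test_symmetry_random(self):
        rng = random.Random(31)
        rows = ["".join(rng.choice("ACDE-") for _ in range(50)) for _ in range(8)]
        rows = [r.replace("-", "A") if set(r) == {"-"} else r for r in rows]
        d = p_distance_matrix(self._msa(rows))
        assert np.allclose(d, d.T)

    def test_incomparable_pair_flagged(self):
        with pytest.warns(UserWarning, match="no comparable columns"):
            d = p_distance_matrix(self._msa(["A-", "-A"]))
        assert np.isnan(d[0, 1])


def random_additive_tree(rng, names):
    """Random binary tree with positive branch lengths; returns its exact
    path-distance matrix (the oracle for NJ recovery)."""
    lengths = {}
    active = [(nm,) for nm in names]
    parent_len = {(nm,): rng.uniform(0.2, 1.5) for nm in names}
    while len(active) > 1:
        a = active.pop(rng.randrange(len(active)))
        b = active.pop(rng.randrange(len(active)))
        merged = a + b
        parent_len[merged] = rng.uniform(0.2, 1.5)
        lengths[(merged, a)] = parent_len[a]
        lengths[(merged, b)] = parent_len[b]
        active.append(merged)
    root = active[0]

    # path lengths leaf-to-leaf
    def paths(cluster, acc, out):
        if len(cluster) == 1:
            out[cluster[0]] = acc
            return
        for (p, c), ln in lengths.items():
            if p == cluster:
                paths(c, acc + ln, out)

    n = len(names)
    D = np.zeros((n, n))

    def pairs(cluster):
        kids = [c for (p, c) in lengths if p == cluster]
        for c in kids:
            if len(c) > 1:
                pairs(c)
        if len(kids) == 2:
            left, right = {}, {}
            paths(kids[0], lengths[(cluster, kids[0])], left)
            paths(kids[1], lengths[(cluster, kids[1])], right)
            for u, du in left.items():
                for v, dv in right.items():
                    i, j = names.index(u), names.index(v)
                    D[i, j] = D[j, i] = du + dv

    pairs(root)
    return D


class TestNeighborJoining:
    def test_three_taxon_hand_solution(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        t = neighbor_joining(d, ["A", "B", "C"])
        lengths = {c.name: bl for c, bl in t.root.children}
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_additive_five_taxon_recovery(self, seed):
        rng = random.Random(seed)
        names = ["A", "B", "C", "D", "E"]
        D = random_additive_tree(rng, names)
        t = neighbor_joining(D, names)
        P, order = tree_path_distances(t)
        idx = [order.index(nm) for nm in names]
        assert np.abs(P[np.ix_(idx, idx)] - D).max() < 1e-9

    def test_ultrametric_pairs_are_siblings(self):
        names = ["A", "B", "C", "D"]
        D = np.array(
            [[0, 0.1, 1, 1], [0.1, 0, 1, 1], [1, 1, 0, 0.1], [1, 1, 0.1, 0]]
        )
        t = neighbor_joining(D, names)
        assert frozenset({"A", "B"}) in t.splits() or frozenset({"C", "D"}) in t.splits()

    def test_matches_scikit_bio_topology(self):
        """Independent oracle: scikit-bio's NJ on the same matrix yields the
        same set of splits."""
        import io

        from skbio import DistanceMatrix
        from skbio.tree import nj

        rng = random.Random(41)
        names = list("ABCDEFG")
        D = random_additive_tree(rng, names)
        ours = neighbor_joining(D, names).splits()
        sk_tree = nj(DistanceMatrix(D, ids=names))
        sk_splits = set()
        for node in sk_tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(names) - 1:
                other = frozenset(names) - side
                sk_splits.add(min(side, other, key=lambda s: (len(s), tuple(sorted(s)))))
        ours_canon = {
            min(s, frozenset(names) - s, key=lambda x: (len(x), tuple(sorted(x))))
            for s in ours
        }
        assert ours_canon == sk_splits

    def test_degenerate_two_taxon_warning(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = neighbor_joining(np.array([[0, 1.0], [1.0, 0]]), ["A", "B"])
        assert set(t.leaf_names) == {"A", "B"}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(np.array([[0, 1], [2, 0]], float), ["A", "B"])

    def test_branch_lengths_non_negative(self):
        rng = random.Random(55)
        n = 8
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = rng.uniform(0.01, 1.0)
        t = neighbor_joining(D, [f"s{i}" for i in range(n)])

        def walk(node):
            for c, bl in node.children:
                assert bl >= 0
                walk(c)

        walk(t.root)


class TestNewick:
    def test_round_trip_through_dendropy(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        t = neighbor_joining(d, ["A", "B", "C"])
        parsed = dendropy.Tree.get(data=t.newick(), schema="newick")
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == {"A", "B", "C"}
        total = sum(e.length for e in parsed.edges() if e.length)
        assert total == pytest.approx(5.0)


class TestBootstrap:
    def _template_msa(self, model, seed=61):
        from shsp.simulate import GeneratorConfig, generate_repertoire

        cfg = GeneratorConfig(
            n_per_cluster={"A1": 3, "A2": 3, "B1": 3},
            sub_rate_strand=0.03, sub_rate_loop=0.03,
            n_random_decoys=0, n_near_miss_decoys=0, seed=seed,
        )
        rep = generate_repertoire(cfg)
        cores = []
        for p in rep.proteins:
            hits, arch = detect_acds(p, model)
            assert arch.label == "monomeric"
            cores.append((p.id, p.seq[hits[0].start : hits[0].end]))
        return align_cores(cores, model)

    def test_identical_duplicates_full_support(self, model):
        core_a = build_template("A1").core_seqs[0]
        core_b = build_template("B1").core_seqs[0]
        core_c = build_template("B3").core_seqs[0]
        msa = align_cores(
            [("a1", core_a), ("a2", core_a), ("b1", core_b), ("c1", core_c)], model
        )
        t = bootstrap_supports(msa, n_reps=50, seed=3)
        assert t.supports()[frozenset({"a1", "a2"})] == 100.0

    def test_same_seed_identical_supports(self, model):
        msa = self._template_msa(model)
        s1 = bootstrap_supports(msa, n_reps=30, seed=9).supports()
        s2 = bootstrap_supports(msa, n_reps=30, seed=9).supports()
        assert s1 == s2

    def test_planted_clusters_monophyletic(self, model):
        msa = self._template_msa(model)
        t = bootstrap_supports(msa, n_reps=50, seed=5)
        splits = t.splits()
        for lab in ("A1", "A2", "B1"):
            members = frozenset(i for i in msa.ids if f"_{lab}_" in i)
            assert members in splits, f"{lab} not monophyletic"
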