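"""vOTU clustering, MCL, VC construction, taxonomy, lifestyle, rarefaction."""

import itertools

import numpy as np
import pytest

from phageome.catalogue import (
    assign_taxonomy,
    build_vcs,
    classify_lifestyle,
    cluster_proteins,
    cluster_votus,
    mcl,
    rarefy,
)
from phageome.seqcore import estimate_ani
from phageome.synthetic_community import mutate, random_dna


def exhaustive_votu_clusters(genomes, ani_min=0.95, cov_min=0.85):
    """Independent oracle: order genomes by length, then greedily assign each
    to the first earlier centroid meeting the thresholds, computing every
    ANI from scratch with no prescreen."""
    order = sorted(genomes, key=lambda g: (len(g[1]), g[0]), reverse=True)
    clusters = []
    for gid, seq in order:
        for cluster in clusters:
            cid, cseq = cluster[0]
            ani, af = estimate_ani(seq, cseq)
            if ani >= ani_min and af >= cov_min:
                cluster.append((gid, seq))
                break
        else:
            clusters.append([(gid, seq)])
    return sorted(tuple(sorted(g for g, _ in c)) for c in clusters)


class TestVotuClustering:
    def test_exact_duplicate_joins(self, rng):
        g = random_dna(rng, 12000)
        votus = cluster_votus([("a", g), ("b", g)])
        assert len(votus) == 1 and set(votus[0].members) == {"a", "b"}

    def test_divergence_thresholds(self, rng):
        g = random_dna(rng, 12000)
        near = mutate(g, 0.02, rng)  # 2% diverged: same species
        far = mutate(g, 0.10, rng)  # 10% diverged: distinct species
        votus = cluster_votus([("ref", g), ("near", near), ("far", far)])
        by_member = {m: v.votu_id for v in votus for m in v.members}
        assert by_member["ref"] == by_member["near"] != by_member["far"]

    def test_matches_exhaustive_oracle_on_planted_species(self, rng):
        """3 planted species x 4 variants at <= 3% divergence -> 3 vOTUs,
        identical to brute-force clustering."""
        genomes = []
        for s in range(3):
            base = random_dna(rng, 8000 + 2000 * s)
            genomes.append((f"s{s}_0", base))
            for k in range(1, 4):
                genomes.append((f"s{s}_{k}", mutate(base, rng.uniform(0.002, 0.015), rng)))
        votus = cluster_votus(genomes)
        got = sorted(tuple(sorted(v.members)) for v in votus)
        assert len(votus) == 3
        assert got == exhaustive_votu_clusters(genomes)

    def test_partition_and_representative_thresholds(self, rng):
        base = random_dna(rng, 9000)
        genomes = [("a", base), ("b", mutate(base, 0.02, rng)), ("c", random_dna(rng, 9000))]
        votus = cluster_votus(genomes)
        members = [m for v in votus for m in v.members]
        assert sorted(members) == ["a", "b", "c"]  # a partition
        for v in votus:
            assert v.representative in v.members
            rep_seq = dict(genomes)[v.representative]
            for m in v.members:
                if m == v.representative:
                    continue
                ani, af = estimate_ani(dict(genomes)[m], rep_seq)
                assert ani >= 0.95 and af >= 0.85


def mcl_oracle(A, inflation=2.0, tol=1e-8):
    """Independent per-column loop implementation of the same iteration."""
    A = np.array(A, dtype=float)
    n = A.shape[0]
    for i in range(n):
        col_max = A[:, i].max()
        A[i, i] = col_max if col_max > 0 else 1.0
    for i in range(n):
        A[:, i] /= A[:, i].sum()
    for _ in range(200):
        prev = A.copy()
        A = A @ A
        for i in range(n):
            for j in range(n):
                A[j, i] = A[j, i] ** inflation
        A[A < 1e-5] = 0.0
        for i in range(n):
            A[:, i] /= A[:, i].sum()
        if np.abs(A - prev).max() < tol:
            break
    # connected components of the non-zero structure
    seen, comps = set(), []
    adj = (A > 1e-5) | (A > 1e-5).T
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(np.nonzero(adj[u])[0].tolist())
        seen |= comp
        comps.append(tuple(sorted(comp)))
    return sorted(comps)


class TestMcl:
    def test_block_diagonal_cliques(self):
        A = np.zeros((6, 6))
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in itertools.combinations(block, 2):
                A[i, j] = A[j, i] = 1.0
        assert mcl(A) == [(0, 1, 2), (3, 4, 5)]

    def test_three_node_path_regression(self):
        A = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        assert mcl(A) == mcl_oracle(A) == [(0, 1, 2)]

    def test_single_node(self):
        assert mcl(np.zeros((1, 1))) == [(0,)]

    def test_matches_independent_iteration_oracle(self, rng):
        """Random graphs up to 20 nodes with planted two-community structure."""
        for trial in range(10):
            n = int(rng.integers(6, 21))
            A = np.zeros((n, n))
            half = n // 2
            for i, j in itertools.combinations(range(n), 2):
                same = (i < half) == (j < half)
                p = 0.7 if same else 0.05
                if rng.random() < p:
                    w = float(rng.uniform(0.5, 2.0))
                    A[i, j] = A[j, i] = w
            assert mcl(A) == mcl_oracle(A)

    def test_node_relabeling_invariance(self, rng):
        n = 10
        A = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            if rng.random() < 0.3:
                A[i, j] = A[j, i] = float(rng.uniform(0.5, 2))
        perm = rng.permutation(n)
        P = np.eye(n)[perm]
        relabeled = P @ A @ P.T
        orig = mcl(A)
        back = sorted(tuple(sorted(int(perm[i]) for i in comp)) for comp in mcl(relabeled))
        # mapping: relabeled node k corresponds to original node perm[k]
        assert back == orig

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            mcl(np.zeros((2, 3)))
        with pytest.raises(ValueError):
            mcl(np.array([[0.0, -1.0], [-1.0, 0.0]]))


class TestProteinClusters:
    def test_identical_pair_plus_stranger(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        p = "".join(rng.choice(list(aa), 120))
        q = "".join(rng.choice(list(aa), 120))
        pcs = cluster_proteins([("p1", p), ("p2", p), ("q", q)])
        sizes = sorted(len(pc.members) for pc in pcs)
        assert sizes == [1, 2]

    def test_two_families_with_weak_cross_edge(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        fam_a = "".join(rng.choice(list(aa), 150))
        fam_b = "".join(rng.choice(list(aa), 150))

        def variant(base):
            out = list(base)
            for i in rng.choice(len(base), 8, replace=False):
                out[i] = aa[(aa.index(out[i]) + 1) % 20]
            return "".join(out)

        proteins = [(f"a{i}", variant(fam_a)) for i in range(10)]
        proteins += [(f"b{i}", variant(fam_b)) for i in range(10)]
        pcs = cluster_proteins(proteins)
        assert len(pcs) == 2
        assert all(len({m[0] for m in pc.members}) == 1 for pc in pcs)

    def test_no_edges_gives_singletons(self, rng):
        aa = "ACDEFGHIKLMNPQRSTVWY"
        proteins = [(f"x{i}", "".join(rng.choice(list(aa), 80))) for i in range(5)]
        assert len(cluster_proteins(proteins)) == 5


class TestViralClusters:
    def test_shared_fraction_above_threshold_groups(self):
        votu_pcs = {"A": {f"pc{i}" for i in range(10)}, "B": {f"pc{i}" for i in range(3)} | {"x1", "x2", "x3", "x4", "x5", "x6", "x7", "x8", "x9"}}
        # shared = 3, min(10, 12) = 10 -> 0.30 > 0.20
        vcs = build_vcs(votu_pcs)
        assert len(vcs) == 1 and set(vcs[0].members) == {"A", "B"}

    def test_exactly_twenty_percent_not_grouped(self):
        votu_pcs = {"A": {f"pc{i}" for i in range(10)}, "B": {"pc0", "pc1"} | {f"y{i}" for i in range(8)}}
        # shared = 2, min = 10 -> 0.20 exactly: strict > excludes
        assert len(build_vcs(votu_pcs)) == 2

    def test_disjoint_pcs_separate(self):
        votu_pcs = {"A": {"p1", "p2"}, "B": {"q1", "q2"}}
        assert len(build_vcs(votu_pcs)) == 2

    def test_permutation_invariance(self, rng):
        votu_pcs = {f"v{i}": {f"pc{j}" for j in rng.choice(30, 10, replace=False)} for i in range(8)}
        vcs1 = build_vcs(dict(sorted(votu_pcs.items())))
        vcs2 = build_vcs(dict(sorted(votu_pcs.items(), reverse=True)))
        assert sorted(v.members for v in vcs1) == sorted(v.members for v in vcs2)


class TestTaxonomyVote:
    def test_quarter_share_wins(self):
        fams = ["Siphoviridae"] * 5 + [None] * 15
        assert assign_taxonomy(fams) == "Siphoviridae"

    def test_exact_twenty_percent_unclassified(self):
        fams = ["Siphoviridae"] * 4 + [None] * 16
        assert assign_taxonomy(fams) == "unclassified"

    def test_tie_unclassified(self):
        fams = ["Siphoviridae"] * 5 + ["Podoviridae"] * 5 + [None] * 2
        assert assign_taxonomy(fams) == "unclassified"

    def test_no_hits_unclassified(self):
        assert assign_taxonomy([None] * 5) == "unclassified"


class TestLifestyle:
    @pytest.mark.parametrize(
        "score,alignments,expected",
        [
            (0.85, (), "temperate"),
            (0.5, [(1500, 0.96)], "temperate"),
            (0.2, (), "virulent"),
            (0.8, (), "virulent"),  # strict >
            (0.5, [(900, 0.99)], "virulent"),  # alignment too short
            (0.5, [(1500, 0.95)], "virulent"),  # identity not strictly above
        ],
    )
    def test_rule(self, score, alignments, expected):
        assert classify_lifestyle(score, alignments) == expected


class TestRarefaction:
    def test_extremes_and_monotonicity(self, rng):
        det = rng.random((20, 50)) < 0.3
        curve = rarefy(det, depths=range(1, 21), reps=40, rng=rng)
        assert curve[20] == float(det.any(axis=0).sum())
        assert curve[1] == pytest.approx(det.sum(axis=1).mean(), abs=2.0)
        values = [curve[d] for d in range(1, 21)]
        assert all(b >= a - 1e-9 for a, b in zip(values, values[1:]))

    def test_depth_out_of_range_raises(self, rng):
        det = rng.random((5, 10)) < 0.5
        with pytest.raises(ValueError):
            rarefy(det, depths=[6], rng=rng)
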