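"""Six-criterion classifier, provirus estimation, recovery, and evaluation."""

import numpy as np
import pytest

from phageome.config import PipelineConfig
from phageome.discovery import (
    classify_contig,
    completeness_tier,
    estimate_contamination,
    estimate_provirus_fraction,
    evaluate_pipeline,
    recover_linear,
    run_discovery,
    screen_circular,
)
from phageome.io import ContigRecord, GeneAnnotation
from phageome.synthetic_community import generate_phage_genome, random_dna


def make_contig(length, gene_specs, kmer_p=0.01, contig_id="c", rng=None):
    """gene_specs: list of (start, end, flag_dict)."""
    rng = rng or np.random.default_rng(0)
    seq = random_dna(rng, length)
    genes = [
        GeneAnnotation(gene_id=f"{contig_id}_g{i}", start=s, end=e, protein_seq="", **flags)
        for i, (s, e, flags) in enumerate(gene_specs)
    ]
    return ContigRecord(id=contig_id, seq=seq, genes=genes, kmer_p=kmer_p)


VIRAL = {"viral_hallmark": True, "viral_db_hit": True}


class TestClassifier:
    def test_small_contig_rejected_at_size(self):
        contig = make_contig(8000, [(100, 700, dict(VIRAL))])
        report = classify_contig(contig)
        assert report.rejected_at == 1 and report.verdict == "rejected"

    def test_single_bacterial_marker_rejects_at_four(self):
        specs = [(100 + 800 * i, 700 + 800 * i, dict(VIRAL)) for i in range(10)]
        specs[4] = (specs[4][0], specs[4][1], {"bacterial_marker": True})
        report = classify_contig(make_contig(12000, specs))
        assert report.rejected_at == 4

    def test_planted_phage_matches_rule_table_oracle(self):
        """Cross-check against an independently scripted evaluation of the
        six printed rules."""
        specs = [(100 + 800 * i, 700 + 800 * i, dict(VIRAL)) for i in range(14)]
        contig = make_contig(12000, specs, kmer_p=0.01)
        report = classify_contig(contig)

        def oracle(contig):
            n_viral = sum(g.viral_db_hit for g in contig.genes)
            n_plasmid = sum(g.plasmid_db_hit for g in contig.genes)
            rules = [
                len(contig.seq) >= 10000,
                contig.kmer_p <= 0.05,
                any(g.viral_hallmark for g in contig.genes)
                and not any(g.plasmid_hallmark for g in contig.genes),
                not any(g.bacterial_marker or g.rRNA for g in contig.genes),
                not (n_plasmid > n_viral),
                estimate_provirus_fraction(contig) >= 0.8,
            ]
            return all(rules)

        assert report.verdict == "phage" and oracle(contig)

    def test_db_count_tie_is_kept(self):
        specs = [(100 + 800 * i, 700 + 800 * i, dict(VIRAL)) for i in range(6)]
        contig = make_contig(12000, specs)
        for g in contig.genes:
            g.plasmid_db_hit = True  # 6 vs 6: not strictly more
        assert classify_contig(contig).dbcount_pass

    def test_verdict_is_monotone_in_criteria(self):
        """Flipping any single criterion pass->fail never turns a rejection
        into a phage call."""
        specs = [(100 + 800 * i, 700 + 800 * i, dict(VIRAL)) for i in range(10)]
        breakers = [
            lambda c: setattr(c, "kmer_p", 0.5),
            lambda c: [setattr(g, "viral_hallmark", False) for g in c.genes],
            lambda c: setattr(c.genes[0], "rRNA", True),
            lambda c: [setattr(g, "plasmid_db_hit", True) for g in c.genes]
            and [setattr(g, "viral_db_hit", False) for g in c.genes],
        ]
        for brk in breakers:
            contig = make_contig(12000, [(s, e, dict(f)) for s, e, f in specs])
            base = classify_contig(contig)
            brk(contig)
            broken = classify_contig(contig)
            assert base.verdict == "phage" and broken.verdict == "rejected"
            assert sum(broken.passes) < sum(base.passes)

    def test_missing_annotations_raise_with_contig_name(self):
        contig = ContigRecord(id="bare", seq="ACGT" * 3000, genes=[], kmer_p=0.01)
        with pytest.raises(ValueError, match="bare"):
            classify_contig(contig)


class TestProvirusFraction:
    def test_all_viral_genes_give_one(self):
        specs = [(100 + 800 * i, 700 + 800 * i, dict(VIRAL)) for i in range(5)]
        assert estimate_provirus_fraction(make_contig(10000, specs)) == 1.0

    def test_viral_run_between_host_genes(self):
        """30 kb viral run inside a 100 kb host contig -> ~0.3."""
        specs = [(1000, 34000, {"bacterial_marker": True})]
        specs += [(35000 + 3000 * i, 37000 + 3000 * i, dict(VIRAL)) for i in range(10)]
        specs += [(65500, 66400, {"bacterial_marker": True})]
        frac = estimate_provirus_fraction(make_contig(100000, specs))
        assert frac == pytest.approx((64000 - 35000 + 1) / 100000)

    def test_no_genes_give_zero(self):
        contig = ContigRecord(id="x", seq="ACGT" * 1000, genes=[], kmer_p=0.01)
        assert estimate_provirus_fraction(contig) == 0.0

    def test_low_provirus_fraction_reported_alongside_marker_failure(self):
        specs = [(500, 1400, {"bacterial_marker": True})]
        specs += [(35000 + 3000 * i, 37000 + 3000 * i, dict(VIRAL)) for i in range(10)]
        specs += [(90000, 90900, {"rRNA": True})]
        report = classify_contig(make_contig(100000, specs))
        assert report.provirus_fraction == pytest.approx(29001 / 100000)
        assert not report.provirus_pass
        assert report.rejected_at == 4  # markers fail first; 6 is still reported

    def test_open_segment_extends_to_contig_ends(self):
        # no host genes anywhere: the viral region reaches both contig ends
        specs = [(500, 1400, {})]
        specs += [(35000 + 3000 * i, 37000 + 3000 * i, dict(VIRAL)) for i in range(10)]
        assert estimate_provirus_fraction(make_contig(100000, specs)) == 1.0


class TestContamination:
    def test_pure_phage_is_clean(self):
        specs = [(100 + 800 * i, 700 + 800 * i, dict(VIRAL)) for i in range(8)]
        assert estimate_contamination(make_contig(10000, specs)) == 0.0

    def test_host_flanks_count(self):
        specs = [(100, 700, {})]  # evidence-free flank gene
        specs += [(1000 + 800 * i, 1600 + 800 * i, dict(VIRAL)) for i in range(8)]
        specs += [(8000, 8600, {})]
        contig = make_contig(10000, specs)
        assert estimate_contamination(contig) == pytest.approx(2 / 10)


class TestScreenAndRecovery:
    def test_circular_phage_becomes_complete_call(self, noisefree_community, noisefree_discovery):
        calls, _ = noisefree_discovery
        complete = {c.contig_id for c in calls if c.tier == "complete"}
        planted = {p.contig_id for p in noisefree_community.phages if p.circular}
        assert complete == planted
        for c in calls:
            if c.tier == "complete":
                assert c.circular and c.completeness == 1.0

    def test_circular_plasmid_not_called(self, noisefree_community, noisefree_discovery):
        calls, _ = noisefree_discovery
        called = {c.contig_id for c in calls}
        assert not any(cid.startswith("plasmid") for cid in called)

    def test_draft_recovery_tiers_match_truncation(self):
        rng = np.random.default_rng(3)
        src = generate_phage_genome(24000, n_hallmarks=3, circular=True, rng_seed=rng, contig_id="src")
        src.kmer_p = 0.01
        completes, _, _ = screen_circular([src])
        assert len(completes) == 1

        def fragment(ratio, cid):
            length = int(24000 * ratio)
            genes = [g for g in src.genes if g.end <= length]
            frag = ContigRecord(
                id=cid,
                seq=src.seq[:length],
                genes=[
                    GeneAnnotation(
                        gene_id=f"{cid}_{g.gene_id}", start=g.start, end=g.end, strand=g.strand,
                        protein_seq=g.protein_seq, viral_hallmark=g.viral_hallmark,
                        viral_db_hit=g.viral_db_hit,
                    )
                    for g in genes
                ],
                kmer_p=0.01,
            )
            frag.genes[0].viral_db_hit = frag.genes[-1].viral_db_hit = True
            if not any(g.viral_hallmark for g in frag.genes):
                frag.genes[0].viral_hallmark = True
            return frag

        recovered, _ = recover_linear([fragment(0.8, "f80"), fragment(0.5, "f50")], completes)
        by_id = {c.contig_id: c for c in recovered}
        assert "f80" in by_id and by_id["f80"].tier == "medium"
        assert by_id["f80"].completeness == pytest.approx(0.8, abs=0.01)
        assert "f50" not in by_id  # size ratio 0.5 is outside (0.7, 1.2)

    def test_unrelated_contig_not_recovered(self, noisefree_discovery):
        calls, _ = noisefree_discovery
        rng = np.random.default_rng(1)
        completes = [c for c in calls if c.tier == "complete"]
        stranger = ContigRecord(
            id="stranger",
            seq=random_dna(rng, len(completes[0].genome)),
            genes=[GeneAnnotation(gene_id="s_g1", start=100, end=700, protein_seq="MKLVW" * 40, viral_hallmark=True)],
            kmer_p=0.01,
        )
        recovered, _ = recover_linear([stranger], completes)
        assert recovered == []

    def test_complete_and_draft_ids_disjoint(self, noisefree_discovery):
        calls, _ = noisefree_discovery
        ids = [c.contig_id for c in calls]
        assert len(ids) == len(set(ids))

    def test_completeness_tier_bounds(self):
        assert completeness_tier(0.95) == "high"
        assert completeness_tier(0.9) == "high"
        assert completeness_tier(0.7) == "medium"
        assert completeness_tier(0.4) == "low"


class TestEvaluation:
    def test_tpr_arithmetic(self):
        calls, _ = run_discovery([])  # empty is fine for constructing calls manually
        from phageome.discovery import PhageCall

        calls = [
            PhageCall(f"p{i}", True, 1.0, 0.0, "complete", None, "A" * 10, ()) for i in range(8)
        ]
        truth = {f"p{i}": "phage" for i in range(10)}
        truth.update({f"n{i}": "plasmid" for i in range(20)})
        tpr, fpr = evaluate_pipeline(calls, truth)
        assert tpr == 0.8 and fpr == 0.0

    def test_empty_truth_raises(self):
        with pytest.raises(ValueError):
            evaluate_pipeline([], {})
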