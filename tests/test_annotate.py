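"""Captured genes, insertion sites, flank composition, fragment search, summary."""

import numpy as np
import pytest

from heliscan.annotate import (
    GeneModel,
    captured_genes,
    flank_at_content,
    fragment_search,
    insertion_site_check,
    promoter_interval,
    read_gene_models,
    summarize,
    CapturedGene,
)
from heliscan.families import HelitronElement
from heliscan.sequence import GenomeSequence, Interval, reverse_complement


def element(scaffold="s", start=100, end=400, strand="+", **kw):
    return HelitronElement(
        candidate_id=f"{scaffold}:{end}:{strand}",
        interval=Interval(scaffold, start, end, strand),
        family_id=1,
        start5_found=True,
        **kw,
    )


class TestCapturedGenes:
    def _genes(self):
        return [
            GeneModel("inside", Interval("s", 180, 250)),
            GeneModel("straddle", Interval("s", 350, 450)),
            GeneModel("outside", Interval("s", 600, 700)),
            GeneModel("in_rephel", Interval("s", 120, 160)),
            GeneModel("rephel", Interval("s", 110, 170), is_rephel=True),
        ]

    def test_containment_and_rephel_exclusion(self):
        got = captured_genes(
            element(), self._genes(), rephel_span=Interval("s", 110, 170)
        )
        assert [g.gene_id for g in got] == ["inside"]

    def test_straddling_gene_not_captured(self):
        got = captured_genes(element(), self._genes())
        assert "straddle" not in {g.gene_id for g in got}

    def test_gene_beyond_scaffold_rejected(self):
        genome = {"s": GenomeSequence("s", "ACGT" * 100)}
        with pytest.raises(ValueError):
            captured_genes(
                element(), [GeneModel("far", Interval("s", 390, 4000))],
                genome=genome,
            )

    def test_simulated_cargo_counts(self, small_sim):
        by_elem = {}
        for g in small_sim.genes:
            if not g.is_rephel:
                by_elem.setdefault(g.gene_id.rsplit("_", 1)[0], []).append(g)
        models = [
            GeneModel(g.gene_id, g.interval, g.name, g.is_rephel)
            for g in small_sim.genes
        ]
        n = 0
        for t in small_sim.truth:
            if t.truncated:
                continue
            el = element(
                t.interval.scaffold, t.interval.start, t.interval.end,
                t.interval.strand,
            )
            got = captured_genes(el, models, rephel_span=t.rephel)
            assert len(got) == len(t.cargo)
            n += 1
        assert n >= 10

    def test_gff3_round_trip(self, tmp_path, small_sim):
        from heliscan.simulate import write_genes_gff3

        p = tmp_path / "genes.gff3"
        write_genes_gff3(small_sim.genes, p)
        models = read_gene_models(p)
        assert len(models) == len(small_sim.genes)
        assert sum(m.is_rephel for m in models) == sum(
            g.is_rephel for g in small_sim.genes
        )


class TestInsertionSite:
    def _genome(self, left, right):
        return {"s": GenomeSequence("s", "G" * 98 + left + "C" * 301 + right + "G" * 99)}

    def test_at_junction_true(self):
        res = insertion_site_check(element(start=100, end=400), self._genome("A", "T"))
        assert res.at_site is True and res.dinucleotide == "AT"

    def test_wrong_left_base_false(self):
        res = insertion_site_check(element(start=100, end=400), self._genome("G", "T"))
        assert res.at_site is False

    def test_edge_indeterminate(self):
        genome = {"s": GenomeSequence("s", "A" * 400)}
        res = insertion_site_check(element(start=1, end=400), genome)
        assert res.at_site is None

    def test_all_planted_elements_inserted_at_AT(self, small_sim, small_genome_map):
        for t in small_sim.truth:
            el = element(
                t.interval.scaffold, t.interval.start, t.interval.end,
                t.interval.strand,
            )
            assert insertion_site_check(el, small_genome_map).at_site is True


class TestFlanks:
    def test_pure_at_flanks(self):
        g = {"s": GenomeSequence("s", "AT" * 50 + "G" * 100 + "TA" * 50)}
        res = flank_at_content(element(start=101, end=200), g, flank=50)
        assert (res.at5, res.at3, res.mean) == (1.0, 1.0, 1.0)

    def test_zero_flank_rejected(self):
        g = {"s": GenomeSequence("s", "A" * 400)}
        with pytest.raises(ValueError):
            flank_at_content(element(), g, flank=0)

    def test_minus_strand_orientation(self):
        left = "A" * 50
        right = "G" * 50
        g = {"s": GenomeSequence("s", "C" * 50 + left + "T" * 100 + right + "C" * 50)}
        el = element(start=101, end=200, strand="-")
        res = flank_at_content(el, g, flank=50)
        # element-strand 5' flank is the right (plus) flank, revcomp'd
        assert res.at5 == 0.0 and res.at3 == 1.0

    def test_simulated_flank_enrichment_recovered(self, small_sim, small_genome_map):
        vals = []
        for t in small_sim.truth:
            el = element(
                t.interval.scaffold, t.interval.start, t.interval.end,
                t.interval.strand,
            )
            vals.append(flank_at_content(el, small_genome_map).mean)
        mean = float(np.mean(vals))
        assert mean == pytest.approx(0.57, abs=0.03)


class TestFragmentSearch:
    def test_exact_copy(self, rng):
        q = "".join(rng.choice(list("ACGT"), 60))
        g = [GenomeSequence("s", "".join(rng.choice(list("ACGT"), 500)) + q + "".join(rng.choice(list("ACGT"), 500)))]
        hits = fragment_search(q, g)
        assert any(
            h.length == 60 and h.identity == 100.0 and h.genomic.start == 501
            for h in hits
        )

    def test_two_mismatch_copy(self, rng):
        q = "".join(rng.choice(list("ACGT"), 60))
        mut = list(q)
        mut[25] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[25]]
        mut[35] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mut[35]]
        g = [GenomeSequence("s", "C" * 300 + "".join(mut) + "G" * 300)]
        hits = fragment_search(q, g)
        assert any(
            h.length == 60 and h.identity == pytest.approx(96.67, abs=0.01)
            for h in hits
        )

    def test_minus_strand_copy_found(self, rng):
        q = "".join(rng.choice(list("ACGT"), 80))
        g = [
            GenomeSequence(
                "s",
                "".join(rng.choice(list("ACGT"), 400))
                + reverse_complement(q)
                + "".join(rng.choice(list("ACGT"), 400)),
            )
        ]
        hits = fragment_search(q, g)
        assert any(h.genomic.strand == "-" and h.length >= 80 for h in hits)

    def test_short_query_rejected(self):
        with pytest.raises(ValueError):
            fragment_search("ACGT", [GenomeSequence("s", "ACGT" * 100)])

    def test_thresholds_strict(self, rng):
        # a 50-bp exact copy does NOT qualify (> 50 bp required)
        q = "".join(rng.choice(list("ACGT"), 50))
        g = [GenomeSequence("s", "C" * 200 + q + "G" * 200)]
        hits = [h for h in fragment_search(q, g, min_len=50) if h.length <= 50]
        assert hits == []

    def test_matches_sliding_window_oracle(self, rng):
        # plant several degraded copies in a 10-kb toy genome and compare
        # against a per-diagonal exhaustive segment oracle
        q = "".join(rng.choice(list("ACGT"), 120))
        bg = "".join(rng.choice(list("ACGT"), 10_000))
        copies = []
        pos = 1000
        for nmut in (0, 2, 4):
            c = list(q)
            for i in rng.choice(len(q), nmut, replace=False):
                c[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[c[i]]
            copies.append((pos, "".join(c)))
            pos += 2000
        g = bg
        for p, c in copies:
            g = g[:p] + c + g[p + len(c):]
        hits = fragment_search(q, [GenomeSequence("s", g)])
        plus_hits = [h for h in hits if h.genomic.strand == "+"]
        # every planted copy must be recovered as (at least) one hit whose
        # span covers the copy's high-identity core
        for p, c in copies:
            ident = sum(a == b for a, b in zip(q, c)) / len(q)
            if ident <= 0.95:
                continue
            assert any(
                h.genomic.start <= p + 10 and h.genomic.end >= p + len(c) - 10
                for h in plus_hits
            )
        # and every reported hit must verify against a recount
        for h in plus_hits:
            frag_g = g[h.genomic.start - 1 : h.genomic.end]
            frag_q = q[h.query_start - 1 : h.query_end]
            matches = sum(a == b for a, b in zip(frag_q, frag_g))
            assert matches / h.length * 100.0 == pytest.approx(h.identity)
            assert h.length > 50 and h.identity > 95.0


class TestPromoter:
    def test_rephel_to_gene_interval(self):
        span = Interval("s", 100, 400, "+")
        gene = CapturedGene("g", Interval("s", 600, 800))
        iv = promoter_interval(span, gene)
        assert (iv.start, iv.end) == (100, 600)

    def test_gene_inside_span_gives_none(self):
        span = Interval("s", 100, 400, "+")
        gene = CapturedGene("g", Interval("s", 50, 90))
        assert promoter_interval(span, gene) is None


class TestSummary:
    def _genomes(self):
        return [
            GenomeSequence("sc1", "ACGT" * 500_000),
            GenomeSequence("sc2", "ACGT" * 250_000),
        ]

    def test_published_style_size(self):
        e = element("sc1", 1_404_200, 1_417_948)
        stats, rows = summarize([e], self._genomes())
        assert rows[0]["size_kb"] == "13.7"

    def test_comma_separator(self):
        e = element("sc1", 1_404_200, 1_417_948)
        _, rows = summarize([e], self._genomes(), decimal_sep=",")
        assert rows[0]["size_kb"] == "13,7"

    def test_empty_elements(self):
        stats, rows = summarize([], self._genomes())
        assert stats.element_count == 0 and stats.genome_fraction_pct == 0.0
        assert rows == []

    def test_family_counts_conserved_and_fraction_invariant(self):
        els = [
            element("sc1", 1000 + 5000 * i, 3000 + 5000 * i)
            for i in range(4)
        ]
        for i, e in enumerate(els):
            e.family_id = 1 + i % 2
        genomes = self._genomes()
        stats, _ = summarize(els, genomes)
        assert sum(stats.per_family.values()) == stats.element_count == 4
        stats_perm, _ = summarize(els, genomes[::-1])
        assert stats_perm.genome_fraction_pct == stats.genome_fraction_pct
        expected = 100.0 * sum(e.interval.length for e in els) / 3_000_000
        assert stats.genome_fraction_pct == pytest.approx(expected)
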