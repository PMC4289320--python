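"""RepHel motif scanning, window extraction and autonomy calls."""

import numpy as np
import pytest

from heliscan.helend import scan_genome
from heliscan.rephel import (
    AutonomyPolicy,
    MotifModel,
    call_autonomous,
    extract_upstream_window,
    import_domain_table,
    load_motif_models,
    parse_pattern,
    scan_candidate_window,
    scan_motifs,
    _prot_to_genomic,
)
from heliscan.sequence import translate_frame
from heliscan.simulate import rephel_orf_dna

AA = "ACDEFGHIKLMNPQRSTVWY"


def oracle_scan(protein, models):
    hits = []
    for m in models:
        for off in range(len(protein) - m.length + 1):
            score = sum(
                1
                for k, allowed in enumerate(m.positions)
                if not allowed or protein[off + k] in allowed
            )
            if score >= m.min_score:
                hits.append((m.name, off + 1, off + m.length, score))
    return sorted(hits)


class TestMotifModels:
    def test_shipped_config_loads(self):
        models = load_motif_models()
        names = {m.name for m in models}
        assert {"rep1", "rep2", "rep3", "helI", "helII", "helVI"} <= names
        for m in models:
            assert 0 < m.min_score <= m.length

    def test_pattern_parsing(self):
        pos = parse_pattern("G[SA]xK")
        assert pos[0] == frozenset("G")
        assert pos[1] == frozenset("SA")
        assert pos[2] == frozenset()
        assert pos[3] == frozenset("K")

    def test_bad_pattern_rejected(self):
        with pytest.raises(ValueError):
            parse_pattern("G[]K")
        with pytest.raises(ValueError):
            MotifModel("m", parse_pattern("GK"), min_score=3)


class TestScanMotifs:
    def test_consensus_scores_full_length(self):
        models = load_motif_models()
        m = models[0]
        hits = scan_motifs(m.consensus, [m])
        assert (m.name, 1, m.length, m.length) in hits

    def test_too_short_protein_no_hits(self):
        models = load_motif_models()
        assert scan_motifs("MK", models) == []

    def test_matches_per_offset_oracle_on_random_proteins(self, rng):
        models = load_motif_models()
        for _ in range(30):
            protein = "".join(rng.choice(list(AA), 120))
            assert sorted(scan_motifs(protein, models)) == oracle_scan(
                protein, models
            )


@pytest.fixture(scope="module")
def sim_candidates(small_sim, small_genome_map):
    cands = scan_genome(small_sim.genome)
    truth = {
        (t.interval.scaffold, t.end3, t.interval.strand): t
        for t in small_sim.truth
    }
    planted = [
        (c, truth[(c.scaffold, c.end3, c.strand)])
        for c in cands
        if (c.scaffold, c.end3, c.strand) in truth
    ]
    return planted


class TestWindows:
    def test_window_is_upstream_of_helend(self, sim_candidates, small_genome_map):
        for cand, _ in sim_candidates[:5]:
            win = extract_upstream_window(cand, small_genome_map, 3600)
            assert len(win.seq) <= 3600
            if cand.strand == "+":
                assert win.hi == cand.hairpin.arm5_interval.start - 1
            else:
                assert win.lo == cand.hairpin.arm5_interval.end + 1

    def test_edge_clip_flagged(self, small_genome_map):
        from conftest import make_candidate
        import dataclasses
        from heliscan.helend import Hairpin
        from heliscan.sequence import Interval

        c = make_candidate("A" * 26 + "CTGG", scaffold="scaffold_1", end3=300)
        arm = Interval("scaffold_1", 250, 259, "+")
        c = dataclasses.replace(
            c, hairpin=Hairpin(arm, arm, 3, 10, 0, 6)
        )
        win = extract_upstream_window(c, small_genome_map, 3600)
        assert win.edge_clipped and win.lo == 1 and len(win.seq) == 249

    def test_protein_to_genomic_round_trip(self, sim_candidates, small_genome_map):
        cand, _ = sim_candidates[0]
        win = extract_upstream_window(cand, small_genome_map, 3600)
        for frame in (0, 1, 2):
            for p1, p2 in ((1, 10), (7, 33)):
                iv = _prot_to_genomic(win, frame, p1, p2)
                assert iv.length == 3 * (p2 - p1 + 1)
                # invert the mapping
                if win.strand == "+":
                    off = iv.start - win.lo
                else:
                    off = win.hi - iv.end
                assert off % 3 == frame or (off - frame) % 3 == 0
                assert (off - frame) // 3 + 1 == p1


class TestAutonomy:
    def test_planted_rephel_elements_called_autonomous(
        self, sim_candidates, small_genome_map
    ):
        models = load_motif_models()
        n_auto = n_non = 0
        for cand, truth in sim_candidates:
            win = extract_upstream_window(cand, small_genome_map, 3600)
            hits = scan_candidate_window(win, models)
            call = call_autonomous(win, hits)
            assert call.autonomous == truth.autonomous
            n_auto += truth.autonomous
            n_non += not truth.autonomous
        assert n_auto >= 5 and n_non >= 5

    def test_helicase_only_is_orphan_not_autonomous(self):
        from heliscan.rephel import HEL_MOTIFS, WindowInfo

        models = load_motif_models()
        by_name = {m.name: m for m in models}
        protein = "M" + "GGSGGS".join(by_name[n].consensus for n in HEL_MOTIFS)
        dna = "".join(
            {"*": "TAA"}.get(aa)
            or __import__("heliscan.simulate", fromlist=["x"])._AA_TO_CODON[aa]
            for aa in protein
        )
        win = WindowInfo("c1", "s", dna, 1, len(dna), "+", False)
        hits = scan_candidate_window(win, models)
        call = call_autonomous(win, hits)
        assert not call.autonomous
        assert call.orphan_helicase
        assert len(call.hel_motifs) >= 4

    def test_empty_hits_non_autonomous(self):
        from heliscan.rephel import WindowInfo

        win = WindowInfo("c1", "s", "ACG" * 50, 1, 150, "+", False)
        call = call_autonomous(win, [])
        assert not call.autonomous and call.rephel_span is None

    def test_rep_must_precede_helicase(self):
        from heliscan.rephel import HEL_MOTIFS, REP_MOTIFS, WindowInfo
        from heliscan.simulate import _protein_to_dna

        models = load_motif_models()
        by_name = {m.name: m for m in models}
        wrong = "M" + "GGSGGS".join(
            by_name[n].consensus for n in HEL_MOTIFS + REP_MOTIFS
        )
        win = WindowInfo("c1", "s", _protein_to_dna(wrong), 1, len(wrong) * 3, "+", False)
        call = call_autonomous(win, scan_candidate_window(win, models))
        assert not call.autonomous


class TestExternalTable:
    def _window(self, sim_candidates, small_genome_map):
        cand, _ = sim_candidates[0]
        return extract_upstream_window(cand, small_genome_map, 3600)

    def test_evalue_cutoff_drops_rows(self, tmp_path, sim_candidates, small_genome_map):
        win = self._window(sim_candidates, small_genome_map)
        p = tmp_path / "hits.tsv"
        p.write_text(
            f"{win.query_id(0)}\tPF14214\t10\t40\t0.5\n"
            f"{win.query_id(0)}\tPF05970\t60\t90\t1e-6\n"
        )
        hits = import_domain_table(p, [win])
        assert [h.motif for h in hits] == ["PF05970"]

    def test_coordinate_arithmetic(self, tmp_path, sim_candidates, small_genome_map):
        win = self._window(sim_candidates, small_genome_map)
        p = tmp_path / "hits.tsv"
        p.write_text(f"{win.query_id(1)}\tPF14214\t10\t20\t1e-9\n")
        (hit,) = import_domain_table(p, [win])
        if win.strand == "+":
            assert hit.genomic.start == win.lo + 1 + 3 * (10 - 1)
        else:
            assert hit.genomic.end == win.hi - 1 - 3 * (10 - 1)

    def test_unknown_query_id_listed(self, tmp_path, sim_candidates, small_genome_map):
        win = self._window(sim_candidates, small_genome_map)
        p = tmp_path / "hits.tsv"
        p.write_text("nosuch|f0\tPF14214\t1\t5\t1e-9\n")
        with pytest.raises(ValueError, match="nosuch"):
            import_domain_table(p, [win])

    def test_empty_table_empty_hits(self, tmp_path, sim_candidates, small_genome_map):
        win = self._window(sim_candidates, small_genome_map)
        p = tmp_path / "hits.tsv"
        p.write_text("")
        assert import_domain_table(p, [win]) == []

    def test_external_policy_overrides_builtin(
        self, tmp_path, sim_candidates, small_genome_map
    ):
        # pick a planted non-autonomous candidate; an external table
        # asserting both domains must win over the (empty) builtin signal
        models = load_motif_models()
        for cand, truth in sim_candidates:
            if not truth.autonomous:
                break
        win = extract_upstream_window(cand, small_genome_map, 3600)
        p = tmp_path / "hits.tsv"
        p.write_text(
            f"{win.query_id(0)}\tPF14214\t10\t40\t1e-9\n"
            f"{win.query_id(0)}\tPF05970\t60\t90\t1e-9\n"
        )
        ext = import_domain_table(p, [win])
        call = call_autonomous(
            win, scan_candidate_window(win, models), external_hits=ext
        )
        assert call.autonomous and call.policy == "external"


class TestOrfBuilder:
    def test_orf_contains_all_motifs_in_order(self):
        models = load_motif_models()
        dna = rephel_orf_dna()
        protein = translate_frame(dna, 0)
        hits = scan_motifs(protein, models)
        names = {h[0] for h in hits}
        assert names == {m.name for m in models}

    def test_randomized_orfs_diverge_at_dna_level(self):
        rng1 = np.random.default_rng(1)
        rng2 = np.random.default_rng(2)
        a, b = rephel_orf_dna(rng=rng1), rephel_orf_dna(rng=rng2)
        n = min(len(a), len(b))
        ident = sum(x == y for x, y in zip(a[:n], b[:n])) / n
        assert ident < 0.7
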