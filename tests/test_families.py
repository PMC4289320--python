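"""Family clustering, 5' boundary recovery and element naming."""

import networkx as nx
import numpy as np
import pytest

from conftest import make_candidate
from heliscan.families import (
    HelitronElement,
    assign_subfamilies,
    build_elements,
    cluster_families,
    end_identity,
    five_prime_30mer,
    locate_5prime_boundary,
    name_elements,
)
from heliscan.helend import scan_genome
from heliscan.sequence import Interval


def mutate_end30(base: str, n: int, rng) -> str:
    pos = rng.choice(30, size=n, replace=False)
    arr = list(base)
    for i in pos:
        arr[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arr[i]]
    return "".join(arr)


class TestEndIdentity:
    def test_identical(self):
        assert end_identity("A" * 30, "A" * 30) == 100.0

    def test_inclusive_family_boundary_at_80(self, rng):
        base = "".join(rng.choice(list("ACGT"), 30))
        assert end_identity(base, mutate_end30(base, 6, rng)) == pytest.approx(80.0)

    def test_seven_differences_fall_below(self, rng):
        base = "".join(rng.choice(list("ACGT"), 30))
        ident = end_identity(base, mutate_end30(base, 7, rng))
        assert ident == pytest.approx(76.67, abs=0.01)

    def test_unequal_length_rejected(self):
        with pytest.raises(ValueError):
            end_identity("ACGT", "ACG")

    def test_n_never_matches(self):
        assert end_identity("NNNN", "NNNN") == 0.0


class TestClusterFamilies:
    def test_transitive_closure(self, rng):
        a = "".join(rng.choice(list("ACGT"), 30))
        b = mutate_end30(a, 5, rng)  # 83.3% to a
        c = mutate_end30(b, 5, rng)  # 83.3% to b, typically < 80% to a
        cands = [
            make_candidate(a, end3=100, cid="A"),
            make_candidate(b, end3=300, cid="B"),
            make_candidate(c, end3=500, cid="C"),
        ]
        fams = cluster_families(cands)
        assert len(fams) == 1
        assert sorted(fams[0].members) == ["A", "B", "C"]

    def test_all_dissimilar_gives_singletons(self, rng):
        cands = [
            make_candidate("".join(rng.choice(list("ACGT"), 30)), end3=100 * (i + 1),
                           cid=f"c{i}")
            for i in range(8)
        ]
        fams = cluster_families(cands)
        assert len(fams) == 8

    def test_matches_graph_components_oracle(self, rng):
        # mixture: a few seeded clusters plus random singletons
        seeds = ["".join(rng.choice(list("ACGT"), 30)) for _ in range(4)]
        end30s = []
        for i in range(50):
            if i < 30:
                end30s.append(mutate_end30(seeds[i % 4], int(rng.integers(0, 5)), rng))
            else:
                end30s.append("".join(rng.choice(list("ACGT"), 30)))
        cands = [
            make_candidate(e, end3=1000 + 50 * i, cid=f"c{i}")
            for i, e in enumerate(end30s)
        ]
        got = {frozenset(f.members) for f in cluster_families(cands)}
        g = nx.Graph()
        g.add_nodes_from(c.candidate_id for c in cands)
        for i in range(50):
            for j in range(i + 1, 50):
                if end_identity(end30s[i], end30s[j]) >= 80.0:
                    g.add_edge(f"c{i}", f"c{j}")
        oracle = {frozenset(comp) for comp in nx.connected_components(g)}
        assert got == oracle

    def test_family_ids_by_size_then_coordinate(self, rng):
        a = "".join(rng.choice(list("ACGT"), 30))
        b = "".join(rng.choice(list("ACGT"), 30))
        cands = [
            make_candidate(b, end3=100, cid="lone"),
            make_candidate(a, end3=500, cid="x1"),
            make_candidate(a, end3=900, cid="x2"),
        ]
        fams = cluster_families(cands)
        assert len(fams[0].members) == 2 and fams[0].family_id == 1

    def test_edge_truncated_candidates_quarantined(self, rng):
        import dataclasses

        c = make_candidate("".join(rng.choice(list("ACGT"), 30)), cid="ok")
        short = dataclasses.replace(
            make_candidate("ACGTACGTAC" * 2, cid="short"),
            end30_truncated=True,
        )
        fams = cluster_families([c, short])
        assert all("short" not in f.members for f in fams)


class TestBoundaries:
    def test_planted_copies_recover_exact_5prime_start(self, small_sim, small_genome_map):
        cands = scan_genome(small_sim.genome)
        by_key = {(c.scaffold, c.end3, c.strand): c for c in cands}
        fams = cluster_families(cands)
        by_id = {c.candidate_id: c for c in cands}
        truth_by_key = {
            (t.interval.scaffold, t.end3, t.interval.strand): t
            for t in small_sim.truth
        }
        checked = 0
        for fam in fams:
            members = [by_id[m] for m in fam.members]
            truths = [
                truth_by_key.get((m.scaffold, m.end3, m.strand)) for m in members
            ]
            if sum(t is not None for t in truths) < 4:
                continue  # not a planted family
            for m, t in zip(members, truths):
                if t is None or t.truncated:
                    continue
                start5 = locate_5prime_boundary(m, members, small_genome_map)
                expected = (
                    t.interval.start if t.interval.strand == "+" else t.interval.end
                )
                assert start5 == expected
                checked += 1
        assert checked >= 15

    def test_random_upstream_means_truncated(self, small_sim, small_genome_map):
        cands = scan_genome(small_sim.genome)
        truth_keys = {
            (t.interval.scaffold, t.end3, t.interval.strand)
            for t in small_sim.truth
        }
        noise = [
            c for c in cands if (c.scaffold, c.end3, c.strand) not in truth_keys
        ]
        # chance candidates have unrelated upstream context: no boundary
        n = 0
        for c in noise[:10]:
            assert (
                locate_5prime_boundary(c, noise[:10], small_genome_map) is None
            )
            n += 1
        assert n == 10

    def test_boundary_begins_with_t_cg(self, small_sim, small_genome_map):
        cands = scan_genome(small_sim.genome)
        fams = cluster_families(cands)
        big = [f for f in fams if len(f.members) >= 4]
        elements = build_elements(cands, big, small_genome_map)
        saw = 0
        for e in elements:
            if not e.start5_found:
                continue
            head = five_prime_30mer(e, small_genome_map)
            assert head[0] == "T" and head[1] in "CG"
            saw += 1
        assert saw >= 10


class TestSubfamilies:
    def _elements(self, small_sim, small_genome_map):
        cands = scan_genome(small_sim.genome)
        by_id = {c.candidate_id: c for c in cands}
        truth_keys = {
            (t.interval.scaffold, t.end3, t.interval.strand)
            for t in small_sim.truth
        }
        fams = [
            f
            for f in cluster_families(cands)
            if sum(
                (by_id[m].scaffold, by_id[m].end3, by_id[m].strand) in truth_keys
                for m in f.members
            )
            >= 4
        ]
        elements = build_elements(cands, fams, small_genome_map)
        return cands, fams, elements

    def test_two_subfamilies_per_planted_family(self, small_sim, small_genome_map):
        cands, fams, elements = self._elements(small_sim, small_genome_map)
        for f in fams:
            subs = assign_subfamilies(f, elements, small_genome_map)
            assert len(subs) == 2
            # partition refines the family
            assert sorted(m for ids in subs.values() for m in ids) == sorted(
                e.candidate_id
                for e in elements
                if e.family_id == f.family_id and e.start5_found
            )

    def test_identical_5prime_ends_one_subfamily(self, small_sim, small_genome_map):
        cands, fams, elements = self._elements(small_sim, small_genome_map)
        f = fams[0]
        subs = assign_subfamilies(f, elements, small_genome_map)
        by_id = {e.candidate_id: e for e in elements}
        for ids in subs.values():
            if len(ids) < 2:
                continue
            heads = [five_prime_30mer(by_id[i], small_genome_map) for i in ids]
            for h in heads[1:]:
                assert end_identity(heads[0], h) >= 80.0


class TestNaming:
    def _element(self, fam_id, sub_id, autonomous):
        return HelitronElement(
            candidate_id=f"e{fam_id}{sub_id}",
            interval=Interval("s", 100, 200, "+"),
            family_id=fam_id,
            subfamily_id=sub_id,
            start5_found=True,
            autonomous=autonomous,
        )

    def test_case_encodes_autonomy(self):
        a = self._element(1, 1, True)
        b = self._element(1, 3, False)
        name_elements([a, b], prefix="HELPO")
        assert a.name == "HELPO1.1"
        assert b.name == "helpo1.3"

    def test_no_subfamily_uses_family_only(self):
        e = self._element(2, None, False)
        name_elements([e], prefix="HELPO")
        assert e.name == "helpo2"

    def test_naming_deterministic(self):
        e = self._element(1, 2, True)
        name_elements([e], prefix="HEL")
        first = e.name
        name_elements([e], prefix="HEL")
        assert e.name == first
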