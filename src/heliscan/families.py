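"""Family/subfamily classification of helend candidates and boundary calls.

Elements sharing at least 80% identity over the terminal 30 bp of the 3'
end belong to one family; the rule is a pairwise relation, so families
are its single-linkage transitive closure, which makes the partition
well-defined and deterministic. Families whose members drop below 80%
identity over the 5'-terminal 30 bp split into subfamilies the same way.

The 5' boundary of an element cannot be read off the helend; it is
recovered by conservation: sibling copies of a family share sequence from
the 5' T[C/G] start to the 3' terminus, while their flanks are unrelated
(helitrons make no target-site duplication), so the conserved block ends
exactly at the element boundary. An element with a located 5' start is
*intact*; one with only the 3' helend is *truncated*.
"""

from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Iterable, Optional, Sequence

import numpy as np

from .helend import HelendCandidate
from .sequence import GenomeSequence, Interval, reverse_complement


def end_identity(a: str, b: str) -> float:
    """Gapless percent identity of two equal-length end 30-mers.

    Positions where either sequence has N never count as a match.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths {len(a)} != {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    a, b = a.upper(), b.upper()
    matches = sum(
        1 for x, y in zip(a, b) if x == y and x != "N"
    )
    return matches / len(a) * 100.0


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


@dataclasses.dataclass
class HelitronFamily:
    family_id: int
    members: list[str]  # candidate ids
    consensus_end30: str
    subfamilies: dict[int, list[str]] = dataclasses.field(default_factory=dict)


def _consensus(seqs: Sequence[str]) -> str:
    if not seqs:
        return ""
    length = min(len(s) for s in seqs)
    cols = []
    for i in range(length):
        counts = Counter(s[i] for s in seqs if s[i] != "N")
        cols.append(counts.most_common(1)[0][0] if counts else "N")
    return "".join(cols)


def _single_linkage(keys: Sequence[str], threshold: float) -> list[list[int]]:
    """Indices grouped by single-linkage closure of identity >= threshold."""
    n = len(keys)
    uf = _UnionFind(n)
    if n > 300 and len({len(k) for k in keys}) == 1:
        # blockwise vectorized pairwise comparison for genome-scale inputs
        L = len(keys[0])
        mat = np.frombuffer("".join(keys).encode(), dtype=np.uint8).reshape(n, L)
        valid = mat != ord("N")
        need = threshold / 100.0 * L - 1e-9
        step = max(1, 2_000_000 // max(n, 1))
        for i0 in range(0, n, step):
            blk = mat[i0 : i0 + step]
            bval = valid[i0 : i0 + step]
            eq = (blk[:, None, :] == mat[None, :, :]) & bval[:, None, :]
            scores = eq.sum(axis=2)
            ii, jj = np.nonzero(scores >= need)
            for a, b in zip(ii, jj):
                if i0 + a != b:
                    uf.union(i0 + int(a), int(b))
    else:
        for i in range(n):
            for j in range(i + 1, n):
                if end_identity(keys[i], keys[j]) >= threshold - 1e-9:
                    uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    return list(groups.values())


def cluster_families(
    candidates: Sequence[HelendCandidate], threshold: float = 80.0
) -> list[HelitronFamily]:
    """Group candidates into families by 3'-end 30-mer identity.

    Candidates with edge-truncated end30 are quarantined (excluded).
    Family ids are assigned by descending member count, ties broken by
    the leftmost genomic coordinate of the family's members.
    """
    usable = [c for c in candidates if not c.end30_truncated]
    groups = _single_linkage([c.end30 for c in usable], threshold)

    def sort_key(group: list[int]):
        leftmost = min(
            (usable[i].scaffold, usable[i].motif_interval.start) for i in group
        )
        return (-len(group), leftmost)

    groups.sort(key=sort_key)
    families = []
    for fid, group in enumerate(groups, start=1):
        members = sorted(
            group, key=lambda i: (usable[i].scaffold, usable[i].motif_interval.start)
        )
        families.append(
            HelitronFamily(
                family_id=fid,
                members=[usable[i].candidate_id for i in members],
                consensus_end30=_consensus([usable[i].end30 for i in members]),
            )
        )
    return families


# ------------------------------------------------------- 5' boundaries


def upstream_window(
    candidate: HelendCandidate, genome: dict[str, GenomeSequence], window: int
) -> str:
    """Element-strand-oriented sequence ending at the 3'-terminal base."""
    seq = genome[candidate.scaffold]
    if candidate.strand == "+":
        lo = max(1, candidate.end3 - window + 1)
        return seq.slice1(lo, candidate.end3)
    hi = min(seq.length, candidate.end3 + window - 1)
    return reverse_complement(seq.slice1(candidate.end3, hi))


def _end_anchored_matches(a: str, b: str) -> np.ndarray:
    """match[k] (k>=1): do a and b agree k bases before their 3' ends?"""
    n = min(len(a), len(b))
    xa = np.frombuffer(a[-n:].encode(), dtype=np.uint8)
    xb = np.frombuffer(b[-n:].encode(), dtype=np.uint8)
    m = (xa == xb) & (xa != ord("N"))
    return m[::-1]  # index 0 = last base


def _member_profiles(
    candidate: HelendCandidate,
    others: Sequence[HelendCandidate],
    genome: dict[str, GenomeSequence],
    window: int,
    block: int = 30,
) -> tuple[str, list[tuple[np.ndarray, np.ndarray]]]:
    """Candidate window plus, per sibling, (end-anchored match array,
    sliding ``block``-sum of matches)."""
    wc = upstream_window(candidate, genome, window)
    profiles = []
    kernel = np.ones(block, dtype=np.int32)
    for other in others:
        wo = upstream_window(other, genome, window)
        m = _end_anchored_matches(wc, wo)
        if len(m) < block:
            continue
        sums = np.convolve(m.astype(np.int32), kernel, mode="valid")
        profiles.append((m, sums))
    return wc, profiles


def _supporters_at(
    profiles, d: int, need: float, block: int = 30
) -> list[np.ndarray]:
    """Match arrays of siblings whose window at distance d is conserved."""
    out = []
    for m, sums in profiles:
        if d <= len(m) and sums[d - block] >= need:
            out.append(m)
    return out


def _conserved_edge(
    wc: str,
    profiles,
    window: int,
    threshold: float,
    guard: int = 6,
) -> Optional[int]:
    """Farthest distance d from the 3' end at which the candidate is still
    conserved with >= 1 sibling, requiring the ``guard`` bases at the
    window start to agree with every supporting sibling (chance flank
    matches must not inflate the edge; the shared insertion-junction base
    still leaves ~1-2 bp of slack)."""
    need = threshold / 100.0 * 30 - 1e-9
    for d in range(min(window, len(wc)), 30, -1):
        sup = _supporters_at(profiles, d, need)
        if sup and all(
            all(m[d - 1 - g] for g in range(min(guard, d - 1)))
            for m in sup
        ):
            return d
    return None


def _snap_to_tcg(wc: str, edge: int, slack: int = 3) -> Optional[int]:
    """Largest d in [edge-slack, edge] whose window start reads T[C/G]."""
    lc = len(wc)
    for d in range(edge, max(30, edge - slack) - 1, -1):
        if d > lc:
            continue
        if wc[lc - d] == "T" and wc[lc - d + 1] in "CG":
            return d
    return None


def locate_family_boundaries(
    members: Sequence[HelendCandidate],
    genome: dict[str, GenomeSequence],
    window: int = 3000,
    threshold: float = 80.0,
) -> tuple[dict[str, Optional[int]], dict[str, Optional[int]]]:
    """Joint 5' boundary calls for all members of one family.

    Per member, the candidate boundary is the conservation edge (how far
    upstream of the 3' terminus sibling identity persists) snapped to
    the nearest T[C/G] start within a few bases. A truncation cut is
    itself a conservation edge, so an edge alone does not prove a 5'
    end: the boundary *depth* must recur — at least two members must
    snap to the same distance from the 3' terminus, which truncation
    cuts (uniform per copy) essentially never do, while genuine element
    starts always do. Members without a recurring snapped edge are
    truncated.

    Returns (boundary depth per member or None, conservation edge per
    member or None); depths are distances from the 3' terminal base,
    i.e. the element length when intact.
    """
    starts: dict[str, Optional[int]] = {m.candidate_id: None for m in members}
    edges: dict[str, Optional[int]] = {m.candidate_id: None for m in members}
    if len(members) < 2:
        return starts, edges
    snapped: dict[str, Optional[int]] = {}
    for cand in members:
        others = [m for m in members if m.candidate_id != cand.candidate_id]
        wc, profiles = _member_profiles(cand, others, genome, window)
        if not profiles:
            snapped[cand.candidate_id] = None
            continue
        edge = _conserved_edge(wc, profiles, window, threshold)
        edges[cand.candidate_id] = edge
        snapped[cand.candidate_id] = (
            _snap_to_tcg(wc, edge) if edge is not None else None
        )
    counts = Counter(d for d in snapped.values() if d is not None)
    for cid, d in snapped.items():
        if d is not None and counts[d] >= 2:
            starts[cid] = d
    return starts, edges


def locate_5prime_boundary(
    candidate: HelendCandidate,
    family_members: Sequence[HelendCandidate],
    genome: dict[str, GenomeSequence],
    window: int = 3000,
    threshold: float = 80.0,
) -> Optional[int]:
    """Genomic plus-strand coordinate of one element's 5' start, or None.

    Convenience wrapper over :func:`locate_family_boundaries`; the
    boundary exists when the candidate's conservation edge snaps to a
    T[C/G] start at a depth shared with at least one sibling. None for
    singletons or members without such a conserved start (truncated).
    """
    starts, _ = locate_family_boundaries(
        list(family_members), genome, window, threshold
    )
    d = starts.get(candidate.candidate_id)
    if d is None:
        return None
    if candidate.strand == "+":
        return candidate.end3 - d + 1
    return candidate.end3 + d - 1


def conserved_extent(
    candidate: HelendCandidate,
    family_members: Sequence[HelendCandidate],
    genome: dict[str, GenomeSequence],
    window: int = 3000,
    threshold: float = 80.0,
    guard: int = 6,
) -> Optional[int]:
    """Farthest-upstream conserved distance from the 3' end (bp), or None.

    Used to delimit truncated elements (their 5' extent is whatever
    sibling conservation supports, without a T[C/G] start).
    """
    others = [m for m in family_members if m.candidate_id != candidate.candidate_id]
    if not others:
        return None
    wc, profiles = _member_profiles(candidate, others, genome, window)
    if not profiles:
        return None
    return _conserved_edge(wc, profiles, window, threshold, guard)


# ------------------------------------------------------------ elements


@dataclasses.dataclass
class HelitronElement:
    """A classified helitron element (autonomy filled in by the RepHel stage)."""

    candidate_id: str
    interval: Interval
    family_id: int
    subfamily_id: Optional[int] = None
    start5_found: bool = False
    end3_found: bool = True
    autonomous: bool = False
    name: str = ""
    boundary_method: str = "conservation"  # or "homology" / "helend-only"
    rephel_span: Optional[Interval] = None
    captured_gene_ids: list[str] = dataclasses.field(default_factory=list)

    @property
    def status(self) -> str:
        return "intact" if (self.start5_found and self.end3_found) else "truncated"

    @property
    def length_kb(self) -> float:
        return self.interval.length / 1000.0


def build_elements(
    candidates: Sequence[HelendCandidate],
    families: Sequence[HelitronFamily],
    genome: dict[str, GenomeSequence],
    window: int = 3000,
    threshold: float = 80.0,
) -> list[HelitronElement]:
    """Call element boundaries and intact/truncated status per candidate."""
    by_id = {c.candidate_id: c for c in candidates}
    elements: list[HelitronElement] = []
    for fam in families:
        members = [by_id[m] for m in fam.members]
        starts, edges = locate_family_boundaries(members, genome, window, threshold)
        for cand in members:
            d = starts[cand.candidate_id]
            if d is not None:
                if cand.strand == "+":
                    iv = Interval(cand.scaffold, cand.end3 - d + 1, cand.end3, "+")
                else:
                    iv = Interval(cand.scaffold, cand.end3, cand.end3 + d - 1, "-")
                elements.append(
                    HelitronElement(
                        candidate_id=cand.candidate_id,
                        interval=iv,
                        family_id=fam.family_id,
                        start5_found=True,
                    )
                )
                continue
            # truncated: extend as far as conservation (or the helend) supports
            ext = edges[cand.candidate_id]
            method = "conservation"
            if ext is None:
                hp = cand.hairpin
                far = (
                    min(hp.arm5_interval.start, hp.arm5_interval.end)
                    if cand.strand == "+"
                    else max(hp.arm5_interval.start, hp.arm5_interval.end)
                )
                ext = abs(cand.end3 - far) + 1
                method = "helend-only"
            if cand.strand == "+":
                iv = Interval(cand.scaffold, cand.end3 - ext + 1, cand.end3, "+")
            else:
                iv = Interval(cand.scaffold, cand.end3, cand.end3 + ext - 1, "-")
            elements.append(
                HelitronElement(
                    candidate_id=cand.candidate_id,
                    interval=iv,
                    family_id=fam.family_id,
                    start5_found=False,
                    boundary_method=method,
                )
            )
    elements.sort(key=lambda e: (e.interval.scaffold, e.interval.start))
    return elements


def five_prime_30mer(
    element: HelitronElement, genome: dict[str, GenomeSequence]
) -> str:
    """Element-strand 30-mer beginning at the located 5' T[C/G] start."""
    seq = genome[element.interval.scaffold]
    iv = element.interval
    if iv.strand == "+":
        return seq.slice1(iv.start, min(iv.start + 29, iv.end))
    return reverse_complement(seq.slice1(max(iv.end - 29, iv.start), iv.end))


def assign_subfamilies(
    family: HelitronFamily,
    elements: Sequence[HelitronElement],
    genome: dict[str, GenomeSequence],
    threshold: float = 80.0,
) -> dict[int, list[str]]:
    """Split a family into subfamilies by 5'-terminal 30-mer identity.

    Only elements with a located 5' boundary participate; truncated
    members stay unassigned (subfamily None). The partition refines the
    family by construction.
    """
    located = [
        e
        for e in elements
        if e.family_id == family.family_id and e.start5_found
    ]
    if not located:
        family.subfamilies = {}
        return {}
    keys = [five_prime_30mer(e, genome) for e in located]
    full = [i for i, k in enumerate(keys) if len(k) == 30]
    groups = _single_linkage([keys[i] for i in full], threshold)
    # elements with short 5' 30-mers (tiny elements) each form a singleton
    groups = [[full[i] for i in g] for g in groups] + [
        [i] for i, k in enumerate(keys) if len(k) < 30
    ]

    def sort_key(group: list[int]):
        leftmost = min(
            (located[i].interval.scaffold, located[i].interval.start) for i in group
        )
        return (-len(group), leftmost)

    groups.sort(key=sort_key)
    subfamilies: dict[int, list[str]] = {}
    for sid, group in enumerate(groups, start=1):
        ids = []
        for i in group:
            located[i].subfamily_id = sid
            ids.append(located[i].candidate_id)
        subfamilies[sid] = sorted(ids)
    family.subfamilies = subfamilies
    return subfamilies


def name_elements(
    elements: Iterable[HelitronElement], prefix: str = "HEL"
) -> None:
    """Assign names: PREFIX + family [+ '.' + subfamily], case by autonomy.

    Putative autonomous elements are named in uppercase, non-autonomous
    in lowercase (e.g. HELPO1.1 vs helpo1.3 for a species tag 'PO').
    Elements without a subfamily carry the family number only.
    """
    for e in elements:
        base = f"{prefix}{e.family_id}"
        if e.subfamily_id is not None:
            base += f".{e.subfamily_id}"
        e.name = base.upper() if e.autonomous else base.lower()
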