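"""Scoring of pipeline output against simulator ground truth.

Elements are matched to planted copies by their 3'-terminal coordinate
and strand (the helend anchor is the one coordinate both sides define
identically). Intact 5' boundaries are compared exactly; truncated 5'
edges within a small slack, because the host junction base shared by
every insertion makes the last base or two of a truncated edge
formally unidentifiable from sequence alone.
"""

from __future__ import annotations

from typing import Sequence

from .pipeline import PipelineResult
from .simulate import TruthAnnotation


def _partitions_equal(labels_a: dict, labels_b: dict) -> bool:
    """Do two labelings of the same keys induce the same partition?"""
    keys = sorted(labels_a)
    if sorted(labels_b) != keys:
        return False
    groups_a: dict = {}
    groups_b: dict = {}
    for k in keys:
        groups_a.setdefault(labels_a[k], set()).add(k)
        groups_b.setdefault(labels_b[k], set()).add(k)
    return sorted(map(sorted, groups_a.values())) == sorted(
        map(sorted, groups_b.values())
    )


def evaluate_against_truth(
    result: PipelineResult,
    truth: Sequence[TruthAnnotation],
    truncated_slack: int = 3,
) -> dict:
    by_id = {c.candidate_id: c for c in result.candidates}
    truth_key = {(t.interval.scaffold, t.end3, t.interval.strand): t for t in truth}
    pairs = []
    unmatched_elements = 0
    for e in result.elements:
        cand = by_id[e.candidate_id]
        t = truth_key.get((cand.scaffold, cand.end3, cand.strand))
        if t is None:
            unmatched_elements += 1
        else:
            pairs.append((e, t))
    matched_truths = {id(t) for _, t in pairs}

    n_truth = len(truth)
    recall = len(matched_truths) / n_truth if n_truth else 0.0
    precision = (
        len(pairs) / len(result.elements) if result.elements else 0.0
    )

    intact_ok = sum(
        1 for e, t in pairs if (e.status == "intact") == (not t.truncated)
    )
    autonomy_ok = sum(1 for e, t in pairs if e.autonomous == t.autonomous)

    intact_pairs = [(e, t) for e, t in pairs if not t.truncated]
    boundary_exact = sum(
        1
        for e, t in intact_pairs
        if (e.interval.start, e.interval.end) == (t.interval.start, t.interval.end)
    )
    trunc_pairs = [(e, t) for e, t in pairs if t.truncated]
    trunc_ok = 0
    for e, t in trunc_pairs:
        if e.interval.strand == "+":
            d5 = t.interval.start - e.interval.start
            same3 = e.interval.end == t.interval.end
        else:
            d5 = e.interval.end - t.interval.end
            same3 = e.interval.start == t.interval.start
        if same3 and abs(d5) <= truncated_slack:
            trunc_ok += 1

    fam_truth = {e.candidate_id: (t.family,) for e, t in pairs}
    fam_called = {e.candidate_id: (e.family_id,) for e, _ in pairs}
    families_match = _partitions_equal(fam_truth, fam_called)

    sub_truth = {
        e.candidate_id: (t.family, t.subfamily)
        for e, t in pairs
        if e.status == "intact" and not t.truncated
    }
    sub_called = {
        e.candidate_id: (e.family_id, e.subfamily_id)
        for e, t in pairs
        if e.status == "intact" and not t.truncated
    }
    subfamilies_match = _partitions_equal(sub_truth, sub_called)

    captured_ok = 0
    captured_total = 0
    for e, t in intact_pairs:
        if e.candidate_id not in result.captured:
            continue
        captured_total += 1
        got = {
            (g.interval.start, g.interval.end)
            for g in result.captured[e.candidate_id]
        }
        want = {(iv.start, iv.end) for _, iv in t.cargo}
        if got == want:
            captured_ok += 1

    # the A|T junction is only meaningful where both boundaries are real:
    # a truncated 5' edge is not an insertion site
    insertion_ok = sum(
        1
        for e, _ in intact_pairs
        if (res := result.insertion.get(e.candidate_id)) and res.at_site
    )

    return {
        "n_truth": n_truth,
        "n_elements": len(result.elements),
        "n_matched": len(pairs),
        "recall": recall,
        "precision": precision,
        "unmatched_elements": unmatched_elements,
        "intact_status_agreement": intact_ok / len(pairs) if pairs else 0.0,
        "autonomy_agreement": autonomy_ok / len(pairs) if pairs else 0.0,
        "intact_boundaries_exact": (
            boundary_exact / len(intact_pairs) if intact_pairs else 1.0
        ),
        "truncated_edges_within_slack": (
            trunc_ok / len(trunc_pairs) if trunc_pairs else 1.0
        ),
        "families_match_truth_partition": families_match,
        "subfamilies_match_truth_partition": subfamilies_match,
        "captured_gene_sets_exact": (
            captured_ok / captured_total if captured_total else 1.0
        ),
        "at_insertion_fraction_intact": (
            insertion_ok / len(intact_pairs) if intact_pairs else 1.0
        ),
    }
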