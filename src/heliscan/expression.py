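"""RPKM quantification of elements and captured genes from read placements.

Input is a placement table (read_id, scaffold, start, end, n_placements)
rather than raw alignments: alignment itself is out of scope and any
coordinate-sorted aligner output is trivially reduced to this form. Each
placement of a multi-mapped read counts fully toward every feature it
overlaps (multiple mapping was allowed in the source protocol; fractional
assignment is deliberately not attempted). The library-size denominator
is the number of *distinct* reads, not placements.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .sequence import Interval

PLACEMENT_COLUMNS = ["read_id", "scaffold", "start", "end", "n_placements"]


@dataclasses.dataclass(frozen=True)
class ReadPlacement:
    read_id: str
    scaffold: str
    start: int  # 1-based inclusive
    end: int
    n_placements: int = 1

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"read {self.read_id}: start > end")
        if self.n_placements < 1:
            raise ValueError(f"read {self.read_id}: n_placements < 1")


@dataclasses.dataclass(frozen=True)
class ExpressionRecord:
    feature_id: str
    count: int
    length_bp: int
    rpkm: float


def read_placements_tsv(path) -> list[ReadPlacement]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(PLACEMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"placement TSV missing columns: {sorted(missing)}")
    return [
        ReadPlacement(
            str(r.read_id), str(r.scaffold), int(r.start), int(r.end),
            int(r.n_placements),
        )
        for r in df.itertuples(index=False)
    ]


def count_overlaps(
    features: Sequence[tuple[str, Interval]],
    placements: Iterable[ReadPlacement],
    min_overlap: int = 1,
    known_scaffolds: set[str] | None = None,
) -> dict[str, int]:
    """Per-feature placement counts by interval overlap.

    A placement contributes to every feature it overlaps by at least
    ``min_overlap`` bp; strand is ignored. Placements on scaffolds absent
    from ``known_scaffolds`` (when given) raise an error.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for fid, iv in features:
        # half-open tree coordinates; shrink both ends by (min_overlap-1) so
        # a tree match implies >= min_overlap overlapping bases
        trees.setdefault(iv.scaffold, IntervalTree()).addi(
            iv.start, iv.end + 1, fid
        )
    counts = {fid: 0 for fid, _ in features}
    for p in placements:
        if known_scaffolds is not None and p.scaffold not in known_scaffolds:
            raise ValueError(f"placement on unknown scaffold {p.scaffold!r}")
        tree = trees.get(p.scaffold)
        if tree is None:
            continue
        for hit in tree.overlap(p.start, p.end + 1):
            overlap = min(p.end, hit.end - 1) - max(p.start, hit.begin) + 1
            if overlap >= min_overlap:
                counts[hit.data] += 1
    return counts


def rpkm(count: int, feature_len: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of feature per million mapped reads."""
    if feature_len <= 0:
        raise ValueError("feature length must be positive")
    if total_mapped_reads <= 0:
        raise ValueError("total mapped reads must be positive")
    return count * 1e9 / (total_mapped_reads * feature_len)


def quantify(
    features: Sequence[tuple[str, Interval]],
    placements: Sequence[ReadPlacement],
    min_overlap: int = 1,
    known_scaffolds: set[str] | None = None,
) -> list[ExpressionRecord]:
    """Count overlaps and compute RPKM for every feature."""
    counts = count_overlaps(features, placements, min_overlap, known_scaffolds)
    total = len({p.read_id for p in placements})
    records = []
    for fid, iv in features:
        c = counts[fid]
        records.append(
            ExpressionRecord(
                feature_id=fid,
                count=c,
                length_bp=iv.length,
                rpkm=rpkm(c, iv.length, total) if total > 0 else 0.0,
            )
        )
    return records


def write_expression_tsv(records: Sequence[ExpressionRecord], path,
                         header_lines: Sequence[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("feature\tcount\tlength\trpkm\n")
        for r in records:
            fh.write(f"{r.feature_id}\t{r.count}\t{r.length_bp}\t{r.rpkm:.4f}\n")
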