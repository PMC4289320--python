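"""Post-classification annotation of helitron elements.

Covers captured-gene calls (full-length gene models inside element
boundaries, excluding the RepHel helicase itself), the AT-dinucleotide
insertion-site check (helitrons insert precisely between an A and a T
and make no target-site duplication), flank base composition, a
seed-and-extend search for captured-gene fragments elsewhere in the
genome, and per-genome summary statistics.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import gffutils

from .families import HelitronElement
from .sequence import (
    GenomeSequence,
    Interval,
    at_content,
    reverse_complement,
)


@dataclasses.dataclass(frozen=True)
class GeneModel:
    gene_id: str
    interval: Interval
    name: str = ""
    is_rephel: bool = False


@dataclasses.dataclass(frozen=True)
class CapturedGene:
    gene_id: str
    interval: Interval
    name: str = ""


def read_gene_models(path) -> list[GeneModel]:
    """Read gene models from GFF3 (features of type ``gene``)."""
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for feat in db.features_of_type("gene", order_by=("seqid", "start")):
        name = feat.attributes.get("Name", [feat.id])[0]
        is_rephel = feat.attributes.get("rephel", ["false"])[0].lower() == "true"
        models.append(
            GeneModel(
                gene_id=feat.id,
                interval=Interval(
                    feat.seqid, feat.start, feat.end, feat.strand if feat.strand in "+-" else "+"
                ),
                name=name,
                is_rephel=is_rephel,
            )
        )
    return models


def captured_genes(
    element: HelitronElement,
    gene_models: Sequence[GeneModel],
    rephel_span: Optional[Interval] = None,
    genome: Optional[dict[str, GenomeSequence]] = None,
) -> list[CapturedGene]:
    """Full-length gene models inside the element, minus the RepHel gene.

    A gene is captured only if its whole span lies within the element
    boundaries; genes overlapping the RepHel ORF span (or flagged as
    RepHel models) are never captured.
    """
    iv = element.interval
    if genome is not None:
        for g in gene_models:
            scaffold = genome.get(g.interval.scaffold)
            if scaffold is not None and g.interval.end > scaffold.length:
                raise ValueError(
                    f"gene {g.gene_id} extends past scaffold "
                    f"{g.interval.scaffold} end"
                )
    out = []
    for g in gene_models:
        if g.is_rephel or g.interval.scaffold != iv.scaffold:
            continue
        if not (iv.start <= g.interval.start and g.interval.end <= iv.end):
            continue
        if rephel_span is not None and rephel_span.scaffold == iv.scaffold:
            if not (
                g.interval.end < rephel_span.start
                or g.interval.start > rephel_span.end
            ):
                continue
        out.append(CapturedGene(g.gene_id, g.interval, g.name))
    return out


@dataclasses.dataclass(frozen=True)
class InsertionSiteResult:
    at_site: Optional[bool]  # None: indeterminate (scaffold edge)
    dinucleotide: str  # flanking bases, 5' then 3' on the plus strand


def insertion_site_check(
    element: HelitronElement, genome: dict[str, GenomeSequence]
) -> InsertionSiteResult:
    """Is the element inserted between an A and a T?

    The A|T rule is strand-symmetric, so the check reads the plus
    strand: the base before the element start must be A and the base
    after its end must be T. Elements touching a scaffold edge are
    indeterminate.
    """
    iv = element.interval
    seq = genome[iv.scaffold]
    if iv.start <= 1 or iv.end >= seq.length:
        return InsertionSiteResult(None, "")
    left = seq.slice1(iv.start - 1, iv.start - 1)
    right = seq.slice1(iv.end + 1, iv.end + 1)
    return InsertionSiteResult(left == "A" and right == "T", left + right)


@dataclasses.dataclass(frozen=True)
class FlankComposition:
    at5: float
    at3: float
    mean: float
    clipped: bool


def flank_at_content(
    element: HelitronElement,
    genome: dict[str, GenomeSequence],
    flank: int = 50,
) -> FlankComposition:
    """AT content of the two ``flank``-bp regions around the element.

    Fractions are reported per element-strand flank (5' then 3'); the
    mean pools both flanks. Flanks clipped at scaffold edges are flagged.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    iv = element.interval
    seq = genome[iv.scaffold]
    left = seq.slice1(max(1, iv.start - flank), iv.start - 1) if iv.start > 1 else ""
    right = (
        seq.slice1(iv.end + 1, min(seq.length, iv.end + flank))
        if iv.end < seq.length
        else ""
    )
    clipped = len(left) < flank or len(right) < flank
    if not left or not right:
        raise ValueError("element at scaffold edge: no flank available")
    if iv.strand == "+":
        f5, f3 = left, right
    else:
        f5, f3 = reverse_complement(right), reverse_complement(left)
    return FlankComposition(
        at5=at_content(f5),
        at3=at_content(f3),
        mean=at_content(f5 + f3),
        clipped=clipped,
    )


# -------------------------------------------------------- fragment search


@dataclasses.dataclass(frozen=True)
class FragmentHit:
    query_start: int  # 1-based inclusive, query coordinates
    query_end: int
    genomic: Interval
    length: int
    identity: float  # percent


def _extend_xdrop(
    q: str, g: str, q0: int, g0: int, seed_len: int, xdrop: int = 6
) -> tuple[int, int, int]:
    """Extend an exact seed at (q0, g0) both ways; return (q_lo, q_hi, matches)
    as 0-based inclusive query bounds of the trimmed maximal-score extension."""
    # right extension
    score = best = seed_len
    best_right = q0 + seed_len - 1
    matches_right = 0
    best_matches_right = 0
    i, j = q0 + seed_len, g0 + seed_len
    while i < len(q) and j < len(g):
        if q[i] == g[j] and q[i] != "N":
            score += 1
            matches_right += 1
        else:
            score -= 2
        if score > best:
            best = score
            best_right = i
            best_matches_right = matches_right
        if score <= best - xdrop:
            break
        i += 1
        j += 1
    # left extension
    score = best = 0
    best_left = q0
    matches_left = 0
    best_matches_left = 0
    i, j = q0 - 1, g0 - 1
    while i >= 0 and j >= 0:
        if q[i] == g[j] and q[i] != "N":
            score += 1
            matches_left += 1
        else:
            score -= 2
        if score > best:
            best = score
            best_left = i
            best_matches_left = matches_left
        if score <= best - xdrop:
            break
        i -= 1
        j -= 1
    matches = seed_len + best_matches_right + best_matches_left
    # mismatches inside the kept span also count toward its length
    return best_left, best_right, matches


def fragment_search(
    query: str,
    genome: Iterable[GenomeSequence],
    min_len: int = 50,
    min_identity: float = 95.0,
    seed_len: int = 20,
) -> list[FragmentHit]:
    """Find near-exact copies of ``query`` in the genome, both strands.

    Deterministic seed-and-extend: exact ``seed_len``-mers seed ungapped
    two-sided X-drop extensions; overlapping extensions on one diagonal
    merge; hits longer than ``min_len`` bp with identity above
    ``min_identity`` percent are reported (both thresholds strict, as in
    the published filtering rule).
    """
    query = query.upper()
    if len(query) < min_len:
        raise ValueError(f"query shorter than {min_len} bp")
    seeds: dict[str, list[int]] = {}
    for i in range(len(query) - seed_len + 1):
        kmer = query[i : i + seed_len]
        if "N" not in kmer:
            seeds.setdefault(kmer, []).append(i)
    hits: list[FragmentHit] = []
    for scaffold in genome:
        for strand in "+-":
            g = scaffold.residues if strand == "+" else reverse_complement(
                scaffold.residues
            )
            L = len(g)
            spans: dict[int, list[tuple[int, int, int]]] = {}  # diagonal -> spans
            for j in range(L - seed_len + 1):
                kmer = g[j : j + seed_len]
                positions = seeds.get(kmer)
                if not positions:
                    continue
                for q0 in positions:
                    diag = j - q0
                    done = False
                    for lo, hi, _ in spans.get(diag, ()):
                        if lo <= q0 and q0 + seed_len - 1 <= hi:
                            done = True
                            break
                    if done:
                        continue
                    q_lo, q_hi, matches = _extend_xdrop(query, g, q0, j, seed_len)
                    spans.setdefault(diag, []).append((q_lo, q_hi, matches))
            for diag, diag_spans in spans.items():
                for q_lo, q_hi, matches in _merge_diag(query, g, diag, diag_spans):
                    length = q_hi - q_lo + 1
                    identity = matches / length * 100.0
                    if length > min_len and identity > min_identity:
                        g_lo0, g_hi0 = q_lo + diag, q_hi + diag
                        if strand == "+":
                            iv = Interval(scaffold.id, g_lo0 + 1, g_hi0 + 1, "+")
                        else:
                            iv = Interval(
                                scaffold.id, L - g_hi0, L - g_lo0, "-"
                            )
                        hits.append(
                            FragmentHit(q_lo + 1, q_hi + 1, iv, length, identity)
                        )
    hits.sort(key=lambda h: (h.genomic.scaffold, h.genomic.start, h.genomic.strand))
    return hits


def _merge_diag(query, g, diag, spans):
    """Merge overlapping/adjacent extensions on one diagonal; recount matches."""
    spans = sorted(set((lo, hi) for lo, hi, _ in spans))
    merged: list[list[int]] = []
    for lo, hi in spans:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    out = []
    for lo, hi in merged:
        matches = sum(
            1
            for k in range(lo, hi + 1)
            if query[k] == g[k + diag] and query[k] != "N"
        )
        out.append((lo, hi, matches))
    return out


def promoter_interval(
    rephel_span: Interval, gene: CapturedGene
) -> Optional[Interval]:
    """Coordinates from the RepHel ORF start to a captured gene's start.

    A convenience for extracting putative promoter regions of captured
    genes; returns None when the gene starts inside the RepHel span.
    """
    if rephel_span.scaffold != gene.interval.scaffold:
        return None
    if rephel_span.strand == "+":
        lo, hi = rephel_span.start, gene.interval.start
    else:
        lo, hi = gene.interval.end, rephel_span.end
    if lo >= hi:
        return None
    return Interval(rephel_span.scaffold, lo, hi, rephel_span.strand)


# --------------------------------------------------------------- summary


@dataclasses.dataclass
class SummaryStats:
    element_count: int
    intact_count: int
    autonomous_count: int
    element_bp: int
    genome_bp: int
    genome_fraction_pct: float
    per_family: dict[int, int]


def summarize(
    elements: Sequence[HelitronElement],
    genomes: Iterable[GenomeSequence],
    captured: Optional[dict[str, list[CapturedGene]]] = None,
    rpkm: Optional[dict[str, float]] = None,
    decimal_sep: str = ".",
) -> tuple[SummaryStats, list[dict]]:
    """Per-element table rows plus genome-level statistics.

    The genome fraction is 100 x (summed element bp / summed genome bp)
    and is invariant under scaffold order. Sizes print in kb with one
    decimal (separator configurable to match published tables).
    """
    genome_bp = sum(g.length for g in genomes)
    element_bp = sum(e.interval.length for e in elements)
    per_family: dict[int, int] = {}
    rows = []
    for e in elements:
        per_family[e.family_id] = per_family.get(e.family_id, 0) + 1
        size_kb = f"{e.interval.length / 1000.0:.1f}".replace(".", decimal_sep)
        caps = (captured or {}).get(e.candidate_id, [])
        row = {
            "name": e.name,
            "scaffold": e.interval.scaffold,
            "start": e.interval.start,
            "end": e.interval.end,
            "orientation": e.interval.strand,
            "size_kb": size_kb,
            "autonomous": "*" if e.autonomous else "",
            "captured_genes": ", ".join(c.name or c.gene_id for c in caps),
            "intact": "*" if e.status == "intact" else "",
        }
        if rpkm is not None:
            row["rpkm"] = f"{rpkm.get(e.candidate_id, 0.0):.2f}"
        rows.append(row)
    stats = SummaryStats(
        element_count=len(elements),
        intact_count=sum(1 for e in elements if e.status == "intact"),
        autonomous_count=sum(1 for e in elements if e.autonomous),
        element_bp=element_bp,
        genome_bp=genome_bp,
        genome_fraction_pct=(
            100.0 * element_bp / genome_bp if genome_bp else 0.0
        ),
        per_family=per_family,
    )
    return stats, rows


def write_summary_tsv(stats: SummaryStats, rows: Sequence[dict], path,
                      header_lines: Sequence[str] = ()) -> None:
    import pandas as pd

    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            f"# elements={stats.element_count} intact={stats.intact_count} "
            f"autonomous={stats.autonomous_count} "
            f"genome_fraction_pct={stats.genome_fraction_pct:.3f}\n"
        )
        if rows:
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
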