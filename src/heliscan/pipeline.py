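"""End-to-end orchestration: scan -> classify -> RepHel -> annotate -> quantify.

Chance helends are common in ~50% GC sequence (roughly one compliant
hairpin+terminus per 70 bp of motif occurrences), so raw structural
candidates need curation, mirroring the manual false-positive removal of
the original protocol with two automated rules: an element is *validated*
when (a) its 3'-end family has at least ``min_family_size`` candidates,
or (b) it is a singleton whose upstream window carries a RepHel signature
plus an upstream T[C/G] start ("intact by homology") and whose span does
not overlap a family-derived element (chance helends inside a real
element are not independent elements).
"""

from __future__ import annotations

import dataclasses
import hashlib
from typing import Optional, Sequence

from . import annotate as ann
from . import families as fam
from . import rephel as rh
from .expression import ExpressionRecord, ReadPlacement, quantify
from .helend import HelendCandidate, ScanParams, scan_genome
from .sequence import GenomeSequence, Interval, iter_scaffold_map

__version__ = "0.1.0"


@dataclasses.dataclass
class PipelineConfig:
    scan: ScanParams = dataclasses.field(default_factory=ScanParams)
    family_threshold: float = 80.0
    subfamily_threshold: float = 80.0
    boundary_window: int = 3000
    rephel_window: int = 3600
    min_family_size: int = 2
    min_element_len: int = 100
    rescue_singletons: bool = True
    rescue_tc_search: int = 200  # bp upstream of the ORF to look for T[C/G]
    autonomy: rh.AutonomyPolicy = dataclasses.field(default_factory=rh.AutonomyPolicy)
    prefix: str = "HEL"
    flank: int = 50
    evalue_cutoff: float = 0.01
    motif_config: Optional[str] = None

    def as_flat_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self.scan):
            d[f"scan.{f.name}"] = getattr(self.scan, f.name)
        for f in dataclasses.fields(self.autonomy):
            d[f"autonomy.{f.name}"] = getattr(self.autonomy, f.name)
        for name in (
            "family_threshold subfamily_threshold boundary_window rephel_window "
            "min_family_size min_element_len rescue_singletons rescue_tc_search "
            "prefix flank evalue_cutoff motif_config"
        ).split():
            d[name] = getattr(self, name)
        return d

    def config_hash(self) -> str:
        text = ";".join(f"{k}={v}" for k, v in sorted(self.as_flat_dict().items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def provenance(self) -> list[str]:
        return [f"heliscan {__version__}", f"config {self.config_hash()}"]


_SCAN_FIELDS = {f.name: f.type for f in dataclasses.fields(ScanParams)}


def config_from_file(path, overrides: dict | None = None) -> PipelineConfig:
    """Plain-text ``key=value`` config (``scan.``-prefixed keys reach the
    scanner bounds); CLI overrides win over file values."""
    values: dict[str, str] = {}
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"bad config line: {raw!r}")
            k, v = line.split("=", 1)
            values[k.strip()] = v.strip()
    values.update(overrides or {})
    return _config_from_values(values)


def _config_from_values(values: dict[str, str]) -> PipelineConfig:
    scan_kwargs = {}
    cfg_kwargs = {}
    for k, v in values.items():
        if k.startswith("scan."):
            name = k[5:]
            if name == "terminal_motifs":
                scan_kwargs[name] = tuple(m.strip() for m in v.split(","))
            else:
                scan_kwargs[name] = int(v)
        elif k in (
            "family_threshold", "subfamily_threshold", "evalue_cutoff"
        ):
            cfg_kwargs[k] = float(v)
        elif k in (
            "boundary_window", "rephel_window", "min_family_size",
            "min_element_len", "rescue_tc_search", "flank",
        ):
            cfg_kwargs[k] = int(v)
        elif k == "rescue_singletons":
            cfg_kwargs[k] = v.lower() in ("1", "true", "yes")
        elif k in ("prefix", "motif_config"):
            cfg_kwargs[k] = v
        else:
            raise ValueError(f"unknown config key {k!r}")
    return PipelineConfig(scan=ScanParams(**scan_kwargs), **cfg_kwargs)


@dataclasses.dataclass
class PipelineResult:
    config: PipelineConfig
    candidates: list[HelendCandidate]
    families: list[fam.HelitronFamily]
    elements: list[fam.HelitronElement]
    autonomy: dict[str, rh.AutonomyCall]
    captured: dict[str, list[ann.CapturedGene]]
    insertion: dict[str, ann.InsertionSiteResult]
    flanks: dict[str, ann.FlankComposition]
    expression: list[ExpressionRecord]
    stats: Optional[ann.SummaryStats]
    summary_rows: list[dict]


def _resolve_overlaps(
    elements: list[fam.HelitronElement],
    family_size: dict[str, int],
    slack: int = 10,
) -> list[fam.HelitronElement]:
    """Curation: one element per locus.

    Repeated copies turn chance helends *inside* real elements into bona
    fide multi-member families, and mirrored copy pairs can even project
    chance structures into spans straddling two real elements. Elements
    are therefore admitted in priority order — larger family first (more
    copies, more evidence), then longer span — and an element
    overlapping an already-admitted element by more than ``slack`` bp is
    dropped as a shadow of it.
    """
    order = sorted(
        elements,
        key=lambda e: (-family_size.get(e.candidate_id, 1), -e.interval.length),
    )
    kept: list[fam.HelitronElement] = []
    for e in order:
        iv = e.interval
        shadow = any(
            k.interval.scaffold == iv.scaffold
            and min(k.interval.end, iv.end) - max(k.interval.start, iv.start) + 1
            > slack
            for k in kept
        )
        if not shadow:
            kept.append(e)
    kept.sort(key=lambda e: (e.interval.scaffold, e.interval.start))
    return kept


def _prune_families(
    families: list[fam.HelitronFamily], surviving: set[str]
) -> list[fam.HelitronFamily]:
    out = []
    for f in families:
        f.members = [m for m in f.members if m in surviving]
        if f.members:
            out.append(f)
    return out


def _check_scaffold_namespace(genome_map, intervals, what: str) -> None:
    unknown = sorted({iv.scaffold for iv in intervals if iv.scaffold not in genome_map})
    if unknown:
        raise ValueError(f"{what} reference unknown scaffolds: {', '.join(unknown)}")


def _rescue_singleton(
    cand: HelendCandidate,
    genome_map,
    models,
    config: PipelineConfig,
    external_hits,
) -> Optional[tuple[fam.HelitronElement, rh.AutonomyCall]]:
    win = rh.extract_upstream_window(cand, genome_map, config.rephel_window)
    hits = rh.scan_candidate_window(win, models)
    call = rh.call_autonomous(
        win, hits, None, config.autonomy, external_hits=external_hits
    )
    if not call.autonomous or call.rephel_span is None:
        return None
    off = (
        call.rephel_span.start - win.lo
        if win.strand == "+"
        else win.hi - call.rephel_span.end
    )
    start_off = None
    for t in range(off, max(-1, off - config.rescue_tc_search) - 1, -1):
        if t + 1 < len(win.seq) and win.seq[t] == "T" and win.seq[t + 1] in "CG":
            start_off = t
            break
    if start_off is None:
        return None
    if win.strand == "+":
        start5 = win.lo + start_off
        iv = Interval(cand.scaffold, start5, cand.end3, "+")
    else:
        start5 = win.hi - start_off
        iv = Interval(cand.scaffold, cand.end3, start5, "-")
    element = fam.HelitronElement(
        candidate_id=cand.candidate_id,
        interval=iv,
        family_id=0,  # renumbered later
        start5_found=True,
        boundary_method="homology",
        autonomous=True,
        rephel_span=call.rephel_span,
    )
    return element, call


def run_pipeline(
    genome: Sequence[GenomeSequence],
    config: PipelineConfig | None = None,
    gene_models: Sequence[ann.GeneModel] | None = None,
    placements: Sequence[ReadPlacement] | None = None,
    external_domains: Optional[str] = None,
) -> PipelineResult:
    """Run the full identification/classification/annotation pipeline."""
    config = config or PipelineConfig()
    genome = list(genome)
    genome_map = iter_scaffold_map(genome)
    if gene_models:
        _check_scaffold_namespace(
            genome_map, [g.interval for g in gene_models], "gene models"
        )

    candidates = scan_genome(genome, config.scan)
    by_id = {c.candidate_id: c for c in candidates}
    all_families = fam.cluster_families(candidates, config.family_threshold)
    kept = [f for f in all_families if len(f.members) >= config.min_family_size]

    elements = fam.build_elements(
        candidates=[by_id[m] for f in kept for m in f.members],
        families=kept,
        genome=genome_map,
        window=config.boundary_window,
        threshold=config.family_threshold,
    )
    sizes = {m: len(f.members) for f in kept for m in f.members}
    elements = _resolve_overlaps(elements, sizes, slack=10)
    # spans too short to be an element (bare helend structures) are noise
    elements = [
        e for e in elements if e.interval.length >= config.min_element_len
    ]
    kept = _prune_families(kept, {e.candidate_id for e in elements})
    # families decimated by the curation rules are no longer validated
    kept = [f for f in kept if len(f.members) >= config.min_family_size]
    valid_ids = {m for f in kept for m in f.members}
    elements = [e for e in elements if e.candidate_id in valid_ids]

    models = rh.load_motif_models(config.motif_config)
    windows = {
        c.candidate_id: rh.extract_upstream_window(
            by_id[c.candidate_id], genome_map, config.rephel_window
        )
        for c in (by_id[e.candidate_id] for e in elements)
    }
    external_hits: list[rh.DomainHit] = []
    if external_domains:
        all_windows = [
            rh.extract_upstream_window(c, genome_map, config.rephel_window)
            for c in candidates
        ]
        external_hits = rh.import_domain_table(
            external_domains, all_windows, config.evalue_cutoff
        )
    autonomy: dict[str, rh.AutonomyCall] = {}
    for e in elements:
        win = windows[e.candidate_id]
        hits = rh.scan_candidate_window(win, models)
        call = rh.call_autonomous(
            win, hits, e, config.autonomy, external_hits=external_hits
        )
        autonomy[e.candidate_id] = call
        e.autonomous = call.autonomous
        e.rephel_span = call.rephel_span

    if config.rescue_singletons:
        singles = [f.members[0] for f in all_families if len(f.members) == 1]
        rescued: list[fam.HelitronElement] = []
        for cid in singles:
            cand = by_id[cid]
            near = any(
                e.interval.scaffold == cand.scaffold
                and e.interval.start - config.rephel_window
                <= cand.end3
                <= e.interval.end + config.rephel_window
                for e in elements
            )
            if near:
                continue
            res = _rescue_singleton(
                cand, genome_map, models, config, external_hits
            )
            if res is None:
                continue
            element, call = res
            overlaps = any(
                e.interval.scaffold == element.interval.scaffold
                and not (
                    element.interval.end < e.interval.start
                    or element.interval.start > e.interval.end
                )
                for e in elements + rescued
            )
            if overlaps:
                continue
            rescued.append(element)
            autonomy[element.candidate_id] = call
        if rescued:
            for el in rescued:
                kept.append(
                    fam.HelitronFamily(
                        family_id=0,
                        members=[el.candidate_id],
                        consensus_end30=by_id[el.candidate_id].end30,
                    )
                )
            elements.extend(rescued)

    # renumber families over the validated set: size desc, then leftmost
    def _fam_key(f: fam.HelitronFamily):
        leftmost = min(
            (by_id[m].scaffold, by_id[m].motif_interval.start) for m in f.members
        )
        return (-len(f.members), leftmost)

    kept.sort(key=_fam_key)
    remap: dict[str, int] = {}
    for new_id, f in enumerate(kept, start=1):
        f.family_id = new_id
        for m in f.members:
            remap[m] = new_id
    for e in elements:
        e.family_id = remap[e.candidate_id]

    for f in kept:
        fam.assign_subfamilies(f, elements, genome_map, config.subfamily_threshold)
    fam.name_elements(elements, config.prefix)
    elements.sort(key=lambda e: (e.interval.scaffold, e.interval.start))

    captured: dict[str, list[ann.CapturedGene]] = {}
    insertion: dict[str, ann.InsertionSiteResult] = {}
    flanks: dict[str, ann.FlankComposition] = {}
    for e in elements:
        insertion[e.candidate_id] = ann.insertion_site_check(e, genome_map)
        try:
            flanks[e.candidate_id] = ann.flank_at_content(
                e, genome_map, config.flank
            )
        except ValueError:
            pass  # scaffold-edge element: no flank
        if gene_models and e.status == "intact":
            captured[e.candidate_id] = ann.captured_genes(
                e, gene_models, e.rephel_span, genome_map
            )
            e.captured_gene_ids = [g.gene_id for g in captured[e.candidate_id]]

    expression: list[ExpressionRecord] = []
    rpkm_map: dict[str, float] | None = None
    if placements is not None:
        _check_scaffold_namespace(
            genome_map,
            [Interval(p.scaffold, p.start, p.end) for p in placements],
            "read placements",
        )
        features = [(e.candidate_id, e.interval) for e in elements]
        expression = quantify(
            features, placements, known_scaffolds=set(genome_map)
        )
        rpkm_map = {r.feature_id: r.rpkm for r in expression}

    stats, rows = ann.summarize(
        elements, genome, captured if gene_models else None, rpkm_map
    )
    return PipelineResult(
        config=config,
        candidates=candidates,
        families=kept,
        elements=elements,
        autonomy=autonomy,
        captured=captured,
        insertion=insertion,
        flanks=flanks,
        expression=expression,
        stats=stats,
        summary_rows=rows,
    )


def write_elements_gff3(
    result: PipelineResult, path, header_lines: Sequence[str] = ()
) -> None:
    """Elements as GFF3 mobile_genetic_element features; RepHel motif hits
    of autonomous elements attach as polypeptide_motif children."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for line in header_lines:
            fh.write(f"#{line}\n")
        for e in result.elements:
            iv = e.interval
            ins = result.insertion.get(e.candidate_id)
            attrs = (
                f"ID={e.candidate_id};Name={e.name};family={e.family_id};"
                f"subfamily={e.subfamily_id if e.subfamily_id else 'NA'};"
                f"status={e.status};autonomous={str(e.autonomous).lower()};"
                f"boundary_method={e.boundary_method};"
                f"at_insertion={'NA' if ins is None or ins.at_site is None else str(ins.at_site).lower()}"
            )
            if e.captured_gene_ids:
                attrs += ";captured_genes=" + ",".join(e.captured_gene_ids)
            fh.write(
                f"{iv.scaffold}\theliscan\tmobile_genetic_element\t{iv.start}\t"
                f"{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            call = result.autonomy.get(e.candidate_id)
            if call and call.rephel_span:
                rs = call.rephel_span
                fh.write(
                    f"{rs.scaffold}\theliscan\tpolypeptide_motif\t{rs.start}\t"
                    f"{rs.end}\t.\t{rs.strand}\t.\tID={e.candidate_id}.rephel;"
                    f"Parent={e.candidate_id};Name=RepHel;"
                    f"motifs={'|'.join(call.rep_motifs + call.hel_motifs)}\n"
                )
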