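"""Homology-based detection of the RepHel protein behind each helend.

Putative autonomous helitrons encode a RepHel protein: a rolling-circle
replication initiator (Rep) followed by an SF1/PIF1-family helicase
(Hel). The region upstream of each helend is translated in the three
forward frames of the element strand and scanned with degenerate
amino-acid motif patterns: three Rep motifs and six helicase motifs.
The default autonomy policy requires at least 2/3 Rep motifs and 4/6
helicase motifs with the Rep block upstream of the helicase block — the
published criterion is domain *presence* within element boundaries, and
these counts are this package's operational reading of it.

An external domain-hit table (e.g. from an offline CDD or HMMER run
against PF14214/PF05970) can override the built-in scanner; when both
are supplied the external table wins.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from typing import Iterable, Optional, Sequence

from .families import HelitronElement
from .helend import HelendCandidate
from .sequence import GenomeSequence, Interval, reverse_complement, translate_frame

REP_MOTIFS = ("rep1", "rep2", "rep3")
HEL_MOTIFS = ("helI", "helIa", "helII", "helIII", "helV", "helVI")
DEFAULT_REQUIRED_ACCESSIONS = ("PF14214", "PF05970")

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


@dataclasses.dataclass(frozen=True)
class MotifModel:
    """A degenerate amino-acid pattern with a minimum-match score."""

    name: str
    positions: tuple[frozenset[str], ...]  # empty set = wildcard
    min_score: int

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError(f"motif {self.name!r}: empty pattern")
        if not (0 < self.min_score <= len(self.positions)):
            raise ValueError(f"motif {self.name!r}: min_score out of range")

    @property
    def length(self) -> int:
        return len(self.positions)

    @property
    def consensus(self) -> str:
        """One representative sequence: first allowed residue per position."""
        return "".join(
            sorted(p)[0] if p else "A" for p in self.positions
        )

    def score_at(self, protein: str, offset: int) -> int:
        s = 0
        for k, allowed in enumerate(self.positions):
            if not allowed or protein[offset + k] in allowed:
                s += 1
        return s


def parse_pattern(text: str) -> tuple[frozenset[str], ...]:
    """Parse ``G[SA]AGxGK[ST]``-style patterns into per-position sets."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch == "[":
            j = text.index("]", i)
            allowed = text[i + 1 : j]
            if not allowed or set(allowed) - set(AA_ALPHABET):
                raise ValueError(f"bad pattern set {text[i:j+1]!r}")
            positions.append(frozenset(allowed))
            i = j + 1
        elif ch == "x":
            positions.append(frozenset())
            i += 1
        elif ch in AA_ALPHABET:
            positions.append(frozenset(ch))
            i += 1
        else:
            raise ValueError(f"bad pattern character {ch!r} in {text!r}")
    return tuple(positions)


def load_motif_models(path=None) -> list[MotifModel]:
    """Load motif models from a config file (default: the shipped set)."""
    if path is None:
        text = (
            resources.files("heliscan").joinpath("data/rephel_motifs.txt").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    models = []
    for raw in text.splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"motif config line needs 3 tab-separated fields: {raw!r}")
        name, pattern, min_score = fields
        models.append(
            MotifModel(
                name=name,
                positions=parse_pattern(pattern.strip()),
                min_score=int(min_score),
            )
        )
    if not models:
        raise ValueError("motif config contains no models")
    return models


@dataclasses.dataclass(frozen=True)
class WindowInfo:
    """An extracted upstream window, oriented to the element strand."""

    candidate_id: str
    scaffold: str
    seq: str  # element-strand orientation
    lo: int  # 1-based plus-strand span of the window
    hi: int
    strand: str
    edge_clipped: bool

    def query_id(self, frame: int) -> str:
        return f"{self.candidate_id}|f{frame}"


def extract_upstream_window(
    candidate: HelendCandidate,
    genome: dict[str, GenomeSequence],
    window: int = 3600,
) -> WindowInfo:
    """Window of ``window`` bp upstream (element strand) of the helend.

    "Upstream of the helend" means upstream of the hairpin's 5' arm; the
    returned sequence is oriented so its three forward frames are the
    element's forward frames. Windows clipped at a scaffold edge are
    flagged.
    """
    seq = genome[candidate.scaffold]
    hp = candidate.hairpin
    if candidate.strand == "+":
        helend_start = hp.arm5_interval.start
        lo = max(1, helend_start - window)
        hi = helend_start - 1
        if hi < lo:
            raise ValueError(f"candidate {candidate.candidate_id}: no upstream room")
        return WindowInfo(
            candidate.candidate_id,
            seq.id,
            seq.slice1(lo, hi),
            lo,
            hi,
            "+",
            edge_clipped=(hi - lo + 1) < window,
        )
    helend_start = hp.arm5_interval.end
    lo = helend_start + 1
    hi = min(seq.length, helend_start + window)
    if hi < lo:
        raise ValueError(f"candidate {candidate.candidate_id}: no upstream room")
    return WindowInfo(
        candidate.candidate_id,
        seq.id,
        reverse_complement(seq.slice1(lo, hi)),
        lo,
        hi,
        "-",
        edge_clipped=(hi - lo + 1) < window,
    )


@dataclasses.dataclass(frozen=True)
class DomainHit:
    candidate_id: str
    frame: int  # 0, 1, 2 on the oriented window
    motif: str  # motif name or external accession
    prot_start: int  # 1-based inclusive protein coordinates in the frame
    prot_end: int
    genomic: Interval
    score: float
    source: str = "builtin"  # or "external"


def scan_motifs(protein: str, models: Sequence[MotifModel]) -> list[tuple]:
    """Slide every model over a protein; report (name, start1, end1, score)
    for each offset where matched positions >= min_score."""
    import numpy as np

    hits = []
    n = len(protein)
    codes = np.frombuffer(protein.encode(), dtype=np.uint8)
    for model in models:
        L = model.length
        if n < L:
            continue
        w = n - L + 1
        acc = np.zeros(w, dtype=np.int16)
        for k, allowed in enumerate(model.positions):
            col = codes[k : k + w]
            if not allowed:
                acc += 1
            else:
                lut = np.zeros(256, dtype=np.int16)
                for aa in allowed:
                    lut[ord(aa)] = 1
                acc += lut[col]
        for off in np.nonzero(acc >= model.min_score)[0]:
            hits.append(
                (model.name, int(off) + 1, int(off) + L, int(acc[off]))
            )
    hits.sort(key=lambda h: (h[0], h[1]))
    return hits


def _prot_to_genomic(win: WindowInfo, frame: int, p1: int, p2: int) -> Interval:
    """Map 1-based protein interval [p1,p2] of a frame to plus coordinates."""
    o_start = frame + 3 * (p1 - 1)  # 0-based oriented offsets
    o_end = frame + 3 * p2 - 1
    if win.strand == "+":
        return Interval(win.scaffold, win.lo + o_start, win.lo + o_end, "+")
    return Interval(win.scaffold, win.hi - o_end, win.hi - o_start, "-")


def scan_candidate_window(
    win: WindowInfo, models: Sequence[MotifModel]
) -> list[DomainHit]:
    """Translate a window in three frames and scan all motif models."""
    hits: list[DomainHit] = []
    if len(win.seq) < 3:
        return hits
    for frame in (0, 1, 2):
        protein = translate_frame(win.seq, frame)
        for name, p1, p2, score in scan_motifs(protein, models):
            hits.append(
                DomainHit(
                    candidate_id=win.candidate_id,
                    frame=frame,
                    motif=name,
                    prot_start=p1,
                    prot_end=p2,
                    genomic=_prot_to_genomic(win, frame, p1, p2),
                    score=score,
                )
            )
    return hits


@dataclasses.dataclass
class AutonomyCall:
    autonomous: bool
    policy: str  # "builtin" or "external"
    rep_motifs: tuple[str, ...]
    hel_motifs: tuple[str, ...]
    rephel_span: Optional[Interval]
    orphan_helicase: bool = False


@dataclasses.dataclass(frozen=True)
class AutonomyPolicy:
    min_rep_motifs: int = 2
    min_hel_motifs: int = 4
    require_rep_upstream: bool = True
    required_accessions: tuple[str, ...] = DEFAULT_REQUIRED_ACCESSIONS


def _oriented_offset(win: WindowInfo, iv: Interval) -> int:
    return iv.start - win.lo if win.strand == "+" else win.hi - iv.end


def _hull_with_stops(
    win: WindowInfo, hits: Sequence[DomainHit]
) -> Optional[Interval]:
    """Hull of hits extended to the nearest in-frame stop codons.

    Hits in different frames (introns shift the frame) are merged into
    one hull when collinear within 1 kb.
    """
    if not hits:
        return None
    spans: list[tuple[int, int]] = []  # oriented 0-based [start, end]
    for frame in (0, 1, 2):
        fh = [h for h in hits if h.frame == frame]
        if not fh:
            continue
        protein = translate_frame(win.seq, frame)
        p_lo = min(h.prot_start for h in fh) - 1  # 0-based
        p_hi = max(h.prot_end for h in fh) - 1
        while p_lo > 0 and protein[p_lo - 1] != "*":
            p_lo -= 1
        while p_hi < len(protein) - 1 and protein[p_hi + 1] != "*":
            p_hi += 1
        spans.append((frame + 3 * p_lo, frame + 3 * (p_hi + 1) - 1))
    spans.sort()
    merged = [spans[0]]
    for lo, hi in spans[1:]:
        if lo - merged[-1][1] <= 1000:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    lo, hi = max(merged, key=lambda x: x[1] - x[0])
    if win.strand == "+":
        return Interval(win.scaffold, win.lo + lo, win.lo + hi, "+")
    return Interval(win.scaffold, win.hi - hi, win.hi - lo, "-")


def _within_boundaries(iv: Interval, element: Optional[HelitronElement]) -> bool:
    if element is None or not element.start5_found:
        return True  # 5' end unknown: accept any hit in the searched window
    e = element.interval
    return iv.scaffold == e.scaffold and e.start <= iv.start and iv.end <= e.end


def call_autonomous(
    win: WindowInfo,
    hits: Sequence[DomainHit],
    element: Optional[HelitronElement] = None,
    policy: AutonomyPolicy | None = None,
    external_hits: Sequence[DomainHit] = (),
) -> AutonomyCall:
    """Decide autonomy for one candidate from its window's domain hits.

    With an external table the decision is presence of the two required
    accessions within the boundaries; otherwise the built-in motif-count
    policy applies. The external table wins when both are available.
    """
    policy = policy or AutonomyPolicy()
    ext = [h for h in external_hits if h.candidate_id == win.candidate_id]
    if ext:
        usable = [h for h in ext if _within_boundaries(h.genomic, element)]
        accs = {h.motif for h in usable}
        ok = all(a in accs for a in policy.required_accessions)
        return AutonomyCall(
            autonomous=ok,
            policy="external",
            rep_motifs=(),
            hel_motifs=tuple(sorted(accs)),
            rephel_span=_hull_plain(usable) if ok else None,
        )
    usable = [
        h
        for h in hits
        if h.candidate_id == win.candidate_id
        and _within_boundaries(h.genomic, element)
    ]
    rep = tuple(sorted({h.motif for h in usable if h.motif in REP_MOTIFS}))
    hel = tuple(sorted({h.motif for h in usable if h.motif in HEL_MOTIFS}))
    ok = len(rep) >= policy.min_rep_motifs and len(hel) >= policy.min_hel_motifs
    if ok and policy.require_rep_upstream:
        rep_start = min(
            _oriented_offset(win, h.genomic) for h in usable if h.motif in REP_MOTIFS
        )
        hel_start = min(
            _oriented_offset(win, h.genomic) for h in usable if h.motif in HEL_MOTIFS
        )
        ok = rep_start < hel_start
    span = _hull_with_stops(win, usable) if ok else None
    return AutonomyCall(
        autonomous=ok,
        policy="builtin",
        rep_motifs=rep,
        hel_motifs=hel,
        rephel_span=span,
        orphan_helicase=(not ok) and len(hel) >= policy.min_hel_motifs,
    )


def _hull_plain(hits: Sequence[DomainHit]) -> Optional[Interval]:
    if not hits:
        return None
    sc = hits[0].genomic.scaffold
    return Interval(
        sc,
        min(h.genomic.start for h in hits),
        max(h.genomic.end for h in hits),
        hits[0].genomic.strand,
    )


def import_domain_table(
    path,
    windows: Iterable[WindowInfo],
    evalue_cutoff: float = 0.01,
) -> list[DomainHit]:
    """Read an external domain-hit table into DomainHits.

    Tab-separated columns: query_id, accession, start, end, evalue;
    query ids are ``<candidate_id>|f<frame>`` as produced for the
    exported translations. Rows above the E-value cutoff are dropped;
    unknown query ids raise an error naming every offender.
    """
    index = {w.query_id(f): (w, f) for w in windows for f in (0, 1, 2)}
    hits: list[DomainHit] = []
    unknown: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("query_id\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise ValueError(f"domain table row needs 5 columns: {line!r}")
            qid, acc, start, end, evalue = fields[:5]
            if qid not in index:
                unknown.append(qid)
                continue
            if float(evalue) >= evalue_cutoff:
                continue
            win, frame = index[qid]
            p1, p2 = int(start), int(end)
            hits.append(
                DomainHit(
                    candidate_id=win.candidate_id,
                    frame=frame,
                    motif=acc,
                    prot_start=p1,
                    prot_end=p2,
                    genomic=_prot_to_genomic(win, frame, p1, p2),
                    score=float(evalue),
                    source="external",
                )
            )
    if unknown:
        raise ValueError(
            "domain table references unknown query ids: "
            + ", ".join(sorted(set(unknown)))
        )
    return hits
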