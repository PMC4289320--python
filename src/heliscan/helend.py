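"""Structure-based detection of helitron 3'-terminal signatures (helends).

A helend is the 3'-end anchor of a helitron: a subterminal palindromic
hairpin, a short spacer, and a terminal CTRR-type 4-mer. The scan looks
for, on both strands:

    5' ... [arm5] [loop 2-4 bp] [arm3] [spacer 5-8 bp] [CTRR] 3'

where arm5/arm3 form a DNA stem of at least 6 Watson-Crick pairs with at
most 2 mismatches. CTRR expands to {CTAA, CTAG, CTGA, CTGG}; CTTG is in
the default motif set as well because a known helitron family terminates
in CTTG instead of a strict CTRR.

Pairing is strict Watson-Crick (A-T, G-C; no G-T wobble: this is a DNA
duplex, not RNA). Stems containing N are rejected. Among alternative
hairpin geometries upstream of one terminal motif, the ranking is:
maximal stem length, then fewest mismatches, then smallest spacer, then
smallest loop — prefer the strongest, most proximal structure.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Optional, Sequence

import numpy as np

from .sequence import GenomeSequence, Interval, reverse_complement

CTRR_MOTIFS = ("CTAA", "CTAG", "CTGA", "CTGG")
DEFAULT_MOTIFS = CTRR_MOTIFS + ("CTTG",)

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
# Watson-Crick complement code; N (4) deliberately maps to an unpairable 5
_COMP_CODE = np.array([3, 2, 1, 0, 5], dtype=np.int8)


@dataclasses.dataclass(frozen=True)
class ScanParams:
    """Bounds of the helend geometry search."""

    min_stem_pairs: int = 6
    max_stem_mismatches: int = 2
    loop_min: int = 2
    loop_max: int = 4
    spacer_min: int = 5
    spacer_max: int = 8
    terminal_motifs: tuple[str, ...] = DEFAULT_MOTIFS
    max_stem_pairs: int = 20

    def __post_init__(self) -> None:
        if min(self.min_stem_pairs, self.loop_min, self.spacer_min) < 1:
            raise ValueError("all geometry bounds must be positive")
        if self.max_stem_mismatches < 0:
            raise ValueError("max_stem_mismatches must be >= 0")
        if self.loop_min > self.loop_max:
            raise ValueError("loop_min > loop_max")
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min > spacer_max")
        if self.min_stem_pairs > self.max_stem_pairs:
            raise ValueError("min_stem_pairs > max_stem_pairs")
        motifs = tuple(m.upper() for m in self.terminal_motifs)
        for m in motifs:
            if len(m) != 4 or set(m) - set("ACGT"):
                raise ValueError(f"terminal motif {m!r} is not an ACGT 4-mer")
        object.__setattr__(self, "terminal_motifs", motifs)

    @property
    def max_upstream(self) -> int:
        """Longest stretch a compliant helend can occupy upstream of the motif."""
        return 2 * self.max_stem_pairs + self.loop_max + self.spacer_max


@dataclasses.dataclass(frozen=True)
class MotifHit:
    """A terminal-motif occurrence, in plus-strand coordinates."""

    scaffold: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    motif: str  # motif as read on the element strand


@dataclasses.dataclass(frozen=True)
class Hairpin:
    arm5_interval: Interval
    arm3_interval: Interval
    loop_len: int
    stem_pairs: int
    mismatches: int
    spacer: int


@dataclasses.dataclass(frozen=True)
class HelendCandidate:
    """A detected helend: terminal motif + supporting hairpin + 3' 30-mer."""

    candidate_id: str
    motif_interval: Interval
    hairpin: Hairpin
    terminal_motif: str
    end30: str
    strand: str
    end30_truncated: bool = False

    @property
    def scaffold(self) -> str:
        return self.motif_interval.scaffold

    @property
    def end3(self) -> int:
        """Plus-strand coordinate of the element-strand terminal base."""
        return self.motif_interval.end if self.strand == "+" else self.motif_interval.start


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(
        seq.encode().translate(bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))),
        dtype=np.int8,
    )


def find_terminal_motifs(seq: GenomeSequence, params: ScanParams) -> list[MotifHit]:
    """Locate terminal-motif 4-mers on both strands.

    Minus-strand hits are reported in plus coordinates; ``motif`` is the
    4-mer as read on the element (hit) strand.
    """
    hits: list[MotifHit] = []
    s = seq.residues
    L = len(s)
    for motif in params.terminal_motifs:
        start = 0
        while True:
            p = s.find(motif, start)
            if p < 0:
                break
            hits.append(MotifHit(seq.id, p + 1, p + 4, "+", motif))
            start = p + 1
        rc = reverse_complement(motif)
        start = 0
        while True:
            p = s.find(rc, start)
            if p < 0:
                break
            hits.append(MotifHit(seq.id, p + 1, p + 4, "-", motif))
            start = p + 1
    hits.sort(key=lambda h: (h.start, h.strand, h.motif))
    return hits


def _combo_key(params: ScanParams, arm: int, mism: int, spacer: int, loop: int) -> int:
    return (
        ((params.max_stem_pairs - arm) << 15)
        | (mism << 10)
        | (spacer << 4)
        | loop
    )


def _decode_key(params: ScanParams, key: int) -> tuple[int, int, int, int]:
    arm = params.max_stem_pairs - (key >> 15)
    mism = (key >> 10) & 0x1F
    spacer = (key >> 4) & 0x3F
    loop = key & 0xF
    return arm, mism, spacer, loop


_SENTINEL = 1 << 30


def _best_geometry_scalar(
    oriented: str, motif_start0: int, params: ScanParams
) -> Optional[tuple[int, int, int, int]]:
    """Best (arm, mismatches, spacer, loop) upstream of an oriented motif start."""
    best_key = _SENTINEL
    best = None
    p = motif_start0
    for arm in range(params.max_stem_pairs, params.min_stem_pairs - 1, -1):
        for spacer in range(params.spacer_min, params.spacer_max + 1):
            for loop in range(params.loop_min, params.loop_max + 1):
                lo = p - spacer - 2 * arm - loop
                if lo < 0:
                    continue
                mism = 0
                has_n = False
                ok = True
                for i in range(arm):
                    x = oriented[lo + i]
                    y = oriented[p - spacer - 1 - i]
                    if x == "N" or y == "N":
                        has_n = True
                        break
                    if (x, y) not in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")):
                        mism += 1
                        if mism > params.max_stem_mismatches:
                            ok = False
                            break
                if has_n or not ok:
                    continue
                key = _combo_key(params, arm, mism, spacer, loop)
                if key < best_key:
                    best_key = key
                    best = (arm, mism, spacer, loop)
    return best


def find_hairpin_upstream(
    seq: GenomeSequence, motif: MotifHit, params: ScanParams
) -> Optional[Hairpin]:
    """Best compliant hairpin upstream (element strand) of a motif hit, or None."""
    s = seq.residues
    if motif.strand == "+":
        oriented = s
        p0 = motif.start - 1
    else:
        oriented = reverse_complement(s)
        p0 = len(s) - motif.end  # 0-based motif start in oriented coords
    geom = _best_geometry_scalar(oriented, p0, params)
    if geom is None:
        return None
    return _geometry_to_hairpin(seq, motif, geom)


def _geometry_to_hairpin(
    seq: GenomeSequence, motif: MotifHit, geom: tuple[int, int, int, int]
) -> Hairpin:
    arm, mism, spacer, loop = geom
    L = seq.length
    if motif.strand == "+":
        p0 = motif.start - 1
        a3_lo = p0 - spacer - arm
        a5_lo = p0 - spacer - 2 * arm - loop
        arm5 = Interval(seq.id, a5_lo + 1, a5_lo + arm, "+")
        arm3 = Interval(seq.id, a3_lo + 1, a3_lo + arm, "+")
    else:
        # oriented coords -> plus coords: plus0 = L - 1 - oriented0
        p0 = L - motif.end
        a3_lo = p0 - spacer - arm
        a5_lo = p0 - spacer - 2 * arm - loop
        arm5 = Interval(seq.id, L - (a5_lo + arm) + 1, L - a5_lo, "-")
        arm3 = Interval(seq.id, L - (a3_lo + arm) + 1, L - a3_lo, "-")
    return Hairpin(arm5, arm3, loop, arm, mism, spacer)


def _scan_oriented_vector(
    codes: np.ndarray, positions: np.ndarray, params: ScanParams
) -> np.ndarray:
    """Vector of best geometry keys (or sentinel) per oriented motif start."""
    best = np.full(len(positions), _SENTINEL, dtype=np.int64)
    if len(positions) == 0:
        return best
    comp = _COMP_CODE
    n = len(codes)
    is_n = codes == 4
    for arm in range(params.min_stem_pairs, params.max_stem_pairs + 1):
        for spacer in range(params.spacer_min, params.spacer_max + 1):
            for loop in range(params.loop_min, params.loop_max + 1):
                lo = positions - spacer - 2 * arm - loop
                ok = lo >= 0
                if not ok.any():
                    continue
                safe_lo = np.where(ok, lo, 0)
                mism = np.zeros(len(positions), dtype=np.int32)
                bad = ~ok
                for i in range(arm):
                    xs = safe_lo + i
                    ys = np.where(ok, positions - spacer - 1 - i, 0)
                    bad = bad | is_n[xs] | is_n[ys]
                    mism += comp[codes[xs]] != codes[ys]
                valid = ok & ~bad & (mism <= params.max_stem_mismatches)
                if not valid.any():
                    continue
                keys = (
                    ((params.max_stem_pairs - arm) << 15)
                    | (mism.astype(np.int64) << 10)
                    | (spacer << 4)
                    | loop
                )
                keys = np.where(valid, keys, _SENTINEL)
                np.minimum(best, keys, out=best)
    return best


def scan_sequence(seq: GenomeSequence, params: ScanParams) -> list[HelendCandidate]:
    """Scan one scaffold on both strands for helend candidates.

    At most one candidate is emitted per (strand, terminal-motif end
    position); candidates are sorted by start coordinate.
    """
    s = seq.residues
    L = len(s)
    codes_fwd = _encode(s)
    codes_rev = _encode(reverse_complement(s))
    candidates: list[HelendCandidate] = []
    # group motif hits per strand, dedup on element-strand motif end position
    hits = find_terminal_motifs(seq, params)
    by_strand: dict[str, list[MotifHit]] = {"+": [], "-": []}
    seen_end: set[tuple[str, int]] = set()
    for h in hits:
        end_pos = h.end if h.strand == "+" else h.start
        if (h.strand, end_pos) in seen_end:
            continue
        seen_end.add((h.strand, end_pos))
        by_strand[h.strand].append(h)

    for strand, strand_hits in by_strand.items():
        if not strand_hits:
            continue
        if strand == "+":
            codes = codes_fwd
            pos0 = np.array([h.start - 1 for h in strand_hits], dtype=np.int64)
        else:
            codes = codes_rev
            pos0 = np.array([L - h.end for h in strand_hits], dtype=np.int64)
        keys = _scan_oriented_vector(codes, pos0, params)
        for h, key in zip(strand_hits, keys):
            if key >= _SENTINEL:
                continue
            geom = _decode_key(params, int(key))
            hairpin = _geometry_to_hairpin(seq, h, geom)
            end30, truncated = _extract_end30(seq, h)
            cid = f"{seq.id}:{h.end if strand == '+' else h.start}:{strand}"
            candidates.append(
                HelendCandidate(
                    candidate_id=cid,
                    motif_interval=Interval(seq.id, h.start, h.end, strand),
                    hairpin=hairpin,
                    terminal_motif=h.motif,
                    end30=end30,
                    strand=strand,
                    end30_truncated=truncated,
                )
            )
    candidates.sort(key=lambda c: (c.motif_interval.start, c.strand))
    return candidates


def _extract_end30(seq: GenomeSequence, motif: MotifHit) -> tuple[str, bool]:
    """30-mer on the element strand ending at the motif's last base."""
    if motif.strand == "+":
        lo = max(1, motif.end - 29)
        frag = seq.slice1(lo, motif.end)
    else:
        hi = min(seq.length, motif.start + 29)
        frag = reverse_complement(seq.slice1(motif.start, hi))
    return frag, len(frag) < 30


def scan_genome(
    genome: Iterable[GenomeSequence], params: ScanParams | None = None
) -> list[HelendCandidate]:
    """Scan a genome (collection of scaffolds) for helend candidates.

    Output is sorted by (scaffold, start); deterministic for identical
    input and parameters.
    """
    params = params or ScanParams()
    out: list[HelendCandidate] = []
    genome = list(genome)
    if not genome:
        raise ValueError("empty genome")
    for seq in genome:
        out.extend(scan_sequence(seq, params))
    out.sort(key=lambda c: (c.scaffold, c.motif_interval.start, c.strand))
    return out


# ---------------------------------------------------------------- output


CANDIDATE_TSV_COLUMNS = (
    "candidate_id scaffold start end strand motif stem_pairs mismatches "
    "loop spacer end30".split()
)


def candidates_to_rows(candidates: Sequence[HelendCandidate]) -> list[dict]:
    rows = []
    for c in candidates:
        rows.append(
            {
                "candidate_id": c.candidate_id,
                "scaffold": c.scaffold,
                "start": c.motif_interval.start,
                "end": c.motif_interval.end,
                "strand": c.strand,
                "motif": c.terminal_motif,
                "stem_pairs": c.hairpin.stem_pairs,
                "mismatches": c.hairpin.mismatches,
                "loop": c.hairpin.loop_len,
                "spacer": c.hairpin.spacer,
                "end30": c.end30,
            }
        )
    return rows


def write_candidates_tsv(candidates, path, header_lines: Sequence[str] = ()) -> None:
    import pandas as pd

    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(
            candidates_to_rows(candidates), columns=CANDIDATE_TSV_COLUMNS
        ).to_csv(fh, sep="\t", index=False)


def write_candidates_bed(candidates, path, header_lines: Sequence[str] = ()) -> None:
    """BED6: 0-based half-open motif interval, score = stem pairs."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for c in candidates:
            fh.write(
                f"{c.scaffold}\t{c.motif_interval.start - 1}\t{c.motif_interval.end}"
                f"\t{c.candidate_id}\t{c.hairpin.stem_pairs}\t{c.strand}\n"
            )
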