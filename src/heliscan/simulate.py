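"""Synthetic genomes with planted helitrons and full ground truth.

The generator emulates the conditions the detection pipeline is built
for: multi-scaffold assemblies near 50% GC carrying helitron families
with the canonical architecture —

    5' T[C/G] + head + body (optional RepHel ORF, cargo gene ORFs)
       + family-shared 3' block + hairpin (arm/loop/arm') + spacer
       + terminal CTRR-type 4-mer 3'

Every copy is inserted between an A and a T dinucleotide of the host
sequence (helitrons make no target-site duplication), with AT-enriched
50-bp flanks. Copies of one subfamily share head and body; subfamilies
of one family share the 3' tail (so the 30-bp 3' ends cluster at 100%
while 5' 30-mers diverge below the subfamily threshold); families have
mutually dissimilar tails. Truncated copies lose a random 5' fraction
(head, and the RepHel ORF when one is present). Point mutations, when
enabled, spare the terminal 30-mers so family membership stays a
controlled variable.

Seeds are mandatory and all randomness flows from one generator, so a
SimSpec reproduces byte-identical output.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np

from .expression import ReadPlacement
from .helend import ScanParams
from .rephel import HEL_MOTIFS, REP_MOTIFS, MotifModel, load_motif_models
from .sequence import (
    GenomeSequence,
    Interval,
    _CODON_TABLE,
    reverse_complement,
)

BASES = np.array(list("ACGT"))


@dataclasses.dataclass
class SubfamilySpec:
    body_len: int
    rephel: bool
    n_cargo: int
    copies: int
    truncation_fraction: float = 0.2
    mutation_rate: float = 0.0
    expression_rate: float = 0.1


@dataclasses.dataclass
class FamilySpec:
    arm: int = 10
    loop: int = 3
    spacer: int = 6
    motif: str = "CTGG"
    shared3_len: int = 40
    subfamilies: list[SubfamilySpec] = dataclasses.field(default_factory=list)


@dataclasses.dataclass
class SimSpec:
    seed: int
    genome_length: int = 1_000_000
    n_scaffolds: int = 4
    gc: float = 0.51  # background AT content 0.49, as in the genomes emulated
    flank_at: float = 0.57  # AT fraction of the measured 50-bp flanks
    flank_len: int = 50
    margin: int = 4000  # keep insertions away from scaffold edges
    spacing: int = 1500  # minimum distance between insertion sites
    families: list[FamilySpec] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("SimSpec requires an explicit seed")
        if not (0.0 <= self.gc <= 1.0 and 0.0 <= self.flank_at <= 1.0):
            raise ValueError("fractions must lie in [0,1]")
        for fam in self.families:
            for sub in fam.subfamilies:
                if not 0.0 <= sub.truncation_fraction <= 1.0:
                    raise ValueError("truncation_fraction outside [0,1]")
                if sub.copies < 1:
                    raise ValueError("copies must be >= 1")


def default_simspec(seed: int) -> SimSpec:
    """Three families, two subfamilies each, five copies per subfamily
    (30 elements), one RepHel-bearing subfamily per family (half the
    copies autonomous by template), 20% truncation."""
    return SimSpec(
        seed=seed,
        families=[
            FamilySpec(
                arm=10, loop=3, spacer=6, motif="CTGG",
                subfamilies=[
                    SubfamilySpec(2200, True, 1, 5, expression_rate=0.8),
                    SubfamilySpec(1500, False, 2, 5, expression_rate=0.1),
                ],
            ),
            FamilySpec(
                arm=12, loop=2, spacer=7, motif="CTAG",
                subfamilies=[
                    SubfamilySpec(2400, True, 1, 5, expression_rate=0.4),
                    SubfamilySpec(1000, False, 1, 5, expression_rate=0.05),
                ],
            ),
            FamilySpec(
                arm=8, loop=4, spacer=5, motif="CTTG",
                subfamilies=[
                    SubfamilySpec(2000, True, 2, 5, expression_rate=0.2),
                    SubfamilySpec(800, False, 1, 5, expression_rate=0.02),
                ],
            ),
        ],
    )


@dataclasses.dataclass
class TruthAnnotation:
    """Ground truth for one planted copy (mirror of a called element)."""

    element_id: str
    family: int  # 1-based template indices (not the recovered ids)
    subfamily: int
    interval: Interval
    truncated: bool
    autonomous: bool
    end3: int  # plus-strand coordinate of the terminal motif's last base
    rephel: Optional[Interval]
    cargo: list[tuple[str, Interval]]
    hairpin_arm: int
    hairpin_loop: int
    spacer: int
    motif: str
    expression_rate: float


@dataclasses.dataclass
class GeneRow:
    gene_id: str
    name: str
    interval: Interval
    is_rephel: bool


@dataclasses.dataclass
class SimResult:
    spec: SimSpec
    genome: list[GenomeSequence]
    truth: list[TruthAnnotation]
    genes: list[GeneRow]


# --------------------------------------------------------- raw sequence


def _rand_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    if n <= 0:
        return ""
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=p))


def random_genome(spec: SimSpec, rng: np.random.Generator | None = None) -> list[GenomeSequence]:
    """Background scaffolds: i.i.d. bases at the configured GC."""
    rng = rng or np.random.default_rng(spec.seed)
    per = spec.genome_length // spec.n_scaffolds
    out = []
    for i in range(spec.n_scaffolds):
        n = per if i < spec.n_scaffolds - 1 else spec.genome_length - per * (
            spec.n_scaffolds - 1
        )
        out.append(GenomeSequence(id=f"scaffold_{i+1}", residues=_rand_dna(rng, n, spec.gc)))
    return out


# ------------------------------------------------------ element master


_AA_TO_CODON: dict[str, str] = {}
_SYNONYMS: dict[str, list[str]] = {}
for codon in sorted(_CODON_TABLE):
    aa = _CODON_TABLE[codon]
    _AA_TO_CODON.setdefault(aa, codon)
    if "N" not in codon:
        _SYNONYMS.setdefault(aa, []).append(codon)


def _protein_to_dna(protein: str) -> str:
    return "".join(_AA_TO_CODON[aa] for aa in protein)


def rephel_orf_dna(
    models: Sequence[MotifModel] | None = None,
    rng: np.random.Generator | None = None,
) -> str:
    """A compact RepHel ORF: Rep motif consensus blocks followed by the
    helicase motif blocks, joined by linkers, with start and stop.

    Deliberately much shorter than a natural RepHel protein so that it
    fits comfortably inside desk-scale simulated elements. With an rng,
    linker residues and codon choices are randomized, mimicking real
    RepHel genes: homologous at the protein-motif level but divergent
    as DNA (deterministic DNA would give every family an identical ORF
    and with it unrealistic genome-wide self-similarity)."""
    models = models or load_motif_models()
    by_name = {m.name: m for m in models}
    aas = sorted(a for a in _AA_TO_CODON if a not in "*X")

    def linker() -> str:
        if rng is None:
            return "GSSGQA"
        return "".join(rng.choice(aas) for _ in range(6))

    parts = ["M", linker()]
    for name in REP_MOTIFS:
        parts += [by_name[name].consensus, linker()]
    parts.append(linker())  # widen the rep/helicase gap slightly
    for name in HEL_MOTIFS:
        parts += [by_name[name].consensus, linker()]
    protein = "".join(parts)
    if rng is None:
        return _protein_to_dna(protein) + "TAA"
    dna = "".join(
        _SYNONYMS[aa][rng.integers(0, len(_SYNONYMS[aa]))] for aa in protein
    )
    return dna + "TAA"


def _cargo_orf_dna(rng: np.random.Generator, n_codons: int = 98) -> str:
    aas = [a for a in _AA_TO_CODON if a not in "*X"]
    body = "".join(rng.choice(aas) for _ in range(n_codons))
    return _protein_to_dna("M" + body) + "TAA"


@dataclasses.dataclass
class ElementMaster:
    """The master sequence of one subfamily plus local (0-based) truth."""

    family_idx: int  # 1-based
    subfamily_idx: int
    seq: str
    rephel_local: Optional[tuple[int, int]]  # 0-based inclusive
    cargo_local: list[tuple[str, int, int]]
    arm: int
    loop: int
    spacer: int
    motif: str


def build_element(
    family: FamilySpec,
    sub: SubfamilySpec,
    rng: np.random.Generator,
    spec: SimSpec,
    family_idx: int = 1,
    subfamily_idx: int = 1,
    params: ScanParams | None = None,
    decoy: bool = False,
    tail_override: str | None = None,
    head_override: str | None = None,
) -> ElementMaster:
    """Assemble a subfamily master element and its local annotation.

    The template is validated against the scan bounds unless ``decoy``
    is set (decoys deliberately violate them, e.g. an oversized spacer).
    """
    params = params or ScanParams()
    if not decoy:
        ok = (
            params.min_stem_pairs <= family.arm <= params.max_stem_pairs
            and params.loop_min <= family.loop <= params.loop_max
            and params.spacer_min <= family.spacer <= params.spacer_max
            and family.motif in params.terminal_motifs
        )
        if not ok:
            raise ValueError(
                "template geometry violates scan bounds (use decoy=True "
                "to plant a deliberately non-compliant element)"
            )
    head = head_override or (
        "T" + ("C" if rng.random() < 0.5 else "G") + _rand_dna(rng, 28, spec.gc)
    )
    # body with optional ORFs
    cursor = 60
    rephel_local = None
    cargo_local: list[tuple[str, int, int]] = []
    pieces: list[str] = []
    filled = 0

    def pad_to(target: int) -> None:
        nonlocal filled
        if target > filled:
            pieces.append(_rand_dna(rng, target - filled, spec.gc))
            filled = target

    if sub.rephel:
        pad_to(cursor)
        orf = rephel_orf_dna(rng=rng)
        rephel_local = (filled, filled + len(orf) - 1)
        pieces.append(orf)
        filled += len(orf)
        cursor = filled + 60
    for k in range(sub.n_cargo):
        pad_to(cursor)
        orf = _cargo_orf_dna(rng)
        cargo_local.append((f"cap{chr(ord('A') + k)}", filled, filled + len(orf) - 1))
        pieces.append(orf)
        filled += len(orf)
        cursor = filled + 60
    if filled > sub.body_len:
        raise ValueError(
            f"body_len {sub.body_len} too small for its ORFs ({filled} bp needed)"
        )
    pad_to(sub.body_len)
    body = "".join(pieces)

    if tail_override is not None:
        tail = tail_override
    else:
        shared3 = _rand_dna(rng, family.shared3_len, spec.gc)
        arm5 = _rand_dna(rng, family.arm, spec.gc)
        loop = _rand_dna(rng, family.loop, spec.gc)
        spacer_seq = _rand_dna(rng, family.spacer, spec.gc)
        tail = shared3 + arm5 + loop + reverse_complement(arm5) + spacer_seq + family.motif
    seq = head + body + tail
    off = len(head)
    return ElementMaster(
        family_idx=family_idx,
        subfamily_idx=subfamily_idx,
        seq=seq,
        rephel_local=(
            (rephel_local[0] + off, rephel_local[1] + off) if rephel_local else None
        ),
        cargo_local=[(n, a + off, b + off) for n, a, b in cargo_local],
        arm=family.arm,
        loop=family.loop,
        spacer=family.spacer,
        motif=family.motif,
    )


def _identity_pct(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n * 100.0


def build_masters(spec: SimSpec, rng: np.random.Generator) -> list[ElementMaster]:
    """Masters for every subfamily, honouring the identity constraints:
    family 3' 30-mers mutually < 80% identical, subfamily 5' 30-mers of
    one family < 80% identical (regenerated until satisfied)."""
    masters: list[ElementMaster] = []
    end30s: list[str] = []
    for fi, fam in enumerate(spec.families, start=1):
        # shared tail per family, re-drawn until distinct from other families
        for _ in range(100):
            shared3 = _rand_dna(rng, fam.shared3_len, spec.gc)
            arm5 = _rand_dna(rng, fam.arm, spec.gc)
            loop = _rand_dna(rng, fam.loop, spec.gc)
            spacer_seq = _rand_dna(rng, fam.spacer, spec.gc)
            tail = (
                shared3 + arm5 + loop + reverse_complement(arm5)
                + spacer_seq + fam.motif
            )
            end30 = tail[-30:]
            if all(_identity_pct(end30, other) < 80.0 for other in end30s):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not draw a distinct family tail")
        end30s.append(end30)
        heads: list[str] = []
        for si, sub in enumerate(fam.subfamilies, start=1):
            for _ in range(100):
                head = (
                    "T" + ("C" if rng.random() < 0.5 else "G")
                    + _rand_dna(rng, 28, spec.gc)
                )
                if all(_identity_pct(head, h) < 80.0 for h in heads):
                    break
            else:  # pragma: no cover
                raise RuntimeError("could not draw a distinct subfamily head")
            heads.append(head)
            masters.append(
                build_element(
                    fam, sub, rng, spec,
                    family_idx=fi, subfamily_idx=si,
                    tail_override=tail, head_override=head,
                )
            )
    return masters


# ------------------------------------------------------------- planting


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Point mutations at ``rate`` per bp, sparing both terminal 30-mers."""
    if rate <= 0 or len(seq) <= 60:
        return seq
    arr = np.array(list(seq))
    hit = np.nonzero(rng.random(len(seq) - 60) < rate)[0] + 30
    for i in hit:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def plant_elements(
    genome: list[GenomeSequence],
    masters: Sequence[ElementMaster],
    spec: SimSpec,
    rng: np.random.Generator,
) -> tuple[list[GenomeSequence], list[TruthAnnotation], list[GeneRow]]:
    """Insert element copies into AT dinucleotides of the background.

    Each copy lands between an A and a T; 49 bp on each side of the
    junction is re-drawn at an AT rate chosen so the measured 50-bp
    flank (which includes the junction A or T) has the configured AT
    fraction in expectation. Truncated copies keep a random 3' fraction
    of the element; point mutations follow the subfamily rate.
    """
    flank_inner = spec.flank_len - 1
    # flank AT rate for the 49 drawn bases, so that the 50-bp flank
    # (junction base included) averages exactly spec.flank_at
    q = (spec.flank_len * spec.flank_at - 1) / flank_inner
    if not 0.0 <= q <= 1.0:
        raise ValueError("flank_at incompatible with flank_len")

    sub_lookup = {
        (m.family_idx, m.subfamily_idx): sub
        for m, sub in zip(
            masters,
            [s for fam in spec.families for s in fam.subfamilies],
        )
    }

    # eligible AT sites per scaffold
    site_pool: list[tuple[int, int]] = []  # (scaffold index, 0-based pos of A)
    for gi, g in enumerate(genome):
        s = g.residues
        p = s.find("AT", spec.margin)
        while p != -1 and p < g.length - spec.margin:
            site_pool.append((gi, p))
            p = s.find("AT", p + 1)
    if not site_pool:
        raise ValueError("insufficient AT dinucleotide sites for planting")

    chosen: dict[int, list[int]] = {gi: [] for gi in range(len(genome))}
    placements = []  # (scaffold idx, pos, master, truncated, strand, copy idx)
    order = rng.permutation(len(site_pool))
    cursor = 0
    copy_counter = 0
    for master in masters:
        sub = sub_lookup[(master.family_idx, master.subfamily_idx)]
        for _copy in range(sub.copies):
            truncated = bool(rng.random() < sub.truncation_fraction)
            strand = "+" if rng.random() < 0.5 else "-"
            placed = False
            while cursor < len(order):
                gi, p = site_pool[order[cursor]]
                cursor += 1
                if all(abs(p - q0) >= spec.spacing for q0 in chosen[gi]):
                    chosen[gi].append(p)
                    placements.append(
                        (gi, p, master, truncated, strand, copy_counter)
                    )
                    placed = True
                    break
            if not placed:
                raise ValueError("insufficient AT dinucleotide sites for planting")
            copy_counter += 1

    truths: list[TruthAnnotation] = []
    genes: list[GeneRow] = []
    new_genome: list[GenomeSequence] = []
    by_scaffold: dict[int, list] = {gi: [] for gi in range(len(genome))}
    for rec in placements:
        by_scaffold[rec[0]].append(rec)

    for gi, g in enumerate(genome):
        bg = g.residues
        recs = sorted(by_scaffold[gi], key=lambda r: r[1])
        parts: list[str] = []
        prev = 0
        out_len = 0
        for _gi, p, master, truncated, strand, copy_idx in recs:
            sub = sub_lookup[(master.family_idx, master.subfamily_idx)]
            elem = master.seq
            cut = 0
            if truncated:
                cut = int(len(elem) * rng.uniform(0.35, 0.65))
            elem = elem[cut:]
            elem = _mutate(elem, sub.mutation_rate, rng)
            # local features surviving truncation, coordinates after the cut
            rephel_loc = None
            if master.rephel_local and master.rephel_local[0] >= cut:
                rephel_loc = (
                    master.rephel_local[0] - cut,
                    master.rephel_local[1] - cut,
                )
            cargo_loc = [
                (n, a - cut, b - cut)
                for n, a, b in master.cargo_local
                if a >= cut
            ]
            left = _rand_dna(rng, flank_inner, 1 - q)
            right = _rand_dna(rng, flank_inner, 1 - q)
            ins = elem if strand == "+" else reverse_complement(elem)
            parts.append(bg[prev : p - flank_inner])
            out_len += (p - flank_inner) - prev
            parts.append(left + "A")
            out_len += flank_inner + 1
            start = out_len + 1  # 1-based element start
            parts.append(ins)
            out_len += len(ins)
            end = out_len
            parts.append("T" + right)
            out_len += 1 + flank_inner
            prev = p + 2 + flank_inner

            L = len(ins)

            def to_genomic(lo: int, hi: int) -> Interval:
                if strand == "+":
                    return Interval(g.id, start + lo, start + hi, "+")
                return Interval(g.id, start + (L - 1 - hi), start + (L - 1 - lo), "-")

            eid = f"elem_{copy_idx:03d}"
            rephel_iv = to_genomic(*rephel_loc) if rephel_loc else None
            cargo_iv = [(n, to_genomic(a, b)) for n, a, b in cargo_loc]
            truths.append(
                TruthAnnotation(
                    element_id=eid,
                    family=master.family_idx,
                    subfamily=master.subfamily_idx,
                    interval=Interval(g.id, start, end, strand),
                    truncated=truncated,
                    autonomous=rephel_loc is not None,
                    end3=end if strand == "+" else start,
                    rephel=rephel_iv,
                    cargo=cargo_iv,
                    hairpin_arm=master.arm,
                    hairpin_loop=master.loop,
                    spacer=master.spacer,
                    motif=master.motif,
                    expression_rate=sub.expression_rate,
                )
            )
            if rephel_iv is not None:
                genes.append(
                    GeneRow(f"{eid}_rephel", "RepHel", rephel_iv, True)
                )
            for n, iv in cargo_iv:
                genes.append(GeneRow(f"{eid}_{n}", n, iv, False))
        parts.append(bg[prev:])
        new_genome.append(GenomeSequence(id=g.id, residues="".join(parts)))
    truths.sort(key=lambda t: (t.interval.scaffold, t.interval.start))
    genes.sort(key=lambda r: (r.interval.scaffold, r.interval.start))
    return new_genome, truths, genes


def simulate(spec: SimSpec) -> SimResult:
    """Full generation: background genome, masters, planting."""
    rng = np.random.default_rng(spec.seed)
    genome = random_genome(spec, rng)
    masters = build_masters(spec, rng)
    genome, truth, genes = plant_elements(genome, masters, spec, rng)
    return SimResult(spec=spec, genome=genome, truth=truth, genes=genes)


# ------------------------------------------------------------ reads


def simulate_reads(
    genome: list[GenomeSequence],
    truth: Sequence[TruthAnnotation],
    rng: np.random.Generator,
    rates: dict[str, float] | None = None,
    read_len: int = 50,
    depth: float = 50.0,
    background_rate: float = 0.02,
) -> list[ReadPlacement]:
    """Reads placed uniformly within expressed elements at Poisson counts
    proportional to rate x length, plus uniform background reads."""
    placements: list[ReadPlacement] = []
    ridx = 0
    for t in truth:
        rate = (rates or {}).get(t.element_id, t.expression_rate)
        lam = rate * t.interval.length * depth / read_len
        n = int(rng.poisson(lam)) if lam > 0 else 0
        span = t.interval.length - read_len
        for _ in range(n):
            off = int(rng.integers(0, max(1, span + 1)))
            s = t.interval.start + off
            placements.append(
                ReadPlacement(f"read_{ridx}", t.interval.scaffold, s, s + read_len - 1)
            )
            ridx += 1
    total_bp = sum(g.length for g in genome)
    n_bg = int(rng.poisson(background_rate * total_bp * depth / read_len))
    lens = np.array([g.length for g in genome], dtype=float)
    probs = lens / lens.sum()
    for _ in range(n_bg):
        gi = int(rng.choice(len(genome), p=probs))
        g = genome[gi]
        s = int(rng.integers(1, max(2, g.length - read_len + 1)))
        placements.append(
            ReadPlacement(f"read_{ridx}", g.id, s, min(g.length, s + read_len - 1))
        )
        ridx += 1
    return placements


# ------------------------------------------------------------ writers


def write_truth_gff3(truth: Sequence[TruthAnnotation], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truth:
            iv = t.interval
            attrs = (
                f"ID={t.element_id};family={t.family};subfamily={t.subfamily};"
                f"truncated={str(t.truncated).lower()};"
                f"autonomous={str(t.autonomous).lower()}"
            )
            fh.write(
                f"{iv.scaffold}\thelitron-sim\tmobile_genetic_element\t"
                f"{iv.start}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def write_genes_gff3(genes: Sequence[GeneRow], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            attrs = f"ID={g.gene_id};Name={g.name};rephel={str(g.is_rephel).lower()}"
            fh.write(
                f"{iv.scaffold}\thelitron-sim\tgene\t{iv.start}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def write_placements_tsv(placements: Sequence[ReadPlacement], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tscaffold\tstart\tend\tn_placements\n")
        for p in placements:
            fh.write(f"{p.read_id}\t{p.scaffold}\t{p.start}\t{p.end}\t{p.n_placements}\n")


def write_simspec(spec: SimSpec, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"seed={spec.seed}\n")
        fh.write(f"genome_length={spec.genome_length}\n")
        fh.write(f"n_scaffolds={spec.n_scaffolds}\n")
        fh.write(f"gc={spec.gc}\nflank_at={spec.flank_at}\n")
        for i, fam in enumerate(spec.families, 1):
            fh.write(
                f"family{i}=arm:{fam.arm},loop:{fam.loop},spacer:{fam.spacer},"
                f"motif:{fam.motif}\n"
            )
            for j, sub in enumerate(fam.subfamilies, 1):
                fh.write(
                    f"family{i}.{j}=body:{sub.body_len},rephel:{sub.rephel},"
                    f"cargo:{sub.n_cargo},copies:{sub.copies},"
                    f"trunc:{sub.truncation_fraction},mut:{sub.mutation_rate},"
                    f"expr:{sub.expression_rate}\n"
                )
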