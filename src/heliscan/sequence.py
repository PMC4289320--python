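"""Sequence I/O and elementary nucleotide/protein utilities.

All genomic coordinates at external interfaces are 1-based inclusive
(the convention of GFF3 and of published element tables). ``N`` bases
never pair, never match in identity computations, and are excluded from
composition denominators: unmasked assemblies contain gap runs and those
must not inflate any statistic.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

VALID_DNA = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: standard genetic code, stops rendered as '*'
_CODON_TABLE: dict[str, str] = {}


def _build_codon_table() -> None:
    bases = "TCAG"
    aas = (
        "FFLLSSSSYY**CC*W"
        "LLLLPPPPHHQQRRRR"
        "IIIMTTTTNNKKSSRR"
        "VVVVAAAADDEEGGGG"
    )
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1


_build_codon_table()


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
        self.line = line


@dataclasses.dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence (one scaffold of an assembly)."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - VALID_DNA
        if bad:
            raise ValueError(
                f"scaffold {self.id!r}: non-IUPAC residues {sorted(bad)}"
            )
        if not self.residues:
            raise ValueError(f"scaffold {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def gc(self) -> float:
        return gc_content(self.residues)

    def slice1(self, start: int, end: int) -> str:
        """Residues for the 1-based inclusive interval [start, end]."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"interval {start}-{end} outside scaffold {self.id!r} "
                f"(length {self.length})"
            )
        return self.residues[start - 1 : end]


@dataclasses.dataclass(frozen=True, order=True)
class Interval:
    """A 1-based inclusive stranded genomic interval."""

    scaffold: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise ValueError(f"bad interval {self.start}-{self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def read_fasta(path) -> list[GenomeSequence]:
    """Read a (multi-)FASTA file into :class:`GenomeSequence` records.

    Residues are uppercased on ingest (soft-masking is discarded); file
    order is preserved; duplicate ids and non-IUPAC residues are rejected.
    """
    records: list[GenomeSequence] = []
    seen: set[str] = set()
    # SeqIO tolerates many malformed inputs silently; pre-check structure
    # line by line so errors can name the offending line.
    with open(path) as fh:
        lineno = 0
        header_seen = False
        for raw in fh:
            lineno += 1
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                header_seen = True
                if len(line) == 1:
                    raise FastaFormatError("empty FASTA header", lineno)
            else:
                if not header_seen:
                    raise FastaFormatError(
                        "sequence data before first header", lineno
                    )
                bad = set(line.upper()) - VALID_DNA
                if bad:
                    raise FastaFormatError(
                        f"non-IUPAC residues {sorted(bad)}", lineno
                    )
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in seen:
            raise FastaFormatError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if not residues:
            raise FastaFormatError(f"empty record {rec.id!r}")
        records.append(GenomeSequence(id=rec.id, residues=residues))
    if not records:
        raise FastaFormatError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path, width: int = 80) -> None:
    """Write records as FASTA, wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.residues[i : i + width] + "\n")


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution; N maps to N."""
    seq = seq.upper()
    bad = set(seq) - VALID_DNA
    if bad:
        raise ValueError(f"cannot reverse-complement residues {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


_TRANS_BYTES = bytes.maketrans(b"ACGTN", bytes([0, 1, 2, 3, 4]))
_AA_LUT: "object" = None


def _codon_lut():
    """125-entry base-5 codon -> amino-acid lookup (N anywhere -> X)."""
    global _AA_LUT
    if _AA_LUT is None:
        import numpy as np

        lut = np.full(125, ord("X"), dtype=np.uint8)
        order = "ACGTN"
        for i, b1 in enumerate(order[:4]):
            for j, b2 in enumerate(order[:4]):
                for k, b3 in enumerate(order[:4]):
                    lut[i * 25 + j * 5 + k] = ord(_CODON_TABLE[b1 + b2 + b3])
        _AA_LUT = lut
    return _AA_LUT


def translate_frame(seq: str, frame: int) -> str:
    """Translate one forward frame; '*' for stops, translation spans stops."""
    s = seq[frame:]
    n = len(s) - len(s) % 3
    if n >= 300:
        import numpy as np

        codes = np.frombuffer(s[:n].encode().translate(_TRANS_BYTES), dtype=np.uint8)
        codes = codes.reshape(-1, 3).astype(np.int32)
        idx = codes[:, 0] * 25 + codes[:, 1] * 5 + codes[:, 2]
        return _codon_lut()[idx].tobytes().decode()
    return "".join(
        _CODON_TABLE.get(s[i : i + 3], "X") for i in range(0, n, 3)
    )


def translate_three_frames(seq: str) -> tuple[str, str, str]:
    """Translate the three forward reading frames (standard code).

    Stop codons are rendered as ``*`` and do not halt translation, so a
    downstream domain scan can span them. Codons containing N translate
    to ``X``. Trailing partial codons are dropped.
    """
    if len(seq) < 3:
        raise ValueError("sequence shorter than one codon")
    return tuple(translate_frame(seq, f) for f in (0, 1, 2))  # type: ignore[return-value]


def at_content(seq: str) -> float:
    """(A+T) / non-N length. Undefined (ValueError) for empty or all-N input."""
    if not seq:
        raise ValueError("at_content of empty sequence")
    seq = seq.upper()
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("at_content undefined: all-N sequence")
    return (seq.count("A") + seq.count("T")) / denom


def gc_content(seq: str) -> float:
    """(G+C) / non-N length; complements :func:`at_content` for N-free input."""
    if not seq:
        raise ValueError("gc_content of empty sequence")
    seq = seq.upper()
    denom = len(seq) - seq.count("N")
    if denom == 0:
        raise ValueError("gc_content undefined: all-N sequence")
    return (seq.count("G") + seq.count("C")) / denom


def iter_scaffold_map(genome: Iterable[GenomeSequence]) -> dict[str, GenomeSequence]:
    out: dict[str, GenomeSequence] = {}
    for g in genome:
        if g.id in out:
            raise ValueError(f"duplicate scaffold id {g.id!r}")
        out[g.id] = g
    return out
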