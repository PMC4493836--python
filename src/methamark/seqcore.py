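"""IUPAC degenerate-sequence algebra and sequence file I/O.

Degenerate PCR primers are written over the 15-letter IUPAC nucleotide
alphabet, where an ambiguity code such as ``R`` stands for the base set
{A, G}.  A degenerate oligo therefore denotes a pool of concrete
sequences; its *degeneracy* is the pool size, the product of the
per-position set sizes.  This module provides that algebra (expansion,
degeneracy, reverse complement, per-base matching) together with the
FASTA/FASTQ plumbing used by every other module.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from itertools import product as _iproduct
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

# ---------------------------------------------------------------------------
# IUPAC tables
# ---------------------------------------------------------------------------

#: IUPAC nucleotide ambiguity codes -> set of concrete bases.
IUPAC_EXPANSION: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

IUPAC_CODES = frozenset(IUPAC_EXPANSION)

_BASE_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: code of the complemented base set (R<->Y, K<->M, D<->H, V<->B, W/S/N fixed)
IUPAC_COMPLEMENT: dict[str, str] = {
    code: next(
        c
        for c, s in IUPAC_EXPANSION.items()
        if s == frozenset(_BASE_COMPLEMENT[b] for b in bases)
    )
    for code, bases in IUPAC_EXPANSION.items()
}

# 4-bit mask per code (A=1, C=2, G=4, T=8) for vectorised matching.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8}
IUPAC_MASK: dict[str, int] = {
    code: sum(_BASE_BIT[b] for b in bases) for code, bases in IUPAC_EXPANSION.items()
}

#: 256-entry lookup: ASCII ordinal -> bit mask (0 for invalid characters).
MASK_TABLE = np.zeros(256, dtype=np.uint8)
for _code, _mask in IUPAC_MASK.items():
    MASK_TABLE[ord(_code)] = _mask
    MASK_TABLE[ord(_code.lower())] = _mask
MASK_TABLE[ord("U")] = _BASE_BIT["T"]
MASK_TABLE[ord("u")] = _BASE_BIT["T"]

#: Hard cap on materialised expansions; degeneracy itself is always cheap.
DEFAULT_EXPANSION_CAP = 10**6


class InvalidIupacError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""

    def __init__(self, char: str, position: int, context: str = ""):
        self.char = char
        self.position = position
        msg = f"invalid IUPAC nucleotide code {char!r} at position {position}"
        if context:
            msg = f"{context}: {msg}"
        super().__init__(msg)


def normalize_seq(seq: str, context: str = "") -> str:
    """Uppercase, map U->T, and validate against the IUPAC alphabet."""
    up = seq.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in IUPAC_CODES:
            raise InvalidIupacError(ch, i, context)
    return up


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DegenerateOligo:
    """An IUPAC-ambiguity nucleotide string, e.g. a degenerate primer."""

    name: str
    seq: str
    orientation: str = "forward"  # forward | reverse

    def __post_init__(self):
        object.__setattr__(self, "seq", normalize_seq(self.seq, context=self.name))
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"orientation must be forward|reverse, got {self.orientation!r}")

    def __len__(self) -> int:
        return len(self.seq)

    @property
    def degeneracy(self) -> int:
        return degeneracy(self)


@dataclass
class NucleotideRecord:
    """A named nucleotide sequence (may contain IUPAC ambiguity codes)."""

    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.seq:
            raise ValueError(f"record {self.id!r}: sequence must be non-empty")
        self.seq = self.seq.upper().replace("U", "T")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class ReadPair:
    """A paired-end read with Phred quality scores (one pair, both mates)."""

    id: str
    seq1: str
    seq2: str
    qual1: list[int]
    qual2: list[int]

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read pair {self.id!r}: sequence/quality length mismatch")


# ---------------------------------------------------------------------------
# Degenerate algebra
# ---------------------------------------------------------------------------


def _as_seq(oligo: DegenerateOligo | str) -> str:
    if isinstance(oligo, DegenerateOligo):
        return oligo.seq
    return normalize_seq(oligo)


def degeneracy(oligo: DegenerateOligo | str) -> int:
    """Number of concrete sequences the oligo denotes.

    Computed multiplicatively from per-position set sizes, never by
    enumeration, so N-rich oligos stay cheap.
    """
    seq = _as_seq(oligo)
    d = 1
    for ch in seq:
        d *= len(IUPAC_EXPANSION[ch])
    return d


def expand(oligo: DegenerateOligo | str, cap: int = DEFAULT_EXPANSION_CAP) -> set[str]:
    """Materialise the set of concrete A/C/G/T sequences an oligo denotes.

    Raises ``ValueError`` when the degeneracy exceeds *cap* (default 10^6):
    enumeration of such pools is almost certainly a mistake.
    """
    seq = _as_seq(oligo)
    d = degeneracy(seq)
    if d > cap:
        raise ValueError(f"degeneracy {d} exceeds expansion cap {cap}")
    return {"".join(p) for p in _iproduct(*(sorted(IUPAC_EXPANSION[ch]) for ch in seq))}


def revcomp(oligo: DegenerateOligo | str) -> DegenerateOligo | str:
    """Reverse complement; ambiguity codes map to the code of the
    complemented base set (R<->Y, K<->M, D<->H, V<->B; W, S, N fixed)."""
    if isinstance(oligo, DegenerateOligo):
        rc = "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(oligo.seq))
        flipped = "reverse" if oligo.orientation == "forward" else "forward"
        return DegenerateOligo(name=oligo.name, seq=rc, orientation=flipped)
    seq = _as_seq(oligo)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(seq))


def base_match(primer_code: str, template_code: str, strict: bool = False) -> bool:
    """Does a primer position bind a template position?

    Default semantics: the two expansions intersect (a template ``N`` in a
    draft genome matches any primer base).  With ``strict=True`` the
    template expansion must be a subset of the primer expansion.
    """
    p = IUPAC_MASK.get(primer_code.upper().replace("U", "T"))
    t = IUPAC_MASK.get(template_code.upper().replace("U", "T"))
    if p is None:
        raise InvalidIupacError(primer_code, 0, "primer")
    if t is None:
        raise InvalidIupacError(template_code, 0, "template")
    if strict:
        return (t & ~p) == 0
    return (p & t) != 0


def encode_mask(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array of IUPAC bit masks.

    Invalid characters encode to 0 (they match nothing) and are reported
    by :func:`normalize_seq` where validation is wanted.
    """
    return MASK_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


# ---------------------------------------------------------------------------
# File I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[NucleotideRecord]:
    """Read a (possibly empty) multi-record FASTA file."""
    records = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.id!r} (#{i + 1}) has an empty sequence")
        records.append(
            NucleotideRecord(id=rec.id, seq=str(rec.seq), description=rec.description)
        )
    return records


def write_fasta(records: Iterable[NucleotideRecord], path: str | Path, wrap: int = 60) -> None:
    """Write records as FASTA, wrapped at *wrap* columns."""
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id
            if rec.description and rec.description != rec.id:
                header = rec.description if rec.description.startswith(rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), wrap):
                fh.write(rec.seq[i : i + wrap] + "\n")


def read_fastq(path: str | Path) -> list[tuple[str, str, list[int]]]:
    """Read FASTQ (Phred+33) as (id, sequence, quality) tuples."""
    out = []
    try:
        for rec in SeqIO.parse(str(path), "fastq"):
            out.append((rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    except ValueError as exc:  # Biopython flags seq/qual length mismatches etc.
        raise ValueError(f"{path}: malformed FASTQ record near record {len(out) + 1}: {exc}") from exc
    return out


def write_fastq(reads: Iterable[tuple[str, str, list[int]]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            if len(seq) != len(qual):
                raise ValueError(f"read {rid!r}: sequence/quality length mismatch")
            fh.write(f"@{rid}\n{seq}\n+\n{''.join(chr(q + 33) for q in qual)}\n")


def read_fastq_pairs(path1: str | Path, path2: str | Path) -> list[ReadPair]:
    """Read two synchronised FASTQ files into :class:`ReadPair` objects."""
    r1 = read_fastq(path1)
    r2 = read_fastq(path2)
    if len(r1) != len(r2):
        raise ValueError(
            f"paired FASTQ files differ in record count: {len(r1)} vs {len(r2)}"
        )
    return [
        ReadPair(id=a[0], seq1=a[1], qual1=a[2], seq2=b[1], qual2=b[2])
        for a, b in zip(r1, r2)
    ]


def translate(seq: str, frame: int) -> str:
    """Translate one reading frame (+1..+3 forward, -1..-3 on the reverse
    complement) with the standard genetic code; '*' marks stops."""
    if frame not in (1, 2, 3, -1, -2, -3):
        raise ValueError(f"frame must be in ±1..±3, got {frame}")
    s = seq if frame > 0 else str(Seq(seq).reverse_complement())
    off = abs(frame) - 1
    coding = s[off : off + 3 * ((len(s) - off) // 3)]
    return str(Seq(coding).translate())


# ---------------------------------------------------------------------------
# Primer fixtures
# ---------------------------------------------------------------------------


def load_primer_table() -> pd.DataFrame:
    """The four published degenerate primer pairs (8 oligos) targeting the
    mcrB, mcrG, mtaB and mtbA methanogenesis marker genes."""
    with importlib.resources.files("methamark.data").joinpath("primers_table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
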