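"""Amplicon read validation: merge, translated search, filters, sensitivity.

This is the high-throughput validation stage for degenerate marker-gene
primers.  Paired reads are merged on their overlap, merged reads are
translated in all six frames and searched against a reference peptide
set by local alignment (BLOSUM62, affine gaps, Karlin–Altschul
E-values), and the surviving translated fragments — "inferred peptides"
— are counted.  Primer sensitivity is the fraction of merged reads that
yield an inferred peptide, reported as a floor integer percent.

Reads are discarded when they have no reference hit at the E-value
threshold, when the best HSP contains a stop codon (a frameshift
symptom), or when the HSP peptide is shorter than 30 amino acids.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner, substitution_matrices

from .seqcore import NucleotideRecord, ReadPair, revcomp, translate

# Karlin–Altschul parameters for gapped BLOSUM62 with gap cost 11 + k
# (existence 11, extension 1) — the standard constants used by BLAST.
KA_LAMBDA = 0.267
KA_K = 0.041


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ProteinRecord:
    id: str
    seq: str
    description: str = ""

    def __post_init__(self):
        if not self.id or not self.seq:
            raise ValueError("protein record needs a non-empty id and sequence")
        self.seq = self.seq.upper()


def read_protein_fasta(path) -> list[ProteinRecord]:
    return [
        ProteinRecord(id=r.id, seq=str(r.seq), description=r.description)
        for r in SeqIO.parse(str(path), "fasta")
    ]


@dataclass
class MergeConfig:
    min_overlap: int = 10
    max_overlap_mismatch_fraction: float = 0.25

    def __post_init__(self):
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0 <= self.max_overlap_mismatch_fraction <= 1:
            raise ValueError("mismatch fraction must be in [0, 1]")


@dataclass
class PipelineConfig:
    evalue_threshold: float = 0.001
    min_peptide_len_aa: int = 30
    discard_stop_codons: bool = True
    substitution_matrix: str = "BLOSUM62"
    db_size_for_evalue: float = 1e6  # effective search-space letters

    def __post_init__(self):
        if self.evalue_threshold <= 0 or self.min_peptide_len_aa <= 0 or self.db_size_for_evalue <= 0:
            raise ValueError("pipeline thresholds must be positive")


@dataclass
class Hit:
    """Best translated-search HSP for one merged read."""

    read_id: str
    frame: int
    peptide: str  # ungapped query residues of the best HSP (may contain '*')
    best_ref_id: str
    score: float
    pct_identity: float
    evalue: float


@dataclass
class InferredPeptide:
    read_id: str
    frame: int
    peptide: str
    best_ref_id: str
    score: float
    pct_identity: float
    evalue: float

    def __post_init__(self):
        if "*" in self.peptide:
            raise ValueError(f"inferred peptide {self.read_id!r} contains a stop symbol")


@dataclass
class SensitivityReport:
    n_paired: int
    n_merged: int
    n_peptides: int
    n_no_hit: int = 0
    n_stop: int = 0
    n_short: int = 0

    @property
    def sensitivity_pct(self) -> int:
        return sensitivity(self.n_merged, self.n_peptides)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "paired": self.n_paired,
                    "merged": self.n_merged,
                    "peptides": self.n_peptides,
                    "sensitivity_pct": self.sensitivity_pct,
                }
            ]
        )


# ---------------------------------------------------------------------------
# Read merging (FLASH-like overlap consensus)
# ---------------------------------------------------------------------------


def _merge_one(pair: ReadPair, cfg: MergeConfig) -> str | None:
    r1 = np.frombuffer(pair.seq1.encode(), dtype=np.uint8)
    rc2 = np.frombuffer(revcomp(pair.seq2).encode(), dtype=np.uint8)
    q1 = np.asarray(pair.qual1)
    q2 = np.asarray(pair.qual2)[::-1]  # reversed to follow rc2
    n1, n2 = len(r1), len(rc2)
    best = None  # (matches, -mismatches, overlap)
    for o in range(cfg.min_overlap, min(n1, n2) + 1):
        m = int(np.count_nonzero(r1[n1 - o :] == rc2[:o]))
        key = (m, m - o, o)
        if best is None or key > best[0]:
            best = (key, o, m)
    if best is None:
        return None
    _, o, m = best
    if (o - m) / o > cfg.max_overlap_mismatch_fraction:
        return None
    # overlap consensus: higher-quality base wins; ties go to read 1
    ov1 = r1[n1 - o :].copy()
    ov2 = rc2[:o]
    conflict = ov1 != ov2
    take2 = conflict & (q2[:o] > q1[n1 - o :])
    ov1[take2] = ov2[take2]
    merged = bytes(r1[: n1 - o]) + bytes(ov1) + bytes(rc2[o:])
    return merged.decode()


def merge_pairs(
    reads: list[ReadPair], cfg: MergeConfig | None = None
) -> tuple[list[NucleotideRecord], int]:
    """Merge read pairs on their best overlap; returns (merged, n_unmerged).

    For each pair the overlap maximising the number of matched bases over
    all offsets >= min_overlap is chosen; pairs whose best overlap still
    exceeds the mismatch-fraction cap are left unmerged.  Merged length
    is len1 + len2 - overlap.
    """
    cfg = cfg or MergeConfig()
    merged: list[NucleotideRecord] = []
    n_unmerged = 0
    for pair in reads:
        seq = _merge_one(pair, cfg)
        if seq is None:
            n_unmerged += 1
        else:
            merged.append(NucleotideRecord(id=pair.id, seq=seq))
    return merged, n_unmerged


# ---------------------------------------------------------------------------
# Translated homology search
# ---------------------------------------------------------------------------


def make_aligner(matrix: str = "BLOSUM62") -> PairwiseAligner:
    """Local protein aligner with BLAST-style affine gaps (11 + k)."""
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    # Biopython charges open for the first gap residue; open=-12/extend=-1
    # reproduces BLAST's cost 11 + k for a gap of length k.
    aligner.open_gap_score = -12
    aligner.extend_gap_score = -1
    return aligner


def karlin_altschul_evalue(score: float, query_len: int, db_size: float) -> float:
    """E = K * m * n * exp(-lambda * S) for the gapped BLOSUM62 regime."""
    return KA_K * query_len * db_size * math.exp(-KA_LAMBDA * score)


def translated_search(
    merged: NucleotideRecord | str,
    refs: list[ProteinRecord],
    cfg: PipelineConfig | None = None,
    aligner: PairwiseAligner | None = None,
) -> Hit | None:
    """Best six-frame local-alignment hit against the reference peptides,
    or None when no alignment reaches the E-value threshold."""
    cfg = cfg or PipelineConfig()
    if not refs:
        raise ValueError("reference peptide set is empty")
    if isinstance(merged, NucleotideRecord):
        read_id, seq = merged.id, merged.seq
    else:
        read_id, seq = "read", merged
    aligner = aligner or make_aligner(cfg.substitution_matrix)
    best = None  # (score, frame, pep, ref)
    for frame in (1, 2, 3, -1, -2, -3):
        pep = translate(seq, frame)
        if len(pep) < 5:
            continue
        for ref in refs:
            score = aligner.score(ref.seq, pep)
            if best is None or score > best[0]:
                best = (score, frame, pep, ref)
    if best is None:
        return None
    score, frame, pep, ref = best
    evalue = karlin_altschul_evalue(score, len(pep), cfg.db_size_for_evalue)
    if evalue > cfg.evalue_threshold:
        return None
    aln = aligner.align(ref.seq, pep)[0]
    qseg = aln.aligned[1]
    qstart, qend = int(qseg[0][0]), int(qseg[-1][1])
    hsp_pep = pep[qstart:qend]
    counts = aln.counts()
    aligned_cols = counts.identities + counts.mismatches
    pct_id = 100.0 * counts.identities / aligned_cols if aligned_cols else 0.0
    return Hit(
        read_id=read_id,
        frame=frame,
        peptide=hsp_pep,
        best_ref_id=ref.id,
        score=float(score),
        pct_identity=pct_id,
        evalue=evalue,
    )


def filter_peptides(
    hits: list[Hit | None], cfg: PipelineConfig | None = None
) -> tuple[list[InferredPeptide], dict[str, int]]:
    """Keep stop-free HSP peptides of >= 30 aa with a reference hit.

    Returns the inferred peptides plus discard counts by reason
    (no_hit, stop, short); kept + discarded always equals the input.
    """
    cfg = cfg or PipelineConfig()
    kept: list[InferredPeptide] = []
    counts = {"no_hit": 0, "stop": 0, "short": 0}
    for hit in hits:
        if hit is None:
            counts["no_hit"] += 1
        elif cfg.discard_stop_codons and "*" in hit.peptide:
            counts["stop"] += 1
        elif len(hit.peptide) < cfg.min_peptide_len_aa:
            counts["short"] += 1
        else:
            kept.append(
                InferredPeptide(
                    read_id=hit.read_id,
                    frame=hit.frame,
                    peptide=hit.peptide,
                    best_ref_id=hit.best_ref_id,
                    score=hit.score,
                    pct_identity=hit.pct_identity,
                    evalue=hit.evalue,
                )
            )
    return kept, counts


def sensitivity(n_merged: int, n_peptides: int) -> int:
    """Primer sensitivity: floor(100 * inferred peptides / merged reads)."""
    if n_merged <= 0:
        raise ValueError("sensitivity undefined for zero merged reads")
    if n_peptides > n_merged:
        raise ValueError(f"n_peptides ({n_peptides}) exceeds n_merged ({n_merged})")
    return (100 * n_peptides) // n_merged


# ---------------------------------------------------------------------------
# Nucleotide-read QC (16S-style filters)
# ---------------------------------------------------------------------------

_UNAMBIGUOUS = set("ACGT")


def _homopolymer_fraction(seq: str, min_run: int) -> float:
    in_runs = 0
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_run:
            in_runs += j - i
        i = j
    return in_runs / n if n else 0.0


def qc_nucleotide_reads(
    reads: list[NucleotideRecord],
    min_aligned_len: int = 50,
    max_ambiguity_frac: float = 0.02,
    max_homopolymer_frac: float = 0.02,
    homopolymer_min_run: int = 8,
) -> list[NucleotideRecord]:
    """Drop reads shorter than 50 nt, with >2% ambiguity codes, or with
    >2% of bases inside homopolymer runs (runs >= 8 nt by default)."""
    out = []
    for rec in reads:
        n = len(rec.seq)
        if n < min_aligned_len:
            continue
        amb = sum(1 for ch in rec.seq if ch not in _UNAMBIGUOUS) / n
        if amb > max_ambiguity_frac:
            continue
        if _homopolymer_fraction(rec.seq, homopolymer_min_run) > max_homopolymer_frac:
            continue
        out.append(rec)
    return out


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------


def run_pipeline(
    pairs: list[ReadPair],
    refs: list[ProteinRecord],
    cfg: PipelineConfig | None = None,
    merge_cfg: MergeConfig | None = None,
) -> tuple[SensitivityReport, list[InferredPeptide]]:
    """Merge -> translated search -> filters -> sensitivity, in one call."""
    cfg = cfg or PipelineConfig()
    merged, _ = merge_pairs(pairs, merge_cfg)
    aligner = make_aligner(cfg.substitution_matrix)
    hits = [translated_search(m, refs, cfg, aligner) for m in merged]
    peptides, discards = filter_peptides(hits, cfg)
    report = SensitivityReport(
        n_paired=len(pairs),
        n_merged=len(merged),
        n_peptides=len(peptides),
        n_no_hit=discards["no_hit"],
        n_stop=discards["stop"],
        n_short=discards["short"],
    )
    return report, peptides
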