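"""Degenerate primer design from nucleotide multiple alignments.

A conserved region is operationalised as a gap-bounded alignment window
whose minimal covering IUPAC consensus stays under a degeneracy cap.
Candidate primer pairs are then ranked by total degeneracy (lowest
first) under a maximum product size, reproducing the selection rule
used for the published methanogenesis marker primers: lowest degree of
degeneracy, amplicons not exceeding 500 bp.

Hypervariable families that admit no pair are partitioned into
designable clusters along a neighbor-joining guide tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .seqcore import (
    IUPAC_EXPANSION,
    IUPAC_MASK,
    DegenerateOligo,
    NucleotideRecord,
    base_match,
    degeneracy,
    revcomp,
)

logger = logging.getLogger(__name__)

GAP = "-"

# minimal IUPAC code for every non-empty base subset (bitmask -> code)
_MASK_TO_CODE = {mask: code for code, mask in IUPAC_MASK.items()}


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class Alignment:
    """A gapped nucleotide multiple alignment ('-' gaps, equal lengths)."""

    records: list[NucleotideRecord]

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no sequences")
        lengths = {len(r.seq) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0].seq)

    @property
    def n_seqs(self) -> int:
        return len(self.records)


@dataclass
class ConservedWindow:
    """An alignment window with its minimal covering consensus."""

    start: int
    end: int  # 0-based half-open columns
    consensus: DegenerateOligo
    coverage: float  # fraction of sequences fully matched by the consensus
    degeneracy: int


@dataclass
class PrimerPair:
    forward: DegenerateOligo
    reverse: DegenerateOligo
    expected_product_bp: int
    max_mismatch: int = 2
    gene: str = ""

    def __post_init__(self):
        if self.expected_product_bp < len(self.forward.seq) + len(self.reverse.seq):
            raise ValueError(
                "expected product shorter than the two primers: "
                f"{self.expected_product_bp} < {len(self.forward.seq)} + {len(self.reverse.seq)}"
            )

    @property
    def pair_degeneracy(self) -> int:
        return degeneracy(self.forward) * degeneracy(self.reverse)


@dataclass
class DesignConfig:
    primer_len_min: int = 16
    primer_len_max: int = 25
    max_product_bp: int = 500
    min_product_bp: int = 0  # raise for sequencing designs needing long amplicons
    max_primer_degeneracy: int = 1024
    min_coverage: float = 1.0
    max_gap_fraction: float = 0.0

    def __post_init__(self):
        if self.primer_len_min < 1 or self.primer_len_max < self.primer_len_min:
            raise ValueError("primer length range is empty")
        if self.max_product_bp <= 0 or self.max_primer_degeneracy < 1:
            raise ValueError("bounds must be positive")
        if not 0 <= self.min_product_bp <= self.max_product_bp:
            raise ValueError("min_product_bp must lie in [0, max_product_bp]")
        if not (0 < self.min_coverage <= 1) or not (0 <= self.max_gap_fraction <= 1):
            raise ValueError("fractions out of range")


@dataclass
class SequenceGroup:
    """One cluster from :func:`partition_by_tree` with its design status."""

    records: list[NucleotideRecord]
    designable: bool
    best_pair: PrimerPair | None = None


# ---------------------------------------------------------------------------
# Conserved windows
# ---------------------------------------------------------------------------


def _column_profiles(aln: Alignment, cfg: DesignConfig):
    """Per-column minimal covering consensus code, degeneracy and gap mask.

    A column's consensus covers bases (most frequent first) until their
    cumulative weight reaches ``min_coverage`` of the sequences; with the
    default min_coverage=1.0 every observed base is covered.  Input
    ambiguity codes contribute all their expansion bases.
    """
    n = aln.n_seqs
    ncol = aln.length
    codes = [""] * ncol
    degs = np.ones(ncol, dtype=np.int64)
    admissible = np.zeros(ncol, dtype=bool)
    cols = np.array([list(r.seq) for r in aln.records])
    for c in range(ncol):
        column = cols[:, c]
        gap_frac = float(np.mean(column == GAP))
        if gap_frac > cfg.max_gap_fraction:
            continue
        counts: dict[str, float] = {}
        for ch in column:
            if ch == GAP:
                continue
            bases = IUPAC_EXPANSION.get(ch)
            if bases is None:
                raise ValueError(f"invalid character {ch!r} in alignment column {c}")
            w = 1.0 / len(bases)
            for b in bases:
                counts[b] = counts.get(b, 0.0) + w
        if not counts:
            continue
        need = cfg.min_coverage * n
        mask = 0
        covered = 0.0
        for b, w in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
            mask |= IUPAC_MASK[b]
            covered += w
            if covered >= need - 1e-9:
                break
        code = _MASK_TO_CODE[mask]
        codes[c] = code
        degs[c] = len(IUPAC_EXPANSION[code])
        admissible[c] = True
    return codes, degs, admissible


def find_conserved_windows(aln: Alignment, cfg: DesignConfig | None = None) -> list[ConservedWindow]:
    """All admissible windows with consensus degeneracy under the cap,
    sorted ascending by degeneracy then by start column."""
    cfg = cfg or DesignConfig()
    if aln.n_seqs < 2:
        raise ValueError("need at least 2 aligned sequences")
    if cfg.primer_len_min > aln.length:
        raise ValueError(
            f"primer length range {cfg.primer_len_min}-{cfg.primer_len_max} "
            f"exceeds alignment length {aln.length}"
        )
    codes, degs, admissible = _column_profiles(aln, cfg)
    logdeg = np.log(degs.astype(float))
    # per-row strict match against the column consensus (vectorised masks)
    from .seqcore import encode_mask

    row_masks = np.vstack([encode_mask(r.seq) for r in aln.records])
    code_masks = np.array(
        [IUPAC_MASK.get(c, 0) for c in codes], dtype=np.uint8
    )
    col_ok = ((row_masks & ~code_masks[None, :]) == 0) & (row_masks != 0)
    ok_prefix = np.concatenate(
        [np.zeros((aln.n_seqs, 1), dtype=int), np.cumsum(col_ok, axis=1)], axis=1
    )
    windows: list[ConservedWindow] = []
    cap = float(np.log(cfg.max_primer_degeneracy) + 1e-9)
    for L in range(cfg.primer_len_min, min(cfg.primer_len_max, aln.length) + 1):
        ok = np.convolve(admissible.astype(int), np.ones(L, dtype=int), mode="valid") == L
        wdeg = np.convolve(logdeg, np.ones(L), mode="valid")
        for s in np.nonzero(ok & (wdeg <= cap))[0]:
            s = int(s)
            consensus = "".join(codes[s : s + L])
            d = degeneracy(consensus)
            if d > cfg.max_primer_degeneracy:
                continue
            coverage = float(np.mean(ok_prefix[:, s + L] - ok_prefix[:, s] == L))
            windows.append(
                ConservedWindow(
                    start=s,
                    end=s + L,
                    consensus=DegenerateOligo(name=f"win_{s}_{s + L}", seq=consensus),
                    coverage=coverage,
                    degeneracy=d,
                )
            )
    windows.sort(key=lambda w: (w.degeneracy, w.start, w.end - w.start))
    return windows


# ---------------------------------------------------------------------------
# Pair enumeration
# ---------------------------------------------------------------------------


def _ungapped_cumsum(aln: Alignment) -> np.ndarray:
    """U[s, c] = number of non-gap characters of sequence s in columns [0, c)."""
    arr = np.array([list(r.seq) for r in aln.records]) != GAP
    return np.concatenate(
        [np.zeros((aln.n_seqs, 1), dtype=int), np.cumsum(arr, axis=1)], axis=1
    )


def enumerate_pairs(
    windows: list[ConservedWindow],
    aln: Alignment,
    cfg: DesignConfig | None = None,
    max_mismatch: int = 2,
    max_windows: int = 500,
    top_n: int | None = None,
) -> list[PrimerPair]:
    """Rank candidate primer pairs: lowest pair degeneracy first, longer
    products break ties (more phylogenetic signal), then leftmost start.

    The expected product length is the median ungapped distance between
    the forward window start and the reverse window end across the
    aligned sequences — robust to outlier indels.
    """
    cfg = cfg or DesignConfig()
    if not windows:
        logger.warning("no conserved windows supplied; no pairs possible")
        return []
    wins = sorted(windows, key=lambda w: (w.degeneracy, w.start))[:max_windows]
    U = _ungapped_cumsum(aln)
    starts = np.array([w.start for w in wins])
    ends = np.array([w.end for w in wins])
    degs = np.array([w.degeneracy for w in wins], dtype=np.int64)
    # products[i, j] = median over sequences of ungapped distance from
    # window i's start to window j's end
    a = U[:, starts]  # (n_seqs, W)
    b = U[:, ends]
    products = np.median(b[:, None, :] - a[:, :, None], axis=0).astype(int)  # (W fwd, W rev)
    lens = ends - starts
    valid = (
        (starts[None, :] >= ends[:, None])  # reverse window downstream, no overlap
        & (products >= lens[:, None] + lens[None, :])
        & (products >= cfg.min_product_bp)
        & (products <= cfg.max_product_bp)
    )
    n_len_rejected = int(
        ((starts[None, :] >= ends[:, None]) & (products > cfg.max_product_bp)).sum()
    )
    fi, ri = np.nonzero(valid)
    if fi.size == 0:
        logger.warning(
            "no admissible primer pair: %d candidate pairs exceeded max_product_bp=%d; "
            "%d conserved windows available",
            n_len_rejected,
            cfg.max_product_bp,
            len(wins),
        )
        return []
    pair_deg = degs[fi] * degs[ri]
    order = np.lexsort((starts[ri], starts[fi], -products[fi, ri], pair_deg))
    if top_n is not None:
        order = order[:top_n]
    pairs = []
    for k in order:
        wf, wr = wins[fi[k]], wins[ri[k]]
        fwd = DegenerateOligo(
            name=f"F_{wf.start}_{wf.end}", seq=wf.consensus.seq, orientation="forward"
        )
        rev = revcomp(DegenerateOligo(name=f"R_{wr.start}_{wr.end}", seq=wr.consensus.seq))
        pairs.append(
            PrimerPair(
                forward=fwd,
                reverse=rev,
                expected_product_bp=int(products[fi[k], ri[k]]),
                max_mismatch=max_mismatch,
            )
        )
    return pairs


def design_pairs(
    aln: Alignment, cfg: DesignConfig | None = None, top_n: int | None = None
) -> list[PrimerPair]:
    """Convenience: conserved windows + pair enumeration in one call."""
    cfg = cfg or DesignConfig()
    return enumerate_pairs(find_conserved_windows(aln, cfg), aln, cfg, top_n=top_n)


# ---------------------------------------------------------------------------
# Tree-guided partitioning of hypervariable families
# ---------------------------------------------------------------------------


def p_distance_matrix(records: list[NucleotideRecord]) -> DistanceMatrix:
    """Pairwise p-distances (fraction of differing shared non-gap columns)."""
    arr = np.array([list(r.seq) for r in records])
    n = len(records)
    dm = np.zeros((n, n))
    nongap = arr != GAP
    for i in range(n):
        for j in range(i + 1, n):
            shared = nongap[i] & nongap[j]
            ns = int(shared.sum())
            d = float(np.mean(arr[i][shared] != arr[j][shared])) if ns else 1.0
            dm[i, j] = dm[j, i] = d
    return DistanceMatrix(dm, ids=[r.id for r in records])


def _longest_internal_split(tree: TreeNode, ids: set[str]) -> tuple[set[str], set[str]] | None:
    """Leaf bipartition across the longest internal branch (both sides >= 2)."""
    best = None
    best_len = -1.0
    for node in tree.non_tips():
        if node.parent is None or node.length is None:
            continue
        below = {t.name for t in node.tips()}
        above = ids - below
        if len(below) < 2 or len(above) < 2:
            continue
        if node.length > best_len:
            best_len = node.length
            best = (below, above)
    return best


def _is_designable(records: list[NucleotideRecord], cfg: DesignConfig) -> PrimerPair | None:
    try:
        pairs = design_pairs(Alignment(records), cfg, top_n=1)
    except ValueError:
        return None
    return pairs[0] if pairs else None


def partition_by_tree(
    seqs: list[NucleotideRecord], cfg: DesignConfig | None = None, max_groups: int = 2
) -> list[SequenceGroup]:
    """Split a gene family into designable clusters along an NJ guide tree.

    Builds a neighbor-joining tree from pairwise p-distances on the
    alignment and iteratively bisects the non-designable group at its
    longest internal branch until every group admits a primer pair or
    ``max_groups`` is reached.  Groups that still admit no pair are
    returned flagged not-designable.
    """
    cfg = cfg or DesignConfig()
    if len(seqs) < 4:
        raise ValueError("need at least 4 sequences to partition")
    if max_groups > len(seqs):
        raise ValueError(f"cannot form {max_groups} groups from {len(seqs)} sequences")
    by_id = {r.id: r for r in seqs}
    groups: list[list[NucleotideRecord]] = [list(seqs)]
    while len(groups) < max_groups:
        split_done = False
        for gi, grp in enumerate(groups):
            if _is_designable(grp, cfg) is not None:
                continue
            if len(grp) < 4:
                continue
            tree = nj(p_distance_matrix(grp))
            split = _longest_internal_split(tree, {r.id for r in grp})
            if split is None:
                continue
            below, above = split
            groups[gi : gi + 1] = [
                [by_id[i] for i in grp_ids]
                for grp_ids in (
                    [r.id for r in grp if r.id in below],
                    [r.id for r in grp if r.id in above],
                )
            ]
            split_done = True
            break
        if not split_done:
            break
    out = []
    for grp in groups:
        pair = _is_designable(grp, cfg)
        out.append(SequenceGroup(records=grp, designable=pair is not None, best_pair=pair))
    return out


# ---------------------------------------------------------------------------
# Fixture primer pairs
# ---------------------------------------------------------------------------


def fixture_primer_pairs() -> dict[str, PrimerPair]:
    """The four published marker-gene primer pairs, keyed by gene.

    The mcrG pair carries a 4-mismatch budget (its primers are longer);
    the others use the standard 2-mismatch budget.
    """
    from .seqcore import load_primer_table

    df = load_primer_table()
    pairs = {}
    for gene, sub in df.groupby("gene", sort=False):
        fwd_row = sub[sub.orientation == "forward"].iloc[0]
        rev_row = sub[sub.orientation == "reverse"].iloc[0]
        pairs[gene] = PrimerPair(
            forward=DegenerateOligo(fwd_row["name"], fwd_row.sequence, "forward"),
            reverse=DegenerateOligo(rev_row["name"], rev_row.sequence, "reverse"),
            expected_product_bp=int(fwd_row.expected_product_bp),
            max_mismatch=4 if gene == "mcrG" else 2,
            gene=gene,
        )
    return pairs
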