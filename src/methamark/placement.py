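"""Simplified phylogenetic placement of inferred peptides.

Queries are projected into a fixed reference protein alignment, scored
against every leaf by alignment identity, and attached either to the
single best leaf or — when several leaves tie within a margin — to the
last common ancestor of the near-ties, each placement carrying a mass.
Placements are then trimmed at a minimal mass threshold (0.01 of the
total by default), classified with the composite score
(% identity + % coverage) / 2 > 93, aggregated into abundance tables,
and exported as a "fat tree" PhyloXML document in which branch width
tracks assigned read counts and branches on root-to-placement paths are
colored red.

This scorer is a deliberately simple stand-in for full ML evolutionary
placement: it shares the interface (query -> tree node + mass) so an
ML backend can be swapped in without touching callers.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd
from Bio import Phylo
from Bio.Phylo import PhyloXML
from skbio.tree import TreeNode

from .amplicon_pipeline import ProteinRecord, make_aligner

GAP = "-"


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------


@dataclass
class ReferenceSet:
    """Protein reference alignment + rooted tree + leaf taxonomy."""

    alignment: list[ProteinRecord]  # gapped rows, equal length
    newick: str
    taxonomy: pd.DataFrame  # index: leaf id; columns: ranked lineage
    tree: TreeNode = field(init=False)

    def __post_init__(self):
        lengths = {len(r.seq) for r in self.alignment}
        if len(lengths) != 1:
            raise ValueError("reference alignment rows have unequal lengths")
        self.tree = TreeNode.read(io.StringIO(self.newick))
        leaf_ids = {t.name for t in self.tree.tips()}
        aln_ids = {r.id for r in self.alignment}
        if leaf_ids != aln_ids:
            raise ValueError(
                f"tree leaves and alignment ids differ: only-tree={sorted(leaf_ids - aln_ids)}, "
                f"only-alignment={sorted(aln_ids - leaf_ids)}"
            )
        if len(leaf_ids) < 3:
            raise ValueError("reference tree needs at least 3 leaves")

    @property
    def n_columns(self) -> int:
        return len(self.alignment[0].seq)


@dataclass
class AlignedQuery:
    """A query peptide projected into reference alignment columns."""

    peptide_id: str
    row: str  # gapped string of reference column count
    matched_columns: int
    coverage_pct: float  # placed residues / peptide length
    unalignable: bool


@dataclass
class Placement:
    peptide_id: str
    node: TreeNode  # leaf or internal node of the reference tree
    mass: float
    score: float  # best percent identity supporting the placement

    @property
    def node_key(self) -> frozenset:
        return frozenset(t.name for t in self.node.tips()) or frozenset([self.node.name])


# ---------------------------------------------------------------------------
# Query projection
# ---------------------------------------------------------------------------

MIN_MATCHED_COLUMNS = 10


def align_to_reference(
    peptide: str | tuple[str, str], refs: ReferenceSet | list[ProteinRecord]
) -> AlignedQuery:
    """Project a peptide into the reference alignment's columns.

    The query is locally aligned against every ungapped reference row;
    the best-scoring row anchors the projection (query residues inherit
    the columns of the row positions they align to; insertions relative
    to that row are dropped).  Queries placing fewer than 10 residues
    are flagged unalignable.
    """
    if isinstance(peptide, tuple):
        pid, pep = peptide
    else:
        pid, pep = "query", peptide
    rows = refs.alignment if isinstance(refs, ReferenceSet) else refs
    aligner = make_aligner()
    best = None  # (score, row, alignment)
    for row in rows:
        ungapped = row.seq.replace(GAP, "")
        if not ungapped:
            continue
        try:
            score = aligner.score(ungapped, pep)
        except ValueError:
            continue
        if best is None or score > best[0]:
            best = (score, row)
    ncol = len(rows[0].seq)
    if best is None or best[0] <= 0:
        return AlignedQuery(pid, GAP * ncol, 0, 0.0, True)
    _, row = best
    ungapped = row.seq.replace(GAP, "")
    aln = aligner.align(ungapped, pep)[0]
    # map ungapped row index -> alignment column
    col_of = [i for i, ch in enumerate(row.seq) if ch != GAP]
    out = [GAP] * ncol
    placed = 0
    for (tstart, tend), (qstart, qend) in zip(aln.aligned[0], aln.aligned[1]):
        for k in range(tend - tstart):
            out[col_of[tstart + k]] = pep[qstart + k]
            placed += 1
    unalignable = placed < MIN_MATCHED_COLUMNS
    return AlignedQuery(
        peptide_id=pid,
        row="".join(out),
        matched_columns=placed,
        coverage_pct=100.0 * placed / len(pep) if pep else 0.0,
        unalignable=unalignable,
    )


def identity_to_rows(query: AlignedQuery, rows: list[ProteinRecord]) -> dict[str, float]:
    """Percent identity of the projected query to every reference row,
    over columns where both have residues."""
    out = {}
    for row in rows:
        matches = 0
        compared = 0
        for q, r in zip(query.row, row.seq):
            if q == GAP or r == GAP:
                continue
            compared += 1
            if q == r:
                matches += 1
        out[row.id] = 100.0 * matches / compared if compared else 0.0
    return out


# ---------------------------------------------------------------------------
# Placement
# ---------------------------------------------------------------------------


def place(
    peptide: str | tuple[str, str],
    refs: ReferenceSet,
    near_tie_margin: float = 2.0,
    multi: bool = False,
    top_k: int = 3,
) -> list[Placement]:
    """Attach one peptide to the reference tree.

    Leaves within ``near_tie_margin`` percentage points of identity of
    the best leaf are near-ties: a single candidate is placed at its
    leaf with mass 1, several candidates at their last common ancestor
    with mass 1.  In ``multi`` mode mass is instead spread over the top
    *k* leaves proportional to identity.  Unalignable queries get no
    placement (callers count them as unclassified).
    """
    query = align_to_reference(peptide, refs)
    if query.unalignable:
        return []
    ids = identity_to_rows(query, refs.alignment)
    best_id = max(ids.values())
    if multi:
        top = sorted(ids.items(), key=lambda kv: -kv[1])[:top_k]
        total = sum(v for _, v in top)
        if total <= 0:
            return []
        return [
            Placement(query.peptide_id, refs.tree.find(leaf), v / total, v) for leaf, v in top
        ]
    candidates = [leaf for leaf, v in ids.items() if v >= best_id - near_tie_margin]
    if len(candidates) == 1:
        node = refs.tree.find(candidates[0])
    else:
        node = refs.tree.lca(candidates)
    return [Placement(query.peptide_id, node, 1.0, best_id)]


def trim_placements(placements: list[Placement], min_mass: float = 0.01) -> list[Placement]:
    """Remove placements at nodes whose aggregated mass is below
    ``min_mass`` of the total; a node at exactly the threshold survives."""
    total = sum(p.mass for p in placements)
    if total <= 0:
        return []
    agg: dict[frozenset, float] = {}
    for p in placements:
        agg[p.node_key] = agg.get(p.node_key, 0.0) + p.mass
    return [p for p in placements if agg[p.node_key] >= min_mass * total - 1e-12]


def classify_score(identity_pct: float, coverage_pct: float, threshold: float = 93.0) -> bool:
    """Composite classification: (% identity + % coverage) / 2 must
    exceed the threshold (93 by default); equal-to does not classify."""
    for v, name in ((identity_pct, "identity"), (coverage_pct, "coverage")):
        if not 0 <= v <= 100:
            raise ValueError(f"{name} percentage out of [0, 100]: {v}")
    return (identity_pct + coverage_pct) / 2 > threshold


# ---------------------------------------------------------------------------
# Fat-tree export
# ---------------------------------------------------------------------------

_RED = PhyloXML.BranchColor(255, 0, 0)
_BLACK = PhyloXML.BranchColor(0, 0, 0)
_MAX_WIDTH = 10.0
_BASE_WIDTH = 1.0


def export_fat_tree(refs: ReferenceSet, placements: list[Placement], path) -> PhyloXML.Phylogeny:
    """Write a PhyloXML 'fat tree': branch width proportional to the
    number of reads assigned at each node, root-to-placement paths red,
    everything else black with uniform width."""
    bp_tree = Phylo.read(io.StringIO(refs.newick), "newick")
    phylo = bp_tree.as_phyloxml()
    phylo.rooted = True
    counts: dict[frozenset, int] = {}
    for p in placements:
        counts[p.node_key] = counts.get(p.node_key, 0) + 1
    total = sum(counts.values())
    for clade in phylo.find_clades():
        clade.color = _BLACK
        clade.width = _BASE_WIDTH
    for key, n in counts.items():
        target = phylo.common_ancestor({"name": name} for name in key)
        target.width = _MAX_WIDTH * n / total
        for clade in phylo.get_path(target):
            clade.color = _RED
    Phylo.write(phylo, str(path), "phyloxml")
    return phylo


# ---------------------------------------------------------------------------
# Abundance tables
# ---------------------------------------------------------------------------


def abundance_table(
    placements: list[Placement],
    taxonomy: pd.DataFrame,
    rank: str,
    n_unclassified: int = 0,
) -> pd.DataFrame:
    """Aggregate placements into taxon abundances at a requested rank.

    A placement at an internal node is attributed to the deepest rank
    shared by all leaves of its subtree; when that shared rank is
    shallower than the requested one, the count stays at the shared
    rank's taxon (it cannot honestly be attributed deeper).  Fractions
    sum to 1 over classified taxa plus the unclassified bucket.
    """
    ranks = list(taxonomy.columns)
    if rank not in ranks:
        raise ValueError(f"rank {rank!r} not in taxonomy columns {ranks}")
    want_depth = ranks.index(rank)
    masses: dict[str, float] = {}
    for p in placements:
        leaves = sorted(p.node_key)
        missing = [l for l in leaves if l not in taxonomy.index]
        if missing:
            raise KeyError(f"leaf {missing[0]!r} missing from the taxonomy table")
        shared_depth = -1
        for d, r in enumerate(ranks):
            vals = set(taxonomy.loc[leaves, r])
            if len(vals) == 1:
                shared_depth = d
            else:
                break
        if shared_depth < 0:
            label = "unresolved"
        else:
            label_depth = min(shared_depth, want_depth)
            label = str(taxonomy.loc[leaves[0], ranks[label_depth]])
        masses[label] = masses.get(label, 0.0) + p.mass
    total = sum(masses.values()) + n_unclassified
    rows = [
        {"taxon": taxon, "count": mass, "fraction": (mass / total if total else 0.0)}
        for taxon, mass in sorted(masses.items())
    ]
    rows.append(
        {
            "taxon": "unclassified",
            "count": float(n_unclassified),
            "fraction": (n_unclassified / total if total else 0.0),
        }
    )
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# Reference-set I/O
# ---------------------------------------------------------------------------


def load_reference_set(alignment_fasta, newick_path, taxonomy_tsv) -> ReferenceSet:
    """Assemble a ReferenceSet from an aligned protein FASTA, a Newick
    tree and a taxonomy TSV (first column: leaf id; rest: ranks)."""
    from .amplicon_pipeline import read_protein_fasta

    rows = read_protein_fasta(alignment_fasta)
    with open(newick_path) as fh:
        nwk = fh.read()
    tax = pd.read_csv(taxonomy_tsv, sep="\t", index_col=0)
    return ReferenceSet(alignment=rows, newick=nwk, taxonomy=tax)
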