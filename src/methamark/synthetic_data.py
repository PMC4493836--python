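"""Synthetic gene families, reference sets and amplicon libraries.

Every other module is exercised against data generated here with known
ground truth: gene families evolved along a random tree with planted
conserved blocks (emulating the conserved regions that degenerate
marker-gene primers target), protein reference sets derived from those
families, and paired-end amplicon libraries with a planted on-target
fraction, per-base substitution errors and off-target contamination —
the knobs that drive the primer-sensitivity statistic.

The default model uses substitutions only (no indels), so positional
Hamming in-silico PCR and truth-table checks stay exact, and constant
Phred-35 qualities, so merging is deterministic.  Identical seeds give
identical outputs.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio.tree import TreeNode

from .amplicon_pipeline import ProteinRecord
from .insilico_pcr import Amplicon, PcrConfig, predict_amplicons
from .placement import ReferenceSet
from .primer_design import PrimerPair
from .seqcore import NucleotideRecord, ReadPair, revcomp, translate

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_AAS = list("ACDEFGHIKLMNPQRSTVWY")


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------


@dataclass
class FamilyModel:
    """A gene family evolved from a random ancestor along a random tree.

    ``conserved_blocks`` are (start, length, rate multiplier) triples;
    a multiplier of 0.05 makes a block twenty-fold slower than the
    background — a planted conserved region for primer design.
    """

    ancestor_len: int = 900  # nt, multiple of 3 in codon-aware mode
    n_leaves: int = 12
    subst_rate: float = 1.0  # substitutions per site per unit branch length
    branch_scale: float = 0.08  # mean branch length of the random tree
    conserved_blocks: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(120, 60, 0.05), (480, 60, 0.05)]
    )
    codon_aware: bool = True
    seed: int = 0

    def __post_init__(self):
        for start, length, mult in self.conserved_blocks:
            if start < 0 or start + length > self.ancestor_len:
                raise ValueError(f"conserved block ({start}, {length}) outside the ancestor")
            if mult < 0:
                raise ValueError("block rate multiplier must be >= 0")
        if self.subst_rate < 0 or self.branch_scale <= 0:
            raise ValueError("rates must be non-negative")
        if self.codon_aware and self.ancestor_len % 3:
            raise ValueError("codon-aware ancestor length must be a multiple of 3")


@dataclass
class LibraryModel:
    """A paired-end amplicon sequencing run (MiSeq-like 250-bp reads)."""

    n_read_pairs: int = 2000
    read_len: int = 250
    on_target_fraction: float = 0.9
    error_rate: float = 0.002  # substitutions per base
    quality: int = 35  # constant Phred score
    contaminant: str = "random"  # 'random' fragments as off-target source
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.on_target_fraction <= 1:
            raise ValueError("on_target_fraction must be in [0, 1]")
        if not 0 <= self.error_rate < 1 or self.n_read_pairs < 0 or self.read_len < 1:
            raise ValueError("invalid library model")


@dataclass
class SimulatedFamily:
    records: list[NucleotideRecord]  # no indels: aligned == unaligned
    newick: str
    tree: TreeNode
    blocks: list[tuple[int, int, float]]
    model: FamilyModel
    clade_of: dict[str, str] = field(default_factory=dict)  # planted labels


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def _random_ancestor(rng: np.random.Generator, length: int, codon_aware: bool) -> str:
    if not codon_aware:
        return "".join(rng.choice(_BASES, size=length))
    codons = []
    while len(codons) < length // 3:
        c = "".join(rng.choice(_BASES, size=3))
        if c not in _STOPS:
            codons.append(c)
    return "".join(codons)


def _site_multipliers(length: int, blocks: list[tuple[int, int, float]]) -> np.ndarray:
    mult = np.ones(length)
    for start, blen, m in blocks:
        mult[start : start + blen] = m
    return mult


def _mutate(
    seq: str,
    p_site: np.ndarray,
    rng: np.random.Generator,
    codon_aware: bool,
) -> str:
    """Substitute each site with its own probability; in codon-aware mode
    a substitution that would create an in-frame stop codon is redrawn."""
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < p_site)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        rng.shuffle(choices)
        for b in choices:
            old = arr[i]
            arr[i] = b
            if codon_aware:
                c0 = 3 * (i // 3)
                if "".join(arr[c0 : c0 + 3]) in _STOPS:
                    arr[i] = old
                    continue
            break
    return "".join(arr)


def _random_tree(rng: np.random.Generator, n_leaves: int, scale: float) -> TreeNode:
    nodes = [TreeNode(name=f"L{i + 1}") for i in range(n_leaves)]
    for node in nodes:
        node.length = float(rng.exponential(scale))
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.exponential(scale))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = None
    return root


def _newick(tree: TreeNode) -> str:
    buf = io.StringIO()
    tree.write(buf)
    return buf.getvalue().strip()


def simulate_family(model: FamilyModel) -> SimulatedFamily:
    """Evolve a gene family down a random bifurcating tree.

    Conserved blocks evolve at ``rate * multiplier``; with rate 0 all
    leaves equal the ancestor.  Deterministic under the model seed.
    """
    rng = np.random.default_rng(model.seed)
    ancestor = _random_ancestor(rng, model.ancestor_len, model.codon_aware)
    tree = _random_tree(rng, model.n_leaves, model.branch_scale)
    mult = _site_multipliers(model.ancestor_len, model.conserved_blocks)
    records: list[NucleotideRecord] = []

    def walk(node: TreeNode, seq: str):
        for child in node.children:
            p = np.minimum(0.75, model.subst_rate * (child.length or 0.0) * mult)
            child_seq = _mutate(seq, p, rng, model.codon_aware)
            if child.is_tip():
                records.append(NucleotideRecord(id=child.name, seq=child_seq))
            else:
                walk(child, child_seq)

    walk(tree, ancestor)
    records.sort(key=lambda r: int(r.id[1:]))
    return SimulatedFamily(
        records=records,
        newick=_newick(tree),
        tree=tree,
        blocks=list(model.conserved_blocks),
        model=model,
    )


def simulate_two_clade_family(
    model: FamilyModel,
    between_divergence: float = 0.30,
    within_divergence: float = 0.02,
) -> SimulatedFamily:
    """Two planted clades: clade ancestors differ at ``between_divergence``
    of sites (everywhere — the clades do not share conserved regions),
    leaves diverge from their clade ancestor at ``within_divergence``
    with conserved blocks respected.  Leaf names carry the clade label
    (A_*, B_*); ``clade_of`` records the planted partition."""
    rng = np.random.default_rng(model.seed)
    root = _random_ancestor(rng, model.ancestor_len, model.codon_aware)
    anc = {
        "A": root,
        "B": _mutate(
            root, np.full(model.ancestor_len, between_divergence), rng, model.codon_aware
        ),
    }
    mult = _site_multipliers(model.ancestor_len, model.conserved_blocks)
    n_per = model.n_leaves // 2
    records = []
    clade_of = {}
    subtrees = []
    for clade in ("A", "B"):
        tips = []
        for i in range(n_per):
            name = f"{clade}_{i + 1}"
            seq = _mutate(anc[clade], within_divergence * mult, rng, model.codon_aware)
            records.append(NucleotideRecord(id=name, seq=seq))
            clade_of[name] = clade
            tip = TreeNode(name=name)
            tip.length = within_divergence
            tips.append(tip)
        sub = TreeNode(children=tips)
        sub.length = between_divergence / 2
        subtrees.append(sub)
    tree = TreeNode(children=subtrees)
    return SimulatedFamily(
        records=records,
        newick=_newick(tree),
        tree=tree,
        blocks=list(model.conserved_blocks),
        model=model,
        clade_of=clade_of,
    )


# ---------------------------------------------------------------------------
# Reference sets
# ---------------------------------------------------------------------------


def simulate_reference_set(family: SimulatedFamily) -> ReferenceSet:
    """Translate a codon-aware family into a protein reference set with a
    matching tree and a synthetic clade-based taxonomy."""
    if not family.model.codon_aware:
        raise ValueError("reference sets require a codon-aware family")
    rows = []
    for rec in family.records:
        pep = translate(rec.seq, 1)
        if "*" in pep:
            raise ValueError(f"unexpected stop codon in {rec.id} (codon-aware violation)")
        rows.append(ProteinRecord(id=rec.id, seq=pep))
    # genus by child-of-root subtree, species = leaf
    genus_of = {}
    for gi, child in enumerate(family.tree.children):
        names = [t.name for t in child.tips()] or [child.name]
        for name in names:
            genus_of[name] = f"genus_{gi + 1}"
    tax = pd.DataFrame(
        {
            "domain": "Archaea",
            "order": "Synthorder",
            "family": "Synthaceae",
            "genus": [genus_of[r.id] for r in rows],
            "species": [r.id for r in rows],
        },
        index=pd.Index([r.id for r in rows], name="leaf_id"),
    )
    return ReferenceSet(alignment=rows, newick=family.newick, taxonomy=tax)


def mutate_protein(seq: str, divergence: float, rng: np.random.Generator) -> str:
    """Substitute ~divergence of residues with different amino acids."""
    out = list(seq)
    for i in np.nonzero(rng.random(len(out)) < divergence)[0]:
        out[i] = rng.choice([a for a in _AAS if a != out[i]])
    return "".join(out)


# ---------------------------------------------------------------------------
# Amplicon libraries
# ---------------------------------------------------------------------------


def _sequencing_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    for i in np.nonzero(rng.random(len(arr)) < rate)[0]:
        arr[i] = rng.choice([b for b in "ACGT" if b != arr[i]])
    return "".join(arr)


def simulate_amplicon_library(
    family: SimulatedFamily,
    pair: PrimerPair,
    model: LibraryModel,
    pcr_cfg: PcrConfig | None = None,
) -> tuple[list[ReadPair], pd.DataFrame]:
    """Paired reads from a family's predicted amplicons plus contamination.

    On-target pairs are drawn from amplicons of random family members
    (read 1 from the 5' end, read 2 from the 3' end reverse-complemented)
    with per-base substitution errors; off-target pairs come from random
    fragments of the expected product length.  The truth table records
    the origin of every read pair.
    """
    rng = np.random.default_rng(model.seed)
    pcr_cfg = pcr_cfg or PcrConfig(max_mismatch_per_primer=pair.max_mismatch)
    amplicons: dict[str, Amplicon] = {}
    for rec in family.records:
        amps = predict_amplicons(rec, pair, pcr_cfg)
        if amps:
            amplicons[rec.id] = amps[0]
    if model.n_read_pairs > 0 and model.on_target_fraction > 0 and not amplicons:
        raise ValueError("primer pair amplifies no family member; cannot build a library")
    sources = sorted(amplicons)
    reads: list[ReadPair] = []
    truth_rows = []
    qual = [model.quality]
    for i in range(model.n_read_pairs):
        rid = f"read_{i:05d}"
        on_target = bool(rng.random() < model.on_target_fraction)
        if on_target:
            leaf = sources[int(rng.integers(len(sources)))]
            fragment = amplicons[leaf].sequence
        else:
            leaf = ""
            fragment = "".join(rng.choice(_BASES, size=pair.expected_product_bp))
        r1 = _sequencing_errors(fragment[: model.read_len], model.error_rate, rng)
        r2 = _sequencing_errors(revcomp(fragment)[: model.read_len], model.error_rate, rng)
        reads.append(
            ReadPair(id=rid, seq1=r1, seq2=r2, qual1=qual * len(r1), qual2=qual * len(r2))
        )
        truth_rows.append({"read_id": rid, "on_target": on_target, "source_leaf": leaf})
    truth = pd.DataFrame(truth_rows, columns=["read_id", "on_target", "source_leaf"])
    return reads, truth
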