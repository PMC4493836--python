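"""Placement scoring, mass trimming, classification, export, abundances."""

import numpy as np
import pandas as pd
import pytest
from Bio import Phylo

from methamark import (
    Placement,
    ProteinRecord,
    ReferenceSet,
    abundance_table,
    align_to_reference,
    classify_score,
    export_fat_tree,
    mutate_protein,
    place,
    trim_placements,
)

AAS = list("ACDEFGHIKLMNPQRSTVWY")


@pytest.fixture(scope="module")
def toy_refs():
    """Four leaves: (L1,L2) sisters, (L3,L4) sisters; two genera."""
    rng = np.random.default_rng(7)
    base = "".join(rng.choice(AAS, 80))
    l2 = mutate_protein(base, 0.05, rng)
    far = "".join(rng.choice(AAS, 80))
    l4 = mutate_protein(far, 0.05, rng)
    rows = [
        ProteinRecord("L1", base),
        ProteinRecord("L2", l2),
        ProteinRecord("L3", far),
        ProteinRecord("L4", l4),
    ]
    tax = pd.DataFrame(
        {
            "domain": ["Archaea"] * 4,
            "order": ["O1"] * 4,
            "family": ["F1"] * 4,
            "genus": ["G1", "G1", "G2", "G2"],
            "species": ["L1", "L2", "L3", "L4"],
        },
        index=pd.Index(["L1", "L2", "L3", "L4"], name="leaf_id"),
    )
    return ReferenceSet(
        alignment=rows,
        newick="((L1:0.05,L2:0.05):0.4,(L3:0.05,L4:0.05):0.4);",
        taxonomy=tax,
    )


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def test_identical_fragment_projects_at_full_identity(toy_refs):
    from methamark.placement import identity_to_rows

    pep = toy_refs.alignment[0].seq[10:50]
    q = align_to_reference(("q", pep), toy_refs)
    assert not q.unalignable
    assert q.coverage_pct == 100.0
    assert identity_to_rows(q, toy_refs.alignment)["L1"] == 100.0


def test_all_x_peptide_is_unalignable(toy_refs):
    q = align_to_reference(("q", "X" * 40), toy_refs)
    assert q.unalignable


def test_two_substitutions_over_forty_gives_95_percent(toy_refs):
    from methamark.placement import identity_to_rows

    pep = list(toy_refs.alignment[0].seq[10:50])
    for i in (5, 25):
        pep[i] = "W" if pep[i] != "W" else "Y"
    q = align_to_reference(("q", "".join(pep)), toy_refs)
    assert identity_to_rows(q, toy_refs.alignment)["L1"] == pytest.approx(95.0)


# ---------------------------------------------------------------------------
# placement
# ---------------------------------------------------------------------------


def test_query_identical_to_leaf_placed_at_leaf(toy_refs):
    pls = place(("q", toy_refs.alignment[2].seq), toy_refs)
    assert len(pls) == 1
    assert pls[0].node.name == "L3"
    assert pls[0].mass == 1.0


def test_near_tie_goes_to_lca(toy_refs):
    # query exactly midway between L1 and L2: half of the differing
    # positions take L1's residue, half take L2's
    a, b = toy_refs.alignment[0].seq, toy_refs.alignment[1].seq
    diffs = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    mid = list(a)
    for k, i in enumerate(diffs):
        mid[i] = a[i] if k % 2 == 0 else b[i]
    # force an even split: if odd count, revert the last to a neutral 'X'
    if len(diffs) % 2:
        mid[diffs[-1]] = "X"
    mid = "".join(mid)
    pls = place(("q", mid), toy_refs)
    assert len(pls) == 1
    names = {t.name for t in pls[0].node.tips()}
    assert names == {"L1", "L2"}


def test_unalignable_query_gets_no_placement(toy_refs):
    assert place(("q", "X" * 40), toy_refs) == []


def test_multi_placement_masses_sum_to_one(toy_refs):
    pls = place(("q", toy_refs.alignment[0].seq[5:70]), toy_refs, multi=True, top_k=3)
    assert len(pls) == 3
    assert sum(p.mass for p in pls) == pytest.approx(1.0)


def test_simulated_queries_land_at_source_or_ancestor(refset, rng):
    ok = n = 0
    for _ in range(50):
        leaf = refset.alignment[int(rng.integers(len(refset.alignment)))]
        start = int(rng.integers(0, len(leaf.seq) - 60))
        pep = mutate_protein(leaf.seq[start : start + 60], 0.05, rng)
        pls = place((leaf.id, pep), refset)
        n += 1
        if pls:
            names = {t.name for t in pls[0].node.tips()} or {pls[0].node.name}
            ok += leaf.id in names
    assert ok / n >= 0.85


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------


def _leaf_placement(refs, leaf, mass, pid="p"):
    return Placement(pid, refs.tree.find(leaf), mass, 100.0)


def test_trim_drops_below_threshold(toy_refs):
    pls = [_leaf_placement(toy_refs, "L1", 0.995), _leaf_placement(toy_refs, "L2", 0.005)]
    kept = trim_placements(pls, min_mass=0.01)
    assert [p.node.name for p in kept] == ["L1"]


def test_trim_boundary_mass_exactly_at_threshold_survives(toy_refs):
    pls = [_leaf_placement(toy_refs, "L1", 0.99), _leaf_placement(toy_refs, "L2", 0.01)]
    assert len(trim_placements(pls, min_mass=0.01)) == 2


def test_trim_keeps_single_full_mass(toy_refs):
    pls = [_leaf_placement(toy_refs, "L1", 1.0)]
    assert trim_placements(pls) == pls


def test_trim_never_adds_nodes(toy_refs, rng):
    pls = [
        _leaf_placement(toy_refs, leaf, float(m), pid=f"p{i}")
        for i, (leaf, m) in enumerate(
            zip(rng.choice(["L1", "L2", "L3", "L4"], 30), rng.random(30))
        )
    ]
    kept = trim_placements(pls, 0.05)
    assert {p.node_key for p in kept} <= {p.node_key for p in pls}


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "identity,coverage,expected",
    [(90, 94, False), (96, 92, True), (93, 93, False)],
)
def test_composite_classification_threshold(identity, coverage, expected):
    assert classify_score(identity, coverage) is expected


def test_classification_rejects_out_of_range():
    with pytest.raises(ValueError):
        classify_score(101, 50)


# ---------------------------------------------------------------------------
# fat-tree export
# ---------------------------------------------------------------------------


def test_zero_placements_export_uniform_black(toy_refs, tmp_path):
    path = tmp_path / "fat.xml"
    export_fat_tree(toy_refs, [], path)
    tree = Phylo.read(str(path), "phyloxml")
    clades = list(tree.find_clades())
    assert all(c.width == 1.0 for c in clades)
    assert all(
        c.color is None or (c.color.red, c.color.green, c.color.blue) == (0, 0, 0)
        for c in clades
    )


def test_read_counts_set_width_ratio_and_red_path(toy_refs, tmp_path):
    pls = [_leaf_placement(toy_refs, "L1", 1.0, f"a{i}") for i in range(75)]
    pls += [_leaf_placement(toy_refs, "L3", 1.0, f"b{i}") for i in range(25)]
    path = tmp_path / "fat.xml"
    export_fat_tree(toy_refs, pls, path)
    tree = Phylo.read(str(path), "phyloxml")
    by_name = {c.name: c for c in tree.find_clades() if c.name}
    assert by_name["L1"].width == pytest.approx(3 * by_name["L3"].width)
    assert (by_name["L1"].color.red, by_name["L1"].color.blue) == (255, 0)
    assert by_name["L2"].color.red == 0  # sibling not on a placement path


# ---------------------------------------------------------------------------
# abundance tables
# ---------------------------------------------------------------------------


def test_all_reads_in_one_genus(toy_refs):
    pls = [_leaf_placement(toy_refs, "L1", 1.0, f"p{i}") for i in range(100)]
    tab = abundance_table(pls, toy_refs.taxonomy, "genus")
    assert tab.loc["G1", "fraction"] == pytest.approx(1.0)


def test_lca_across_genera_counts_at_shared_rank(toy_refs):
    node = toy_refs.tree.lca(["L1", "L3"])  # spans G1 and G2, same family
    pls = [Placement("p", node, 1.0, 90.0)]
    tab = abundance_table(pls, toy_refs.taxonomy, "genus")
    assert tab.loc["F1", "count"] == 1.0  # attributed to the family, not a genus


def test_fraction_conservation_with_unclassified(toy_refs):
    pls = [
        _leaf_placement(toy_refs, "L1", 1.0, "a"),
        _leaf_placement(toy_refs, "L4", 1.0, "b"),
    ]
    tab = abundance_table(pls, toy_refs.taxonomy, "genus", n_unclassified=2)
    assert tab.fraction.sum() == pytest.approx(1.0, abs=1e-9)
    assert tab.loc["unclassified", "fraction"] == pytest.approx(0.5)


def test_empty_placements_give_zero_table(toy_refs):
    tab = abundance_table([], toy_refs.taxonomy, "genus")
    assert tab.fraction.sum() == 0.0


def test_missing_taxonomy_leaf_raises(toy_refs):
    tax = toy_refs.taxonomy.drop("L3")
    pls = [_leaf_placement(toy_refs, "L3", 1.0)]
    with pytest.raises(KeyError, match="L3"):
        abundance_table(pls, tax, "genus")


def test_reference_set_validates_leaf_alignment_correspondence(toy_refs):
    with pytest.raises(ValueError, match="differ"):
        ReferenceSet(
            alignment=toy_refs.alignment[:3],
            newick=toy_refs.newick,
            taxonomy=toy_refs.taxonomy,
        )
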