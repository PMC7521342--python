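"""Pairwise alignment, corrected distances, neighbor joining against an
additive-matrix oracle, bootstrap supports and clade assignment."""

import numpy as np
import pytest
from skbio import DistanceMatrix, TreeNode

from alkapks import synthetic_data as sd
from alkapks.ks_phylo import (
    Msa,
    assign_clade,
    bootstrap_support,
    global_align,
    nj_tree,
    p_distance,
    tree_bipartitions,
)
from conftest import random_additive_matrix


# --- global alignment -----------------------------------------------------

def brute_force_best_score(a, b, sub, gap):
    """Exhaustive recursion over all global alignments (tiny inputs)."""
    if not a:
        return gap * len(b)
    if not b:
        return gap * len(a)
    return max(
        sub(a[0], b[0]) + brute_force_best_score(a[1:], b[1:], sub, gap),
        gap + brute_force_best_score(a[1:], b, sub, gap),
        gap + brute_force_best_score(a, b[1:], sub, gap),
    )


def test_identity_alignment_scores_diagonal_sum():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    a1, a2, score = global_align("MKVLW", "MKVLW")
    assert (a1, a2) == ("MKVLW", "MKVLW")
    assert score == sum(float(blosum[c, c]) for c in "MKVLW")


def test_single_substitution_column():
    a1, a2, _ = global_align("A", "G")
    assert (a1, a2) == ("A", "G")


def test_alignment_score_matches_exhaustive_enumeration():
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")

    def sub(x, y):
        return float(blosum[x, y])

    rng = np.random.default_rng(13)
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    for _ in range(15):
        a = "".join(rng.choice(alphabet, rng.integers(1, 7)))
        b = "".join(rng.choice(alphabet, rng.integers(1, 7)))
        _, _, got = global_align(a, b, gap_penalty=-8.0)
        want = brute_force_best_score(a, b, sub, -8.0)
        assert got == pytest.approx(want)


def test_alignment_rejects_empty_input():
    with pytest.raises(ValueError):
        global_align("", "A")


# --- distances ------------------------------------------------------------

def test_p_distance_closed_form_and_symmetry():
    rows = ["A" * 90 + "C" * 10, "A" * 100]
    msa = Msa(ids=("x", "y"), rows=tuple(rows))
    dm = p_distance(msa)
    assert dm["x", "y"] == pytest.approx(-np.log(0.9), abs=1e-12)
    assert dm["x", "x"] == 0.0


def test_p_distance_pairwise_deletion_of_gaps():
    msa = Msa(ids=("x", "y"), rows=("AC-G", "ACTG"))
    dm = p_distance(msa, poisson_correct=False)
    assert dm["x", "y"] == 0.0  # gap column excluded, 3 identical compared


def test_p_distance_saturation_capped_with_warning():
    msa = Msa(ids=("x", "y"), rows=("A" * 50, "C" * 50))
    with pytest.warns(UserWarning, match="capped"):
        dm = p_distance(msa)
    assert np.isfinite(dm["x", "y"])


def test_p_distance_no_comparable_columns_is_an_error():
    msa = Msa(ids=("x", "y"), rows=("A-", "-A"))
    with pytest.raises(ValueError):
        p_distance(msa)


# --- neighbor joining -----------------------------------------------------

def test_three_taxa_closed_form_branch_lengths():
    dm = DistanceMatrix(
        np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], float), ["a", "b", "c"]
    )
    tree = nj_tree(dm)
    tips = {t.name: t.length for t in tree.tips()}
    # three-point formulas: la = (dab + dac - dbc)/2 etc.
    assert tips["a"] == pytest.approx(1.0)
    assert tips["b"] == pytest.approx(2.0)
    assert tips["c"] == pytest.approx(3.0)


def test_nj_needs_three_taxa():
    with pytest.raises(ValueError):
        nj_tree(DistanceMatrix(np.array([[0, 1], [1, 0]], float), ["a", "b"]))


def test_nj_recovers_random_additive_matrices_exactly():
    rng = np.random.default_rng(5)
    for _ in range(8):
        dm = random_additive_matrix(8, rng)
        tree = nj_tree(dm)
        tips = {t.name: t for t in tree.tips()}
        for i in range(8):
            for j in range(i + 1, 8):
                want = dm[f"t{i}", f"t{j}"]
                got = tips[f"t{i}"].distance(tips[f"t{j}"])
                assert abs(got - want) < 1e-9


def test_nj_topology_invariant_to_input_order():
    rng = np.random.default_rng(8)
    dm = random_additive_matrix(7, rng)
    perm = list(rng.permutation(dm.ids))
    dm_perm = dm.filter(perm)
    t1, t2 = nj_tree(dm), nj_tree(dm_perm)
    assert set(tree_bipartitions(t1)) == set(tree_bipartitions(t2))


def test_newick_round_trip_preserves_leaves():
    rng = np.random.default_rng(2)
    tree = nj_tree(random_additive_matrix(6, rng))
    back = TreeNode.read([str(tree)])
    assert {t.name for t in back.tips()} == {f"t{i}" for i in range(6)}


# --- bootstrap ------------------------------------------------------------

def clade_msa(rate=0.1, per_clade=3, seed=1):
    spec = sd.CladeSimSpec(
        clades=("FAS", "alkamide"), sequences_per_clade=per_clade,
        substitution_rate=rate,
    )
    records, labels = sd.simulate_clade_sequences(spec, seed=seed)
    return Msa.from_records(records), labels


def test_two_separated_clades_get_high_support():
    msa, labels = clade_msa()
    tree, supports = bootstrap_support(msa, b_replicates=200, seed=3)
    split = frozenset(i for i in msa.ids if labels[i] == "alkamide")
    sides = {s if "FAS_r1" not in s else frozenset(msa.ids) - s
             for s in supports}
    assert any(split == s for s in sides)
    key = split if split in supports else frozenset(msa.ids) - split
    assert supports[key] >= 95


def test_single_replicate_supports_are_binary():
    msa, _ = clade_msa()
    _, supports = bootstrap_support(msa, b_replicates=1, seed=3)
    assert set(supports.values()) <= {0.0, 100.0}


def test_bootstrap_deterministic_under_seed():
    msa, _ = clade_msa()
    _, s1 = bootstrap_support(msa, b_replicates=50, seed=9)
    _, s2 = bootstrap_support(msa, b_replicates=50, seed=9)
    assert s1 == s2


# --- clade assignment -----------------------------------------------------

def test_queries_assigned_to_their_generating_clade():
    spec = sd.CladeSimSpec()
    records, labels = sd.simulate_clade_sequences(
        spec, seed=21, n_queries_per_clade=5
    )
    msa = Msa.from_records(records)
    queries = [i for i in msa.ids if i.startswith("q")]
    refs = {i: labels[i] for i in msa.ids if not i.startswith("q")}
    assignments = assign_clade(queries, refs, msa, b_replicates=50, seed=21)
    correct = sum(labels[a.query_id] == a.clade for a in assignments)
    assert correct / len(assignments) >= 0.95
    assert all(0 <= a.support <= 100 for a in assignments)


def test_assignment_requires_query_in_alignment():
    msa, labels = clade_msa()
    with pytest.raises(ValueError):
        assign_clade(["ghost"], labels, msa)


def test_assignment_accuracy_monotone_in_ancestor_divergence():
    rates = []
    for div in (0.08, 0.25, 0.6):
        spec = sd.CladeSimSpec(ancestor_divergence=div, sequences_per_clade=4)
        records, labels = sd.simulate_clade_sequences(
            spec, seed=30, n_queries_per_clade=5
        )
        msa = Msa.from_records(records)
        queries = [i for i in msa.ids if i.startswith("q")]
        refs = {i: labels[i] for i in msa.ids if not i.startswith("q")}
        assigns = assign_clade(queries, refs, msa, b_replicates=20, seed=30)
        rates.append(
            sum(labels[a.query_id] == a.clade for a in assigns) / len(assigns)
        )
    assert rates[0] <= rates[1] <= rates[2] or (
        rates[1] >= rates[0] and rates[2] >= rates[0]
    )


def test_monophyly_test_invariant_to_rerooting():
    spec = sd.CladeSimSpec()
    records, _ = sd.simulate_clade_sequences(spec, seed=2)
    msa = Msa.from_records(records)
    tree = nj_tree(p_distance(msa))
    b1 = set(tree_bipartitions(tree))
    rerooted = tree.root_at(list(tree.tips())[3].parent)
    b2 = set(tree_bipartitions(rerooted))
    assert b1 == b2
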