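"""Distance-based placement of ketosynthase (KS) domain sequences.

Pairwise Poisson-corrected p-distances on an aligned protein block feed a
neighbor-joining tree; bootstrap support comes from column resampling; a
query sequence is assigned to the reference clade (plant FAS, plant
type-III PKS, microbial type-I PKS, or the alkamide clade) with which it
forms a monophyletic group, with that edge's bootstrap as confidence.
Monophyly is evaluated on unrooted bipartitions, so assignments do not
depend on where the tree is rooted.  Ungapped global pairwise alignment
(Needleman-Wunsch) is provided for distance computation on unaligned
pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from skbio import DistanceMatrix, TreeNode
from skbio.tree import nj

__all__ = [
    "Msa",
    "global_align",
    "p_distance",
    "nj_tree",
    "tree_bipartitions",
    "bootstrap_support",
    "assign_clade",
    "CladeAssignment",
]

GAP = "-"
#: Maximum usable proportion of differing sites; beyond this the Poisson
#: correction diverges and the distance is capped.
P_CAP = 0.95


@dataclass(frozen=True)
class Msa:
    """Aligned protein sequences: equal-length rows over 20 aa + '-' + 'X'."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if self.rows:
            width = len(self.rows[0])
            if any(len(r) != width for r in self.rows):
                raise ValueError("alignment rows have unequal lengths")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "Msa":
        return cls(
            ids=tuple(r[0] for r in records),
            rows=tuple(r[1].upper() for r in records),
        )

    def subsample_columns(self, columns: np.ndarray) -> "Msa":
        rows = tuple("".join(r[c] for c in columns) for r in self.rows)
        return Msa(ids=self.ids, rows=rows)


# --- pairwise global alignment -------------------------------------------

def global_align(
    a: str,
    b: str,
    substitution: Optional[Mapping[tuple[str, str], float]] = None,
    gap_penalty: float = -8.0,
) -> tuple[str, str, float]:
    """Needleman-Wunsch optimal global alignment with a linear gap penalty.

    Ties break deterministically: diagonal over up (gap in ``b``) over
    left.  Returns the two gapped rows and the optimal score.  The default
    substitution matrix is BLOSUM62.
    """
    if not a or not b:
        raise ValueError("global alignment requires non-empty sequences")
    if substitution is None:
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")

        def sub(x: str, y: str) -> float:
            return float(blosum[x, y])
    else:
        def sub(x: str, y: str) -> float:
            return float(substitution[(x, y)])

    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1))
    move = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    score[1:, 0] = gap_penalty * np.arange(1, n + 1)
    score[0, 1:] = gap_penalty * np.arange(1, m + 1)
    move[1:, 0] = 1
    move[0, 1:] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            options = (
                score[i - 1, j - 1] + sub(a[i - 1], b[j - 1]),
                score[i - 1, j] + gap_penalty,
                score[i, j - 1] + gap_penalty,
            )
            k = int(np.argmax(options))  # first maximum: diag > up > left
            score[i, j] = options[k]
            move[i, j] = k
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        k = move[i, j]
        if k == 0:
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif k == 1:
            out_a.append(a[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), float(score[n, m])


# --- distances ------------------------------------------------------------

def p_distance(msa: Msa, poisson_correct: bool = True) -> DistanceMatrix:
    """Pairwise distances with pairwise deletion of gap/X columns.

    p = mismatches / compared columns; the Poisson correction
    d = -ln(1 - p) accounts for multiple hits; p >= 0.95 is capped with a
    warning (the correction diverges as p -> 1).
    """
    if len(msa) < 2:
        raise ValueError("need >= 2 sequences")
    arr = np.array([list(r) for r in msa.rows])
    valid = (arr != GAP) & (arr != "X")
    n = len(msa)
    d = np.zeros((n, n))
    capped = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            compared = int(both.sum())
            if compared == 0:
                raise ValueError(
                    f"no comparable columns between {msa.ids[i]!r} and "
                    f"{msa.ids[j]!r}"
                )
            p = float((arr[i, both] != arr[j, both]).mean())
            if poisson_correct:
                if p >= P_CAP:
                    capped.append((msa.ids[i], msa.ids[j]))
                    p = P_CAP
                dist = -np.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    if capped:
        warnings.warn(
            f"{len(capped)} pairwise distances capped at p={P_CAP} "
            f"(saturated), e.g. {capped[0]}"
        )
    return DistanceMatrix(d, ids=list(msa.ids))


# --- trees ----------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining; negative branch lengths clamped to 0.

    Additive matrices are recovered exactly (topology and branch lengths).
    """
    if dm.shape[0] < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    return nj(dm, neg_as_zero=True)


def tree_bipartitions(tree: TreeNode) -> dict[frozenset, TreeNode]:
    """Unrooted internal bipartitions, each canonicalized as the leaf-name
    side NOT containing the lexicographically smallest leaf."""
    leaves = sorted(n.name for n in tree.tips())
    anchor = leaves[0]
    all_leaves = frozenset(leaves)
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if anchor in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(leaves) - 2:
            out[side] = node
    return out


def bootstrap_support(
    msa: Msa, b_replicates: int = 200, seed: int = 7
) -> tuple[TreeNode, dict[frozenset, float]]:
    """NJ tree from the full alignment with internal-edge bootstrap support
    (percent of column-resampled replicates containing each bipartition).

    Supports are written onto internal node names of the returned tree.
    """
    if b_replicates < 1:
        raise ValueError("need >= 1 bootstrap replicate")
    tree = nj_tree(p_distance(msa))
    observed = tree_bipartitions(tree)
    counts = {side: 0 for side in observed}
    rng = np.random.default_rng([seed, 6])
    for _ in range(b_replicates):
        cols = rng.integers(0, msa.width, msa.width)
        rep_tree = nj_tree(p_distance(msa.subsample_columns(cols)))
        rep_sides = set(tree_bipartitions(rep_tree))
        for side in counts:
            if side in rep_sides:
                counts[side] += 1
    supports = {
        side: 100.0 * counts[side] / b_replicates for side in counts
    }
    for side, node in observed.items():
        node.name = f"{supports[side]:.0f}"
    return tree, supports


# --- clade assignment -----------------------------------------------------

@dataclass(frozen=True)
class CladeAssignment:
    query_id: str
    clade: str
    support: float
    monophyletic: bool


def assign_clade(
    queries: Sequence[str],
    reference_labels: Mapping[str, str],
    msa: Msa,
    b_replicates: int = 200,
    seed: int = 7,
) -> list[CladeAssignment]:
    """Assign each query to a reference clade on the NJ tree.

    A query takes label L when some unrooted bipartition separates
    {query, all L-references, possibly other queries} from every other
    reference; the smallest such side wins and its edge's bootstrap is the
    reported support.  A query grouping with no clade falls back to its
    nearest reference by corrected distance (lexicographic tie-break) with
    support 0.
    """
    if len(set(reference_labels.values())) < 2:
        raise ValueError("references must span >= 2 clades")
    missing = (set(queries) | set(reference_labels)) - set(msa.ids)
    if missing:
        raise ValueError(f"sequences absent from alignment: {sorted(missing)}")
    dm = p_distance(msa)
    tree, supports = bootstrap_support(msa, b_replicates, seed)
    sides = tree_bipartitions(tree)
    by_label: dict[str, set[str]] = {}
    for rid, label in reference_labels.items():
        by_label.setdefault(label, set()).add(rid)
    query_set = set(queries)
    out = []
    for q in queries:
        best: Optional[tuple[int, str, float]] = None
        for side in sides:
            members = side if q in side else frozenset(dm.ids) - side
            refs_in = members & set(reference_labels)
            if not refs_in:
                continue
            labels_in = {reference_labels[r] for r in refs_in}
            if len(labels_in) != 1:
                continue
            label = labels_in.pop()
            if refs_in != by_label[label]:
                continue  # incomplete clade
            if members - refs_in - query_set:
                continue  # stray non-query, non-reference leaf
            cand = (len(members), label, supports[side])
            if best is None or cand[0] < best[0]:
                best = cand
        if best is not None:
            out.append(CladeAssignment(q, best[1], best[2], True))
        else:
            row = dm[q]
            ref_ids = sorted(reference_labels)
            nearest = min(ref_ids, key=lambda r: (row[dm.index(r)], r))
            out.append(
                CladeAssignment(q, reference_labels[nearest], 0.0, False)
            )
    return out
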