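"""Progressive multiple sequence alignment with conservation scoring.

A self-contained MSA engine: affine-gap global pairwise alignment (Gotoh),
a UPGMA guide tree over identity distances, and profile-profile progressive
alignment up the tree.  Column conservation is entropy-based; families are
extracted from the profile by single-linkage grouping on gapped identity.

Scoring defaults to BLOSUM62 with gap open 10 and gap extend 0.5 (a gap of
length g costs open + (g-1)*extend).  The lowercase d-initiator 'y' is
scored as 'Y' but preserved in display.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio.Align import substitution_matrices

from .cluster import sequence_identity

__all__ = [
    "AlignmentProfile",
    "FamilyAssignment",
    "TreeNode",
    "pairwise_align",
    "build_guide_tree",
    "progressive_align",
    "column_conservation",
    "consensus_string",
    "extract_families",
    "gapped_identity",
    "write_aligned_fasta",
    "write_clustal",
    "logo_matrix",
]

_LN20 = math.log(20.0)
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _matrix_score(matrix, x: str, y: str) -> float:
    return float(matrix[x.upper(), y.upper()])


@dataclass(frozen=True)
class TreeNode:
    """Rooted (binary) guide-tree node; leaves carry sequence ids."""

    label: str | None = None
    children: tuple["TreeNode", ...] = ()
    height: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]  # type: ignore[list-item]
        out: list[str] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._newick(parent_height=self.height) + ";"

    def _newick(self, parent_height: float) -> str:
        length = parent_height - self.height
        if self.is_leaf:
            return f"{self.label}:{length:.6g}"
        inner = ",".join(c._newick(self.height) for c in self.children)
        return f"({inner}):{length:.6g}"

    def cophenetic(self) -> dict[tuple[str, str], float]:
        """Tree distance (2 x merge height) between every leaf pair."""
        out: dict[tuple[str, str], float] = {}

        def walk(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]  # type: ignore[list-item]
            groups = [walk(c) for c in node.children]
            for i in range(len(groups)):
                for j in range(i + 1, len(groups)):
                    for a in groups[i]:
                        for b in groups[j]:
                            key = (a, b) if a <= b else (b, a)
                            out[key] = 2.0 * node.height
            return [leaf for g in groups for leaf in g]

        walk(self)
        return out


@dataclass
class AlignmentProfile:
    """An MSA with per-column conservation and a consensus string."""

    aligned: list[tuple[str, str]]  # (id, gapped row), all rows equal length
    conservation: list[float]
    consensus: str
    guide_tree: TreeNode | None = None

    @property
    def ids(self) -> list[str]:
        return [i for i, _ in self.aligned]

    @property
    def width(self) -> int:
        return len(self.aligned[0][1]) if self.aligned else 0

    def row(self, seq_id: str) -> str:
        for i, row in self.aligned:
            if i == seq_id:
                return row
        raise KeyError(seq_id)


@dataclass
class FamilyAssignment:
    """Partition of profile rows into families with per-family consensus."""

    families: dict[int, list[str]]  # family id -> member ids
    consensus: dict[int, str]  # family id -> gapped consensus

    def family_of(self, seq_id: str) -> int:
        for fam, members in self.families.items():
            if seq_id in members:
                return fam
        raise KeyError(seq_id)


# ---------------------------------------------------------------------------
# profile-profile Gotoh alignment


def _column_counts(rows: Sequence[str]) -> list[Counter]:
    width = len(rows[0])
    cols = [Counter() for _ in range(width)]
    for row in rows:
        for j, ch in enumerate(row):
            if ch != "-":
                cols[j][ch.upper()] += 1
    return cols


def _profile_gotoh(
    rows_a: Sequence[str],
    rows_b: Sequence[str],
    matrix,
    match: float,
    mismatch: float,
    gap_open: float,
    gap_extend: float,
) -> tuple[list[int], float]:
    """Align two profiles; return the merged column script and the score.

    The script is a list over merged columns: 0 = take from both, 1 = column
    from A against gaps (deletion), 2 = column from B against gaps
    (insertion).  Traceback ties prefer match > deletion > insertion.
    """
    na, nb = len(rows_a[0]), len(rows_b[0])
    wa, wb = len(rows_a), len(rows_b)
    cols_a = _column_counts(rows_a)
    cols_b = _column_counts(rows_b)

    def col_score(i: int, j: int) -> float:
        s = 0.0
        for x, cx in cols_a[i].items():
            for y, cy in cols_b[j].items():
                if matrix is not None:
                    s += cx * cy * _matrix_score(matrix, x, y)
                else:
                    s += cx * cy * (match if x == y else mismatch)
        return s / (wa * wb)

    NEG = float("-inf")
    # DP over (na+1) x (nb+1); three states: M, X (gap in B), Y (gap in A)
    M = [[NEG] * (nb + 1) for _ in range(na + 1)]
    X = [[NEG] * (nb + 1) for _ in range(na + 1)]
    Y = [[NEG] * (nb + 1) for _ in range(na + 1)]
    M[0][0] = 0.0
    for i in range(1, na + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, nb + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            s = col_score(i - 1, j - 1)
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            Y[i][j] = max(
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
            )

    end_scores = (M[na][nb], X[na][nb], Y[na][nb])
    score = max(end_scores)
    state = end_scores.index(score)  # prefers M, then X (deletion), then Y

    script: list[int] = []
    i, j = na, nb
    while i > 0 or j > 0:
        if state == 0:
            script.append(0)
            prev = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            state = _argmax_pref(prev)
            i, j = i - 1, j - 1
        elif state == 1:
            script.append(1)
            prev = (
                M[i - 1][j] - gap_open,
                X[i - 1][j] - gap_extend,
                Y[i - 1][j] - gap_open,
            )
            state = _argmax_pref(prev)
            i -= 1
        else:
            script.append(2)
            prev = (
                M[i][j - 1] - gap_open,
                X[i][j - 1] - gap_open,
                Y[i][j - 1] - gap_extend,
            )
            state = _argmax_pref(prev)
            j -= 1
        if i == 0 and j > 0:
            state = 2
        elif j == 0 and i > 0:
            state = 1
    script.reverse()
    return script, score


def _argmax_pref(candidates: tuple[float, float, float], eps: float = 1e-9) -> int:
    """Index of the maximum; ties within eps prefer M, then X, then Y."""
    best = max(candidates)
    for idx, value in enumerate(candidates):
        if value >= best - eps:
            return idx
    raise RuntimeError("traceback failed")  # pragma: no cover


def _apply_script(rows_a: Sequence[str], rows_b: Sequence[str], script: list[int]):
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for op in script:
        if op in (0, 1):
            for r, row in enumerate(rows_a):
                out_a[r].append(row[ia])
            ia += 1
        else:
            for r in range(len(rows_a)):
                out_a[r].append("-")
        if op in (0, 2):
            for r, row in enumerate(rows_b):
                out_b[r].append(row[ib])
            ib += 1
        else:
            for r in range(len(rows_b)):
                out_b[r].append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def pairwise_align(
    a: str,
    b: str,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    *,
    match: float = 1.0,
    mismatch: float = -1.0,
    use_blosum: bool = True,
) -> tuple[str, str, float]:
    """Optimal global affine-gap alignment of two sequences.

    Returns (gapped a, gapped b, score).  With no explicit matrix, BLOSUM62
    is used unless ``use_blosum`` is False (then match/mismatch scores
    apply).  Traceback is deterministic: ties prefer match over deletion
    (gap in b) over insertion (gap in a).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if matrix is None and use_blosum:
        matrix = _BLOSUM62
    script, score = _profile_gotoh([a], [b], matrix, match, mismatch, gap_open, gap_extend)
    rows_a, rows_b = _apply_script([a], [b], script)
    return rows_a[0], rows_b[0], score


# ---------------------------------------------------------------------------
# guide tree


def _as_pairs(sequences) -> list[tuple[str, str]]:
    if isinstance(sequences, Mapping):
        return list(sequences.items())
    return list(sequences)


def build_guide_tree(sequences, distances: Mapping[tuple[str, str], float] | None = None) -> TreeNode:
    """UPGMA tree over d = 1 - sequence_identity.

    ``sequences`` is a mapping id -> sequence or an iterable of (id, seq)
    pairs.  A precomputed ``distances`` map keyed by sorted id pairs may be
    supplied instead of identity distances.  Ties in the minimum distance
    are broken by the lexicographically smallest (sorted) pair of cluster
    member-minimum ids, making the tree a pure function of the input set.
    """
    pairs = _as_pairs(sequences)
    if len(pairs) == 0:
        raise ValueError("need at least one sequence")
    if len(pairs) == 1:
        return TreeNode(label=pairs[0][0])

    ids = [i for i, _ in pairs]
    seqs = dict(pairs)
    dist: dict[tuple[str, str], float] = {}
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            a, b = ids[i], ids[j]
            key = (a, b) if a <= b else (b, a)
            if distances is not None:
                dist[key] = distances[key]
            else:
                dist[key] = 1.0 - sequence_identity(seqs[a], seqs[b])

    # active clusters: min member id -> (node, size)
    active: dict[str, tuple[TreeNode, int]] = {
        i: (TreeNode(label=i), 1) for i in ids
    }
    d = {k: v for k, v in dist.items()}

    def get(a: str, b: str) -> float:
        return d[(a, b) if a <= b else (b, a)]

    while len(active) > 1:
        keys = sorted(active)
        best = None
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                cur = get(keys[i], keys[j])
                if best is None or cur < best[0] - 1e-12:
                    best = (cur, keys[i], keys[j])
        assert best is not None
        dmin, ka, kb = best
        node_a, size_a = active.pop(ka)
        node_b, size_b = active.pop(kb)
        merged = TreeNode(children=(node_a, node_b), height=dmin / 2.0)
        new_key = min(ka, kb)
        for other in list(active):
            avg = (size_a * get(ka, other) + size_b * get(kb, other)) / (size_a + size_b)
            d[(new_key, other) if new_key <= other else (other, new_key)] = avg
        active[new_key] = (merged, size_a + size_b)
    (root, _), = active.values()
    return root


# ---------------------------------------------------------------------------
# progressive alignment & profile statistics


def progressive_align(
    sequences,
    guide_tree: TreeNode | None = None,
    *,
    matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    use_blosum: bool = True,
    match: float = 1.0,
    mismatch: float = -1.0,
) -> AlignmentProfile:
    """Progressive profile-profile MSA up the guide tree.

    Rows come back in the input order; removing gaps from any row
    reproduces its input sequence exactly.
    """
    pairs = _as_pairs(sequences)
    if not pairs:
        raise ValueError("need at least one sequence")
    if matrix is None and use_blosum:
        matrix = _BLOSUM62
    seqs = dict(pairs)
    if guide_tree is None:
        guide_tree = build_guide_tree(pairs)

    def align_node(node: TreeNode) -> tuple[list[str], list[str]]:
        if node.is_leaf:
            return [node.label], [seqs[node.label]]  # type: ignore[list-item]
        ids_l, rows_l = align_node(node.children[0])
        for child in node.children[1:]:
            ids_r, rows_r = align_node(child)
            script, _ = _profile_gotoh(
                rows_l, rows_r, matrix, match, mismatch, gap_open, gap_extend
            )
            rows_l, rows_r = _apply_script(rows_l, rows_r, script)
            ids_l = ids_l + ids_r
            rows_l = rows_l + rows_r
        return ids_l, rows_l

    ids, rows = align_node(guide_tree)
    by_id = dict(zip(ids, rows))
    aligned = [(i, by_id[i]) for i, _ in pairs]
    conservation = column_conservation([r for _, r in aligned])
    consensus = consensus_string([r for _, r in aligned])
    return AlignmentProfile(
        aligned=aligned,
        conservation=conservation,
        consensus=consensus,
        guide_tree=guide_tree,
    )


def column_conservation(rows: Sequence[str] | AlignmentProfile) -> list[float]:
    """Per-column conservation: 1 - H/ln(20) over non-gap residue
    frequencies; columns with a gap fraction above 0.5 score 0."""
    if isinstance(rows, AlignmentProfile):
        rows = [r for _, r in rows.aligned]
    if not rows:
        raise ValueError("empty profile")
    n = len(rows)
    out: list[float] = []
    for col in _column_counts(rows):
        non_gap = sum(col.values())
        if non_gap < n - non_gap or non_gap == 0:  # gap fraction > 0.5
            out.append(0.0)
            continue
        h = 0.0
        for count in col.values():
            p = count / non_gap
            h -= p * math.log(p)
        out.append(max(0.0, 1.0 - h / _LN20))
    return out


def consensus_string(rows: Sequence[str]) -> str:
    """Majority residue per column; '-' where gaps hold the majority.

    Residue ties break lexicographically (uppercased comparison)."""
    n = len(rows)
    chars: list[str] = []
    for j, col in enumerate(_column_counts(rows)):
        non_gap = sum(col.values())
        if non_gap < n - non_gap or non_gap == 0:
            chars.append("-")
            continue
        best = max(sorted(col), key=lambda ch: col[ch])
        chars.append(best)
    return "".join(chars)


def gapped_identity(row_a: str, row_b: str) -> float:
    """Identity of two already-aligned rows: identical non-gap columns over
    the shorter ungapped length."""
    matches = sum(
        1
        for x, y in zip(row_a, row_b)
        if x != "-" and y != "-" and x.upper() == y.upper()
    )
    la = sum(1 for x in row_a if x != "-")
    lb = sum(1 for x in row_b if x != "-")
    if la == 0 or lb == 0:
        raise ValueError("empty row")
    return matches / min(la, lb)


def extract_families(
    profile: AlignmentProfile, linkage_threshold: float = 0.6
) -> FamilyAssignment:
    """Single-linkage grouping of profile rows at a gapped-identity
    threshold; family ids are 1-based in order of first member row."""
    rows = profile.aligned
    n = len(rows)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if gapped_identity(rows[i][1], rows[j][1]) >= linkage_threshold:
                parent[find(j)] = find(i)

    families: dict[int, list[str]] = {}
    consensus: dict[int, str] = {}
    root_to_family: dict[int, int] = {}
    for i, (seq_id, _) in enumerate(rows):
        root = find(i)
        if root not in root_to_family:
            root_to_family[root] = len(root_to_family) + 1
        families.setdefault(root_to_family[root], []).append(seq_id)
    for fam, members in families.items():
        member_rows = [row for seq_id, row in rows if seq_id in set(members)]
        consensus[fam] = consensus_string(member_rows)
    return FamilyAssignment(families=families, consensus=consensus)


# ---------------------------------------------------------------------------
# export


def write_aligned_fasta(profile: AlignmentProfile, path) -> None:
    with open(path, "w") as fh:
        for seq_id, row in profile.aligned:
            fh.write(f">{seq_id}\n{row}\n")


def write_clustal(profile: AlignmentProfile, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        fh.write("CLUSTAL format alignment\n\n")
        total = profile.width
        name_w = max((len(i) for i, _ in profile.aligned), default=0) + 2
        for start in range(0, total, width):
            for seq_id, row in profile.aligned:
                fh.write(f"{seq_id:<{name_w}}{row[start:start + width]}\n")
            fh.write("\n")


def logo_matrix(profile: AlignmentProfile):
    """Position x residue frequency matrix (non-gap normalized) as a
    DataFrame, suitable for sequence-logo rendering."""
    import pandas as pd

    rows = [r for _, r in profile.aligned]
    data = []
    for col in _column_counts(rows):
        non_gap = sum(col.values())
        data.append(
            {aa: (col.get(aa, 0) / non_gap if non_gap else 0.0) for aa in sorted(set("ACDEFGHIKLMNPQRSTVWY") | set(col))}
        )
    return pd.DataFrame(data).fillna(0.0)
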