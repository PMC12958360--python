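"""Greedy incremental identity clustering with a short-word prefilter.

The whole unique-peptide set of a round is condensed by a single
abundance-ordered pass: each peptide joins the first existing cluster whose
representative it matches at >= the identity threshold, otherwise it founds
a new cluster.  Identity is identical aligned positions under global
alignment divided by the length of the shorter sequence.  A conservative
k-word count bound prunes representative comparisons without ever changing
the partition.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from Bio import Align

from .enrich import PeptideRecord, rank_sequences

__all__ = [
    "Cluster",
    "Clustering",
    "sequence_identity",
    "word_prefilter",
    "min_shared_words",
    "greedy_cluster",
    "write_clusters",
    "parse_clusters",
    "write_representatives_fasta",
    "clustering_to_frame",
]

# Identity alignment scoring: maximize identical positions net of gaps.
# Exact values are immaterial for equal-length near-duplicates but are
# pinned for reproducibility.
_IDENTITY_ALIGNER = Align.PairwiseAligner(
    mode="global",
    match_score=1,
    mismatch_score=0,
    open_gap_score=-2,
    extend_gap_score=-1,
)


def sequence_identity(a: str, b: str) -> float:
    """Fraction of identical aligned positions over the shorter length.

    Global alignment with match 1, mismatch 0, gap open -2, gap extend -1;
    the denominator is min(len(a), len(b)).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if a == b:
        return 1.0
    if len(a) == len(b):
        # fast path: when no gapped alignment scores above the diagonal,
        # the gapless alignment is optimal and its matches are the identity
        diagonal = sum(x == y for x, y in zip(a, b))
        if _IDENTITY_ALIGNER.score(a, b) == diagonal:
            return diagonal / len(a)
    aln = _IDENTITY_ALIGNER.align(a, b)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for x, y in zip(a[a0:a1], b[b0:b1]):
            if x == y:
                matches += 1
    return matches / min(len(a), len(b))


def _word_counts(seq: str, k: int) -> Counter:
    return Counter(seq[i : i + k] for i in range(len(seq) - k + 1))


def min_shared_words(len_a: int, len_b: int, k: int, threshold: float) -> int:
    """Minimum k-word multiset overlap any pair with identity >= threshold
    must exhibit (0 if the bound is vacuous).

    With L = shorter length and M = ceil(threshold * L) identical aligned
    positions, at most L - M shorter-sequence positions are unmatched (each
    spoiling <= k words) and the longer sequence carries at most
    (L - M) + |len_a - len_b| gap columns (each insertion run spoiling
    <= k - 1 words), giving a conservative lower bound.
    """
    L = min(len_a, len_b)
    delta = abs(len_a - len_b)
    m_min = math.ceil(threshold * L - 1e-9)
    unmatched = L - m_min
    bound = (L - k + 1) - k * unmatched - (k - 1) * (unmatched + delta)
    return max(0, bound)


def word_prefilter(a: str, b: str, k: int, threshold: float) -> bool:
    """May this pair reach the identity threshold?

    Conservative: returns False only when the shared k-word count provably
    rules out identity >= threshold; never rejects a qualifying pair.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    required = min_shared_words(len(a), len(b), k, threshold)
    if required == 0:
        return True
    shared = sum((_word_counts(a, k) & _word_counts(b, k)).values())
    return shared >= required


@dataclass
class Cluster:
    index: int  # 1-based, creation order
    representative: str
    members: list[tuple[str, float]] = field(default_factory=list)  # (peptide, identity to rep)


@dataclass
class Clustering:
    clusters: list[Cluster]
    threshold: float

    def __len__(self) -> int:
        return len(self.clusters)

    def partition(self) -> dict[str, int]:
        """peptide -> cluster index."""
        return {pep: c.index for c in self.clusters for pep, _ in c.members}

    def cluster_of(self, peptide: str) -> Cluster:
        for c in self.clusters:
            if any(pep == peptide for pep, _ in c.members):
                return c
        raise KeyError(peptide)


class _WordIndex:
    """Inverted k-word index over cluster representatives.

    A coarse second index at word size ``k_coarse`` (5) prescreens
    candidates when its own conservative bound is non-vacuous for the pair
    of lengths involved — the same lemma as :func:`min_shared_words`, so
    pruning never drops a qualifying pair.  At the high thresholds used for
    near-duplicate condensation this keeps candidate scans near-constant
    instead of linear in the number of representatives.
    """

    def __init__(self, k: int, k_coarse: int = 5):
        self.k = k
        self.k_coarse = max(k, k_coarse)
        self.rep_words: list[Counter] = []  # per-rep k-word multisets
        self.coarse: dict[str, list[tuple[int, int]]] = {}
        self.lengths: list[int] = []
        self.by_length: dict[int, list[int]] = {}

    def add(self, rep: str) -> None:
        pos = len(self.lengths)
        self.lengths.append(len(rep))
        self.by_length.setdefault(len(rep), []).append(pos)
        self.rep_words.append(_word_counts(rep, self.k))
        for word, n in _word_counts(rep, self.k_coarse).items():
            self.coarse.setdefault(word, []).append((pos, n))

    def candidates(self, query: str, threshold: float) -> list[int]:
        lengths = sorted(self.by_length)
        coarse_req = {
            L: min_shared_words(len(query), L, self.k_coarse, threshold) for L in lengths
        }
        if all(r > 0 for r in coarse_req.values()):
            shared = Counter()
            for word, qn in _word_counts(query, self.k_coarse).items():
                for pos, rn in self.coarse.get(word, ()):
                    shared[pos] += min(qn, rn)
            pool = sorted(
                pos for pos, n in shared.items() if n >= coarse_req[self.lengths[pos]]
            )
        else:
            # coarse bound vacuous for some length: scan everything there,
            # prescreen the rest
            pool = set()
            for L in lengths:
                if coarse_req[L] == 0:
                    pool.update(self.by_length[L])
            shared = Counter()
            for word, qn in _word_counts(query, self.k_coarse).items():
                for pos, rn in self.coarse.get(word, ()):
                    shared[pos] += min(qn, rn)
            pool.update(
                pos for pos, n in shared.items() if n >= coarse_req[self.lengths[pos]]
            )
            pool = sorted(pool)
        # exact fine-grained bound at the contract word size
        query_words = _word_counts(query, self.k)
        out = []
        for pos in pool:
            required = min_shared_words(len(query), self.lengths[pos], self.k, threshold)
            if required == 0:
                out.append(pos)
                continue
            fine = sum((query_words & self.rep_words[pos]).values())
            if fine >= required:
                out.append(pos)
        return out


def greedy_cluster(
    records: Sequence[PeptideRecord] | Mapping[str, PeptideRecord] | Sequence[str],
    threshold: float = 0.90,
    *,
    round_index: int | None = None,
    k: int = 2,
    use_prefilter: bool = True,
) -> Clustering:
    """Single greedy abundance-ordered clustering pass.

    ``records`` may be peptide strings already in rank order, or
    :class:`PeptideRecord` objects (``round_index`` then required; they are
    ranked by descending round count with the lexicographic tie-break).
    Disabling the prefilter never changes the partition, only the runtime.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    if isinstance(records, Mapping) or (
        len(records) > 0 and isinstance(next(iter(records)), PeptideRecord)
    ):
        if round_index is None:
            raise ValueError("round_index required when clustering PeptideRecords")
        ordered = [r.peptide for r in rank_sequences(records, round_index)]
    else:
        ordered = list(records)

    clusters: list[Cluster] = []
    index = _WordIndex(k) if use_prefilter else None
    for pep in ordered:
        if index is not None:
            candidate_pos = index.candidates(pep, threshold)
        else:
            candidate_pos = range(len(clusters))
        placed = False
        for pos in candidate_pos:
            rep = clusters[pos].representative
            ident = sequence_identity(pep, rep)
            if ident >= threshold:
                clusters[pos].members.append((pep, ident))
                placed = True
                break
        if not placed:
            c = Cluster(index=len(clusters) + 1, representative=pep)
            c.members.append((pep, 1.0))
            clusters.append(c)
            if index is not None:
                index.add(pep)
    return Clustering(clusters=clusters, threshold=threshold)


def write_clusters(clustering: Clustering, path) -> None:
    """Emit a CD-HIT ``.clstr``-compatible cluster file.

    Headers are 0-based (">Cluster 0" holds the first-created cluster);
    the peptide string doubles as the sequence id.
    """
    with open(path, "w") as fh:
        for c in clustering.clusters:
            fh.write(f">Cluster {c.index - 1}\n")
            for i, (pep, ident) in enumerate(c.members):
                if pep == c.representative:
                    fh.write(f"{i}\t{len(pep)}aa, >{pep}... *\n")
                else:
                    fh.write(f"{i}\t{len(pep)}aa, >{pep}... at {100 * ident:.2f}%\n")


_MEMBER_RE = re.compile(r"^\d+\t(\d+)aa, >(.+)\.\.\. (?:\*|at ([0-9.]+)%)$")


def parse_clusters(path, threshold: float = 0.0) -> Clustering:
    """Parse a ``.clstr`` file written by :func:`write_clusters`."""
    clusters: list[Cluster] = []
    current: Cluster | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">Cluster"):
                current = Cluster(index=int(line.split()[1]) + 1, representative="")
                clusters.append(current)
                continue
            m = _MEMBER_RE.match(line)
            if not m or current is None:
                raise ValueError(f"malformed .clstr line: {line!r}")
            pep = m.group(2)
            if m.group(3) is None:
                current.representative = pep
                current.members.append((pep, 1.0))
            else:
                current.members.append((pep, float(m.group(3)) / 100))
    return Clustering(clusters=clusters, threshold=threshold)


def write_representatives_fasta(
    clustering: Clustering,
    path,
    *,
    library_tag: str = "L",
    records: Mapping[str, PeptideRecord] | None = None,
    round_index: int | None = None,
) -> None:
    """Representative FASTA; headers carry library, cluster, rank and count."""
    with open(path, "w") as fh:
        for c in clustering.clusters:
            rep = c.representative
            rank = count = 0
            if records is not None and round_index is not None and rep in records:
                rank = records[rep].rank.get(round_index, 0)
                count = records[rep].counts.get(round_index, 0)
            fh.write(
                f">{library_tag}{c.index}-{rank} cluster={c.index} rank={rank} "
                f"count={count} size={len(c.members)}\n{rep}\n"
            )


def clustering_to_frame(clustering: Clustering):
    import pandas as pd

    rows = [
        {
            "cluster": c.index,
            "peptide": pep,
            "is_representative": pep == c.representative,
            "identity_to_representative": ident,
        }
        for c in clustering.clusters
        for pep, ident in c.members
    ]
    return pd.DataFrame(rows)
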