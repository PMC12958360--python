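"""Hit naming, per-family reporting, and truncation suggestions.

Hits are named "[library][cluster]-[abundance rank]": e.g. "L21-34" is the
l-library peptide founding or belonging to cluster 21 that ranks 34th by
abundance in the analysis round.  Truncation candidates are flagged when
the macrocycle (initiator through the first Cys) is markedly better
conserved than the lariat tail that follows it.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .align import AlignmentProfile, FamilyAssignment
from .cluster import Clustering
from .enrich import PeptideRecord

__all__ = [
    "HitName",
    "TruncationSuggestion",
    "name_hit",
    "parse_hit_name",
    "split_macrocycle_tail",
    "suggest_truncation",
    "family_report",
    "NoCysteineError",
]


class NoCysteineError(ValueError):
    """Raised when a peptide contains no cysteine to cyclize onto."""


_HIT_RE = re.compile(r"^([LD])(\d+)-(\d+)$")


@dataclass(frozen=True)
class HitName:
    library_tag: str
    cluster_index: int
    abundance_rank: int

    def __post_init__(self) -> None:
        if self.library_tag not in ("L", "D"):
            raise ValueError(f"library_tag must be 'L' or 'D', got {self.library_tag!r}")
        if self.cluster_index < 1 or self.abundance_rank < 1:
            raise ValueError("cluster_index and abundance_rank must be >= 1")

    @property
    def rendered(self) -> str:
        return f"{self.library_tag}{self.cluster_index}-{self.abundance_rank}"

    def __str__(self) -> str:
        return self.rendered


def name_hit(library_tag: str, cluster_index: int, abundance_rank: int) -> HitName:
    """Build the conventional hit name, e.g. ('L', 21, 34) -> "L21-34"."""
    return HitName(library_tag, cluster_index, abundance_rank)


def parse_hit_name(name: str) -> HitName:
    m = _HIT_RE.match(name)
    if not m:
        raise ValueError(f"not a valid hit name: {name!r}")
    return HitName(m.group(1), int(m.group(2)), int(m.group(3)))


def split_macrocycle_tail(peptide: str) -> tuple[tuple[int, int], tuple[int, int] | None]:
    """1-based inclusive spans of the macrocycle (through the first 'C')
    and the tail after it (None when the peptide is a pure macrocycle).

    The first cysteine closes the ring even if later cysteines exist."""
    pos = peptide.upper().find("C", 1)  # the initiator cannot close onto itself
    if pos < 0:
        raise NoCysteineError(f"no cysteine in peptide {peptide!r}")
    cycle = (1, pos + 1)
    if pos + 1 == len(peptide):
        return cycle, None
    return cycle, (pos + 2, len(peptide))


@dataclass(frozen=True)
class TruncationSuggestion:
    peptide_id: str
    cycle_span: tuple[int, int]
    tail_span: tuple[int, int] | None
    cycle_conservation: float
    tail_conservation: float
    suggest_cycle_only: bool


def suggest_truncation(
    profile: AlignmentProfile,
    peptide_id: str,
    gap_threshold: float = 0.3,
) -> TruncationSuggestion:
    """Compare mean conservation of a row's macrocycle vs its tail.

    Span means are taken over the profile columns holding the row's
    residues (columns where the row is gapped do not contribute).  An empty
    tail yields tail_conservation 0 and no suggestion.  The suggestion
    fires when cycle - tail >= gap_threshold (>= is deliberate: a zero
    threshold with equal conservations suggests truncation).
    """
    row = profile.row(peptide_id)
    peptide = row.replace("-", "")
    cycle_span, tail_span = split_macrocycle_tail(peptide)

    # residue position (1-based) -> profile column
    col_of: dict[int, int] = {}
    pos = 0
    for col, ch in enumerate(row):
        if ch != "-":
            pos += 1
            col_of[pos] = col

    def span_mean(span: tuple[int, int]) -> float:
        cols = [col_of[p] for p in range(span[0], span[1] + 1)]
        return sum(profile.conservation[c] for c in cols) / len(cols)

    cycle_cons = span_mean(cycle_span)
    if tail_span is None:
        return TruncationSuggestion(
            peptide_id, cycle_span, None, cycle_cons, 0.0, False
        )
    tail_cons = span_mean(tail_span)
    return TruncationSuggestion(
        peptide_id,
        cycle_span,
        tail_span,
        cycle_cons,
        tail_cons,
        cycle_cons - tail_cons >= gap_threshold,
    )


def family_report(
    families: FamilyAssignment,
    records: Mapping[str, PeptideRecord],
    clustering: Clustering,
    profile: AlignmentProfile,
    round_index: int,
    *,
    from_round: int | None = None,
    id_to_peptide: Mapping[str, str] | None = None,
    truncation_gap_threshold: float = 0.3,
) -> pd.DataFrame:
    """One row per family: representative, hit name, size, summed round
    frequency, enrichment ratio, consensus, truncation flag.

    ``id_to_peptide`` maps profile row ids to peptide strings; by default
    row ids are assumed to be the peptides themselves.  Sorted by summed
    frequency, descending.
    """
    id_to_peptide = dict(id_to_peptide or {})
    partition = clustering.partition()

    def peptide_of(seq_id: str) -> str:
        return id_to_peptide.get(seq_id, seq_id)

    rows = []
    for fam_id, member_ids in families.families.items():
        member_peps = [peptide_of(i) for i in member_ids]
        # family frequency sums over every clustered peptide behind each member
        cluster_ids = {partition[p] for p in member_peps if p in partition}
        covered = [
            pep
            for c in clustering.clusters
            if c.index in cluster_ids
            for pep, _ in c.members
        ]
        summed_freq = sum(
            records[p].frequencies.get(round_index, 0.0) for p in covered if p in records
        )
        rep_id = max(
            member_ids,
            key=lambda i: (
                records.get(peptide_of(i), PeptideRecord("", "L")).counts.get(round_index, 0),
                i,
            ),
        )
        rep_pep = peptide_of(rep_id)
        rec = records.get(rep_pep)
        tag = rec.library_tag if rec else "L"
        cluster_index = partition.get(rep_pep, 0)
        rank = rec.rank.get(round_index, 0) if rec else 0
        hit = (
            name_hit(tag, cluster_index, rank).rendered
            if cluster_index >= 1 and rank >= 1
            else ""
        )
        ratio = float("nan")
        if from_round is not None and rec is not None:
            from_total = sum(
                r.counts.get(from_round, 0) for r in records.values()
            )
            to_total = sum(r.counts.get(round_index, 0) for r in records.values())
            if from_total and to_total:
                f_from = rec.counts.get(from_round, 0) / from_total or 0.5 / from_total
                ratio = (rec.counts.get(round_index, 0) / to_total) / f_from
        try:
            trunc = suggest_truncation(
                profile, rep_id, gap_threshold=truncation_gap_threshold
            ).suggest_cycle_only
        except NoCysteineError:
            trunc = False
        rows.append(
            {
                "family": fam_id,
                "representative": rep_pep,
                "hit_name": hit,
                "member_count": len(member_ids),
                "summed_frequency": summed_freq,
                "enrichment_ratio": ratio,
                "consensus": families.consensus[fam_id].replace("-", ""),
                "suggest_cycle_only": trunc,
            }
        )
    frame = pd.DataFrame(rows).sort_values(
        "summed_frequency", ascending=False, kind="mergesort"
    )
    return frame.reset_index(drop=True)


def write_report(frame: pd.DataFrame, tsv_path=None, json_path=None) -> None:
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
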