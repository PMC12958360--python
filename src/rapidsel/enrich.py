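"""Per-round peptide counting, ranking, and convergence statistics.

Unique decoded peptides are accumulated into :class:`PeptideRecord` objects
carrying per-round counts, frequencies and abundance ranks.  Ranks are
total: descending count, ties broken lexicographically on the peptide
string, so the whole downstream pipeline is order-independent.
Libraries ('L' and 'D') are never pooled.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .libcode import DecodedPeptide

__all__ = [
    "PeptideRecord",
    "RoundSummary",
    "count_unique",
    "rank_sequences",
    "top_n_fraction",
    "enrichment_trajectory",
    "select_top_k",
    "round_summary",
    "records_to_frame",
    "write_count_table",
    "write_top_k_fasta",
]


@dataclass
class PeptideRecord:
    """A unique peptide with per-round counts, frequencies, and ranks."""

    peptide: str
    library_tag: str
    counts: dict[int, int] = field(default_factory=dict)
    frequencies: dict[int, float] = field(default_factory=dict)
    rank: dict[int, int] = field(default_factory=dict)


@dataclass(frozen=True)
class RoundSummary:
    round_index: int
    total_reads: int
    unique_peptides: int
    top_n_fraction: dict[int, float]

    def to_json(self) -> str:
        return json.dumps(
            {
                "round": self.round_index,
                "total_reads": self.total_reads,
                "unique_peptides": self.unique_peptides,
                "top_n_fraction": {str(n): f for n, f in self.top_n_fraction.items()},
            },
            indent=2,
        )


def count_unique(
    peptides: Iterable[DecodedPeptide | str],
    round_index: int,
    *,
    library_tag: str | None = None,
    records: dict[str, PeptideRecord] | None = None,
) -> dict[str, PeptideRecord]:
    """Tally accepted peptides for one round into a record collection.

    Accepts :class:`DecodedPeptide` objects (rejected records are ignored)
    or bare peptide strings (``library_tag`` then required).  Passing an
    existing ``records`` dict accumulates additional rounds in place.
    """
    records = records if records is not None else {}
    tag = library_tag
    tally: dict[str, int] = {}
    for item in peptides:
        if isinstance(item, DecodedPeptide):
            if not item.accepted:
                continue
            if tag is None:
                tag = item.library_tag
            elif item.library_tag != tag:
                raise ValueError("mixed library tags in one counting pass")
            pep = item.peptide
        else:
            if tag is None:
                raise ValueError("library_tag required for bare peptide strings")
            pep = item
        tally[pep] = tally.get(pep, 0) + 1

    total = sum(tally.values())
    for pep, n in tally.items():
        rec = records.get(pep)
        if rec is None:
            rec = records[pep] = PeptideRecord(peptide=pep, library_tag=tag or "L")
        rec.counts[round_index] = rec.counts.get(round_index, 0) + n
    if total:
        round_total = sum(r.counts.get(round_index, 0) for r in records.values())
        for rec in records.values():
            c = rec.counts.get(round_index)
            if c:
                rec.frequencies[round_index] = c / round_total
    return records


def rank_sequences(
    records: Mapping[str, PeptideRecord] | Iterable[PeptideRecord], round_index: int
) -> list[PeptideRecord]:
    """Assign 1-based abundance ranks for one round.

    Descending count, ties broken by lexicographic order of the peptide
    string.  Returns the ranked records in rank order.
    """
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    present = [r for r in recs if r.counts.get(round_index, 0) > 0]
    present.sort(key=lambda r: (-r.counts[round_index], r.peptide))
    for i, rec in enumerate(present, start=1):
        rec.rank[round_index] = i
    return present


def top_n_fraction(
    records: Mapping[str, PeptideRecord] | Iterable[PeptideRecord],
    round_index: int,
    n: int,
) -> float:
    """Summed frequency of the ``n`` most abundant peptides in a round."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = rank_sequences(records, round_index)
    return float(sum(r.frequencies[round_index] for r in ranked[:n]))


def enrichment_trajectory(
    records: Mapping[str, PeptideRecord] | Iterable[PeptideRecord],
    from_round: int,
    to_round: int,
) -> dict[str, float]:
    """Frequency ratio to_round/from_round per peptide present in to_round.

    Peptides unseen in the earlier round receive a pseudo-frequency of
    0.5/total_reads of that round, keeping every ratio finite.
    """
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    to_total = sum(r.counts.get(to_round, 0) for r in recs)
    if to_total == 0:
        raise ValueError(f"round {to_round} has no counts")
    from_total = sum(r.counts.get(from_round, 0) for r in recs)
    if from_total == 0:
        raise ValueError(f"round {from_round} has no counts")
    pseudo = 0.5 / from_total
    out: dict[str, float] = {}
    for rec in recs:
        if rec.counts.get(to_round, 0) == 0:
            continue
        f_to = rec.counts[to_round] / to_total
        f_from = rec.counts.get(from_round, 0) / from_total or pseudo
        out[rec.peptide] = f_to / f_from
    return out


def select_top_k(
    records: Mapping[str, PeptideRecord] | Iterable[PeptideRecord],
    round_index: int,
    k: int,
) -> list[str]:
    """Peptides of ranks 1..k for one round (all of them if fewer exist)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = rank_sequences(records, round_index)
    if len(ranked) < k:
        warnings.warn(
            f"requested top {k} but only {len(ranked)} unique peptides in round "
            f"{round_index}; returning all",
            stacklevel=2,
        )
    return [r.peptide for r in ranked[:k]]


def round_summary(
    records: Mapping[str, PeptideRecord] | Iterable[PeptideRecord],
    round_index: int,
    ns: Iterable[int] = (1, 10, 100, 200),
) -> RoundSummary:
    ranked = rank_sequences(records, round_index)
    total = sum(r.counts[round_index] for r in ranked)
    fracs = {}
    for n in sorted(set(ns)):
        fracs[n] = float(sum(r.frequencies[round_index] for r in ranked[:n]))
    return RoundSummary(
        round_index=round_index,
        total_reads=total,
        unique_peptides=len(ranked),
        top_n_fraction=fracs,
    )


def records_to_frame(
    records: Mapping[str, PeptideRecord] | Iterable[PeptideRecord],
    analysis_round: int | None = None,
) -> pd.DataFrame:
    recs = list(records.values()) if isinstance(records, Mapping) else list(records)
    rounds = sorted({r for rec in recs for r in rec.counts})
    rows = []
    for rec in recs:
        row: dict[str, object] = {"peptide": rec.peptide, "library": rec.library_tag}
        for r in rounds:
            row[f"count_r{r}"] = rec.counts.get(r, 0)
        if analysis_round is not None:
            row[f"freq_r{analysis_round}"] = rec.frequencies.get(analysis_round, 0.0)
            row[f"rank_r{analysis_round}"] = rec.rank.get(analysis_round, 0)
        rows.append(row)
    frame = pd.DataFrame(rows)
    if analysis_round is not None and not frame.empty:
        frame = frame.sort_values(
            [f"count_r{analysis_round}", "peptide"], ascending=[False, True]
        ).reset_index(drop=True)
    return frame


def write_count_table(records, path, analysis_round: int | None = None) -> None:
    records_to_frame(records, analysis_round).to_csv(path, sep="\t", index=False)


def write_top_k_fasta(records, round_index: int, k: int, path) -> None:
    """FASTA export of the top-K peptides for external aligners."""
    ranked = rank_sequences(records, round_index)
    with open(path, "w") as fh:
        for rec in ranked[:k]:
            fh.write(
                f">{rec.library_tag}_r{round_index}_rank{rec.rank[round_index]}"
                f"_count{rec.counts[round_index]}\n{rec.peptide}\n"
            )
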