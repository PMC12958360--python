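"""End-to-end round analysis: cluster -> align -> families -> report.

The default analysis round is 3 (the penultimate-diversity round); the
identity threshold, family linkage threshold and representative cap are all
exposed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .align import AlignmentProfile, FamilyAssignment, extract_families, progressive_align
from .cluster import Clustering, greedy_cluster
from .enrich import PeptideRecord, rank_sequences
from .hits import family_report

DEFAULT_ANALYSIS_ROUND = 3

__all__ = ["RoundAnalysis", "analyze_round", "DEFAULT_ANALYSIS_ROUND"]


@dataclass
class RoundAnalysis:
    round_index: int
    clustering: Clustering
    profile: AlignmentProfile
    families: FamilyAssignment
    report: pd.DataFrame


def analyze_round(
    records: Mapping[str, PeptideRecord],
    round_index: int = DEFAULT_ANALYSIS_ROUND,
    *,
    cluster_id: float = 0.90,
    family_id: float = 0.60,
    max_representatives: int | None = 500,
    from_round: int | None = None,
) -> RoundAnalysis:
    """Cluster a whole round, align representatives, extract families.

    ``max_representatives`` caps the number of cluster representatives fed
    to the MSA stage (most abundant first; None aligns all of them).
    """
    rank_sequences(records, round_index)
    clustering = greedy_cluster(records, cluster_id, round_index=round_index)
    reps = [c.representative for c in clustering.clusters]
    if max_representatives is not None:
        reps = reps[:max_representatives]
    if len(reps) == 1:
        from .align import column_conservation, consensus_string

        rows = [(reps[0], reps[0])]
        profile = AlignmentProfile(
            aligned=rows,
            conservation=column_conservation([reps[0]]),
            consensus=consensus_string([reps[0]]),
        )
    else:
        profile = progressive_align([(r, r) for r in reps])
    families = extract_families(profile, family_id)
    report = family_report(
        families, records, clustering, profile, round_index, from_round=from_round
    )
    return RoundAnalysis(round_index, clustering, profile, families, report)
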