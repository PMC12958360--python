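"""The headline simulation scenario: one dominant binder family plus four
minor families hidden under it.

Top-200 picking at the final round sees almost nothing but the dominant
family, while full-dataset clustering + MSA at round 3 recovers all five —
the qualitative contrast the whole pipeline exists to fix.  Parameters are
frozen here and shared by the acceptance tests.
"""

from rapidsel.enrich import count_unique, rank_sequences, select_top_k
from rapidsel.pipeline import analyze_round
from rapidsel.simsel import FamilySpec, SelectionSimConfig, simulate_selection

DOMINANT_SEED = "FWTLYGPIAKDEQRS"
# mutually dissimilar (pairwise identity < 0.2) so planted families stay
# distinct under the 0.6 family-linkage threshold
MINOR_SEEDS = (
    "MNHVVKPGWDEITAK",
    "RGEYHNAFPLSKTDW",
    "KPDSFHWIVRLGYEN",
    "ETAWGKRNHYDMPVL",
)
HEADLINE_SEEDS = tuple(range(10))
ANALYSIS_ROUND = 3
FINAL_ROUND = 5


def headline_config(seed: int) -> SelectionSimConfig:
    """One dominant family (~95% of round-5 reads) over four minor families
    (~0.5% each at round 5) on a random background."""
    families = (
        FamilySpec(DOMINANT_SEED, mutation_rate=0.08, fitness=5.6, initial_fraction=0.05),
    ) + tuple(
        FamilySpec(s, mutation_rate=0.16, fitness=2.6, initial_fraction=0.006)
        for s in MINOR_SEEDS
    )
    return SelectionSimConfig(
        seed=seed, families=families, rounds=FINAL_ROUND, reads_per_round=10_000
    )


def records_for_round(result, round_index: int):
    """Error-free decoded peptide records for one simulated round."""
    truth = result.truth(round_index)
    sym = "Y" if result.config.library_tag == "L" else "y"
    peptides = [
        sym + pep + "C"
        for pep, n in truth.multiplicities.items()
        for _ in range(n)
    ]
    records = count_unique(peptides, round_index, library_tag=result.config.library_tag)
    rank_sequences(records, round_index)
    return records, truth


def run_headline(seed: int):
    """Returns (families covered by top-200 at round 5, planted-seed match
    fractions of the best family consensus at round 3)."""
    config = headline_config(seed)
    result = simulate_selection(config)

    records5, truth5 = records_for_round(result, FINAL_ROUND)
    top200 = select_top_k(records5, FINAL_ROUND, 200)
    covered = {
        truth5.labels[p[1:-1]]
        for p in top200
        if truth5.labels.get(p[1:-1], "background") != "background"
    }

    records3, _ = records_for_round(result, ANALYSIS_ROUND)
    analysis = analyze_round(
        records3, ANALYSIS_ROUND, cluster_id=0.9, family_id=0.6, max_representatives=200
    )
    matches = {}
    for planted in (DOMINANT_SEED,) + MINOR_SEEDS:
        wrapped = "Y" + planted + "C"
        best = 0.0
        for consensus in analysis.families.consensus.values():
            cons = consensus.replace("-", "")
            frac = sum(a == b for a, b in zip(wrapped, cons)) / len(wrapped)
            best = max(best, frac)
        matches[planted] = best
    return covered, matches
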