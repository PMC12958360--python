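# rapidsel

Analysis toolkit for mRNA-display (RaPID-style) selection sequencing.

Selections against a target enrich binder peptides over successive rounds.
The sequencing output of such a campaign is dominated by one family by the
final round, and the classic "take the top 200 sequences and align them"
analysis sees little else. `rapidsel` implements the full-dataset
alternative — decode everything, condense the round by greedy identity
clustering, align the cluster representatives, and mine the alignment for
conserved families and truncation candidates — together with a synthetic
selection simulator so each stage is testable without any external data.

## What it does

- **`rapidsel.libcode`** — library architecture (constant flanks, AUG
  initiator reassigned to a Tyr initiator, 15 NNK codons, downstream Cys,
  GSGSGS spacer) and read decoding under the reprogrammed genetic code,
  with explicit per-read rejection reasons (no anchor, internal stop,
  ambiguous base, length mismatch).
- **`rapidsel.enrich`** — unique-peptide counting per round, abundance
  ranks (total order: count desc, then lexicographic), top-N read
  fractions, enrichment trajectories, top-K selection.
- **`rapidsel.cluster`** — CD-HIT-style greedy incremental clustering of a
  whole round at a configurable identity threshold (default 0.90), with a
  conservative short-word prefilter that changes runtime but never the
  partition; `.clstr`-compatible output.
- **`rapidsel.align`** — self-contained progressive MSA (UPGMA guide tree,
  affine-gap profile–profile alignment, BLOSUM62), entropy-based column
  conservation, consensus strings, single-linkage family extraction.
- **`rapidsel.hits`** — "[library][cluster]-[rank]" hit naming (e.g.
  `L21-34`), macrocycle/tail splitting at the first cysteine, truncation
  suggestions from the conservation contrast, per-family reports.
- **`rapidsel.simsel`** — multi-round selection simulator: NNK background,
  planted binder families (seed + per-position mutation rate + fitness),
  multinomial fitness-weighted round updates, per-base sequencing error,
  FASTQ emission with full ground truth.

## CLI

```bash
# generate a synthetic 5-round selection
rapidsel simulate --config sim.yaml --outdir run/

# decode a round's FASTQ (plain or .gz) into peptides
rapidsel decode --fastq run/L_round3.fastq --out decoded_r3.tsv --rejects-out rejects.tsv

# build the multi-round count table
rapidsel count --decoded decoded_r3.tsv 3 --out counts.tsv --round 3

# cluster one round (CD-HIT-compatible .clstr + representatives FASTA)
rapidsel cluster --counts counts.tsv --round 3 --cluster-id 0.9 --library L --out-prefix r3

# full analysis: cluster → MSA of representatives → families → report
rapidsel analyze --counts counts.tsv --round 3 --out-prefix r3
```

A simulation config looks like:

```yaml
seed: 21
rounds: 5
reads_per_round: 10000
library_tag: L
per_base_error: 0.0
families:
  - seed: FWTLYGPIAKDEQRS
    mutation_rate: 0.08
    fitness: 5.6
    initial_fraction: 0.05
```

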