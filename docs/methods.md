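# Methods

`scfatlas` re-implements, as a tested pipeline, the genome-based workflow used
to characterise human-gut *Clostridia*: protein-level relatedness indices (AAI
and POCP) and their use for genus delineation, rule-based reconstruction of
butyrate/propionate biosynthetic capability from per-genome reaction
presence/absence, and community-level quantification of producer abundance
from species abundance tables. Every stage is exercised against synthetic data
with planted ground truth; no external genomes or metagenomes are required.

## Relatedness indices

All pairwise protein comparisons use optimal Smith–Waterman local alignment
with BLOSUM62 and affine gap penalties (first gap residue 11, each further
residue 1 — the BLAST-family regime). From each alignment we take

- *percent identity* = identical columns / alignment columns × 100,
- *coverage* = aligned (non-gap) positions of the **shorter** sequence / its
  full length × 100.

The shorter-sequence coverage denominator means a fragment/full-length pair
is judged by the fragment; the alternative (longer-sequence denominator) would
silently discard genuine conserved fragments. A hit *passes* when identity
≥ 40% and coverage ≥ 50% (both inclusive) — the conventional
conserved-protein cutoffs.

**AAI** is the mean percent identity over reciprocal best hits (RBH): for each
protein the best passing hit by score, ties broken by higher identity then
lexicographically smaller partner ID, and a pair is an RBH when each member is
the other's best hit. When no RBH exists, AAI is *undefined* and carried as an
explicit flag (NaN in matrices), never coerced to 0; undefined pairs are
excluded from minima and reported as a count.

**POCP** = 100 × (C1 + C2)/(T1 + T2), where C1/C2 count proteins of each
genome with **at least one** passing hit in the other (reciprocity not
required — mirroring the distinction between an RBH-based AAI tool and an
orthology-table POCP tool), and T1/T2 are the proteome sizes.

Alignments are computed once per unordered proteome pair and reused for both
directions, so AAI and POCP are symmetric by construction, not by rounding.

A deliberately independent full-DP Gotoh oracle (with the identical gap
convention) lives in the test suite and is never used by the implementation;
best-hit maps are checked against it exhaustively on small proteomes.

Note one property that is often mis-stated: the best *local* alignment of two
unrelated random proteins frequently exceeds 40% identity, because the optimal
local segment is short and enriched for matches. What keeps random pairs out
of the conserved-protein counts is the *joint* identity-and-coverage filter;
in 100 seeded draws of length-200 random pairs no alignment passed both, while
about a fifth passed the identity cutoff alone.

## Genus delineation

For every genus with ≥ 2 species the minimum pairwise AAI (minAAI) and POCP
(minPOCP) are computed and compared, inclusively, with the conventional
thresholds of 65% (AAI) and 50% (POCP):

| group | minAAI ≥ 65 | minPOCP ≥ 50 |
|-------|-------------|--------------|
| A     | yes         | yes          |
| B     | yes         | no           |
| C     | no          | yes          |
| D     | no          | no           |

Single-species genera are reported as singletons; singletons + A–D partition
the genus list exactly. If every AAI pair of a genus is undefined, POCP alone
decides (C or D) and the verdict is flagged. For failing genera the module:

- finds *outliers* — species whose single removal lifts both minima over the
  thresholds (brute force over single removals; the removal must also leave
  no undefined AAI pair);
- proposes *partitions* — connected components of the within-genus graph whose
  edges join pairs meeting **both** thresholds (undefined AAI counts as below
  threshold). Each multi-member component is re-verified internally; failing
  components are reported as unresolved rather than proposed. Components were
  chosen over clique enumeration: deterministic, near-linear, and adequate for
  the two-to-three-cluster structures this analysis encounters;
- reports cross-genus *merge* candidates — components of the same graph built
  over all species that span more than one nominal genus label. No renaming is
  attempted.

The same minimum statistic is available at family rank (`family_min_aai`),
with undefined pairs counted separately rather than guessed into the minimum.
A packaged transcription of the published genus-group table (77 multi-species
genera: 51 A, 12 B, 6 C, 8 D) ships as reference data; it preserves the
table's spelling of each genus verbatim, including one variant
("Pseudoflavonifactor") that appears elsewhere as "Pseudoflavonifractor".

## Pathway catalog and producer calls

The engine consumes reaction *presence/absence* per genome — the output
abstraction of homology-based pathway screeners — rather than sequences, which
keeps the calling logic exact and exhaustively testable. The packaged catalog
declares 15 pathways over 37 blocks:

- butyrate routes to crotonyl-CoA: acetyl-CoA/thiolase (B1), succinate
  semialdehyde (B2), glutarate (B3, exactly four blocks, including
  2-oxoglutarate reductase EC 1.1.1.399), lysine (B4, including the *ato*
  step);
- the crotonyl-CoA → butyryl-CoA gateway (butyryl-CoA dehydrogenase);
- butyrate terminal branches: *but* (butyryl-CoA:acetate CoA-transferase) and
  *buk* (phosphate butyryltransferase + butyrate kinase);
- propionate routes to propionyl-CoA: succinate (P1, including
  methylmalonyl-CoA carboxytransferase), acrylate (P2, including lactoyl-CoA
  dehydratase and propionate:lactoyl-CoA transferase), propanediol (P3,
  including propanal dehydrogenase);
- propionate terminal branches: phosphate propionyltransferase + propionate
  kinase, and propionyl-CoA:lactate/acetate transferase;
- cross-feeding: acetate utilisation via acetate kinase + phosphate
  acetyltransferase or via AMP-forming acetyl-CoA synthetase; lactate
  utilisation via D/L-lactate dehydrogenase **and** pyruvate:ferredoxin
  oxidoreductase (both required).

The succinate propionate route is included although it is consistently
interrupted in gut *Clostridia*, so that negative result is reproducible on
real-style inputs. Block inventories of B2, B4 (beyond *ato*) and P1 follow
the standard fermentation ladders and are explicitly editable catalog content;
users can supply their own catalog JSON, and an import adapter’s job is only a
column mapping from screener output to block IDs.

A pathway is *complete* with 0 missing blocks, *near-complete* with exactly
one, *incomplete* otherwise. A genome is called a **butyrate producer** iff
gateway AND (≥1 route) AND (≥1 terminal) each have ≤ `max_missing` blocks
missing; **propionate** analogously without a gateway. `max_missing` is global
per run and restricted to {0, 1}: 0 reproduces strict "complete pathway"
counts, 1 the "lacking one metabolic block" counts. *but*/*buk* branches
present without the gateway are flagged as orphan terminals and never counted.
Published totals for the strict calls contain one internal inconsistency
(605 + 268 − 187 = 686 against a stated 687); the engine enforces consistent
set algebra (both = butyrate ∩ propionate; exclusives = totals − both), so
that discrepancy is documented here, not reproduced.

## Community profiling

Producer abundance joins a species × sample relative-abundance table (percent
scale; per-sample sums may be < 100 when the table covers only part of the
community, never > 100) with taxonomy and producer calls. Per sample we sum
abundances over category members (butyrate, propionate, both, and route/branch
splits); a dual-capability species counts once in each category. Distribution
statistics across samples (mean, median, min, max, quartiles) use
mean-across-samples averaging, not pooled reads. Because published producer
percentages are ambiguous about their denominator (total reads vs total
bacteria), both the table-scale sums and the per-sample shares of the table
total are emitted; neither is asserted as "the" published definition.

The *dominance set* is the smallest prefix of producers, sorted by mean
abundance descending (ties lexicographic), whose cumulative share of total
producer abundance reaches a target (default 80%). Report percentages are
rounded half-up to one decimal. Species missing from a table are treated as
absent (0), not as missing data.

## Synthetic data

The generator plants known answers for every stage:

- **Proteome pairs**: orthologs are linked by point substitutions only — each
  mutated position receives a uniformly random *different* residue, so
  realized identity is directly countable; indel robustness is the aligner
  tests' job, not the generator's. Pair and community simulation substitute an
  *exact* count of positions, `round((1−p)·L)`, because per-position binomial
  noise at realistic protein lengths (σ ≈ 2.9 points at L = 150) would leave
  individual orthologs several points off target; the standalone
  `mutate_protein` keeps per-position Bernoulli semantics with the identity as
  the exact expectation. Unique proteins are uniform random sequences over the
  20 canonical residues (no composition model is claimed).
- **Reaction profiles**: a genome's profile is exactly the block set of its
  planted route/terminal combination; each block is then dropped independently
  at the chosen rate. Default label frequencies follow the observed prevalence
  of the capabilities among gut *Clostridia* species (23.3% butyrate-only,
  9.5% propionate-only, 4.1% both, 63.1% neither). At dropout 0 and
  `max_missing=0` labels are recovered exactly; recovery under dropout is
  evaluated at `max_missing=1`, since that relaxation is precisely the
  mechanism for tolerating single missing blocks (at strictness 0 a five-block
  butyrate chain survives 5% dropout only with probability 0.95⁵ ≈ 0.77).
- **Abundance tables**: symmetric Dirichlet compositions × 100 (columns sum to
  100 within 1e-9), so the expected share of any species group is its fraction
  of the species list. `simulate_abundance_table` defaults to concentration
  α = 1 (a strongly uneven community). The community simulator
  (`simulate_community`, 30 genomes × 10 samples by default) uses α = 5: with
  only 10 samples, the Monte-Carlo standard error of a ~25% group share must
  sit well inside the ±3-point band used to judge recovery (at α = 1 the
  per-sample σ is ≈ 8 points, making a 10-sample comparison uninformative),
  while per-species abundances remain visibly uneven.
- **Communities**: genomes are grouped into genera of 1–4 members; members
  share 80% of their proteins at a genus-level planted identity drawn in
  [0.70, 0.90] (mutated from a genus ancestor), the rest being unrelated, so
  within-genus AAI is high and cross-genus AAI undefined or far below any
  threshold. Default community proteomes are 20 proteins of 80–160 residues —
  deliberately miniature so an all-vs-all comparison of 30 genomes stays in
  the minutes range on one CPU; identity-recovery experiments use the fuller
  100-protein, 150–400-residue condition.

What the synthetic data does **not** emulate: real amino-acid composition and
indels, genome incompleteness correlated with phylogeny, co-occurrence
structure between pathways, and read-level compositional noise. Passing tests
therefore demonstrate the correctness of the metrics, rules and bookkeeping —
not the biological accuracy of homology screening, which is out of scope by
design (the engine starts from presence/absence).

## Numerical conventions

- Threshold comparisons (40/50 hit filter, 65/50 genus thresholds) are all
  inclusive (≥); boundaries pass.
- Best-hit ties break by score, then identity, then lexicographic ID; ranking
  and dominance ties break lexicographically — every output is deterministic.
- Undefined AAI is NaN/None end to end; it is never 0.
- All randomness flows from a single integer seed per entry point;
  sub-streams are spawned deterministically.
- Report rounding is half-up at one decimal; internal computation is never
  rounded.

## Known limitations

- All-vs-all Smith–Waterman is exact but quadratic; hundreds of full-size
  proteomes would need a prefilter (k-mer seeding) that this package does not
  implement.
- The catalog ships one block inventory per pathway; strain-level enzyme
  variants must be handled by the user's block mapping.
- `find_outliers` considers single removals only, matching the "one divergent
  species" pattern it reports; multi-species exclusions surface through the
  partition proposals instead.
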