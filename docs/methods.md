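# Methods

## Scope and assumptions

funtax estimates community functional potential by projecting a 16S-derived
taxonomic profile through a genome–function copy-number map. The approach
assumes (i) that the taxa in the input table can be matched to annotated
reference genomes at their deepest named rank, (ii) that the mean copy
number over matched genomes is representative of the environmental
population, and (iii) that gene content, not expression, is the quantity of
interest — this is *potential*, not activity. No hidden-state prediction
across a phylogeny is attempted: an unmatched taxon contributes nothing and
its mass is reported as dropped, per sample, in the coverage report.

## Taxon-to-genome aggregation

A query lineage matches a genome when the normalized names agree at the
query's deepest rank and at every shallower rank the query provides.
Normalization lower-cases, strips `x__` rank prefixes and bracketed
qualifiers. Copy numbers (16S and per-unit) are aggregated by **unweighted
arithmetic mean** over all matched genomes. The mean is the convention of
this tool genre, is order-independent, and avoids privileging heavily
sequenced species; sum or best-hit aggregation would do either. Lineages
are truncated at "unclassified"/"uncultured"/"unknown" tokens so that such
placeholders never match real genomes.

## Pathway scoring

**Quorum (PEC).** A pathway is present in a sample iff the fraction of its
member units with strictly positive inferred abundance is at least the
cut-off. Presence counts *detected units*, not abundance mass, so a single
low-abundance enzyme counts as detected; there is no minimum-abundance
floor. The grid is {50, 60, 70, 80, 90}% with unfiltered (0%) output always
emitted alongside. By construction presence sets are nested along the grid.
Under CoM the quorum is evaluated on the pooled community profile; under
ICo on each taxon's private unit vector — pooling can only add detected
units, so CoM presence is always a superset of ICo presence.

**Multiplicity split.** A unit belonging to `m` pathways contributes
`U(u,s)/m` to each. This prevents promiscuous enzymes from being counted
`m` times and makes the sum of raw pathway scores conserve unit mass; it is
the package's own convention, flagged in output provenance, and can be
disabled (`split=False` / `--no-split`) for a plain per-pathway sum.
Multiplicity is a property of the database, so it is identical under CoM
and ICo; consequently a single-taxon community makes the two algorithms
coincide exactly (a tested invariant).

**Conservation.** The ICo contribution tensor is stored pre-normalization
with the per-sample normalizer retained, so `Σ_taxa tensor = raw profile`
holds to 1e-9 (tested on random fixtures and in the acceptance script).

## Statistics

- Two classes: two-sided Wilcoxon rank-sum. The exact distribution is
  enumerated when both groups have ≤ 8 samples and the pooled values are
  tie-free (reproducible small-sample p values, e.g. p = 0.1 for
  {1,2,3} vs {10,20,30}); otherwise the normal approximation with tie
  correction is used.
- More than two classes: Kruskal–Wallis.
- Functions constant across all samples are skipped and listed rather than
  assigned a p value.
- Benjamini–Hochberg step-up across all tested functions; raw and adjusted
  p values are both reported. Default alpha 0.05 on adjusted values.
- PEC consensus: a function scores at a level only if it was present
  (survived the filter, non-constant) *and* significant there; the
  consensus score is the fraction of the five levels, hence lies in
  {0, 0.2, …, 1}.

## Ordination

Samples are compared by Jensen–Shannon divergence with base-2 logarithms
after adding a 1e-9 pseudocount and renormalizing columns; `sqrt(JSD)` is
used as the embedded distance because it is a metric and bounded in [0, 1].
Classical PCoA double-centers `−d²/2` and eigendecomposes; negative
eigenvalues are reported, never silently dropped; axes are ordered by
eigenvalue with variance explained taken over the positive spectrum; each
axis is sign-fixed so its first nonzero loading is positive (deterministic
output). The implementation is ~20 lines of numpy by design — the sign and
negative-eigenvalue contracts are part of the output format — and is
cross-checked against scikit-bio's PCoA in the test suite.

## Co-contribution networks

Contributions always come from the ICo algorithm (functional exclusiveness
between members). For every taxon pair and every function contributed by
both (non-zero, non-constant series), the Spearman correlation across
samples is computed; candidates with rho ≥ 0.6 (positive only — the
hypothesis is *co*-contribution) enter a single BH correction over all
(pair, function) tests, and an edge is kept when at least one function
survives alpha = 0.05, with survivors listed as the edge's supporting
functions. Rank correlation is used because contributions are compositional
and heavy-tailed. At least 4 samples are required; below that, correlation
is meaningless and the call fails loudly. Degree, normalized betweenness
and local clustering are computed on the final simple graph.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `pec` | grid {0, 50–90}% | quorum of detected member units for presence |
| `split` | on | divide shared units' mass across their pathways |
| `abundance_floor` | 0.02 | relative-abundance floor for core functions |
| `prevalence_floor` | 0.75 | fraction of group samples required for core |
| `alpha` | 0.05 | significance level on BH-adjusted p values |
| `rho_min` | 0.6 | minimum Spearman rho for a candidate network edge |
| `min_samples` | 4 | samples required before correlating contributions |
| JSD pseudocount | 1e-9 | keeps divergences finite on zero-heavy profiles |

Core-function floors are package defaults (the genre publishes no standard
values); both are exposed everywhere they apply.

## Synthetic data

`generate_synthetic_db` emulates the *structure* of a genome–function map:
random lineages over a small generated taxonomy, 16S copy numbers uniform
on [1, 15] (the span observed across sequenced genomes, which exercises the
correction non-trivially), unit copies uniform on [0, max_copies], pathways
of 3–12 EC members under a full 3-level hierarchy, plus a KO catalog and an
EC→KO cross-map with 1–2 targets per enzyme. `generate_synthetic_study`
emulates a two-factor treated/control × timepoint design: genus-level
lognormal profiles (noise sigma 0.5), 12 samples (three per cell), and a
3-fold planted effect on 30% of genera in the treated class.

What the generator does **not** emulate: sequencing error, zero inflation,
phylogenetic correlation of gene content, or realistic pathway overlap
topology. Passing tests therefore demonstrate the algebra, contracts and
determinism of the pipeline — not calibration against real communities or
a curated genome database.

## Numerical choices and degenerate inputs

- All per-sample renormalizations guard zero columns (left all-zero and
  flagged rather than NaN-filled).
- Ranking ties break lexicographically by function id; all outputs are
  deterministic given inputs and seed, and TSVs are written with a fixed
  float format so reruns are byte-identical.
- Samples in which no taxon matches any genome are flagged "uninferable"
  and excluded downstream.
- KEGG color export bins the log2 class ratio (pseudocount 1e-9) clipped to
  ±2 into 5 equal-width diverging bins; units undetected in both classes
  are neutral gray. The palette is configurable; the scheme is this
  package's own convention for two-class enzyme comparison.

## Problem sizes

The test suite and the acceptance script run on deliberately small
instances: the two-genome hand-checkable fixture, 100 synthetic communities
(5 databases × 10 samples, checked under both algorithms) for quorum
nesting, 20 databases of ≤ 5 genomes and ≤ 3 pathways for brute-force
oracle agreement, and 12-sample studies for the CLI workflow. These sizes
were chosen so every expected value is independently recomputable; the
implementation itself is vectorized over pandas/numpy and scales to
hundreds of taxa and samples.

## Known limitations

- Inference quality is bounded by the genome database: funtax ships a
  schema, loader and synthetic generator, not a curated multi-thousand
  genome map; users supply their own tables (`funtax db-build`).
- The multiplicity split and the unweighted-mean taxon aggregation are
  documented conventions, not biological ground truth.
- Pathway presence is binary per quorum level; partial pathways below the
  cut-off contribute nothing at that level.
- Contribution networks are correlational; edges are hypotheses about
  interaction, not demonstrations of it.
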