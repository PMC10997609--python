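# Methods

## Data model and coordinate conventions

Cytosine reports are Bismark-style five-column TSVs: contig, 1-based
position of the cytosine on the plus-strand coordinate system, strand,
methylated read count, unmethylated read count.  The two cytosines of a
CpG are separate records (the plus cytosine at the C's coordinate, the
minus cytosine at the G's coordinate) and are filtered, averaged and
pooled separately throughout, because the coverage rule is per cytosine.
All interval files (CGIs, genes, tiles, ChIP reads) are 0-based
half-open, BED-style.  Genome sequences are normalized to uppercase
{A,C,G,T,N}: U→T, any other letter →N.  Any 6-base context window that
runs off a contig, contains an N, or is not centred on CG is excluded
from context analyses, with the exclusion count logged.

## Flanking-context preference correlation

For each cytosine with coverage ≥ `min_coverage` (default 10 reads) the
level is n_meth/(n_meth+n_unmeth).  The observed profile assigns each of
the 256 NNCGNN hexamers the **unweighted mean of per-site levels** over
the sites carrying that context; an alternative read-pooled mean is
deliberately not the default because the per-site level is the primary
quantity and deep sites would otherwise dominate.  Contexts with zero
observed sites stay missing and are dropped pairwise from correlations
rather than imputed.

The correlation between an observed profile and an enzyme preference
profile is Pearson *r* on the raw paired values (`pearson_values`,
default).  `pearson_ranks` — Pearson on average-tie rank vectors, i.e.
Spearman ρ — is retained as an option because ranking both vectors is a
natural alternative reading of the workflow; since ranking is invariant
to monotone transforms, the two differ only through the shape of the
value scale.  Zero variance in either operand raises an error rather
than returning a silent 0.

Symmetrization (averaging each hexamer with its reverse complement,
reflecting the two-fold symmetry of the CpG site) is applied by default
only to the DNMT3A and DNMT3B profiles, the two enzymes whose published
preference tables are conventionally symmetrized; a flag extends it to
any profile.  The 256 contexts partition into 120 complementary pairs
and 16 palindromes, so a symmetrized profile has at most 136 distinct
values.

In-vitro preference tables are external inputs (hexamer/value TSVs,
validated for completeness).  The package does not re-derive them from
kinetic data; the simulator ships synthetic stand-ins (256 i.i.d.
standard-normal draws min–max rescaled to [0,1]).

## Tile differential methylation

The genome is segmented into fixed 1-kb non-overlapping adjacent tiles
(terminal tiles truncated, retained).  Replicates within a condition are
pooled by summing counts per (contig, position, strand).  Tiles need at
least `min_cpg` (default 3) covered cytosines in **both** conditions;
the threshold is a guard against single-site tiles driving calls, and is
configurable because no principled universal value exists.

Each tile's 2×2 pooled table [[meth_a, unmeth_a], [meth_b, unmeth_b]] is
tested with the two-sided Fisher exact test (sum of hypergeometric
probabilities of tables, at fixed margins, no more probable than the
observed one), implemented through `scipy.stats.fisher_exact` and
verified in the test suite against exhaustive enumeration for all tables
with row sums ≤ 30.  Multiple testing uses Benjamini–Hochberg across all
tested tiles.  A tile is hypomethylated when diff ≤ −25 pp and q < 0.01,
hypermethylated at the mirror image; diff is the pooled percentage of
condition B minus condition A.  The pooled-Fisher design treats reads,
not replicates, as the sampling unit; with deep pooled counts it is
anti-conservative relative to a replicate-level model when between-
replicate variance is real, which is the main caveat when interpreting
absolute DMR counts (the thresholds, 25 pp and q < 0.01, do the heavy
lifting in practice).

Feature annotation labels a tile `promoter` if it overlaps any TSS ±
1 kb window (TSS = gene start on plus-strand genes, gene end − 1 on
minus-strand), else `gene_body` on any gene overlap, else `intergenic`.

## CGI histone-mark analysis

ChIP read counting is overlap-by-≥1-bp on half-open intervals (each read
may count toward several islands).  Normalization: islands with fewer
than 4 raw ChIP reads are excluded; remaining counts get a +0.5 offset,
are scaled to counts per 10 million mapped reads, and divided by the
identically offset-scaled input; islands with zero coverage in both
tracks are removed.  The offset keeps scores finite and positive at zero
input and makes the score strictly monotone in the chip count.

Per CGI and depletion arm, methylation change is the pooled-count
percentage at the depleted timepoint minus baseline, and the statistic
of interest is dd = Δ_cofactor − Δ_enzyme.  Islands are ranked by
normalized score into 10 equal bins (bin 1 = lowest; remainder islands
go to the lowest-index bins; ties broken by genomic position) for the
box-plot summary (median, quartiles by linear interpolation, whiskers at
quartile ± 1.5 IQR clipped to the data range).  The trend test is a
Spearman correlation **across CGIs**, not across the 10 bins — ten
points would have negligible power and the bins exist for display; a
permutation p-value (seeded, ≥10 000 permutations) is available for
small n, the default being the t-approximation with n − 2 degrees of
freedom.

## Synthetic data generator

What it emulates: a deeply sequenced human-like methylome whose
context-level structure is written by a small set of enzymes with known
flanking preferences, measured before and after acute depletion.

* Genome: i.i.d. bases at GC 0.41 (human-like); CpG islands are planted
  blocks (default 800–1000 bp) with explicit CpG dinucleotides inserted
  at 0.10 per bp, evenly spaced so islands never overlap.
* True methylation per strand-cytosine:
  m = logistic(α₀ + Σₑ δₑ·wₑ·zₑ(c) + ε), with zₑ the enzyme profile
  standardized over the 256 contexts, ε ~ N(0, σ²) i.i.d. per site.
  Defaults: α₀ = 1.39 (≈80 % genome-wide methylation, a typical
  colorectal-cancer-line level), σ = 0.5, weights DNMT1 = 1.0,
  DNMT3A = 0.8, DNMT3B = 0.1 so that at baseline the observed profile
  correlates strongly with the first two enzymes and not the third.
* Depletion: multiplicative residual-activity factors δₑ per timepoint.
  The enzyme-depletion arm sets δ_DNMT1 = 0; the cofactor-depletion arm
  sets all three to 0.05 — a degron removes the protein within hours, so
  by day 4 residual activity is small.  Because the zₑ are mean-zero, a
  uniform δ-rescaling redistributes methylation across contexts without
  changing the genome-wide mean; global methylation loss enters the
  synthetic data only through the island coupling below.
* Histone coupling: per island a latent h ~ LogNormal(0,1); ChIP reads
  ~ Poisson(depth·len/1kb·h), input ~ Poisson(depth·len/1kb); at coupled
  timepoints island sites are scaled m ← m·(1 − β·h̃) with h̃ min–max
  normalized.  β defaults to 0.4.
* Reads: coverage ~ Poisson(λ = 30 by default; zero-coverage sites
  omitted), n_meth ~ Binomial(coverage, m + (1−m)·f) where f is the
  bisulfite conversion-failure rate (default 0; failure inflates
  apparent methylation of unmethylated molecules only — over-conversion
  is not modelled).
* Determinism: all draws derive from one config seed through named
  CRC-keyed substreams, so identical configs give byte-identical files.

What it does **not** emulate: negative-binomial coverage dispersion,
sequencing error, hemimethylation dynamics, replication timing,
neighbouring-site correlation of methylation state, and real CGI
sequence composition.  Passing the planted-signal tests therefore shows
that the statistics recover the signals they are defined to measure
under their own sampling assumptions — not that those assumptions hold
on any particular real dataset.

## Calibration experiments and problem sizes

The validation suite (also re-run by `scripts/acceptance.py`) uses:

* Footprint recovery: one enzyme at weight 2.0, α₀ = 0, σ = 0, λ = 100,
  ~50 000 CpGs.  Weight 2 pushes the logit to ±~5, so logistic
  saturation alone caps the value-scale Pearson near 0.96–0.97; the
  ≥0.95 pass criterion reflects that analytic ceiling, and an
  independent random profile stays |r| < 0.2 (null sd at n = 256 is
  ≈ 0.063).
* Depletion monotonicity: weight 0.75 (inside the logistic's
  near-linear range, where uniform δ-scaling cannot *raise* r through
  reduced saturation), σ = 1.0, λ = 30, ~4 000 CpGs, so per-context
  noise is the limiting factor and r falls monotonically with δ; mean
  over 10 seeds across δ ∈ {1, 0.75, 0.5, 0.25, 0}.
* DMR null: two conditions sharing identical true levels (σ = 0) with
  independent read sampling, 500 tiles; planted DMRs use a constructed
  10-tile fixture with three 40-pp losses at 500 pooled reads per tile.
* CGI coupling: 500 islands of 800 bp at density 0.10 (~80 CpGs each),
  λ = 30, β = 0.4 vs β = 0, ChIP depth 50 reads/kb.

These sizes give each check comfortable statistical resolution while
keeping the full suite interactive.

## Known limitations

* The pooled Fisher test ignores replicate-level overdispersion (see
  above); a per-replicate binomial GLM would be the next refinement.
* Site-level logit noise is independent across sites and (by default)
  across timepoints; real methylomes have spatially correlated noise,
  which would widen the null of the tile test.
* The ChIP model has no fragment-length extension or peak structure;
  read counting is plain interval overlap.
* `pearson_values` depends on the value scale of the preference tables;
  when comparing profiles measured on different scales, prefer
  `pearson_ranks`.
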