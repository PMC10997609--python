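# methcontext

Analysis toolkit for whole-genome bisulfite sequencing (WGBS) methylomes
from protein-depletion (degron) experiments, centred on three questions:

1. **Which enzymes shaped this methylome?**  Every CpG sits in one of 256
   NNCGNN flanking contexts, and DNA methyltransferases (DNMT1, DNMT3A,
   DNMT3B) and TET oxidases have measurable in-vitro rate preferences over
   those contexts.  `methcontext` extracts contexts strand-awarely from a
   reference, averages observed per-cytosine methylation within each
   context, and computes the Pearson correlation *r* between the resulting
   256-vector and each enzyme's preference profile.  A high *r* means the
   enzyme's favourite sites are among the most methylated; a drop in *r*
   after depleting a factor means that factor sustained activity at those
   sites.
2. **Where is methylation lost?**  The genome is segmented into 1-kb
   tiles; replicate cytosine reports are pooled per condition and each
   tile is tested with a two-sided Fisher exact test on the pooled counts.
   Tiles with |Δmethylation| ≥ 25 percentage points and Benjamini–Hochberg
   *q* < 0.01 are called hypo-/hypermethylated regions (DMRs).
3. **Does histone context predict reliance on a maintenance cofactor?**
   CpG islands are scored by input-normalised ChIP signal (+0.5 offset,
   counts per 10 million, ≥4-read filter), ranked into deciles, and the
   per-CGI difference between two depletions' methylation losses
   (Δ<sub>cofactor</sub> − Δ<sub>enzyme</sub>) is tested against the
   histone score with a Spearman rank correlation.

Because the interesting statistical behaviour only shows under known
ground truth, the package ships a synthetic generator: per-site true
methylation follows a logit-linear mixture of standardized enzyme
preference profiles, `m = logistic(α₀ + Σₑ δₑ·wₑ·zₑ(context) + ε)`, with
Poisson coverage, binomial read sampling, CpG-island blocks, and an
optional coupling that demethylates islands in proportion to a latent
histone score.  Depletion is modelled by scaling enzyme weights with
residual-activity factors δₑ ∈ [0, 1].

Intended users: epigenomics analysts who have Bismark-style cytosine
reports and want the flanking-context / tile-DMR / CGI-decile analyses as
a reusable, tested library instead of one-off scripts.

## Worked example

The built-in demo simulates a 400-kb genome with 120 CpG islands, three
enzymes (weights DNMT1 = 1.0, DNMT3A = 0.8, DNMT3B = 0.1), and three
timepoints: `day0` (all active), `day4_enzyme` (maintenance enzyme fully
depleted, δ = 0) and `day4_cofactor` (all three activities reduced to
δ = 0.05, plus histone-coupled island demethylation at β = 0.4):

```
methcontext run --config examples/demo_config.yaml --out out/
```

`out/context_correlations.tsv` from this exact run:

```
    sample_id enzyme         method   n      r
         day0  DNMT1 pearson_values 256  0.727
         day0 DNMT3A pearson_values 256  0.523
         day0 DNMT3B pearson_values 256  0.092
  day4_enzyme  DNMT1 pearson_values 256 -0.131
  day4_enzyme DNMT3A pearson_values 256  0.961
  day4_enzyme DNMT3B pearson_values 256  0.122
day4_cofactor  DNMT1 pearson_values 256  0.525
day4_cofactor DNMT3A pearson_values 256  0.303
day4_cofactor DNMT3B pearson_values 256  0.127
```

Reading it: at day 0 the methylome correlates with the profiles of the
two enzymes that shaped it (DNMT1 r = 0.73, DNMT3A r = 0.52) but not with
the near-inactive DNMT3B (r = 0.09).  Depleting the maintenance enzyme
erases its own footprint (r → −0.13) while the de-novo enzyme's footprint
strengthens (r → 0.96) because it now dominates the mixture.  Depleting
the cofactor weakens every footprint at once (0.73 → 0.53, 0.52 → 0.30).

`out/cgi_bin_summary.tsv` shows the decile analysis: the median
cofactor-vs-enzyme methylation difference falls from ≈ 0 pp in the three
lowest histone-signal bins to −11.9 pp in the top bin — islands with high
histone signal rely disproportionately on the cofactor.  The Spearman
test across CGIs quantifies the trend (ρ = −0.72, p ≈ 6e−79 at seed 0).

The same analyses run on real files through the `context`, `dmr` and
`cgi` subcommands (`methcontext context --help` etc.), or in Python:

```python
from methcontext import ContextPreferenceModel, read_cytosine_report, read_fasta, read_preference_table

genome = read_fasta("hg38.fa")
samples = [read_cytosine_report(p, min_coverage=10) for p in report_paths]
enzymes = [read_preference_table(p) for p in preference_paths]
results = ContextPreferenceModel(samples, genome, enzymes).fit()
print(results.summary())
```

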