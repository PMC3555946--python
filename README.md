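# isletmir

Small RNA-seq miRNA profiling for pancreatic islet biology: fractional
read counting against a prioritized reference stack, median-of-ratios
normalization, tissue-specificity scoring with a permutation FDR, and
GWAS gene-set enrichment for predicted miRNA targets.

## What this is for

Profiling the miRNA complement of human islets and FACS-enriched beta-cells
from small RNA sequencing raises three linked questions that this package
answers as a tested, reproducible pipeline:

1. **Which miRNAs are expressed, and how much?** Reads are adaptor-clipped,
   filtered, and aligned against three consecutive references —
   contaminants, miRNA hairpins + other ncRNAs, genome — with class priority
   miRNA > ncRNA > genome. Hairpin hits are split into mature / star /
   hairpin-only using the annotated sub-intervals padded by 3 nt. A read
   mapping ambiguously to *k* features adds 1/k to each, and features under
   100 total reads are background. Libraries are made comparable via
   inflation factors `i_l = median_g(n_gl / GM_g)` (median-of-ratios), with
   expression reported as `n_gl / i_l` or `log2(n_gl / i_l)`.
2. **Which miRNAs are tissue-specific?** Against a multi-tissue panel,
   near-duplicate profiles (islet and beta-cell) are merged by
   single-linkage clustering of correlation-matrix rows at Euclidean
   distance 0.25, and each miRNA gets a specificity score
   `s(m,t) = x(m,t) / Σ_t' x(m,t')` — the fraction of its reads
   attributable to profile *t* — with `s > 0.5` defining specificity and a
   permutation FDR for calls in a reference profile.
3. **Do predicted targets of these miRNAs carry disease association?**
   Lead GWAS variants are expanded by LD (haplotype `r² > 0.8`) and
   intersected with precursor and target-site intervals; per-miRNA
   target-gene sets are tested by counting genes above the 75th percentile
   of confounder-adjusted association scores against random same-size gene
   draws (permutation p with +1 correction), with Storey robust q-values
   and significance at `p < 0.01` and `q < 0.1`.

Because the original sequencing data and external databases are not
redistributable, a synthetic-data module (`isletmir.simulate`) generates
every input — read libraries, the tissue panel, GWAS summary statistics
with LD structure — with planted ground truth, so the whole chain is
testable end to end. See `docs/methods.md` for models, parameter defaults
and limitations.

## Worked example

```python
import isletmir as im

sim = im.simulate_tissue_panel(im.SimulationConfig(seed=4))
factors = im.inflation_factors(sim.counts)
panel = im.filter_min_expression(
    im.average_by_tissue(im.normalized_linear(sim.counts, factors),
                         sim.library_tissues))
profiles = im.merge_similar_profiles(im.profile_correlation(panel), panel)
scores = im.specificity_scores(profiles)
calls = im.call_specific(scores)
print(len(panel), sorted(profiles.provenance), len(calls))
```

prints

```
47 ['adipose', 'beta_cell+islet', 'brain', 'kidney', 'liver', 'muscle', 'spleen'] 25
```

— 47 of 150 simulated miRNAs pass the ≥1000 normalized-read filter, the
islet and beta-cell profiles (generated as near-duplicates) merge into one
while the six other tissues stay separate, and 25 miRNAs are called
tissue-specific, including all 12 planted ones in their designated tissues
(`examples/tissue_specificity.py` shows the full run, including the
permutation FDR report). The other scripts in `examples/` each demonstrate
one capability — read simulation + preprocessing, quantification,
normalization, LD/overlap, and target-set enrichment — and print a short
interpretation of their output.

The sorted-versus-bulk arithmetic is also exposed directly: a miRNA at 42% of
beta-cell reads and 27% of islet reads is `im.fold_enrichment(0.42, 0.27)`
≈ 1.56-fold enriched, against the bound
`im.expected_enrichment(0.9, 0.5) = 1.8` expected for a transcript confined
to beta-cells (90% sort purity, ~50% beta-cell share of the islet) — the
signature of predominantly beta-cell expression.

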