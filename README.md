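# aflpzone

Genome-scan and linkage-disequilibrium analysis of dominant (AFLP)
markers in hybrid zones.

## The problem

Chromosomal rearrangements can suppress recombination in heterozygotes,
and recombination-suppression models of speciation predict that loci
differentiating two hybridising taxa should cluster in such
low-recombination regions.  With anonymous dominant markers (AFLP band
presence/absence) and no genome, the signature is statistical: in admixed
individuals, migration alone creates gametic disequilibrium D between any
two differentiated loci in proportion to the product of their parental
allele-frequency differences, (p−q)(r−s), while loci sharing a
low-recombination region show *more* LD than that product predicts.

`aflpzone` implements the full workflow for testing this on
presence/absence data from a two-race contact zone:

* allele-frequency estimation under HWE for dominant loci — √(k/n),
  Lynch–Milligan bias-corrected, and a Bayesian estimator with a
  non-uniform Beta prior fitted across loci (`dominant_freq`);
* population structure: band-sharing / Euclidean / Jaccard distances,
  classical MDS, Hudson-style multi-locus F_ST with permutation tests, and
  a 4-level AMOVA (races / populations / sites / within sites) with
  level-appropriate permutation p-values (`structure_stats`);
* a maximum-likelihood hybrid index Q with the "<98% from the nominal
  parental population" hybrid designation rule (`structure_stats`);
* a Bayesian F_ST-outlier scan for dominant markers: reversible-jump MCMC
  over a multinomial-Dirichlet model with logit(F_ST,ij) = α_i + β_j,
  log₁₀ posterior odds (log PO > 1 = strong evidence) and q-value FDR
  control (`outlier_scan`);
* EM maximum-likelihood haplotype frequencies and D for pairs of dominant
  loci (|D| ≤ 0.25), and the outlier-vs-neutral LD contrast controlled by
  (p−q)(r−s) with one-tailed Welch t-tests per product tail
  (`ld_analysis`);
* a synthetic-data generator producing Balding–Nichols-differentiated
  parental populations, admixed hybrids with ancestry-mosaic haplotypes,
  and an optional zero-recombination block carrying the outlier loci,
  with full ground truth (`synthetic_data`).

See `docs/methods.md` for the models, priors and numerical choices.

## Worked example

Simulate a study-shaped dataset (two parental populations at F_ST 0.38,
seven fixed-difference outliers inside a zero-recombination block, 51
hybrids), then run the LD contrast:

```python
from aflpzone import (SimConfig, simulate_study, allele_freq_table,
                      outlier_vs_neutral_contrast, pairwise_fst)

cfg = SimConfig(seed=0)  # outliers_in_block=True by default
dataset, hierarchy, truth = simulate_study(cfg)
hybrids = hierarchy.individuals_in("hybrid")

freqs = allele_freq_table(dataset, hierarchy, method="bayes", exclude=hybrids)
freqs = freqs[freqs.population.isin(["pop1", "pop2"])]

fst = pairwise_fst(freqs, dataset, hierarchy, "pop1", "pop2")
print(f"parental F_ST = {fst.fst:.3f}")

outliers = {l for l, f in zip(truth.locus_ids, truth.outlier_flag) if f}
result, _, _ = outlier_vs_neutral_contrast(
    dataset, hybrids, freqs, "pop1", "pop2", outliers, cutoff=0.75)
for tail in (result.positive, result.negative):
    print(f"{tail.tail} tail: mean outlier D = {tail.mean_outlier:.3f}, "
          f"mean neutral D = {tail.mean_neutral:.3f}, "
          f"t = {tail.t:.2f}, df = {tail.df:.1f}, p = {tail.p:.2g}")
```

Output:

```
parental F_ST = 0.378
positive tail: mean outlier D = 0.248, mean neutral D = 0.067, t = 39.63, df = 108.2, p = 1.6e-66
negative tail: mean outlier D = 0.215, mean neutral D = 0.118, t = 14.98, df = 106.0, p = 3.2e-28
```

Block-bound outlier pairs sit at the admixture maximum (D ≈ 0.25: pure
parental two-locus haplotypes), far above the neutral pairs with a
comparable allele-frequency-difference product (D ≈ 0.07–0.12, the level
migration alone sustains) — the recombination-suppression signature on
both product tails.  Re-running with `outliers_in_block=False` (same
allele-frequency architecture, outliers scattered over the map) makes
both tests non-significant in most replicates.

The same stages are available from the shell:

```bash
aflpzone simulate --out zone/ --seed 0
aflpzone outliers --genotypes zone/genotypes.tsv --popmap zone/population_map.tsv \
    --pop-a pop1 --pop-b pop2 --out scan.tsv
aflpzone ld-compare --genotypes zone/genotypes.tsv --popmap zone/population_map.tsv \
    --pop1 pop1 --pop2 pop2 --hybrid-pop hybrid --outliers-from scan.tsv --out ld.tsv
```

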