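# subsetnet

Comparing how two related cell subsets respond to the same stimulus is a
recurring problem in systems immunology: the subsets share their core
signalling machinery, yet mount partially distinct transcriptional
programs. When each subset × condition cell pool is profiled only once —
the common situation for sorted primary cells — standard replicate-based
statistics do not apply. `subsetnet` implements the full analysis chain
for this design as a tested Python package:

1. **Counting** against chimeric gene models (per-gene union of
   protein-coding exons), with a 50%-exon expression filter and
   intersection-nonempty read assignment (multi-mapped and gene-ambiguous
   reads discarded).
2. **Single-replicate differential expression**: median-of-ratios size
   factors s_j = median_g k_gj/(Π_v k_gv)^{1/m}; a "blind" mean–variance
   trend v(μ) = μ + (a0 + a1 μ)μ pooled over all samples with "fit-only"
   sharing; and an exact conditional NB test that sums P(a)P(b) over all
   splits of the observed total with probability ≤ the observed pair's.
3. **Over-representation analysis** with length-bias correction: a
   monotone P(DE | length) weighting and the Wallenius noncentral
   hypergeometric tail, odds ratio = odds(DE in term)/odds(non-DE in
   term), a ≥10-observed-genes filter and BH adjustment; plus the
   hypergeometric gene-list overlap test.
4. **Network analyses**: cleaning of interaction tables (duplicates,
   self-loops, promiscuous ubiquitin), first-order expansion of a curated
   core-molecule seed list, partitioning of DE first-order interactors
   ("pathway modulators") into subset-specific Venn classes; and an
   unbiased active-subnetwork search — z_i = Φ⁻¹(1 − p_i), set score
   z_A = Σz_i/√k calibrated against random node sets, simulated annealing
   with connected-component extraction — followed by hub classification
   (≥5 interactions hub, ≥15 highly interconnected) and concordance
   between the two analyses.
5. **Synthetic data generators** with planted ground truth for every
   stage, so the whole chain is testable without downloads.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic design (5000 genes, 48 core molecules, two subsets ×
steady/stimulated, 150 planted responders per subset of which 30 are
core-attached modulators):

```bash
python analysis/01_simulate.py
python analysis/03_differential_expression.py
python analysis/05_filtered_network.py
python analysis/07_hubs_concordance.py   # needs 06 first
```

Step 03 prints:

```
size factors: {'A_steady': 0.917, 'A_stim': 0.989, 'B_steady': 1.078, 'B_stim': 1.028}
variance trend: v(mu) = mu + (0.0000 + 0.0387*mu)*mu
subset A: 140 DE genes at BH p<=0.05 (sensitivity 0.93, FDR 0.000 vs truth)
subset B: 143 DE genes at BH p<=0.05 (sensitivity 0.95, FDR 0.000 vs truth)
receptor proxy CORE01 steady-state CPM: subset A 78, subset B 79 (detectable in both)
```

— the caller recovers 93–95% of the planted fold-change-4 responders with
no false discoveries, and the first core molecule (a stand-in for the
stimulus receptor) is detectably expressed in both subsets. Step 05 then
reports the pathway-modulator screen (111 and 113 modulators, ~42%
subset-specific), step 06 the annealed subnetworks, and step 07 the hub
tables and the concordance between the filtered and unbiased analyses
(87/111 = 78% for subset A, 99/113 = 88% for subset B on this seed).

The same stages are scriptable via the `subsetnet` CLI
(`simulate | count | de | ora | overlap | network | activemod | hubs |
run-all`), e.g. `subsetnet run-all --out bundle/ --seed 7`.

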