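# agosort

Positional sorting-signal analysis of miRNA–Argonaute association in
*Arabidopsis thaliana*-style small-RNA co-immunoprecipitation data.

## The problem

Plant genomes encode many Argonaute (AGO) paralogs, and each mature miRNA
is loaded into a specific AGO — the *sorting* decision that fixes the
miRNA's downstream mode of action. The classical view is that the
5′-terminal nucleotide alone determines sorting (5′-U → AGO1, 5′-A → AGO2,
5′-C → AGO5), but four bases cannot address ten AGOs. This package
implements a complete, reusable pipeline for asking whether positions
*beyond* the 5′ terminus carry sorting information:

1. **Confidence set** — from per-AGO co-IP read libraries (FASTQ or count
   tables), reads are adapter-trimmed to ≤30 nt, matched to mature miRNAs
   by exact substring, normalized to reads per million (RPM = count /
   library total × 10⁶), and each miRNA labeled with an AGO when one
   library holds > 70% of its signal at ≥ 10 RPM total. Sequences are
   deduplicated and 5′-anchored (trimmed to 21 nt).
2. **Univariate statistics** — per-position mutual information between the
   AGO label vector and each sequence column,

   MI(AGO; Seqᵢ) = Σ_{ago,base} P(ago, base) · log₂ [ P(ago, base) /
   (P(ago) P(base)) ],

   with empirical p-values from per-position label shuffling,
   Benjamini–Hochberg FDR over the 21 positions, 5′-base enrichment ratios
   against the background of all annotated miRNAs, and sequence-logo
   information content R_i = 2 − H_i.
3. **Duplex structure** — the miRNA:miRNA\* pairing pattern (Watson–Crick /
   G:U wobble / unpaired) from a deterministic duplex alignment after
   removing the 2-nt 3′ overhangs; a precursor quality filter (> 6
   mismatches or a bulge > 3 nt fails); per-class pairing-frequency
   profiles over positions 1–19.
4. **Higher-order signals** — a from-scratch class-balanced random forest
   over categorical position features (balanced bootstrap of 20 draws per
   class, exhaustive binary category-subset splits minimizing Gini, trees
   grown to purity), evaluated by out-of-bag (OOB) accuracy, per-sample
   margins (vote fraction for the true class minus the best alternative),
   permutation variable importance (mean decrease in OOB accuracy), and a
   repeated-run protocol reporting the median two-sided Wilcoxon rank-sum
   p-value between margin vectors of two feature conditions.
5. **Targets** — expected random overlap n₁n₂/N between AGO target sets
   and Fisher-exact GO-slim enrichment with BH-FDR.

A first-class synthetic-data generator plants known sorting signals —
per-position class-conditional base distributions, conditional
two-position rules (e.g. "5′-C with G/U at position 9 → AGO1, else
AGO5"), hairpins with controlled wobbles/mismatches/bulges, and
Dirichlet-multinomial read preferences — so every stage is testable
without external data.

## Worked example

```python
from agosort import RunConfig, run_pipeline

cfg = RunConfig(n_trees=50, n_runs=3, n_perm=100, seed=42)
out = run_pipeline(cfg, "demo_run")
print(out["confidence_set"].class_counts)
print(out["results"]["rf_report"][["condition", "oob_accuracy"]])
```

prints (seed 42):

```
{'AGO1': 39, 'AGO2': 23, 'AGO4': 8, 'AGO5': 19}
          condition  oob_accuracy
0  A_class_shuffled      0.320988
1    B_seq_no_first      0.283951
2      C_first_only      0.753086
3         D_seq_all      0.654321
4         E_pairing      0.246914
```

Reading: of 126 simulated miRNAs, 89 pass the 10-RPM/70% preference rules
and the precursor filter; a forest seeing only the (planted) 5′ base sorts
three classes at 75% OOB accuracy, while class-shuffled labels and the
pairing pattern (no planted structure signal) sit at the ~1/3 chance
level. `demo_run/` then contains one TSV per stage (confidence set, MI
profiles with permutation nulls, composition, logo matrices, duplex
patterns, pairing profile, forest report, importance, comparisons) plus a
JSON manifest with the config and seed.

The same stages are available as a CLI: `agosort simulate | count |
confidence | duplex | mi | logo | rf | compare | enrich | run-all`.

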