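# oxymet

Did oxygen drive the expansion and chemical diversification of metabolic
networks — or do phylogenetic signal and species-sampling bias explain most
of the apparent effect?  `oxymet` packages the statistical machinery needed
to ask that question properly:

* **Network expansion.** For each species the *increase rate* is the ratio
  of classified enzymes (or metabolites) in its network to the *anoxic*
  subset — the metabolic space available without oxygen.  Aerobes and
  anaerobes are compared twice: with a naive two-group linear model /
  Wilcoxon–Mann–Whitney (WMW) test, and with **brunch-style phylogenetically
  independent contrasts** for a binary predictor, which use each tip at most
  once and test the standardized contrasts against zero
  (*t* = mean/(sd/√k), df = k−1).
* **Chemical diversity.** For every species and chemical descriptor
  (AlogP98, SOL, FNSA, FPSA, pLC50, RotBonds, …) the oxic and anoxic
  metabolites of its network are compared by a one-tailed WMW test, with
  effect size

      ES = z / √(N_oxic + N_anoxic),   z = Φ⁻¹(1 − p_one-tailed),

  so ES > 0 when oxic metabolites have the larger descriptor median.  The
  **evaluation value**

      EV = |ES_int − M_ES| / |Q_c − M_ES|

  compares the pooled ("integral") network's effect size against the median
  (M_ES) and the 2.5%/97.5% quantile (Q_c, chosen on the side of ES_int) of
  the per-species effect sizes; EV > 1 means the pooled network over- or
  underestimates the chemical difference relative to the central 95% of
  individual networks.
* **Annotation completeness.** The fraction of functionally-unknown proteins
  per genome (keyword matching) compared across oxygen classes with a
  Kruskal–Wallis test — a control that annotation quality does not confound
  the network metrics.
* **Synthetic studies.** A generator producing complete input bundles
  (clade-structured Yule phylogeny, Markov-evolved oxygen requirement,
  oxic/anoxic reaction universe, per-species networks, descriptor tables,
  annotations) with configurable effect sizes, so every stage can be
  exercised and calibrated offline.  A shift confined to
  "higher-organism-specific" compounds retained preferentially by
  multicellular species reproduces, by construction, the integral-network
  overestimation phenomenon.

## Worked example

Generate a synthetic study (with the multicellular-specific shift switched
on) and run every stage:

```sh
cat > demo.yaml <<'YAML'
seed: 42
study_dir: demo/study
out_dir: demo/out
simulate:
  n_bacteria: 80
  n_archaea: 8
  n_unicellular_eukaryotes: 28
  n_multicellular_eukaryotes: 28
  n_global_reactions: 1000
  n_global_compounds: 1400
  delta_specific: 2.0
YAML
oxymet run-all --config demo.yaml
```

`demo/out/models.json` (enzyme basis) then contains:

```
without_phylogeny: median aerobes 1.947, median anaerobes 1.393 (n = 129/15),
                   WMW p = 2.5e-10, lm estimate 0.585 ± 0.036, t = 16.4
with_phylogeny:    k = 7 contrasts, estimate 0.397 ± 0.038, t = 10.4, p = 4.7e-5
```

i.e. aerobe networks are about twice their anoxic core while anaerobe
networks are ~1.4×, and here the difference survives phylogenetic control
because the generator really does give aerobes a higher oxic-reaction
retention rate.  `demo/out/diversity.tsv` shows the sampling-bias
phenomenon for AlogP98 (hydrophobicity):

```
descriptor  group                    es_int    m_es      ev        verdict
AlogP98     aerobic_bacteria         0.340171  0.239855  1.92088   over_or_under_estimated
AlogP98     unicellular_eukaryotes   0.340171  0.222269  1.91237   over_or_under_estimated
AlogP98     multicellular_eukaryotes 0.340171  0.356392  0.62642   consistent
```

The integral network's effect size (0.34) overstates the difference seen in
individual unicellular networks (medians ≈ 0.22–0.24, EV ≈ 1.9 > 1) but is
consistent with multicellular networks (EV 0.63) — the compounds driving the
pooled signal live mostly in multicellular species.  Finally
`demo/out/unknown_test.json` reports Kruskal–Wallis H = 3.16, p = 0.21 for
unknown-protein fractions across the three oxygen classes: no evidence of
differential annotation quality.

Every stage is also available separately
(`oxymet simulate|expansion|phylo|diversity|unknown`), and from Python via
`oxymet.pipeline` / the functions re-exported from `oxymet`.

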