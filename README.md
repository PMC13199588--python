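# hfrpam

Expert-panel human-factors risk probability assessment. Given a panel of
integer Likert ratings (experts × 8 factors arranged in a two-stage
hierarchy: a core stage X1 with children X2–X4 and an external stage X5 with
children X6–X8), the pipeline runs five stages:

1. **QC** — Cronbach's alpha, content validity indices (I-CVI / S-CVI),
   optional test–retest ICC(2,1), and per-factor descriptive moments.
2. **Risk level** — ratings are mapped to correlation levels (low ≤2,
   medium =3, high ≥4), tallied, and combined into counting-based
   prior/likelihood/posterior records per factor and level, banded
   low (p ≤ 0.4) / medium (0.4 < p < 0.8) / high (p ≥ 0.8).
3. **Risk weight** — entropy-reduction weights: column shares → Shannon
   entropy with coefficient 1/ln(n) → difference coefficients g = 1 − E →
   weights w = g / Σg.
4. **Sensitivity** — pairwise mutual information (nats, plug-in estimate)
   over all factor pairs; the sensitivity value of a factor is the mean of
   its MI with the two stage-level factors (self-MI counted as 0).
5. **Optimization** — index OI = SV + weight, ranked into an activity
   sequence; consecutive rank pairs form four directed paths labeled by
   stage membership (core = subjective, external = objective).

A Gaussian-copula simulator generates synthetic panels with target ordinal
marginals (means/SDs) and a configurable latent correlation, so the whole
pipeline is testable without survey data. The published MI matrix and
weight table ship as plain-text replay inputs under `src/hfrpam/data/`.

## CLI

```bash
# simulate a 62-expert panel
hfrpam simulate --n 62 --seed 1 --out panel.csv

# run all five stages; writes report.json + CSV tables
hfrpam run --panel panel.csv --out report/

# rebuild the optimization table from weight + MI tables
# (defaults to the bundled reference tables)
hfrpam replay --weights report/weights.csv --mi report/mi_matrix.csv --out table.csv
hfrpam replay
```

`hfrpam run` accepts `--config cfg.yaml` to override anchors, band edges,
counting denominators, entropy normalization mode, and MI discretization;
all defaults follow the published procedure.

## Notes on interpretation choices

- The sensitivity aggregation rule (mean MI with the two stage factors,
  self-MI = 0) is an interpretation of an ambiguous published sentence; it
  is the unique simple rule that reproduces every published sensitivity
  value from the published MI matrix.
- The counting denominators in the risk-level stage are ambiguous in the
  source; defaults are stage-group cells for priors and pooled secondary
  cells for likelihoods, with `stage`/`secondary`/`all`/`column` all
  configurable.
- The published band edges leave [0.80, 0.81) unlabeled; it is assigned to
  the high band so the bands partition [0, 1].
- Report SV/OI values are rounded half away from zero at 4 decimals to
  match the published table convention.
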