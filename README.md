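# medconn

Does adherence to a Mediterranean-style diet (MeDi) change how longitudinal
shifts in resting-state functional connectivity (rsFC) relate to cognitive
decline? `medconn` implements the full analysis pipeline behind that
question as a tested, reusable Python package for biostatisticians and
cognitive-neuroscience researchers:

1. **MeDi scoring** — eleven food-frequency components scored 0–5 each
   (reverse-scored for poultry, red meat, and full-fat dairy; a unimodal
   rule for alcohol), summing to a 0–55 adherence index split into
   low/moderate/high tertile groups.
2. **Network connectivity summarization** — per subject-visit, a 264×264
   ROI Pearson correlation matrix is Fisher z-transformed
   (z = arctanh r); the diagonal, ROI pairs closer than 20 mm, and
   negative correlations are excluded; valid pairs are averaged into 10
   within-network values, 45 between-network block values, and overall
   within/between means across ten canonical resting-state networks.
3. **Cognitive composites** — four reference abilities (fluid reasoning,
   memory, speed, vocabulary), each the mean of up to six cohort-z-scored
   tasks with timed tasks sign-flipped; change = follow-up − baseline.
4. **Moderation models** — covariate-adjusted OLS of cognitive change on
   Δconnectivity × MeDi group with Wald confidence intervals, joint
   interaction Wald chi-square tests (b′V⁻¹b, df = number of interaction
   terms), MeDi-stratified slopes, age-tertile-stratified tests, a
   continuous-MeDi sensitivity model, and descriptive group comparisons
   (ANOVA / Pearson chi-square).

Because cohort data of this kind are not publicly deposited, the package
ships a first-class **synthetic-data generator**: block-covariance
multivariate-normal ROI time series with per-subject connectivity drift
across two visits, an FFQ table spanning the adherence scale, a cognitive
task battery with a *planted* MeDi-group-specific slope of memory change on
Δconnectivity, and a follow-up/missingness roster reproducing a fixed
exclusion cascade (562 enrolled → 254 returned → 174 with diet and
two-visit rsFC → 124 analytic). Every downstream stage is validated by
parameter-recovery and calibration experiments against these planted
truths.

## Worked example

Recover the planted group-specific slopes (low −4.397, moderate −0.751,
high +3.287 memory-change points per z-unit of Δ between-network
connectivity) from 200 simulated cohorts of 500 subjects:

```python
from medconn.config import SimulationConfig
from medconn import models

cfg = SimulationConfig(n_subjects=500, seed=0)
report = models.recovery_experiment(cfg, n_replicates=200)
print(report.per_group.to_string(index=False))
print("sign flip recovered:", report.sign_flip_rate)
print("interaction rejection rate:", report.interaction_rejection_rate)
```

prints

```
   group  planted  mean_est      bias     rmse  coverage  sign_rate
     low   -4.397 -4.362829  0.034171 0.672094     0.970      1.000
moderate   -0.751 -0.802747 -0.051747 0.636147     0.960      0.875
    high    3.287  3.302660  0.015660 0.664929     0.965      1.000
sign flip recovered: 1.0
interaction rejection rate: 1.0
```

Each row is one MeDi group: the mean stratified-slope estimate across
replicates sits on the planted value (bias well under one tenth of the
replicate-to-replicate RMSE), the nominal 95% Wald confidence intervals
cover the planted slope 96–97% of the time, and every replicate recovers
the qualitative moderation signature — a negative slope in the
low-adherence group flipping to positive in the high-adherence group — with
the joint interaction Wald test rejecting in all 200 replicates.

The same machinery is available from the shell:

```bash
medconn run --seed 1 --out run1          # simulate → score → summarize → fit
medconn recover --seed 0 --out rec.json  # the experiment above
cat run1/report.md                        # four-section human-readable summary
```

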