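# camshield

Analysis tools for camera-trap studies of how human activity reshapes
predator–prey interactions — the "human shield" question: do ungulate prey
reduce predation risk by concentrating where (and when) people are active,
while large predators avoid them?

The package takes timestamped camera-trap detection records from a gridded
survey (one station per 1-km² cell, daily occasions) and runs three
complementary analyses:

1. **Co-occurrence occupancy modelling.** Latent presence of S detection
   units (prey guild, predator guild, humans) at a site is a binary vector
   z ∈ {0,1}^S with a multinomial-logit log-linear distribution,
   P(z) ∝ exp(Σₛ fₛ zₛ + Σ_{j<k} f_jk z_j z_k), where first-order natural
   parameters fₛ govern single units and second-order f_jk govern pairwise
   co-occurrence. Conditional on z, detections are occasion-wise Bernoulli
   with per-guild detection probability pₛ, so imperfect detection is
   integrated out of the likelihood. Models with and without interaction
   terms are fit by maximum likelihood and compared by AIC; marginal,
   pairwise and conditional occupancy probabilities (e.g. ψ_prey | humans
   present) are derived from the fitted state distribution with
   delta-method or parametric-bootstrap intervals.
2. **Diel activity overlap.** Detection clock times are angles on the 24-h
   circle; each species' activity density is a von Mises kernel estimate
   with a data-driven concentration, and pairwise overlap is the
   coefficient of overlapping Δ = ∫ min(f, g), estimated by Δ̂₁, Δ̂₄ or Δ̂₅
   depending on sample size, with seeded smoothed-bootstrap confidence
   intervals and a low / moderate / high classification.
3. **Spatiotemporal overlap.** Independent detections are aggregated into
   grid × hour-of-day matrices per guild; exclusive, pairwise (Jaccard) and
   triple overlap of the active (grid, hour) cells quantify simultaneous
   use of the same place at the same time of day, with grid-level bootstrap
   intervals and Venn region counts.

A seeded synthetic-survey generator with known occupancy structure,
encounter rates and diel mixtures ties everything together: it is the
ground truth for the test suite and the default input of the pipeline.

## Worked example

```python
import camshield as cs

cfg = cs.paper_like_preset(seed=1)          # 88 grids x 20 days
records, design, truth = cs.simulate_survey(cfg)
filtered = cs.filter_independent(records)   # 15-min independence rule
gm = cfg.guild_map()

hists = {g: cs.build_detection_history(filtered, design, gm, g) for g in gm.guilds}
fit = cs.fit_msom(hists, cs.MSOMSpec(gm.guilds, interaction_order=2), seed=1)
print(cs.conditional_occupancy(fit, "prey", "human", present=True))
print(cs.conditional_occupancy(fit, "prey", "human", present=False))
```

```
Estimate(value=0.9000024454346484, se=np.float64(0.047433727496472435), ci_low=np.float64(0.8070340478890752), ci_high=np.float64(0.9929708429802215))
Estimate(value=0.6666658271155278, se=np.float64(0.06804138962878951), ci_low=np.float64(0.5333071539850431), ci_high=np.float64(0.8000245002460125))
```

Prey occupancy conditional on human presence (0.90) clearly exceeds
occupancy where humans are absent (0.67): under the generator's positive
human–prey interaction the model recovers the human-shield signature.
Activity overlap for the same run:

```python
from camshield.activity import records_to_sample
human = records_to_sample(filtered, "human")
tiger = records_to_sample(filtered, "tiger")
print(cs.overlap_delta(human, tiger, "Dhat1"))   # 0.2321... -> "low" overlap
```

The command-line interface wraps the same stages
(`camshield simulate | filter | occupancy | activity | stoverlap | report`),
driven by a YAML configuration; `camshield report` writes effort,
occupancy, activity and spatiotemporal tables plus a run manifest.

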