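# ncrpipe

Functional near-infrared spectroscopy (fNIRS) measures cortical
hemodynamics through the scalp, but its clinical use in neuropsychiatry
has been held back by poor sensitivity and specificity: the recorded
[HbO] signals are dominated by systemic physiological background that is
common to every channel. `ncrpipe` implements a connectivity pipeline
that removes this confound statistically and condenses a multichannel
Stroop-task recording into a single biomarker, the **neurocognitive
ratio (NCR)**, which separates healthy controls from patients with
migraine, OCD, or schizophrenia.

The pipeline, stage by stage:

1. **Preprocessing.** A 16-channel forehead recording at 1.77 Hz is cut
   into its task blocks; for each Stroop stimulus type (neutral N,
   congruent C, incongruent I) the blocks are concatenated in temporal
   order. A systemic regressor is built by high-pass filtering every
   channel (8th-order Butterworth, zero-phase) and averaging across
   channels.
2. **Connectivity.** For every channel pair (i, j) the stimulus-wise
   functional connectivity matrix holds the first-order partial
   correlation controlling for the regressor k:
   `r_ij|k = (r_ij − r_ik r_jk) / sqrt((1 − r_ik²)(1 − r_jk²))`.
3. **CM/DM separation.** Each FC matrix is eigendecomposed
   (`FC = Σ_k λ_k v_k v_kᵀ`) and split additively into a cognitive-mode
   part `FC_CM` (a selected component subset) and a default-mode part
   `FC_DM` (the complement). The subset and the binarization budget
   Θ_CM are chosen per subject group by a combinatorial search that
   minimizes the across-stimulus ANOVA p-value of GE_CM — the cognitive
   network should respond to task demand — while Θ_DM maximizes the
   analogous p-value for GE_DM.
4. **Graph metrics.** Matrices are binarized by keeping the ⌊Θ/2⌋
   strongest absolute off-diagonal pairs (Θ counts directed entries, so
   Θ = 24..48 keeps the top 10–20% of a 16-channel matrix) and scored
   with global efficiency `GE = 1/(N(N−1)) Σ_{i≠j} 1/d_ij`, the average
   inverse shortest-path length (unreachable pairs contribute zero).
5. **Biomarker.** Per stimulus type, the cognitive quotient is
   `CQ = ACC/RT` (accuracy % over reaction time in s), the network ratio
   is `R = GE_CM/GE_DM`, and `NCR = CQ × R`; the across-stimulus mean
   NCR̄ is the classification score, evaluated with ANOVA and ROC
   analyses (Youden-optimal operating point, rank-statistic AUC).

No recordings are distributable, so the package ships a seeded synthetic
cohort generator (`ncrpipe.synthetic`) that emulates the study design:
shared low-frequency systemic background, double-gamma hemodynamic
responses to the block design, a demand-scaled task network whose
coherence is set by a group-level coupling strength, and behavioral
distributions matching the published group tables. Every stage of the
pipeline is tested against this generator and against independent
numerical oracles.

## Worked example

```python
from ncrpipe import RunConfig, run_pipeline

result = run_pipeline(RunConfig(seed=1))   # simulate the 4-group cohort
df = result.results_frame()
print(df.groupby("group")[["ge_cm", "ge_dm", "cq", "ncr"]].mean().round(2))
rep = result.roc["NCR_bar"]
print(f"NCR-bar ROC: SENS={rep.sensitivity:.1f} SPEC={rep.specificity:.1f} "
      f"ACCUR={rep.accuracy:.1f} AUC={rep.auc:.1f}")
```

prints

```
          ge_cm  ge_dm     cq    ncr
group
control    0.25   0.40  94.68  59.29
migraine   0.23   0.39  82.46  49.38
ocd        0.22   0.39  60.31  33.84
schizo     0.21   0.39  45.09  24.03
NCR-bar ROC: SENS=100.0 SPEC=77.6 ACCUR=81.2 AUC=91.3
```

Reading the output: the simulated healthy controls recover the highest
cognitive-mode global efficiency (0.25) and the patient groups decline
with their planted coupling deficits; combined with the behavioral
gradient in CQ this yields a monotone NCR ordering
(controls ≫ migraine > OCD > schizophrenia), and NCR̄ separates controls
from the pooled patients with AUC ≈ 91% at a Youden-optimal operating
point with 100% sensitivity.

The same run is available from the shell, stage by stage or end-to-end:

```bash
ncrpipe simulate --out data --seed 1
ncrpipe fc --scan data/control_001_scan.csv --schedule data/control_001_schedule.tsv \
           --out-dir fcs --subject-id control_001
ncrpipe efficiency --fc fcs/control_001__N.csv --theta 43
ncrpipe run-all --out results --seed 1
```

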