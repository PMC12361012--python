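# impactlevels

Tools for turning a graded-response-model (GRM) item bank into an
impact-level classification system for patient-reported outcome scores:

1. **irt** — GRM category probabilities, most-likely-response maps, and EAP
   pattern scoring on the T metric (T = 50 + 10·θ).
2. **vignettes** — assemble content-balanced score vignettes (each item at
   its most likely response for a target T-score) and calibrate them by
   scoring the assembled pattern.
3. **bookmarks** — convert panelists' bookmark placements between ordered
   vignettes into individual thresholds (rounded mean of the two adjacent
   calibrated scores) and aggregate them into modal group thresholds.
4. **classify** — classify T-scores against a threshold set (ties go to the
   higher level), and independently classify 6-item GCPS-R records
   (two frequency items + three 0–10 PEG items; both-items-frequent → high
   impact, PEG ≥ 12 → bothersome).
5. **stats** — ordinal cross-tabulation, tie-corrected (midrank) Spearman
   correlation computed directly from contingency counts, and one-way ANOVA
   with Bonferroni post-hoc comparisons reconstructed from per-group
   (n, mean, SD) summaries.
6. **simulate** — seed-deterministic generators for item banks, respondent
   response matrices, clinic-like samples, panel placements, and GCPS-R
   records, so the whole pipeline runs end-to-end without external data.

## CLI

```bash
# generate a complete synthetic data set
impactlevels simulate --seed 1 --out-dir data/

# build and calibrate 8 vignettes, 5 T apart
impactlevels build-vignettes --bank data/bank.json --n 8 --t-min 45 --t-max 80 \
    --items-per-vignette 6 --out vignettes.json

# EAP-score a response matrix
impactlevels score --bank data/bank.json --responses data/responses.csv --out scores.csv

# modal thresholds from panel bookmark placements
impactlevels derive-thresholds --vignettes vignettes.json --placements data/panel.csv \
    --panel PLwCP --out thresholds.json

# classify scores / GCPS-R records
impactlevels classify --scores scores.csv --thresholds thresholds.json --out levels.csv
impactlevels gcpsr --responses data/gcpsr.csv --gate chronic_pain --out gcpsr_levels.csv

# statistics from packaged printed-table fixtures (or any CSV in the same shape)
impactlevels concordance --table src/impactlevels/data/table2_counts.csv
impactlevels anova --summaries src/impactlevels/data/table3_summaries.csv --posthoc bonferroni

# everything end-to-end from one YAML config, with a reproducible run manifest
impactlevels run --config demo.yaml --out-dir pipeline_out/
```

A pipeline config looks like:

```yaml
seed: 1
simulate:
  n_respondents: 2000
vignettes:
  n: 8
  t_min: 45
  t_max: 80
  n_items: 6
gcpsr:
  gate: chronic_pain
```

## File formats

Everything is plain text: item banks and vignette sets as JSON (banks accept
either boundary-location `b` or slope-intercept `c` parameters), response
matrices / placements / GCPS-R records / summary tables as CSV. See the
module docstrings for the exact schemas.
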