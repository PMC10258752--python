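# airepi

Adaptive immune receptor repertoire (AIRR) metrics and their association
with acute respiratory infection (ARI) counts, as one reusable pipeline:

- **`airepi.io`** — AIRR-style clonotype TSVs (one row per unique CDR3
  nucleotide clone), productivity / minimum-count filtering, and depth
  normalization by seeded rarefaction (multivariate hypergeometric).
- **`airepi.metrics`** — clonality (1 − Pielou's evenness, J = H′/log2 S),
  Shannon (bits) and Simpson (1 − Σp²) diversity, richness, mean CDR3
  amino-acid length, somatic hypermutation fraction (strict < 98% germline
  V identity, IGH only), V-gene usage matrices and their PCA.
- **`airepi.pgen`** — a small, exactly enumerable V(D)J generative model:
  generation probability of a nucleotide CDR3 by marginalizing over all
  recombination events, a forward sampler, and repertoire annotation.
  Public clonotypes are those with pgen > 1e−9.
- **`airepi.episodes`** — ARI episode calling from daily symptom diaries
  (a day qualifies with ≥ 1 A-symptom or ≥ 2 B-symptoms; an episode ends
  after a configurable gap of non-qualifying days), diary completeness,
  cumulative episode counts per year of life.
- **`airepi.association`** — per-metric adjusted models: linear
  (additional infections per 1 SD, adjusted for older siblings) and
  Poisson (relative risk per 1 SD across time intervals), Wald 95% CIs.
- **`airepi.simulate`** — synthetic cohorts with known ground truth
  (Dirichlet-multinomial clone abundances, model-generated sequences,
  planted infection episodes with a metric-dependent Poisson rate).
- **`airepi.pipeline` / `airepi.cli`** — orchestration with a YAML config
  and a reproducibility manifest.

## CLI

```sh
airepi simulate --scenario scenario.yaml --out-dir sim/   # synthetic cohort
airepi metrics  --in sim/repertoires --locus TRB --normalize 50000 \
                --seed 1 --model sim/model.yaml --out metrics.tsv
airepi pgen     --model sim/model.yaml --in rep.tsv --out rep.pgen.tsv
airepi episodes --diary sim/diary.tsv --gap 3 --min-completeness 0.8 \
                --out episodes.tsv
airepi associate --cohort cohort.tsv --model linear --model poisson \
                --out effects.json
airepi run      --config config.yaml   # full pipeline + run_manifest.json
```

`airepi run` reads a `RunConfig` YAML (paths plus `normalize_target`,
`min_count`, `identity_threshold_pct`, `gap_days`, `min_completeness`,
`public_threshold`, `seed`) and writes `metrics.tsv`, `episodes.tsv`,
`effects.json` and `run_manifest.json` deterministically for a fixed
seed.

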