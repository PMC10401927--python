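# taxatopics

Topic modeling of gut-microbiome count tables. A sample is treated as a
"document" over genus "terms"; latent Dirichlet allocation fitted by
variational EM discovers latent bacterial **community types**, which are
validated across cohorts and tested for differential abundance between a
disease and a control group.

The package provides, as composable modules and a single pipeline:

- **data_model** — validated samples × features count containers; TSV/CSV
  and BIOM (JSON or HDF5) readers, metadata/taxonomy attachment, writers
  with lossless float round-trip.
- **preprocess** — low-prevalence filtering (relative abundance < 1e-5 by
  default), rank aggregation (e.g. ASVs → genera), relative abundance.
- **lda** — variational-EM LDA written from scratch: batched document
  E-step, smoothed M-step, Newton re-estimation of the symmetric Dirichlet
  concentration, a monotone ELBO trace, deterministic seeded restarts.
- **model_selection** — topic-number selection over a K grid by two
  minimized criteria: mean pairwise topic cosine (topic density) and the
  symmetric KL divergence between beta's singular-value spectrum and the
  length-weighted topic distribution.
- **topic_pipeline** — read-to-topic assignment (gamma × library size),
  cross-cohort topic cosine matrices on union-aligned genus vocabularies,
  thresholded many-to-many topic matching (default cosine ≥ 0.80), top-term
  extraction.
- **diff_abundance** — two-group differential abundance on log2 relative
  abundances with mode-based compositional bias correction, optional
  winsorization, Benjamini–Hochberg q-values, and the dual significance
  rule p ≤ 0.05 ∧ q ≤ 0.25.
- **networks** — within-topic Spearman co-occurrence networks on relative
  abundances.
- **synthetic_data** — Dirichlet-multinomial cohort simulator with known
  topics, group effects in the Dirichlet concentrations, paired-cohort mode
  with controllable topic jitter and partially overlapping vocabularies,
  and recovery evaluation.
- **pipeline / cli** — end-to-end orchestration with persisted artifacts
  and a JSON summary.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance battery (normalization and
conservation invariants, ELBO monotonicity, oracle equivalence against
independent brute-force implementations, agreement with scikit-learn's
variational LDA, seeded parameter recovery, K-selection sanity, DA
calibration and power, cross-cohort matching logic, and the end-to-end
qualitative finding).

## CLI

```sh
taxatopics simulate --profile paired --seed 1 --out sim/
taxatopics preprocess --counts counts.tsv --threshold 1e-5 --out filtered.tsv
taxatopics choose-k --counts filtered.tsv --grid 2:20 --seed 1 --out curves.tsv
taxatopics fit --counts filtered.tsv --k 30 --seed 1 --starts 5 --out model/
taxatopics assign --counts filtered.tsv --model model/ --out assigned.tsv
taxatopics match --model-a model_a/ --model-b model_b/ --threshold 0.80 --out matches.tsv
taxatopics da --counts assigned.tsv --metadata meta.tsv --on topics --out da.tsv
taxatopics run --config config.yaml
```

A pipeline config names one or two cohorts (count + metadata tables) or a
simulation profile:

```yaml
cohorts:
  - name: exploratory
    counts: chen_counts.tsv
    metadata: chen_meta.tsv
  - name: validation
    counts: yadav_counts.tsv
    metadata: yadav_meta.tsv
group_key: status
k: 30            # or k_grid: [2, ..., 40]
seed: 1
starts: 5
cosine_threshold: 0.80
p_max: 0.05
q_max: 0.25
winsorize_genera: true
```

The run directory contains every intermediate (filtered counts, beta/gamma,
topic abundances, cosine matrix, matches, per-topic genus DA tables,
network edge lists) plus `summary.json` listing matched community types
with validation status, effect directions, and shared genera.

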