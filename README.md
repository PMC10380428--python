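# volatax

Chemotaxonomic identification from GC-MS headspace profiles.

Given an aligned compound × sample peak table and per-sample metadata
(technical replicates, a-priori groups such as species or host plant),
volatax runs hierarchical rounds of **canonical analysis of principal
coordinates (CAP)**: principal coordinates of a chosen dissimilarity,
canonical discriminant analysis on the first *m* axes, leave-one-out
allocation, and permutation tests. Compound vectors (correlations with the
first two canonical axes) are thresholded by squared length into
**essential biomarkers** (EB, `X²+Y² ≥ 0.49`) and **semi-essential
biomarkers** (SEB, `0.29 ≤ X²+Y² < 0.49`) per group, accumulated across
rounds into a **dichotomous key** (EB inner circle, SEB outer circle), and
unknown volatile profiles are matched against the key.

## Modules

| module | role |
|---|---|
| `volatax.io_formats` | peak table / metadata CSV, key JSON (versioned) |
| `volatax.preprocess` | replicate averaging, transforms, dissimilarities |
| `volatax.cap` | PCoA, m selection, canonical analysis, LOO, permutation tests, compound vectors |
| `volatax.biomarkers` | EB/SEB classification, key construction, profile matching |
| `volatax.cascade` | plan-driven hierarchical rounds, unknown diagnosis |
| `volatax.synthetic` | seeded dataset generator with planted ground truth, recovery experiments |
| `volatax.cli` | `volatax` command-line entry point |

## CLI

```sh
# generate a synthetic dataset (peaks.csv, samples.csv, plan.json, ground_truth.json)
volatax simulate --out demo/

# run the cascade: round reports + dichotomous key
volatax cascade --peaks demo/peaks.csv --meta demo/samples.csv \
    --plan demo/plan.json --out demo/run/

# inspect the key
volatax key --key demo/run/key.json

# identify an unknown profile (CSV with replicate columns)
volatax identify --profile unknown.csv --key demo/run/key.json --out ident.json
```

`volatax preprocess` and `volatax cap` expose the individual stages. All
JSON output has sorted keys; identical seeded invocations are
byte-identical.

## File formats

* **Peak table** — wide CSV/TSV: `compound_id[,rt_min,name,class]`, then one
  numeric column per sample. Blank cells are read as 0 (not detected).
* **Metadata** — CSV: `sample_id,replicate_group,group_label`
  `[,is_outgroup,host_plant,location]`. A replicate group must map to a
  single group label.
* **Cascade plan** — JSON: global `defaults` (transform, metric,
  presence_threshold, n_perm, seed) and `rounds`, each with `round_id`,
  `groups` (≥ 3; an outgroup may be added just to reach that minimum),
  significance/EB/SEB `thresholds`, and `groups_to_remove_after`.
* **Key** — JSON with `schema_version` and per-taxon EB/SEB lists with
  squared lengths and round provenance.

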