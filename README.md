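# aucscreen

Analysis pipeline for plate-based compound viability screens: raw per-well
luminescence → per-plate DMSO-vehicle normalization → dose–response AUC
scoring → mean ± SD hit calling with on-plate control QC → target-level
aggregation of hits. A synthetic screen generator with planted ground
truth (Hill-shaped inhibitors, enhancers, biphasic profiles, lognormal
measurement noise) makes every stage testable without external data.

## The statistic

Each compound's relative viability (well luminescence ÷ mean DMSO
luminescence of the same plate and condition) is measured on a dose grid
(default 0.2, 1, 5, 25 μM, 4 replicates). The score is the trapezoidal
area under the piecewise-linear viability curve on the **linear**
concentration axis from 0 to the top concentration, with a fixed vehicle
anchor at (0 μM, viability 1.0). A no-effect compound on the default grid
scores exactly 25; lower = inhibition, higher = enhancement. Per-replicate
AUCs are averaged per compound. Hits are called with strict inequalities
at mean ± 1 SD of the library AUC distribution (controls/vehicle excluded)
and grouped by annotated target.

## CLI

```sh
# generate a synthetic screen (defaults: 225 compounds, 4 doses, 4 replicates)
aucscreen simulate --out sim/ --seed 1 [--config cfg.yaml]

# analyze a measurement + annotation table pair
aucscreen analyze --measurements sim/measurements.csv \
                  --annotations sim/annotations.csv --out report/ \
                  [--threshold-multiplier 1.0] [--sd-flavor sample] [--qc-strict]

# simulate + analyze with one seed (CI round-trip)
aucscreen reproduce --seed 1 --out run/
```

`simulate` writes `measurements.csv`, `annotations.csv`, `truth.csv` (the
planted effect parameters) and a `manifest.json` with the seed and file
hashes; identical seed + config ⇒ byte-identical files. `analyze` writes a
report bundle: `summary.json` (screen statistics, thresholds, QC),
`auc_table.csv`, `hits.csv`, `target_groups.csv`. With `--qc-strict` a
failed control gate exits with status 3 after writing the report.

A YAML config for `simulate`/`reproduce` may set `n_compounds`,
`n_replicates`, `noise_cv`, `grid`, `seed`, plate layout fields, and
planted effect counts (`n_inhibitors`, `n_enhancers`, `n_biphasic`).

## Layout

- `src/aucscreen/model.py` — domain types and CSV/JSON readers/writers
- `src/aucscreen/normalization.py` — relative viability, fold-change t-test
- `src/aucscreen/auc.py` — trapezoidal AUC scoring
- `src/aucscreen/hits.py` — screen summary, thresholds, hit calls, control QC
- `src/aucscreen/targets.py` — target-level hit aggregation
- `src/aucscreen/synth.py` — synthetic screen generator with planted truth
- `src/aucscreen/pipeline.py`, `cli.py` — orchestration and CLI
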