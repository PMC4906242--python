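# svpop

Population-imaging analysis of synaptic vesicle (SV) cycling, with a
ground-truth simulator, clustered statistics and Boltzmann voltage-clamp
fitting.

The pipeline quantifies vGlut1-pHluorin (vGpH) movies acquired under a
two-train stimulation paradigm: boutons are segmented from the first-train
ΔF response map, per-bouton traces are normalized to the NH4Cl plateau,
exocytic rates are the initial slope of the bafilomycin-train rise, and the
endocytic component is the onset-aligned difference between the two trains.
Bouton-level outcomes are analyzed with a linear mixed model (random field
intercepts, preparation fixed effects, REML) that respects intra-field
correlation. A companion module fits driving-force and single-Boltzmann
models to I-V and tail-current data. Because raw recordings of the original
study are not public, a first-class simulator renders movies and traces with
known ground truth so every stage is verifiable end to end.

## Modules

| module | contents |
| --- | --- |
| `svpop.synthetic` | SV pool kinetics (`simulate_pools`), Ca²⁺ transients (`simulate_ca_trace`), movie rendering (`render_movie`), hierarchical experiments (`simulate_experiment`) |
| `svpop.segmentation` | drift re-alignment (`realign`), ΔF response maps (`response_map`), thresholding/dilation/size-gating (`segment`) |
| `svpop.traces` | trace extraction and NH4Cl normalization, QC filtering, `exo_rate`, `endo_trace`, `endo_rate`, `pool_plateau`, Ca²⁺ peak summaries, `percent_inhibition` |
| `svpop.stats` | REML mixed model (`fit_lmm`), Wald tests with Satterthwaite df, field-heterogeneity F test, field-averaging and naive-pooled comparators |
| `svpop.ephys` | Boltzmann I-V fit (`fit_iv`), tail-current activation fit (`fit_activation`), per-cell group comparisons, sweep simulation |
| `svpop.cli` / `svpop.config` | `svpop` command line, validated YAML run configs, manifests |

## Command line

All stages read one YAML config (all fields have defaults; see
`svpop.config.RunConfig`). Each stage writes its effective config and a run
manifest (config hash, seed, QC counts) next to its outputs.

```bash
# render synthetic movies (one TIFF per field + manifest + ground truth)
svpop simulate -c config.yaml -o out/sim

# segment boutons, extract traces, estimate rates -> rate_table.csv
svpop analyze -c config.yaml -i out/sim -o out/analysis

# mixed-model inference on the rate table
svpop stats -c config.yaml -i out/analysis/rate_table.csv -o out/stats

# Boltzmann fits on voltage-clamp sweeps (CSV: cell_id,group,V_mV,I_pA[,Cm_pF])
svpop ephys -i sweeps.csv -o out/ephys --model iv

# or everything in one pass
svpop all -c config.yaml -o out
```

A minimal config:

```yaml
seed: 7
hierarchy:
  n_preps: 3
  fields_per_prep: 6
  boutons_per_field: 50
  group_effects: {ctrl: 1.0, kd: 0.6}
```

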