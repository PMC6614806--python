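# pitbind

Single-molecule analysis of supercoil-induced DNA unwinding in nanopit
confinement: simulation of probe/plasmid binding dynamics, spot tracking,
diffusion-based bound/free classification, binding time-course assembly, and
fitting of the saturating second-order kinetic model

    B(t) = U0 * (1 - exp(-K t)),      K = k * (P0 - U0)

to recover the initial unwound-site concentration `U0` and binding rate
constant `k`, together with solution-condition bookkeeping (total ionic
strength, crowder excluded volume, semidilute crossover).

## Modules

| module       | role |
|--------------|------|
| `conditions` | solution conditions: ionic strength, excluded-volume fraction, crossover concentration |
| `synth`      | ground-truthed generators: pit-confined two-species Brownian trajectories with stochastic binding, fluorescence video rendering, topoisomer gel lanes |
| `track`      | spot detection (DoG band-pass + local maxima + centroid), greedy nearest-neighbour linking, MSD diffusion estimation |
| `classify`   | threshold-diffusion bound/free classification and per-video binding counts |
| `kinetics`   | time-course assembly (mean ± SEM over replicate videos) and weighted nonlinear fitting of the binding model |
| `topo`       | linking-number / superhelical-density conversions and Gaussian-envelope fitting of gel-lane band intensities |
| `config`, `pipeline`, `cli` | YAML run configuration, end-to-end orchestration, command line |

## CLI

```bash
pitbind run-all --config run.yaml --outdir runs/demo --plot
pitbind simulate --config run.yaml --outdir runs/sim --render   # TIFF stacks
pitbind track --config run.yaml --tiff runs/sim/video_0000.tif --outdir runs/tracked
pitbind classify --config run.yaml --estimates runs/tracked/diffusion_estimates.csv --outdir runs/cls
pitbind fit --counts runs/cls/counts.csv --out fit.json
pitbind compare runs/a runs/b runs/c --covariate ionic_strength_mM
pitbind gel-fit --profile lane.csv --bands bands.csv --plasmid-length 2686 --out gel.json
```

The YAML schema is documented in `pitbind.config`. A minimal config:

```yaml
seed: 1
n_replicates: 10
condition:
  nacl_mM: 137.5
  crowder: {species: PEG, mw_da: 8000, conc_wv_pct: 10.0}
kinetics: {P0: 100.0, U0: 10.0, K: 5.0e-4}
```

Pit geometry defaults to 3 µm diameter × 500 nm deep; acquisition defaults
to one video burst per minute over 2 h at 50 ms exposure. Replicate fields
("videos" in the figure sense) are simulated as independent pit blocks.

## Units

% w/v is g per 100 mL; excluded volume is % v/v; ionic strengths in mM;
lengths in µm; times in s; diffusion coefficients in µm²/s; binding counts
per 100 probes (so `U0`, `P0` share that unit and `k` is per-100-probes⁻¹·s⁻¹).
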