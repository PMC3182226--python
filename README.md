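# fncnet

Small-world graph analysis of **functional network connectivity (FNC)** —
the temporal relationships among independent-component (IC) time courses
from resting-state fMRI.

Given per-subject component time-course matrices (timepoints × components)
and a cohort manifest, `fncnet`:

1. band-pass filters each time course (0.01 < f < 0.10 Hz by default);
2. estimates the N×N **partial-correlation** FNC matrix per subject — the
   correlation of each component pair after controlling for the other
   N−2 components, computed as the normalised Schur complement
   `S11 − S12 S22⁻¹ S21` of the pair against the rest (equivalently
   `r(j,k) = −P_jk / √(P_jj P_kk)` with precision `P = S⁻¹`), then applies
   the Fisher r-to-z transform;
3. builds **cost-matched binary graphs**: at each analysed connection
   density `K_cost = 2E / (N(N−1))` every subject's graph keeps exactly
   the E strongest |z| pairs, so group differences cannot be driven by
   edge-count differences;
4. computes nodal and network topology — degree `K`, clustering `C`,
   characteristic path length `L`, global efficiency `E_global` (mean
   reciprocal shortest-path length), local efficiency `E_local` (global
   efficiency of each node's neighbour subgraph);
5. compares against **degree-preserving random references** (Maslov–Sneppen
   double-edge-swap ensembles, 100 graphs per subject per cost) to obtain
   `γ = C/C_random`, `λ = L/L_random`, and small-worldness `σ = γ/λ`;
6. runs the group statistics: pooled-variance two-sample two-tailed t-tests
   per cost for each network metric (α = 0.05, uncorrected), per-node
   post-hoc tests with Benjamini–Hochberg q-values reported alongside, and
   Pearson correlations of metrics with PANSS-like symptom scores within
   the patient group.

A synthetic cohort generator (`fncnet.synthetic`) draws Gaussian time
series from precision matrices with known graph support, so the entire
pipeline is testable without any imaging data: the ground-truth
partial-correlation network, the group effect, and the symptom coupling
are all known by construction.

## Worked example

Simulate a two-group cohort at the default study conditions (19 + 19
subjects, 57 components, 194 timepoints at TR = 1.5 s; the patient-like
group has higher ground-truth clustering at equal density) and analyse it
at four costs spanning 0.351–0.417:

```sh
fncnet simulate --out cohort --seed 7

cat > cfg.yaml <<'YAML'
manifest: cohort/manifest.tsv
out_dir: results
filter_method: none      # the simulated signals are broadband
edge_counts: [560, 665, 35]
n_ensemble: 20
seed: 1
YAML

fncnet run-all --config cfg.yaml
```

This prints (about two minutes on one core):

```
pipeline complete -> results; summary: {'n_grid_points': 4, 'alpha': 0.05,
'false_positive_budget': 0.2, 'network_significant': {'c_net': 3,
'l_net': 0, 'e_global': 0, 'e_local': 3, 'gamma': 4, 'lambda': 0,
'sigma': 4}, 'nodal_significant_uncorrected': 127}
```

and `results/stats/network_tests.tsv` holds rows such as

```
metric  edge_count  k_cost     t          p         significant
c_net   560         0.350877  -3.024112   0.004578  True
c_net   595         0.372807  -2.694541   0.010642  True
c_net   630         0.394737  -2.253581   0.030408  True
c_net   665         0.416667  -1.949052   0.059114  False
```

t is oriented control-minus-patient, so the negative values say the
patient-like group's clustering coefficient is significantly *higher* at
three of the four costs — the direction built into the generator. The
symptom table shows the designed positive coupling between characteristic
path length and the negative symptom scale, e.g. `r = 0.604, p = 0.006`
at cost 0.395 (`results/stats/symptom_correlations.tsv`). With a fixed
seed the whole run is bit-reproducible; outputs are tidy TSV/JSON per
stage (`fnc/`, `grid.json`, `curves_full.tsv`, `nulls/`, `stats/`), and
each CLI stage subcommand (`connectivity`, `graphs`, `metrics`, `nulls`,
`stats`) can resume from the previous stage's files.

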