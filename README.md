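# modcart

Modular organization and functional cartography of resting-state brain
networks, and its covariate-adjusted association with a continuous
symptom score.

`modcart` is for researchers studying individual differences in functional
brain-network organization — e.g. whether self-rated ADHD symptom strength
in a non-clinical adult sample relates to how modular a person's intrinsic
connectivity network is, globally or region by region. It implements the
full analysis chain from per-subject node time series to statistics, plus a
synthetic-cohort generator so every stage is testable without access to
imaging data.

## The analysis

Per subject, node-wise Pearson correlations of the time series are pruned
of short-range pairs (< 20 mm apart), proportionally thresholded at five
densities (top 10–30 % of strongest positive correlations), and binarized.
On each graph, Louvain community detection maximizes the modularity

$$Q = \sum_{s=1}^{m}\left[\frac{l_{in_s}}{L} - \left(\frac{k_s}{2L}\right)^2\right],$$

where $l_{in_s}$ is the edge count inside module $s$, $L$ the total edge
count and $k_s$ the summed degree of module $s$; $Q > 0.3$ conventionally
indicates modular organization. Four whole-brain measures (Q, number of
modules, average and SD of module size) and two nodal maps are derived:
the participation coefficient

$$p_i = 1 - \sum_{m \in M}\left(\frac{k_i(m)}{k_i}\right)^2$$

(diversity of node $i$'s edges across modules) and the within-module degree

$$z_i = \frac{k_i(m_i) - \bar{k}(m_i)}{\sigma_{k}(m_i)}$$

(standardized within-module connection count). The Guimerà–Amaral
cartography turns $(p_i, z_i)$ into seven node roles (hubs at $z_i \ge 1$,
split by $p_i$ at 0.30/0.75; non-hubs split at 0.05/0.62/0.80). Metrics are
averaged across the five densities per subject.

Associations with the symptom score control for age, sex, handedness,
FSIQ and mean framewise displacement (FD): partial correlations with
Bonferroni family correction and JZS Bayes factors (BF01 > 3 read as
substantial null evidence) for the global measures; mass-univariate
node-wise regression with Monte-Carlo-calibrated cluster-extent correction
(voxel p < 0.005, cluster size k > k_min) for the nodal maps. Motion QC
(FD formula, mean-FD > 0.2 mm exclusion), four post hoc controls
(extreme-group tests, canonical 7-network block connectivity,
distance-dependent motion diagnostics, cluster rank positions) and a full
synthetic-cohort generator round out the pipeline.

## Worked example

```bash
modcart simulate --out demo_cohort --n-subjects 30 --n-nodes 60 \
    --n-volumes 120 --seed 7
cat > demo.yaml <<EOF
cohort_dir: demo_cohort
output_dir: runs
louvain_restarts: 5
n_null_iter: 500
extreme_group_n: 8
seed: 1
EOF
modcart all --config demo.yaml     # ~4 s; outputs in runs/run-<confighash>/
```

`global_metrics.csv` then holds each subject's threshold-averaged
modularity profile — for this cohort (4 planted modules of 15 nodes):

```
subject_id density        q  number_of_modules  average_module_size  variability_in_module_size
  sub-0000     avg 0.569705                4.2                 14.4                    1.992271
  sub-0001     avg 0.547726                4.2                 14.4                    1.396182
```

Q ≈ 0.55 (well above the 0.3 modularity convention) with ~4 recovered
modules of ~15 nodes reflects the planted block structure. Because this
demo plants no brain–behavior effect, `global_associations.csv` shows the
null pattern the statistics should produce:

```
                   measure  r_part  p_part  bf01  n_used  significant  bonferroni_p
                         q   0.042   0.845 4.577      30        False         0.013
         number_of_modules   0.109   0.611 4.126      30        False         0.013
       average_module_size  -0.214   0.327 2.917      29        False         0.013
variability_in_module_size   0.152   0.479 3.683      30        False         0.013
```

— small partial correlations, none passing the Bonferroni threshold
(0.05/4 → .013), and Bayes factors leaning toward the null (BF01 ≈ 3–5).
One subject is dropped for `average_module_size` by the 3-SD outlier rule
(`n_used` 29). The run directory also contains the nodal t-maps, cluster
tables, QC summaries and a SHA-256 manifest; rerunning the same config on
the same cohort reproduces the manifest byte for byte.

## Documentation

See `docs/methods.md` for the modelling assumptions, parameter defaults,
what the synthetic cohorts do and do not emulate, and numerical
conventions (tie-breaks, degenerate cases, seeds).
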