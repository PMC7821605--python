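# dmnconn

Resting-state functional connectivity networks over a 48-region default
mode network (DMN) parcellation, estimated with a leave-one-volume-out
jackknife correlation pipeline.

## The problem

Resting-state fMRI connectivity is usually summarized by Pearson
correlations between region-of-interest (ROI) time series. In populations
that move in the scanner — here the motivating case is young adults with
Down syndrome — a handful of aberrant volumes can dominate a plain
correlation and fabricate edges. This package implements a pipeline that
estimates each ROI-pair correlation robustly and turns the result into
weighted and binary brain graphs:

1. For each of the 1128 pairs among 48 AAL90 regions (grouped into
   posterior, anterior and ventral DMN, sensorimotor and visual
   subnetworks), compute the *n* leave-one-volume-out correlations
   *r*₁, …, *rₙ* and summarize them as

   - jackknife mean  θ = (1/n) Σᵢ rᵢ
   - jackknife SE    SE = √[ ((n−1)/n) Σᵢ (rᵢ − θ)² ]
   - bias            Bias = (n−1)(θ − r̂),  r̂ the full-sample Pearson r

2. When |Bias| is close to zero, θ is carried forward; otherwise the
   Student-t confidence-interval bound of smaller magnitude replaces it,
   shrinking suspect estimates toward zero (type-I protection).
3. Correlations are positivized and Fisher-transformed,
   z = ½·ln((1+r)/(1−r)); the edge test refers |z|·√(n−3) to the standard
   normal, and edges with two-sided p < .001 form the binary adjacency.
4. Graph summaries per ROI: weighted degree (sum of z weights over
   significant edges), binary degree, local clustering; per network:
   density and a high/medium/low density tertile classification of each
   cohort; per study: a two-group degree comparison table.
5. Group-level networks come from "stacked" data: each subject's series is
   standardized and concatenated along time before the same chain runs.

No public dataset accompanies the motivating study, so the package ships a
first-class synthetic cohort generator (block-structured Gaussian series
with AR(1) autocorrelation and motion-like global spike artifacts) that
reproduces the data dimensions the analysis assumes: 220 volumes at
TR = 2 s, 48 ROIs, 22 subjects per group, and a continuum of per-subject
connectivity density.

## Worked example

```python
import numpy as np
import dmnconn as dc

atlas = dc.load_atlas()                      # 48 ROIs, 5 subnetworks
covs = dc.study_covariances(atlas)           # block covariances per density class
cohort = dc.CohortSpec(group_label="ds", n_subjects=22, seed=1)
subjects = dc.simulate_cohort(covs, cohort, roi_names=atlas.column_order)

stack = dc.stack_group(subjects)             # 22 x 220 volumes -> 4840 rows
mats, net = dc.group_network(stack)          # jackknife -> Fisher -> p<.001

print(f"stacked volumes: {stack.n_volumes}")
print(f"significant edges: {net.n_edges} / 1128")
wd = dc.weighted_degree(net.z_matrix, net.adjacency)
for i in np.argsort(wd)[::-1][:5]:
    r = atlas.records[i]
    print(f"{r.name:<22s} {r.subnetwork.value:<14s} weighted degree {wd[i]:.2f}")
```

prints

```
stacked volumes: 4840
significant edges: 1128 / 1128
Postcentral_R          Sensorimotor   weighted degree 16.88
Frontal_Mid_R          Sensorimotor   weighted degree 16.87
Occipital_Mid_L        Visual         weighted degree 16.82
Lingual_L              Visual         weighted degree 16.78
Supp_Motor_Area_R      Sensorimotor   weighted degree 16.75
```

With 4840 stacked volumes the p < .001 threshold is tiny
(|z| > 3.29/√4837 ≈ 0.047), so every edge of this structured cohort is
significant and the graph is complete; the weighted degrees still expose
the designed structure — sensorimotor and visual regions, simulated with
stronger within-network coupling, head the ranking, the same qualitative
ordering the pipeline is meant to detect in real cohorts.

The same analysis is scriptable from a shell: `dmnconn simulate`,
`dmnconn connectivity`, `dmnconn group`, `dmnconn export-brainnet`
(BrainNet Viewer `.node`/`.edge` files) and `dmnconn run` for the full
two-group report bundle.

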