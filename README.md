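# caprimorph

Geometric-morphometric species identification of sheep (*Ovis aries*) and
goat (*Capra hircus*) from isolated third lower molars, with the group
statistics used to compare modern and archaeological populations.

Sheep and goat were herded together around the Mediterranean since the
Neolithic, but their teeth — often the best-preserved remains in
archaeological assemblages — are notoriously hard to tell apart.
`caprimorph` implements a landmark-based identification pipeline for the
occlusal outline of the third lower molar (M3): 7 fixed anatomical
landmarks plus 48 sliding semi-landmarks on 6 curves of 8 points, a joint
Generalized Procrustes superimposition, shape PCA, and an ensemble of
balanced predictive linear discriminant analyses whose votes identify each
unknown specimen. Molecular identifications (e.g. ZooMS collagen peptide
mass fingerprinting) can be attached to the archaeological specimens to
quantify the congruence of the two approaches.

## Method

For configurations of k landmarks in 2-D:

- **Size** is centroid size, CS = √Σᵢ‖pᵢ − p̄‖², analysed as log CS.
- **Shape** comes from Generalized Procrustes Analysis: all specimens are
  centered, scaled to unit CS and rotated (never reflected; left molars
  are mirrored beforehand) onto an iteratively re-estimated consensus.
  Semi-landmarks slide along the chord through their outline neighbors to
  minimize Procrustes distance to the consensus, alternating with
  re-superimposition.
- **Identification**: Procrustes residuals enter a PCA; each of 100
  iterations draws a without-replacement subsample of the majority species
  equal to the minority count (balanced design), fits a pooled-covariance
  LDA with equal priors on the first 20 PC scores, and records its
  leave-one-out cross-validation percentage (CVP) plus a species vote for
  every unknown. Only iterations with CVP at or above the third quartile
  of all CVPs are retained; each unknown is labeled by the majority of the
  retained votes, reported as a percentage.
- **Group comparisons**: permutation Procrustes ANOVA (residual
  randomization, sequential SS) for shape, morphological disparity
  (per-group Procrustes variance with pairwise permutation tests),
  Fligner–Killeen and pairwise Wilcoxon rank-sum tests (Bonferroni) for
  log CS, a classical two-way size ANOVA, Mahalanobis distances between
  group means in PC space, and a neighbor-joining tree of those distances.

A seeded synthetic generator (`caprimorph.simulate`) draws molar-like
datasets with controllable species/period shape effects, landmark noise,
log-normal size and molecular label flips, so the whole pipeline is
testable without access to collection data. See `docs/methods.md` for the
model, parameter defaults and their rationale.

## Worked example

The shipped demo config simulates a 150-specimen modern reference and 50
archaeological unknowns with a 5% molecular label-flip rate, then runs the
full study:

```
$ caprimorph run-all --config examples/demo.yaml --out demo_out
50 unknowns scored; congruence 86.0% (43 agree / 7 disagree); report in demo_out
```

`demo_out/summary.json` contains, among other tables:

```json
"identification": {
  "n_unknowns": 50,
  "counts": {"sheep": 27, "goat": 22, "unresolved": 1},
  "q3_cvp_threshold": 90.0,
  "n_retained_lda": 40,
  "min_retained_cvp": 90.0
}
```

Reading: of the 100 balanced discriminant analyses, the 40 whose
leave-one-out CVP reached the third quartile (90%) were retained; their
majority votes call 27 unknowns sheep and 22 goat (one exact tie is left
unresolved rather than guessed). 43 of the 50 calls match the simulated
molecular labels — with a 5% flip rate and a classifier operating in the
low-90s CVP regime, mid-80s congruence is the expected outcome. The
report directory also holds the identification table (per-specimen vote
percentages), ANOVA/disparity/size-test tables as CSV, the Mahalanobis
matrix and its neighbor-joining tree in newick form, e.g.

```
('archaeological_goat':0.465,('archaeological_sheep':0.795,'modern_sheep':0.603):1.564,'modern_goat':0.942);
```

in which the two sheep groups join before either joins a goat group:
specimens resemble their species across periods more than their
contemporaries of the other species.

The same stages are available as library calls (`align_gpa`, `pca_shape`,
`ensemble_identify`, `congruence_report`, `procrustes_anova`, ...) and as
individual subcommands (`simulate`, `align`, `identify`, `compare`).

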