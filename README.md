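# tractcrowd

Along-tract white-matter bundle analysis with a cognitive-profile
(crowding) association layer:

- **I/O** for TCK/TRK streamlines (world-mm RAS internally), NIfTI scalar
  volumes with trilinear world-space sampling, and a TSV subject table.
- **Geometry**: uniform arc-length resampling (50 vertices), second-central-
  difference curvature (endpoints set to zero), endpoint-sphere / waypoint /
  exclusion ROI dissection (with shipped AF/ILF presets), midsagittal
  mirroring, medoid representative streamlines, and rigid ICP alignment.
- **Joint parameterization**: one-class-SVM outlier removal (nu = 0.1),
  a shared 1-D ISOMAP coordinate over the pooled vertex cloud of all
  subjects and hemispheres rescaled to [0, 1], core extraction by subject
  coverage and vertex density, 7 equal-width bins, and per-subject per-bin
  scalar profiles normalized by a skeleton-mean scalar.
- **Statistics**: bin-wise tie-corrected Mann-Whitney z-scores, 1-D TFCE
  (E = 0.5, H = 2, Δh = 0.01), max-statistic permutation family-wise error
  correction, Welch whole-tract comparisons with Cohen's d, Barnard's
  unconditional exact test, the VIQ − PIQ ≥ 10 crowding rule, and three
  logistic crowding models (age covariate + normalized FA + affected
  hemisphere) reporting AIC/BIC/pseudo-R²/LLR-p and the design condition
  number.
- **Synthetic cohorts**: arc-shaped bundles with smooth jitter and displaced
  outliers, FA volumes with a localized group effect of specified Cohen's d
  injected in world space over one of seven arc segments, and VIQ/PIQ
  scores with a specified crowding prevalence — everything a pure function
  of (spec, seed).

## CLI

```bash
# generate a synthetic cohort (TCK + NIfTI + TSV)
tractcrowd simulate --config cohort.yaml --out data/

# ROI dissection of a single bundle
tractcrowd dissect data/bundles/sub-p01_hemi-left_AF.tck out.tck --rois af

# joint parameterization + bin profiles only
tractcrowd parameterize data/ --out profiles.tsv

# TFCE group comparison on a saved profile table
tractcrowd stats profiles.tsv data/subjects.tsv --out bins.tsv --hemisphere right

# full study replica: dissection -> alignment -> parameterization ->
# profiles -> all contrasts -> TSV/JSON/PNG reports
tractcrowd run data/ --out report/ --seed 1
```

`cohort.yaml` holds `CohortSpec` fields (e.g. `n_group_a`, `effect_bin`,
`effect_size_d`, `crowding_prevalence`); the `run` config holds
`AnalysisConfig` fields with a nested `tfce:` block.

## Data layout

```
data/
  subjects.tsv                      # subject_id, group, contralesional_hemisphere,
                                    # etiology, viq, piq, ages, skeleton_mean_fa
  bundles/sub-<id>_hemi-<side>_<tract>.tck
  volumes/sub-<id>_<metric>.nii[.gz]
```

Patients contribute their contralesional hemisphere only; controls
contribute both.

## Tests

```bash
python -m pytest tests/
```

`tests/test_acceptance.py` carries the acceptance criteria (TFCE oracle
equivalence, the single-bin analytic limit, permutation FWE calibration,
power/localization, geometry oracles, exact-test oracles, the crowding
rule, outlier-fraction behavior, and logistic model recovery).  One
criterion — Mann-Whitney normal-approximation p within 0.01 of exact
enumeration for group sizes down to 2 — is mathematically unattainable and
intentionally left failing; see the test's comment.

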