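# hepatoscope

Quantitative analysis of liver microarchitecture from 2D tissue sections:
spatial statistics on portal-tract / central-vein point patterns, hexagon-
paradigm lobule geometry, and nuclear-morphology cell classification with
stepwise binuclear reclassification — all exercisable end-to-end on a
synthetic tissue generator with known ground truth.

## Who this is for

Hepatic histology produces two kinds of quantitative questions that this
package answers from point annotations alone (no pixel data required):

1. **Is the lobular architecture normal?**  Annotated centres of portal
   tracts and central veins form a marked point pattern per section.  The
   package computes per-mark intensities, the edge-corrected Ripley
   L-function `L(r) = sqrt(K(r)/π)` (values below the CSR reference
   `L(r) = r` indicate the regular spacing of healthy vascular trees), and
   a grouped studentized permutation test comparing groups of sections:

   `T = Σ_{i<j} ∫ ( L̄_i(r) − L̄_j(r) )² / ( s_i²(r)/m_i + s_j²(r)/m_j ) dr`

   with p-values from random permutation of the section-to-group
   assignment.

2. **How big are the lobules, and what cells fill them?**  For each
   central vein the distances to its k nearest portal tracts show a jump
   ("step") at the k = 3:4 boundary — a lobule cross-section owns three
   portal tracts.  The mean distance r to the three nearest portal tracts
   gives the lobule-as-hexagon area estimate

   `A = (3√3 / 2) · r²`.

   Nuclei (area, perimeter, circularity, elongation, intensity, spatial
   context) are classified hepatocyte-vs-other by a depth-limited decision
   tree (default depth 7, 1 sample/leaf, 5-fold CV, stratified 70/30
   split), then touching pairs of hepatocyte-predicted nuclei are promoted
   to binucleated hepatocytes by an ordered rule cascade (touching
   distance, combined-area window around the typical 70 µm² hepatocyte
   nucleus, exclusion of dense mutually-touching cliques).  Model quality
   is reported as a binary error matrix with nine statistics: PPV, NPV,
   sensitivity, specificity, accuracy, falsePos/realPos, FDR, FNR, FOR.

The synthetic generator realises the classical lobule idealisation — a
jittered honeycomb with central veins at hexagon centres and portal tracts
at a subset of apices — plus class-conditional nuclear populations, so
every estimator can be validated against closed-form ground truth.

## Worked example

```python
import numpy as np
import hepatoscope as hs

cfg = hs.SyntheticTissueConfig(lattice_radius_r0=100.0, jitter_sd=8.0,
                               window_width=2000.0, window_height=2000.0, seed=42)
pat = hs.generate_lobular_lattice(cfg)
print("points:", len(pat))

prof = hs.step_profile(hs.restrict_sources(pat, hs.CENTRAL, 220.0))
print("mean distance to kth portal (um):", np.round(prof.mean_distance_per_k, 1))
print("largest step at k =", hs.detect_step(prof).k_star)

est = hs.lobule_estimates(pat, exclude_boundary=True)
print("mean lobule area: %.0f um^2 (generative truth %.0f)"
      % (est.section_mean_area, hs.hexagon_area(100)))
print("portal density: %.1f per mm^2" % hs.portal_density(pat))
```

prints

```
points: 310
mean distance to kth portal (um): [ 90.4 100.2 110.9 189.4 201.  210.3]
largest step at k = 3
mean lobule area: 26280 um^2 (generative truth 25981)
portal density: 40.2 per mm^2
```

The first three neighbour distances cluster near the 100 µm hexagon
circumradius and the next three near 200 µm (the second lattice shell), so
the detected step at k = 3 recovers the three-portal lobule; the
boundary-excluded hexagon-area estimate lands within ~1% of the generating
hexagon's 25 981 µm².

A command-line pipeline chains all stages
(`hepatoscope simulate | spatial | lobule | classify | stats | pipeline`);
`hepatoscope pipeline --config run.yaml` runs synthetic sections for ≥ 2
groups through spatial statistics, lobule metrics, classification and
group comparisons, writing CSV/JSON reports.  Annotations can also be
imported from ImageJ/FIJI point-ROI files (`.roi` / ROI-set `.zip`) with a
µm-per-pixel scale factor.

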