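# Methods

`lesionsynth` segments abnormally hyperintense tissue on FLAIR MRI as an
outlier-detection problem, trained only on healthy tissue.  This note
records the model, its assumptions, the tunable parameters, what the
synthetic phantoms do and do not emulate, and the numerical choices made
where the design was genuinely open.

## Pipeline

All stages operate voxel-wise on a common lattice ("model space"); inputs
are co-registered, skull-stripped, bias-corrected T1-w/FLAIR pairs with
WM/GM probability maps, a ventricle mask and a lesion-probability atlas.
Registration, brain extraction and bias correction are upstream concerns;
the package consumes their outputs.

1. **Intensity normalisation** (`normalise`).  Voxels with >95% WM (resp.
   GM) probability are sampled, trimmed to the central 95% of their
   intensity distribution, and averaged; the mean of the WM and GM means
   is a fixed point scaled linearly to 1000.  Because lesion voxels rarely
   get >95% WM confidence from a T1-driven segmenter, and are trimmed as
   intensity outliers when they do, the scale factor is invariant to
   lesion load — the property that motivates this scheme over min-max
   scaling, z-scoring or histogram matching, all of which are biased by
   hyperintensity burden.
2. **Pseudo-healthy synthesis** (`synthesis`).  At each voxel a
   Nadaraya–Watson regression with Gaussian kernel (bandwidth `h`) maps T1
   intensity to FLAIR intensity, fitted on the pooled voxels of an
   `a`³ patch around the voxel across all training subjects (T1 capped at
   `t_max`).  The curve is tabulated at `m` points; synthesis is the
   lookup `S_x = M_x[⌈m·t/t_max⌉]`.  In single-tissue patches the curve is
   near-constant, so a T1-hypointense lesion is still synthesised as
   healthy WM.  A monotone histogram-matching transfer function (median of
   per-subject quantile maps) restores the contrast that kernel smoothing
   compresses.  Synthetic WM within 15 mm of the ventricles is capped at a
   healthy-WM level so that benign "bands and caps" present in healthy
   training data are not reproduced.  The residual `L_SYN = F − S` is the
   first abnormality map.
3. **Voxel-wise intensity model** (`flair_model`).  A two-component 1-D
   Gaussian mixture per voxel, EM-fitted to the nonzero FLAIR intensities
   pooled from a `b`³ patch across training subjects (one tissue, or two
   at boundaries).  The abnormality map `L_FLAIR` is the negative log
   mixture density at the observed intensity, shifted so the most ordinary
   scored voxel sits at 0, and exactly 0 below the normalised intensity
   1000 so only *hyper*-intensity is flagged.  A raw-density variant is
   available (`mode="density"`).
4. **One-class fusion** (`fusion`).  Per brain voxel the 3-vector
   `[L_SYN, L_FLAIR, atlas]` is routed to a WM or GM one-class SVM (RBF
   kernel) by the larger tissue probability; voxels with
   `wm_prob + gm_prob < 0.5` are excluded.  Each classifier trains on
   50,000 vectors sampled from healthy training subjects (voxels under
   one-voxel-dilated lesion masks removed first) with training outlier
   fractions ν_WM = 0.05 and ν_GM = 0.003.  A voxel's score is its
   distance beyond the decision boundary (0 for inliers), assembled into
   `L_SVM`.
5. **Dense-CRF binarisation** (`crf`).  A fully connected two-label Potts
   CRF over the volume with a spatial smoothness kernel (σ_α) and an
   intensity-sensitive appearance kernel (σ_β, σ_γ), inferred by mean
   field; the binary mask is the per-voxel argmax.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `m` | 100 | – | curve evaluation points per voxel |
| `t_max` | 1500 | norm. units | T1 cap before regression |
| `h` | 50 | norm. units | kernel-regression bandwidth (~t_max/30: smooth curves that keep the GM peak) |
| `a`, `b` | 5 | voxels | training patch edges (synthesis, GMM) |
| ν_WM, ν_GM | 0.05, 0.003 | – | one-class training outlier fractions |
| `n_samples` | 50,000 | – | training points per classifier |
| `gamma` | 0.2 | – | RBF width on IQR-scaled features (see below) |
| `w1`, `w2` | 1, 8 | – | CRF smoothness / appearance weights |
| σ_α, σ_β | 3 | mm | CRF spatial kernel widths |
| σ_γ | 2.5 | 8-bit-scaled units | CRF intensity width (normalised intensity × 255/2000) |
| `tau_quantile` | 0.90 | – | CRF unary temperature = this quantile of positive training scores |

## Synthetic phantoms

The study cohort is emulated by concentric-shell phantoms: a CSF core
("ventricles"), a WM shell and a GM rim on a 48³ 1 mm lattice, with
per-class Gaussian intensities (T1: WM bright / GM darker / CSF dark;
FLAIR: GM brightest / WM middle / CSF suppressed), partial-volume Gaussian
smoothing, and additive scanner noise.  Lesions are hard-edged spheres
placed in the WM, FLAIR-hyperintense (+0.30 on an order-one raw scale,
≈ +390 normalised units) and T1-hypointense (−0.15), passed through the
same partial-volume smoothing so boundary voxels carry intermediate
contrast and exercise the CRF boundary placement.  Tissue probability maps
emulate a T1-driven segmenter: smoothed hard labels, deliberately degraded
inside lesions (WM 0.45 / GM 0.50) because lesion tissue looks GM-like on
T1 — without this no voxel-probability filter could be lesion-load
invariant.  Healthy subjects optionally carry periventricular "bands and
caps" (+0.15 in a 2-voxel shell).  Band prevalence is 0.6 of healthy
subjects: benign periventricular brightening is common in ageing cohorts
but not universal, and a one-class model must see both periventricular
states during training — with bands in *every* subject the band-free state
is itself novel ("too healthy for its location") and is flagged as
abnormal.  The atlas for healthy cohorts is the analytic prior
`exp(−d/τ)` of ventricle distance (τ = 5 mm), mimicking periventricular
predominance; cohorts with truth masks use their voxel-wise mean.

What the phantoms do **not** emulate: cortical folding and anatomical
variability (the geometry is identical across subjects, so registration
error is absent), MR physics (no bias fields, ringing, eddy-current
distortion, or slice-thickness partial volume), multi-protocol contrast
differences, and non-WMH pathology (lacunes, microbleeds, perivascular
spaces).  Passing tests therefore demonstrate the correctness of the
per-stage algorithms and the end-to-end signal path under the stated
statistical structure; they do not certify performance on clinical data,
where segmentation quality is additionally limited by registration and
artefact robustness.

## Numerical choices

- **Binned bank fits.**  Fitting 110k voxel-wise models on pooled patches
  is made tractable by histogram binning: the synthesis bank bins T1 into
  150 bins over [0, t_max] (width 10 units vs h = 50) so all kernel sums
  become two matrix products; the GMM bank runs weighted EM over 200
  FLAIR-intensity bins (EM on intensities quantised to bin centres),
  vectorised across voxels with an active set and per-sample convergence
  tolerance (|Δll| < tol·n).  The exact estimators (`kernel_regress`,
  `em_fit_two_component`) remain the reference implementations and the
  test suite checks the binned fits against them.
- **Fusion score scale.**  One-class SVM decision values scale with the
  dual budget ν·n, so WM and GM scores are divided by it before fusion —
  otherwise the two routes differ ~17× in scale and no single unary
  temperature fits both.
- **Fusion kernel width.**  The RBF width is fixed at γ = 0.2 on
  IQR-scaled features rather than matched to the sample variance
  (γ ≈ 0.6).  With the variance-matched width the decision value reaches
  its floor ≈2.5 IQR outside the healthy cloud, so moderately and
  extremely abnormal voxels score identically and the fused map is
  near-binary; the wider kernel keeps scores grading abnormality out to
  ~5+ IQR, which is what lets the CRF place lesion boundaries.  The
  trained-outlier fraction still tracks ν closely (0.0500/0.0030 at
  n = 50,000; solver tolerance 1e-4).
- **CRF kernel normalisation.**  Pairwise kernels are divided by their
  mean row mass (clamped ≥ 1), making `w1`/`w2` penalties per
  average-neighbourhood disagreement: an unnormalised 3 mm Gaussian
  couples each voxel to hundreds of others and any weight ≥ 1 collapses
  small lesions into the majority label.  The normaliser is a per-instance
  constant, so the model stays a valid dense Potts energy shared by mean
  field, the exhaustive oracle and the graph-cut oracle.
- **CRF inference back ends.**  Volumes ≤ 4096 voxels use the exact dense
  kernel matrix; larger volumes use spatially truncated (3σ) separable
  convolutions plus a sampled bilateral grid for the appearance kernel.
  The exact MAP is available at any size via max-flow/min-cut (the binary
  Potts energy with non-negative weights is submodular; capacities are
  scaled to integers by 1e6), cross-checked against exhaustive enumeration
  on ≤12-voxel instances.
- **Unary bridge.**  `p_lesion = 1 − exp(−s/τ)` clipped to
  [1e-6, 1−1e-6], with τ the 90th percentile of positive training scores.
- **Periventricular cap value.**  The scalar median of training FLAIR over
  WM voxels in the ≤15 mm shell.  A per-voxel across-subject mean would
  include the band brightening the cap exists to suppress (bands sit at
  fixed locations); the pooled median is robust to the thin band shell.
- **95% interval.**  The normalisation's outlier trim uses the empirical
  2.5–97.5 percentile interval (distribution-free); a mean ± 1.96 SD
  variant is exposed (`interval="sd"`).
- **Degenerate inputs.**  All-identical or <8-sample EM pools return both
  components at the sample mean with σ at the floor (1 unit); synthesis
  patches pooling no brain voxel get an all-zero sentinel curve and
  synthesise 0; empty-mask metric conventions are Dice 1 (both empty) /
  Dice 0 with missing surface distances (one empty).
- **Ties and ordering.**  Mixture components are reported sorted by mean;
  the Bland–Altman mean-difference test is a two-sided one-sample t-test;
  lesion connected components use 26-connectivity and surfaces are
  6-connected boundary voxels with distances between voxel centres.

## Known limitations

- Mean-field inference matches the exact MAP in the operating regime
  (decisive score-derived unaries; piecewise-smooth intensities) but can
  settle in higher-energy consensus states when unaries are weakly
  informative and pairwise terms dominate; the graph-cut MAP is available
  where exactness matters.
- The one-class formulation flags *any* departure from the training
  distribution, including "too-healthy" configurations (see band
  prevalence above); training cohorts must span the healthy variability
  of the population.
- Hypointensity detection (lacunar cavities) is out of scope: the
  intensity model hard-zeros below the 1000 fixed point by design.
- The demo study uses 20 training / 10 test subjects at 48³ with 2–4 mm
  lesions; these sizes keep a full train/segment/evaluate cycle around
  five minutes on one CPU while leaving every stage's statistics
  (patch pools of 2500, 50,000-point classifiers) at their full defaults.
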