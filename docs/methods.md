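# Methods

## The feature panel

All features are computed from a 3D SUV volume (body-weight standardized
uptake values, unitless) and a binary lesion mask on the identical grid;
masks are never resampled, and spacing may be anisotropic (the clinical
range emulated here is 3.4×3.4×2.0 to 4.3×4.3×5.0 mm, default
3.5×3.5×3.4 mm). Let {xᵢ} be the n lesion-voxel SUVs and v the voxel
volume in ml (dx·dy·dz/1000).

**Standard metrics.** Max and Min are extrema; Mean is the arithmetic
mean; MTV = n·v (ml); TLG = Mean·MTV (ml). Peak is the largest mean over a
1 cm³ sphere (radius (3000/4π)^⅓ ≈ 6.2035 mm): every lesion-voxel center
is a candidate center, membership is voxel-center-in-sphere in physical
mm, spheres may extend past the lesion but are clipped at the image
boundary (the mean is taken over in-grid members only, implemented as a
ratio of two box-filter correlations).

**Distributional features.** Std is the population (divide-by-n) standard
deviation and RMS = √(mean of squares), so RMS² = Mean² + Std² holds
exactly and is tested. Quartiles use linear interpolation between order
statistics. Upper Adjacent is the boxplot upper whisker end: the largest
observation ≤ Q3 + 1.5·IQR. The grayscale quarters split [Min, Max] into
four equal bins, half-open except the last; Qk Distribution is the percent
of lesion voxels in bin k (summing to 100) and Glycolysis Qk is
Σ xᵢ·v over bin k (summing to TLG). A degenerate range (Max = Min) puts
every voxel in the first quarter — a fixed, documented convention chosen
so constant lesions are handled deterministically.

**Rim features.** The rim is built by `width` iterations (default 2) of
binary dilation with the 6-connected face-adjacency structuring element,
minus the lesion; this equals the set of voxels at city-block distance
1..width from the lesion (verified exhaustively in tests) and is clipped
at the image boundary. "Two voxels wide" is interpreted in voxel space,
not mm, matching the voxel-denominated definition of the feature; the
structuring element is exposed (`connectivity=3` gives the
26-neighborhood) because the upstream tooling does not pin it down. RA is
the arithmetic mean SUV over the rim. SAM is computed over the measurement
region A = lesion ∪ rim with the rim mean as the background estimate:

    SAM = Σ_{v∈A} SUV(v)·v − RA·V(A)   (ml)

The exact region A used by the original SAM tooling is not published; the
lesion-plus-rim choice is the natural one given that the rim is the only
auxiliary region the pipeline constructs, and it yields the algebraic
identities the tests assert (flat field → 0; uniform lesion L over uniform
rim B → (L−B)·V_lesion). This interpretation is the panel's main free
choice and is recorded here deliberately.

## Normalization and change

All SUV-based features are divided by the mean SUV of a liver reference
region (mask or scalar; automatic liver detection is out of scope). MTV
and the Q1–Q4 Distribution percentages are dimensionless in intensity and
are left unchanged. Normalization is a separate pass after raw extraction
so both raw and normalized tables can be produced. SAM is computed raw
first, then divided by the liver mean. Change features are
ΔQIF = QIF(t₀) − QIF(t₁) on normalized features (raw-on-raw differencing
is allowed but mixing states is an error); subjects with a complete
response have no t₁ vector and hence no Δ row.

## Survival screening

DFS is months from treatment to recurrence or death, right-censored at
last follow-up. Each feature is divided by its sample SD (n−1 denominator,
complete cases for that feature) and fitted alone in a Cox
proportional-hazards model with the Efron tie approximation (the default
of the R `survival` toolchain this analysis style mirrors; lifelines uses
the same). Reported per feature: HR = exp(β̂) per SD, 95% Wald CI on the
log-hazard scale, two-sided Wald p, and Harrell's c index of the fitted
risk score on the same data (no cross-validation — the naive in-sample
estimate). BH FDR is adjusted across exactly the screened family (the 22
baseline features and the 22 change features separately), with a 10%
significance threshold. Kaplan–Meier tertiles cut at the 33.3/66.7
percentiles with ties going to the lower group. Non-convergent fits
(monotone likelihood) raise with the feature named; they are never
silently clipped. Formatted tables print HR/CI to 2 decimals and
p/FDR/c to 3, mirroring the conventional printed layout.

## Synthetic data

`make_phantom` renders a hot lesion sphere and a disjoint uniform liver
sphere on a uniform background, with uniform, Gaussian-blurred or
radial-gradient lesion profiles and optional additive Gaussian noise
(clipped at 0). For the uniform noise-free profile the whole panel has
closed forms (Mean = Max = Min = L, RA = B, SAM = (L−B)·MTV, liver mean
exact), which the tests assert exactly; MTV carries voxelization error
bounded by one voxel shell and converging as spacing shrinks. The blurred
profile exists to demonstrate mechanically that RA responds to edge
gradients; no physical acquisition realism (PSF, reconstruction, noise
texture) is claimed, so passing tests say nothing about scanner effects.

`make_cohort` draws the 22 features (and optionally 22 Δ features for a
residual-lesion subset) from multivariate normals with exchangeable
correlation ρ = 0.3, then generates event times from an exponential
proportional-hazards model, hazard = λ₀·exp(Σ βₖzₖ) with the *true*
standardized features, and independent exponential censoring. Subjects
without Δ features contribute 0 to Δ terms of the linear predictor — the
population-average hazard — which keeps the generator well-defined when a
change feature drives risk but only a subset has change data. Default
rates λ₀ = 0.011/month and λc = 0.0145/month target ≈43% events, the
profile of a 58-subject cohort with 25 DFS events; `make_paper_like_cohort`
fixes n = 58 with 25 residual-lesion subjects and puts β = ln 1.95 per SD
on ΔRA. It is an end-to-end smoke-test input, not a numeric reproduction
of any real cohort. One `numpy` Generator seeded explicitly drives all
randomness; every stochastic test states its replicate count.

## Numerical and design choices

- Double precision throughout; identities are asserted at 1e-9 relative
  (1e-12 for pure arithmetic oracles).
- Harrell's c uses the standard comparable-pair rule (shorter time must be
  an event; risk ties count ½) and equals an O(n²) enumeration oracle
  exactly on every tested cohort; cohorts with no comparable pair raise.
- BH re-adjustment of already-adjusted values is *not* a fixed point in
  general; the tests assert the true monotonicity properties instead.
- Problem sizes in tests and the acceptance script (e.g. 200 recovery
  replicates at n = 500, 2000 null cohorts at n = 60, 1000 random
  phantoms at ~10³ voxels) were chosen as the smallest sizes at which the
  Monte-Carlo bands quoted in the assertions are comfortably stable.

## Limitations

- Segmentation, DICOM ingestion, decay correction, scan registration and
  automatic liver detection are out of scope; inputs are SUV volumes with
  masks (NRRD/NIfTI) or per-subject CSV tables.
- The published-cohort reproduction requires the study's per-subject
  supplementary CSV, which is not redistributed here; without it the
  synthetic/property surface carries the validation.
- The c index is in-sample; no optimism correction is attempted.
- Texture/shape radiomics beyond the 22-feature panel, multivariable or
  clinically adjusted models, and the normalized SAM variant are
  deliberately not implemented.
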