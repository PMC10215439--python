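# Methods

## Scope and model

`thrombomap` post-processes near-wall hemodynamics on abdominal aortic
aneurysm (AAA) surfaces. Its inputs are the products a segmentation +
CFD workflow would hand over: a triangulated luminal surface, an outer
intraluminal-thrombus (ILT) surface in the same frame, and a per-vertex
wall-shear-stress (WSS) vector time series τ(t) (Pa) over one cardiac
cycle of period T. The flow solve itself is out of scope; a synthetic
generator with closed-form ground truth stands in for it (below).

Per-vertex indices, with n the outward unit surface normal and
τ̄ = (1/T)∫₀ᵀ τ dt the cycle-mean vector:

- **TAWSS** = (1/T)∫₀ᵀ ‖τ‖ dt  (Pa)
- **OSI** = ½(1 − ‖τ̄‖/TAWSS) ∈ [0, 0.5]
- **RRT** = 1/((1 − 2·OSI)·TAWSS) = 1/‖τ̄‖  (Pa⁻¹)
- **ECAP** = OSI/TAWSS  (Pa⁻¹)
- **TransWSS** = (1/T)∫₀ᵀ |τ·(n × ê)| dt with ê = τ̄/‖τ̄‖  (Pa)
- **NTransWSS** = TransWSS / max over the region of interest

The RRT identity 1/‖τ̄‖ holds algebraically and is enforced in tests to
1e-9; it is the strongest internal consistency check the index set
admits.

## Quadrature

All cycle integrals use periodic trapezoidal quadrature: samples at
strictly increasing times t₀ … t_{K−1} ∈ [0, T) are closed by wrapping
t₀ + T, so the weights sum exactly to T and non-uniform sampling is
handled without special cases. For band-limited integrands the rule
converges spectrally; 360 uniform samples reproduce closed-form index
values to well under 0.1%, and doubling K moves band-limited indices by
less than 1e-3 relative (tested).

## Degenerate vertices and data quality

Division-free policy: vertices with TAWSS below `tawss_floor` (default
1e-6 Pa) or with (1 − 2·OSI)·TAWSS below it have RRT/ECAP capped at
`cap` (default 1e6 Pa⁻¹) and are flagged, never NaN'd, so regional
order statistics remain computable. Where ‖τ̄‖ < `mean_floor` (1e-9 Pa)
the mean direction — hence TransWSS — is undefined; TransWSS is set to
0 and flagged. WSS vectors are projected onto the local tangent plane
before the transverse decomposition; a tangency residual
max_t |τ·n|/‖τ‖ above 5% raises a data-quality warning but does not
abort. Vertex normals, when not supplied, are area-weighted averages of
incident face normals (consistent outward winding assumed; the closed
synthetic tube has positive signed volume by construction).

## ILT thickness

Thickness at each lumen vertex is the minimum Euclidean distance to the
outer ILT surface minus a constant wall mask (default 2 mm, the
conventional assumed AAA wall thickness; in vivo estimates span roughly
1–4.3 mm, so the mask is configurable), clamped at zero — sub-mask
distances are ILT-free wall by construction. The default measures to
the outer vertex set with a k-d tree; an exact point-to-triangle mode
(vectorized triangle distance with provably exact centroid-ball
pruning) removes discretisation bias on coarse outer meshes.

Known estimator bias: minimum distance is a *shortcut* metric. Where
the true thickness field has steep tangential gradients, the nearest
outer point is not the one reached along the local normal, and the
estimate undershoots — on the synthetic Gaussian bump's flanks by up to
~15%, while flat or smoothly-varying regions (including the bump apex,
where the recovery is exact to <2%) are unaffected. This bias is a
property of the minimum-distance definition itself, not of the
implementation, and applies equally to thickness maps produced this way
from segmented patient surfaces. No registration is performed; surfaces
must share one frame in mm.

## Regionalization and statistics

The region of interest (ROI) is the aneurysm sac, selected by axial
bounds or an explicit vertex label set (the parent vessel and iliacs
are masked out). Within it:

- **ILT / ILT-free**: thickness above/below `ilt_presence_min`
  (0.1 mm — sub-voxel thickness at 1–2 mm CT slice spacing is
  segmentation noise, so it does not count as thrombus). These two
  partition the ROI exactly.
- **Thickest / thinnest ILT**: thickness ≥ 1.7 cm and 0 < t ≤ 0.15 cm
  by default (1.5 / 0.3 cm offered as the common alternatives);
  disjoint by construction since thresholds are validated as ordered.
  Thickness is mm internally; these cm thresholds are converted by an
  explicit factor of 10 so units never mix silently.
- **Favorable-hemodynamics maps**: TAWSS < 0.4 Pa, OSI > 0.2 (alt 0.3),
  ECAP > 1.4 Pa⁻¹, RRT > 10 Pa⁻¹ — the literature cut-offs for
  conditions favorable to thrombus deposition — plus their conjunction.
- **Flow nature**: an octant classification {low,high}TAWSS ×
  {low,high}OSI × {low,high}NTransWSS; the NTransWSS split (0.5) has no
  literature value and is echoed in every report.

Summaries use median, linear-interpolation (type-7) quartiles, IQR and
the 10th/90th percentiles — the convention is stated because medians
and whiskers depend on it. Co-localization is quantified by Spearman's
rank correlation of each index against ILT thickness over the ILT
vertex set, with average ranks for ties and a two-sided large-sample t
approximation for p. Spatial autocorrelation between neighbouring
vertices is deliberately ignored — vertices are not independent
samples, so p-values are optimistic; they should be read as descriptive,
and the reports say so implicitly by carrying n (vertex counts in the
thousands).

## Synthetic generator

The generator emulates the study inputs with known answers:

- **Geometry**: a surface of revolution R(z) = R₀ + ΔR·exp(−(z−z₀)²/2σ²)
  — a 2 cm diameter infrarenal aorta (R₀ = 10 mm) dilated to ~4.4 cm
  (ΔR = 12 mm, σ = 15 mm) over a 12 cm segment; analytic outward
  normals; vertices with R − R₀ > 0.05·ΔR tagged "sac".
- **WSS field**: τ(t) = (m + a·cos 2πt/T)·ê_ax + b·sin(2πt/T)·ê_circ in
  each vertex's tangent frame. Closed forms: b = 0, m ≥ a gives
  TAWSS = m, OSI = 0, TransWSS = 0; m = b = 0 gives TAWSS = (2/π)a,
  OSI = 0.5; a = 0, m > 0 gives TransWSS = (2/π)b. The default scenario
  lets m fall as (R₀/R)² (mass conservation: near-wall shear drops as
  the lumen widens), places a purely oscillatory patch (m = 0,
  a = 0.5 Pa) on the posterior sac and a transverse patch
  (b = 0.3 Pa) anteriorly — so low TAWSS, high OSI and thick ILT
  co-locate the way they do in thrombus-laden aneurysms. In the smooth
  blending rings between regimes no elementary closed form exists;
  ground-truth arrays are NaN there and tests compare only where
  defined (~75–80% of vertices at defaults).
- **ILT**: the outer surface is the lumen displaced along its normals by
  g(v) + 2 mm wall, with g a Gaussian cap (peak 19 mm) on the distal
  posterior sac, wide enough (σ_z = 20 mm, σ_θ = 1.4 rad) to stay in
  the smooth regime where minimum-distance recovery is reliable.
- **Inflow**: a triphasic velocity waveform (systolic peak at 15% of the
  cycle, diastolic reverse lobe, small late forward lobe) as an explicit
  10-harmonic Fourier series — synthetic by design, emulating the shape
  of in vivo infrarenal waveforms, not any measured cohort average.

What passing on this generator shows: the index algebra, quadrature,
distance fields, masks and statistics are correct. What it does not
show: realism of any particular patient's hemodynamics — there are no
vortices, jets or bifurcations, and WSS is prescribed, not solved.

## Grid convergence

`gci` implements the Richardson-based three-grid method with safety
factor 1.25: observed order p = ln|(f_c−f_m)/(f_m−f_f)|/ln r (requires
monotone convergence; oscillatory triplets are rejected rather than
silently reported), GCI_fine = 1.25·|(f_m−f_f)/f_f|/(rᵖ−1)·100%. The
asymptotic-range ratio is computed from absolute consecutive errors,
|f_c−f_m|/(rᵖ|f_m−f_f|), which equals 1 identically for an exact
power-law sequence; f_f = 0 falls back to the absolute error form.

## Numerical and design choices

- Fourier fitting of waveforms is linear least squares on the
  trigonometric design matrix, not an FFT, so non-uniform sampling
  works; a ≤K-harmonic signal at >2K+1 uniform samples is recovered to
  machine precision.
- All coordinates are mm in one frame; thresholds stated in cm are
  converted explicitly.
- Reports embed the full effective configuration and are byte-
  deterministic given identical inputs and config.
- Problem sizes in the test suite: meshes of ~200–11 000 vertices and
  24–3000 time samples, chosen so the full suite runs in seconds while
  still crossing the resolutions where quadrature and discretisation
  errors are visible.

## Limitations

- Minimum-distance thickness undershoots on steep ILT flanks (above).
- The OSI/RRT caps make degenerate-vertex values conventional, not
  physical; downstream statistics should exclude flagged vertices when
  the flagged fraction is non-negligible.
- p-values ignore spatial autocorrelation.
- The synthetic WSS family cannot represent fields whose direction
  rotates through more than the two fixed tangent axes; multidirectional
  metrics beyond TransWSS are out of scope.
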