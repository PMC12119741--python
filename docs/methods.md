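# Methods

This note documents the models behind `garange`, the defaults and why they
were chosen, what the synthetic data do and do not emulate, and the numerical
decisions a user extending the package should know about.

## Positron transport and the range kernel

Positron range is modelled in two stages:

1. **Emission spectrum.** β⁺ kinetic energies follow the allowed Fermi shape
   N(E) ∝ F(Z,E)·p·E_tot·(E_max − E)², with the nonrelativistic positron
   Coulomb factor F(Z,E) = 2πη/(1 − e^(−2πη)), η = −Zα/β (repulsive sign:
   slow positrons are suppressed). Z is the *daughter* atomic number
   (Zn, Z = 30 for Ga-68; O, Z = 8 for F-18); endpoints are 1899 keV and
   635 keV. Sampling is inverse-CDF on a 4096-point tabulation. The sampled
   means (≈843.5 keV for Ga-68, ≈251 keV for F-18) agree with the published
   mean emission energies to well under 1%.
2. **Transport.** Each energy is converted to a continuous-slowing-down
   (CSDA) path length in water with the empirical Katz–Penfold relation
   R[g/cm²] = 0.412·E^(1.265 − 0.0954·ln E) (E in MeV; linear ramp below its
   10 keV validity floor), at water density 1 g/cm³. Positron tracks are
   tortuous, so the net 3D displacement is the path length times a **detour
   factor**, default 0.65 — the literature ratio of net displacement to path
   length clusters around 0.6–0.7, and 0.65 reproduces the accepted mean
   Ga-68 annihilation displacement in water of ≈2.2 mm (and ≈0.42 mm for
   F-18). Directions are isotropic. This deliberately skips condensed-history
   electron transport: the kernel needs the correct displacement *statistics*
   at voxel resolution, not track structure.

Kernels are histograms of 10⁶ displacement vectors (default) on the
reconstruction voxel grid, truncated at ±10 mm per axis (≈4.5× the Ga-68 mean
range; a warning fires if < 99.9% of the mass is covered), symmetrized by
averaging with the point reflection (removing odd-order binning bias of the
nearest-voxel assignment), and normalized to unit sum so convolution
conserves total activity. The kernel is tissue-independent (water), matching
the correction being studied; tissue-dependent kernels are out of scope.

## Digital patients

The cohort generator produces seeded, bit-reproducible patients. Anatomy is
a stylized torso defined in fractions of the field of view: a soft-tissue
body ellipsoid whose axial semi-axis exceeds the grid (a truncated whole-body
scan, so every slice contains tissue), a liver, a low-density lung region and
a dense bone structure running through all slices. Defaults:

| quantity | value | rationale |
|---|---|---|
| grid | 64 × 64 × 16 at 2.73 × 2.73 × 2.80 mm | clinical voxel size; desk-scale axial truncation |
| weights | uniform 51–118 kg | the emulated cohort's reported range |
| dosing | 1.5 MBq/kg | the emulated clinical protocol |
| background SUV | soft 1.0, liver 5.0, lung 0.3, bone 0.5 | reproduces the two background regimes (high-uptake liver vs low background); placeholders, not clinical values |
| lesion SUV | uniform 4–20 | placeholder; lesion-to-background ratios are unreported for the emulated cohort |
| densities | soft 1.0, liver 1.05, lung 0.3, bone 1.9 g/cm³ ×μ_water = 0.0096/mm | standard 511 keV values |

Lesions are spheres (size classes are volume-defined; shapes are not
specified by the delineation protocol), placed by sampling a center among all
voxels whose distance-transform depth inside the host tissue exceeds the
lesion radius plus a 1.5 mm margin; an explicit placement error names the
lesion when no such voxel exists. The default plan gives each patient three
lesions (soft, bone, lung) cycling small/medium, with every third patient
carrying a **large lung lesion** (20–26 cm³): the large class must stay above
10 cm³ *after* 50% isocontour delineation, which shrinks a sphere's measured
volume by roughly one voxel shell plus a noise-peak effect, and only the lung
region of the stylized torso can host such a lesion together with its
≥10 cm³ same-tissue background shell. Large lesions are the rarest class, as
in clinical cohorts. On single-slice grids (2D test mode) lesions become
disks and placement constrains in-plane only.

SUV bookkeeping: activity[kBq/mL] = SUV × injected[kBq]/weight[g] at
1 g/mL, so reconstructed concentrations convert back to SUV exactly.

## Acquisition model

Per axial slice, a 2D parallel-beam system (default 60 angles over [0, π),
bins = in-plane grid, bin spacing = pixel spacing) stands in for the
cylindrical scanner; time-of-flight and the full 3D system matrix are out of
scope. The projector rotates each slice with **push (scatter) bilinear
interpolation** materialized as a sparse matrix and sums along an axis:
interior columns sum to exactly 1, so projection conserves mass, and the
backprojector is the exact sparse transpose — the composite operator passes
an adjoint identity test at ~1e-15. Detector resolution is a radial Gaussian
(default FWHM 4 mm — a configuration default, not a measured scanner value),
zero-padded and therefore self-adjoint. Attenuation uses survival factors
exp(−∫μ dl) computed with the same line integrals.

Expected data are ȳ = c_z·[PSF(A(k ∗ activity))·att] + r, with the per-slice
calibration c_z set so slice-summed expected true counts equal `count_scale`
(default 2×10⁵ — chosen, together with β, so reconstructed liver COV falls in
the realistic 5–15% band) and a flat background r totalling
`background_fraction`·count_scale (default 0.1) standing in for
randoms + scatter; the same r is supplied to reconstruction as a known
additive mean, so background estimation is out of scope. One Poisson
realization per (patient, seed).

## Reconstruction

BSREM over ordered angle subsets (default 6, bit-reversal ordering, 20 full
passes, relaxation α_n = 1/(1 + 0.05·n)):

x ← x + α_n (x/s_m)[A_mᵀ(y_m/ȳ_m) − s_m − (β/M)∇R(x)],  ȳ = A x + r,

with non-negativity clipping. With β = 0, one subset and no relaxation the
update is algebraically classical MLEM; the test suite verifies voxelwise
agreement with an independently coded dense-matrix MLEM at 1e-10 and
monotone Poisson log-likelihood. The penalty is the relative difference
prior R(x) = Σ_pairs w_jk (x_j−x_k)²/(x_j+x_k+γ|x_j−x_k|+ε), γ = 2,
26-neighbor 1/distance weights, ε = 1e-9, counted **once per unordered
pair**; its gradient is analytic and validated against central differences.
The vendor's exact prior constants are unpublished; this is the published
RDP family.

**β scale.** Clinical β values (700 non-PRC / 600 PRC) live on a vendor
scale that does not transfer to this operator normalization. The package's
β_nonPRC = 0.08 default puts liver COV near 10% (inside the observed 5–15%
band); the PRC arm's β is then **noise-matched**: bisection (liver COV is
monotonically non-increasing in β) until the median liver COV over the first
3 patients matches the non-PRC reference median within 5% relative. The
clinical 700→600 ratio is retained only as the intuition that PRC needs less
regularization — the in-loop convolution itself suppresses noise — and the
matched β indeed comes out ≈0.04–0.05. PRC placement: the kernel multiplies
the image before forward projection and the backprojection is followed by
the kernel adjoint; because kernels are symmetrized this equals the kernel
itself, but the adjoint flag is exposed.

Stopping is a fixed iteration budget shared by both arms (no early
stopping), so arm comparisons are at matched iterations.

## Quantification

Lesion VOIs follow the two-arm comparison protocol: delineation on the PRC
image with a 50% isocontour of the regional maximum (inclusive ≥, no
background correction), keeping the 26-connected component containing the
maximum; the *identical voxel set* is then mapped to the non-PRC image, so
metric differences cannot come from re-segmentation. The search region
seeding a delineation is the ground-truth lesion label dilated by 2 voxels —
a documented surrogate for the physician's lesion identification, which is
not reproducible. Per patient and tissue at most the 5 largest lesions are
analyzed (ties by higher SUVmax, then lower index). Size classes: small
≤ 1 cm³ < medium ≤ 10 cm³ < large, computed from the delineated VOI volume.

Background VOIs take host-tissue voxels at ≥ 5 mm from the lesion border
(distance transform), nearest first, until ≥ 10 cm³. SUVpeak is the highest
mean over 1 mL spheres centered at VOI voxel centers (voxel-center-in-sphere
membership; spheres may extend beyond the VOI, and voxels outside the grid
are excluded from the mean). CNR = (lesion mean − background mean)/
background SD and liver COV = SD/mean·100% both use the sample SD (n−1).
The liver noise sphere (10 mm radius) sits at the deepest point of the
lesion-free liver label — deterministic and never near lesions.

## Statistics

Percentage changes 100·(PRC − nonPRC)/nonPRC are tested with the Wilcoxon
signed-rank test: zeros dropped, mid-ranks for ties, **exact** p for n ≤ 25
via dynamic programming over doubled integer ranks (equivalent to full 2ⁿ
sign enumeration, verified bit-for-bit against a brute-force oracle), normal
approximation with continuity and tie corrections above; two-sided by
doubling the smaller tail (the emulated analysis does not state sidedness).
Normality screening uses the D'Agostino–Pearson K² omnibus test
(scipy's `normaltest`). Binomial tests are exact tail sums in rational
arithmetic; two-sided by the minimum-likelihood method.

Gwet's AC1 for two categories: pa = mean over items of Σ_q r_iq(r_iq−1)/
(r(r−1)), pe = Σ_q π_q(1−π_q)/(Q−1), AC1 = (pa−pe)/(1−pe), variance by
Gwet's closed-form linearization estimator, 95% CI = AC1 ± 1.96·SE clipped
to [−1, 1], interpreted on the Altman scale (Poor ≤ 0.20 < Fair ≤ 0.40 <
Moderate ≤ 0.60 < Good ≤ 0.80 < Very Good). AC1 is used instead of Cohen-
style kappa because the preference tables are highly prevalence-skewed; a
property test confirms AC1 ≥ mean pairwise kappa on seeded skewed tables.

The **synthetic readers** exist only to exercise this machinery: reader r
prefers category 1 ("PRC similar or better") with probability
σ(a_r + b_eff·effect + b_noise·noise), where effect is the patient's median
CNR change and noise the patient's liver-COV change. Four readers respond to
effect size; one smoothness-averse reader (negative b_noise, near-zero a)
mimics a deviating reviewer driven by per-patient noise fluctuations. They
model no perceptual psychology and validate nothing about human readers.

## What passing tests do and do not show

The synthetic study reproduces the *mechanism* and the *analysis chain*:
range blur simulated and corrected with the same kernel family, noise-matched
arms, identical-VOI quantification, and the full statistical layer. Passing
tests therefore show the pipeline's internal correctness and the qualitative
clinical pattern (positive ΔSUVmax/ΔCNR in every tissue stratum, small >
large, matched liver noise). They do **not** show clinical effect sizes: the
desk-scale study uses ~30 lesions, a 2D projector without ToF/scatter/
randoms physics, placeholder uptake levels, and simulation/reconstruction
share the same forward-model family (an inverse-crime setting), so
percentage changes here are larger than the few-percent clinical values.
The null control (no simulated blur, no correction) yields exactly zero
changes, confirming the effect is the correction, not the pipeline.

## Numerical choices and degenerate inputs

- Adjoint exactness: sparse-transpose backprojection; symmetric zero-padded
  convolutions (PSF, kernel) are self-adjoint; composite test at 1e-8.
- FFT-based kernel convolution clips the ~1e-16 negative ripple for
  non-negative inputs.
- EM limit behavior: on noiseless uniform-cylinder data the deep interior is
  quantitatively exact (mean to <0.1%) with RMS nonuniformity <1%, but edge
  ringing of a few percent persists near the rim at any iteration count —
  a discretization null-space of the desk-scale projector, not a bug; the
  corresponding test erodes the rim before asserting.
- Degenerate inputs raise explicit errors: empty VOIs, zero background SD,
  constant input to the normality test, all-zero Wilcoxon differences,
  unbracketed β matching, lesions that do not fit their host tissue.
- Study sizes: the default 10-patient study (64 × 64 × 16 grid, 60 angles,
  20 passes) was sized to make the full two-arm experiment, including β
  matching, a minutes-scale computation; a larger cohort or grid changes no
  code path.

## Known limitations

2D parallel-beam geometry (no ToF, no 3D system matrix); tissue-independent
kernel only; flat background instead of scatter/randoms modelling; spherical
lesions with uniform uptake; reconstruction shares the simulator's operator
family; reader model is a logistic toy. These bound what the package can say
about real scanners, not the correctness of the implemented methods.
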