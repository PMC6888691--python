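# Methods

## Phantom geometry (`npgeom`)

The phantom is a water sphere of volume *V* (default 50 µm³, radius
(3V/4π)^⅓ ≈ 2.285 µm) containing *N* identical core-shell nanoparticles
(default 191; 3 nm Au cores, 2 nm shells of Au or Pt). Centres are drawn
uniformly in the sphere shrunk by the particle outer radius and accepted
only if they do not overlap any placed particle (hard spheres, centre
distance > sum of outer radii), with a cap of 10⁵ attempts per particle —
at the default dilution the rejection rate is negligible, and the
resulting centre distribution is uniform (checked by a Kolmogorov–Smirnov
test of the radial CDF against r³/R³).

The particle count is a configuration input rather than a quantity
derived from the metal concentration. Converting the nominal
concentration (4.23 × 10⁻⁵ mol/L) with ~10³ atoms per 3 nm particle into
a 50 µm³ volume gives ≈ 1274 particles, not the 191 used in the reference
geometry; since the assumptions behind that reference number are not
reconstructible, the package exposes the converter
(`particles_from_concentration`, tested against its own closed form) and
defaults the pipeline to the literal 191.

## Synthetic energy-deposition generator (`tracks`)

The generator is parametric, not mechanistic: it emulates the *output* of
a track-structure transport calculation — a cloud of point energy
deposits labelled with the five electron processes in liquid water
(elastic, electronic excitation, vibrational excitation, ionization,
molecular attachment) — without transporting particles. Features modelled:

* **process mix** — labels are drawn from configurable relative weights.
  Defaults use reported per-run averages for ionization (5.37 × 10⁴),
  vibrational excitation (1.61 × 10⁵) and attachment (467); the elastic
  (2.7 × 10⁵) and electronic-excitation (2.4 × 10⁴) weights are
  order-of-magnitude transport values, expected to be set from config
  when they matter. No endpoint statistic depends on these defaults.
* **energy spectra** — per-process exponential with configurable means
  (ionization 25 eV, electronic excitation 10 eV, attachment 5 eV,
  vibrational 0.5 eV; elastic deposits exactly 0). These are
  order-of-magnitude placeholders; the strand-break threshold (8.22 eV)
  interacts only with the shape near the threshold, and all acceptance
  statistics are ratios that do not depend on the absolute spectrum.
* **dose closure** — events are generated until the cumulative deposited
  energy reaches `target_dose × water mass`; the final event is truncated
  so the realized total equals the target exactly. The field
  `background_event_density` is nominal provenance; the dose target
  governs the count.
* **nanoparticle proximity enhancement** — extra events are placed
  uniformly in a spherical annulus of configurable thickness (default
  20–25 nm) outside each particle surface, at a density of
  `enhancement_factor` (per shell material) times background. This
  uniform-annulus form is a declared modelling choice: it captures the
  locally increased secondary-electron fluence near a metal particle
  without asserting any particular radial profile.

Dose accounting classifies deposits into water / shells / cores by exact
distance to every particle (chunked; a nearest-centre shortcut would
misclassify for mixed particle sizes) and uses bulk densities
1000 / 19300 / 21450 kg·m⁻³ for water / Au / Pt. Absolute region doses
and absolute process counts of the reference transport calculations are
*not* reproduction targets of this package — they depend on cross-section
physics outside its scope; the generator provides structure, the scored
statistics of interest are ratios.

## Sensitive-volume geometry (`dnageom`)

Default geometry is a procedural B-DNA duplex: backbone site *k* of
strand *s* at azimuth `k·36° + s·180°` on a 0.94 nm helix, rising 0.34 nm
per bp (10 bp/turn). Each site is a sphere of capture radius 0.35 nm by
default (sugar-phosphate moiety scale; a config knob that acceptance
statistics do not depend on). A PDB reader is provided for scoring real
structures: one site per residue at the centroid of its backbone atoms
(P/O5'/C5'/C4'/C3'/O3' for nucleotides, N/CA/C/O for proteins, Å
converted to nm), the first two chains mapping positionally to strands 0
and 1. The procedural duplex is the default because SSB/DSB semantics
require well-defined strands and base-pair indices, which a protein
surrogate structure only supplies by convention.

## Strand-break scoring (`damage`)

Deposits are assigned to the nearest sensitive site when within its
capture radius (KD-tree; each deposit counted at most once) and site
energies accumulated. An SSB is called where accumulated energy is
**strictly greater than** 8.22 eV. DSBs are found by a single sweep over
SSBs sorted by base-pair index: a growing cluster absorbs the next SSB if
its gap to the cluster's **last** member is ≤ 10 bp (inclusive; ties on
opposite strands are gap 0), and a closed cluster is one DSB iff it
contains both strands. The sweep is proven equivalent to an independent
union-find oracle linking *all* pairs within the gap threshold (the
"≤ 10 bp" convention is inclusive; gap 11 does not link). Multiple DSBs
are never counted inside one cluster. Yields are normalized as
`n_DSB / dose / (length/10⁹)` (Gy⁻¹·Gbp⁻¹).

Note a saturation property of the one-cluster-one-DSB rule: when breaks
are dense (mean SSB spacing comparable to the 10 bp threshold) clusters
merge and the DSB count *falls* with increasing damage density. Scoring
studies should stay in the sparse regime; the desk-scale pipeline
defaults below do.

## Gel quantification and forward model (`gelquant`)

Analysis chain per lane: `total = 1.47·S + R + L` (staining factor
correcting the weaker ethidium-bromide uptake of the supercoiled form),
`L' = L/total`, and the Poisson inversion `μ = L'/(1−L')` breaks per
plasmid. The dose response is an unweighted least-squares line of μ
against dose pooling all replicate lanes, intercept left free (native
plasmid can carry background damage); per-dose SDs across replicates are
retained for error bars. Uncertainties on AF and OH% use first-order
propagation of the two slope standard errors.

The forward generator inverts this chain exactly: `l = μ/(1+μ)` with
`μ = m_DSB·D`, supercoiled survival `s = (1−l)·exp(−m_SSB·D)` (the
exponential SSB channel only populates the S/R bands; SSB yields are not
an endpoint), measured bands `(s/1.47, r, l)` plus independent Gaussian
noise of configurable SD on each band, truncated at zero (an all-zero
lane is redrawn — an unmeasurable lane would be re-run in practice).
With zero noise, analysis of synthesized lanes returns the generating
yield to 10⁻¹⁰ relative, and the staining factor cancels whenever the
same value is used on both sides.

The zero-truncation makes low-dose linear bands slightly biased upward,
which depresses the recovered slope by ~3% at the default noise
(SD 0.01 on band intensities at the control yield 17.47 × 10⁻⁵
breaks·plasmid⁻¹·Gy⁻¹, doses 0–500 Gy, triplicates). This is a property
of the declared noise model, not a fitting defect; recovery stays within
3 standard errors of truth in ≥ 95% of realizations.

The scavenger decomposition computes OH% = 100·(m − m_DMSO)/m per
condition. For reference, published yields give 83.3% (control) and
84.9% (Au), matching their printed values; the bimetallic cell computes
to 87.5% from its printed yields although 86 ± 1 was printed — likely a
per-replicate averaging difference — and is therefore not treated as a
reproducible statistic.

## XPS shell thickness (`xpsshell`)

`T = L_film·cos(θ)·ln(1 + R)` with the angle accepted in degrees. The
default attenuation length is 1.02 nm (Au-4f photoelectrons attenuated by
the shell), which with θ = 0° and R = 3 gives 1.414 → 1.4 nm; the Pt
value (1.05 nm → 1.456 nm) is available via config. R enters the
logarithm as a dimensionless parameter set to the mean-core-diameter
value 3.

## Pipeline (`pipeline`, `cli`)

`run_simulation_arm` builds one phantom and scores two passes with
**common random numbers**: a control pass with the enhancement switched
off and an NP pass with the configured shell-material enhancement.
Sharing the event seed makes identical configurations give AF exactly 0
and reduces the variance of the enhancement contrast. DSB counts are
pooled over `n_repeats` independent event seeds before rates and AF are
formed. `run_experimental_arm` accepts, per condition (control, NP and
the optional DMSO pair), either a lane CSV or a generating truth for the
synthetic gel, fits all arms and reports AFs and OH effects with
propagated uncertainties. Both runners emit a manifest (seeds, config
digest, package version) sufficient to re-run bit-identically.

### Desk-scale simulation geometry

Full-scale event statistics (micrometre phantom, ~10⁷ histories) are a
transport-code workload. The packaged study conditions
(`desk_simulation_config`) scale the geometry down while preserving its
structure: a 40 nm-radius water sphere with 12 core-shell particles
around a 120 bp duplex at the centre (capture radius 0.5 nm), scored at a
local nanodosimetric dose of 2.5 × 10⁵ Gy per repeat × 12 repeats
(~10⁵ deposits per repeat). The dose per repeat is deliberately low
enough to keep breaks sparse on the duplex (see the saturation note
above). At these conditions the control arm scores ~8 DSBs per run and
the enhanced arm reliably more, so the qualitative contrast AF > 0 under
near-particle enhancement is testable in seconds. What passing these
tests shows is that the scoring chain responds correctly to spatial
structure in the deposit field; it does not validate absolute DSB rates
against experiment — those depend on transport physics this package
deliberately replaces with a parametric surrogate.

## Numerical choices and limitations

* All randomness flows through `numpy.random.default_rng` with explicit
  integer seeds; reports are bit-reproducible for fixed seeds.
* Deposit-to-site assignment breaks distance ties by KD-tree order;
  capture spheres of neighbouring sites overlap only if the capture
  radius exceeds half the inter-site spacing (not the case at defaults).
* `fit_dose_response` requires ≥ 3 distinct doses; an all-linear lane
  (L' = 1) is rejected as out of the Poisson inversion's domain.
* Indirect (radical-diffusion) chemistry, base damage, repair kinetics,
  Auger cascades and photon transport are out of scope; the DMSO
  decomposition quantifies the radical contribution purely from yields.
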