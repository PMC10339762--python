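# Methods

`hsqcscreen` implements the analysis chain of a protein-observed
¹H-¹⁵N HSQC fragment screen: pooled-library triage, chemical shift
perturbation (CSP) mapping, dissociation-constant fitting, and
dual-ligand additivity analysis.  Because no experimental spectra are
distributed with such screens, the package also contains a synthetic-data
generator that reproduces the statistical structure the analysis assumes;
it is first-class, tested code, and the packaged campaign runs entirely
on it.

## Binding model

All simulation and fitting uses the exact single-site ligand-depletion
equilibrium.  For total protein *P* (μM, converted to mM internally),
total ligand *L* (mM) and dissociation constant *K*d (mM), the fraction
of bound protein is

    f = (b − sqrt(b² − 4·P·L)) / (2·P),   b = P + L + Kd,

evaluated in the cancellation-free form `f = 2L / (b + sqrt(b² − 4PL))`
so the dilute-protein limit `f → L/(L+Kd)` is reached without loss of
precision.  The quadratic is used everywhere, including the ligand-excess
regime, because it is exact and costs nothing.

Fast exchange is assumed throughout: each amide peak appears at the
population-weighted average position and moves continuously with ligand
concentration (the regime evidenced by continuous peak movement in
grayscale titration overlays).  No intermediate/slow-exchange broadening,
relaxation or temperature effects are modelled.

Two-ligand samples are solved from the coupled mass balance
(`dual_species`).  In `independent_sites` mode the species are P, PA, PB
and the ternary complex PAB with site-independent affinities and no
cooperativity — the simplest model consistent with simultaneous binding;
free-ligand balances are root-solved with Brent's method to machine
precision (the independent-site system decouples per ligand, and a test
cross-checks the solver against the single-ligand quadratic).  In
`competitive` mode a single shared site gives species P, PA, PB only,
solved via the free-protein balance.

## Synthetic data: what it emulates, and what it does not

The generator emulates:

* a ~75-residue assigned backbone fingerprint (plus one side-chain NH
  entry, `Q69sc`), with peak positions rejection-sampled to keep a
  minimum scaled separation of 0.25 ppm and heights uniform in 0.8–1.3;
* fast-exchange peak movement under the depletion isotherm, with each
  fragment of a pooled sample contributing independently (appropriate
  for weak binders in ligand excess);
* Gaussian positional noise, sd 0.004 ppm (¹H) and 0.02 ppm (¹⁵N) per
  axis — about a fifth of a linewidth, the typical digital precision of
  peak picking; no figure is published, so this is the package's choice;
* the study conditions: 50 μM protein (the methods value; one figure
  caption says 100 μM — 50 is the default and both are configurable),
  500 μM per fragment in 12-plex/3-plex/single screening rounds,
  validation titrations 0–6 mM (7 points), dual titrations to 3 mM,
  and the 1–100 mM sulfotyrosine ladder.

The packaged fixture (`make_ccl28_fixture`) is a 2,678-fragment library
in 224 twelve-plexes with ground truth: 13 specific binders (4 in the
N-loop/helix sub-site, 8 in the sulfotyrosine cleft, 1 bridging both,
with Kd from 0.6 to 8 mM including the two published affinities of
0.85 mM and 6.6 mM), 8 non-specific actives (Kd 25–35 mM, perturbing a
shared set of surface residues away from either sub-site, unsaturable at
6 mM), and 4 pH artifacts (saturable shifts restricted to the three
histidines).  Residues named in the study (C11, S20, R21, L24, E25, K49,
R50, R52, I53, C54, M66, Q69/Q69sc, K83) are present with matching
one-letter codes; shift magnitudes and directions are synthesized per
seed.  Within a sub-site, binders share per-residue shift *directions*
(as chemically similar ligands in one pocket do), the shared-cleft
residues S20/R21/L24 move in opposite directions for the two sub-sites,
and alternate residues are forced ¹H-dominant so every perturbation
pattern is visible on both axes.

What the generator does **not** emulate — and hence what passing tests
do not demonstrate about real data: chemical-structure realism, exchange
broadening and peak-intensity loss, overlapping/crowded regions beyond
the enforced minimum separation, baseline and phasing artifacts, and
assignment errors.  The screen-recovery results are statements about the
pipeline's behaviour under its own stated noise model.

## Triage

Spectra are rendered from peak lists with separable Gaussian lineshapes
(default FWHM 0.02/0.15 ppm on a 512×256 amide-region grid; axes stored
ascending in ppm).  For triage the pipeline renders with deliberately
broadened linewidths (0.05/0.5 ppm) on a 512×512 grid: the default ¹⁵N
sampling (0.137 ppm/point) undersamples a 0.15 ppm line, making rendered
heights alias with sub-pixel peak position, and broadening — the digital
analogue of the apodisation applied to real screening spectra — makes
the difference-intensity statistic stable and pushes positional-noise
lobes far below real-shift lobes.

DIA (difference intensity analysis) is the summed |intensity| of the
(sample − reference) difference spectrum over grid nodes above a noise
floor.  Rendered synthetic spectra carry no additive grid noise, so the
region-standard-deviation floor estimator returns zero on them; the
pipeline instead floors at 0.35 × the median apo peak height, chosen so
that positional-noise difference lobes (≤ ~0.2 × height under the triage
linewidths) fall below it while genuine shift lobes (≥ ~0.45 × height)
survive.

PCA operates on flattened, mean-centred grids with the component sign
fixed (largest-magnitude loading made positive) for bit-stable
coordinates; k-means uses k-means++ seeding with 10 restarts and labels
renumbered so cluster 1 holds the reference sample.  The published
presentation uses a 2-component embedding with k = 3, and those remain
the operation defaults; the *pipeline* clusters in 5 components with
k = 12 because the fixture contains four distinct perturbation classes
(two sub-sites, non-specific, pH) plus a large inert blob — two
components cannot represent all hit directions, and too few centroids
leave weak-binder satellites attached to the reference cluster.

A sample is flagged when it clusters away from the reference **and** its
DIA exceeds a threshold.  The reference-cluster-median × multiplier rule
remains the `flag_hits` default, but the inert DIA distribution is
heavy-tailed and its median collapses in small deconvolution rounds, so
the pipeline uses an absolute threshold with a physical meaning: 0.8 ×
the DIA of one fully-displaced median-height peak (computed from the
rendering configuration; a hit must displace at least the better part of
one amide peak).  Under the default conditions this sits at ≈45 DIA
units, between the inert tail (≈37) and the weakest active plex (≈62);
the three-round screen then recovers all 25 planted actives with zero
false positives across 15 fixture seeds.  Flags are advisory; every
threshold is a configuration knob.

Deconvolution splits each flagged plex into next-round groups in
manifest order (12 → 3 → 1), dropping fragments from unflagged plexes.

## CSP analysis

The combined CSP is `sqrt(Δδ_H² + (0.2·Δδ_N)²)` — the community-standard
¹⁵N down-weighting; the same scaled metric is the distance for peak
tracking.  Tracking is globally greedy nearest-neighbour: candidate
pairs are accepted in ascending distance until a cutoff (`max_jump`,
default 0.25 scaled ppm), beyond which a reference peak is reported lost
rather than mismatched; titrations are tracked point-to-point in
concentration order.  The sulfotyrosine ladder is coarse (1 → 5 mM with
~1 ppm total shifts), so the hotspot analysis raises `max_jump` to 0.45.
A known limitation of greedy chains: a peak whose trajectory passes
within noise distance of a static peak at some ladder step can have its
chain captured by the bystander; fine-stepped ladders (validation,
duals) are essentially immune, coarse ladders are not, and the packaged
campaign's deterministic seeds track cleanly.

Significance is mean + 2·SD of the combined CSP over all tracked
residues (computing a profile with fewer than 5 tracked residues is
refused); hotspots use the absolute > 0.6 ppm rule.  Sub-site assignment
is a majority vote of significant residues over disjoint site
definitions, with "both" requiring at least two significant residues in
each site and ties broken toward the larger summed CSP.

## Kd fitting and classification

The fit target is the combined CSP magnitude versus total ligand (the
standard presentation; signed-component fitting would be an extension).
In the default global mode one Kd is shared across residues and each
residue's maximal shift is profiled out analytically
(`dmax_r = Σyf / Σf²`), reducing the search to one dimension over
log₁₀ Kd in 1 μM–1000 mM: a dense log-spaced scan (≥203 points,
subsuming the 7 nominal multi-starts) followed by bounded Brent
refinement.  Noiseless round-trips recover generating Kd values to
<0.1% with RSS < 1e-12; under default noise the median relative error
over 200 replicates (Kd log-uniform 0.1–3 mM) is below 15%, degrading
for Kd well beyond the 6 mM top point — which is why published estimates
beyond ~10 mM are soft.  The standard error comes from the curvature of
the objective at the optimum; an estimate pinned at a search bound is
flagged poorly determined.  Per-residue mode fits each responding
residue separately (flat residues are excluded — Kd is unidentifiable on
a zero curve) and reports the median.

Classification rules, in order: significant residues exclusively
histidine → pH artifact; Kd at a bound, or saturation fraction at the
top point < 0.2 (an invented, configurable cutoff), or no significant
residue in either sub-site → non-specific; otherwise specific.  An empty
significant set is inconclusive.

## Dual-titration additivity

Simultaneous sub-site occupancy predicts that the peak displacement with
both ligands present equals the vector sum of the single-ligand
displacements, independent of addition order.  The verdict is evaluated
at the endpoint (both ligands at 3 mM), mirroring the serial-addition
experiment; full-trajectory residuals are reported but not used.  The
apo reference for dual shift vectors is the average of the two single
titrations' apo points (the dual series themselves start with the fixed
ligand already present; their first point is labelled by matching against
the fixed ligand's single-titration endpoint, whose labels chain back to
apo).  The aggregate residual is the RMS scaled-space mismatch between
observed and predicted shifts over residues significant in either single
profile; the order discrepancy is the RMS distance between the two dual
endpoints.  Exact additivity holds in independent-sites mode only up to
ligand depletion coupling, which at 50 μM protein versus 3 mM ligands is
below 1e-6 ppm — asserted by a dedicated noiseless test, not assumed.
With the default tolerance of 0.02 ppm (≈5× the ¹H noise, against a
noise floor of ≈0.011 ppm in the residual statistic), independent-site
fixtures read "simultaneous" and shared-site fixtures with Kd ≤ 2 mM
read "competitive" across 20 noise realisations of each.

## Determinism and problem sizes

Every stage draws randomness from seeds derived deterministically from
the single configured seed (NumPy `SeedSequence`); reruns are
byte-identical, including the JSON summary.  The full packaged campaign
— 224 + ~90 + ~75 rendered spectra across three rounds, 25 validation
titrations, sub-site assignment, the sulfotyrosine ladder and two dual
analyses — completes in well under a minute on one CPU at the default
512×512 triage grid; the test suite adds a 200-replicate Kd-recovery
sweep and 40 dual analyses and stays in the tens of seconds.

## Known limitations

* Greedy chain tracking can swap peaks on coarse ladders (above).
* The mean+2SD significance rule is self-referential: when a large
  fraction of residues is perturbed with similar magnitude, the
  threshold rises toward the perturbed level; the fixture keeps
  per-fragment perturbation sets at 3–8 of ~76 residues, where the rule
  has ~30% headroom.
* The DIA hit threshold and the non-specific saturation cutoff are
  invented, documented knobs — the published workflow couples these
  statistics with manual inspection, for which no surrogate is provided.
* `estimate_noise_floor` measures additive grid noise only; on purely
  positional-noise simulations it returns zero and a height-based floor
  must be used instead.
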