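# hsqcscreen

Protein-observed 2D NMR fragment screening analysis: pooled-library
triage, chemical shift perturbation (CSP) mapping, dissociation-constant
fitting, and dual-ligand additivity — with a first-class synthetic-data
generator modelled on a fragment screen against the mucosal chemokine
CCL28.

## Who this is for

Fragment-based drug discovery by ¹H-¹⁵N HSQC NMR screens thousands of
small compounds in pools against an isotope-labelled protein and reads
binding off amide peak movement.  This package implements that analysis
chain end to end for anyone building or benchmarking such a screen:

1. **Triage** — difference spectra against a solvent-only reference,
   a difference-intensity statistic (DIA), PCA of whole spectra and
   k-means clustering flag perturbed pools; flagged 12-plexes are
   deconvoluted to 3-plexes and singles.
2. **Validation** — candidate singles are titrated (0–6 mM), peaks are
   tracked through the series, and the combined CSP
   `Δδ = sqrt(Δδ_H² + (0.2·Δδ_N)²)` is fit with the exact single-site
   ligand-depletion isotherm

       Δδ(L) = Δδmax · (b − sqrt(b² − 4·P·L)) / (2·P),  b = P + L + Kd,

   with one global Kd and per-residue Δδmax.  Candidates are classified
   specific / non-specific / pH artifact (perturbations restricted to
   histidines).
3. **Mapping** — residues with CSP > mean + 2·SD assign each hit to a
   binding sub-site; an absolute 0.6 ppm cutoff maps the sulfotyrosine
   hotspot.
4. **Dual titrations** — two fragments occupy adjoining sub-sites
   simultaneously when the two-ligand peak displacement equals the
   vector sum of the single-ligand displacements, regardless of the
   order of addition; competition for a shared site suppresses both.

Because screens of this kind publish counts and affinities rather than
spectra, the `synth` module generates the full campaign synthetically —
fast-exchange peak movement under ligand depletion, pooled mixtures,
noise, and a 2,678-fragment library with ground-truth labels — so every
stage is testable against known truth.  See `docs/methods.md` for the
models, parameter choices and limitations.

## Worked example

Run the packaged campaign (a ~30 s, one-CPU job) and summarise it:

```sh
$ hsqcscreen run-all --seed 1 --outdir out/
{
 "n_screened": 2678,
 "n_candidates": 25,
 "candidate_rate_percent": 0.9,
 "n_hits": 13,
 "n_nonhits": 12
}
$ hsqcscreen report --summary out/summary.json
fragments screened : 2678
candidates         : 25 (0.9%)
validated hits     : 13
non-hits           : 12
site split         : {'both': 1, 'site1_Nloop_helix': 4, 'site2_sY_cleft': 8, 'unassigned': 0}
sTyr hotspots      : ['C11', 'I53', 'K49', 'K83', 'R50', 'R52']
dual (competitive): ['SPB07625', 'SY2-03'] -> competitive
dual (independent_sites): ['SPB07625', 'CC10501'] -> simultaneous
```

Reading the numbers: the three-round triage reduces 2,678 fragments to
25 single-compound candidates (a 0.9% candidate rate); titration
validation keeps 13 as specific, saturable, site-localised binders and
rejects 12 (8 non-specific, 4 pH artifacts).  CSP significance splits
the hits 4 / 8 / 1 between the N-loop/helix cleft, the sulfotyrosine
recognition cleft, and both.  The sulfotyrosine probe perturbs exactly
the six residues above 0.6 ppm that outline the receptor-binding
hotspot.  The dual titration of the independent-site pair
SPB07625 + CC10501 is verdict "simultaneous" (shift vectors add,
order-independent), while a shared-site pair reads "competitive".
`out/` also contains per-round triage TSVs, a per-candidate Kd table
(`validation.tsv` — e.g. SPB07625 fits at ≈0.92 mM and CC10501 at
≈6.4 mM under default noise) and a config snapshot.

Library use mirrors the CLI:

```python
from hsqcscreen import PipelineConfig, run_pipeline
summary = run_pipeline(PipelineConfig(seed=1))
```

Individual stages (`read_peak_list`, `render_spectrum`, `dia_statistic`,
`track_peaks`, `csp_profile`, `fit_kd`, `analyze_dual`, ...) are plain
functions over documented dataclasses; `fit-kd`, `csp` and `dual`
subcommands consume Sparky-style `.list` peak lists plus a small YAML
titration schedule.

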