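# replichore

Replication-dynamics modelling and marker-frequency analysis (MFA) for
circular bacterial chromosomes carrying one or more replication origins.

The package models how a population of *E. coli*-like cells replicates a
circular chromosome when several origins fire simultaneously and polar
*ter*/Tus fork traps are present, and processes binned sequencing read
counts the way MFA studies do. It provides:

- **`genome_model`** — circular coordinate arithmetic (arc distances and
  midpoints, genetic-map minutes ↔ bp) and a validated annotation model,
  with a bundled MG1655 fixture: oriC plus the ectopic origins oriX/oriY/oriZ,
  the ten polar ter sites A–J, the seven rrn operons, the ribosomal-protein
  gene cluster and three IS5 elements.
- **`replication_engine`** — per-bin fork-arrival times for a *cell class*
  (a set of synchronously firing origins, trap on/off, constant fork speed,
  optional head-on slowdown inside highly transcribed features), computed
  analytically and by an independent time-stepped event simulator used as
  its oracle; conversion to marker-frequency profiles `2^(-t/tau)` and
  linear mixtures of classes.
- **`mfa_pipeline`** — stationary-phase-control normalisation, circular
  (periodic) tricube degree-2 LOESS at a 10 % span, and feature calling:
  global low point, origin peaks, ter-labelled steps, free discontinuities,
  relative origin activities, plus masking of depletion-prone loci.
- **`rearrangements`** — inversion and tandem-duplication operators on maps
  (flipping contained ter polarities and transcription directions),
  profile projection between rearranged and reference coordinates, and
  continuity scoring that identifies which candidate rearrangement restores
  a discontinuous read-depth profile.
- **`mixture_fit`** — non-negative least-squares deconvolution of
  subpopulation origin usage from an observed profile, with optional tau
  grid search and non-identifiability flagging.
- **`synthetic_data`** — named scenario bundles (counts + control + truth
  record) with Poisson/negative-binomial noise and the protein-occupancy
  depletion artifact, so the whole pipeline is testable offline.

## CLI

A single entry point `replichore` exposes the stages:

```sh
# synthetic dataset for a named scenario
replichore synth --scenario oriC_oriX --seed 1 --outdir out/

# normalise against the stationary control and smooth
replichore profile --sample out/sample.tsv --control out/control.tsv \
    --out out/smoothed.tsv --raw-out out/normalized.tsv

# call low point, peaks, ter steps, discontinuities
replichore features --profile out/smoothed.tsv \
    --raw-profile out/normalized.tsv --out out/features.json

# model profile for an arbitrary origin set
replichore simulate --origins oriC,oriX --no-tus --out model.tsv

# score rearrangement candidates (IS-element breakpoint pairs)
replichore invert --profile out/normalized.tsv --search-is --out cands.json

# fit subpopulation weights
replichore fit --profile out/smoothed.tsv \
    --classes oriC+oriX,oriC+oriZ,oriC+oriX+oriZ --out fit.json

# or everything end to end
replichore report --scenario triple_origin_mix --seed 1 --outdir out/
```

Scenarios: `wild_type`, `oriC_oriX`, `oriC_oriX_dtus`, `doriC_oriX_inv820`,
`doriC_oriX_rpo_inv895`, `triple_origin_mix`, `dup175`. All commands accept
`--config <yaml>`; explicit flags override config keys, and outputs carry
provenance headers (version, config hash, seed).

## Conventions

Coordinates are 0-based bp on a circular chromosome, intervals half-open;
"clockwise" means increasing coordinate. A ter site's `blocks` field names
the travel direction that is arrested. Profiles are per-bin relative copy
numbers with an explicit validity mask; counts and profiles travel as
headered TSV/bedGraph text.
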