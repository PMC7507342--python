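# Methods

This note documents the models, parameter choices and numerical
conventions behind `lanthiseek`, and what the synthetic-data tests do and
do not demonstrate.

## Mining scheme

Candidates pass four independent predicates, applied as a funnel only for
reporting convenience (the final set is order-independent):

* **Length** — 40–80 aa inclusive. Class I precursor peptides (leader +
  core) fall in this band; both boundaries are kept inclusive.
* **Motif** — `SxSLCTPGCxTG`, `x` = any residue, unanchored, overlapping
  matches allowed. Matching is case-insensitive; an `X` (unknown residue)
  in the data never satisfies a fixed position, but is accepted at an `x`
  slot. If a record has several hits, all are reported and the leftmost
  anchors core extraction (a deterministic tie-break).
* **Gene context** — a supporting neighbor must lie within ±10 gene
  indices on the same contig (offsets 1..10 each side; the candidate
  itself never supports; strand is ignored — gene order is the only
  spatial information modeled). A neighbor supports if its product
  description contains one of the Lan keywords (lanthionine, dehydratase,
  cyclase, lantibiotic, LanB/LanC/LanM, NisB/NisC; case-insensitive), or
  if its sequence locally aligns to a packaged Lan reference at ≥30%
  identity over ≥50% of the reference. The annotation judgment behind
  "LanBC-like or LanM-like" is not standardized anywhere, so both routes
  and both thresholds are explicit, configurable parameters. The packaged
  references are synthetic stand-ins (so labelled in the FASTA); users
  mining real data should substitute genuine NisB/NisC/LanM sequences.
* **Novelty** — best identity against the known-core database must be
  < 0.90 (configurable). Identity is the *ordered-match identity*: the
  maximum number of residue matches achievable in a global alignment with
  free gaps (the longest-common-subsequence count `L`), normalized by the
  induced alignment length, `L / (|a| + |b| − L)`. This measure is
  parameter-free (no substitution matrix or gap penalty to justify),
  equals 1.0 exactly on identical sequences, and is implementation-
  independent — any optimal aligner recovers the same value, which is what
  the test oracle exploits. It is slightly more permissive than a
  penalized global alignment; for the exclusion of near-identical known
  cores at a 0.90 threshold the two agree. The packaged database holds
  the nisin A and nisin Z cores; it is deliberately minimal and meant to
  be extended with a user FASTA for real campaigns.

## Precursor design

* **Core extraction** starts `offset` residues before the motif (default
  2, clamped at residue 1), because the motif begins at residue 3 of the
  nisin core. Applied to the packaged core listings themselves, this rule
  reproduces every one of them; it remains a heuristic for arbitrary
  precursors and the offset is configurable.
* **Protease-site adjustment**: cores starting `IT`/`VT` are untouched; a
  core starting `T` gets a single `I` (minimal insertion reaching `IT-`);
  everything else gets `IT`. The operation is idempotent and reproduces
  all five footnoted listings in the packaged table from their
  de-prefixed forms.
* **Leader fusion** concatenates the 23-aa canonical nisin (NisA) leader
  with the adjusted core. The leader sequence is an external constant —
  it is not derivable from the packaged tables — and every entry point
  accepts an override.
* **Saturation library**: positions 4, 12, 15, 24, 29 of the nisin Z core
  (1-based on the core, leader excluded), each independently drawn from
  all 20 residues (true saturation; the wild-type residue is a legal
  draw). Sampling is without replacement over distinct variants, the
  unmutated core is excluded from the output, and the feasible output
  size is therefore 20^5 − 1. Amino-acid-level saturation is modeled;
  codon-level artifacts (e.g. spontaneous off-target mutations observed
  in real libraries) are not.

## Mass model

Monoisotopic throughout. Residue masses are computed from elemental
monoisotopic masses (H 1.00782503207, C 12, N 14.0030740048,
O 15.99491461956, S 31.97207100), so derived peptide masses agree with
independent residue-sum implementations at < 1e-6 Da. Dehydration removes
one water (18.0105647 Da) and is bounded by the Ser+Thr count; one NEM
adduct adds C6H7NO2 (125.0476785 Da, reported nominally as +125) and is
bounded by the Cys count; thioether cyclization is mass-neutral, so the
ring count is #Cys − observed adducts. `m/z = (M + z·1.00727646688)/z`.
This choice of constants reproduces the reference [M+5H]5+ anchor of
eightfold-dehydrated nisin Z (666.71312) to 3e-7.

Peak assignment matches each observed peak to the species with the
smallest absolute ppm error within a tolerance (default 10 ppm,
appropriate for Orbitrap-class accuracy; configurable). Ties break toward
the lower dehydration count; two species within tolerance at < 1e-6 ppm
separation flag the assignment ambiguous. Observed dehydration counts are
rendered as `a-b (k)` for contiguous runs, comma-separated otherwise,
`(k)` when nothing is assigned, with k the Ser+Thr capacity. N-terminal
dehydro-residue degradation and oxidation adducts are not modeled, nor
are isotope envelopes, MS2 fragments or retention times.

## Screening

Round 1 ranks raw OD600 within each plate (the reported protocol compares
within a batch; per-plate is the default and the conservative reading) and
keeps the k lowest test wells (default 5, exact rather than
"approximately"), ties broken in row-major well order (A1..H12). Round 2
computes ΔOD600 against the arithmetic mean of the plate's own control
wells (aggregation method unstated in practice; mean is the default) and
calls strictly negative ΔOD600 a hit — a mutant must beat the nisin
control, not tie it. MIC is the literal rule: lowest concentration with
OD600 ≤ threshold (default 0.05); a non-monotone series warns but still
returns the literal answer.

## Calibration

The zone curve is ordinary least squares of zone diameter on
log10(activity) — the standard agar-diffusion linearization; an identity
transform is available. The valid range is the span of standards
(5–1000 IU/mL defaults); inverse predictions outside it are flagged, with
1e-9 relative slack at the boundaries so round-trips at the edge
standards do not spuriously flag. Horizontal/vertical caliper readings
are averaged when both are given. The internal-standard curve fits
concentration against the analyte/IS ratio by OLS (unweighted — no
weighting scheme is standard here) and flags quantities outside the
10–20 000 ppb linear range. 40 IU = 1 µg nisin converts activity to mass.

## Synthetic data

The generators define the test conditions; all randomness flows from one
`numpy` `default_rng(seed)` per call, making outputs byte-identical under
a fixed spec.

* **Proteome** (defaults: 3 plants, 200 decoys, seed 42): each plant is a
  random leader fused to a published analog core (RL6, RL8, bagelicin),
  placed at gene index 10 of its own 21-gene contig with Lan neighbors at
  the specified offsets (products carry Lan keywords and sequences are
  slices of the packaged references, so both context routes fire). Decoy
  proportions are 50% random protein (i.i.d. uniform over the 20 amino
  acids, lengths 30–120 — the simplest null, which cannot contain the
  10-fixed-position motif except at negligible rates; enforced at
  generation), 20% motif-without-context, 20% context-without-motif and
  10% replanted nisin Z cores with full context (which must fall exactly
  at the novelty stage). Gene coordinates are ordinal per contig — the
  context rule is gene-count based, so base-pair coordinates add nothing.
  The generator does not emulate the composition of a real protein
  database: mining sensitivity/specificity on it demonstrates that the
  filters implement their definitions, not that they would achieve any
  particular precision on NCBI-scale data.
* **Peak lists**: one peak per species at the theoretical m/z perturbed
  by Normal(0, ppm_noise_sd), plus uniform decoy peaks over a 10%-padded
  m/z range. No isotope structure or chromatographic dimension.
* **Plates**: Gaussian OD noise truncated at 0 (an unvalidated but
  testable noise model); control wells A1–A3 of each plate; inhibitor
  wells have expectation baseline − effect. 32 plates × 93 test wells
  reproduce the ~3000-mutant screening scale.

## Problem sizes and determinism

The default test proteome (323 records) mines in about a second; the
end-to-end pipeline test uses 60 decoys and 2 plates and runs in under
two seconds; property suites use up to 300 hypothesis examples,
derandomized. The full suite completes in well under a minute on one
CPU. Pipeline stage seeds are derived from the run seed by fixed small
offsets, keeping every derived seed a small integer.

## Known limitations

* The novelty and similarity measures are pragmatic stand-ins for curated
  database annotation; thresholds (0.90 identity; 30%/50% similarity) are
  defaults to be tuned per campaign.
* The packaged Lan references are synthetic; similarity-route results on
  real data require real enzyme sequences.
* Core-boundary extraction assumes nisin-like motif placement; class II–IV
  precursors and HMM-based detection are out of scope.
* Activity figures in the pipeline dossier derive from a synthetic,
  noise-free zone curve; they demonstrate the calibration path, not a
  measured potency.
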