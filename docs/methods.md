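# Methods

This note documents the models, rules and numerical choices behind
`tmtquant`, and what its synthetic-data validation does and does not
establish.

## Identification model

**Search space.** Proteins are digested in silico with trypsin: cleavage
C-terminal to K or R, suppressed when the next residue is proline, with up
to three missed cleavages (both are the conventional settings for this
workflow). Peptides are deduplicated by sequence; a peptide occurring in
several proteins keeps all parent accessions (no parsimony — quantification
averages over the "protein subgroup", and proteins whose accepted peptide
sets are identical collapse to one representative accession, the
lexicographically smallest). Reversed copies of every target protein
(accession prefix `REV_`) are appended as decoys.

**Masses and modifications.** Standard monoisotopic residue masses; water
18.0105647 Da; proton 1.00727647 Da. Static modifications: the six-plex TMT
tag, +229.1629 Da, on every peptide N-terminus and every lysine, and
carbamidomethyl, +57.02146 Da, on every cysteine. Variable: methionine
oxidation, +15.9949 Da, enumerated over all site combinations up to two per
peptide (`SearchConfig.max_oxidations`; >2 oxidations per tryptic peptide
is rare enough to ignore and the cap bounds the combinatorics). Candidate
masses are restricted to 500–5000 Da. Mass arithmetic is additive and tested
to 1e−6 Da.

**Matching and scoring.** A spectrum's candidates are those whose
theoretical m/z at the spectrum charge (2 or 3) lies within ±25 ppm of the
observed precursor, found by binary search on the sorted candidate mass
list. The score is the fraction of the peptide's theoretical singly charged
b/y ions (2·(n−1) for length n) found in the spectrum within ±600 ppm; each
observed peak may satisfy at most one theoretical ion, consumed greedily in
ascending m/z. This deliberately replaces a search engine's
cross-correlation score: the contract tested here is identification
correctness on synthetic ladder spectra, not search-engine fidelity.
Length-1 peptides have no internal fragments and score 0 with a warning.
The best-scoring candidate per spectrum becomes the PSM; ties break by
smaller absolute precursor error, then sequence, and never by target/decoy
status (which would bias the FDR estimate).

**FDR control.** A single global sweep over descending PSM scores selects
the lowest score cutoff whose accepted set keeps
(#decoy PSMs)/(#target PSMs) below the nominal 0.01; tied scores are
accepted or rejected together. Decoys are then discarded and a protein
requires at least two distinct accepted spectra. The FDR is controlled at
PSM level with a protein evidence rule (whether the original workflow
filtered at PSM or protein level is not determinable; this is the
conventional reading of a DTASelect-style filter). Calibration is verified
on simulated target/decoy score mixtures: the mean realized false-discovery
proportion over 20 seeded replicates stays within 1.5× nominal.

## Quantification model

**Pairing.** An HCD scan pairs with the nearest preceding CID scan that has
the same precursor m/z within 1e−4 Th and no other CID scan in between; a
second HCD claiming the same CID is dropped with a warning. Reporter ions
only exist in the HCD scan; sequence ions only in the CID scan.

**Reporter extraction.** Canonical six-plex reporter m/z values
126.12773, 127.13108, 128.13443, 129.13779, 130.14114, 131.13818 (the
reagent's published monoisotopic values; ±20 ppm is ≈ ±0.0025 Th at m/z
126). Within each window the most intense peak wins, ties broken by smaller
absolute mass error; an empty window leaves the channel missing. The found
reporters are inserted into the paired CID spectrum at their canonical m/z,
preserving all CID peaks and m/z ordering.

**Aggregation and QC.** Channel means are arithmetic means over all of a
protein's quantifiable PSMs; a PSM missing any of the six channels is
excluded from *all* channels so the means stay comparable (missing-channel
policy chosen here; the alternative — per-channel means over available
PSMs — makes ratios depend on which channel happened to be missing). Group
means average the two duplicate channels. Duplicate-label variation is
|a−b|/((a+b)/2) per group; a protein is excluded when any group exceeds
0.30, or when a duplicate pair is all-zero (variation undefined). QC is
applied at protein level after aggregation. Contrasts are
log2(IR/sham) and log2(TALE/IR) of group means; no channel-loading
normalization is applied (none is part of the emulated workflow).

## Differential calling

Only proteins quantified *and* QC-passing in both independent replicate
sets enter; the two sets' log2 contrasts are averaged before thresholding
(averaging-then-calling, not per-set voting), and the evidence count is the
smaller spectrum count across sets. IR-related: mean log2(IR/sham) strictly
greater than +0.6 (up) or strictly less than −0.6 (down) with ≥2 spectra.
The TALE contrast has no separately stated rule in the emulated study; the
IR rule is reused, applied only among IR-related proteins, and this reuse
is flagged in the output summary. Thresholds are pure fold changes — no
p-values or multiple-testing control, by design.

## Synthetic-data generator

The generator states a world and the tests measure recovery in it.

* **Proteome.** Each protein is a concatenation of ≥5 tryptic "blocks":
  5–18 random non-K/R residues (never starting with P) terminated by K or
  R. Hence every protein has ≥4 cleavage sites, its zero-missed-cleavage
  digest is exactly the block list, and every block's TMT-labelled mass
  lies in [600, 4000] Da (worst case, an all-tryptophan 19-mer, is
  ~3954 Da), so every protein yields ≥3 quantifiable peptides. Lengths are
  clamped to [50, 500].
* **Ground truth.** round(frac_de_ir·n) proteins (default 0.2) get IR
  multipliers 2^(±effect_log2) (default effect 1.0; half up, half down,
  ties to up); round(frac_de_tale·n_ir) of *those* (default 0.5 —
  interpreted as a fraction of the IR-affected set, mirroring the study
  where TALE effects were assessed among IR-related proteins) additionally
  get TALE multipliers 2^(±effect_log2) relative to IR. Everything else is
  null (all multipliers equal).
* **Spectra.** Per selected peptide: one CID scan with the full singly
  charged b/y ladder at unit intensity (identification is exercised, not
  fragmentation realism), immediately followed by an HCD scan on the same
  precursor with exactly the six reporter peaks. Charge is 2 for masses
  ≤2400 Da, else 3. Reporter intensity = base × group multiplier ×
  duplicate factor × exp(N(0, noise_sigma²)). The base is log-uniform in
  [1e4, 1e6] per peptide, exercising averaging across unequal intensities.
  The duplicate factor is a per-protein, per-group lognormal offset
  (sigma = duplicate_sigma, default 0) applied to the second label,
  emulating systematic labelling differences. A qc_failure_frac of proteins
  (default 0) get one group's second channel scaled by 1.5, i.e. duplicate
  variation 0.4 at zero noise — reliably beyond the 0.30 QC cut.
* **Replicate sets.** Sets share the ground truth and QC-failure choices
  but re-draw all intensities from set-specific sub-seeds
  (`numpy.random.SeedSequence(seed, spawn_key=...)`); every draw is fixed
  by the single config seed, and outputs are byte-identical across reruns.

**What a green test establishes.** At zero noise the full pipeline recovers
every true label exactly, and at 10% noise it achieves ≥95% sensitivity
with ≤5% false discoveries over 20 seeds — i.e. the plumbing and the rules
are implemented correctly and the thresholds behave as designed under the
stated noise model. The generator does *not* emulate isotope envelopes,
channel cross-contamination (isotopic impurity), chimeric spectra,
retention-time structure, or fractionation, so these results say nothing
about performance on real LC-MS/MS data; defaults are stated assumptions,
not fits to any dataset (the emulated study reports neither spectral counts
nor intensity distributions).

## Numerical and degenerate-input choices

* ppm error is 1e6·(obs−theo)/theo everywhere; window membership is
  inclusive at the boundary.
* Precursor-window candidate lookup inverts the ppm inequality to a closed
  theoretical-mass interval and binary-searches it.
* All-decoy PSM input to the FDR filter yields an empty result, not an
  error; zero decoys yields FDR estimate 0 (all targets accepted).
* A protein with no complete-reporter PSM is dropped with a logged reason;
  zero group means flag the protein rather than producing infinities.
* The manifest hashes the full configuration (minus the output directory)
  and records stage counts; identical config + seed reproduce identical
  manifests and outputs.

## Known limitations

* The scorer is not a cross-correlation score; absolute score values are
  not comparable to any search engine's.
* Semi-tryptic peptides, isotope-error correction, charge states beyond
  2–3 and N-terminal methionine clipping are out of scope.
* Annotation summaries depend entirely on the user-supplied snapshot table;
  live ontology-database queries are deliberately not performed, so
  published category percentages can only be reproduced against the same
  snapshot.
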