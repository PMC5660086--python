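# Methods

This note records the models, conventions and numerical choices behind
`sumoremnant`, and what the synthetic-data tests do and do not demonstrate.

## Remnant model

A ubiquitin-like modifier is represented by its mature sequence, which must
end in the attachment diglycine (custom modifiers may relax this to a
warning). Conjugation is an isopeptide bond between the modifier's
C-terminal glycine and a substrate lysine ε-amine; because that bond
condenses one water exactly like a backbone bond, a remnant of sequence *r*
adds the plain residue-chain mass of *r* to the carrying peptide. The
remnant under a protease is the modifier suffix downstream of its
C-terminal-most cleavage site (the whole modifier if no site exists). Two
consequences follow directly and are property-tested: the remnant is always
a suffix, and any protease cutting after the modifier's antepenultimate
residue (but not after glycine) leaves exactly "GG" (+114.0429 Da
monoisotopic, reported to four decimals throughout).

Remnant identity for distinguishability grouping is compared by sequence,
not mass: leucine/isoleucine isobars would wrongly merge under mass
comparison. A mass mode (±1e-4 Da) is available for the MS-realistic view.

All masses are monoisotopic; residue masses come from the standard tables
(via pyteomics). No average-mass mode is provided. Fragment conventions:
b = prefix + H⁺, y = suffix + H₂O + H⁺, c = b + NH₃, z = y − NH₃ + H (the
ETD z-dot ion); stated here because z-ion nomenclature varies.

## Digestion

Coordinates are 1-based inclusive; "cleavage after position i" cuts between
i and i+1, and a cleave-after residue at the protein C-terminus counts as a
vacuous site. Built-in specificities:

- trypsin: after K/R, not before P, and *blocked by modification* — a
  remnant-bearing lysine is not a tryptic substrate. This blocking rule is
  what makes "which fully-tryptic peptide would have covered this modified
  site" well-posed (`peptide_covering_site`): its boundaries are the nearest
  unblocked cleavage sites or the protein termini. Sites in long K/R-free
  stretches yield very long covering peptides (e.g. 57 residues), sites in
  K/R-dense stretches very short ones (e.g. 6) — both poorly observable in
  a standard tryptic run, which is the motivation for the orthogonal
  protease.
- walp (wild-type α-lytic protease): after {A, S, T, V, L, I}. The enzyme
  prefers Thr in P1, also cuts after Ala/Ser/Val and Leu with some Ile, and
  rarely after Arg — hence R is excluded. The enzyme's true preference is a
  distribution, not a set; the set is a deliberate, user-configurable
  simplification, and custom specs load from a plain key-value file.
- nonspecific: a permissive cleave-after-everything spec used to emulate
  "no enzyme specificity" searches. Enumerating all substrings is
  combinatorially explosive and deliberately not done.

Missed cleavages join up to k+1 adjacent fully-cleaved fragments.
Semi-specific mode adds sub-peptides retaining at least one specific
terminus. Protein N-terminal Met is kept; `excise_nterm_met` is an explicit
preprocessing flag.

## PSM post-processing

**Heavy/light merging.** SILAC heavy searches report a remnant-bearing heavy
lysine as one composite delta (label 8.0142 + remnant 114.0429 =
122.0571 Da). Merging decomposes composite K modifications within 1e-3 Da
into explicit label + remnant annotations, normalizes plain-label lysines,
and passes light records through. A heavy K modification matching neither
pattern is *flagged*, never silently merged.

**FDR.** Decoys are reversed protein sequences (prefix `decoy_`). FDR at
score s is `#decoys ≥ s / max(1, #targets ≥ s)`; q-values are the running
minimum over decreasing score; decoys are counted before targets at tied
scores (conservative) and are never returned. Retained set: targets with
q ≤ threshold (default 0.01).

**Localization.** An Ascore/PhosphoRS-family binomial scheme rather than a
re-implementation of any specific external localizer (which the upstream
workflow treats as a black box with a 0.9 cut anyway). For each candidate
lysine the remnant is placed there; site-determining ions are the
theoretical fragments not shared by all placements; matches are counted in
the `peak_depth` (default 10) most intense peaks per 100 m/z at tolerance
0.5 Da (ion-trap MS/MS); the chance of a random ion match is
p = (peak_depth/100)·2·tolerance. A placement with k of n determining ions
matched is weighted 1/P(Binomial(n, p) ≥ k), and weights are normalized so
placement probabilities sum to 1. More matches ⇒ less explicable by chance
⇒ more probable; complete one-sided evidence gives > 0.9, zero evidence on
a two-lysine peptide gives 0.5/0.5. Peptides with several confident
remnants contribute several sites (poly-modification support).

**Site collapsing.** Site identity is (accession, 1-based residue,
modification). Placements below the 0.9 probability cut are dropped; best
probability, best score and PSM support are aggregated per site. Peptides
shared between accessions yield one site per accession flagged `ambiguous`
— a reporting policy, not protein-group inference, which is out of scope.

## SILAC quantitation

Weighted averaging happens in log2 space (symmetric for up/down
regulation); a linear-space mode exists because the choice is genuinely
open. Weights are summed H+L intensity per peptide, renormalized to 1 — a
proxy for measurement precision. Site ratios are median-centered across the
experiment; the s.d. for the "changing" flag (default 1 s.d.) is computed
on the normalized site-level ratios of the full experiment. Twofold flags
fire at |log2 ratio| ≥ 1. Measurements with a zero channel carry no ratio:
heavy-only/light-only sites are qualitative and excluded from ratio
statistics, never imputed. Condition comparison is a two-tailed Welch
t-test; groups with fewer than two values are reported not-computed, and
identical zero-variance groups return p = 1 (t taken as 0). With
lysine-only heavy labeling every remnant peptide contains a labeled
residue, so every confidently localized site is in principle quantifiable;
the simulator enforces K-containing peptides accordingly.

## Motif classification

Windows are 2·flank+1 residues (default flank 5 for display; the rules need
only ±2), '-'-padded at termini; padding never matches any residue class.
Forward consensus: position −1 ∈ Ψ and +2 ∈ {E, D}; inverted: −2 ∈ {E, D}.
Ψ defaults to {A, I, L, M, P, F, V}, the standard hydrophobic set of the
SUMO consensus, and is configurable. A window satisfying both patterns
counts as forward — the canonical, better-characterized motif. Fractions
are exact rationals on counts, so they always sum to 1.

## Synthetic data

The generator plants everything the pipeline later estimates. Proteins draw
residues uniformly over the 20 amino acids (a configurable background;
uniform keeps lysine density predictable), lengths uniform in 80–240.
Planted sites sit ≥ 11 residues apart so window edits never collide; the
window around each site is edited to realize its assigned class, and class
counts follow largest-remainder rounding of the configured fractions
(default 0.31/0.09/0.60). True PSMs are real digestion products of the
edited proteins (site cleavage-blocked, remnant attached); scores are
Gaussian (true μ=3, decoy μ=0, σ=1 — arbitrary but fixed; FDR calibration
uses them). Decoys come from reversed sequences, and an optional entrapment
fraction adds known-false *target* PSMs from shuffled sequences so the
realized false-discovery proportion is measurable. Heavy/light intensities
are log-normal: per-channel log2 noise σ (default 0.2) around a planted
log2 ratio; changed sites carry |log2| = 1.5 (at least twofold) at a 10%
rate by default. Spectra contain the true placement's b/y ions with
site-determining ions observed at 90% by default. Everything derives from
`numpy.random.default_rng(seed)`: identical configs give byte-identical
outputs.

Passing tests on this generator demonstrate internal consistency —
estimator correctness, FDR calibration, localization behavior, exact motif
recovery — on data whose noise structure is idealized. They do not
demonstrate robustness to real-world features the generator omits:
non-uniform amino-acid composition, chromatographic and charge-state
effects, isotope envelopes, chimeric spectra, correlated search-engine
scores, or enzyme-efficiency variation.

## Problem sizes and runtime choices

Unit and property suites run on peptides ≤ 30 residues and proteomes of
40–80 proteins with 60–150 planted sites; the acceptance script uses 100
sites for the motif split, 150 sites for identification/quantitation, and
300 replicate sites per peptide-count level for the RMSE curve. These sizes
give stable statistics (binomial intervals, sensitivity ≥ 95% checks) while
keeping the whole suite in seconds.

## Known limitations

- The packaged modifier FASTA is a curated snapshot of mature SUMO1-4,
  ubiquitin and NEDD8; FAT10 and FUB1 are not shipped and must be supplied
  as custom modifiers. Grouping claims about non-packaged modifiers are
  documented, not asserted.
- The worked examples for very long / very short blocked tryptic peptides
  use synthetic stand-in sequences engineered to have 57- and 6-residue
  covering peptides; they exercise the identical computation a real
  accession would, but are not real human proteins.
- No database search scoring, no mixture-model rescoring, no
  retention-time or XIC modeling: the package starts from PSM tables and
  peak lists and ends at site tables.
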