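# sumoremnant

Site-level profiling of SUMOylation and ubiquitylation from diglycyl-remnant
(KGG) proteomics.

Ubiquitin-like modifiers attach to substrate lysines through an isopeptide
bond between the modifier's C-terminal ...GG carboxyl and the lysine
ε-amine. Digesting a conjugated proteome leaves a stub of the modifier on
that lysine: trypsin cuts ubiquitin after ...LR|GG and leaves the classic
K-ε-GG remnant (+114.0429 Da), but mature SUMO paralogs have no tryptic site
near their C terminus, so trypsin leaves a long, antibody-invisible tail.
Wild-type α-lytic protease (WaLP) cleaves after the threonine of the SUMO
C-terminal ...T|GG — producing the *same* diglycyl remnant from SUMO sites,
so the standard KGG-enrichment workflow can map endogenous SUMOylation (and,
with trypsin in parallel, ubiquitylation) without engineered SUMO mutants.

`sumoremnant` implements the computational side of that strategy for
proteomics researchers:

- **chem** — monoisotopic mass bookkeeping for peptides, branched isopeptide
  remnants, and b/y/c/z fragment ions.
- **digestion** — in-silico proteolysis under configurable specificity
  rules (trypsin, WaLP, custom), missed cleavages, and the
  modified-lysine-blocks-cleavage convention needed to reason about which
  tryptic peptide *would have* covered a site.
- **conjugates** — modifier attachment topology, remnant prediction
  (`remnant`), and remnant-indistinguishability grouping (Ub ≡ NEDD8 under
  trypsin; SUMO-family modifiers collapse under WaLP).
- **identify** — PSM post-processing: SILAC heavy/light composite-mass
  merging, target-decoy FDR with q-values, Ascore-style binomial site
  localization, collapsing to unique (protein, residue) sites, and
  overlap/novelty reports against known-site tables.
- **quant** — SILAC site quantitation: intensity-weighted mean of
  log2(H/L), median normalization, "changing" (±1 s.d.) and twofold flags,
  Welch two-sample comparisons, and dual SUMO/Ub per-lysine join tables.
- **motif** — sequence windows around acceptor lysines and classification
  against the forward (ΨKX[E|D]) and inverted ([E|D]XK) SUMO consensus.
- **simulate** — a seeded synthetic-data generator (proteomes, planted
  sites, PSM/measurement tables, MGF spectra) providing full ground truth.

## The statistics in brief

- FDR at score *s*: `#decoys ≥ s / max(1, #targets ≥ s)`; q-values are the
  running minimum over decreasing score; PSMs kept at q ≤ 0.01.
- Localization over candidate lysines: with *n* site-determining fragment
  ions and *k* of them matched in the top-10-per-100-m/z peaks, a placement
  is weighted `1 / P(Binomial(n, p) ≥ k)` with chance-match probability
  `p = (depth/100)·2·tol`; weights normalize to probabilities and sites with
  best probability < 0.9 are discarded.
- Site ratio: `Σ wᵢ·log2(Hᵢ/Lᵢ) / Σ wᵢ` with `wᵢ = Hᵢ + Lᵢ`, median-centered
  across the experiment; "changing" if outside 1 s.d. from the median,
  twofold if |log2 ratio| ≥ 1.

## Worked example

Predict what each built-in modifier leaves behind under trypsin vs WaLP:

```python
from sumoremnant import builtin_modifiers, remnant
from sumoremnant.digestion import TRYPSIN, WALP

for name, m in builtin_modifiers().items():
    for spec in (TRYPSIN, WALP):
        seq, mass = remnant(m, spec)
        print(f"{name:6s} {spec.name:8s} remnant={seq:<34s} {mass:9.4f} Da")
```

```
SUMO1  trypsin  remnant=ELGMEEEDVIEVYQEQTGG                2135.9205 Da
SUMO1  walp     remnant=GG                                  114.0429 Da
SUMO2  trypsin  remnant=FDGQPINETDTPAQLEMEDEDTIDVFQQQTGG   3549.5366 Da
SUMO2  walp     remnant=GG                                  114.0429 Da
SUMO3  trypsin  remnant=FDGQPINETDTPAQLEMEDEDTIDVFQQQTGG   3549.5366 Da
SUMO3  walp     remnant=GG                                  114.0429 Da
SUMO4  trypsin  remnant=FDGQPINETDTPAQLEMEDEDTIDVFQQQTGG   3549.5366 Da
SUMO4  walp     remnant=GG                                  114.0429 Da
Ub     trypsin  remnant=GG                                  114.0429 Da
Ub     walp     remnant=RGG                                 270.1440 Da
Nedd8  trypsin  remnant=GG                                  114.0429 Da
Nedd8  walp     remnant=RGG                                 270.1440 Da
```

Reading the table: under trypsin only Ub/NEDD8 give the enrichable +114.0429
diglycyl-lysine, while SUMO1-4 leave kilodalton tails; under WaLP every SUMO
paralog collapses to the same GG stub (and Ub/NEDD8 to RGG). That symmetry —
and its flip side, that co-migrating modifiers become indistinguishable —
is the whole method.

A full synthetic experiment runs from the shell:

```sh
sumoremnant pipeline --seed 2 --n-sites 100 --outdir run/
```

which writes the proteome FASTA, ground-truth site table, PSM table,
FDR-filtered localized site table, site-level quant table and motif summary
into `run/`.

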