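# Methods

This note documents the models, defaults and design choices behind
`hapid`, and what the synthetic benchmarks do and do not demonstrate.

## Database construction

Proteins are grouped by genome/MAG. High-abundance proteins (HAPs) are
flagged by either of two evidence paths, and the flag is their union:

* **Keywords** — case-insensitive substring match of the product
  annotation against "ribosomal protein" and "elongation factor" (the
  default list is exactly those two phrases). Substring matching is
  deliberate: annotation capitalization is inconsistent across
  RefSeq-style and MAG-derived records.
* **Domain scans** — rows of an HMM domain-scan table (HMMER3
  per-domain tabular output or a 3-column TSV) restricted to a curated
  profile list (a ribosomal-protein/elongation-factor list ships with
  the package and can be replaced) at E ≤ 1e−10. The cutoff is applied
  per reported hit row (the independent domain E-value in the HMMER
  dialect); applying it to full-sequence E-values instead would be a
  defensible alternative, and the parser makes that a one-line change.

Deduplication is exact string identity. At a 100% identity threshold
a clustering tool and exact string comparison select the same
representatives, so no external clusterer is needed. The first record
seen keeps the sequence (deterministic, order-stable); the removed→kept
map is retained so profiling can credit *every* genome that carried an
identical HAP, not just the representative's genome.

Decoys are full sequence reversals, one per target, id-prefixed
(default `XXX_`, configurable). Reversal preserves length and
composition; palindromic sequences produce decoys equal to their
targets and are only logged, since they are vanishingly rare in real
proteins.

## Built-in search engine

The engine exists so the pipeline logic is testable end to end at desk
scale; production users can substitute any engine via the PSM-table
adapter, and the pipeline treats both identically.

* **Digestion.** Trypsin cleaves C-terminal to K/R; the trypsin/P
  dialect (default) also cleaves before proline, the strict dialect
  does not. Up to 2 missed cleavages (default); semi-tryptic mode
  (default on, matching common high-resolution settings) adds peptides
  with exactly one tryptic terminus. Peptide length bounds default to
  [6, 50]; engines rarely publish their internal bounds, so these are
  explicit, configurable parameters.
* **Masses.** Monoisotopic residue masses come from pyteomics; water
  18.010565 Da per peptide; proton 1.007276 Da; isotope spacing
  1.00335 Da. Fixed carbamidomethyl-C (+57.02146) and variable
  oxidation-M (+15.99491), at most 3 variable modifications per peptide
  (combinations capped at 64 variants per peptide to bound the index).
  Residue X is legal in databases but peptides containing it are
  excluded from the index (no defined mass).
* **Precursor filter.** |observed neutral mass − k·1.00335 − peptide
  mass| ≤ 15 ppm for some integer isotope error k in [−1, 2].
* **Score.** Hyperscore-style: ln(Nb!) + ln(Ny!) + ln(1 + Σ matched
  intensities) over singly charged b/y ions at 20 ppm. This is a
  simplification of generating-function or expectation-based scores;
  it ranks a true ladder above competitors reliably, which is all the
  pipeline logic requires. Ties break by peptide string, then target
  before decoy, making PSM tables byte-reproducible.
* **Spectra.** Fewer than 10 peaks → skipped. Charges outside [1, 7]
  → rejected at parse time.

## FDR control

Simple D/T estimator at PSM level: FDR(t) = #decoys ≥ t / max(1,
#targets ≥ t), threshold chosen to maximize targets kept subject to
FDR ≤ α (default 1%). No +1 correction and no q-value monotonization;
the 2D/(T+D) variant is switchable. PSM-level control is the default
because the two-step design reports only the second search's
identifications — peptide-level control across merged searches is
exactly the complication the design avoids.

## Profiling

"Unique spectra" is read as *distinct spectra, each counted once*, with
set-cover semantics: a spectrum is creditable to any genome containing
its peptide but covered only once. The greedy cover re-ranks after
every selection (true greedy set cover), since a one-shot ranking can
overstate genomes that share their spectra with already-selected ones.
The alternative reading — count only spectra mapping to a single
genome — is available as `unique_only`. Ties break lexicographically
by genome id. The default coverage threshold is 0.8: covering the tail
of one-or-two-spectrum genomes mostly admits false identifications and
inflates the expanded database.

Taxonomic roll-ups credit a spectrum to every genome that can explain
it and normalize percentages over credited (spectrum, genome) pairs;
the `min_unique_peptides` filter (e.g. ≥ 3 distinct peptides) trims
genomes with too little evidence before the roll-up.

## Expanded search

The step-2 database is all proteins of the selected genomes plus every
HAP with spectral support in step 1 (≥ 1 FDR-passing PSM by default,
configurable), deduplicated and decoy-augmented. Supported HAPs from
*unselected* genomes are included deliberately: their peptides are
demonstrably present, and leaving them out would re-assign those
spectra to wrong peptides in step 2. Final results are step-2
identifications only; step-1 results are profiling output and never
merged into the peptide table.

## Evaluation metrics

* **Consistency rate** compares shared-spectrum PSMs I/L-blind (I→L
  mapping, idempotent) and modification-blind by default; a strict
  mode compares exact modified peptides.
* **Identification rate** is 100·identified/acquired spectra.
* **Operon detection** uses 1-based inclusive coordinates with
  gap = start₂ − end₁ − 1 (end-to-start distance, not midpoints);
  genes are chained per contig and strand in coordinate order while
  gap ≤ 100, overlaps count as gap 0, and maximal chains of ≥ 2 genes
  with mean spectral support strictly > 10 are reported. Results are
  sorted by (contig, start) and are invariant to input order.

## Synthetic data generator

The generator emulates a defined mixed community (in the spirit of
simplified-gut-community standards): genomes with a specified abundance
vector, a designated HAP subset per genome expressed above background,
and spectra sampled abundance-proportionally.

Defaults, chosen once as realistic desk-scale study conditions:

| parameter | default | rationale |
|---|---|---|
| genomes × proteins | 8 × 20 | smallest community exercising profiling |
| HAPs per genome | 3 | minority subset, like real proteomes |
| abundance (8 genomes) | 0.40, 0.25, 0.16, 0.11, 0.07, 0.006, 0.003, 0.001 | top-5 mass 0.99 with separable adjacent ranks; one member near-undetectable |
| HAP expression boost | 5× | HAPs dominate detectable signal per genome |
| noise spectra | 20% | typical unidentifiable fraction |
| m/z noise | 5 ppm | well inside the 15/20 ppm tolerances |
| protein length | 80–400 aa | bacterial range |
| precursor charge | 2 | simplest case exercising neutral-mass arithmetic |
| intensities | lognormal(3, 1) | heavy-tailed like real peaks |

Protein sequences are uniform-random over the 20 residues with K/R
boosted (≈11% each) so tryptic peptides are guaranteed. True spectra
are complete, noisy b/y ladders of a tryptic peptide (fully tryptic,
≤ 2 missed cleavages, length 7–30) of a protein sampled ∝ abundance ×
HAP boost. Optionally a fraction of non-HAP proteins derives from
shared ancestor sequences mutated per genome (off by default); this
gives nested databases the cross-genome near-identical peptides that
make small-versus-large database consistency experiments informative.

**What passing these benchmarks shows — and does not.** The synthetic
spectra have complete ladders, single charge, no co-isolation, no
retention-time structure and no isotope envelopes, and the synthetic
proteomes lack real homology structure (unless the homolog option is
used) and real annotation noise. Success here validates the *pipeline
logic* — database construction, FDR arithmetic, cover selection,
bookkeeping — not the sensitivity of the bundled scorer on real data,
which is why the external-engine adapter exists.

## Benchmark problem sizes

The shipped test suite and acceptance script use: a 2,000-spectrum
eight-genome run for profiling recovery; ten 800-spectrum six-genome
runs for FDR calibration (pooled realized-false proportion compared to
3× nominal, allowing sampling error); a 2,500-spectrum hundred-genome
community (50% homologous proteins, full-tryptic search) for the
nested-database consistency pattern; 200 random incidences against a
greedy oracle plus exhaustive minimum covers; and 500 random sequences
against a brute-force digestion oracle. These sizes make every claim
checkable in minutes on one CPU while leaving each effect comfortably
larger than its sampling noise.

## Known limitations

* The scorer uses singly charged b/y ions only — no higher fragment
  charges, neutral losses, deisotoping or rescoring.
* FDR control is PSM-level; peptide- or protein-level control is not
  implemented.
* Quantification is spectral counting; intensity-based label-free
  quantification is out of scope.
* mzML input is supported only insofar as spectra are converted to the
  internal record type; MGF is the native format.
* The greedy cover approximates the minimum genome list (within the
  standard harmonic-number factor); the exact minimum is exponential
  and unnecessary in practice.
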