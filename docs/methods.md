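# Methods

## Scope and data model

`seromap` starts from an identified, quantified peptide table (the
MaxQuant `peptides.txt` dialect) and an annotated amino-acid V-region
database; it does not process raw spectra, run a search engine, or perform
V/D/J annotation — those belong to upstream tools. The in-memory model has
five layers: `AntibodyClone` (one repertoire record with 0-based half-open
region intervals), `CloneGroup` (a CDRH3 clonotype), `PeptideRecord`
(per-sample intensities), `EnrichmentResult` / `MappingResult` (per-peptide
stage outputs), and `RepertoireSummary` (the integrated tables behind every
report plot).

Clonality is defined by CDRH3 amino-acid identity, the conventional
clonotype identifier for heavy-chain repertoires; a stricter
CDR3-plus-V-gene key is available (`clonotype_key=cdr3_aa_plus_v_call`).
Group representative labels (isotype, gene calls) come from the member
with the largest read count, ties broken by record id, so summaries are
deterministic.

## Enrichment filter

With elution replicate intensities $e_1..e_n$ and flow-through
$f_1..f_m$ (zeros kept — under label-free quantification a missing value
is evidence of absence), the fold change is

$$FC = \frac{\bar e}{\bar f},$$

with $FC = +\infty$ when $\bar f = 0 < \bar e$ and $FC = 0$ when
$\bar e = 0$. A peptide is antigen-specific iff $FC$ **strictly** exceeds
the threshold (default 5) **and** it is detected ($>0$) in at least
`min_detected` (default 2) elution replicates. Choices made here, all
exposed in configuration:

- **Aggregation** is the arithmetic mean including zeros (median optional).
  The mean is the simplest faithful reading of "relative intensity" across
  replicates; the guard on detected elution replicates protects against a
  single-replicate artifact dominating a mean of zeros.
- **Infinite fold passes the filter**: a peptide present only in the
  antigen-bound fraction is the strongest possible enrichment signal.
- **No cross-sample normalization** is applied; LFQ intensities are assumed
  comparable across runs, which is the quantification tool's job upstream.
- No replicate-level statistical test is performed — the filter is a fold
  change by definition, and with 2–3 replicates a moderated test would add
  little beyond the detection guard.

The filter is scale-invariant (multiplying all intensities by one constant
changes nothing) and monotone in the threshold (raising it can only shrink
the antigen-specific set); both are enforced by property tests.

## Peptide-to-clone mapping

Matching is exact substring search; mismatch-tolerant alignment is
deliberately excluded because somatic variants are distinct records in the
personal database by construction. Isoleucine and leucine are isobaric and
indistinguishable by standard MS/MS, so both peptides and clone sequences
are folded I→L before matching (configurable off for strict mode). All
occurrences of all peptides across all clones are enumerated with an
Aho-Corasick automaton built over the folded peptide set, giving running
time proportional to total repertoire length plus hits; a naive
sliding-window scanner serves as the test oracle for equivalence on
randomized instances.

Uniqueness is judged at the clonotype-group level: a peptide hitting three
records that share one CDRH3 is informative, not multi-mapped. CDR3
localization requires at least `min_cdr3_overlap` residues (default 1) of
interval overlap between the hit and the clone's CDR3 bounds; full
containment can be demanded by raising this parameter. Peptides with
residues outside the 20-letter alphabet plus X are reported unmapped with
a warning rather than erroring, since a single malformed peptide should
not abort a run.

## Clone quantification and summaries

Each informative peptide contributes its elution-mean intensity to exactly
its one clonotype; the group value is the **sum** over its informative
peptides (the standard peptide-to-protein roll-up; mean available). The
roll-up conserves total informative signal to relative tolerance 1e-9.
BCR-Seq frequency is the group's read count over total repertoire reads.
Distributions (isotype, CDR3 length, gene usage) are computed over the
antigen-specific groups only — the analysis characterizes what was found
in serum, not the whole repertoire. Groups lacking a D-gene call are
excluded from D-containing usage tables and counted separately. Plots are
artifacts rendered from the TSV tables; the tables, not the images, are
the tested surface, and re-running on identical input reproduces the TSVs
byte-for-byte.

## Digestion model

Fully specific cleavage only: cut after a residue in `cleave_after` unless
the next residue is in `blocked_by_next`. Trypsin (default) cuts after
K/R, not before P, matching the common search-engine convention; Lys-C and
chymotrypsin variants are built in, and arbitrary rules can be given in
the YAML config. Fragments spanning up to 2 missed cleavages and 6–40
residues are kept by default — the window of practically observable
tryptic peptides in shotgun LC-MS/MS. No mass, charge, modification, or
retention-time modeling is attempted.

## Synthetic experiments

The simulator emulates the experimental design the pipeline assumes, with
enough structure that every code path is exercised:

- **Repertoire.** Clones share germline-like FR1–FR4 framework segments;
  CDR1/CDR2 vary per scaffold (default 5 scaffolds) and CDR3 is a random
  insert per clone (default length 8–22). Shared scaffolds make framework
  peptides multi-map while CDR3 peptides stay informative, so the
  unmapped / multi-mapped / informative trichotomy arises naturally. Read
  counts are geometric (heavy-tailed clone sizes).
- **CDR3 composition.** CDR3 inserts avoid K, R and P, and the flanking
  frameworks carry planted lysines (FR3 ends in K; FR4 has an early K), so
  each clone's CDR3 lies inside one tryptic peptide of bounded length.
  This is a deliberate idealization: real CDR3s contain K/R/P and can
  fragment into sub-observable pieces, so real experiments will miss some
  clones that the simulation recovers. Passing recovery tests therefore
  demonstrates correctness of the pipeline logic, not expected sensitivity
  on real serum.
- **Intensities.** Each (peptide, origin clone) pair draws a base-10
  log-normal base intensity (defaults: mean 7.0, sd 0.6 in log10 units,
  i.e. ~10^7 median LFQ intensity). Flow-through intensity is the sum of a
  peptide's components; elution multiplies components from
  antigen-specific origins by `enrichment_fold` (default 20), so peptides
  shared between specific and background clones show intermediate folds.
  Replicates (default 3 per fraction, mirroring triplicate designs)
  multiply by log-normal noise (`noise_sd`, default 0.1) and drop to zero
  with probability `detection_dropout` (default 0.05). All draws come from
  one seeded generator; identical seeds give byte-identical fixtures.

Features of real data the simulator does not model: chimeric/decoy
identifications, intensity-dependent missingness, shared peptides across
isotypes of one lineage, somatic-hypermutation lineages, and
between-replicate normalization drift.

## Numerical and degenerate-input conventions

All coordinates are 0-based half-open. Sorting rules are total (fold
descending, then elution mean, then peptide; hits by record, start, end;
groups by key) so outputs are deterministic. Missing intensity cells are
0, never imputed. Empty inputs: an empty repertoire file is an error, an
empty mapping input yields all-zero summaries, and an empty summary writes
header-only tables with no images. Infinity is serialized as `Inf` in
TSVs. Conservation and proportion checks use relative tolerance 1e-9.

## Problem sizes used in the tests

Unit and acceptance tests run on simulated repertoires of 40–100 clones
with 3 replicates per fraction (a few hundred unique tryptic peptides),
and oracle-equivalence suites on hundreds of randomized small instances;
these sizes exercise every code path while keeping the default suite
around a few seconds. The mapping index and the vectorized table
operations scale linearly, so realistic repertoires (10^4–10^6 records)
are within reach of the same code.

## Known limitations

- Exact matching cannot rescue peptides with residues mutated relative to
  the database (by design); sensitivity is bounded by BCR-Seq depth.
- Fold-change filtering with 2–3 replicates has no error control; the
  threshold is a heuristic, not a test statistic.
- Light chains are carried through (`chain` field) but CDR3 clonotyping is
  heavy-chain-centric; pairing information is out of scope.
- The `bcr_frequency` denominator is the uploaded database's total reads,
  which inherits any upstream amplification bias.
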