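# Methods

This note documents the models, rules and numerical choices behind each
pipeline stage, what the synthetic generators emulate (and do not), and the
design decisions taken where the conventions of published gene-family
surveys leave room.

## Coordinates, formats and containers

All genomic coordinates are 1-based inclusive (GFF3 convention); promoter
extraction converts internally to string slices.  FASTA IDs are the first
whitespace-delimited token; trailing `*` stop marks are stripped from
proteins on read.  Gene "position" for distance computations is the
`[start, end]` interval, never a midpoint.  Files are parsed exactly once
into `GeneRecord` objects; every stage consumes those records, and all
reports are UTF-8 TSV with `.` for missing values plus one JSON summary.
The survey table's `bp` column is the CDS length **including** the stop
codon, so `aa = bp/3 − 1` for a clean gene model.

## Segment model

The three dehydrin segments are modelled as degenerate consensi — ordered
allowed-residue sets:

* K: `E K K G I M [ED] K I K E K L P G` (15 positions),
* Y: `[TV] D [EQ] Y G N P` (7 positions),
* S: prefix `L H R S G`, then a serine run of 4–10 (the last serine of the
  canonical `LHRSGS` opens the run), then three residues from `{E, D}`.

A window matches when its mismatch count is within the segment's budget
(defaults K = 2, Y = 1, S = 1).  The budgets are a design choice: the
consensus literature gives no tolerances, real Triticeae segments diverge
from the consensus, and these defaults guarantee that exact consensi always
match.  For the S-segment the run must be perfect serine and mismatches are
counted on prefix + suffix only; per start position the best run length
(fewest mismatches, then longest) is kept.  `X` is accepted in input but
never matches a consensus position.

Overlap resolution is leftmost-first greedy with ties broken by fewer
mismatches then longer span — deterministic and independent of scan
direction.  When Y, S and K are scanned jointly, candidates from all three
motifs enter one greedy pass, so cross-type overlaps cannot occur.  The
scanner is verified against an exhaustive window-scoring oracle on sequences
up to 200 aa.

Class collapse: no K → `non_dehydrin` (the family definition is ≥ 1
K-segment); Y and S present → YnSKn; Y only → YnKn; S only → SKn, unless
every S lies C-terminal of every K (KnS); otherwise Kn.

## Identification screen

External domain-search results (HMMER/BLASTP tabular hits for the dehydrin
domain) are ingested as `(query, domain, E-value)` rows with configurable
column mapping.  Rows with E ≤ 1e-20 are merged, de-duplicated by query and
confirmed by K-segment presence.  Re-running a full-genome search is outside
the package: hit tables are inputs, and the screen's contract (threshold,
dedup, confirmation) is what is tested.

## Physico-chemical properties

Molecular weight uses average residue masses plus one water (18.0153 Da),
the ProtParam convention (computed via Biopython's mass tables).  The pI
solves net charge = 0 under Henderson–Hasselbalch with the Bjellqvist pKa
set, including its terminal-residue-specific N/C-terminal adjustments;
cysteines are free (no disulfide correction).  Bisection runs on (0, 14)
until the bracket is below 1e-4 pH; an early exit on |charge| uses a much
tighter cut (1e-9) because the charge curve is nearly flat for peptides with
few ionizable groups, where a loose charge criterion would stop far from the
root.  The result is bracket-independent (verified) and agrees with an
independent Brent root-finder to 1e-3 pH and with Biopython's
`IsoelectricPoint` (given the full pH bracket; its default lower bound of
4.05 clamps strongly acidic peptides) to 0.02.  GC% excludes `N` from the
denominator.

## Tandem screen

Criteria (all strict): alignable length > 70 % of the longer gene, aligned
identity > 70 %, chromosomal distance < 500 kb.  Distance is the gap between
the closest gene ends (0 when intervals overlap or abut).  Alignment is
affine-gap local (match +1, mismatch −1, open −2, extend −0.5) on the CDS by
default — "alignable sequence" implies a local alignment, and 70 % is the
conventional nucleotide cut-off for duplicate screens; a protein mode is
available.  Coverage is the aligned span on the longer sequence over its
length; identity is identical columns over all aligned columns.  Pairs are
only formed within one species (chromosome names recur across species, and
physical distance is only defined within one genome).  Arrays are connected
components of the tandem relation; the relation is symmetric and the
clusters partition their members.

## Homoeolog groups

Grouping is single-linkage at a similarity threshold (default 0.70) on a
normalised identity (identical aligned positions / longer length, i.e.
coverage × identity), restricted to genes whose homologous-group numbers
agree; unplaced genes are compatible with any group.  This deterministic
similarity surrogate replaces the phylogenetic + syntenic evidence a manual
curation would weigh, and is documented as such: it recovers planted truth
exactly on synthetic scenarios but does not adjudicate genuinely reticulate
histories.  The homologous-group number of a chromosome is the leading digit
of its name (`3A` → 3).  Groups are indexed 1..n in genomic order
(homologous group, then start).

Naming: species prefix + `DHN` + family index; polyploid members append the
sub-genome letter, slots with several tandem copies append consecutive
ordinals in start order (`TaDHN4-A1`, `TaDHN4-A2`), and diploids omit the
sub-genome letter (`TuDHN7`; diploid tandems `TuDHN4-1`).  Name assignment
is injective by construction and collisions raise.

Missing slots are expected (species × sub-genome) cells with no member,
where expectation follows ploidy (Ta: A/B/D; Td: A/B; Tu: A; Aet: D).
Unplaced genes take the chromosome implied by their group's homologous
group plus the best-matching slot's sub-genome letter (forced for diploids),
and are flagged `reassigned`.  Anomaly flags compare each member with the
group majority: a different class → `misannotated`; same class with fewer
K-segments, or protein length under 70 % of the group median → `truncated`.
Theoretical family sizes take a per-subgenome slot base as input and sum it
over each species' sub-genomes; the slot base is an input, not inferred,
because observed counts confound losses and gains.

## Promoters, cis-elements, SSRs

Promoters are the `length` (default 1500) bp upstream of the translation
start: `[start−L, start−1]` on +, reverse complement of `[end+1, end+L]` on
−, truncated with a warning at contig edges.  Element scanning is exact
IUPAC matching on both strands; hits are reported at their forward-strand
start.  The default motif table (ABRE `ACGTG`, DRE core `RCCGAC`, MBS
`CAACTG`, LTR `CCGAAA`, MeJA-RE `CGTCA`/`TGACG`, TCA `CCATCTTTTT`, TC-rich
`ATTTTCTTCA`, ARE `AAACCA`) is PlantCARE-conventional and fully
configurable; element databases differ in exact site definitions, so counts
from different tables are not comparable and per-gene presence/absence is
reported alongside raw hit counts.

SSR mining reports maximal perfect tandem repeats of unit length 2–5
meeting per-unit minima (di ≥ 6, tri ≥ 4, tetra ≥ 3, penta ≥ 3 — chosen to
approximate common microsatellite-tool defaults, configurable).  Units are
normalised to the lexicographically smallest rotation; a unit that is itself
periodic is excluded (so mononucleotide runs and `ATAT`-style pseudo-units
never appear), and overlapping reports collapse to the smallest unit
explaining the region.  Mining is invariant to reverse complementation up to
coordinate mirroring, provided flanking bases do not phase-shift a run.

## Expression rules

Bins: low < 1, medium [1, 10], high > 10 TPM.  "> 10" is strict, so 10.0 is
medium; 1 is assigned to medium so that "expressed" (max TPM ≥ 1) coincides
with "medium or above".  UR requires fold change (treatment/control) > 1
**and** ΔTPM > 10; the fold threshold of 1 is literal (any increase), so the
Δ guard does the real work, and the threshold is configurable because a
stricter fold may be wanted.  DR is defined as the exact mirror of UR (the
convention source does not spell out its DR rule), which makes
`call(a,b) = UR ⇔ call(b,a) = DR` a theorem and is tested as such.  A zero
control is guarded by a pseudocount (default 0.01) in the fold ratio only.

## Synthetic data: what it does and does not emulate

Every generator draws from `default_rng([stream, seed])` with a fixed
per-generator stream constant, so one seed drives the whole scenario and
adding a generator never perturbs another; same-seed regeneration is
byte-identical.

* **Proteins**: planted Y…S…K segments with ≥ 5-residue random spacers;
  mutations only inside segments; backgrounds are redrawn if they would
  contain a spurious segment at scanner tolerance, so recovery at mutation
  rate 0 is exact by construction, and recovery degrades monotonically (on
  average) past the tolerance.
* **Family sets**: one ancestral CDS per family encoding a dehydrin-like
  protein with a planted architecture (default YSK2; segment-coding nt are
  protected from divergence), 3 % substitutions per sub-genome copy, ≤ 1 %
  between tandem copies placed 60 kb apart, deletions and unplaced slots per
  spec.  Families are laid out on homologous groups 3–7 in ascending genomic
  order so recovered family indices equal planted numbers.  Chromosomes are
  named in wheat style (`3A`, `6D`, `Un`).
* **Promoters / SSR sequences**: planted motifs or repeats at recorded
  positions; spurious background matches are destroyed by point edits
  outside planted spans, so planted-truth recovery is exact.
* **Expression**: log-normal noise around representative per-bin values
  (0.2 / 5 / 40 TPM) or per-label (treatment, control) pairs
  (40, 3 / 3, 40 / 12, 11); exact recovery at σ = 0.

What passing these tests shows is that each stage implements its stated rule
faithfully and recovers planted structure under the stated conditions.  What
it does not show: robustness to real annotation noise (split/merged gene
models, intron-containing genomic spans, segmental duplications that mimic
tandems), to genuinely divergent segment variants beyond the mismatch
budgets, or to expression normalisation artefacts — real surveys should
treat borderline calls as candidates for manual inspection, as curated
surveys do.

## Problem sizes

The bundled test suite runs synthetic scenarios at 2–13 families (up to
~110 genes, pairwise-aligned for similarity), 50-seed scanner/oracle sweeps,
100-peptide property checks and 100 random expression matrices; the whole
suite completes in well under a minute on one CPU, and the acceptance script
(a deterministic tally of the bundled 117-gene table) in seconds.

## Reference table and the one documented re-annotation

The bundled reference survey transcribes the published table of 117
dehydrin genes (names, loci, types, positions, strands, truncation /
mis-annotation footnotes).  The published headline class tally counts one
member (TaDHN12-A3, printed SK2) under its corrected type YSK2, following
the published finding that its annotated first 28 residues were
mis-annotated and hid the Y-segment.  The table therefore carries both
`type` (as printed) and `type_corrected` (the documented correction), and
`tally_table(reannotated=True)` — the default — applies corrections where
present.  Tallying the printed types verbatim gives 80/26/11 instead of
81/26/10; both behaviours are exposed and tested.
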