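# Methods

## Data model and I/O

The pipeline currency is the AIRR Rearrangement TSV: one row per transcript
with `sequence_id`, `sequence`, `v_call`/`j_call`/`c_call`, `junction`,
`junction_aa`, `productive`, `duplicate_count`, plus subject/subset labels.
Unknown columns are carried through untouched. Missing optional columns get
documented defaults: `duplicate_count` = 1; `productive` inferred as
"junction in frame and stop-free" (overridable by an explicit column);
multi-allele `v_call` assignments keep the first call and set a
`call_ambiguous` flag, since the analysis operates at gene level.

Transcript collapsing merges records identical on
(`sequence`, `c_call`, `subject_id`, `subset_label`), summing
`duplicate_count`. Isotype stays in the keys so IgM and IgG copies of one
heavy chain remain distinct — per-isotype tallies downstream depend on it.
Collapsing is idempotent and conserves total duplicate count exactly.

## Germline alignment and mutation calling

Each transcript's V region is aligned to its germline V gene with edlib in
infix (semi-global) mode: the read runs V-through-J and is longer than the
germline, so end gaps on the read are free while internal gaps are penalized.
One boundary case needs care: a mutation in the last V-region base admits an
equal-cost terminal-deletion alignment; when read bases remain past the
alignment end the substitution reading is preferred. Alignments below a 70%
identity floor (configurable) are treated as V-gene misassignments.

Mutations are called per mismatch column in 1-based germline coordinates.
Silent versus replacement is decided by translating the **full observed
codon**, so two hits in one codon are judged jointly rather than
independently. Codons disrupted by a gap yield no per-site calls and the
profile is flagged `has_indel`; mismatch columns with an ambiguous base (N)
are skipped and tallied separately. Regions (FR1/CDR1/FR2/CDR2/FR3) come from
1-based inclusive amino-acid bounds attached to the germline reference.

## Hotspot classification

The hotspot scheme holds 1-based amino-acid positions in the translated
mature V region: the FR1 hydrophobic-patch core A24 V25 Y26 (with auxiliary
Q6 W7), the CDR2 N-glycosylation sequon N57 H58 S59, and FR3 K90 L91 S92.
Linear numbering is used throughout; an alternative numbering can be supplied
via the scheme configuration. Classification precedence is

AVY > NHS > KLS > OTHER_REPLACEMENT > SILENT_ONLY > GERMLINE,

reflecting the relative weight of hydrophobic-patch loss for 9G4 idiotope
reactivity. The auxiliary Q6/W7 positions do not trigger AVY by default
(configurable), and indel-bearing profiles are UNCLASSIFIABLE. Because
precedence is a modeling choice where categories overlap, non-exclusive
per-hotspot flags (`hits_avy`, `hits_aux`, `hits_nhs`, `hits_kls`) are always
emitted so any other precedence can be re-derived from the output.
Classification is per unique (collapsed) transcript, and junction/CDR3
mutations never affect the category — the germline reference spans FR1–FR3
only, so the junction lies outside the aligned region by construction.

## Clonal inference

Records are partitioned by (V gene, J gene, junction length); within a
partition, normalized junction Hamming distance ≤ 0.15 defines relatedness
(Hamming rather than edit distance: junctions in a partition are equal
length, making the comparison alignment-free, the standard convention for
clonal grouping). Single linkage takes connected components of the threshold
graph; complete linkage cuts a hierarchical clustering at the threshold. The
0.15 default is the common operating point for heavy-chain junctions and is
exposed in configuration. Clone ids are content-addressed (SHA-1 of sorted
member ids) and all tie-breaks are lexicographic, so outputs are stable for
golden-file comparison. Connectivity networks place one node per member with
clone/category/isotype/size attributes and connect same-clone members whose
junctions differ by ≤ 1 nt (configurable); group subsampling uses Python's
integer Mersenne Twister on the clone-id-sorted list, which is bit-stable
across platforms.

Top-clone enumeration ranks heavy-chain V-region amino-acid sequences by the
number of distinct CDR3s (`junction_aa`) carried. The V-region key is the
translation of the read prefix preceding the literal junction substring
(falling back to the full translation when the junction is not found), which
avoids requiring explicit junction coordinates.

## Repertoire statistics

Chao1 uses singleton/doubleton counts; the bias-corrected form is the default
and the classic form falls back to it when f₂ = 0 (where it is undefined).
The clonotype key defaults to the nucleotide junction; amino-acid CDR3s are a
switch. V-J usage is reported as percentages of all pairs and includes
non-productive rearrangements by default — these never saw antigen selection,
so they read out recombination-signal preference directly. Counting is
clone-weighted (each unique clonotype once) by default, with record- and
duplicate-weighted modes; after collapsing, duplicate weighting recovers
pre-collapse abundances. CDR3 is the junction minus the two conserved
anchors (Cys-104, Trp/Phe-118), toggleable. Hydrophobicity uses the
Kyte–Doolittle scale as a named, swappable table. Distal-J usage is the
fraction of rearrangements on JH5/JH6.

## Synthetic repertoire generator

The generator defines the study conditions used by the tests. Clones are
drawn until the requested sequence count is reached, sizes following
Zipf(α) (default α = 1.5, the oligoclonal-expansion regime) or a shifted
negative binomial; each clone receives a V gene, a J gene, an in-frame random
junction flanked by the Cys/Trp anchor codons, and its members receive
isotypes and productivity flags independently. Non-productive members get a
1-nt-truncated (frameshifted) junction. Distal-J depletion multiplies the
JH5/JH6 mass by the factor and redistributes the removed mass over proximal
genes, so a baseline distal mass of 0.30 at factor 0.5 yields exactly 0.15.

Two mutation regimes are mutually exclusive by design. With a
`category_mix`, each clone receives the single minimal edit realizing its
drawn category (a non-synonymous single-nucleotide change inside the
category's hotspot set, a synonymous one outside all sets for SILENT_ONLY,
etc.) and no background mutation touches the V region — the truth label is
then exact and classification recovery can be tested at 100%. Without a mix,
a site-independent substitution process at `shm_rate` (with optional
per-hotspot-set rate multipliers) drives V-region mutation. This is
deliberately not a motif-based (WRC/GYW) SHM model: category control comes
from explicit injection, and the site-independent process is only a
background.

Preset conditions: the healthy-donor-like preset uses IGHV4-34 fraction 0.07
(the 5–10% band of circulating naive cells), no distal depletion, Zipf α = 3.0
(polyclonal), and a category mix with 25% germline and AVY+NHS around half —
the pattern reported for CD27⁺IgM⁺ cells of healthy donors. The
affected-sibling-like preset uses IGHV4-34 fraction 0.50, distal depletion
0.5, Zipf α = 1.5 (oligoclonal), and a mix with AVY rare (2%) and
KLS/silent/other elevated. Junction lengths follow a triangular law over
10–20 aa peaked at 15. All randomness flows from one numpy Generator seeded
by the config, making output byte-identical under a fixed seed.

The generator emulates repertoire *structure*, not biology: junctions are
random in-frame sequences (no TdT/exonuclease model), germlines are synthetic
(hotspot residues placed at canonical linear positions; other gene names are
derived variants), and SHM is site-independent. Passing recovery tests
therefore demonstrates correctness of the analysis logic on data with known
truth — not performance on real reads, where V-gene assignment, indels and
motif-biased SHM are harder.

## Pipeline and determinism

The pipeline runs read → collapse → repertoire statistics → IGHV4-34 filter →
mutation profiling → clonal grouping → connectivity graph (optionally on a
seeded 200-group subsample) → top-clone table, writing every intermediate
plus a manifest with a config hash, per-stage record counts and per-file
SHA-256 checksums. The manifest deliberately carries no timestamps and the
config hash excludes the output directory, so two runs of the same analysis
are byte-identical; wall-clock information goes to the stderr log. Chao1 in
the pipeline uses duplicate weighting because it runs after collapsing.

## Problem sizes

Simulation-based tests use 120–2,000 sequences for unit-level checks and
10,000 sequences for parameter-recovery and preset-contrast checks — large
enough that binomial sampling error (3 SE bands) separates the configured
effects cleanly. The brute-force clonal-grouping oracle runs on 100 random
instances of 20–200 sequences, where all-pairs distance matrices are exact
and cheap.

## Known limitations

- Germline references are synthetic; no IMGT database or allele-level
  resolution is shipped.
- Reads are assumed to start at the V-region start (no 5' truncation model);
  V assignment is taken from `v_call`, not re-derived.
- No lineage trees, ancestral reconstruction, or light-chain pairing.
- The classic Chao1 variance/CI is not computed; only the point estimate.
- Complete-linkage clustering materializes per-partition distance matrices;
  partitions beyond ~10⁴ members would need a sparser approach.
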