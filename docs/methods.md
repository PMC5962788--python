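# Methods

## The marker model

A conserved signature indel (CSI) is modelled as a single insertion or
deletion event on the stem branch of a clade: every descendant carries
the derived state, every taxon outside the clade the ancestral one, and
conserved flanking residues guarantee that the aligned columns are
positionally homologous rather than alignment artifacts. The detector
does not infer the event on a tree; it tests the observable consequences
in a multiple sequence alignment — column-wise exclusivity of the
residue/gap state plus flank conservation — and then asks which named
clade the carrier set matches. A conserved signature protein (CSP) is
the presence/absence analogue at the whole-gene level: significant
homologs inside the clade, none outside, judged from a tabular homology
hit table rather than from alignments.

Both marker types tolerate *exceptions*: clade members documented as
lacking the signature (gene loss, a deep-branching lineage that split
before the event). Exceptions are always named taxa in the output,
bounded by `max_exceptions`, and never absorbed into fractional
thresholds.

## Column classification and block discovery

For the designated in-group, a column is *in-group exclusive residue*
iff fraction(in-group rows with a residue) ≥ τ_in and
fraction(out-group rows gapped) ≥ τ_out, and symmetrically *in-group
exclusive gap*. Defaults τ_in = τ_out = 1.0 encode strict "all members"
exclusivity. Maximal runs of equal exclusive state merge into candidate
blocks; the indel size range is taken over carriers (residue count per
carrier for insertions, missing-residue count for deletions), so
carriers with partial occupancy yield honest ranges such as "6 ~ 8 aa".

Taxa absent from an alignment are missing data: they are excluded from
occupancy denominators and from clade membership during matching, and
they can never count for or against a signature.

One mechanical consequence of strict occupancy required a design choice:
with τ_in = 1.0 an exception taxon would stop the column from ever
classifying as exclusive, so the block containing the signature would
not exist to be matched. `detect_csis` therefore relaxes the effective
τ_in to (n_in − max_exceptions)/n_in (never above the user's τ_in)
during block discovery only. Exceptions are still identified and named
exclusively by clade matching; occupancy slack is not a user-facing
exception mechanism.

## Flank conservation

Flanks are scored over the nearest W (default 30, configurable up to the
40 sometimes used for this rule) gap-free columns on each side of the
block — columns gapped in any row are skipped rather than counted
against the rule, keeping the criterion about residues. A column is
conserved when all residues are identical, or (default rule) when they
fall within a single Clustal "strong" substitution group (STA, NEQK,
NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW); `identical_only` is available
for stricter scans. The block passes when both sides reach F (default
5, the permissive end of the conventional 5–6 range). Windows truncated
at alignment edges use whatever columns exist, which deliberately makes
signatures near protein termini harder to support — fewer scorable
columns, same threshold.

## Clade matching

Every (rank, label) pair in the manifest is a candidate clade. With
membership restricted to taxa present in the alignment, a clade
qualifies when no carrier lies outside it and at most `max_exceptions`
members are non-carriers. Among qualifying clades the smallest wins,
with ties broken by fewest exceptions, then label — so a signature
carried by exactly one genus reports the genus even though the enclosing
family also qualifies at a higher exception count.

## Signature segments and specificity validation

For database probing, a 60–100 aa segment of the ungapped reference
sequence is cut centered on the block midpoint, shifted (never
shortened) at sequence ends; references shorter than 60 aa yield the
whole sequence with a warning. Specificity checking walks the hit table
in descending bitscore order over the top N (default 500) distinct
subjects and asks, per subject, whether it carries the indel: the
segment is globally aligned to the subject (BLOSUM62, gap open 11,
extend 1) and a gap run of length within [size_min, size_max] at the
block-homologous position decides presence/absence. An out-clade carrier
or an in-clade non-carrier not listed as an exception is a violation;
subjects with unresolvable taxa or missing sequences are recorded as
unevaluated and excluded from the verdict.

## CSP calling

Per query protein (≥ 50 aa): collapse hits to the best E-value per
subject taxon; count in-group taxa at E ≤ e_in (the query's own taxon
always counts, so a query absent from the table hits only itself);
emit iff coverage ≥ min_ingroup_fraction and no out-group taxon at
E ≤ e_out. Defaults e_in = 1e−5, e_out = 1e−3,
min_ingroup_fraction = 0.8. These operationalize a "significant hits
only inside the clade" criterion that is conventional rather than
universal; the 0.8 floor tolerates the draft-genome absences expected
when a marker is present in "almost all" sequenced members. The
deliberately weaker e_out bounds a different event (any out-group
homology at all), which is why e_in ≤ e_out is not required. Judgement
is by E-value only; a minimum query-coverage filter exists but is off by
default.

## Distance phylogenetics

- **K2P**: d = −½·ln((1−2P−Q)·√(1−2Q)) with transition fraction P and
  transversion fraction Q over pairwise-comparable sites (gap or N in
  either sequence excluded — pairwise deletion, the common default for
  distance trees). Arguments of the logarithm ≤ 0 raise a saturation
  error naming P and Q rather than returning infinity.
- **Neighbor joining**: Saitou–Nei agglomeration on the rate-corrected
  criterion Q(i,j) = (r−2)d(i,j) − R_i − R_j. Ties resolve to the pair
  whose clusters' smallest leaf names sort first, making the tree a
  deterministic function of the matrix. Negative intermediate branch
  lengths are clamped to zero with the deficit moved to the sibling
  edge, preserving the pair's summed length.
- **Bootstrap**: B column resamples with replacement; support of an
  internal edge is the percentage of replicate trees containing the same
  bipartition, mapped onto the full-data tree (not a consensus tree),
  matching how such trees are usually figured.
- **Trimming** is Gblocks-like, not bit-compatible with the original
  binary: columns with any gap are rejected (gap policy "none");
  remaining columns are conserved at ≥ b1 = ⌊n/2⌋+1 identical rows and
  highly conserved at ≥ b2 = ⌈0.85n⌉; runs of more than b3 = 8
  non-conserved columns are rejected; surviving blocks are trimmed at
  both ends to highly conserved columns and dropped below b4 = 10
  columns. Column status depends only on the column itself, which makes
  the operation idempotent. A maximum-likelihood tree on the trimmed
  supermatrix is out of scope; the bootstrapped NJ tree over the
  concatenated data is the in-package surrogate and is documented as
  such.
- **Concatenation** joins per-gene alignments row-wise by taxon;
  `strict` errors on any taxon missing from any partition (naming both),
  `gap-fill` pads with gaps.

## The simulator and what it does (not) show

`synthetic` evolves protein families on trees: a uniform-random root
sequence, per-branch Poisson(site rate × substitution rate × branch
length) substitution events with uniform replacement residues, and each
planted indel applied exactly once on the stem branch of its target
clade. Flanking sites (default 35 per side, ≥ W by construction) are
frozen at rate 0 so planted signatures satisfy the flank rule by
design; planned exception taxa have the indel reverted on their terminal
branch. The emitted alignment is the true residue homology — there is
no realignment step — so detector tests are decoupled from aligner
error. Trees are either user Newick, uniform-topology random trees
(leaf insertion on a uniformly chosen edge, exponential branch lengths),
or clade-respecting random trees in which every manifest clade is
monophyletic. A noise knob plants indels whose carrier sets follow no
clade pattern (applied homoplastically on terminal branches) to exercise
the rejection path.

Default study conditions: 400 aa root length, branch-length mean 0.05,
substitution rate 1 per site per unit branch length, indel sizes 1–10;
proteomes use 5 background proteins of 200 aa shared by all taxa and
per-taxon mutation probability 0.05 per site. These are realistic for
well-conserved single-copy bacterial proteins at class-level divergence
while keeping families small enough to scan exhaustively in tests.

What passing recovery tests shows: the scanning, flank, clade-matching
and calling logic is correct against ground truth. What it does not
show: robustness to real-world alignment error, empirical substitution
preferences (the simulator replaces uniformly, not by an exchangeability
matrix), realistic indel length distributions, homoplasy of genuine
signatures, or database-scale homology search artifacts. Counts of
markers found in real genome sets depend on the sequence database
snapshot used and are not reproducible from simulations.

The pseudo-E-values of the internal k-mer similarity search use fixed
Karlin–Altschul-style constants (λ = 0.267, K = 0.041); the contract is
the relative ordering of hits and a sane absolute scale for thresholds,
not calibration against any external search tool.

## Numerical and format choices

- Coordinates: 0-based half-open internally; 1-based inclusive in every
  file and report (the convention of published indel tables).
- Gap dialects `.` and `~` normalize to `-` on read; only `-` is
  written. Columns that are entirely gaps are dropped at alignment
  construction.
- Hit tables are 12-column BLAST-style tabular with an optional 13th
  subject-taxon column; otherwise the taxon parses from a
  `taxon|protein` subject id, falling back to "unknown" (excluded from
  exclusivity decisions, with a warning).
- Hit ordering (query, bitscore desc, E-value, subject id) is total, so
  results are invariant under permutation of input lines.
- Reports use `-` for identity with the top line and `.` for gaps —
  two distinct characters so the report is losslessly invertible, which
  the test suite exploits as a round-trip check.
- Run configs are YAML with a versioned schema key; unknown keys are
  rejected outright. `run.json` records parameters, seed and SHA-256
  digests of all inputs, sufficient to re-execute a run.

## Problem sizes used in verification

The recovery experiments use 100 simulated families (CSI) and 20
proteome bundles (CSP) at the default study conditions above, 1,000
random alignments for the block-scanner oracle check, 30 random additive
matrices of 4–8 taxa for neighbor joining (with exhaustive topology
enumeration as the independent oracle at 5–6 taxa), and 100 bootstrap
replicates for the clean-split check. At these sizes the full
verification completes in seconds.

## Known limitations

- CSI detection is protein-only; nucleotide CSIs are out of scope.
- The detector consumes alignments; it neither builds nor re-optimizes
  them, and misalignment shows up as failed flank conservation rather
  than being repaired.
- Homology search is not performed by the package (the internal k-mer
  search exists for simulation); real analyses should bring BLAST-style
  tabular output.
- The trimmer reproduces the published Gblocks rules by description,
  not the binary's exact column decisions.
- Clade matching requires the manifest's clades; paraphyletic or
  overlapping "clades" are matched purely set-theoretically.
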