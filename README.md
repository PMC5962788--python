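# sigscan

Discovery of clade-specific molecular markers from protein sequence data:

- **Conserved signature indels (CSIs)** — insertions or deletions of fixed
  size in a protein family that are present in (nearly) all members of one
  clade and absent outside it, flanked on both sides by conserved residues
  that pin down positional homology. A CSI of this kind is most simply
  explained by a single indel event in the clade's common ancestor, which
  makes it a rare-genomic-change marker for defining and delineating taxa
  (e.g. a 6–8 aa insertion in DNA-directed RNA polymerase subunit beta'
  found only in one bacterial class).
- **Conserved signature proteins (CSPs)** — proteins whose significant
  homologs occur only within a given clade, judged from a BLAST-style
  tabular hit table.

The package is aimed at microbial taxonomists and comparative genomicists
who already have protein alignments, proteomes and homology-search output
and want a reproducible, scriptable scan in place of manual alignment
inspection. It also ships the supporting distance phylogenetics used
alongside such scans — Kimura two-parameter and p distances,
neighbor-joining with bootstrap supports, Gblocks-style conserved-block
trimming, multi-gene concatenation — and a simulator that evolves protein
families on trees with planted, ground-truthed signatures so that every
stage is testable without downloading sequence data.

## The scan in brief

Given an alignment, a taxon→clade manifest, occupancy thresholds
(τ_in, τ_out) and a flank rule (F conserved columns within the nearest W
gap-free columns on each side):

1. classify each column: *in-group exclusive residue* iff the fraction of
   in-group rows bearing a residue ≥ τ_in and the fraction of out-group
   rows gapped ≥ τ_out (symmetrically for exclusive gaps);
2. merge maximal runs of exclusive columns into candidate indel blocks
   (insertions or deletions relative to the out-group);
3. reject blocks whose flanks do not reach F conserved columns per side
   (a column is conserved when identical, or within one Clustal strong
   group: STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW);
4. match the carrier set against every named clade in the manifest,
   allowing at most `max_exceptions` clade members to lack the signature
   (exception taxa are reported by name, never silently absorbed);
5. report reference-protein coordinates, size range over carriers, and a
   dash-for-identity signature alignment; optionally validate specificity
   against the top-N most similar subjects from a hit table.

CSP calling is an E-value test per query protein: emitted iff qualifying
hits (E ≤ e_in) cover ≥ 80% of in-group taxa and no out-group taxon hits
at E ≤ e_out.

K2P distance follows d = −½·ln((1−2P−Q)·√(1−2Q)) with P/Q the
transition/transversion fractions over pairwise-comparable sites;
neighbor joining uses the Saitou–Nei rate-corrected criterion with
deterministic tie-breaks.

## Worked example

Simulate a small bundle — eight taxa, a class-level 7 aa insertion planted
with one deep-branching exception taxon, and one planted clade-exclusive
protein — then run discovery on it:

```yaml
# sim.yaml
schema_version: 1
seed: 17
taxa:
  A_ferro: {class: Acidimicrobiia}
  F_acidi: {class: Acidimicrobiia}
  I_cocci: {class: Acidimicrobiia}
  M_parvi: {class: Acidimicrobiia}
  IMCC26256: {class: Acidimicrobiia}
  R_radio: {class: Outgroup}
  E_coli: {class: Outgroup}
  B_subt: {class: Outgroup}
seq_length: 400
families:
  - name: rpoC_like
    indels:
      - {rank: class, label: Acidimicrobiia, type: insertion, size: 7,
         position: 200, exceptions: [IMCC26256]}
proteomes:
  n_background: 4
  csps:
    - {rank: class, label: Acidimicrobiia, length: 226}
```

```yaml
# run.yaml
schema_version: 1
seed: 1
manifest: bundle/manifest.tsv
ingroup: {rank: class, label: Acidimicrobiia}
alignments: [bundle/rpoC_like.aln.fasta]
proteome: bundle/proteomes/A_ferro.fasta
proteome_taxon: A_ferro
hits: bundle/hits.tsv
max_exceptions: 1
out_dir: out
```

```
$ sigscan simulate --config sim.yaml --out-dir bundle
simulation written to bundle
$ sigscan discover --config run.yaml
bundle/rpoC_like.aln.fasta: 1 CSI record(s)
1 CSP record(s)
1 CSI, 1 CSP record(s) -> out
```

`out/csi.tsv` holds the recovered marker — an insertion of size 7~7,
matched to the class with the planned exception taxon named, spanning
reference positions 171–237 (indel plus both 30-column flank windows),
with 30 conserved columns on each side:

```
indel_type  size_min  size_max  region_start  region_end  clade_label     exceptions
insertion   7         7         171           237         Acidimicrobiia  IMCC26256
```

`out/csp.tsv` holds the planted protein, found in 4/4 in-group proteomes
and no out-group (empty best out-group E-value):

```
protein_id    length  clade_label     ingroup_coverage  best_outgroup_evalue
A_ferro|csp0  226     Acidimicrobiia  1.000
```

`out/signatures.txt` prints the signature block in the standard
dash-for-identity convention — the top line shows the reference residues,
`-` below means "identical to the top line", and `.` marks a gap; the
exception taxon and the out-group rows show seven gap placeholders at the
insert:

```
# 7 aa ins 171–237 Acidimicrobiia except IMCC26256
F_acidi    GCNFAWMKEGMVALAPWWMMLEARCWSKWQMMIMKYIMVHEISPLINVWHTYDHKKQDTKEERTMIC
I_cocci    -------------------------------------------------------------------
IMCC26256  ------------------------------.......------------------------------
R_radio    ------------------------------.......------------------------------
```

The same steps are available as library calls (`sigscan.detect_csis`,
`sigscan.call_csps`, `sigscan.nj_build`, ...) and as the `sigscan csi`,
`csp`, `tree` subcommands for single files.

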