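"""Detection of clade-specific conserved signature indels (CSIs).

A CSI is an insertion or deletion of fixed size in a protein family,
present in (nearly) all members of one clade and absent outside it, and
flanked on both sides by stretches of conserved residues that pin down
positional homology.  Detection scans alignment columns for in-group
exclusive residue/gap states, merges adjacent exclusive columns into indel
blocks, demands conserved flanks, and matches the carrier set against the
named clades of a group manifest, allowing a bounded number of exception
taxa (clade members documented as lacking the signature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .seq_io import (
    GAP,
    Alignment,
    GroupManifest,
    HitTable,
    SequenceRecord,
    column_to_ungapped_map,
)

logger = logging.getLogger(__name__)

# Clustal "strong" substitution groups: a flank column whose residues all
# fall within one group counts as conserved under identical_or_strong_group.
STRONG_GROUPS = (
    frozenset("STA"),
    frozenset("NEQK"),
    frozenset("NHQK"),
    frozenset("NDEQ"),
    frozenset("QHRK"),
    frozenset("MILV"),
    frozenset("MILF"),
    frozenset("HY"),
    frozenset("FYW"),
)

INGROUP_EXCLUSIVE_RESIDUE = "ingroup_exclusive_residue"
INGROUP_EXCLUSIVE_GAP = "ingroup_exclusive_gap"
SHARED = "shared"
OTHER = "other"


@dataclass(frozen=True)
class ColumnParams:
    """Occupancy thresholds defining an in-group exclusive column.

    tau_in: minimum fraction of in-group rows in the indel state.
    tau_out: minimum fraction of out-group rows in the opposite state.
    Defaults of 1.0 demand strict exclusivity; named exceptions are handled
    downstream by clade matching, not by occupancy slack.
    """

    tau_in: float = 1.0
    tau_out: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class FlankParams:
    """Flank conservation rule: at least F conserved columns within the
    nearest W gap-free columns on each side of the indel block."""

    window: int = 30
    min_conserved: int = 5
    conservation_rule: str = "identical_or_strong_group"

    def __post_init__(self) -> None:
        if not 1 <= self.min_conserved <= self.window:
            raise ValueError("need 1 <= min_conserved <= window")
        if self.conservation_rule not in ("identical_only", "identical_or_strong_group"):
            raise ValueError(f"unknown conservation_rule {self.conservation_rule!r}")


@dataclass(frozen=True)
class IndelBlock:
    """A maximal run of in-group exclusive columns (0-based half-open)."""

    col_start: int
    col_end: int
    indel_type: str  # "insertion" | "deletion", relative to the out-group
    per_taxon_size: dict[str, int]  # residue count within the block
    carrier_set: frozenset[str]

    def __post_init__(self) -> None:
        if self.col_start >= self.col_end:
            raise ValueError("empty block")
        if not self.carrier_set:
            raise ValueError("carrier set empty")

    @property
    def width(self) -> int:
        return self.col_end - self.col_start

    def carrier_sizes(self) -> dict[str, int]:
        """Indel size per carrier: residues carried (insertion) or
        residues missing relative to block width (deletion)."""
        if self.indel_type == "insertion":
            return {t: self.per_taxon_size[t] for t in self.carrier_set}
        return {t: self.width - self.per_taxon_size[t] for t in self.carrier_set}


@dataclass(frozen=True)
class SpecificityResult:
    n_checked: int
    violations: tuple[tuple[str, str], ...]
    unevaluated: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.violations


@dataclass(frozen=True)
class CsiRecord:
    """One detected conserved signature indel."""

    protein_name: str
    reference_taxon: str
    reference_protein_id: str
    indel_type: str
    size_min: int
    size_max: int
    region_start: int  # 1-based inclusive, ungapped reference coordinates
    region_end: int
    left_flank_conserved: int
    right_flank_conserved: int
    clade_rank: str
    clade_label: str
    exceptions: tuple[str, ...]
    col_start: int = 0  # 0-based half-open alignment columns of the block
    col_end: int = 0
    region_col_start: int = 0  # block plus flank windows, alignment columns
    region_col_end: int = 0
    specificity: Optional[SpecificityResult] = None

    def __post_init__(self) -> None:
        if self.size_min > self.size_max:
            raise ValueError("size_min > size_max")
        if self.region_start > self.region_end:
            raise ValueError("region_start > region_end")

    @property
    def size_label(self) -> str:
        if self.size_min == self.size_max:
            return f"{self.size_min} aa"
        return f"{self.size_min} ~ {self.size_max} aa"


def _split_rows(alignment: Alignment, manifest: GroupManifest) -> tuple[list[str], list[str]]:
    ingroup = manifest.ingroup_taxa()
    in_rows, out_rows = [], []
    for taxon in alignment.taxa:
        if taxon not in manifest.known_taxa:
            raise ValueError(f"alignment taxon {taxon!r} missing from manifest")
        (in_rows if taxon in ingroup else out_rows).append(taxon)
    return in_rows, out_rows


def classify_columns(
    alignment: Alignment,
    manifest: GroupManifest,
    params: ColumnParams = ColumnParams(),
) -> list[str]:
    """Classify every column by in-group exclusivity of residue/gap state.

    Taxa absent from the alignment contribute nothing (missing data is not
    gap evidence); every aligned taxon must appear in the manifest.
    """
    in_rows, out_rows = _split_rows(alignment, manifest)
    in_seqs = [alignment.row(t) for t in in_rows]
    out_seqs = [alignment.row(t) for t in out_rows]
    n_in, n_out = len(in_seqs), len(out_seqs)
    states: list[str] = []
    for c in range(alignment.length):
        in_res = sum(1 for s in in_seqs if s[c] != GAP)
        out_res = sum(1 for s in out_seqs if s[c] != GAP)
        in_gap, out_gap = n_in - in_res, n_out - out_res
        if (
            n_in
            and n_out
            and in_res / n_in >= params.tau_in
            and out_gap / n_out >= params.tau_out
        ):
            states.append(INGROUP_EXCLUSIVE_RESIDUE)
        elif (
            n_in
            and n_out
            and in_gap / n_in >= params.tau_in
            and out_res / n_out >= params.tau_out
        ):
            states.append(INGROUP_EXCLUSIVE_GAP)
        elif in_res + out_res == n_in + n_out:
            states.append(SHARED)
        else:
            states.append(OTHER)
    return states


def find_indel_blocks(
    alignment: Alignment,
    column_states: Sequence[str],
    manifest: GroupManifest,
) -> list[IndelBlock]:
    """Merge maximal runs of exclusive columns into insertion/deletion blocks."""
    if len(column_states) != alignment.length:
        raise ValueError("column_states length does not match alignment")
    ingroup = manifest.ingroup_taxa()
    blocks: list[IndelBlock] = []
    c = 0
    n = alignment.length
    while c < n:
        state = column_states[c]
        if state not in (INGROUP_EXCLUSIVE_RESIDUE, INGROUP_EXCLUSIVE_GAP):
            c += 1
            continue
        start = c
        while c < n and column_states[c] == state:
            c += 1
        end = c
        indel_type = (
            "insertion" if state == INGROUP_EXCLUSIVE_RESIDUE else "deletion"
        )
        per_taxon = {
            t: sum(1 for cc in range(start, end) if s[cc] != GAP)
            for t, s in alignment.rows
        }
        width = end - start
        if indel_type == "insertion":
            carriers = frozenset(
                t for t in alignment.taxa if t in ingroup and per_taxon[t] > 0
            )
        else:
            carriers = frozenset(
                t for t in alignment.taxa if t in ingroup and per_taxon[t] < width
            )
        blocks.append(IndelBlock(start, end, indel_type, per_taxon, carriers))
    return blocks


def _column_conserved(residues: str, rule: str) -> bool:
    uniq = set(residues)
    if len(uniq) == 1:
        return True
    if rule == "identical_or_strong_group":
        return any(uniq <= g for g in STRONG_GROUPS)
    return False


def _flank_window(
    alignment: Alignment, from_col: int, direction: int, width: int
) -> list[int]:
    """Up to `width` gap-free columns walking away from the block edge."""
    cols: list[int] = []
    c = from_col
    while 0 <= c < alignment.length and len(cols) < width:
        col = alignment.column(c)
        if GAP not in col:
            cols.append(c)
        c += direction
    return cols


def score_flanks(
    alignment: Alignment, block: IndelBlock, params: FlankParams = FlankParams()
) -> tuple[int, int, bool]:
    """Count conserved columns in the gap-free windows flanking a block.

    Columns that are gap in any row are skipped (the rule is about
    residues); windows truncated at alignment edges use what is available.
    """
    left_cols = _flank_window(alignment, block.col_start - 1, -1, params.window)
    right_cols = _flank_window(alignment, block.col_end, +1, params.window)
    left = sum(
        1
        for c in left_cols
        if _column_conserved(alignment.column(c), params.conservation_rule)
    )
    right = sum(
        1
        for c in right_cols
        if _column_conserved(alignment.column(c), params.conservation_rule)
    )
    passed = left >= params.min_conserved and right >= params.min_conserved
    return left, right, passed


def match_clade_pattern(
    block: IndelBlock,
    manifest: GroupManifest,
    alignment_taxa: Iterable[str],
    max_exceptions: int = 0,
) -> Optional[tuple[str, str, tuple[str, ...]]]:
    """Match the carrier set against named clades, tolerating exceptions.

    Clade membership is restricted to taxa present in the alignment.  A
    clade qualifies when no carrier falls outside it and at most
    `max_exceptions` members are non-carriers.  The smallest qualifying
    clade wins; ties break by fewest exceptions, then label.
    """
    present = set(alignment_taxa)
    carriers = set(block.carrier_set)
    best: Optional[tuple[tuple[int, int, str, str], tuple[str, str, tuple[str, ...]]]] = None
    for rank, label, members in manifest.clades():
        members_here = members & present
        if not members_here:
            continue
        outside = carriers - members_here
        exceptions = members_here - carriers
        if outside or len(exceptions) > max_exceptions:
            continue
        key = (len(members_here), len(exceptions), label, rank)
        cand = (rank, label, tuple(sorted(exceptions)))
        if best is None or key < best[0]:
            best = (key, cand)
    return best[1] if best else None


def extract_signature_segment(
    alignment: Alignment,
    block: IndelBlock,
    reference_taxon: str,
    target_len: int = 80,
    length_bounds: tuple[int, int] = (60, 100),
) -> SequenceRecord:
    """Ungapped reference segment centered on the block, 60-100 aa.

    The window is clamped to the sequence bounds while preserving length;
    references shorter than the lower bound yield the whole sequence with
    a logged warning.
    """
    lo, hi = length_bounds
    target = max(lo, min(hi, target_len))
    ref_gapped = alignment.row(reference_taxon)
    ref_seq = ref_gapped.replace(GAP, "")
    colmap = column_to_ungapped_map(alignment, reference_taxon)
    # ungapped positions (1-based) of reference residues inside/adjacent to block
    block_pos = [
        colmap[c + 1] for c in range(block.col_start, block.col_end) if colmap[c + 1]
    ]
    if block_pos:
        mid = (block_pos[0] + block_pos[-1]) / 2.0
    else:
        # deletion in the reference: center between the nearest residues
        left = next(
            (colmap[c + 1] for c in range(block.col_start - 1, -1, -1) if colmap[c + 1]),
            0,
        )
        mid = left + 0.5
    if len(ref_seq) < lo:
        logger.warning(
            "reference %s shorter than %d aa; using whole sequence as segment",
            reference_taxon,
            lo,
        )
        start, end = 1, len(ref_seq)
    else:
        target = min(target, len(ref_seq))
        start = int(round(mid - target / 2.0)) + 1
        start = max(1, min(start, len(ref_seq) - target + 1))
        end = start + target - 1
    return SequenceRecord(
        identifier=f"{reference_taxon}_segment",
        residues=ref_seq[start - 1 : end],
        description=f"region={start}-{end} indel_cols={block.col_start}-{block.col_end}",
        alphabet_tag="protein",
    )


def _segment_indel_offset(
    alignment: Alignment, block: IndelBlock, reference_taxon: str, segment_start: int
) -> tuple[int, int]:
    """0-based half-open offsets of the block residues within the segment."""
    colmap = column_to_ungapped_map(alignment, reference_taxon)
    positions = [
        colmap[c + 1] for c in range(block.col_start, block.col_end) if colmap[c + 1]
    ]
    if positions:
        return positions[0] - segment_start, positions[-1] - segment_start + 1
    left = next(
        (colmap[c + 1] for c in range(block.col_start - 1, -1, -1) if colmap[c + 1]), 0
    )
    off = left - segment_start + 1
    return off, off


def subject_carries_indel(
    segment: SequenceRecord,
    indel_offsets: tuple[int, int],
    indel_type: str,
    size_range: tuple[int, int],
    subject: SequenceRecord,
) -> bool:
    """Pairwise carrier test: does `subject` bear the signature indel?

    The segment (from a carrier reference) is globally aligned to the
    subject with BLOSUM62, gap open 11 / extend 1.  For an insertion-type
    CSI a non-carrier shows a gap run of the signature size in its aligned
    row across the insert; for a deletion-type CSI a non-carrier forces
    such a run into the segment's row at the deletion point.
    """
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(segment.residues, subject.residues)[0]
    seg_row, sub_row = str(aln[0]), str(aln[1])

    # map segment positions -> alignment columns
    seg_cols: list[int] = []
    for col, ch in enumerate(seg_row):
        if ch != GAP:
            seg_cols.append(col)
    off_start, off_end = indel_offsets
    size_min, size_max = size_range

    def gap_runs(row: str, lo: int, hi: int) -> list[int]:
        """Lengths of maximal gap runs in row overlapping columns [lo, hi)."""
        runs: list[tuple[int, int]] = []
        c = 0
        while c < len(row):
            if row[c] == GAP:
                s = c
                while c < len(row) and row[c] == GAP:
                    c += 1
                runs.append((s, c))
            else:
                c += 1
        return [e - s for s, e in runs if e > lo and s < hi]

    if indel_type == "insertion":
        if off_start >= off_end:  # degenerate
            return False
        lo = seg_cols[off_start] if off_start < len(seg_cols) else len(seg_row)
        hi = seg_cols[off_end - 1] + 1 if off_end - 1 < len(seg_cols) else len(seg_row)
        runs = gap_runs(sub_row, lo, hi)
        # non-carrier: subject gapped across the insert at the signature size
        return not any(size_min <= r <= size_max for r in runs)
    # deletion: look for extra subject residues (gap run in segment row)
    # around the deletion point
    if off_start < len(seg_cols):
        anchor = seg_cols[off_start]
    else:
        anchor = len(seg_row)
    left_col = seg_cols[off_start - 1] if off_start >= 1 else -1
    runs = gap_runs(seg_row, left_col + 1, anchor)
    return not any(size_min <= r <= size_max for r in runs)


def validate_specificity(
    csi: CsiRecord,
    block: IndelBlock,
    alignment: Alignment,
    hits: HitTable,
    subjects: dict[str, SequenceRecord],
    manifest: GroupManifest,
    top_n: int = 500,
) -> SpecificityResult:
    """Check the top-N most similar subjects for presence/absence of the CSI.

    Violations: an out-clade subject carrying the indel, or an in-clade
    subject (not a listed exception) lacking it.  Subjects whose sequence
    is unavailable or whose taxon is unresolvable are recorded as
    unevaluated and excluded from the decision.
    """
    segment = extract_signature_segment(alignment, block, csi.reference_taxon)
    seg_start = int(segment.description.split("region=")[1].split(" ")[0].split("-")[0])
    offsets = _segment_indel_offset(alignment, block, csi.reference_taxon, seg_start)
    clade_members = manifest.members(csi.clade_rank, csi.clade_label)
    violations: list[tuple[str, str]] = []
    unevaluated: list[str] = []
    n_checked = 0
    seen: set[str] = set()
    for hit in hits:
        if n_checked >= top_n:
            break
        if hit.subject_id in seen:
            continue
        seen.add(hit.subject_id)
        taxon = hit.subject_taxon
        if taxon == "unknown":
            logger.warning("subject %s has unresolvable taxon; skipped", hit.subject_id)
            unevaluated.append(hit.subject_id)
            continue
        subject = subjects.get(hit.subject_id)
        if subject is None:
            unevaluated.append(hit.subject_id)
            continue
        n_checked += 1
        carries = subject_carries_indel(
            segment, offsets, csi.indel_type, (csi.size_min, csi.size_max), subject
        )
        in_clade = taxon in clade_members
        if carries and not in_clade:
            violations.append((hit.subject_id, "out-clade subject carries the indel"))
        elif not carries and in_clade and taxon not in csi.exceptions:
            violations.append((hit.subject_id, "in-clade subject lacks the indel"))
    return SpecificityResult(n_checked, tuple(violations), tuple(unevaluated))


def detect_csis(
    alignment: Alignment,
    manifest: GroupManifest,
    column_params: ColumnParams = ColumnParams(),
    flank_params: FlankParams = FlankParams(),
    max_exceptions: int = 0,
    protein_name: str = "",
    reference_taxon: Optional[str] = None,
    reference_protein_id: str = "",
) -> list[CsiRecord]:
    """End-to-end CSI scan of one protein family alignment.

    Pipeline: column classification -> block merging -> flank scoring
    (failing blocks dropped) -> clade matching (unmatched dropped) ->
    reference-coordinate mapping.  Records are sorted by region start.
    """
    in_rows, out_rows = _split_rows(alignment, manifest)
    if len(in_rows) < 2 or len(out_rows) < 2:
        raise ValueError(
            "insufficient taxa: need at least 2 in-group and 2 out-group rows"
        )
    if reference_taxon is None:
        reference_taxon = in_rows[0]
    # Block discovery must tolerate up to max_exceptions in-group rows in
    # the non-indel state, otherwise an exception taxon would hide the
    # column entirely; exceptions themselves are named by clade matching.
    eff_params = column_params
    if max_exceptions > 0:
        n_in = len(in_rows)
        tau_eff = max(1, n_in - max_exceptions) / n_in
        if tau_eff < column_params.tau_in:
            eff_params = replace(column_params, tau_in=tau_eff)
    states = classify_columns(alignment, manifest, eff_params)
    records: list[CsiRecord] = []
    colmap = column_to_ungapped_map(alignment, reference_taxon)
    for block in find_indel_blocks(alignment, states, manifest):
        left, right, passed = score_flanks(alignment, block, flank_params)
        if not passed:
            continue
        match = match_clade_pattern(
            block, manifest, alignment.taxa, max_exceptions=max_exceptions
        )
        if match is None:
            continue
        rank, label, exceptions = match
        sizes = block.carrier_sizes()
        size_min, size_max = min(sizes.values()), max(sizes.values())
        left_cols = _flank_window(alignment, block.col_start - 1, -1, flank_params.window)
        right_cols = _flank_window(alignment, block.col_end, +1, flank_params.window)
        region_cols = sorted(
            set(left_cols) | set(right_cols) | set(range(block.col_start, block.col_end))
        )
        positions = [colmap[c + 1] for c in region_cols if colmap[c + 1] is not None]
        if not positions:
            continue
        records.append(
            CsiRecord(
                protein_name=protein_name,
                reference_taxon=reference_taxon,
                reference_protein_id=reference_protein_id,
                indel_type=block.indel_type,
                size_min=size_min,
                size_max=size_max,
                region_start=min(positions),
                region_end=max(positions),
                left_flank_conserved=left,
                right_flank_conserved=right,
                clade_rank=rank,
                clade_label=label,
                exceptions=exceptions,
                col_start=block.col_start,
                col_end=block.col_end,
                region_col_start=region_cols[0],
                region_col_end=region_cols[-1] + 1,
            )
        )
    records.sort(key=lambda r: (r.region_start, r.region_end))
    return records


IDENTITY_CHAR = "-"  # identity with the top line
GAP_PLACEHOLDER = "."  # row is gapped at this column


def format_signature_report(
    csi: CsiRecord,
    alignment: Alignment,
    manifest: GroupManifest,
    group_order: Optional[Sequence[str]] = None,
) -> str:
    """Render one signature block in the dash-for-identity convention.

    The top line shows the reference residues for the region (its own gaps
    as '.'); every other row prints '-' where identical to the top line,
    the residue where different, and '.' where gapped.  In-clade rows are
    listed first.
    """
    cols = list(range(csi.region_col_start, csi.region_col_end))
    ref_row = alignment.row(csi.reference_taxon)
    top = "".join(
        ref_row[c] if ref_row[c] != GAP else GAP_PLACEHOLDER for c in cols
    )
    clade_members = manifest.members(csi.clade_rank, csi.clade_label)
    if group_order is None:
        in_rows = [t for t in alignment.taxa if t in clade_members]
        out_rows = [t for t in alignment.taxa if t not in clade_members]
        order = in_rows + out_rows
    else:
        order = list(group_order)
    # the reference supplies the top line and must come first
    if csi.reference_taxon in order:
        order.remove(csi.reference_taxon)
    order.insert(0, csi.reference_taxon)
    name_w = max(len(t) for t in order)
    lines = [
        f"# {csi.protein_name or 'protein'} {csi.reference_protein_id}".rstrip(),
        f"# {csi.size_label} {csi.indel_type[:3]} {csi.region_start}–{csi.region_end} "
        f"{csi.clade_label}"
        + (f" except {', '.join(csi.exceptions)}" if csi.exceptions else ""),
    ]
    for taxon in order:
        row = alignment.row(taxon)
        if taxon == csi.reference_taxon:
            body = top
        else:
            chars = []
            for i, c in enumerate(cols):
                ch = row[c]
                if ch == GAP:
                    chars.append(GAP_PLACEHOLDER)
                elif ch == top[i]:
                    chars.append(IDENTITY_CHAR)
                else:
                    chars.append(ch)
            body = "".join(chars)
        lines.append(f"{taxon:<{name_w}}  {body}")
    return "\n".join(lines) + "\n"


def expand_signature_rows(report: str) -> dict[str, str]:
    """Invert the dash-for-identity convention back to gapped residues."""
    rows = [ln for ln in report.splitlines() if ln and not ln.startswith("#")]
    parsed = []
    for ln in rows:
        name, body = ln.rsplit("  ", 1)
        parsed.append((name.strip(), body))
    top = parsed[0][1]
    out: dict[str, str] = {}
    for i, (name, body) in enumerate(parsed):
        if i == 0:
            out[name] = top.replace(GAP_PLACEHOLDER, GAP)
            continue
        chars = []
        for j, ch in enumerate(body):
            if ch == GAP_PLACEHOLDER:
                chars.append(GAP)
            elif ch == IDENTITY_CHAR:
                chars.append(top[j] if top[j] != GAP_PLACEHOLDER else GAP)
            else:
                chars.append(ch)
        out[name] = "".join(chars)
    return out
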