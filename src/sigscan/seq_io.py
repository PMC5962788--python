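"""Readers/writers for sequence, alignment, hit-table and manifest formats.

All coordinates are 0-based half-open internally; anything written to a file
or a report is 1-based inclusive. The only gap character used internally is
``'-'``; the ``'.'`` and ``'~'`` dialects are normalized on read.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO

GAP = "-"
PROTEIN_RESIDUES = set("ACDEFGHIKLMNPQRSTVWYX")
NUCLEOTIDE_RESIDUES = set("ACGTN")
_GAP_DIALECTS = str.maketrans({".": GAP, "~": GAP})


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class SequenceRecord:
    """One ungapped sequence (protein or nucleotide)."""

    identifier: str
    residues: str
    description: str = ""
    alphabet_tag: str = "protein"

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"empty sequence for {self.identifier!r}")
        if GAP in self.residues:
            raise ValueError(f"gap character in ungapped record {self.identifier!r}")

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """Rectangular gapped sequence matrix keyed by taxon identifier.

    Columns consisting entirely of gaps are dropped at construction, so the
    published invariant (every column has at least one residue) holds for any
    Alignment in circulation.
    """

    def __init__(self, rows: Iterable[tuple[str, str]]):
        rows = [(str(t), str(s).upper().translate(_GAP_DIALECTS)) for t, s in rows]
        if len(rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        length = len(rows[0][1])
        for taxon, seq in rows:
            if len(seq) != length:
                raise ParseError(
                    f"ragged alignment row for taxon {taxon!r}: "
                    f"length {len(seq)} != {length}"
                )
        seen: set[str] = set()
        for taxon, _ in rows:
            if taxon in seen:
                raise ParseError(f"duplicate taxon_id {taxon!r} in alignment")
            seen.add(taxon)
        keep = [
            c for c in range(length) if any(seq[c] != GAP for _, seq in rows)
        ]
        if len(keep) != length:
            rows = [(t, "".join(s[c] for c in keep)) for t, s in rows]
        self._rows: list[tuple[str, str]] = rows
        self._index = {t: i for i, (t, _) in enumerate(rows)}

    @property
    def rows(self) -> list[tuple[str, str]]:
        return list(self._rows)

    @property
    def taxa(self) -> list[str]:
        return [t for t, _ in self._rows]

    @property
    def length(self) -> int:
        return len(self._rows[0][1])

    @property
    def n_rows(self) -> int:
        return len(self._rows)

    def row(self, taxon: str) -> str:
        try:
            return self._rows[self._index[taxon]][1]
        except KeyError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._index

    def column(self, c: int) -> str:
        return "".join(seq[c] for _, seq in self._rows)

    def take_columns(self, cols: Sequence[int]) -> "Alignment":
        return Alignment((t, "".join(s[c] for c in cols)) for t, s in self._rows)

    def subset(self, taxa: Sequence[str]) -> "Alignment":
        return Alignment((t, self.row(t)) for t in taxa)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, Alignment) and self._rows == other._rows

    def __repr__(self) -> str:
        return f"<Alignment {self.n_rows} rows x {self.length} cols>"


@dataclass
class GroupManifest:
    """Taxon-to-clade labels at named ranks plus the designated in-group."""

    entries: dict[str, dict[str, str]]
    ingroup_clade: Optional[tuple[str, str]] = None

    @property
    def known_taxa(self) -> set[str]:
        return set(self.entries)

    @property
    def ranks(self) -> list[str]:
        ranks: list[str] = []
        for labels in self.entries.values():
            for r in labels:
                if r not in ranks:
                    ranks.append(r)
        return ranks

    def label_of(self, taxon: str, rank: str) -> str:
        return self.entries[taxon].get(rank, "unassigned")

    def members(self, rank: str, label: str) -> set[str]:
        return {
            t for t, labels in self.entries.items() if labels.get(rank) == label
        }

    def clades(self) -> list[tuple[str, str, frozenset[str]]]:
        """All (rank, label, member set) pairs, 'unassigned' excluded."""
        out: dict[tuple[str, str], set[str]] = {}
        for taxon, labels in self.entries.items():
            for rank, label in labels.items():
                if label != "unassigned":
                    out.setdefault((rank, label), set()).add(taxon)
        return sorted(
            ((r, l, frozenset(m)) for (r, l), m in out.items()),
            key=lambda x: (x[0], x[1]),
        )

    def ingroup_taxa(self) -> set[str]:
        if self.ingroup_clade is None:
            raise ValueError("manifest has no designated in-group clade")
        return self.members(*self.ingroup_clade)

    def with_ingroup(self, rank: str, label: str) -> "GroupManifest":
        if not self.members(rank, label):
            raise ValueError(f"in-group clade ({rank!r}, {label!r}) has no taxa")
        return GroupManifest(self.entries, (rank, label))


@dataclass(frozen=True)
class HitRecord:
    """One pairwise similarity hit, 12-column tabular style (1-based coords)."""

    query_id: str
    subject_id: str
    percent_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    subject_taxon: str = "unknown"

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError("q_start > q_end")
        if self.evalue < 0:
            raise ValueError("negative E-value")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError("percent_identity outside [0, 100]")


class HitTable:
    """Hits held in deterministic (query_id, descending bitscore) order."""

    def __init__(self, hits: Iterable[HitRecord]):
        self._hits = sorted(
            hits, key=lambda h: (h.query_id, -h.bitscore, h.evalue, h.subject_id)
        )

    @property
    def hits(self) -> list[HitRecord]:
        return list(self._hits)

    def for_query(self, query_id: str) -> list[HitRecord]:
        return [h for h in self._hits if h.query_id == query_id]

    def __len__(self) -> int:
        return len(self._hits)

    def __iter__(self):
        return iter(self._hits)


def _taxon_from_subject(subject_id: str) -> str:
    if "|" in subject_id:
        prefix = subject_id.split("|", 1)[0]
        if prefix:
            return prefix
    return "unknown"


def read_fasta(path: str | Path, alphabet_tag: str = "protein") -> list[SequenceRecord]:
    """Read unaligned FASTA; residues uppercased, terminal '*' stripped."""
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    records: list[SequenceRecord] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path.name}: sequence data before any header at line {lineno}"
            )
        break
    seen: set[str] = set()
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        residues = str(rec.seq).upper().rstrip("*")
        if rec.id in seen:
            raise ParseError(f"{path.name}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id) :].strip()
        records.append(
            SequenceRecord(rec.id, residues, desc, alphabet_tag=alphabet_tag)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.identifier}"
            if rec.description:
                header += f" {rec.description}"
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def read_alignment(path: str | Path, dialect: str = "aligned-fasta") -> Alignment:
    """Read an alignment from aligned FASTA or Clustal format."""
    path = Path(path)
    if dialect == "aligned-fasta":
        rows = []
        for rec in SeqIO.parse(str(path), "fasta"):
            rows.append((rec.id, str(rec.seq)))
        if not rows:
            raise ParseError(f"{path.name}: no sequences found")
        return Alignment(rows)
    if dialect == "clustal":
        from Bio import AlignIO

        msa = AlignIO.read(str(path), "clustal")
        return Alignment((rec.id, str(rec.seq)) for rec in msa)
    raise ValueError(f"unknown alignment dialect {dialect!r}")


def write_alignment(alignment: Alignment, path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for taxon, seq in alignment.rows:
            fh.write(f">{taxon}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_hits_tabular(path: str | Path) -> HitTable:
    """Read a 12/13-column tab-separated hit table (BLAST outfmt-6 style).

    The optional 13th column is the subject taxon; otherwise it is parsed
    from a ``taxon|protein`` subject identifier, falling back to "unknown".
    """
    path = Path(path)
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (12, 13):
                raise ParseError(
                    f"{path.name}: expected 12 or 13 columns at line {lineno}, "
                    f"got {len(fields)}"
                )
            try:
                taxon = (
                    fields[12] if len(fields) == 13 else _taxon_from_subject(fields[1])
                )
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                        subject_taxon=taxon,
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path.name}: line {lineno}: {exc}") from exc
    return HitTable(hits)


def write_hits_tabular(table: HitTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in table:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id,
                        h.subject_id,
                        f"{h.percent_identity:.2f}",
                        h.aln_length,
                        h.mismatches,
                        h.gap_opens,
                        h.q_start,
                        h.q_end,
                        h.s_start,
                        h.s_end,
                        f"{h.evalue:.3g}",
                        f"{h.bitscore:.1f}",
                        h.subject_taxon,
                    )
                )
                + "\n"
            )


def read_manifest(path: str | Path) -> GroupManifest:
    """Read a TSV manifest: header ``taxon_id`` plus one column per rank."""
    path = Path(path)
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ParseError(f"{path.name}: empty manifest")
    header = lines[0].split("\t")
    if header[0] != "taxon_id":
        raise ParseError(f"{path.name}: first header column must be 'taxon_id'")
    ranks = header[1:]
    entries: dict[str, dict[str, str]] = {}
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        taxon = fields[0]
        if taxon in entries:
            raise ParseError(f"{path.name}: duplicate taxon_id {taxon!r} at line {lineno}")
        labels = {}
        for i, rank in enumerate(ranks):
            cell = fields[i + 1].strip() if i + 1 < len(fields) else ""
            labels[rank] = cell if cell else "unassigned"
        entries[taxon] = labels
    return GroupManifest(entries)


def write_manifest(manifest: GroupManifest, path: str | Path) -> None:
    ranks = manifest.ranks
    with open(path, "w") as fh:
        fh.write("\t".join(["taxon_id"] + ranks) + "\n")
        for taxon in sorted(manifest.entries):
            labels = manifest.entries[taxon]
            fh.write(
                "\t".join([taxon] + [labels.get(r, "unassigned") for r in ranks]) + "\n"
            )


def column_to_ungapped_map(alignment: Alignment, taxon_id: str) -> dict[int, Optional[int]]:
    """Map 1-based alignment column -> 1-based ungapped position (None at gaps)."""
    seq = alignment.row(taxon_id)
    out: dict[int, Optional[int]] = {}
    pos = 0
    for c, ch in enumerate(seq, start=1):
        if ch == GAP:
            out[c] = None
        else:
            pos += 1
            out[c] = pos
    return out
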