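"""Calling conserved signature proteins (CSPs).

A CSP is a protein whose significant homologs occur in (nearly) all
members of the in-group clade and in none of the taxa outside it, judged
from a tabular homology-hit table.  Significance is an E-value test:
`e_in` bounds what counts as an in-group hit, `e_out` bounds what counts
as a disqualifying out-group hit.  Multiple hits per (query, taxon) are
collapsed to the best E-value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .seq_io import GroupManifest, HitTable, SequenceRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CspParams:
    e_in: float = 1e-5
    e_out: float = 1e-3
    min_ingroup_fraction: float = 0.8
    min_length: int = 50

    def __post_init__(self) -> None:
        if not 0.0 < self.min_ingroup_fraction <= 1.0:
            raise ValueError("min_ingroup_fraction must be in (0, 1]")
        if self.min_length < 1:
            raise ValueError("min_length must be positive")


@dataclass(frozen=True)
class CspRecord:
    protein_id: str
    length: int
    clade_rank: str
    clade_label: str
    ingroup_coverage: float
    best_outgroup_evalue: Optional[float]
    exceptions: tuple[str, ...]


def call_csps(
    query_proteome: Iterable[SequenceRecord],
    hits: HitTable,
    manifest: GroupManifest,
    params: CspParams = CspParams(),
    query_taxon: Optional[str] = None,
) -> list[CspRecord]:
    """Emit every query protein exclusive to the in-group clade.

    A protein qualifies when the fraction of distinct in-group taxa with a
    hit at E <= e_in (the query's own taxon always counts) reaches
    `min_ingroup_fraction`, and no out-group taxon hits at E <= e_out.
    Queries shorter than `min_length` are not considered.  Hits with
    unresolvable taxa are excluded from the decision with a warning.
    """
    rank, label = manifest.ingroup_clade if manifest.ingroup_clade else (None, None)
    if rank is None:
        raise ValueError("manifest has no designated in-group clade")
    ingroup = manifest.ingroup_taxa()
    records: list[CspRecord] = []
    for query in query_proteome:
        if len(query) < params.min_length:
            continue
        best_by_taxon: dict[str, float] = {}
        for hit in hits.for_query(query.identifier):
            taxon = hit.subject_taxon
            if taxon == "unknown":
                logger.warning(
                    "hit %s -> %s has unresolvable taxon; ignored",
                    hit.query_id,
                    hit.subject_id,
                )
                continue
            e = best_by_taxon.get(taxon)
            if e is None or hit.evalue < e:
                best_by_taxon[taxon] = hit.evalue
        if query_taxon is not None:
            best_by_taxon.setdefault(query_taxon, 0.0)
        covered = {
            t for t, e in best_by_taxon.items() if t in ingroup and e <= params.e_in
        }
        out_evalues = [e for t, e in best_by_taxon.items() if t not in ingroup]
        best_out = min(out_evalues) if out_evalues else None
        coverage = len(covered) / len(ingroup)
        if coverage < params.min_ingroup_fraction:
            continue
        if best_out is not None and best_out <= params.e_out:
            continue
        records.append(
            CspRecord(
                protein_id=query.identifier,
                length=len(query),
                clade_rank=rank,
                clade_label=label,
                ingroup_coverage=coverage,
                best_outgroup_evalue=best_out,
                exceptions=tuple(sorted(ingroup - covered)),
            )
        )
    records.sort(key=lambda r: r.protein_id)
    return records


def summarize_csps(records: Iterable[CspRecord]) -> list[tuple[str, str, int]]:
    """Per-clade (rank, label, count) rows, stably ordered."""
    counts: dict[tuple[str, str], int] = {}
    for rec in records:
        key = (rec.clade_rank, rec.clade_label)
        counts[key] = counts.get(key, 0) + 1
    return [(r, l, n) for (r, l), n in sorted(counts.items())]
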