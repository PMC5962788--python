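"""Run orchestration: validated YAML configs, discovery and tree runs,
deterministic TSV/report artifacts, and machine-readable provenance."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from . import csi as csi_mod
from . import csp as csp_mod
from . import phylo as phylo_mod
from .seq_io import (
    read_alignment,
    read_fasta,
    read_hits_tabular,
    read_manifest,
)

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_KNOWN_KEYS = {
    "schema_version",
    "seed",
    "manifest",
    "ingroup",
    "alignments",
    "proteome",
    "proteome_taxon",
    "hits",
    "subjects",
    "max_exceptions",
    "column_params",
    "flank_params",
    "csp_params",
    "trim",
    "concat_policy",
    "bootstrap",
    "distance",
    "out_dir",
}


class ConfigError(ValueError):
    """Invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    manifest: Path
    ingroup: tuple[str, str]
    out_dir: Path
    seed: int = 0
    alignments: list[dict[str, Any]] = field(default_factory=list)
    proteome: Optional[Path] = None
    proteome_taxon: Optional[str] = None
    hits: Optional[Path] = None
    subjects: Optional[Path] = None
    max_exceptions: int = 0
    column_params: csi_mod.ColumnParams = field(default_factory=csi_mod.ColumnParams)
    flank_params: csi_mod.FlankParams = field(default_factory=csi_mod.FlankParams)
    csp_params: csp_mod.CspParams = field(default_factory=csp_mod.CspParams)
    trim: Optional[phylo_mod.TrimParams] = None
    concat_policy: str = "strict"
    bootstrap: int = 100
    distance: str = "p"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        if raw.get("schema_version") != SCHEMA_VERSION:
            raise ConfigError(
                f"{path}: schema_version must be {SCHEMA_VERSION}"
            )
        base = path.parent

        def respath(p) -> Path:
            p = Path(p)
            return p if p.is_absolute() else base / p

        try:
            ingroup = (raw["ingroup"]["rank"], raw["ingroup"]["label"])
            manifest = respath(raw["manifest"])
        except KeyError as exc:
            raise ConfigError(f"{path}: missing required key {exc}") from exc
        alignments = []
        for item in raw.get("alignments", []) or []:
            if isinstance(item, str):
                item = {"path": item}
            item = dict(item)
            item["path"] = respath(item["path"])
            alignments.append(item)
        cfg = cls(
            manifest=manifest,
            ingroup=ingroup,
            out_dir=respath(raw.get("out_dir", "out")),
            seed=int(raw.get("seed", 0)),
            alignments=alignments,
            proteome=respath(raw["proteome"]) if raw.get("proteome") else None,
            proteome_taxon=raw.get("proteome_taxon"),
            hits=respath(raw["hits"]) if raw.get("hits") else None,
            subjects=respath(raw["subjects"]) if raw.get("subjects") else None,
            max_exceptions=int(raw.get("max_exceptions", 0)),
            column_params=csi_mod.ColumnParams(**(raw.get("column_params") or {})),
            flank_params=csi_mod.FlankParams(**(raw.get("flank_params") or {})),
            csp_params=csp_mod.CspParams(**(raw.get("csp_params") or {})),
            trim=(
                phylo_mod.TrimParams(**(raw.get("trim") or {}))
                if raw.get("trim") is not None
                else None
            ),
            concat_policy=raw.get("concat_policy", "strict"),
            bootstrap=int(raw.get("bootstrap", 100)),
            distance=raw.get("distance", "p"),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for p in [self.manifest, self.proteome, self.hits, self.subjects] + [
            a["path"] for a in self.alignments
        ]:
            if p is not None and not Path(p).exists():
                raise ConfigError(f"input file not found: {p}")
        if self.concat_policy not in ("strict", "gap-fill"):
            raise ConfigError(f"unknown concat_policy {self.concat_policy!r}")
        if self.distance not in ("p", "k2p"):
            raise ConfigError(f"unknown distance {self.distance!r}")
        if self.bootstrap < 1:
            raise ConfigError("bootstrap must be >= 1")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def _provenance(config: RunConfig, extra: dict[str, Any]) -> dict[str, Any]:
    inputs = {}
    for p in [config.manifest, config.proteome, config.hits, config.subjects] + [
        a["path"] for a in config.alignments
    ]:
        if p is not None:
            inputs[str(p)] = _digest(p)
    return {
        "schema_version": SCHEMA_VERSION,
        "seed": config.seed,
        "ingroup": list(config.ingroup),
        "max_exceptions": config.max_exceptions,
        "column_params": vars(config.column_params).copy()
        if hasattr(config.column_params, "__dict__")
        else {
            "tau_in": config.column_params.tau_in,
            "tau_out": config.column_params.tau_out,
        },
        "flank_params": {
            "window": config.flank_params.window,
            "min_conserved": config.flank_params.min_conserved,
            "conservation_rule": config.flank_params.conservation_rule,
        },
        "csp_params": {
            "e_in": config.csp_params.e_in,
            "e_out": config.csp_params.e_out,
            "min_ingroup_fraction": config.csp_params.min_ingroup_fraction,
            "min_length": config.csp_params.min_length,
        },
        "input_digests": inputs,
        **extra,
    }


CSI_HEADER = [
    "protein_name",
    "reference_taxon",
    "reference_protein_id",
    "indel_type",
    "size_min",
    "size_max",
    "region_start",
    "region_end",
    "left_flank_conserved",
    "right_flank_conserved",
    "clade_rank",
    "clade_label",
    "exceptions",
    "specificity_passed",
]

CSP_HEADER = [
    "protein_id",
    "length",
    "clade_rank",
    "clade_label",
    "ingroup_coverage",
    "best_outgroup_evalue",
    "exceptions",
]


def write_csi_tsv(records, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CSI_HEADER) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.protein_name,
                        r.reference_taxon,
                        r.reference_protein_id,
                        r.indel_type,
                        r.size_min,
                        r.size_max,
                        r.region_start,
                        r.region_end,
                        r.left_flank_conserved,
                        r.right_flank_conserved,
                        r.clade_rank,
                        r.clade_label,
                        ",".join(r.exceptions),
                        "" if r.specificity is None else r.specificity.passed,
                    )
                )
                + "\n"
            )


def write_csp_tsv(records, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(CSP_HEADER) + "\n")
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.protein_id,
                        r.length,
                        r.clade_rank,
                        r.clade_label,
                        f"{r.ingroup_coverage:.3f}",
                        "" if r.best_outgroup_evalue is None else f"{r.best_outgroup_evalue:.3g}",
                        ",".join(r.exceptions),
                    )
                )
                + "\n"
            )


def run_discover(config: RunConfig) -> dict[str, Any]:
    """CSI + CSP discovery from one config; an empty result is a result."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setLevel(logging.INFO)
    root = logging.getLogger("sigscan")
    root.addHandler(handler)
    try:
        manifest = read_manifest(config.manifest).with_ingroup(*config.ingroup)
        all_csis = []
        reports = []
        for item in config.alignments:
            aln = read_alignment(item["path"], item.get("dialect", "aligned-fasta"))
            records = csi_mod.detect_csis(
                aln,
                manifest,
                column_params=config.column_params,
                flank_params=config.flank_params,
                max_exceptions=config.max_exceptions,
                protein_name=item.get("protein_name", Path(item["path"]).stem),
                reference_taxon=item.get("reference_taxon"),
                reference_protein_id=item.get("reference_protein_id", ""),
            )
            logger.info("%s: %d CSI record(s)", item["path"], len(records))
            all_csis.extend(records)
            for rec in records:
                reports.append(csi_mod.format_signature_report(rec, aln, manifest))
        csps = []
        if config.proteome and config.hits:
            proteome = read_fasta(config.proteome)
            hits = read_hits_tabular(config.hits)
            csps = csp_mod.call_csps(
                proteome,
                hits,
                manifest,
                params=config.csp_params,
                query_taxon=config.proteome_taxon,
            )
            logger.info("%d CSP record(s)", len(csps))
        write_csi_tsv(all_csis, out / "csi.tsv")
        write_csp_tsv(csps, out / "csp.tsv")
        (out / "signatures.txt").write_text("\n".join(reports))
        summary = {
            "n_csi": len(all_csis),
            "n_csp": len(csps),
            "csp_by_clade": [
                list(row) for row in csp_mod.summarize_csps(csps)
            ],
        }
        prov = _provenance(config, {"command": "discover", "summary": summary})
        (out / "run.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
        return summary
    finally:
        root.removeHandler(handler)
        handler.close()


def run_tree(config: RunConfig) -> phylo_mod.PhyloTree:
    """Trim, concatenate, compute distances, NJ + bootstrap, write Newick."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alignments = [
        read_alignment(item["path"], item.get("dialect", "aligned-fasta"))
        for item in config.alignments
    ]
    if config.trim is not None:
        alignments = [
            phylo_mod.trim_conserved_blocks(a, config.trim) for a in alignments
        ]
    combined = phylo_mod.concatenate_alignments(alignments, config.concat_policy)
    fn = phylo_mod.p_distance if config.distance == "p" else phylo_mod.k2p_distance

    def named_fn(a: str, b: str) -> float:
        return fn(a, b)

    # name the offending pair on saturation
    taxa = combined.taxa
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            try:
                fn(combined.row(taxa[i]), combined.row(taxa[j]))
            except phylo_mod.SaturationError as exc:
                raise phylo_mod.SaturationError(
                    f"distance saturated for pair ({taxa[i]}, {taxa[j]}): {exc}"
                ) from exc
    tree = phylo_mod.bootstrap_support(
        combined, B=config.bootstrap, distance_fn=named_fn, seed=config.seed
    )
    (out / "tree.nwk").write_text(tree.newick() + "\n")
    prov = _provenance(
        config,
        {
            "command": "tree",
            "n_taxa": len(taxa),
            "alignment_length": combined.length,
            "bootstrap": config.bootstrap,
        },
    )
    (out / "run.json").write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n")
    return tree
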