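"""Ground-truthed synthetic inputs for the signature-discovery pipeline.

Protein families are evolved on a tree under a Poisson substitution
process with per-site rates; clade-specific indels are planted once on
the stem branch of their target clade, with frozen (rate-zero) flanking
sites so the planted signatures satisfy the flank-conservation rule by
construction.  The emitted alignment is the true residue homology (no
realignment step), so detector tests are decoupled from aligner error.
Proteome simulation plants clade-exclusive proteins next to background
proteins shared by every taxon, and a k-mer seeded similarity search
synthesizes the matching hit table.

Substitution uses a uniform replacement model rather than an empirical
exchangeability matrix: sufficient for exercising gap/conservation logic,
and a documented limitation for anything rate-sensitive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .seq_io import (
    GAP,
    Alignment,
    GroupManifest,
    HitRecord,
    HitTable,
    SequenceRecord,
)
from .phylo import PhyloTree, TreeNode

AA = "ACDEFGHIKLMNPQRSTVWY"


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class IndelPlan:
    """One planted clade-specific indel.

    position: 0-based root-sequence coordinate.  An insertion of `size`
    new residues is placed between root positions position-1 and
    position; a deletion removes root positions [position, position+size)
    in the clade.  `flank_frozen_len` sites on each side are frozen
    (substitution rate zero) so flanks stay identical across taxa.
    """

    clade_rank: str
    clade_label: str
    indel_type: str  # insertion | deletion
    size: int
    position: int
    flank_frozen_len: int = 35
    exceptions: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.indel_type not in ("insertion", "deletion"):
            raise ConfigError(f"unknown indel_type {self.indel_type!r}")
        if self.size < 1:
            raise ConfigError("indel size must be >= 1")

    def root_footprint(self) -> tuple[int, int]:
        """Root-coordinate interval covered by block plus frozen flanks."""
        if self.indel_type == "insertion":
            return (self.position - self.flank_frozen_len,
                    self.position + self.flank_frozen_len)
        return (self.position - self.flank_frozen_len,
                self.position + self.size + self.flank_frozen_len)


@dataclass(frozen=True)
class NoiseIndelPlan:
    """A background indel whose carrier set follows no clade pattern
    (e.g. mixes in-group and out-group taxa).  Applied on terminal
    branches (homoplasy is the point), with no frozen flanks."""

    carriers: tuple[str, ...]
    indel_type: str = "insertion"
    size: int = 3
    position: int = 0

    def __post_init__(self) -> None:
        if self.indel_type not in ("insertion", "deletion"):
            raise ConfigError(f"unknown indel_type {self.indel_type!r}")
        if self.size < 1 or not self.carriers:
            raise ConfigError("noise indel needs size >= 1 and carriers")

    def root_footprint(self) -> tuple[int, int]:
        if self.indel_type == "insertion":
            return (self.position, self.position)
        return (self.position, self.position + self.size)


@dataclass(frozen=True)
class CspPlan:
    clade_rank: str
    clade_label: str
    length: int = 200


@dataclass
class SimConfig:
    """Study conditions for one simulated protein family / proteome set."""

    manifest: GroupManifest
    seed: int
    seq_length: int = 400
    subst_rate: float = 1.0  # expected substitutions/site per unit branch length
    branch_length_mean: float = 0.05
    site_rate_profile: Optional[np.ndarray] = None  # length seq_length; 0 = frozen
    tree_newick: Optional[str] = None
    indel_plan: list[IndelPlan] = field(default_factory=list)
    noise_indel_plan: list[NoiseIndelPlan] = field(default_factory=list)
    csp_plan: list[CspPlan] = field(default_factory=list)
    n_background_proteins: int = 5
    background_protein_length: int = 200
    proteome_mutation_rate: float = 0.05

    def validate(self) -> None:
        if self.seed is None:
            raise ConfigError("seed is mandatory")
        L = self.seq_length
        zones: list[tuple[int, int, str]] = []
        for i, plan in enumerate(self.indel_plan):
            members = self.manifest.members(plan.clade_rank, plan.clade_label)
            if not members:
                raise ConfigError(
                    f"indel plan {i}: clade ({plan.clade_rank}, {plan.clade_label}) "
                    "has no members"
                )
            lo, hi = plan.root_footprint()
            if lo < 0 or hi > L:
                raise ConfigError(
                    f"indel plan {i}: block plus frozen flanks [{lo}, {hi}) "
                    f"outside root sequence of length {L}"
                )
            zones.append((lo, hi, f"plan {i}"))
        for i, noise in enumerate(self.noise_indel_plan):
            unknown = set(noise.carriers) - self.manifest.known_taxa
            if unknown:
                raise ConfigError(f"noise plan {i}: unknown carriers {sorted(unknown)}")
            lo, hi = noise.root_footprint()
            if lo < 0 or hi > L or noise.position > L:
                raise ConfigError(f"noise plan {i}: outside root sequence")
            zones.append((lo, max(hi, lo + 1), f"noise {i}"))
        zones.sort()
        for (al, ah, an), (bl, bh, bn) in zip(zones, zones[1:]):
            if bl < ah:
                raise ConfigError(f"overlapping planted indels: {an} and {bn}")
        for i, plan in enumerate(self.csp_plan):
            if not self.manifest.members(plan.clade_rank, plan.clade_label):
                raise ConfigError(f"csp plan {i}: clade has no members")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one planted signature."""

    signature_id: str
    kind: str  # csi | csp
    clade_rank: str
    clade_label: str
    indel_type: str  # insertion/deletion for csi, "" for csp
    size: int  # aa (indel size or protein length)
    col_start: int  # 0-based half-open alignment columns (csi only)
    col_end: int
    carriers: tuple[str, ...]


# ---------------------------------------------------------------------------
# tree simulation

def simulate_tree(
    n_taxa: int,
    seed: int,
    labels: Optional[Sequence[str]] = None,
    branch_length_mean: float = 0.1,
) -> PhyloTree:
    """Random unrooted bifurcating topology, uniform over labeled shapes.

    Built by attaching each successive leaf to a uniformly chosen edge,
    which makes all (2n-5)!! unrooted labeled topologies equiprobable.
    Branch lengths are exponential with the given mean.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if labels is None:
        labels = [f"t{i + 1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("labels length must equal n_taxa")
    rng = np.random.default_rng(seed)

    def bl() -> float:
        return float(rng.exponential(branch_length_mean))

    root = TreeNode(
        children=[
            (TreeNode(label=labels[0]), bl()),
            (TreeNode(label=labels[1]), bl()),
            (TreeNode(label=labels[2]), bl()),
        ]
    )
    # edges as (parent, child_index)
    edges: list[tuple[TreeNode, int]] = [(root, 0), (root, 1), (root, 2)]
    for i in range(3, n_taxa):
        parent, idx = edges[int(rng.integers(0, len(edges)))]
        child, old_bl = parent.children[idx]
        mid = TreeNode(children=[(child, old_bl), (TreeNode(label=labels[i]), bl())])
        parent.children[idx] = (mid, bl())
        edges.append((mid, 0))
        edges.append((mid, 1))
    return PhyloTree(root)


def simulate_clade_tree(manifest: GroupManifest, seed: int,
                        branch_length_mean: float = 0.05) -> PhyloTree:
    """Random rooted tree over the manifest taxa in which every named clade
    is monophyletic (the clade family must be laminar)."""
    rng = np.random.default_rng(seed)
    taxa = sorted(manifest.known_taxa)
    clades = [set(m) for _, _, m in manifest.clades() if 1 < len(m) < len(taxa)]
    # laminarity check
    for a in clades:
        for b in clades:
            inter = a & b
            if inter and not (a <= b or b <= a):
                raise ConfigError(
                    "manifest clades overlap without nesting; cannot build a "
                    "tree in which all are monophyletic"
                )

    def bl() -> float:
        return float(rng.exponential(branch_length_mean))

    def join(units: list[TreeNode]) -> TreeNode:
        units = list(units)
        while len(units) > 1:
            i, j = sorted(rng.choice(len(units), size=2, replace=False))
            b = units.pop(int(j))
            a = units.pop(int(i))
            units.append(TreeNode(children=[(a, bl()), (b, bl())]))
        return units[0]

    def build(members: set[str], pool: list[set[str]]) -> TreeNode:
        maximal = [
            c for c in pool
            if c < members and not any(c < d < members for d in pool)
        ]
        covered: set[str] = set()
        units: list[TreeNode] = []
        for c in sorted(maximal, key=lambda s: sorted(s)):
            units.append(build(c, [d for d in pool if d < c]))
            covered |= c
        for t in sorted(members - covered):
            units.append(TreeNode(label=t))
        return join(units)

    root = build(set(taxa), clades)
    return PhyloTree(root)


# ---------------------------------------------------------------------------
# family evolution

def _clade_mrca(tree: PhyloTree, members: set[str]) -> TreeNode:
    """The node whose leaf set equals `members` (restricted to tree leaves)."""
    target = members & set(tree.leaf_names)
    if len(target) < 1:
        raise ConfigError("clade has no members in the tree")
    found: list[TreeNode] = []

    def walk(node: TreeNode) -> set[str]:
        if node.is_leaf:
            below = {node.label}
        else:
            below = set()
            for child, _ in node.children:
                below |= walk(child)
        if below == target:
            found.append(node)
        return below

    walk(tree.root)
    if not found:
        raise ConfigError(
            f"clade {sorted(target)} is not monophyletic in the supplied tree"
        )
    return found[0]


def evolve_family(tree: PhyloTree, config: SimConfig) -> tuple[Alignment, list[TruthRecord]]:
    """Evolve one protein family on `tree` with the planted indels.

    The root sequence is uniform over the 20 amino acids; per branch each
    site receives Poisson(site_rate * subst_rate * branch_length)
    substitution events, each drawing a uniform replacement residue.
    Frozen sites (rate 0) never change.  Every planted indel is applied
    exactly once on the stem branch of its clade; planned exception taxa
    have the indel reverted on their terminal branch.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.seq_length
    rates = (
        np.ones(L)
        if config.site_rate_profile is None
        else np.asarray(config.site_rate_profile, dtype=float).copy()
    )
    if rates.shape != (L,):
        raise ConfigError("site_rate_profile length must equal seq_length")

    # freeze flanks (and, for deletions, leave block rates as configured)
    for plan in config.indel_plan:
        lo, hi = plan.root_footprint()
        if plan.indel_type == "insertion":
            rates[lo:plan.position] = 0.0
            rates[plan.position:hi] = 0.0
        else:
            rates[lo:plan.position] = 0.0
            rates[plan.position + plan.size:hi] = 0.0

    # global column layout: insertion columns injected before their root position
    ins_at: dict[int, list[int]] = {}  # root position -> plan indices
    for i, plan in enumerate(config.indel_plan):
        if plan.indel_type == "insertion":
            ins_at.setdefault(plan.position, []).append(i)
    noise_ins_at: dict[int, list[int]] = {}
    for i, noise in enumerate(config.noise_indel_plan):
        if noise.indel_type == "insertion":
            noise_ins_at.setdefault(noise.position, []).append(i)
    col_rate: list[float] = []
    root_col_of: dict[int, int] = {}  # root position -> global column
    plan_cols: dict[int, tuple[int, int]] = {}  # plan index -> (col_start, col_end)
    noise_cols: dict[int, tuple[int, int]] = {}
    for p in range(L + 1):
        for i in ins_at.get(p, ()):
            start = len(col_rate)
            col_rate.extend([1.0] * config.indel_plan[i].size)
            plan_cols[i] = (start, start + config.indel_plan[i].size)
        for i in noise_ins_at.get(p, ()):
            start = len(col_rate)
            col_rate.extend([0.0] * config.noise_indel_plan[i].size)
            noise_cols[i] = (start, start + config.noise_indel_plan[i].size)
        if p < L:
            root_col_of[p] = len(col_rate)
            col_rate.append(float(rates[p]))
    for i, plan in enumerate(config.indel_plan):
        if plan.indel_type == "deletion":
            plan_cols[i] = (
                root_col_of[plan.position],
                root_col_of[plan.position + plan.size - 1] + 1,
            )
    for i, noise in enumerate(config.noise_indel_plan):
        if noise.indel_type == "deletion":
            noise_cols[i] = (
                root_col_of[noise.position],
                root_col_of[noise.position + noise.size - 1] + 1,
            )
    noise_residues = {
        i: rng.integers(0, 20, size=noise.size)
        for i, noise in enumerate(config.noise_indel_plan)
        if noise.indel_type == "insertion"
    }
    n_cols = len(col_rate)
    col_rate_arr = np.array(col_rate)

    root_seq = np.full(n_cols, -1, dtype=np.int16)
    root_residues = rng.integers(0, 20, size=L)
    for p in range(L):
        root_seq[root_col_of[p]] = root_residues[p]

    # stem events and exception reversions
    events: dict[int, list[int]] = {}  # id(node) -> plan indices
    for i, plan in enumerate(config.indel_plan):
        members = config.manifest.members(plan.clade_rank, plan.clade_label)
        mrca = _clade_mrca(tree, members)
        events.setdefault(id(mrca), []).append(i)
    exception_of: dict[str, list[int]] = {}
    for i, plan in enumerate(config.indel_plan):
        for t in plan.exceptions:
            exception_of.setdefault(t, []).append(i)

    rows: list[tuple[str, str]] = []

    def mutate(seq: np.ndarray, branch_length: float) -> None:
        present = seq >= 0
        lam = col_rate_arr * config.subst_rate * branch_length
        nsub = rng.poisson(lam)
        hit = present & (nsub > 0)
        idx = np.nonzero(hit)[0]
        if idx.size:
            seq[idx] = rng.integers(0, 20, size=idx.size)

    def walk(node: TreeNode, seq: np.ndarray) -> None:
        for i in events.get(id(node), ()):
            plan = config.indel_plan[i]
            s, e = plan_cols[i]
            if plan.indel_type == "insertion":
                seq[s:e] = rng.integers(0, 20, size=e - s)
            else:
                seq[s:e] = -1
        if node.is_leaf:
            taxon = node.label
            for i in exception_of.get(taxon, ()):
                plan = config.indel_plan[i]
                s, e = plan_cols[i]
                if plan.indel_type == "insertion":
                    seq[s:e] = -1
                else:
                    seq[s:e] = root_seq[s:e]
            for i, noise in enumerate(config.noise_indel_plan):
                if taxon not in noise.carriers:
                    continue
                s, e = noise_cols[i]
                if noise.indel_type == "insertion":
                    seq[s:e] = noise_residues[i]
                else:
                    seq[s:e] = -1
            rows.append(
                (taxon, "".join(AA[r] if r >= 0 else GAP for r in seq))
            )
            return
        for child, bl in node.children:
            child_seq = seq.copy()
            mutate(child_seq, bl)
            walk(child, child_seq)

    # root-level events (clade = all taxa) are applied before descending
    walk(tree.root, root_seq.copy())

    alignment = Alignment(rows)
    leaves = set(tree.leaf_names)
    truths: list[TruthRecord] = []
    for i, plan in enumerate(config.indel_plan):
        members = config.manifest.members(plan.clade_rank, plan.clade_label)
        carriers = tuple(sorted((members & leaves) - set(plan.exceptions)))
        s, e = plan_cols[i]
        truths.append(
            TruthRecord(
                signature_id=f"csi{i}",
                kind="csi",
                clade_rank=plan.clade_rank,
                clade_label=plan.clade_label,
                indel_type=plan.indel_type,
                size=plan.size,
                col_start=s,
                col_end=e,
                carriers=carriers,
            )
        )
    for i, noise in enumerate(config.noise_indel_plan):
        s, e = noise_cols[i]
        truths.append(
            TruthRecord(
                signature_id=f"noise{i}",
                kind="noise",
                clade_rank="",
                clade_label="",
                indel_type=noise.indel_type,
                size=noise.size,
                col_start=s,
                col_end=e,
                carriers=tuple(sorted(noise.carriers)),
            )
        )
    return alignment, truths


def simulate_family(config: SimConfig) -> tuple[Alignment, list[TruthRecord], PhyloTree]:
    """Convenience wrapper: clade-respecting tree plus evolved family."""
    if config.tree_newick is not None:
        tree = PhyloTree.from_newick(config.tree_newick)
    else:
        tree = simulate_clade_tree(
            config.manifest, config.seed, config.branch_length_mean
        )
    alignment, truths = evolve_family(tree, config)
    return alignment, truths, tree


# ---------------------------------------------------------------------------
# proteome simulation

def _mutate_protein(prototype: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(prototype.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    idx = np.nonzero(hit)[0]
    if idx.size:
        repl = rng.integers(0, 20, size=idx.size)
        for k, r in zip(idx, repl):
            arr[k] = ord(AA[r])
    return arr.tobytes().decode()


def simulate_proteomes(
    manifest: GroupManifest, config: SimConfig
) -> tuple[dict[str, list[SequenceRecord]], HitTable, list[TruthRecord]]:
    """Per-taxon proteomes with planted clade-exclusive proteins.

    Background proteins descend from shared prototypes and appear in every
    taxon; each CSP plan contributes a prototype present only in its clade
    members.  The hit table comes from the internal similarity search over
    all proteins (all-vs-all), with ``taxon|name`` identifiers so subject
    taxa are resolvable.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    taxa = sorted(manifest.known_taxa)
    proteomes: dict[str, list[SequenceRecord]] = {t: [] for t in taxa}
    mu = config.proteome_mutation_rate

    for b in range(config.n_background_proteins):
        proto = "".join(
            AA[r] for r in rng.integers(0, 20, size=config.background_protein_length)
        )
        for t in taxa:
            proteomes[t].append(
                SequenceRecord(
                    f"{t}|bg{b}", _mutate_protein(proto, mu, rng),
                    description=f"background protein {b}",
                )
            )
    truths: list[TruthRecord] = []
    for i, plan in enumerate(config.csp_plan):
        members = sorted(manifest.members(plan.clade_rank, plan.clade_label))
        proto = "".join(AA[r] for r in rng.integers(0, 20, size=plan.length))
        for t in members:
            proteomes[t].append(
                SequenceRecord(
                    f"{t}|csp{i}", _mutate_protein(proto, mu, rng),
                    description=f"planted clade protein {i}",
                )
            )
        truths.append(
            TruthRecord(
                signature_id=f"csp{i}",
                kind="csp",
                clade_rank=plan.clade_rank,
                clade_label=plan.clade_label,
                indel_type="",
                size=plan.length,
                col_start=0,
                col_end=0,
                carriers=tuple(members),
            )
        )
    everything = [rec for t in taxa for rec in proteomes[t]]
    hits = internal_similarity_search(everything, everything)
    return proteomes, hits, truths


# ---------------------------------------------------------------------------
# similarity search

# Karlin-Altschul-style score calibration for the pseudo E-value; the
# relative ordering of hits is the contract, not absolute calibration.
_LAMBDA = 0.267
_K = 0.041


def _blosum_lookup():
    from Bio.Align import substitution_matrices

    m = substitution_matrices.load("BLOSUM62")
    table: dict[tuple[str, str], int] = {}
    for a in m.alphabet:
        for b in m.alphabet:
            table[(a, b)] = int(m[a, b])
    return table


_BLOSUM: Optional[dict[tuple[str, str], int]] = None


def internal_similarity_search(
    queries: Sequence[SequenceRecord],
    database: Sequence[SequenceRecord],
    k: int = 4,
    min_score: int = 50,
    x_drop: int = 20,
) -> HitTable:
    """Exact k-mer seeded, ungapped BLOSUM62 extension search.

    Raw scores map to bitscores via fixed (lambda, K) constants and to a
    pseudo E-value with the database residue count; a query's self-hit is
    always its top hit.  Ungapped extension uses an X-drop cutoff.
    """
    global _BLOSUM
    if _BLOSUM is None:
        _BLOSUM = _blosum_lookup()
    blosum = _BLOSUM
    shortest = min((len(s) for s in list(queries) + list(database)), default=0)
    if k > shortest:
        raise ValueError(f"k={k} larger than shortest sequence ({shortest})")

    index: dict[str, list[tuple[int, int]]] = {}
    for j, rec in enumerate(database):
        s = rec.residues
        for pos in range(len(s) - k + 1):
            index.setdefault(s[pos : pos + k], []).append((j, pos))
    total_db = sum(len(s) for s in database)

    hits: list[HitRecord] = []
    for q in queries:
        qs = q.residues
        best: dict[int, tuple[int, int, int, int, int]] = {}
        seen_diag: set[tuple[int, int]] = set()
        for qpos in range(len(qs) - k + 1):
            for j, spos in enumerate_seeds(index, qs[qpos : qpos + k]):
                diag = qpos - spos
                if (j, diag) in seen_diag:
                    continue
                seen_diag.add((j, diag))
                ss = database[j].residues
                score, q0, q1 = _extend(qs, ss, qpos, spos, k, blosum, x_drop)
                prev = best.get(j)
                if prev is None or score > prev[0]:
                    best[j] = (score, q0, q1, q0 - diag, q1 - diag)
        for j, (score, q0, q1, s0, s1) in best.items():
            if score < min_score:
                continue
            subj = database[j]
            ident = sum(
                1 for a, b in zip(qs[q0:q1], subj.residues[s0:s1]) if a == b
            )
            length = q1 - q0
            bitscore = (_LAMBDA * score - math.log(_K)) / math.log(2.0)
            evalue = len(qs) * total_db * 2.0 ** (-bitscore)
            taxon = subj.identifier.split("|", 1)[0] if "|" in subj.identifier else "unknown"
            hits.append(
                HitRecord(
                    query_id=q.identifier,
                    subject_id=subj.identifier,
                    percent_identity=100.0 * ident / length,
                    aln_length=length,
                    mismatches=length - ident,
                    gap_opens=0,
                    q_start=q0 + 1,
                    q_end=q1,
                    s_start=s0 + 1,
                    s_end=s1,
                    evalue=evalue,
                    bitscore=round(bitscore, 1),
                    subject_taxon=taxon,
                )
            )
    return HitTable(hits)


def enumerate_seeds(index: dict[str, list[tuple[int, int]]], kmer: str):
    return index.get(kmer, ())


def _extend(
    qs: str,
    ss: str,
    qpos: int,
    spos: int,
    k: int,
    blosum: dict[tuple[str, str], int],
    x_drop: int,
) -> tuple[int, int, int]:
    """Ungapped X-drop extension of a seed; returns (score, q_start, q_end)."""
    score = sum(blosum.get((qs[qpos + i], ss[spos + i]), -4) for i in range(k))
    # extend right
    best = score
    cur = score
    qi, si = qpos + k, spos + k
    end = qpos + k
    while qi < len(qs) and si < len(ss):
        cur += blosum.get((qs[qi], ss[si]), -4)
        if cur > best:
            best, end = cur, qi + 1
        if best - cur > x_drop:
            break
        qi += 1
        si += 1
    # extend left
    score2 = best
    cur = best
    qi, si = qpos - 1, spos - 1
    start = qpos
    while qi >= 0 and si >= 0:
        cur += blosum.get((qs[qi], ss[si]), -4)
        if cur > score2:
            score2, start = cur, qi
        if score2 - cur > x_drop:
            break
        qi -= 1
        si -= 1
    return score2, start, end
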