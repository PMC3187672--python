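"""Synthetic alignment + taxonomy generator with full ground truth.

Generates an ultrametric species tree whose between-species path depths all
fall inside a configured window, grafts shallow within-species subtrees
(optionally planting deep cryptic splits), and evolves sequences down the
tree under the exact two-parameter (transition/transversion) substitution
process using the closed-form per-branch transition probabilities — no
event simulation.  All randomness flows from a single master seed via three
named substreams (tree, individuals, sequences).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .seqio import AlignedSeqSet, SequenceRecord, TaxonInfo, TaxonMap

_BASES = "ACGT"


@dataclass(frozen=True)
class SimulationConfig:
    n_species: int = 12
    #: single integer or inclusive (lo, hi) range
    individuals_per_species: int | tuple[int, int] = 5
    seq_length: int = 591
    #: (min, max) expected substitutions/site between species
    interspecific_depth: tuple[float, float] = (0.035, 0.08)
    #: maximum within-species depth (expected substitutions/site)
    intraspecific_depth: float = 0.01
    #: transition/transversion rate ratio (alpha/beta)
    kappa: float = 4.0
    #: root-sequence sampling weights (A, C, G, T); default AT-rich
    base_weights: tuple[float, float, float, float] = (0.345, 0.139, 0.122, 0.394)
    seed: int = 0
    #: fraction of species planted with a deep intraspecific split
    cryptic_fraction: float = 0.0
    #: depth separating the two clades of a planted cryptic species
    cryptic_depth: float = 0.035
    #: group-cut position as a fraction of the species-tree root depth
    group_cut: float = 0.75

    def validate(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")
        lo, hi = self._ind_range()
        if lo < 1 or hi < lo:
            raise ValueError("invalid individuals_per_species")
        if self.seq_length < 1:
            raise ValueError("seq_length must be positive")
        dlo, dhi = self.interspecific_depth
        if not (0 < dlo <= dhi):
            raise ValueError("infeasible interspecific depth constraints")
        if self.intraspecific_depth < 0 or self.cryptic_depth < 0:
            raise ValueError("depths must be non-negative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if abs(sum(self.base_weights) - 1.0) > 1e-9:
            raise ValueError("base_weights must sum to 1")
        if not (0.0 <= self.cryptic_fraction <= 1.0):
            raise ValueError("cryptic_fraction must be in [0, 1]")

    def _ind_range(self) -> tuple[int, int]:
        if isinstance(self.individuals_per_species, int):
            return self.individuals_per_species, self.individuals_per_species
        lo, hi = self.individuals_per_species
        return int(lo), int(hi)


@dataclass
class SimNode:
    """Rooted ultrametric tree node; leaves have depth 0."""

    depth: float
    name: str | None = None
    children: list["SimNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["SimNode"]:
        if self.is_leaf:
            return [self]
        return [lf for c in self.children for lf in c.leaves()]

    def to_newick(self) -> str:
        def render(node: SimNode, parent_depth: float) -> str:
            blen = parent_depth - node.depth
            if node.is_leaf:
                return f"{node.name}:{blen:.8f}"
            inner = ",".join(render(c, node.depth) for c in node.children)
            return f"({inner}):{blen:.8f}"

        inner = ",".join(render(c, self.depth) for c in self.children)
        return f"({inner});"


@dataclass
class GroundTruth:
    root: SimNode
    species_of: dict[str, str]  # specimen -> species
    group_of: dict[str, str]  # species -> group
    cryptic_species: list[str]
    config: SimulationConfig

    def specimen_ids(self) -> list[str]:
        return [lf.name for lf in self.root.leaves()]

    def path_distances(self) -> tuple[list[str], np.ndarray]:
        """True pairwise path distances; ultrametric, so d = 2 * MRCA depth."""
        ids = self.specimen_ids()
        pos = {sid: i for i, sid in enumerate(ids)}
        D = np.zeros((len(ids), len(ids)))

        def walk(node: SimNode) -> list[str]:
            if node.is_leaf:
                return [node.name]
            child_leaves = [walk(c) for c in node.children]
            for i in range(len(child_leaves)):
                for j in range(i + 1, len(child_leaves)):
                    for a in child_leaves[i]:
                        for b in child_leaves[j]:
                            D[pos[a], pos[b]] = D[pos[b], pos[a]] = (
                                2.0 * node.depth
                            )
            return [lf for ls in child_leaves for lf in ls]

        walk(self.root)
        return ids, D

    def taxon_map(self) -> TaxonMap:
        return TaxonMap(
            {
                sid: TaxonInfo(
                    species=self.species_of[sid],
                    group=self.group_of[self.species_of[sid]],
                    ingroup=True,
                )
                for sid in self.specimen_ids()
            }
        )


def _substreams(seed: int) -> tuple[np.random.Generator, ...]:
    ss = np.random.SeedSequence(seed)
    return tuple(np.random.default_rng(child) for child in ss.spawn(3))


def _build_clade(
    names: list[str],
    root_depth: float,
    child_lo: float,
    rng: np.random.Generator,
) -> SimNode:
    """Random binary ultrametric clade: root at ``root_depth``, internal
    child depths drawn uniformly in (child_lo, parent depth)."""
    if len(names) == 1:
        return SimNode(depth=0.0, name=names[0])
    order = [names[i] for i in rng.permutation(len(names))]
    k = int(rng.integers(1, len(names)))
    node = SimNode(depth=root_depth)
    for part in (order[:k], order[k:]):
        if len(part) == 1:
            node.children.append(SimNode(depth=0.0, name=part[0]))
        else:
            depth = float(rng.uniform(child_lo, root_depth))
            node.children.append(_build_clade(part, depth, child_lo, rng))
    return node


def _assign_groups(root: SimNode, cut_depth: float) -> dict[str, str]:
    """Cut the species tree at ``cut_depth``; each hanging clade is a group."""
    clades: list[list[str]] = []

    def walk(node: SimNode) -> None:
        if node.depth < cut_depth or node.is_leaf:
            clades.append(sorted(lf.name for lf in node.leaves()))
        else:
            for c in node.children:
                walk(c)

    walk(root)
    clades.sort(key=lambda c: c[0])
    out: dict[str, str] = {}
    for i, clade in enumerate(clades, start=1):
        for sp in clade:
            out[sp] = f"G{i:02d}"
    return out


def simulate_species_tree(cfg: SimulationConfig) -> GroundTruth:
    """Species-level skeleton: random ultrametric tree, all pairwise path
    depths within cfg.interspecific_depth, reproducible from cfg.seed."""
    cfg.validate()
    tree_rng, _, _ = _substreams(cfg.seed)
    dlo, dhi = cfg.interspecific_depth
    species = [f"sp{i:02d}" for i in range(1, cfg.n_species + 1)]
    root_lo = max(dlo, 0.8 * dhi)
    root_depth = float(tree_rng.uniform(root_lo, dhi)) / 2.0
    if cfg.n_species == 2:
        root_depth = float(tree_rng.uniform(dlo, dhi)) / 2.0
        root = SimNode(depth=root_depth)
        root.children = [
            SimNode(depth=0.0, name=species[0]),
            SimNode(depth=0.0, name=species[1]),
        ]
    else:
        root = _build_clade(species, root_depth, dlo / 2.0, tree_rng)
    group_of = _assign_groups(root, cfg.group_cut * root_depth)
    return GroundTruth(
        root=root,
        species_of={sp: sp for sp in species},
        group_of=group_of,
        cryptic_species=[],
        config=cfg,
    )


def attach_individuals(gt: GroundTruth, cfg: SimulationConfig) -> GroundTruth:
    """Replace each species leaf by a shallow within-species subtree.

    Planted cryptic species receive two subclades joined at
    cfg.cryptic_depth / 2; all other within-species depths stay at or below
    cfg.intraspecific_depth / 2.
    """
    cfg.validate()
    _, ind_rng, _ = _substreams(cfg.seed)
    species_leaves = {lf.name: lf for lf in gt.root.leaves()}
    species = sorted(species_leaves)
    lo, hi = cfg._ind_range()
    n_ind = {
        sp: int(ind_rng.integers(lo, hi + 1)) if hi > lo else lo
        for sp in species
    }
    n_cryptic = round(cfg.cryptic_fraction * len(species))
    eligible = [sp for sp in species if n_ind[sp] >= 2]
    if n_cryptic > len(eligible):
        raise ValueError("not enough multi-individual species for cryptic plants")
    cryptic = sorted(
        ind_rng.choice(eligible, size=n_cryptic, replace=False).tolist()
    ) if n_cryptic else []

    species_of: dict[str, str] = {}
    for sp in species:
        names = [f"{sp}_{k}" for k in range(1, n_ind[sp] + 1)]
        for nm in names:
            species_of[nm] = sp
        leaf = species_leaves[sp]
        if len(names) == 1:
            leaf.name = names[0]
            continue
        if sp in cryptic:
            half_depth = cfg.cryptic_depth / 2.0
            split = max(1, len(names) // 2)
            subtree = SimNode(depth=half_depth)
            for part in (names[:split], names[split:]):
                if len(part) == 1:
                    subtree.children.append(SimNode(depth=0.0, name=part[0]))
                else:
                    h = (cfg.intraspecific_depth / 2.0) * float(
                        ind_rng.uniform(0.3, 1.0)
                    )
                    h = min(h, half_depth * 0.5)
                    subtree.children.append(_build_clade(part, h, 0.0, ind_rng))
        else:
            h = (cfg.intraspecific_depth / 2.0) * float(ind_rng.uniform(0.3, 1.0))
            subtree = _build_clade(names, h, 0.0, ind_rng)
        leaf.name = None
        leaf.depth = subtree.depth
        leaf.children = subtree.children

    return GroundTruth(
        root=gt.root,
        species_of=species_of,
        group_of=gt.group_of,
        cryptic_species=list(cryptic),
        config=cfg,
    )


def _branch_probs(t: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(each transversion)) after branch length t
    (expected substitutions/site), with rates normalized to alpha+2*beta=1."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e_ts = math.exp(-2.0 * (alpha + beta) * t)
    e_tv = math.exp(-4.0 * beta * t)
    p_ts = 0.25 + 0.25 * e_tv - 0.5 * e_ts
    p_tv = 0.25 - 0.25 * e_tv
    return p_ts, p_tv


def _mutate(codes: np.ndarray, t: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    if t <= 0.0:
        return codes.copy()
    p_ts, p_tv = _branch_probs(t, kappa)
    u = rng.random(codes.shape[0])
    out = codes.copy()
    ts = u < p_ts
    tv1 = (u >= p_ts) & (u < p_ts + p_tv)
    tv2 = (u >= p_ts + p_tv) & (u < p_ts + 2.0 * p_tv)
    out[ts] ^= 2  # A<->G, C<->T
    out[tv1] = (out[tv1] + 1) % 4
    out[tv2] = (out[tv2] + 3) % 4
    return out


def evolve_sequences(
    gt: GroundTruth, cfg: SimulationConfig
) -> tuple[AlignedSeqSet, TaxonMap]:
    """Evolve sequences down the ground-truth tree; root drawn from
    cfg.base_weights, exact per-branch transition probabilities thereafter."""
    cfg.validate()
    _, _, seq_rng = _substreams(cfg.seed)
    root_codes = seq_rng.choice(
        4, size=cfg.seq_length, p=np.asarray(cfg.base_weights)
    ).astype(np.int8)

    sequences: dict[str, np.ndarray] = {}

    def walk(node: SimNode, codes: np.ndarray, parent_depth: float) -> None:
        codes = _mutate(codes, parent_depth - node.depth, cfg.kappa, seq_rng)
        if node.is_leaf:
            sequences[node.name] = codes
        else:
            for child in node.children:
                walk(child, codes, node.depth)

    for child in gt.root.children:
        walk(child, root_codes, gt.root.depth)

    records = [
        SequenceRecord(sid, "".join(_BASES[c] for c in sequences[sid]))
        for sid in gt.specimen_ids()
    ]
    return AlignedSeqSet(records), gt.taxon_map()


@dataclass(frozen=True)
class SimulationResult:
    alignment: AlignedSeqSet
    taxonomy: TaxonMap
    truth: GroundTruth


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Full pipeline: species tree -> individuals -> sequences."""
    gt = attach_individuals(simulate_species_tree(cfg), cfg)
    aln, tax = evolve_sequences(gt, cfg)
    return SimulationResult(alignment=aln, taxonomy=tax, truth=gt)


def write_bundle(result: SimulationResult, outdir: str | Path) -> None:
    """Emit FASTA + taxonomy TSV + ground-truth sidecars (Newick, TSV, JSON)."""
    from .seqio import write_fasta, write_taxonomy

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.alignment, outdir / "alignment.fasta")
    write_taxonomy(result.taxonomy, outdir / "taxonomy.tsv")
    (outdir / "true_tree.nwk").write_text(result.truth.root.to_newick() + "\n")
    ids, D = result.truth.path_distances()
    with open(outdir / "true_distances.tsv", "w") as fh:
        fh.write("\t".join([""] + ids) + "\n")
        for i, sid in enumerate(ids):
            fh.write(
                "\t".join([sid] + [f"{D[i, j]:.8f}" for j in range(len(ids))])
                + "\n"
            )
    cfg = result.truth.config
    meta = {
        "seed": cfg.seed,
        "n_species": cfg.n_species,
        "seq_length": cfg.seq_length,
        "kappa": cfg.kappa,
        "interspecific_depth": list(cfg.interspecific_depth),
        "intraspecific_depth": cfg.intraspecific_depth,
        "cryptic_depth": cfg.cryptic_depth,
        "cryptic_species": result.truth.cryptic_species,
        "group_of": result.truth.group_of,
    }
    (outdir / "ground_truth.json").write_text(json.dumps(meta, indent=2) + "\n")
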