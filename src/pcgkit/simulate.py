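"""Phylogenetically constrained community assembly simulator.

Communities are assembled step-wise, mirroring the conceptual model the
detector is built to interrogate:

1. a regional pool of taxa related by a Yule (pure-birth) phylogeny;
2. a set of *niches* per microbial regime — *phylo-niches* whose eligible
   occupants are exactly the leaves of one clade, and *non-phylo-niches*
   whose eligible occupants are a scattered taxon set — each with a
   relative size (weight);
3. within each patch (local community), every niche is filled neutrally:
   either a single winner drawn uniformly from the eligible taxa
   (winner-take-all, reflecting within-niche competition and equal
   fitness) or a small Dirichlet-weighted guild (guild lottery);
4. higher-scale sampling pools several patches per sample with
   Dirichlet-distributed pooling weights (patch preeminence bias), and
   sequencing draws multinomial read counts at a fixed depth.

Every stochastic choice is recorded in a :class:`GroundTruth` object so a
downstream evaluator can score detected core groups against the planted
clades.  All randomness descends deterministically from one master seed:
the tree, each regime's niche map, the regime assignment and each sample
use child generators keyed as ``SeedSequence([master, stream, index])``,
so any part of a dataset can be re-simulated in isolation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from skbio import TreeNode

from .phylogeny import Phylogeny
from .table import AbundanceTable

__all__ = [
    "Niche",
    "NicheMap",
    "GroundTruth",
    "SimConfig",
    "simulate_tree",
    "plant_niches",
    "simulate_patch",
    "simulate_sample",
    "simulate_dataset",
    "load_config",
]

# stream constants for child-seed derivation
_TREE, _NICHES, _REGIMES, _SAMPLE = 0, 1, 2, 3


def _rng(seed) -> np.random.Generator:
    """Generator from an int seed or a [master, stream, ...] key list."""
    if isinstance(seed, np.random.Generator):
        return seed
    if isinstance(seed, (list, tuple)):
        return np.random.default_rng(np.random.SeedSequence(list(seed)))
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class Niche:
    """One niche: who may occupy it, how large it is, how it is filled."""

    kind: str  # "phylo" | "non_phylo"
    eligible_taxa: tuple[str, ...]
    weight: float
    occupancy_model: str = "winner_take_all"  # | "guild_lottery"
    guild_size: int = 1
    lottery_alpha: float = 1.0

    def __post_init__(self):
        if self.kind not in ("phylo", "non_phylo"):
            raise ValueError(f"unknown niche kind: {self.kind!r}")
        if not self.eligible_taxa:
            raise ValueError("eligible_taxa must be nonempty")
        if not (0 < self.weight <= 1):
            raise ValueError("niche weight must be in (0, 1]")
        if self.occupancy_model not in ("winner_take_all", "guild_lottery"):
            raise ValueError(f"unknown occupancy model: {self.occupancy_model!r}")
        if self.guild_size < 1:
            raise ValueError("guild_size must be >= 1")
        if self.lottery_alpha <= 0:
            raise ValueError("lottery_alpha must be positive")


@dataclass(frozen=True)
class NicheMap:
    """All niches of one microbial regime, bound to one phylogeny."""

    tree: Phylogeny
    niches: tuple[Niche, ...]
    regime_id: str = "regime_1"

    def __post_init__(self):
        leaves = set(self.tree.taxa)
        total = 0.0
        phylo_taxa: set[str] = set()
        for n in self.niches:
            extra = set(n.eligible_taxa) - leaves
            if extra:
                raise ValueError(f"niche taxa not in tree: {sorted(extra)[:10]}")
            total += n.weight
            if n.kind == "phylo":
                if phylo_taxa & set(n.eligible_taxa):
                    raise ValueError("phylo niches must occupy disjoint clades")
                phylo_taxa |= set(n.eligible_taxa)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"niche weights sum to {total}, not 1")

    def phylo_clades(self) -> list[frozenset[str]]:
        return [frozenset(n.eligible_taxa) for n in self.niches if n.kind == "phylo"]


@dataclass
class SimConfig:
    """Simulation settings.

    Defaults describe a moderate-complexity benchmark community: 64 taxa,
    four clade-bound niches of 4-8 leaves plus two scattered niches, every
    niche at least 10% of the community, winner-take-all occupancy, 30
    samples pooling 3 patches each, 10,000 reads per sample.
    """

    n_taxa: int = 64
    tree_model: str = "yule"
    k_phylo: int = 4
    k_nonphylo: int = 2
    clade_size_range: tuple[int, int] = (4, 8)
    niche_weight_alpha: float = 1.0
    min_niche_weight: float = 0.10
    occupancy_model: str = "winner_take_all"
    guild_size: int = 2
    lottery_alpha: float = 1.0
    n_samples: int = 30
    patches_per_sample: int = 3
    patch_pool_alpha: float = 1.0
    depth: int = 10_000
    n_regimes: int = 1
    regime_mix: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.tree_model != "yule":
            raise ValueError(f"unknown tree model: {self.tree_model!r}")
        lo, hi = self.clade_size_range
        if not (1 <= lo <= hi <= self.n_taxa):
            raise ValueError("infeasible clade_size_range for n_taxa")
        for name in ("k_phylo", "k_nonphylo", "n_samples", "patches_per_sample",
                     "depth", "n_regimes"):
            if getattr(self, name) < 0 or (name in ("n_samples", "patches_per_sample",
                                                    "depth", "n_regimes")
                                           and getattr(self, name) < 1):
                raise ValueError(f"{name} must be positive")
        if self.k_phylo + self.k_nonphylo < 1:
            raise ValueError("need at least one niche")
        k = self.k_phylo + self.k_nonphylo
        if self.min_niche_weight * k >= 1.0:
            raise ValueError("min_niche_weight infeasible for the niche count")
        if self.regime_mix is not None:
            mix = tuple(self.regime_mix)
            if len(mix) != self.n_regimes:
                raise ValueError("regime_mix length must equal n_regimes")
            if abs(sum(mix) - 1.0) > 1e-9:
                raise ValueError("regime_mix must sum to 1 within 1e-9")
            self.regime_mix = mix

    def mix(self) -> tuple[float, ...]:
        if self.regime_mix is None:
            return tuple([1.0 / self.n_regimes] * self.n_regimes)
        return tuple(self.regime_mix)


def load_config(path) -> SimConfig:
    """Read a SimConfig from YAML (or JSON, a YAML subset)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config field(s): {sorted(unknown)}")
    if "clade_size_range" in raw:
        raw["clade_size_range"] = tuple(raw["clade_size_range"])
    if raw.get("regime_mix") is not None:
        raw["regime_mix"] = tuple(raw["regime_mix"])
    return SimConfig(**raw)


# ----------------------------------------------------------------------
def simulate_tree(n_taxa: int, seed) -> Phylogeny:
    """Yule (pure-birth) tree: starting from two lineages at the root,
    waiting times are Exp(k) for k extant lineages and a uniformly chosen
    lineage bifurcates, until ``n_taxa`` tips exist; tip edges extend one
    further Exp(n) interval and all heights are rescaled so the root sits
    at height 1.0.  Tips are labeled t0001... in left-to-right order."""
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = _rng(seed)
    root = TreeNode()
    birth = {id(root): 0.0}
    active = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        active.append(child)
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        k = int(rng.integers(len(active)))
        node = active.pop(k)
        birth[id(node)] = t
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            active.append(child)
    t_end = t + rng.exponential(1.0 / n_taxa)
    scale = 1.0 / t_end
    for node in root.traverse(include_self=False):
        start = birth[id(node.parent)]
        end = birth.get(id(node), t_end)
        node.length = (end - start) * scale
    root.length = None
    for i, tip in enumerate(root.tips()):
        tip.name = f"t{i + 1:04d}"
    return Phylogeny(root)


def plant_niches(tree: Phylogeny, config: SimConfig, seed, regime_id: str = "regime_1") -> NicheMap:
    """Choose the niche structure of one regime.

    Phylo-niches: ``k_phylo`` pairwise-disjoint tree nodes with leaf-set
    sizes inside ``clade_size_range``, found by rejection sampling over
    the admissible nodes (at most 10,000 attempts).  Non-phylo-niches:
    scattered taxon sets drawn without replacement from the taxa outside
    every phylo clade (and outside each other, so the planted truth is
    unambiguous).  Niche weights are a symmetric Dirichlet draw, rejected
    until every weight reaches ``min_niche_weight``.
    """
    rng = _rng(seed)
    lo, hi = config.clade_size_range
    k = config.k_phylo + config.k_nonphylo
    admissible = [
        node for node in tree.postorder() if lo <= len(tree.leaf_set(node)) <= hi
    ]
    clades: list[frozenset[str]] = []
    if config.k_phylo > 0:
        if len(admissible) < config.k_phylo:
            raise ValueError(
                f"only {len(admissible)} nodes have {lo}-{hi} leaves; "
                f"cannot place {config.k_phylo} phylo niches"
            )
        ok = False
        for _ in range(10_000):
            pick = rng.choice(len(admissible), size=config.k_phylo, replace=False)
            sets = [tree.leaf_set(admissible[i]) for i in pick]
            if all(
                sets[a].isdisjoint(sets[b])
                for a in range(len(sets))
                for b in range(a + 1, len(sets))
            ):
                clades = sets
                ok = True
                break
        if not ok:
            raise ValueError(
                f"could not place {config.k_phylo} disjoint clades of size "
                f"{lo}-{hi} in 10,000 attempts"
            )
    used = set().union(*clades) if clades else set()
    pool = [t for t in tree.taxa if t not in used]
    scattered: list[tuple[str, ...]] = []
    for _ in range(config.k_nonphylo):
        size = int(rng.integers(lo, hi + 1))
        if size > len(pool):
            raise ValueError(
                f"not enough taxa outside phylo clades for a non-phylo niche "
                f"of size {size} (pool has {len(pool)})"
            )
        pick = rng.choice(len(pool), size=size, replace=False)
        members = tuple(pool[i] for i in sorted(pick))
        scattered.append(members)
        pool = [t for i, t in enumerate(pool) if i not in set(pick)]
    for _ in range(10_000):
        weights = rng.dirichlet([config.niche_weight_alpha] * k)
        if weights.min() >= config.min_niche_weight:
            break
    else:
        raise ValueError(
            f"could not draw {k} niche weights all >= {config.min_niche_weight} "
            "in 10,000 attempts"
        )
    niches = []
    for i in range(k):
        if i < config.k_phylo:
            kind, taxa = "phylo", tuple(sorted(clades[i]))
        else:
            kind, taxa = "non_phylo", scattered[i - config.k_phylo]
        niches.append(
            Niche(
                kind=kind,
                eligible_taxa=taxa,
                weight=float(weights[i]),
                occupancy_model=config.occupancy_model,
                guild_size=config.guild_size,
                lottery_alpha=config.lottery_alpha,
            )
        )
    return NicheMap(tree=tree, niches=tuple(niches), regime_id=regime_id)


def simulate_patch(niche_map: NicheMap, seed) -> tuple[dict[str, float], list[dict[str, float]]]:
    """One local community: every niche filled neutrally from its eligible
    taxa.  Returns (composition summing to 1, per-niche occupant shares)."""
    rng = _rng(seed)
    comp: dict[str, float] = {}
    occupants: list[dict[str, float]] = []
    for niche in niche_map.niches:
        eligible = list(niche.eligible_taxa)
        if niche.occupancy_model == "winner_take_all":
            winner = eligible[int(rng.integers(len(eligible)))]
            shares = {winner: 1.0}
        else:
            if niche.guild_size > len(eligible):
                raise ValueError(
                    f"guild_size {niche.guild_size} exceeds the "
                    f"{len(eligible)} eligible taxa of a niche"
                )
            pick = rng.choice(len(eligible), size=niche.guild_size, replace=False)
            fracs = rng.dirichlet([niche.lottery_alpha] * niche.guild_size)
            shares = {eligible[i]: float(f) for i, f in zip(pick, fracs)}
        occupants.append(shares)
        for taxon, f in shares.items():
            comp[taxon] = comp.get(taxon, 0.0) + niche.weight * f
    return comp, occupants


def simulate_sample(
    niche_map: NicheMap, config: SimConfig, seed
) -> tuple[np.ndarray, dict]:
    """One sample: P independent patches, Dirichlet pooling weights, then
    multinomial sequencing at the configured depth.  Returns the counts
    vector (over ``niche_map.tree.taxa`` order) and a full draw record."""
    if config.depth < 1:
        raise ValueError("depth must be >= 1")
    rng = _rng(seed)
    taxa = niche_map.tree.taxa
    idx = {t: i for i, t in enumerate(taxa)}
    P = config.patches_per_sample
    comps = []
    records = []
    for _ in range(P):
        comp, occupants = simulate_patch(niche_map, rng)
        comps.append(comp)
        records.append(occupants)
    pool_w = rng.dirichlet([config.patch_pool_alpha] * P)
    pooled = np.zeros(len(taxa))
    for w, comp in zip(pool_w, comps):
        for taxon, f in comp.items():
            pooled[idx[taxon]] += w * f
    pooled /= pooled.sum()
    counts = rng.multinomial(config.depth, pooled)
    record = {
        "regime": niche_map.regime_id,
        "patches": [
            {
                "pool_weight": float(w),
                "occupants": [
                    {taxon: float(f) for taxon, f in shares.items()}
                    for shares in occupants
                ],
            }
            for w, occupants in zip(pool_w, records)
        ],
    }
    return counts, record


@dataclass
class GroundTruth:
    """Everything needed to re-derive a simulated dataset's expectations:
    the niche maps, each sample's regime, and every occupancy/pooling draw."""

    regimes: dict[str, NicheMap]
    sample_regimes: dict[str, str]
    sample_records: dict[str, dict]
    config: SimConfig

    def phylo_clades(self, regime_id: str) -> list[frozenset[str]]:
        if regime_id not in self.regimes:
            raise KeyError(f"unknown regime: {regime_id!r}")
        return self.regimes[regime_id].phylo_clades()

    def regime_ids(self) -> list[str]:
        return list(self.regimes)

    def samples_of(self, regime_id: str) -> list[str]:
        if regime_id not in self.regimes:
            raise KeyError(f"unknown regime: {regime_id!r}")
        return [s for s, r in self.sample_regimes.items() if r == regime_id]

    # -- JSON round trip ------------------------------------------------
    def to_dict(self) -> dict:
        cfg = asdict(self.config)
        cfg["clade_size_range"] = list(cfg["clade_size_range"])
        if cfg["regime_mix"] is not None:
            cfg["regime_mix"] = list(cfg["regime_mix"])
        return {
            "config": cfg,
            "regimes": {
                rid: {
                    "niches": [
                        {
                            "kind": n.kind,
                            "taxa": list(n.eligible_taxa),
                            "weight": n.weight,
                            "occupancy_model": n.occupancy_model,
                            "guild_size": n.guild_size,
                            "lottery_alpha": n.lottery_alpha,
                        }
                        for n in nmap.niches
                    ]
                }
                for rid, nmap in self.regimes.items()
            },
            "samples": {
                sid: self.sample_records[sid] for sid in self.sample_records
            },
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @staticmethod
    def read_clades(path) -> dict[str, list[frozenset[str]]]:
        """Planted phylo clades per regime from a truth.json file."""
        with open(path) as fh:
            raw = json.load(fh)
        return {
            rid: [
                frozenset(n["taxa"]) for n in reg["niches"] if n["kind"] == "phylo"
            ]
            for rid, reg in raw["regimes"].items()
        }

    @staticmethod
    def read_sample_regimes(path) -> dict[str, str]:
        with open(path) as fh:
            raw = json.load(fh)
        return {sid: rec["regime"] for sid, rec in raw["samples"].items()}


def simulate_dataset(config: SimConfig) -> tuple[AbundanceTable, Phylogeny, GroundTruth]:
    """Full benchmark dataset under one master seed: one tree, independent
    niche maps per regime, a regime per sample, and S simulated samples."""
    mix = np.asarray(config.mix())
    if abs(mix.sum() - 1.0) > 1e-9:
        raise ValueError("regime_mix must sum to 1 within 1e-9")
    master = config.seed
    tree = simulate_tree(config.n_taxa, [master, _TREE])
    regimes: dict[str, NicheMap] = {}
    for r in range(config.n_regimes):
        rid = f"regime_{r + 1}"
        regimes[rid] = plant_niches(tree, config, [master, _NICHES, r], regime_id=rid)
    rng = _rng([master, _REGIMES])
    assignment = rng.choice(config.n_regimes, size=config.n_samples, p=mix)
    width = max(3, len(str(config.n_samples)))
    sample_ids = [f"s{i + 1:0{width}d}" for i in range(config.n_samples)]
    counts = np.zeros((config.n_samples, config.n_taxa), dtype=np.int64)
    sample_regimes: dict[str, str] = {}
    sample_records: dict[str, dict] = {}
    for i, sid in enumerate(sample_ids):
        rid = f"regime_{int(assignment[i]) + 1}"
        vec, record = simulate_sample(regimes[rid], config, [master, _SAMPLE, i])
        counts[i] = vec
        sample_regimes[sid] = rid
        sample_records[sid] = record
    table = AbundanceTable(counts, sample_ids, tree.taxa)
    truth = GroundTruth(
        regimes=regimes,
        sample_regimes=sample_regimes,
        sample_records=sample_records,
        config=replace(config),
    )
    return table, tree, truth
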