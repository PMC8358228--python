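"""Seeded generators for every input the pipeline consumes, with ground truth.

The family generator emulates the structure of a deep paralog-rich GTPase
dataset: a species tree spanning 13 taxonomic groups, several ancestral
paralogs that diverged before the species radiation, designated fast-evolving
lineages (long pendant branches), per-clade conserved intron sites,
presence–absence patterns produced by placed loss events, and noisy external
predictor call tables. No indels are simulated, so alignment columns,
residue indices and intron positions stay in one exact coordinate system and
every planted feature can be checked for exact recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .config import DEFAULT_GROUPS
from .evomodel import AA_ORDER, SubstitutionModel, build_wag
from .introns import GeneStructure, site_to_cds_offset
from .io import AnnotatedSequence, ProteinAlignment, TaxonMap

__all__ = [
    "SimConfig",
    "GroundTruth",
    "FamilySim",
    "sim_tree",
    "sim_alignment",
    "sim_pair",
    "sim_family",
    "sim_gene_structures",
    "sim_presence_absence",
    "sim_predictor_calls",
]


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the emulated study design: 13 taxonomic groups, a few
    species each, 5 ancestral paralogs, alignments of 148 columns (the
    trimmed GTPase-domain length), WAG+Γ rates, and one fast-evolving species
    per group with a 4-fold rate multiplier.
    """

    seed: int = 0
    groups: list[str] = field(default_factory=lambda: list(DEFAULT_GROUPS))
    species_per_group: int = 3
    n_paralogs: int = 5
    L: int = 148
    alpha: float = 1.0
    p_inv: float = 0.0
    n_cat: int = 4
    group_tree_depth: float = 0.4
    within_group_depth: float = 0.2
    paralog_depth: float = 1.0
    n_fast_per_group: int = 1
    fast_factor: float = 4.0
    losses_per_paralog: int = 0
    clock_noise_sd: float = 0.05

    def __post_init__(self):
        if self.species_per_group < 1 or self.n_paralogs < 1 or self.L < 1:
            raise ValueError("counts must be >= 1")
        if self.fast_factor <= 0:
            raise ValueError("rate multipliers must be > 0")
        if self.n_fast_per_group > self.species_per_group:
            raise ValueError("more fast lineages requested than species per group")

    def build_model(self) -> SubstitutionModel:
        return build_wag(alpha=self.alpha, n_cat=self.n_cat, p_inv=self.p_inv)


@dataclass
class GroundTruth:
    """Everything the generators planted, keyed consistently with the files
    they emit."""

    clade_of: dict[str, str] = field(default_factory=dict)
    is_fast: dict[str, bool] = field(default_factory=dict)
    species_tree: dendropy.Tree | None = None
    intron_sites: dict[str, set] = field(default_factory=dict)  # label -> {(residue, phase)}
    loss_edges: dict[str, list] = field(default_factory=dict)   # label -> [frozenset(tips)]
    motif_status: dict[str, dict] = field(default_factory=dict)  # seq_id -> {feature: bool}


@dataclass
class FamilySim:
    sequences: list[AnnotatedSequence]
    alignment: ProteinAlignment
    taxon_map: TaxonMap
    truth: GroundTruth
    config: SimConfig


def sim_tree(n_tips: int, seed: int, *, clock: bool = True,
             noise_sd: float = 0.0, depth: float = 1.0,
             labels: list[str] | None = None) -> dendropy.Tree:
    """Yule (pure-birth) tree, ultrametric with root-to-tip span ``depth``;
    optional multiplicative lognormal branch-length noise breaks the clock."""
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    root = tree.seed_node
    root.birth_time = 0.0
    lineages = [root]
    t = 0.0
    while len(lineages) < n_tips:
        t += rng.exponential(1.0 / len(lineages))
        node = lineages.pop(rng.integers(len(lineages)))
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = t
            node.add_child(child)
            lineages.append(child)
    t_end = t + rng.exponential(1.0 / n_tips)
    names = labels if labels is not None else [f"t{i + 1}" for i in range(n_tips)]
    if len(names) != n_tips:
        raise ValueError("label count does not match n_tips")
    scale = depth / t_end if t_end > 0 else 1.0
    for i, leaf in enumerate(lineages):
        leaf.taxon = taxa.new_taxon(names[i])
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            end = node.birth_time if node.child_nodes() else t_end
            length = (end - node.parent_node.birth_time) * scale
            if not clock:
                length = rng.exponential(depth / np.log2(max(n_tips, 2)))
            if noise_sd > 0:
                length *= rng.lognormal(mean=0.0, sigma=noise_sd)
            node.edge.length = length
    return tree


def _site_classes(model: SubstitutionModel, L: int, rng) -> np.ndarray:
    rates, weights = model.class_rates_weights()
    idx = rng.choice(len(rates), size=L, p=weights)
    return rates[idx]


def _evolve(model: SubstitutionModel, parent: np.ndarray, site_rates: np.ndarray,
            t: float, rng) -> np.ndarray:
    child = parent.copy()
    for r in np.unique(site_rates):
        sites = np.where(site_rates == r)[0]
        if r == 0.0 or t == 0.0:
            continue
        P = model.expm(r * t)
        cum = np.cumsum(P, axis=1)
        u = rng.random(len(sites))
        child[sites] = np.argmax(cum[parent[sites]] > u[:, None], axis=1)
    return child


def _decode(states: np.ndarray) -> str:
    return "".join(AA_ORDER[s] for s in states)


def sim_alignment(tree: dendropy.Tree, model: SubstitutionModel, L: int,
                  seed: int, *, site_rates: np.ndarray | None = None,
                  root_states: np.ndarray | None = None) -> ProteinAlignment:
    """Simulate residues down a tree under the model's CTMC with per-site
    rate classes; no indels, so the output has exactly L columns."""
    rng = np.random.default_rng(seed)
    if site_rates is None:
        site_rates = _site_classes(model, L, rng)
    if root_states is None:
        root_states = rng.choice(20, size=L, p=model.pi)
    states = {id(tree.seed_node): root_states}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            t = node.edge.length or 0.0
            states[id(node)] = _evolve(model, states[id(node.parent_node)],
                                       site_rates, t, rng)
        if node.is_leaf():
            rows.append(AnnotatedSequence(id=node.taxon.label,
                                          residues=_decode(states[id(node)])))
    return ProteinAlignment(rows)


def sim_pair(model: SubstitutionModel, t: float, L: int, seed: int):
    """One sequence pair at true divergence ``t``: ancestor from the
    stationary distribution, descendant evolved with per-site rate classes.
    Returns (row_a, row_b) as residue strings."""
    rng = np.random.default_rng(seed)
    site_rates = _site_classes(model, L, rng)
    a = rng.choice(20, size=L, p=model.pi)
    b = _evolve(model, a, site_rates, t, rng)
    return _decode(a), _decode(b)


def _build_species_tree(cfg: SimConfig, rng) -> tuple[dendropy.Tree, dict, dict]:
    """Species tree with monophyletic groups: a Yule backbone over groups,
    each group tip replaced by a small Yule subtree of its species."""
    backbone = sim_tree(len(cfg.groups), int(rng.integers(2**31)),
                        clock=True, noise_sd=cfg.clock_noise_sd,
                        depth=cfg.group_tree_depth, labels=cfg.groups)
    species_of_group, fast_species = {}, set()
    taxa = dendropy.TaxonNamespace()
    for leaf in list(backbone.leaf_node_iter()):
        group = leaf.taxon.label
        names = [f"{group}_sp{i + 1}" for i in range(cfg.species_per_group)]
        species_of_group[group] = names
        fast = rng.choice(cfg.species_per_group, size=cfg.n_fast_per_group,
                          replace=False)
        fast_species.update(names[i] for i in fast)
        if cfg.species_per_group == 1:
            leaf.taxon = taxa.new_taxon(names[0])
            leaf.edge.length = (leaf.edge.length or 0.0) + cfg.within_group_depth
            continue
        sub = sim_tree(cfg.species_per_group, int(rng.integers(2**31)),
                       clock=True, noise_sd=cfg.clock_noise_sd,
                       depth=cfg.within_group_depth, labels=names)
        leaf.taxon = None
        for child in sub.seed_node.child_nodes():
            leaf.add_child(child)
    # rebuild the taxon namespace after grafting
    newick = backbone.as_string(schema="newick", suppress_rooting=True)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             suppress_internal_node_taxa=True,
                             preserve_underscores=True)
    return tree, species_of_group, fast_species


def sim_family(cfg: SimConfig) -> FamilySim:
    """Simulate a multi-paralog, multi-taxon protein family.

    Every paralog descends from a shared ancestral sequence through its own
    "duplication" burn-in branch (length ``paralog_depth``), then evolves
    down a shared species tree whose designated fast species have their
    pendant branches multiplied by ``fast_factor``. All paralogs share one
    set of per-site rate classes, so columns are comparable family-wide.
    """
    rng = np.random.default_rng(cfg.seed)
    model = cfg.build_model()
    species_tree, species_of_group, fast_species = _build_species_tree(cfg, rng)
    for leaf in species_tree.leaf_node_iter():
        if leaf.taxon.label in fast_species:
            leaf.edge.length = (leaf.edge.length or 0.0) * cfg.fast_factor

    site_rates = _site_classes(model, cfg.L, rng)
    ancestor = rng.choice(20, size=cfg.L, p=model.pi)
    group_of_species = {sp: g for g, sps in species_of_group.items() for sp in sps}

    truth = GroundTruth(species_tree=species_tree)
    paralogs = [f"P{k + 1:02d}" for k in range(cfg.n_paralogs)]

    if cfg.losses_per_paralog > 0:
        pa, loss_truth = sim_presence_absence(
            species_tree, cfg.n_paralogs, cfg.losses_per_paralog,
            int(rng.integers(2**31)), paralog_names=paralogs)
        truth.loss_edges = loss_truth
        lost = {p: {sp for sp in pa.index if pa.loc[sp, p] == 0} for p in paralogs}
    else:
        lost = {p: set() for p in paralogs}
        truth.loss_edges = {p: [] for p in paralogs}

    rows, entries = [], {}
    for paralog in paralogs:
        par_root = _evolve(model, ancestor, site_rates, cfg.paralog_depth, rng)
        aln = sim_alignment(species_tree, model, cfg.L,
                            int(rng.integers(2**31)),
                            site_rates=site_rates, root_states=par_root)
        for r in aln.rows:
            species = r.id
            if species in lost[paralog]:
                continue
            seq_id = f"{paralog}_{species}"
            group = group_of_species[species]
            rows.append(AnnotatedSequence(id=seq_id, residues=r.residues,
                                          species=species, group=group,
                                          label=paralog))
            entries[seq_id] = (species, group)
            truth.clade_of[seq_id] = paralog
            truth.is_fast[seq_id] = species in fast_species

    alignment = ProteinAlignment(rows)
    taxon_map = TaxonMap(entries=entries, groups=list(cfg.groups))
    return FamilySim(sequences=rows, alignment=alignment, taxon_map=taxon_map,
                     truth=truth, config=cfg)


def sim_gene_structures(
    family: FamilySim,
    *,
    n_sites_per_clade: int = 3,
    retention: float = 1.0,
    seed: int = 0,
) -> list[GeneStructure]:
    """Plant per-clade ancestral intron sites and emit gene structures.

    Each paralog clade receives ``n_sites_per_clade`` distinct (residue,
    phase) sites; each member gene inherits each site independently with
    probability ``retention``. Offsets are computed by the exact reverse of
    the offset → (residue, phase) mapping. Planted sites are recorded in
    ``family.truth.intron_sites``.
    """
    rng = np.random.default_rng(seed)
    L = family.config.L
    planted: dict[str, set] = {}
    for paralog in sorted({s.label for s in family.sequences}):
        sites = set()
        while len(sites) < n_sites_per_clade:
            residue = int(rng.integers(2, L))  # avoid terminal codons
            phase = int(rng.integers(0, 3))
            sites.add((residue, phase))
        planted[paralog] = sites
    family.truth.intron_sites = planted

    genes = []
    for s in family.sequences:
        kept = [site for site in sorted(planted[s.label])
                if rng.random() < retention]
        offsets = sorted(site_to_cds_offset(r, p) for r, p in kept)
        genes.append(GeneStructure(gene_id=f"g_{s.id}", seq_id=s.id,
                                   intron_offsets=tuple(offsets)))
    return genes


def sim_presence_absence(
    species_tree: dendropy.Tree,
    n_paralogs: int,
    losses_per_paralog: int,
    seed: int,
    *,
    paralog_names: list[str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Presence–absence matrix from loss events placed on non-nested edges.

    Each paralog is present at the root and independently lost on
    ``losses_per_paralog`` edges chosen so that no chosen edge is nested in
    another (their tip sets are disjoint) and at least one tip stays present.
    Returns the species × paralog 0/1 matrix and the planted loss edges (tip
    sets) per paralog.
    """
    rng = np.random.default_rng(seed)
    tips = [t.taxon.label for t in species_tree.leaf_node_iter()]
    clades = []
    for node in species_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        clades.append(frozenset(t.taxon.label for t in node.leaf_iter()))
    names = paralog_names or [f"P{k + 1:02d}" for k in range(n_paralogs)]
    data = {}
    loss_truth = {}
    def admissible(cand, chosen):
        covered = set().union(*chosen) if chosen else set()
        if cand & covered or len(covered | cand) >= len(tips):
            return False
        # exact recovery requires the chosen clades to be the *maximal*
        # all-absent clades: no tree clade may be tiled by their union
        lost = covered | cand
        trial = chosen + [cand]
        return not any(c <= lost and not any(c <= ch for ch in trial)
                       for c in clades)

    for paralog in names:
        chosen: list[frozenset] = []
        # greedy scan over a shuffled clade order, restarting on dead ends
        for _ in range(1000):
            chosen = []
            order = rng.permutation(len(clades))
            for idx in order:
                if len(chosen) == losses_per_paralog:
                    break
                if admissible(clades[idx], chosen):
                    chosen.append(clades[idx])
            if len(chosen) == losses_per_paralog:
                break
        else:
            raise ValueError(
                f"cannot place {losses_per_paralog} non-nested losses for {paralog}"
            )
        lost = set().union(*chosen) if chosen else set()
        data[paralog] = [0 if sp in lost else 1 for sp in tips]
        loss_truth[paralog] = chosen
    df = pd.DataFrame(data, index=pd.Index(tips, name="species"), dtype="Int64")
    return df, loss_truth


def sim_predictor_calls(
    truth: dict[tuple[str, str], bool],
    tools: dict[str, tuple[float, float]],
    modification: str,
    seed: int,
) -> pd.DataFrame:
    """Noisy per-tool call table from ground-truth modification status.

    ``truth`` maps (seq_id, site) to the true status; each tool reports the
    truth flipped with its (false-positive, false-negative) rates.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for (seq_id, site), status in sorted(truth.items()):
        for tool in sorted(tools):
            p_fp, p_fn = tools[tool]
            if not (0 <= p_fp <= 1 and 0 <= p_fn <= 1):
                raise ValueError(f"tool {tool!r}: rates must lie in [0, 1]")
            if status:
                call = rng.random() >= p_fn
            else:
                call = rng.random() < p_fp
            rows.append({"seq_id": seq_id, "site": str(site), "tool": tool,
                         "modification": modification, "call": bool(call)})
    return pd.DataFrame(rows, columns=["seq_id", "site", "tool", "modification", "call"])
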