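"""Seedable generators of synthetic inputs with the statistical structure
the analysis assumes: a clade-tagged species tree, gene families evolving
by duplication/loss with domain fusion (pseudodimers) and accessory-domain
(aCD) gain, sequences under an empirical substitution model, proteome GO
tables, and toy dimer coordinates with a computable interface.

Every generator is a pure function of (configuration, seed).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .models import SubstitutionModel, load_model
from .records import AlignmentBlock, SequenceRecord, TaxonRecord
from .structio import Atom, Chain, Residue, StructureModel
from .tree import Node, Phylogeny


# ------------------------------------------------------------ species trees
def simulate_species_tree(n_taxa: int, seed: int, depth: float = 1.0,
                          fixed_topology: Optional[Phylogeny] = None,
                          prefix: str = "sp") -> Phylogeny:
    """Ultrametric (Yule-style) species tree with named tips.

    A ``fixed_topology`` is echoed unchanged, so configured backbones can
    be passed through the same interface.
    """
    if fixed_topology is not None:
        return fixed_topology
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    # grow by random splits at exponential waiting times, then rescale
    tips = [Node(f"{prefix}{i + 1:02d}", 0.0) for i in range(2)]
    root = Node()
    root.add(tips[0])
    root.add(tips[1])
    heights = {id(n): 0.0 for n in tips}
    t = 0.0
    k = 2
    while k < n_taxa:
        t += rng.exponential(1.0 / k)
        leaf = tips[rng.integers(len(tips))]
        a = Node(leaf.name, 0.0)
        b = Node(f"{prefix}{k + 1:02d}", 0.0)
        leaf.name = None
        leaf.add(a)
        leaf.add(b)
        heights[id(leaf)] = t
        heights[id(a)] = heights[id(b)] = t
        tips.remove(leaf)
        tips.extend([a, b])
        k += 1
    t += rng.exponential(1.0 / k)
    total = t
    tree = Phylogeny(root, rooted=True)
    for n in tree.postorder():
        if n.parent is None:
            n.length = None
            continue
        start = heights.get(id(n.parent), 0.0)
        end = heights[id(n)] if not n.is_leaf else total
        n.length = (end - start) * depth / total
    return tree


# -------------------------------------------------------------- gene family
@dataclass
class GeneFamily:
    """One subfamily's gene tree inside the species tree, plus event truth."""

    gene_tree: Optional[Phylogeny]           # None if globally extinct
    copies: Dict[str, List[str]]             # species -> gene ids
    fusions: List[Tuple[str, str]]           # fused (N-side, C-side) gene ids
    acd_genes: Set[str]


def simulate_gene_family(species_tree: Phylogeny, duplication_rate: float,
                         loss_rate: float, fusion_prob: float,
                         acd_gain_clade: Optional[Sequence[str]], seed: int,
                         subfamily: str = "fam",
                         forced_loss_species: Sequence[str] = (),
                         protect_primary: bool = False,
                         rate_scale: float = 1.0) -> GeneFamily:
    """Birth-death gene evolution inside the species tree.

    One gene enters at the species-tree root; duplications and losses occur
    at the given per-lineage rates along branches (time units of the
    species tree). ``protect_primary`` exempts one copy per lineage from
    loss (a conditioning used by the default family so anchor taxa retain
    one copy; the plain process keeps the analytic birth-death mean).
    Species in ``forced_loss_species`` lose every copy. With probability
    ``fusion_prob`` per species carrying >= 2 copies, two copies fuse into
    a pseudodimer parent. Genes of species in ``acd_gain_clade`` (or all
    genes if it is None and the subfamily is configured that way upstream)
    gain the aCD accessory domain. Branch lengths of the returned gene
    tree are time * ``rate_scale`` (substitutions/site).
    """
    rng = np.random.default_rng(seed)
    rate = duplication_rate + loss_rate
    forced_loss = set(forced_loss_species)

    def _sim(sp_node: Node, remaining: float, protected: bool) -> Optional[Node]:
        """Gene lineage entering a species branch with ``remaining`` time
        to travel; returns the gene-tree node at the *end* of the species
        branch path below, with .length = time since lineage entry."""
        elapsed = 0.0
        while True:
            dt = rng.exponential(1.0 / rate) if rate > 0 else np.inf
            if dt >= remaining:
                node = _at_species_node(sp_node, protected)
                if node is None:
                    return None
                node.length = (node.length or 0.0) + remaining + elapsed
                return node
            elapsed += dt
            remaining -= dt
            if rng.random() < (duplication_rate / rate if rate > 0 else 0.0):
                a = _sim(sp_node, remaining, protected)
                b = _sim(sp_node, remaining, False)
                if a is None and b is None:
                    return None
                if a is None or b is None:
                    node = a if b is None else b
                    node.length += elapsed
                    return node
                parent = Node(length=elapsed)
                parent.add(a)
                parent.add(b)
                return parent
            else:
                if protected:
                    continue            # loss vetoed on the protected copy
                return None

    def _at_species_node(sp_node: Node, protected: bool) -> Optional[Node]:
        if sp_node.is_leaf:
            return Node(name=f"@{sp_node.name}", length=0.0)
        kids = []
        for child in sp_node.children:
            # protection propagates through speciation: one loss-exempt
            # copy per descendant species lineage
            g = _sim(child, child.length or 0.0, protected)
            if g is not None:
                kids.append(g)
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        parent = Node(length=0.0)
        for g in kids:
            parent.add(g)
        return parent

    root_gene = _at_species_node(species_tree.root, protect_primary)

    copies: Dict[str, List[str]] = {}
    tree = None
    if root_gene is not None:
        # name gene copies deterministically in traversal order (before
        # wrapping: placeholder names repeat per species), pruning
        # forced-loss species
        def walk_leaves(n: Node):
            if n.is_leaf:
                yield n
            else:
                for c in n.children:
                    yield from walk_leaves(c)

        drop = []
        for leaf in walk_leaves(root_gene):
            sp = leaf.name[1:]
            if sp in forced_loss:
                drop.append(leaf)
                leaf.name = f"dropped|{sp}|{id(leaf)}"
                continue
            k = len(copies.setdefault(sp, [])) + 1
            gid = f"{subfamily}|{sp}|g{k}"
            copies[sp].append(gid)
            leaf.name = gid
        tree = Phylogeny(root_gene, rooted=True)
        for leaf in drop:
            _prune_leaf(tree, leaf)
        copies = {s: g for s, g in copies.items() if g}
        if not copies or tree.root.is_leaf:
            tree = None
        else:
            for n in tree.edges():
                n.length = (n.length or 0.0) * rate_scale
            tree.root.length = None

    fusions: List[Tuple[str, str]] = []
    if tree is not None and fusion_prob > 0:
        for sp in sorted(copies):
            ids = copies[sp]
            if len(ids) >= 2 and rng.random() < fusion_prob:
                fusions.append((ids[0], ids[1]))

    acd_genes: Set[str] = set()
    if tree is not None and acd_gain_clade is not None:
        gain = set(acd_gain_clade)
        for sp, ids in copies.items():
            if sp in gain:
                acd_genes.update(ids)

    return GeneFamily(tree, copies, fusions, acd_genes)


def _prune_leaf(tree: Phylogeny, leaf: Node) -> None:
    p = leaf.parent
    if p is None:
        raise ValueError("cannot prune the only node")
    p.children.remove(leaf)
    tree.suppress_unifurcations()


# ---------------------------------------------------------------- sequences
def evolve_sequences(gene_tree: Phylogeny, root_length: int,
                     model: SubstitutionModel, seed: int,
                     indel_rate: float = 0.0,
                     mean_indel_length: float = 3.0) -> List[SequenceRecord]:
    """Evolve site-independent sequences down a tree.

    The root sequence is drawn from the model's equilibrium frequencies;
    each branch applies P(t) row sampling. The default is indel-free so
    the true alignment is the identity; a simple geometric-length indel
    mode is available for aligner stress tests.
    """
    rng = np.random.default_rng(seed)
    k = model.k
    root_states = rng.choice(k, size=root_length, p=model.freqs)

    out: List[SequenceRecord] = []

    def descend(node: Node, states: np.ndarray) -> None:
        for child in node.children:
            P = model.transition_matrix(max(child.length or 0.0, 0.0))
            cum = P.cumsum(axis=1)
            u = rng.random(states.shape[0])
            child_states = (u[:, None] > cum[states]).sum(axis=1)
            if indel_rate > 0:
                child_states = _apply_indels(child_states, rng, model,
                                             indel_rate * (child.length or 0.0),
                                             mean_indel_length)
            if child.is_leaf:
                seq = "".join(model.alphabet[i] for i in child_states)
                out.append(SequenceRecord(child.name, seq))
            else:
                descend(child, child_states)

    if gene_tree.root.is_leaf:
        out.append(SequenceRecord(gene_tree.root.name,
                                  "".join(model.alphabet[i] for i in root_states)))
    else:
        descend(gene_tree.root, root_states)
    return out


def _apply_indels(states: np.ndarray, rng: np.random.Generator,
                  model: SubstitutionModel, expected_events: float,
                  mean_len: float) -> np.ndarray:
    n_events = rng.poisson(expected_events * states.shape[0])
    for _ in range(n_events):
        length = 1 + rng.geometric(1.0 / mean_len)
        pos = int(rng.integers(0, states.shape[0] + 1))
        if rng.random() < 0.5 and states.shape[0] > length:
            states = np.delete(states, slice(pos, pos + length))
        else:
            ins = rng.choice(model.k, size=length, p=model.freqs)
            states = np.insert(states, min(pos, states.shape[0]), ins)
    return states


# ------------------------------------------------------------ proteome table
def make_proteome_tables(species: Sequence[str],
                         photosynthetic_species: Sequence[str], seed: int,
                         superkingdom_of: Optional[Mapping[str, str]] = None,
                         genus_of: Optional[Mapping[str, str]] = None) -> List[TaxonRecord]:
    """Per-species proteome metadata: photosynthetic species draw a GO
    photosynthesis count of at least 11, others at most 10; BUSCO is
    uniform on [60,100] and missing 20% of the time; reference /
    nonredundant flags are Bernoulli(0.3)/Bernoulli(0.5)."""
    rng = np.random.default_rng(seed)
    photo = set(photosynthetic_species)
    out = []
    for sp in species:
        if sp in photo:
            go = 11 + int(rng.poisson(40))
        else:
            go = int(min(10, rng.poisson(3)))
        flags = set()
        if rng.random() < 0.3:
            flags.add("reference")
        if rng.random() < 0.5:
            flags.add("nonredundant")
        busco = None if rng.random() < 0.2 else float(np.round(rng.uniform(60, 100), 1))
        out.append(TaxonRecord(
            organism=sp,
            genus=(genus_of or {}).get(sp, sp.split("_")[0]),
            superkingdom=(superkingdom_of or {}).get(sp, "Eukaryota"),
            go_photosynthesis_count=go,
            proteome_flags=frozenset(flags),
            busco_completeness=busco,
        ))
    return out


# ---------------------------------------------------------------- toy dimer
def make_toy_dimer(separation: float, seed: int = 0, n_residues: int = 20,
                   salt_bridge_distance: Optional[float] = None) -> StructureModel:
    """Two ideal poly-Ala alpha-helices (1.5 A rise, 100 deg twist) with
    parallel axes ``separation`` apart; optionally an Arg/Asp pair whose
    closest side-chain N-O distance equals ``salt_bridge_distance``."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    _ = np.random.default_rng(seed)   # reserved for optional jitter; none by default

    def helix(x_offset: float, chain_id: str) -> Chain:
        residues = []
        for i in range(n_residues):
            theta = np.radians(100.0 * i)
            z = 1.5 * i
            ca = np.array([x_offset + 2.3 * np.cos(theta), 2.3 * np.sin(theta), z])
            radial = np.array([np.cos(theta), np.sin(theta), 0.0])
            tang = np.array([-np.sin(theta), np.cos(theta), 0.0])
            atoms = [
                Atom("N", "N", ca - 1.3 * radial + 0.4 * tang),
                Atom("CA", "C", ca),
                Atom("C", "C", ca + 1.2 * tang + np.array([0, 0, 0.7])),
                Atom("O", "O", ca + 1.2 * tang + 1.1 * radial + np.array([0, 0, 0.9])),
                Atom("CB", "C", ca + 1.5 * radial),
            ]
            residues.append(Residue("ALA", i + 1, "", atoms))
        return Chain(chain_id, residues)

    a = helix(0.0, "A")
    b = helix(separation, "B")
    if salt_bridge_distance is not None:
        mid_z = 1.5 * n_residues + 4.0
        nh1 = np.array([separation / 2 - salt_bridge_distance / 2, 0.0, mid_z])
        od1 = np.array([separation / 2 + salt_bridge_distance / 2, 0.0, mid_z])
        arg = Residue("ARG", n_residues + 1, "", [
            Atom("CA", "C", nh1 + np.array([-3.0, 0, 0])),
            Atom("NE", "N", nh1 + np.array([-1.2, 0.8, 0])),
            Atom("NH1", "N", nh1),
        ])
        asp = Residue("ASP", n_residues + 1, "", [
            Atom("CA", "C", od1 + np.array([3.0, 0, 0])),
            Atom("OD1", "O", od1),
            Atom("OD2", "O", od1 + np.array([1.0, 1.0, 0])),
        ])
        a.residues.append(arg)
        b.residues.append(asp)
    return StructureModel([a, b])


# ======================================================= default family sim
#: fixed ultrametric backbone (time units): photosynthetic bacteria,
#: single-celled plants, land plants
DEFAULT_SPECIES_NEWICK = (
    "((cyano1:0.6,cyano2:0.6):0.4,((alga1:0.3,alga2:0.3):0.4,"
    "((plant1:0.25,plant2:0.25):0.25,(plant3:0.25,plant4:0.25):0.25):0.2):0.3);"
)

DEFAULT_CLADES = {
    "cyanobacteria": frozenset({"cyano1", "cyano2"}),
    "single_celled_plants": frozenset({"alga1", "alga2"}),
    "land_plants": frozenset({"plant1", "plant2", "plant3", "plant4"}),
}


@dataclass
class FamilyConfig:
    """Study conditions for the default synthetic Get3/ArsA family.

    Four subfamilies radiate before the species root and then follow the
    species tree with duplication/loss; the aCD-bearing subfamily loses
    its gene in single-celled plants (emulating the inferred gene loss),
    and the ArsA-like subfamily forms tandem pseudodimers.
    """

    species_newick: str = DEFAULT_SPECIES_NEWICK
    clades: Mapping[str, frozenset] = field(default_factory=lambda: dict(DEFAULT_CLADES))
    subfamilies: Tuple[str, ...] = ("Get3a", "Get3bc", "Get3d", "ArsA")
    stem_lengths: Mapping[str, float] = field(default_factory=lambda: {
        "Get3a": 0.35, "Get3bc": 0.35, "Get3d": 0.40, "ArsA": 0.50})
    rate_scale: float = 0.4            # substitutions/site per unit tree time
    root_length: int = 500             # Get3/ArsA domain sites
    acd_length: int = 110              # accessory aCD sites
    linker_length: int = 16
    duplication_rate: float = 0.15
    loss_rate: float = 0.15
    fusion_prob: Mapping[str, float] = field(default_factory=lambda: {"ArsA": 0.6})
    forced_loss: Mapping[str, str] = field(default_factory=lambda: {
        "Get3d": "single_celled_plants"})
    acd_subfamily: str = "Get3d"
    model_name: str = "LG"
    protect_primary: bool = True
    anchor_species: str = "plant1"     # the A. thaliana-like model organism
    rooting_species: str = "cyano1"


@dataclass
class FamilySimulation:
    """A complete synthetic study: proteins, truth tables, metadata and the
    reference (seed) alignments the pipeline consumes."""

    config: FamilyConfig
    seed: int
    species_tree: Phylogeny
    gene_families: Dict[str, GeneFamily]
    proteins: List[SequenceRecord]
    protein_acd: Set[str]                       # protein ids carrying an aCD
    pseudodimer_pairs: Dict[str, Tuple[str, str]]   # parent -> (gene N, gene C)
    domain_truth: Dict[str, str]                # expected domain id -> subfamily
    domain_to_species: Dict[str, str]
    copy_numbers: Dict[str, Dict[str, int]]     # species -> subfamily -> count
    taxonomy: List[TaxonRecord]
    seed_alignment: AlignmentBlock
    acd_seed_alignment: AlignmentBlock
    anchor_domains: Dict[str, str]              # subfamily -> anchor domain id
    rooting_anchors: Tuple[str, str]


def simulate_family(config: Optional[FamilyConfig] = None,
                    seed: int = 0) -> FamilySimulation:
    """Generate the default synthetic family (pure function of config+seed)."""
    from .tree import read_newick

    cfg = config or FamilyConfig()
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(6)
    sub_seeds = {name: s for name, s in
                 zip(cfg.subfamilies, streams[0].spawn(len(cfg.subfamilies)))}

    species_tree = read_newick(cfg.species_newick)
    species = sorted(species_tree.leaf_names())
    model = load_model(cfg.model_name)

    gene_families: Dict[str, GeneFamily] = {}
    combined_root = Node()
    for name in cfg.subfamilies:
        forced = cfg.forced_loss.get(name)
        gf = simulate_gene_family(
            species_tree,
            duplication_rate=cfg.duplication_rate,
            loss_rate=cfg.loss_rate,
            fusion_prob=cfg.fusion_prob.get(name, 0.0),
            acd_gain_clade=(species if name == cfg.acd_subfamily else None),
            seed=int(sub_seeds[name].generate_state(1)[0] % (2 ** 31)),
            subfamily=name,
            forced_loss_species=(cfg.clades[forced] if forced else ()),
            protect_primary=cfg.protect_primary,
            rate_scale=cfg.rate_scale,
        )
        gene_families[name] = gf
        if gf.gene_tree is not None:
            sub_root = gf.gene_tree.root
            sub_root.length = cfg.stem_lengths[name]
            combined_root.add(sub_root)
    combined = Phylogeny(combined_root, rooted=True)

    dom_seqs = {r.id: r.residues for r in evolve_sequences(
        combined, cfg.root_length, model,
        seed=int(streams[1].generate_state(1)[0] % (2 ** 31)))}

    acd_gf = gene_families[cfg.acd_subfamily]
    acd_seqs: Dict[str, str] = {}
    if acd_gf.gene_tree is not None:
        acd_tree = acd_gf.gene_tree.copy()
        acd_tree.root.length = None
        acd_seqs = {r.id: r.residues for r in evolve_sequences(
            acd_tree, cfg.acd_length, model,
            seed=int(streams[2].generate_state(1)[0] % (2 ** 31)))}

    rng_linker = np.random.default_rng(
        int(streams[3].generate_state(1)[0] % (2 ** 31)))

    proteins: List[SequenceRecord] = []
    protein_acd: Set[str] = set()
    pairs: Dict[str, Tuple[str, str]] = {}
    domain_truth: Dict[str, str] = {}
    domain_to_species: Dict[str, str] = {}
    copy_numbers: Dict[str, Dict[str, int]] = {
        sp: {name: 0 for name in cfg.subfamilies} for sp in species}

    for name in cfg.subfamilies:
        gf = gene_families[name]
        fused_genes = {g for pair in gf.fusions for g in pair}
        k_fused = 0
        for sp in sorted(gf.copies):
            for gid in gf.copies[sp]:
                copy_numbers[sp][name] += 1
            for gid in gf.copies[sp]:
                if gid in fused_genes:
                    continue
                seq = dom_seqs[gid]
                if gid in gf.acd_genes and gid in acd_seqs:
                    seq = seq + acd_seqs[gid]
                    protein_acd.add(gid)
                proteins.append(SequenceRecord(gid, seq))
                domain_truth[gid] = name
                domain_to_species[gid] = sp
        for gid_n, gid_c in gf.fusions:
            k_fused += 1
            sp = gid_n.split("|")[1]
            parent_id = f"{name}|{sp}|fused{k_fused}"
            linker = "".join(model.alphabet[i] for i in rng_linker.choice(
                model.k, size=cfg.linker_length, p=model.freqs))
            proteins.append(SequenceRecord(
                parent_id, dom_seqs[gid_n] + linker + dom_seqs[gid_c]))
            pairs[parent_id] = (gid_n, gid_c)
            for half, gid in ((f"{parent_id}_N", gid_n), (f"{parent_id}_C", gid_c)):
                domain_truth[half] = name
                domain_to_species[half] = sp

    taxonomy = make_proteome_tables(
        species, photosynthetic_species=species,
        seed=int(streams[4].generate_state(1)[0] % (2 ** 31)),
        superkingdom_of={sp: ("Bacteria" if sp.startswith("cyano") else "Eukaryota")
                         for sp in species})
    # the default family emulates well-annotated model proteomes: every
    # species passes the quality filter
    taxonomy = [replace(t, proteome_flags=t.proteome_flags | {"reference"})
                for t in taxonomy]

    def _ref_gene(name: str) -> str:
        gf = gene_families[name]
        for sp in ("cyano1", cfg.anchor_species, *species):
            for gid in gf.copies.get(sp, ()):
                return gid
        raise RuntimeError(f"subfamily {name} extinct everywhere")

    seed_alignment = AlignmentBlock(
        [(f"seedref_{name}", dom_seqs[_ref_gene(name)])
         for name in cfg.subfamilies])

    acd_rows = []
    for sp in ("cyano1", cfg.anchor_species):
        for gid in acd_gf.copies.get(sp, ()):
            if gid in acd_seqs:
                acd_rows.append((f"seedacd_{sp}", acd_seqs[gid]))
                break
    acd_seed_alignment = AlignmentBlock(acd_rows)

    def _domain_id_of(gid: str) -> str:
        for parent, (gn, gc) in pairs.items():
            if gid == gn:
                return f"{parent}_N"
            if gid == gc:
                return f"{parent}_C"
        return gid

    anchor_domains = {}
    for name in cfg.subfamilies:
        gf = gene_families[name]
        src = cfg.anchor_species if gf.copies.get(cfg.anchor_species) else \
            next(sp for sp in species if gf.copies.get(sp))
        anchor_domains[name] = _domain_id_of(gf.copies[src][0])
    arsa_src = cfg.rooting_species if gene_families["ArsA"].copies.get(cfg.rooting_species) \
        else next(sp for sp in species if gene_families["ArsA"].copies.get(sp))
    rooting = (_domain_id_of(gene_families["ArsA"].copies[arsa_src][0]),
               anchor_domains["Get3a"])

    return FamilySimulation(
        config=cfg, seed=seed, species_tree=species_tree,
        gene_families=gene_families, proteins=proteins,
        protein_acd=protein_acd, pseudodimer_pairs=pairs,
        domain_truth=domain_truth, domain_to_species=domain_to_species,
        copy_numbers=copy_numbers, taxonomy=taxonomy,
        seed_alignment=seed_alignment, acd_seed_alignment=acd_seed_alignment,
        anchor_domains=anchor_domains, rooting_anchors=rooting)
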