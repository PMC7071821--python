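"""Seeded synthetic fixtures for the co-expression pipeline.

Everything downstream of read quantification is exercisable without any
sequencing data: an ultrametric species tree, pollination-syndrome trait
tables, a two-stage orthogroup expression matrix with planted co-expression
modules whose eigengenes carry species and trait effects, and in-frame codon
alignments evolved at a specified dN/dS (omega).

All generators are pure functions of their inputs and an integer seed.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "SYNDROME_TRAIT_MAP",
    "ModuleSpec",
    "ModulePlan",
    "CodonSimSpec",
    "simulate_phylogeny",
    "simulate_traits",
    "simulate_expression",
    "simulate_codon_alignments",
    "write_fixture_bundle",
]

# Pollination-syndrome trait suites: each syndrome constrains primary flower
# color, corolla shape and the presence of corolla spurs. Spurs occur only in
# the butterfly syndrome.
SYNDROME_TRAIT_MAP = {
    "bee": {
        "color": ("white", "purple"),
        "shape": ("funnelform",),
        "spur": "absent",
    },
    "hummingbird": {
        "color": ("red", "yellow"),
        "shape": ("tubular", "salverform"),
        "spur": "absent",
    },
    "butterfly": {
        "color": ("purple",),
        "shape": ("salverform",),
        "spur": "present",
    },
}

SYNDROMES = tuple(SYNDROME_TRAIT_MAP)


def _tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths = {}
    for leaf in tree.leaf_node_iter():
        d, node = 0.0, leaf
        while node.parent_node is not None:
            d += node.edge.length or 0.0
            node = node.parent_node
        depths[leaf.taxon.label] = d
    return depths


def simulate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Simulate a pure-birth (Yule) species tree, rescaled so every
    root-to-tip path length equals 1.0.

    Parameters
    ----------
    n_species : number of extant tips (>= 2); tips are labelled sp01, sp02, ...
    seed : RNG seed; the same seed yields an identical Newick string.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng(seed)

    # Yule process: start with two lineages from the root, split a uniformly
    # chosen lineage at exponential waiting times until n tips exist.
    parent = {0: None, 1: None, 2: None}
    children: dict[int, list[int]] = {0: [1, 2]}
    birth: dict[int, float] = {0: 0.0, 1: 0.0, 2: 0.0}
    active = [1, 2]
    t = 0.0
    next_id = 3
    while len(active) < n_species:
        t += rng.exponential(1.0 / len(active))
        i = active.pop(rng.integers(len(active)))
        c1, c2 = next_id, next_id + 1
        next_id += 2
        children[i] = [c1, c2]
        parent[c1] = parent[c2] = i
        birth[c1] = birth[c2] = t
        active.extend([c1, c2])
    t_end = t + rng.exponential(1.0 / len(active))

    labels = {}
    for k, node in enumerate(sorted(active)):
        labels[node] = f"sp{k + 1:02d}"

    def newick(node: int) -> str:
        if node not in children:
            return labels[node]
        parts = []
        for c in children[node]:
            end = birth[children[c][0]] if c in children else t_end
            parts.append(f"{newick(c)}:{end - birth[c]!r}")
        return "(" + ",".join(parts) + ")"

    tree = dendropy.Tree.get(data=newick(0) + ";", schema="newick")
    rescale_to_unit_depth(tree)
    return tree


def rescale_to_unit_depth(tree: dendropy.Tree) -> dendropy.Tree:
    """Rescale branch lengths in place so the root-to-tip depth is 1.0."""
    depth = max(_tip_depths(tree).values())
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = edge.length / depth
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    syndrome_proportions: dict[str, float] | None = None,
    seed: int = 0,
    switch_rate: float = 2.0,
) -> pd.DataFrame:
    """Assign syndromes by a Markov walk on the tree, then draw the dependent
    floral traits (color, shape, spur) from the syndrome's trait suite.

    The walk switches state at exponential times with rate ``switch_rate``
    per unit branch length; each switch resamples the syndrome from
    ``syndrome_proportions``, so the proportions are also the stationary
    distribution. The walk induces phylogenetic clustering of syndromes.
    """
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if not taxa:
        raise ValueError("tree has no tips")
    if syndrome_proportions is None:
        syndrome_proportions = {"bee": 0.25, "butterfly": 1 / 3, "hummingbird": 5 / 12}
    props = np.array([syndrome_proportions.get(s, 0.0) for s in SYNDROMES], float)
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("syndrome proportions must sum to 1")
    rng = np.random.default_rng(seed)

    state: dict[int, int] = {}
    root = tree.seed_node
    state[id(root)] = rng.choice(len(SYNDROMES), p=props)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        s = state[id(node.parent_node)]
        length = node.edge.length or 0.0
        n_switches = rng.poisson(switch_rate * length)
        for _ in range(n_switches):
            s = rng.choice(len(SYNDROMES), p=props)
        state[id(node)] = s

    rows = []
    for leaf in tree.leaf_node_iter():
        syndrome = SYNDROMES[state[id(leaf)]]
        suite = SYNDROME_TRAIT_MAP[syndrome]
        rows.append(
            {
                "species": leaf.taxon.label,
                "syndrome": syndrome,
                "color": suite["color"][rng.integers(len(suite["color"]))],
                "shape": suite["shape"][rng.integers(len(suite["shape"]))],
                "spur": suite["spur"],
            }
        )
    return pd.DataFrame(rows).set_index("species")


@dataclass
class ModuleSpec:
    """One planted co-expression module.

    target_cor is the mean pairwise within-module correlation; per-gene
    memberships are jittered around it (uniform +/- cor_jitter) so genes have
    heterogeneous connectivity, as real modules do. trait_effects maps
    (trait, level) -> additive shift applied to the module eigengene in
    species carrying that trait level, in units of the Brownian species-effect
    standard deviation.
    """

    n_genes: int
    target_cor: float = 0.7
    trait_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    species_effect_sd: float = 1.0
    replicate_sd: float = 0.5
    cor_jitter: float = 0.1

    def __post_init__(self):
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if not (0.0 < self.target_cor <= 1.0):
            raise ValueError("target_cor must be in (0, 1]")


@dataclass
class ModulePlan:
    modules: list[ModuleSpec]
    n_background: int = 0

    def __post_init__(self):
        if not self.modules:
            raise ValueError("plan must contain at least one module")
        if self.n_background < 0:
            raise ValueError("n_background must be >= 0")


def _phylo_correlation(tree: dendropy.Tree, taxa: list[str]) -> np.ndarray:
    """Shared-path-length (Brownian) correlation matrix for a depth-1
    ultrametric tree: C_ij = 1 - patristic(i, j) / 2."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    C = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(tax[taxa[i]], tax[taxa[j]])
        C[i, j] = C[j, i] = max(0.0, 1.0 - d / 2.0)
    return C


def simulate_expression(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    plan: ModulePlan,
    n_replicates: int = 3,
    stages: tuple[str, ...] = ("Bud", "D"),
    seed: int = 0,
):
    """Generate a two-stage orthogroup x sample count matrix with planted
    modules.

    Per stage and module, a species-level eigengene is drawn as Brownian
    motion on the tree plus the module's trait effects; each sample adds
    replicate noise and the eigengene is standardized across samples. Gene i
    of the module is sqrt(r_i) * eigengene + sqrt(1 - r_i) * noise with r_i
    jittered around target_cor, so cor(g_i, g_j) = sqrt(r_i r_j). Background
    genes are independent noise. Values are built on a log2 scale around a
    per-gene baseline and exponentiated to a non-negative count-like scale.

    Returns
    -------
    counts : DataFrame, orthogroups x samples (both stages concatenated)
    meta : DataFrame with sample, species, stage, replicate
    truth : Series mapping orthogroup id -> planted module label (0 = none)
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    taxa = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    unknown = set(traits.index) - set(taxa)
    if unknown:
        raise ValueError(f"traits contain species not in tree: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    C = _phylo_correlation(tree, taxa)
    L = np.linalg.cholesky(C + 1e-10 * np.eye(len(taxa)))

    n_genes = sum(m.n_genes for m in plan.modules) + plan.n_background
    og_ids = [f"OG{i + 1:06d}" for i in range(n_genes)]
    truth = np.zeros(n_genes, int)
    pos = 0
    for k, m in enumerate(plan.modules, start=1):
        truth[pos : pos + m.n_genes] = k
        pos += m.n_genes

    meta_rows, columns = [], []
    for stage in stages:
        for sp in taxa:
            for rep in range(1, n_replicates + 1):
                columns.append(f"{sp}_{stage}_r{rep}")
                meta_rows.append(
                    {"sample": columns[-1], "species": sp, "stage": stage, "replicate": rep}
                )
    meta = pd.DataFrame(meta_rows).set_index("sample")

    n_samples_stage = len(taxa) * n_replicates
    baseline = rng.uniform(4.0, 10.0, size=n_genes)
    blocks = []
    for stage in stages:
        log_expr = np.empty((n_genes, n_samples_stage))
        pos = 0
        for m in plan.modules:
            species_eff = m.species_effect_sd * (L @ rng.standard_normal(len(taxa)))
            shift = np.zeros(len(taxa))
            for (trait, level), eff in m.trait_effects.items():
                for i, sp in enumerate(taxa):
                    if sp in traits.index and traits.loc[sp, trait] == level:
                        shift[i] += eff * m.species_effect_sd
            per_sample = np.repeat(species_eff + shift, n_replicates)
            per_sample = per_sample + rng.normal(0.0, m.replicate_sd, n_samples_stage)
            e = (per_sample - per_sample.mean()) / per_sample.std(ddof=1)
            r = rng.uniform(
                m.target_cor - m.cor_jitter, m.target_cor + m.cor_jitter, m.n_genes
            )
            r = np.clip(r, 0.02, 1.0)
            noise = rng.standard_normal((m.n_genes, n_samples_stage))
            g = np.sqrt(r)[:, None] * e[None, :] + np.sqrt(1.0 - r)[:, None] * noise
            log_expr[pos : pos + m.n_genes] = g
            pos += m.n_genes
        if plan.n_background:
            log_expr[pos:] = rng.standard_normal((plan.n_background, n_samples_stage))
        blocks.append(2.0 ** (baseline[:, None] + log_expr))

    counts = pd.DataFrame(np.hstack(blocks), index=og_ids, columns=columns)
    return counts, meta, pd.Series(truth, index=og_ids, name="module")


# ---------------------------------------------------------------------------
# Codon simulation


def _sense_codons() -> list[str]:
    table = standard_dna_table
    stops = set(table.stop_codons)
    return [
        "".join(c)
        for c in itertools.product("TCAG", repeat=3)
        if "".join(c) not in stops
    ]

SENSE_CODONS = _sense_codons()
_AA = {c: standard_dna_table.forward_table[c] for c in SENSE_CODONS}
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class CodonSimSpec:
    """Codon substitution process: Muse-Gaut-style with uniform codon
    frequencies. Nonsynonymous rates are scaled by omega, transitions by
    kappa; the matrix is normalized to one expected substitution per codon
    per unit branch length, and branch lengths are multiplied by tree_scale.
    """

    omega: float = 0.5
    kappa: float = 2.0
    n_codons: int = 300
    tree_scale: float = 0.5

    def __post_init__(self):
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if self.n_codons < 10:
            raise ValueError("n_codons must be >= 10")


def codon_rate_matrix(omega: float, kappa: float) -> np.ndarray:
    """Build the 61x61 rate matrix (uniform codon frequencies), normalized to
    unit expected substitution rate per codon."""
    n = len(SENSE_CODONS)
    Q = np.zeros((n, n))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diff) != 1:
                continue
            rate = kappa if diff[0] in _TRANSITIONS else 1.0
            if _AA[ci] != _AA[cj]:
                rate *= omega
            Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mean_rate = -np.mean(np.diag(Q))
    if mean_rate > 0:
        Q /= mean_rate
    return Q


def simulate_codon_alignments(
    tree: dendropy.Tree,
    spec: CodonSimSpec,
    n_orthogroups: int = 1,
    seed: int = 0,
) -> dict[str, dict[str, str]]:
    """Evolve codon sequences along the tree; returns
    {orthogroup_id: {species: sequence}} with in-frame, stop-free sequences.
    """
    if n_orthogroups < 1:
        raise ValueError("n_orthogroups must be >= 1")
    from scipy.linalg import expm

    rng = np.random.default_rng(seed)
    Q = codon_rate_matrix(spec.omega, spec.kappa)
    n_states = len(SENSE_CODONS)

    # transition matrices cached per (rounded) branch length
    cache: dict[float, np.ndarray] = {}

    def pmat(length: float) -> np.ndarray:
        key = round(length * spec.tree_scale, 10)
        if key not in cache:
            P = expm(Q * key)
            P = np.clip(P, 0.0, None)
            cache[key] = np.cumsum(P / P.sum(axis=1, keepdims=True), axis=1)
        return cache[key]

    alignments: dict[str, dict[str, str]] = {}
    nodes = list(tree.preorder_node_iter())
    for og in range(n_orthogroups):
        states: dict[int, np.ndarray] = {}
        root = tree.seed_node
        states[id(root)] = rng.integers(n_states, size=spec.n_codons)
        for node in nodes:
            if node is root:
                continue
            Pc = pmat(node.edge.length or 0.0)
            u = rng.random(spec.n_codons)
            parent_states = states[id(node.parent_node)]
            child = np.empty(spec.n_codons, dtype=np.int64)
            for s in np.unique(parent_states):
                mask = parent_states == s
                child[mask] = np.searchsorted(Pc[s], u[mask], side="right")
            states[id(node)] = np.minimum(child, n_states - 1)
        seqs = {}
        for leaf in tree.leaf_node_iter():
            seqs[leaf.taxon.label] = "".join(
                SENSE_CODONS[s] for s in states[id(leaf)]
            )
        alignments[f"OG{og + 1:06d}"] = seqs
    return alignments


# ---------------------------------------------------------------------------
# Fixture-bundle writers


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 60):
                fh.write(seq[k : k + 60] + "\n")


def write_fixture_bundle(
    outdir,
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    truth: pd.Series | None = None,
    alignments: dict[str, dict[str, str]] | None = None,
) -> None:
    """Write the on-disk fixture layout: expression.tsv, metadata.tsv,
    traits.tsv, tree.nwk, truth.tsv and alignments/OG*.fasta."""
    import os

    os.makedirs(outdir, exist_ok=True)
    counts.rename_axis("orthogroup").to_csv(os.path.join(outdir, "expression.tsv"), sep="\t")
    meta.to_csv(os.path.join(outdir, "metadata.tsv"), sep="\t")
    traits.to_csv(os.path.join(outdir, "traits.tsv"), sep="\t")
    tree.write(path=os.path.join(outdir, "tree.nwk"), schema="newick")
    if truth is not None:
        truth.rename_axis("orthogroup").to_csv(os.path.join(outdir, "truth.tsv"), sep="\t")
    if alignments:
        adir = os.path.join(outdir, "alignments")
        os.makedirs(adir, exist_ok=True)
        for og, seqs in alignments.items():
            write_fasta(seqs, os.path.join(adir, f"{og}.fasta"))
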