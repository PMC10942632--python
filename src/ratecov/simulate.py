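"""Synthetic rate-covariation studies with known correlation structure.

The generator stands in for a large multi-species ortholog dataset: a
Yule master species tree, per-gene trees obtained by scaling the master's
branch lengths by gene- and branch-specific rate factors, and optional
random taxon dropout.  Rate structure follows a latent-factor Gaussian
model on log-rates:

    RER[d, b] = sqrt(rho_mod)  * f[module(d), b]
              + sqrt(rho_phys) * g[pair(d), b]
              + sqrt(1 - rho_mod - rho_phys) * e[d, b]

with all factors i.i.d. standard normal per branch, so every cell has
unit variance and the *population* branch-wise correlation between two
units is exactly rho_mod (same module) plus rho_phys (annotated physical
partners) — the quantity pairwise ERC estimates.  Branch lengths are then
``l[g, b] = m_b * exp(sigma_noise * RER[g, b])``.

Randomness is streamed per unit from a single master seed (SeedSequence
with a per-unit counter), so any one gene's data is reproducible
independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .domains import ComplexDefinition
from .genesets import GeneSet
from .phylo import Phylogeny, TreeSet, prune_to_species, key_to_str, write_newick
from .rer import RERMatrix

__all__ = [
    "ModuleSpec",
    "SimConfig",
    "SyntheticStudy",
    "simulate_master_tree",
    "simulate_rers",
    "emit_gene_trees",
    "simulate_study",
]


@dataclass(frozen=True)
class ModuleSpec:
    """One co-functional gene set to simulate.

    ``rho_mod`` is the shared-module latent correlation among all the
    module's units; for complexes, ``rho_phys`` adds an extra pairwise
    factor to designated physically interacting domain pairs.
    """

    module_id: str
    kind: str = "complex"  # or "pathway"
    n_members: int = 6
    rho_mod: float = 0.3
    rho_phys: float = 0.0

    def __post_init__(self) -> None:
        if not (0 <= self.rho_mod < 1 and 0 <= self.rho_phys < 1):
            raise ValueError("rho values must lie in [0, 1)")
        if self.rho_mod + self.rho_phys >= 1:
            raise ValueError(
                f"{self.module_id}: rho_mod + rho_phys must be < 1 "
                "(unit-variance budget)"
            )


@dataclass
class SimConfig:
    S: int = 40
    n_background_genes: int = 200
    modules: list[ModuleSpec] = field(default_factory=list)
    n_domains_per_protein: tuple[int, int] = (2, 3)
    sigma_noise: float = 0.3
    dropout: float = 0.0
    birth_rate: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 20:
            raise ValueError("S >= 20 required so the shared-species filter "
                             "is exercisable")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must lie in [0, 1)")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be > 0")


@dataclass
class SyntheticStudy:
    """A complete generated study plus its ground truth."""

    config: SimConfig
    master: Phylogeny
    trees: TreeSet
    true_rers: RERMatrix  # latent RERs for every unit (proteins + domains)
    truth: pd.DataFrame  # unit_id, level, module_id, protein_id, rho_mod,
    #                       rho_phys, pair_id
    gene_sets: list[GeneSet]
    complexes: list[ComplexDefinition]


def simulate_master_tree(S: int, birth_rate: float = 1.0,
                         seed: int = 0) -> Phylogeny:
    """Rooted binary Yule (pure-birth) tree with S labeled extant leaves.

    Starting from the root's two lineages, each of the k active lineages
    waits Exp(k * birth_rate) before the next split; a uniformly chosen
    lineage splits, until S lineages exist, which then receive a final
    Exp(S * birth_rate) hold.  Expected total tree length is
    (S - 1)/birth_rate, so the mean branch length is 1/(2*birth_rate).
    """
    if S < 3:
        raise ValueError("need at least 3 species")
    rng = np.random.default_rng(seed)
    parent: dict[int, int] = {}
    length: dict[int, float] = {}
    root = 0
    next_id = 1
    active = []
    for _ in range(2):
        parent[next_id] = root
        length[next_id] = 0.0
        active.append(next_id)
        next_id += 1
    k = 2
    while True:
        hold = rng.exponential(1.0 / (k * birth_rate))
        for node in active:
            length[node] += hold
        if k == S:
            break
        split = active[rng.integers(len(active))]
        active.remove(split)
        for _ in range(2):
            parent[next_id] = split
            length[next_id] = 0.0
            active.append(next_id)
            next_id += 1
        k += 1
    width = len(str(S))
    label = {node: f"s{i + 1:0{width}d}" for i, node in enumerate(sorted(active))}
    tree = Phylogeny(parent=parent, length=length, label=label, root=root)
    tree.validate()
    return tree


# ---------------------------------------------------------------------------
# study layout: units, modules, physical pairs
# ---------------------------------------------------------------------------

def _layout(config: SimConfig) -> tuple[pd.DataFrame, list[ComplexDefinition]]:
    """Deterministic unit table and complex definitions from the config."""
    rng = np.random.default_rng([config.seed, 1])
    rows = []
    for i in range(config.n_background_genes):
        rows.append(
            dict(unit_id=f"bg{i + 1:04d}", level="gene", module_id="",
                 protein_id="", rho_mod=0.0, rho_phys=0.0, pair_id="")
        )
    complexes: list[ComplexDefinition] = []
    lo, hi = config.n_domains_per_protein
    for mod in config.modules:
        proteins = [f"{mod.module_id}_p{j + 1}" for j in range(mod.n_members)]
        for prot in proteins:
            rows.append(
                dict(unit_id=prot, level="protein", module_id=mod.module_id,
                     protein_id=prot, rho_mod=mod.rho_mod, rho_phys=0.0,
                     pair_id="")
            )
        if mod.kind != "complex":
            continue
        domains: dict[str, list[str]] = {}
        for prot in proteins:
            n_dom = int(rng.integers(lo, hi + 1))
            domains[prot] = [f"{prot}_d{d + 1}" for d in range(n_dom)]
        # physical protein pairs: consecutive members (p1-p2, p3-p4, ...);
        # one physical domain pair per protein pair (the first domains)
        phys_prot: set[frozenset] = set()
        phys_dom: set[frozenset] = set()
        pair_of_domain: dict[str, str] = {}
        for j in range(0, mod.n_members - 1, 2):
            pa, pb = proteins[j], proteins[j + 1]
            phys_prot.add(frozenset((pa, pb)))
            da, db = domains[pa][0], domains[pb][0]
            phys_dom.add(frozenset((da, db)))
            pair_id = f"{mod.module_id}_pair{j // 2 + 1}"
            pair_of_domain[da] = pair_id
            pair_of_domain[db] = pair_id
        for prot in proteins:
            for dom in domains[prot]:
                pid = pair_of_domain.get(dom, "")
                rows.append(
                    dict(unit_id=dom, level="domain",
                         module_id=mod.module_id, protein_id=prot,
                         rho_mod=mod.rho_mod,
                         rho_phys=mod.rho_phys if pid else 0.0,
                         pair_id=pid)
                )
        complexes.append(
            ComplexDefinition(
                complex_id=mod.module_id, proteins=proteins, domains=domains,
                physical_protein_pairs=phys_prot,
                physical_domain_pairs=phys_dom,
            )
        )
    truth = pd.DataFrame(rows)
    return truth, complexes


def simulate_rers(master: Phylogeny, config: SimConfig) -> tuple[RERMatrix, pd.DataFrame, list[ComplexDefinition]]:
    """Latent true RERs for every unit of the study.

    Returns the RER matrix (rows = units, columns = master branch keys),
    the per-unit truth table, and the complex definitions.
    """
    truth, complexes = _layout(config)
    desc = master.descendant_leaves()
    cols = [key_to_str(frozenset(desc[n])) for n in sorted(master.parent)]
    n_branches = len(cols)

    factor_ids = sorted(set(truth.module_id) - {""}) + sorted(
        set(truth.pair_id) - {""}
    )
    factors = {
        fid: np.random.default_rng([config.seed, 2, i]).standard_normal(n_branches)
        for i, fid in enumerate(factor_ids)
    }

    mat = np.empty((len(truth), n_branches))
    for i, row in enumerate(truth.itertuples(index=False)):
        rng = np.random.default_rng([config.seed, 3, i])
        e = rng.standard_normal(n_branches)
        rer = np.sqrt(1 - row.rho_mod - row.rho_phys) * e
        if row.module_id:
            rer = rer + np.sqrt(row.rho_mod) * factors[row.module_id]
        if row.pair_id:
            rer = rer + np.sqrt(row.rho_phys) * factors[row.pair_id]
        mat[i] = rer

    values = pd.DataFrame(mat, index=list(truth.unit_id), columns=cols)
    species = {u: master.leaves for u in truth.unit_id}
    return RERMatrix(values=values, method="true", species=species), truth, complexes


def emit_gene_trees(
    master: Phylogeny,
    true_rers: RERMatrix,
    sigma_noise: float,
    dropout: float = 0.0,
    seed: int = 0,
) -> TreeSet:
    """Realize per-unit trees: l[g, b] = m_b * exp(sigma_noise * RER[g, b]).

    Each species is then dropped independently with probability
    ``dropout`` and the tree pruned with path lengths summed; a draw
    leaving fewer than 2 species is redrawn.
    """
    desc = master.descendant_leaves()
    key_of_node = {n: key_to_str(frozenset(desc[n])) for n in master.parent}
    leaves = sorted(master.leaves)
    gene_trees: dict[str, Phylogeny] = {}
    for i, unit in enumerate(true_rers.values.index):
        rng = np.random.default_rng([seed, 4, i])
        row = true_rers.values.loc[unit]
        length = {
            n: master.length[n] * float(np.exp(sigma_noise * row[key_of_node[n]]))
            for n in master.parent
        }
        tree = Phylogeny(
            parent=dict(master.parent), length=length,
            label=dict(master.label), root=master.root,
        )
        if dropout > 0:
            while True:
                keep = [sp for sp in leaves if rng.random() >= dropout]
                if len(keep) >= 2:
                    break
            if len(keep) < len(leaves):
                tree = prune_to_species(tree, keep)
        gene_trees[unit] = tree
    return TreeSet(master=master, gene_trees=gene_trees)


def simulate_study(config: SimConfig, out_dir=None) -> SyntheticStudy:
    """Generate a full study; optionally write it as a plain-text directory.

    The directory layout is ``master.nwk``, ``trees/<unit>.nwk``,
    ``sets.tsv``, ``complexes.tsv``, ``interpro.tsv``,
    ``physical_protein_pairs.tsv``, ``physical_domain_pairs.tsv`` and
    ``truth/units.tsv``.
    """
    master = simulate_master_tree(config.S, config.birth_rate, config.seed)
    true_rers, truth, complexes = simulate_rers(master, config)
    trees = emit_gene_trees(
        master, true_rers, config.sigma_noise, config.dropout, config.seed
    )
    gene_sets = [
        GeneSet(
            mod.module_id, mod.kind,
            tuple(f"{mod.module_id}_p{j + 1}" for j in range(mod.n_members)),
        )
        for mod in config.modules
    ]
    study = SyntheticStudy(
        config=config, master=master, trees=trees, true_rers=true_rers,
        truth=truth, gene_sets=gene_sets, complexes=complexes,
    )
    if out_dir is not None:
        _write_study(study, out_dir)
    return study


def _write_study(study: SyntheticStudy, out_dir) -> None:
    import pathlib

    p = pathlib.Path(out_dir)
    (p / "trees").mkdir(parents=True, exist_ok=True)
    (p / "truth").mkdir(exist_ok=True)
    (p / "master.nwk").write_text(write_newick(study.master) + "\n")
    for unit, tree in study.trees.gene_trees.items():
        (p / "trees" / f"{unit}.nwk").write_text(write_newick(tree) + "\n")
    pd.DataFrame(
        [
            {"set_id": s.set_id, "kind": s.kind, "member": m}
            for s in study.gene_sets
            for m in s.members
        ]
    ).to_csv(p / "sets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"complex_id": cx.complex_id, "protein": prot}
            for cx in study.complexes
            for prot in cx.proteins
        ]
    ).to_csv(p / "complexes.tsv", sep="\t", index=False)
    with open(p / "interpro.tsv", "w") as fh:
        for cx in study.complexes:
            for prot in cx.proteins:
                for d_i, dom in enumerate(cx.domains[prot]):
                    start, stop = 100 * d_i + 1, 100 * d_i + 80
                    fh.write(
                        "\t".join(
                            [prot, "-", str(100 * len(cx.domains[prot])),
                             "synthetic", dom, "synthetic domain",
                             str(start), str(stop), "0.0", "T", "-"]
                        ) + "\n"
                    )
    pd.DataFrame(
        [
            {"complex_id": cx.complex_id, "protein_a": a, "protein_b": b}
            for cx in study.complexes
            for a, b in (sorted(pair) for pair in sorted(
                cx.physical_protein_pairs, key=sorted))
        ]
    ).to_csv(p / "physical_protein_pairs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"complex_id": cx.complex_id, "domain_a": a, "domain_b": b}
            for cx in study.complexes
            for a, b in (sorted(pair) for pair in sorted(
                cx.physical_domain_pairs, key=sorted))
        ]
    ).to_csv(p / "physical_domain_pairs.tsv", sep="\t", index=False)
    study.truth.to_csv(p / "truth" / "units.tsv", sep="\t", index=False)
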