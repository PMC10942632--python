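"""Calibration and recovery experiments on synthetic studies.

Each function generates a synthetic study end-to-end — master tree,
per-unit trees, pipeline RERs, pairwise ERC — and measures one property
of the downstream statistics: type-I calibration of the gene-set
permutation test, uniformity of the per-complex AUC permutation p-value
under a label-exchangeable null, monotone response of within-module
ftERC to the latent module correlation, monotone response of ROC-AUC to
the latent physical-pair correlation, and RER round-trip recovery.

These are the package's own quality-control experiments; problem sizes
default to what one CPU handles comfortably while keeping the Monte-Carlo
error well below the effect sizes being checked.
"""

from __future__ import annotations

import numpy as np

from .domains import DegenerateComplexError, build_domain_edge_list
from .erc import all_pairs_erc
from .genesets import GeneSet, size_matched_permutation_test
from .rank_stats import permute_complex_auc, roc_auc
from .rer import rer_from_trees
from .simulate import ModuleSpec, SimConfig, simulate_study

__all__ = [
    "null_set_calibration",
    "null_auc_calibration",
    "module_erc_sweep",
    "physical_auc_sweep",
    "rer_recovery",
]


def _pipeline_erc(config: SimConfig, genes=None):
    """Simulate a study and push it through trees -> RER -> ERC."""
    study = simulate_study(config)
    rers = rer_from_trees(study.trees)
    erc = all_pairs_erc(rers, genes=genes) if genes is not None else None
    return study, rers, erc


def null_set_calibration(
    n_sets: int = 500,
    universe_size: int = 300,
    set_size: int = 8,
    B: int = 1000,
    S: int = 36,
    seed: int = 0,
) -> np.ndarray:
    """Permutation p-values for random gene sets with no modular signal.

    The universe is ``universe_size`` independent background genes
    (``rho_mod = 0`` everywhere); each of the ``n_sets`` tested sets is a
    uniform draw of ``set_size`` genes, so its p-value should be uniform
    on (0, 1] and the fraction with p <= alpha should track alpha.
    """
    cfg = SimConfig(S=S, n_background_genes=universe_size, sigma_noise=0.3,
                    dropout=0.0, seed=seed)
    study, rers, erc = _pipeline_erc(cfg, genes=None)
    universe = list(rers.values.index)
    erc = all_pairs_erc(rers, genes=universe)
    square = erc.fterc_square().reindex(index=universe, columns=universe)
    ft = square.to_numpy()

    rng = np.random.default_rng([seed, 100])
    pvals = np.empty(n_sets)
    for i in range(n_sets):
        members = tuple(
            universe[j] for j in rng.choice(len(universe), set_size, replace=False)
        )
        res = size_matched_permutation_test(
            erc, GeneSet(f"rand{i}", "complex", members), universe,
            B=B, seed=int(rng.integers(0, 2**31 - 1)), _ft_square=ft,
        )
        pvals[i] = res.p
    return pvals


def _complex_study(n_complexes, rho_mod, rho_phys, S, seed,
                   n_members=4, n_background=100):
    mods = [
        ModuleSpec(f"cx{i:03d}", "complex", n_members, rho_mod, rho_phys)
        for i in range(n_complexes)
    ]
    cfg = SimConfig(S=S, n_background_genes=n_background, sigma_noise=0.3,
                    dropout=0.0, seed=seed, modules=mods)
    study = simulate_study(cfg)
    rers = rer_from_trees(study.trees)
    return study, rers


def null_auc_calibration(
    n_complexes: int = 200,
    B: int = 1000,
    S: int = 30,
    rho_mod: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """AUC permutation p-values for complexes with no physical boost.

    Under the fully null model (``rho_mod = rho_phys = 0``) all domains
    are independent, the positive labels carry no information, and the
    permutation p-value is uniform on (0, 1].  With ``rho_mod > 0`` the
    shared module factor induces dependence among edge-list entries that
    the label permutation does not model; the p-values then become
    mildly conservative (shifted toward 1), never anticonservative.
    """
    study, rers = _complex_study(n_complexes, rho_mod=rho_mod, rho_phys=0.0,
                                 S=S, seed=seed)
    rng = np.random.default_rng([seed, 101])
    pvals = []
    for cx in study.complexes:
        erc = all_pairs_erc(rers, genes=cx.all_domains())
        try:
            edges, _ = build_domain_edge_list(erc, cx)
        except DegenerateComplexError:
            continue
        res = permute_complex_auc(edges, B=B,
                                  seed=int(rng.integers(0, 2**31 - 1)))
        pvals.append(res.p)
    return np.asarray(pvals)


def module_erc_sweep(
    rhos=(0.0, 0.3, 0.6, 0.9),
    n_modules: int = 20,
    n_members: int = 6,
    S: int = 30,
    seed: int = 0,
) -> dict[float, float]:
    """Mean within-module ftERC as a function of the module correlation.

    For each ``rho_mod`` a fresh study with ``n_modules`` replicate
    modules is generated; the returned value is the average over modules
    of the mean ftERC over in-module gene pairs.  ftERC is monotone in the
    latent correlation, so the sweep should be strictly increasing.
    """
    out: dict[float, float] = {}
    for k, rho in enumerate(rhos):
        mods = [
            ModuleSpec(f"m{i:02d}", "pathway", n_members, rho_mod=rho)
            for i in range(n_modules)
        ]
        cfg = SimConfig(S=S, n_background_genes=100, sigma_noise=0.3,
                        dropout=0.0, seed=seed * 1000 + k, modules=mods)
        study = simulate_study(cfg)
        rers = rer_from_trees(study.trees)
        means = []
        for s in study.gene_sets:
            erc = all_pairs_erc(rers, genes=list(s.members))
            fts = erc.edges["fterc"].dropna()
            means.append(float(fts.mean()))
        out[rho] = float(np.mean(means))
    return out


def physical_auc_sweep(
    rhos=(0.0, 0.2, 0.4, 0.6),
    n_complexes: int = 20,
    rho_mod: float = 0.3,
    S: int = 30,
    seed: int = 0,
) -> dict[float, np.ndarray]:
    """Per-complex ROC-AUC as a function of the physical-pair correlation.

    Domains annotated as physical partners receive an extra latent factor
    of weight ``rho_phys`` on top of the shared module factor, so their
    ERC — and hence the AUC of the physical class in the ranked edge
    list — should increase with ``rho_phys``.
    """
    out: dict[float, np.ndarray] = {}
    for k, rho in enumerate(rhos):
        study, rers = _complex_study(n_complexes, rho_mod=rho_mod,
                                     rho_phys=rho, S=S,
                                     seed=seed * 1000 + 500 + k)
        aucs = []
        for cx in study.complexes:
            erc = all_pairs_erc(rers, genes=cx.all_domains())
            try:
                edges, _ = build_domain_edge_list(erc, cx)
            except DegenerateComplexError:
                continue
            aucs.append(roc_auc(edges).auc)
        out[rho] = np.asarray(aucs)
    return out


def rer_recovery(
    S: int = 30,
    n_genes: int = 80,
    sigma_noise: float = 0.3,
    dropout: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Per-gene correlation between pipeline RERs and the latent RERs."""
    cfg = SimConfig(S=S, n_background_genes=n_genes, sigma_noise=sigma_noise,
                    dropout=dropout, seed=seed)
    study = simulate_study(cfg)
    rers = rer_from_trees(study.trees)
    cors = []
    for gene in rers.values.index:
        got = rers.values.loc[gene].dropna()
        want = study.true_rers.values.loc[gene][got.index]
        cors.append(float(np.corrcoef(got, want)[0, 1]))
    return np.asarray(cors)
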