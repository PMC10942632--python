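# ratecov

Evolutionary rate covariation (ERC) analysis for phylogenomics.

Proteins that work together tend to experience correlated shifts in their
rates of molecular evolution: when a lineage relaxes or intensifies
selection on a pathway, all of its members speed up or slow down together.
`ratecov` implements the full ERC analysis stack used to ask whether that
covariation is driven by co-functionality alone or additionally by direct
physical contact between protein domains:

1. **Relative evolutionary rates (RERs).** Every gene tree must match a
   master species topology pruned to the gene's taxa. Branches are matched
   across genes by their descendant-species sets, and each branch length is
   expressed relative to the genome-wide average for that branch, after
   removing the gene's overall rate. A gene evolving at a constant multiple
   of the genome-wide tree has RER ≡ 0.
2. **Pairwise ERC.** For two genes, the Pearson correlation *r* of their
   RERs over shared branches (each vector Winsorized, 3 extremes per tail
   condensed to the 4th), Fisher transformed:

   ftERC = arctanh(*r*) · √(*n* − 3)

   with *n* the shared-branch count, so pairs with different branch counts
   are directly comparable (null mean 0, variance ≈ 1). Pairs sharing
   fewer than 15 species are filtered.
3. **Gene-set tests.** The mean ftERC of a complex or pathway is compared
   against 1000 size-matched random gene sets drawn from the whole dataset
   (add-one permutation p-values, so the smallest reportable value is
   1/1001).
4. **Domain-level ranking.** Each complex member is split into domains;
   all inter-protein domain pairs are ranked by ftERC and labeled by
   whether they physically contact in the complex's structure. The
   ranking is scored by ROC-AUC (= U/(n₀·n₁), one-tailed Mann–Whitney),
   by label-permutation nulls per complex and study-wide, and by the
   proportional rank (T − rank)/(T − 1) of the physical pair within each
   protein pair, with a two-level permutation null.
5. **Synthetic studies.** A generator produces complete studies — Yule
   master tree, per-gene trees with taxon dropout, latent-factor Gaussian
   rate structure with tunable module (`rho_mod`) and physical-pair
   (`rho_phys`) correlations — with ground truth, so every stage is
   testable without external data.

## Worked example

Simulate a study with one six-protein complex whose designated physical
domain pairs get an extra latent correlation (`rho_mod = 0.4`,
`rho_phys = 0.4`), then run the three analyses:

```python
from ratecov import (SimConfig, ModuleSpec, simulate_study,
                     rer_from_trees, all_pairs_erc)
from ratecov.genesets import size_matched_permutation_test
from ratecov.domains import build_domain_edge_list
from ratecov.rank_stats import roc_auc, permute_complex_auc

cfg = SimConfig(
    S=30, n_background_genes=120, sigma_noise=0.3, dropout=0.1, seed=11,
    modules=[ModuleSpec("sm5", "complex", 6, rho_mod=0.4, rho_phys=0.4)],
)
study = simulate_study(cfg)
rers = rer_from_trees(study.trees)

members = list(study.gene_sets[0].members)
genes = [u for u in rers.values.index if u.startswith("bg")] + members
erc = all_pairs_erc(rers, genes=genes)
res = size_matched_permutation_test(erc, study.gene_sets[0], genes,
                                    B=1000, seed=1)
print(f"complex mean ftERC = {res.mean_erc:.3f} over {res.n_pairs_used} "
      f"pairs, permutation p = {res.p:.4f}")

cx = study.complexes[0]
dom_erc = all_pairs_erc(rers, genes=cx.all_domains())
edges, dropped = build_domain_edge_list(dom_erc, cx)
roc = roc_auc(edges, complex_id=cx.complex_id)
perm = permute_complex_auc(edges, B=1000, seed=2)
print(f"domain ROC-AUC = {roc.auc:.3f} ({roc.n_pos} physical vs "
      f"{roc.n_neg} other pairs), Mann-Whitney p = {roc.p_mw:.4f}, "
      f"permutation p = {perm.p:.4f}")
```

Output:

```
complex mean ftERC = 3.435 over 15 pairs, permutation p = 0.0390
domain ROC-AUC = 0.933 (3 physical vs 90 other pairs), Mann-Whitney p = 0.0057, permutation p = 0.0010
```

The complex's members covary well above size-matched random sets
(mean ftERC 3.4 where random sets center on 0), and the physically
interacting domain pairs rank near the top of the domain edge list
(AUC 0.93 against a null of 0.5).

The same pipeline runs from the shell:

```bash
ratecov simulate --config sim.yaml --seed 11 --out study/
ratecov run-all --study study/ --B 1000 --seed 11 --out results/
```

which writes `rer.tsv`, `erc_genes.tsv`, `set_tests.tsv`,
`domain_edges.tsv`, `roc.tsv`, `proprank.tsv`, a per-complex
`summary.tsv`, and a reproducibility manifest.

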