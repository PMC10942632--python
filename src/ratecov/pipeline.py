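"""End-to-end study orchestration.

``run_full_study`` chains the stages — trees -> RERs -> pairwise ERC ->
gene-set permutation tests -> per-complex domain edge lists -> ROC-AUC
(per complex and study-wide) -> proportional rank — on a study directory
(as written by :func:`ratecov.simulate.simulate_study` or assembled from
real data in the same layout), writes every intermediate as TSV, and
records a run manifest with the config hash, seeds and per-stage record
and filter tallies so a rerun is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import erc as erc_mod
from . import genesets as gs_mod
from . import rank_stats as rs
from .domains import (
    ComplexDefinition,
    DegenerateComplexError,
    build_domain_edge_list,
    edge_list_to_frame,
    parse_interpro_tsv,
)
from .phylo import TreeSet, read_tree_file
from .rer import rer_from_trees

__all__ = ["PipelineConfig", "RunManifest", "run_full_study", "load_study_inputs"]


@dataclass
class PipelineConfig:
    min_shared_species: int = 15
    winsor_k: int = 3
    B: int = 1000
    member_min: int = 5
    rer_method: str = "log-ratio"
    mask_physical: bool = False  # drop physical pairs from set means
    seed: int = 0

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    counts: dict = field(default_factory=dict)
    filters: dict = field(default_factory=dict)
    skipped_complexes: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=True)


def load_study_inputs(study_dir):
    """Read a study directory into trees, gene sets, and complexes."""
    p = pathlib.Path(study_dir)
    master = read_tree_file(p / "master.nwk")
    gene_trees = {
        f.stem: read_tree_file(f) for f in sorted((p / "trees").glob("*.nwk"))
    }
    trees = TreeSet(master=master, gene_trees=gene_trees)

    sets_df = pd.read_csv(p / "sets.tsv", sep="\t")
    annots = parse_interpro_tsv(p / "interpro.tsv")
    domains: dict[str, list[str]] = {}
    for a in annots:
        domains.setdefault(a.protein_id, []).append(a.domain_id)
    cx_df = pd.read_csv(p / "complexes.tsv", sep="\t")
    ppp = pd.read_csv(p / "physical_protein_pairs.tsv", sep="\t")
    pdp = pd.read_csv(p / "physical_domain_pairs.tsv", sep="\t")
    complexes = []
    for cx_id, grp in cx_df.groupby("complex_id", sort=True):
        prots = list(grp["protein"])
        complexes.append(
            ComplexDefinition(
                complex_id=str(cx_id),
                proteins=prots,
                domains={pr: domains.get(pr, []) for pr in prots},
                physical_protein_pairs={
                    frozenset((r.protein_a, r.protein_b))
                    for r in ppp.itertuples()
                    if r.complex_id == cx_id
                },
                physical_domain_pairs={
                    frozenset((r.domain_a, r.domain_b))
                    for r in pdp.itertuples()
                    if r.complex_id == cx_id
                },
            )
        )
    return trees, sets_df, complexes


def run_full_study(study_dir, out_dir, config: PipelineConfig | None = None) -> RunManifest:
    """Run every analysis stage on a study directory; see module docstring."""
    config = config or PipelineConfig()
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.hash(), seed=config.seed)

    trees, sets_df, complexes = load_study_inputs(study_dir)
    domain_units = {d for cx in complexes for d in cx.all_domains()}
    gene_units = [u for u in trees.gene_trees if u not in domain_units]
    manifest.counts["units"] = len(trees.gene_trees)
    manifest.counts["gene_units"] = len(gene_units)
    manifest.counts["domain_units"] = len(domain_units)

    # --- stage: RER ------------------------------------------------------
    rers = rer_from_trees(trees, method=config.rer_method)
    rers.to_tsv(out / "rer.tsv")
    manifest.outputs["rer"] = "rer.tsv"

    # --- stage: gene-level ERC + set tests -------------------------------
    erc_genes = erc_mod.all_pairs_erc(
        rers, genes=gene_units,
        min_shared_species=config.min_shared_species,
        winsor_k=config.winsor_k,
    )
    erc_genes.to_tsv(out / "erc_genes.tsv")
    tally = erc_genes.edges["filter_reason"].value_counts().to_dict()
    manifest.filters["gene_pairs"] = {str(k): int(v) for k, v in tally.items()}
    manifest.counts["gene_pairs_scored"] = int(
        erc_genes.edges["filter_reason"].isna().sum()
    )

    mask = None
    if config.mask_physical:
        mask = {pair for cx in complexes for pair in cx.physical_protein_pairs}
    gene_sets = []
    dataset = set(gene_units)
    for (set_id, kind), grp in sets_df.groupby(["set_id", "kind"], sort=True):
        members = [m for m in dict.fromkeys(grp["member"]) if m in dataset]
        if len(members) >= config.member_min:
            gene_sets.append(gs_mod.GeneSet(str(set_id), str(kind), tuple(members)))
    set_rng = np.random.default_rng([config.seed, 10])
    set_results = []
    for s in gene_sets:
        set_results.append(
            gs_mod.size_matched_permutation_test(
                erc_genes, s, universe=gene_units, B=config.B,
                seed=int(set_rng.integers(0, 2**31 - 1)), mask=mask,
            )
        )
    gs_mod.write_set_results(set_results, out / "set_tests.tsv")
    manifest.counts["gene_sets_tested"] = len(set_results)

    # --- stage: domain ERC, ROC, proportional rank -----------------------
    roc_rows, prop_rows, edge_frames = [], [], []
    kept_edges = []
    rng = np.random.default_rng([config.seed, 11])
    for cx in sorted(complexes, key=lambda c: c.complex_id):
        erc_dom = erc_mod.all_pairs_erc(
            rers, genes=cx.all_domains(),
            min_shared_species=config.min_shared_species,
            winsor_k=config.winsor_k,
        )
        try:
            edges, dropped = build_domain_edge_list(erc_dom, cx)
        except DegenerateComplexError as exc:
            manifest.skipped_complexes.append(str(exc))
            continue
        frame = edge_list_to_frame(edges)
        frame.insert(0, "complex_id", cx.complex_id)
        edge_frames.append(frame)
        kept_edges.append(edges)

        roc = rs.roc_auc(edges, complex_id=cx.complex_id)
        perm = rs.permute_complex_auc(
            edges, B=config.B, seed=int(rng.integers(0, 2**31 - 1))
        )
        roc_rows.append(
            dict(complex_id=cx.complex_id, auc=roc.auc, n_pos=roc.n_pos,
                 n_neg=roc.n_neg, p_mw=roc.p_mw, p_perm=perm.p,
                 n_dropped_pairs=dropped)
        )

        pair_results = []
        for ppair in sorted(cx.physical_protein_pairs, key=sorted):
            pa, pb = sorted(ppair)
            pair_edges = [
                e for e in edges
                if {e.protein_a, e.protein_b} == {pa, pb}
            ]
            res = rs.protein_pair_prop_rank(pair_edges, cx.physical_domain_pairs)
            if res is not None:
                pair_results.append(res)
        if pair_results:
            ptest = rs.complex_prop_rank_test(
                pair_results, B=config.B,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for res in pair_results:
                prop_rows.append(
                    dict(complex_id=cx.complex_id, protein_a=res.protein_a,
                         protein_b=res.protein_b, T=res.total_pairs,
                         score=res.score, complex_score=ptest.observed,
                         p_complex=ptest.p)
                )

    if edge_frames:
        pd.concat(edge_frames, ignore_index=True).to_csv(
            out / "domain_edges.tsv", sep="\t", index=False
        )
    roc_df = pd.DataFrame(roc_rows)
    roc_df.to_csv(out / "roc.tsv", sep="\t", index=False)
    pd.DataFrame(prop_rows).to_csv(out / "proprank.tsv", sep="\t", index=False)

    if len(kept_edges) >= 2:
        gtest = rs.global_average_auc_test(
            kept_edges, B=config.B, seed=int(rng.integers(0, 2**31 - 1))
        )
        manifest.counts["global_mean_auc"] = float(gtest.observed)
        manifest.counts["global_auc_p"] = float(gtest.p)

    # --- summary table ----------------------------------------------------
    summary_rows = []
    set_by_id = {r.set_id: r for r in set_results}
    roc_by_id = {r["complex_id"]: r for r in roc_rows}
    for cx in sorted(complexes, key=lambda c: c.complex_id):
        if cx.complex_id not in roc_by_id:
            continue
        frame = next(
            f for f in edge_frames if f["complex_id"].iloc[0] == cx.complex_id
        )
        phys = frame[frame.label == 1]["fterc"]
        nonphys = frame[frame.label == 0]["fterc"]
        sr = set_by_id.get(cx.complex_id)
        summary_rows.append(
            dict(
                complex_id=cx.complex_id,
                n_proteins=len(cx.proteins),
                n_domains=len(cx.all_domains()),
                set_mean_erc=(sr.mean_erc if sr else np.nan),
                set_p=(sr.p if sr else np.nan),
                mean_physical_erc=float(phys.mean()),
                mean_nonphysical_erc=float(nonphys.mean()),
                n_physical=int(len(phys)),
                n_nonphysical=int(len(nonphys)),
                auc=roc_by_id[cx.complex_id]["auc"],
                auc_p_perm=roc_by_id[cx.complex_id]["p_perm"],
            )
        )
    pd.DataFrame(summary_rows).to_csv(out / "summary.tsv", sep="\t", index=False)
    manifest.counts["complexes_analyzed"] = len(summary_rows)
    manifest.outputs.update(
        {
            "erc_genes": "erc_genes.tsv",
            "set_tests": "set_tests.tsv",
            "domain_edges": "domain_edges.tsv",
            "roc": "roc.tsv",
            "proprank": "proprank.tsv",
            "summary": "summary.tsv",
        }
    )
    manifest.write(out / "manifest.yaml")
    return manifest
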