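"""Gene-set (complex / pathway) mean ERC and size-matched permutation test.

The observed statistic is the arithmetic mean ftERC over a set's in-set
gene pairs (filtered pairs excluded; optionally masking pairs known to
physically interact, so the test measures co-functional signal net of
physical contact).  Significance comes from comparing against B random
gene sets of the same size drawn from the whole analysis universe — the
analogue of sampling from all genes with computed rates.

p-values use the add-one permutation convention,
p = (1 + #{null >= observed}) / (1 + B), so the smallest reportable value
at B = 1000 is 1/1001 (< 0.001), never zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .erc import ERCMatrix

__all__ = [
    "GeneSet",
    "SetTestResult",
    "set_mean_erc",
    "size_matched_permutation_test",
    "read_gene_sets",
    "perm_pvalue",
]

MEMBER_MIN = 5  # sets must have > 4 members present in the dataset


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    kind: str  # "complex" | "pathway"
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"set {self.set_id}: duplicate members")


@dataclass
class SetTestResult:
    set_id: str
    mean_erc: float
    n_pairs_used: int
    B: int
    null_means: np.ndarray
    p: float
    seed: int
    n_resampled: int = 0


def perm_pvalue(observed: float, null: np.ndarray) -> float:
    """Add-one permutation p-value, one-sided (null >= observed)."""
    return (1 + int(np.sum(null >= observed))) / (1 + len(null))


def _pair_mean(
    ft: np.ndarray, idx: np.ndarray
) -> tuple[float, int]:
    """Mean of the upper-triangle ftERC entries among the given gene indices."""
    sub = ft[np.ix_(idx, idx)]
    iu = np.triu_indices(len(idx), k=1)
    vals = sub[iu]
    vals = vals[~np.isnan(vals)]
    return (float(vals.mean()) if len(vals) else float("nan"), len(vals))


def set_mean_erc(
    erc: ERCMatrix,
    gene_set: GeneSet,
    mask: set[frozenset] | None = None,
) -> tuple[float, int]:
    """Mean ftERC over unordered in-set pairs.

    Filtered pairs and masked pairs (e.g. annotated physical interactions)
    are excluded from both the mean and the pair count.
    """
    total = 0.0
    used = 0
    for a, b in combinations(sorted(gene_set.members), 2):
        if mask and frozenset((a, b)) in mask:
            continue
        ft = erc.fterc_of(a, b)
        if np.isnan(ft):
            continue
        total += ft
        used += 1
    if used == 0:
        raise ValueError(f"set {gene_set.set_id}: no usable gene pairs")
    return total / used, used


def size_matched_permutation_test(
    erc: ERCMatrix,
    gene_set: GeneSet,
    universe: list[str],
    B: int = 1000,
    seed: int = 0,
    mask: set[frozenset] | None = None,
    _ft_square: np.ndarray | None = None,
) -> SetTestResult:
    """Permutation test of a set's mean ERC against size-matched random sets.

    Each replicate draws ``len(members)`` genes uniformly without
    replacement from ``universe`` and computes the mean ftERC under the
    same filtering rules.  Replicates with zero usable pairs are resampled
    (and counted in ``n_resampled``).  Masking applies to the observed set
    only; random sets have no physical-interaction annotation.
    """
    if B < 1:
        raise ValueError("permutation count B must be >= 1")
    members = [g for g in gene_set.members if g in set(universe)]
    if len(universe) <= len(members):
        raise ValueError(
            f"universe ({len(universe)}) must exceed set size ({len(members)})"
        )
    observed, n_used = set_mean_erc(erc, GeneSet(
        gene_set.set_id, gene_set.kind, tuple(members)), mask)

    rng = np.random.default_rng(seed)
    if _ft_square is None:
        order = list(universe)
        square = erc.fterc_square()
        ft = square.reindex(index=order, columns=order).to_numpy()
    else:
        ft = _ft_square
    m = len(members)
    null = np.empty(B)
    n_resampled = 0
    for b in range(B):
        while True:
            idx = rng.choice(len(universe), size=m, replace=False)
            mean, used = _pair_mean(ft, idx)
            if used > 0:
                break
            n_resampled += 1
        null[b] = mean
    p = perm_pvalue(observed, null)
    return SetTestResult(
        set_id=gene_set.set_id,
        mean_erc=observed,
        n_pairs_used=n_used,
        B=B,
        null_means=null,
        p=p,
        seed=seed,
        n_resampled=n_resampled,
    )


def read_gene_sets(path, dataset_genes: set[str] | None = None,
                   member_min: int = MEMBER_MIN) -> list[GeneSet]:
    """Read a set manifest TSV (set_id, kind, member).

    When ``dataset_genes`` is given, members are intersected with it and
    sets with fewer than ``member_min`` surviving members are dropped —
    the "greater than four members" rule.
    """
    df = pd.read_csv(path, sep="\t")
    out: list[GeneSet] = []
    for (set_id, kind), grp in df.groupby(["set_id", "kind"], sort=True):
        members = list(dict.fromkeys(grp["member"]))
        if dataset_genes is not None:
            members = [m for m in members if m in dataset_genes]
        if len(members) >= member_min:
            out.append(GeneSet(str(set_id), str(kind), tuple(members)))
    return out


def write_set_results(results: list[SetTestResult], path) -> None:
    df = pd.DataFrame(
        [
            {
                "set_id": r.set_id,
                "mean_erc": r.mean_erc,
                "n_pairs_used": r.n_pairs_used,
                "B": r.B,
                "p": r.p,
                "seed": r.seed,
                "n_resampled": r.n_resampled,
            }
            for r in results
        ]
    )
    df.to_csv(path, sep="\t", index=False)
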