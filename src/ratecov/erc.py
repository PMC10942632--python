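"""Pairwise evolutionary rate covariation (ERC).

For a pair of genes, ERC is the Pearson correlation of their RERs over the
branches both trees possess, computed after Winsorizing each restricted
vector (the three most extreme values in each tail condensed to the
fourth), and then Fisher transformed:

    ftERC = arctanh(r) * sqrt(n - 3)

where ``n`` is the number of shared branches.  The sqrt(n - 3) factor is
the inverse standard deviation of arctanh(r) under the null, so ftERC has
null mean 0 and variance ~1 regardless of how many branches a pair
shares — pairs with different branch counts are directly comparable.

Pairs whose trees share fewer than ``min_shared_species`` species (15 by
default) are filtered rather than scored, as are pairs left with a
constant vector (zero variance) after restriction and Winsorization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .rer import RERMatrix

__all__ = [
    "ERCValue",
    "ERCMatrix",
    "winsorize",
    "fisher_transform",
    "pairwise_erc",
    "all_pairs_erc",
]

R_CLAMP = 1 - 1e-12  # keeps arctanh finite at |r| = 1
MIN_SHARED_SPECIES = 15
WINSOR_K = 3


@dataclass(frozen=True)
class ERCValue:
    gene_a: str
    gene_b: str
    r: float
    n_branches: int
    n_shared_species: int
    fterc: float
    filter_reason: str | None = None

    @property
    def filtered(self) -> bool:
        return self.filter_reason is not None


@dataclass
class ERCMatrix:
    """Symmetric gene-pair ERC store (edge list + fast lookup)."""

    edges: pd.DataFrame  # gene_a, gene_b, r, n_branches, n_shared_species,
    #                       fterc, filter_reason
    genes: list[str]
    _lookup: dict[frozenset, ERCValue] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._lookup:
            for row in self.edges.itertuples(index=False):
                val = ERCValue(
                    gene_a=row.gene_a,
                    gene_b=row.gene_b,
                    r=row.r,
                    n_branches=int(row.n_branches),
                    n_shared_species=int(row.n_shared_species),
                    fterc=row.fterc,
                    filter_reason=(
                        None if pd.isna(row.filter_reason) else row.filter_reason
                    ),
                )
                self._lookup[frozenset((row.gene_a, row.gene_b))] = val

    def get(self, a: str, b: str) -> ERCValue | None:
        return self._lookup.get(frozenset((a, b)))

    def fterc_of(self, a: str, b: str) -> float:
        """ftERC for an unfiltered pair, NaN otherwise."""
        val = self.get(a, b)
        if val is None or val.filtered:
            return float("nan")
        return val.fterc

    def fterc_square(self) -> pd.DataFrame:
        """Dense symmetric ftERC matrix (NaN diagonal and filtered pairs)."""
        idx = {g: i for i, g in enumerate(self.genes)}
        arr = np.full((len(idx), len(idx)), np.nan)
        for pair, val in self._lookup.items():
            if val.filtered:
                continue
            a, b = tuple(pair)
            arr[idx[a], idx[b]] = arr[idx[b], idx[a]] = val.fterc
        return pd.DataFrame(arr, index=self.genes, columns=self.genes)

    def to_tsv(self, path) -> None:
        self.edges.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "ERCMatrix":
        df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=True)
        genes = sorted(set(df.gene_a) | set(df.gene_b))
        return cls(edges=df, genes=genes)


def winsorize(v: np.ndarray, k: int = WINSOR_K) -> np.ndarray:
    """Condense the k most extreme values per tail to the (k+1)-th.

    Order of elements is preserved; ties at the boundary are resolved by
    value, so every element beyond the (k+1)-th order statistic is capped
    at it.  ``k = 0`` is a no-op.
    """
    v = np.asarray(v, dtype=float)
    if k == 0:
        return v.copy()
    if len(v) <= 2 * k:
        raise ValueError(f"vector of length {len(v)} too short for k={k}")
    srt = np.sort(v)
    lo, hi = srt[k], srt[-(k + 1)]
    return np.clip(v, lo, hi)


def fisher_transform(r: float, n: int) -> float:
    """Fisher z statistic arctanh(r) * sqrt(n - 3); requires n >= 4."""
    if n < 4:
        raise ValueError(f"Fisher transform undefined for n={n} < 4 branches")
    if abs(r) > 1 + 1e-12:
        raise ValueError(f"correlation {r} outside [-1, 1]")
    r = float(np.clip(r, -R_CLAMP, R_CLAMP))
    return float(np.arctanh(r) * np.sqrt(n - 3))


def _score_pair(
    a: str,
    b: str,
    va: np.ndarray,
    vb: np.ndarray,
    n_sp: int,
    min_shared_species: int,
    winsor_k: int,
) -> ERCValue:
    def filtered(reason: str, r=np.nan, n=0, ft=np.nan) -> ERCValue:
        return ERCValue(a, b, r, n, n_sp, ft, filter_reason=reason)

    if n_sp < min_shared_species:
        return filtered("too few shared species")
    ok = ~np.isnan(va) & ~np.isnan(vb)
    xa, xb = va[ok], vb[ok]
    n = len(xa)
    if n <= 2 * winsor_k or n < 4:
        return filtered("too few shared branches", n=n)
    xa = winsorize(xa, winsor_k)
    xb = winsorize(xb, winsor_k)
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return filtered("zero variance", n=n)
    r = float(np.corrcoef(xa, xb)[0, 1])
    return ERCValue(a, b, r, n, n_sp, fisher_transform(r, n))


def pairwise_erc(
    rer: RERMatrix,
    a: str,
    b: str,
    min_shared_species: int = MIN_SHARED_SPECIES,
    winsor_k: int = WINSOR_K,
) -> ERCValue:
    """ERC for one gene pair; filtered pairs carry a ``filter_reason``."""
    va = rer.values.loc[a].to_numpy(dtype=float)
    vb = rer.values.loc[b].to_numpy(dtype=float)
    n_sp = len(rer.gene_species(a) & rer.gene_species(b))
    return _score_pair(a, b, va, vb, n_sp, min_shared_species, winsor_k)


def all_pairs_erc(
    rer: RERMatrix,
    genes: list[str] | None = None,
    min_shared_species: int = MIN_SHARED_SPECIES,
    winsor_k: int = WINSOR_K,
) -> ERCMatrix:
    """ERC over all unordered gene pairs.

    When no gene has missing branches every pair shares the full branch
    set, so vectors can be Winsorized once per gene and correlated in a
    single matrix product; otherwise pairs are scored individually.
    """
    if genes is None:
        genes = list(rer.values.index)
    genes = sorted(genes)
    sub = rer.values.loc[genes]
    complete = not sub.isna().any().any()

    records: list[ERCValue] = []
    if complete:
        arr = sub.to_numpy(dtype=float)
        n = arr.shape[1]
        n_sp = {g: len(rer.gene_species(g)) for g in genes}
        if n > 2 * winsor_k and n >= 4:
            wz = np.array([winsorize(row, winsor_k) for row in arr])
            sd = wz.std(axis=1)
            with np.errstate(invalid="ignore"):
                corr = np.corrcoef(wz)
            scale = np.sqrt(max(n - 3, 0))
            for i, j in combinations(range(len(genes)), 2):
                a, b = genes[i], genes[j]
                sp = min(n_sp[a], n_sp[b])
                if sp < min_shared_species:
                    records.append(
                        ERCValue(a, b, np.nan, 0, sp, np.nan,
                                 "too few shared species")
                    )
                elif sd[i] == 0 or sd[j] == 0:
                    records.append(
                        ERCValue(a, b, np.nan, n, sp, np.nan, "zero variance")
                    )
                else:
                    r = float(np.clip(corr[i, j], -1.0, 1.0))
                    records.append(
                        ERCValue(a, b, r, n, sp, fisher_transform(r, n))
                    )
        else:
            for a, b in combinations(genes, 2):
                records.append(
                    pairwise_erc(rer, a, b, min_shared_species, winsor_k)
                )
    else:
        arr = sub.to_numpy(dtype=float)
        species = {g: rer.gene_species(g) for g in genes}
        for i, j in combinations(range(len(genes)), 2):
            a, b = genes[i], genes[j]
            n_sp = len(species[a] & species[b])
            records.append(
                _score_pair(a, b, arr[i], arr[j], n_sp,
                            min_shared_species, winsor_k)
            )

    edges = pd.DataFrame(
        [
            {
                "gene_a": v.gene_a,
                "gene_b": v.gene_b,
                "r": v.r,
                "n_branches": v.n_branches,
                "n_shared_species": v.n_shared_species,
                "fterc": v.fterc,
                "filter_reason": v.filter_reason,
            }
            for v in records
        ],
        columns=[
            "gene_a", "gene_b", "r", "n_branches", "n_shared_species",
            "fterc", "filter_reason",
        ],
    )
    return ERCMatrix(edges=edges, genes=genes)
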