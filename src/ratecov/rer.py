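"""Relative evolutionary rates (RERs).

A gene's RER on a branch measures how fast the gene evolved there
*relative to the genome-wide average* for that branch, after removing the
gene's overall rate.  A gene whose tree is an exact scalar multiple of the
master tree therefore has RER identically zero, and multiplying a gene's
branch lengths by any positive constant leaves its RERs unchanged.

Two interchangeable estimators are provided:

``log-ratio`` (default)
    ``RER = ln((l/s_g + eps) / (m_b + eps))``, centered per gene; the
    pseudo-length ``eps`` enters after descaling by the gene's overall
    rate ``s_g``, so the statistic is exactly scale invariant.
``residual``
    studentized residuals of ``sqrt(l)`` regressed on ``sqrt(s_g * m_b)``
    across the gene's branches, centered per gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .phylo import TreeSet, branch_keys, key_to_str

__all__ = [
    "BranchLengthMatrix",
    "RERMatrix",
    "build_branch_length_matrix",
    "estimate_master_lengths",
    "compute_rer",
    "rer_from_trees",
]

EPS = 1e-9  # pseudo-length for zero branches; keeps logs finite

METHODS = ("log-ratio", "residual")


@dataclass
class BranchLengthMatrix:
    """genes x branch-key table of branch lengths (NaN = branch absent)."""

    values: pd.DataFrame  # index gene_id, columns branch-key strings
    species: dict[str, frozenset] = field(default_factory=dict)

    def validate(self) -> None:
        arr = self.values.to_numpy()
        if np.nanmin(arr) < 0:
            raise ValueError("negative branch length in matrix")
        counts = self.values.notna().sum(axis=1)
        bad = counts[counts < 2]
        if len(bad):
            raise ValueError(
                f"genes with <2 branches: {list(bad.index[:5])}"
            )

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path) -> "BranchLengthMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(values=df)


@dataclass
class RERMatrix:
    """genes x branch-key table of relative evolutionary rates."""

    values: pd.DataFrame
    method: str
    species: dict[str, frozenset] = field(default_factory=dict)

    def gene_species(self, gene: str) -> frozenset:
        """Species set of a gene; derived from branch keys if not stored."""
        if gene in self.species:
            return self.species[gene]
        row = self.values.loc[gene]
        present = row.index[row.notna()]
        out: set[str] = set()
        for col in present:
            out.update(col.split(";"))
        return frozenset(out)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")

    @classmethod
    def from_tsv(cls, path, method: str = "log-ratio") -> "RERMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(values=df, method=method)


def build_branch_length_matrix(trees: TreeSet) -> BranchLengthMatrix:
    """One row per gene; cell (g, b) = length of gene g's branch keyed b."""
    rows: dict[str, dict[str, float]] = {}
    species: dict[str, frozenset] = {}
    for gene, tree in trees.gene_trees.items():
        keys = branch_keys(tree, trees.master)
        row: dict[str, float] = {}
        for node, key in keys.items():
            col = key_to_str(key)
            if col in row:
                raise ValueError(f"gene {gene}: duplicate branch key {col}")
            row[col] = tree.length[node]
        rows[gene] = row
        species[gene] = tree.leaves
    df = pd.DataFrame.from_dict(rows, orient="index")
    df = df.sort_index(axis=0).sort_index(axis=1)
    mat = BranchLengthMatrix(values=df, species=species)
    mat.validate()
    return mat


def _gene_scales(values: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Per-gene scale s_g = sum_b l_gb / sum_b m_b over the gene's branches."""
    present = ~np.isnan(values)
    num = np.nansum(values, axis=1)
    den = (present * m[None, :]).sum(axis=1)
    return num / den


def estimate_master_lengths(mat: BranchLengthMatrix) -> pd.Series:
    """Genome-wide average branch lengths.

    Alternates between per-gene scales and per-branch means: a provisional
    per-column mean anchors gene scales, then the column mean of the
    descaled lengths is refined once more.  Zero cells get a pseudo-length
    so every estimate is strictly positive.
    """
    df = mat.values
    empty = df.columns[df.notna().sum(axis=0) == 0]
    if len(empty):
        raise ValueError(f"branches with no coverage: {list(empty)}")
    values = df.to_numpy(dtype=float)
    values = np.where(values == 0, EPS, values)

    m = np.nanmean(values, axis=0)  # provisional per-column mean
    for _ in range(2):  # initial pass + one refinement
        s = _gene_scales(values, m)
        m = np.nanmean(values / s[:, None], axis=0)
    m = np.maximum(m, EPS)
    return pd.Series(m, index=df.columns, name="master_length")


def compute_rer(
    mat: BranchLengthMatrix,
    master_lengths: pd.Series,
    method: str = "log-ratio",
) -> RERMatrix:
    """Branch-specific relative rates; see the module docstring for methods.

    Both methods are centered so each gene's mean RER over its non-missing
    branches is zero, and both are invariant to rescaling a gene's lengths
    by a positive constant.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    df = mat.values
    missing = set(df.columns) - set(master_lengths.index)
    if missing:
        raise ValueError(f"master lengths missing for branches: {sorted(missing)[:5]}")
    m = master_lengths.reindex(df.columns).to_numpy(dtype=float)
    values = df.to_numpy(dtype=float)
    s = _gene_scales(np.where(values == 0, EPS, values), m)
    expected = s[:, None] * m[None, :]

    if method == "log-ratio":
        # pseudo-length applied on the descaled (per-gene unit-rate) scale
        # so the statistic is exactly invariant to rescaling a gene
        rer = np.log((values / s[:, None] + EPS) / (m[None, :] + EPS))
    else:
        rer = _studentized_residuals(np.sqrt(values), np.sqrt(expected))

    rer = rer - np.nanmean(rer, axis=1, keepdims=True)
    out = pd.DataFrame(rer, index=df.index, columns=df.columns)
    out = out.where(df.notna())
    return RERMatrix(values=out, method=method, species=dict(mat.species))


def _studentized_residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Row-wise studentized residuals of y on x (with intercept)."""
    out = np.full_like(y, np.nan)
    for i in range(y.shape[0]):
        ok = ~np.isnan(y[i])
        yi, xi = y[i, ok], x[i, ok]
        n = len(yi)
        if n < 3:
            out[i, ok] = 0.0
            continue
        X = np.column_stack([np.ones(n), xi])
        beta, *_ = np.linalg.lstsq(X, yi, rcond=None)
        resid = yi - X @ beta
        # leverage for studentization
        XtX_inv = np.linalg.pinv(X.T @ X)
        h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
        dof = max(n - 2, 1)
        sigma = np.sqrt((resid**2).sum() / dof)
        if sigma < 1e-15:
            out[i, ok] = 0.0
        else:
            out[i, ok] = resid / (sigma * np.sqrt(np.clip(1 - h, 1e-12, None)))
    return out


def write_master_lengths(m: pd.Series, path) -> None:
    m.rename_axis("branch").to_csv(path, sep="\t", header=["master_length"])


def read_master_lengths(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col="branch")
    return df["master_length"]


def rer_from_trees(trees: TreeSet, method: str = "log-ratio") -> RERMatrix:
    """Convenience: trees -> branch lengths -> master lengths -> RERs."""
    mat = build_branch_length_matrix(trees)
    master = estimate_master_lengths(mat)
    return compute_rer(mat, master, method=method)
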