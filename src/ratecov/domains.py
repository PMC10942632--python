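"""Protein complexes, domain annotations, and domain-level ERC edge lists.

Each complex member protein is decomposed into domains (InterProScan-style
annotations); every inter-protein domain pair in the complex gets an ERC
value and a binary label — 1 when the pair is annotated as physically
contacting in the complex's structural reference, 0 otherwise.  The
ranked, labeled edge list is the input to the ROC and proportional-rank
analyses.

Intra-protein domain pairs are excluded by default: domains of one
protein share their gene's rate history trivially and would contaminate
the negative class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd

from .erc import ERCMatrix

__all__ = [
    "DomainAnnotation",
    "ComplexDefinition",
    "DomainEdge",
    "parse_interpro_tsv",
    "merge_overlaps",
    "build_domain_edge_list",
    "DegenerateComplexError",
]


class DegenerateComplexError(ValueError):
    """Edge list lacks a positive or a negative class."""


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    domain_id: str
    start: int  # 1-based inclusive
    stop: int
    source: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.stop):
            raise ValueError(
                f"{self.protein_id}/{self.domain_id}: bad interval "
                f"[{self.start}, {self.stop}]"
            )


@dataclass
class ComplexDefinition:
    complex_id: str
    proteins: list[str]
    domains: dict[str, list[str]]  # protein -> domain ids
    physical_protein_pairs: set[frozenset] = field(default_factory=set)
    physical_domain_pairs: set[frozenset] = field(default_factory=set)

    def __post_init__(self) -> None:
        prot_of = self.protein_of_domain()
        for pair in self.physical_domain_pairs:
            prots = frozenset(prot_of[d] for d in pair)
            if len(prots) != 2 or prots not in self.physical_protein_pairs:
                raise ValueError(
                    f"{self.complex_id}: physical domain pair {sorted(pair)} "
                    "does not map to an annotated physical protein pair"
                )

    def protein_of_domain(self) -> dict[str, str]:
        return {d: p for p, ds in self.domains.items() for d in ds}

    def all_domains(self) -> list[str]:
        return [d for p in self.proteins for d in self.domains.get(p, [])]


@dataclass(frozen=True)
class DomainEdge:
    domain_a: str
    domain_b: str
    protein_a: str
    protein_b: str
    fterc: float
    label: int  # 1 = physical, 0 = non-physical


# InterProScan TSV column positions (0-based): 0 accession, 2 length,
# 3 analysis, 4 signature accession, 6 start, 7 stop
_IPR_MIN_COLS = 11


def parse_interpro_tsv(path) -> list[DomainAnnotation]:
    """Read InterProScan tab-separated output into domain annotations."""
    out: list[DomainAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < _IPR_MIN_COLS:
                raise ValueError(
                    f"line {lineno}: expected >= {_IPR_MIN_COLS} columns, "
                    f"got {len(cols)}"
                )
            try:
                start, stop = int(cols[6]), int(cols[7])
            except ValueError as exc:
                raise ValueError(
                    f"line {lineno}: non-integer coordinates "
                    f"{cols[6]!r}/{cols[7]!r}"
                ) from exc
            try:
                out.append(
                    DomainAnnotation(
                        protein_id=cols[0],
                        domain_id=cols[4],
                        start=start,
                        stop=stop,
                        source=cols[3],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"line {lineno}: {exc}") from exc
    return out


def merge_overlaps(
    annots: list[DomainAnnotation], policy: str = "keep"
) -> list[DomainAnnotation]:
    """Optionally union overlapping intervals on the same protein.

    ``keep`` returns the annotations unchanged; ``merge`` sweeps each
    protein's intervals left to right and unions any that overlap, naming
    the merged domain after its constituents.
    """
    if policy == "keep":
        return list(annots)
    if policy != "merge":
        raise ValueError(f"unknown overlap policy {policy!r}")
    out: list[DomainAnnotation] = []
    by_protein: dict[str, list[DomainAnnotation]] = {}
    for a in annots:
        by_protein.setdefault(a.protein_id, []).append(a)
    for protein, items in by_protein.items():
        items = sorted(items, key=lambda a: (a.start, a.stop))
        current = items[0]
        parts = [current.domain_id]
        for nxt in items[1:]:
            if nxt.start <= current.stop:  # closed intervals: touching merges
                current = DomainAnnotation(
                    protein, current.domain_id, current.start,
                    max(current.stop, nxt.stop), current.source,
                )
                parts.append(nxt.domain_id)
            else:
                out.append(_named(current, parts))
                current, parts = nxt, [nxt.domain_id]
        out.append(_named(current, parts))
    return out


def _named(a: DomainAnnotation, parts: list[str]) -> DomainAnnotation:
    if len(parts) == 1:
        return a
    return DomainAnnotation(
        a.protein_id, "+".join(parts), a.start, a.stop, a.source
    )


def build_domain_edge_list(
    erc: ERCMatrix,
    cx: ComplexDefinition,
    include_intra_protein: bool = False,
) -> tuple[list[DomainEdge], int]:
    """Ranked, labeled domain-vs-domain edge list for one complex.

    Returns the edges sorted by ftERC descending (ties broken by domain
    ids for determinism) and the count of pairs dropped because their ERC
    was filtered.  Raises :class:`DegenerateComplexError` when either the
    positive or the negative class is empty.
    """
    prot_of = cx.protein_of_domain()
    edges: list[DomainEdge] = []
    dropped = 0
    for da, db in combinations(sorted(cx.all_domains()), 2):
        pa, pb = prot_of[da], prot_of[db]
        if pa == pb and not include_intra_protein:
            continue
        ft = erc.fterc_of(da, db)
        if pd.isna(ft):
            dropped += 1
            continue
        label = int(frozenset((da, db)) in cx.physical_domain_pairs)
        edges.append(DomainEdge(da, db, pa, pb, float(ft), label))
    n_pos = sum(e.label for e in edges)
    if n_pos == 0 or n_pos == len(edges):
        raise DegenerateComplexError(
            f"{cx.complex_id}: {n_pos} positives of {len(edges)} edges — "
            "need both classes"
        )
    edges.sort(key=lambda e: (-e.fterc, e.domain_a, e.domain_b))
    return edges, dropped


def edge_list_to_frame(edges: list[DomainEdge]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "domain_a": e.domain_a,
                "domain_b": e.domain_b,
                "protein_a": e.protein_a,
                "protein_b": e.protein_b,
                "fterc": e.fterc,
                "label": e.label,
            }
            for e in edges
        ]
    )
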