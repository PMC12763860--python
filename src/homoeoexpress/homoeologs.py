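"""Shared-ortholog intersection and per-species A/B homoeolog pairing.

Given per-species ortholog catalogs over one subgenome-resolved reference
panel, compute the Venn partition of assigned reference genes across
species (the all-species region being the 1:1:1 ortholog set) and, per
species, emit homoeolog pairs: one pair per A↔B anchor whose both members
have a 1:1-assigned transcript in that species.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .orthologs import OrthologCatalog
from .simulate import ReferencePanel

__all__ = ["HomoeologPair", "intersect_orthologs", "shared_orthologs",
           "build_homoeolog_pairs"]


@dataclass(frozen=True)
class HomoeologPair:
    """One species' transcript pair mapped onto an A↔B anchor."""

    species: str
    anchor_id: str
    gene_a: str
    gene_b: str

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(
                f"anchor {self.anchor_id}: gene_a equals gene_b ({self.gene_a})")


def intersect_orthologs(
    catalogs: dict[str, OrthologCatalog],
) -> dict[frozenset[str], set[str]]:
    """Exclusive Venn regions of assigned reference genes by species subset.

    Returns a mapping from each non-empty species subset to the reference
    genes assigned in exactly that subset of species; all 2^k − 1 subsets
    are present (possibly empty) and region sizes sum to the size of the
    union of assigned genes.
    """
    if len(catalogs) < 2:
        raise ValueError("need at least two catalogs to intersect")
    assigned = {sp: cat.reference_genes for sp, cat in catalogs.items()}
    union = set().union(*assigned.values())
    regions: dict[frozenset[str], set[str]] = {}
    species = sorted(catalogs)
    for gene in union:
        members = frozenset(sp for sp in species if gene in assigned[sp])
        regions.setdefault(members, set()).add(gene)
    # include empty regions for every subset so callers see all 2^k - 1 cells
    from itertools import combinations
    for r in range(1, len(species) + 1):
        for combo in combinations(species, r):
            regions.setdefault(frozenset(combo), set())
    return regions


def shared_orthologs(catalogs: dict[str, OrthologCatalog]) -> set[str]:
    """The 1:1:1 set: reference genes 1:1-assigned in every species."""
    sets = [cat.reference_genes for cat in catalogs.values()]
    if not sets:
        return set()
    return set.intersection(*sets)


def venn_summary(regions: dict[frozenset[str], set[str]]) -> pd.DataFrame:
    rows = [("+".join(sorted(k)), len(v)) for k, v in regions.items()]
    return (pd.DataFrame(rows, columns=["region", "n_genes"])
            .sort_values("region").reset_index(drop=True))


def build_homoeolog_pairs(
    catalog: OrthologCatalog,
    panel: ReferencePanel,
    restrict_to: set[str] | None = None,
) -> list[HomoeologPair]:
    """One pair per anchor whose both members are 1:1-assigned.

    ``restrict_to`` optionally limits pairing to anchors whose two reference
    genes both lie in the given set (e.g. the shared 1:1:1 orthologs).
    Output order is deterministic (by anchor_id).
    """
    known = set(panel.genes["gene_id"])
    query_of = dict(zip(catalog.assigned()["ref_gene"],
                        catalog.assigned()["query_id"]))
    pairs = []
    anchors = panel.anchors.sort_values("anchor_id")
    for anchor_id, ref_a, ref_b in anchors[["anchor_id", "ref_a", "ref_b"]
                                           ].itertuples(index=False):
        if ref_a not in known or ref_b not in known:
            raise KeyError(
                f"anchor {anchor_id} references unknown gene "
                f"{ref_a if ref_a not in known else ref_b!r}")
        if restrict_to is not None and not (
                ref_a in restrict_to and ref_b in restrict_to):
            continue
        if ref_a in query_of and ref_b in query_of:
            pairs.append(HomoeologPair(
                species=catalog.species, anchor_id=anchor_id,
                gene_a=query_of[ref_a], gene_b=query_of[ref_b]))
    return pairs


def pairs_to_frame(pairs: list[HomoeologPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.species, p.anchor_id, p.gene_a, p.gene_b) for p in pairs],
        columns=["species", "anchor_id", "gene_a", "gene_b"])


def pairs_from_frame(frame: pd.DataFrame) -> list[HomoeologPair]:
    return [HomoeologPair(species=r.species, anchor_id=r.anchor_id,
                          gene_a=r.gene_a, gene_b=r.gene_b)
            for r in frame.itertuples(index=False)]
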