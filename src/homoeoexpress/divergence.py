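"""Intersection of differential expression with subgenome dominance, and
generic over-representation enrichment.

Anchors gain a DE direction when either of their two transcripts is in the
up- or down-regulated core gene set; crossing that direction with the
anchor's dominance class yields a 2×2 table ({up, down} × {SubA, SubB}).
Enrichment is annotation-agnostic: one-sided hypergeometric
over-representation of a gene set against term→gene annotations within a
universe, Benjamini–Hochberg-adjusted across tested terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .homoeologs import HomoeologPair

__all__ = ["DivergenceTable", "intersect_de_dominant", "hypergeom_enrich"]


@dataclass
class DivergenceTable:
    """Per-anchor DE direction × dominance class, with the 2×2 cell counts.

    ``table`` columns: anchor_id, de_direction, dominance_class.
    ``counts`` keys: (de_direction, dominance_class) over
    {up, down} × {SubA_dominant, SubB_dominant};
    ``non_dominant`` counts DE anchors whose class is balanced/excluded.
    """

    table: pd.DataFrame
    counts: dict[tuple[str, str], int]
    non_dominant: dict[str, int]

    @property
    def n_de_dominant(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [(d, c, n) for (d, c), n in self.counts.items()]
        rows += [(d, "non_dominant", n) for d, n in self.non_dominant.items()]
        return pd.DataFrame(rows, columns=["de_direction", "dominance_class", "n"])


def intersect_de_dominant(
    core_up: Iterable[str],
    core_down: Iterable[str],
    dominance: pd.DataFrame,
    pairs: Sequence[HomoeologPair],
) -> DivergenceTable:
    """Cross DE direction (lifted from transcripts to anchors via either-
    member membership) with the anchors' dominance classes.

    ``dominance`` is a classified pair table with anchor_id and
    dominance_class columns. A transcript in both core sets is an error.
    """
    up, down = set(core_up), set(core_down)
    both = up & down
    if both:
        raise ValueError(
            f"transcript(s) in both core sets: {sorted(both)[:5]}")
    klass = dict(zip(dominance["anchor_id"], dominance["dominance_class"]))
    rows = []
    for p in pairs:
        if p.gene_a in up or p.gene_b in up:
            direction = "up"
        elif p.gene_a in down or p.gene_b in down:
            direction = "down"
        else:
            direction = "none"
        rows.append((p.anchor_id, direction, klass.get(p.anchor_id, "excluded")))
    table = pd.DataFrame(rows, columns=["anchor_id", "de_direction",
                                        "dominance_class"])
    counts = {(d, c): 0 for d in ("up", "down")
              for c in ("SubA_dominant", "SubB_dominant")}
    non_dominant = {"up": 0, "down": 0}
    for _, direction, c in table.itertuples(index=False):
        if direction == "none":
            continue
        if c in ("SubA_dominant", "SubB_dominant"):
            counts[(direction, c)] += 1
        else:
            non_dominant[direction] += 1
    return DivergenceTable(table=table, counts=counts, non_dominant=non_dominant)


def hypergeom_enrich(
    gene_set: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    alpha: float = 0.05,
    top: int | None = 15,
    include_zero_overlap_in_bh: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    For a term annotating K of the N universe genes, with n genes drawn
    (the query set) and k overlapping, p = P[X ≥ k] for
    X ~ Hypergeometric(N, K, n). BH adjustment runs across terms with
    overlap ≥ 1 (zero-overlap terms are reported with p = q = 1 but kept
    out of the BH family unless requested). Rows are sorted by p; ``top``
    keeps the best N rows after the sort (None keeps all). The ``alpha``
    threshold is reported as a boolean column, not used to drop rows.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("universe is empty")
    gene_set = set(gene_set)
    stray = gene_set - universe
    if stray:
        raise ValueError(
            f"gene set members outside the universe: {sorted(stray)[:5]}")
    n = len(gene_set)
    big_n = len(universe)
    rows = []
    if n == 0:
        return pd.DataFrame(columns=["term_id", "term_size", "overlap",
                                     "p_value", "genes", "q_value",
                                     "significant"])
    for term, genes in annotation.items():
        members = set(genes) & universe
        if not members:
            continue
        overlap = gene_set & members
        k, big_k = len(overlap), len(members)
        if k >= 1:
            p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n))
        else:
            p = 1.0
        rows.append((term, big_k, k, p, ",".join(sorted(overlap))))
    result = pd.DataFrame(
        rows, columns=["term_id", "term_size", "overlap", "p_value", "genes"])
    if result.empty:
        result["q_value"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    in_family = result["overlap"] >= 1 if not include_zero_overlap_in_bh \
        else pd.Series(True, index=result.index)
    result["q_value"] = 1.0
    if in_family.any():
        _, q, _, _ = multipletests(result.loc[in_family, "p_value"],
                                   method="fdr_bh")
        result.loc[in_family, "q_value"] = q
    result["significant"] = result["p_value"] < alpha
    result = result.sort_values(["p_value", "term_id"],
                                kind="mergesort").reset_index(drop=True)
    if top is not None:
        result = result.head(top)
    return result
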