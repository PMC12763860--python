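"""Tiered identity/coverage ortholog assignment from protein alignment hits.

Species transcripts (queries) are assigned to reference genes by filtering
12-column BLAST-tabular hits through progressively relaxed identity/coverage
tiers, keeping the best surviving hit per query, and merging tiers with
strict-tier precedence. Queries passing no tier are 1:0 orthologs; the rest
are 1:1 orthologs with recorded tier provenance. Reference-side uniqueness
is enforced so the 1:1 catalog is injective on reference genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "HitRecord",
    "TierSpec",
    "DEFAULT_TIERS",
    "OrthologCatalog",
    "parse_hit_table",
    "read_lengths",
    "coverage",
    "select_best_hit",
    "assign_orthologs",
]

#: Alignment e-value pre-filter applied when parsing hit tables.
DEFAULT_EVALUE_MAX = 1e-3


@dataclass(frozen=True)
class HitRecord:
    """One pairwise protein alignment hit (identity as a fraction)."""

    query_id: str
    subject_id: str
    identity: float
    align_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    e_value: float
    bit_score: float
    query_length: int
    subject_length: int

    def __post_init__(self):
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError(f"identity out of [0,1]: {self.identity}")
        if self.align_length < 1:
            raise ValueError("align_length must be >= 1")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")
        if self.query_length < 1:
            raise ValueError("query_length must be >= 1")


@dataclass(frozen=True)
class TierSpec:
    """Ordered (min_identity, min_coverage) thresholds, strictest first.

    Thresholds are strict: a hit passes tier k when identity > min_identity
    AND coverage > min_coverage. Both components must strictly decrease down
    the list.
    """

    thresholds: tuple[tuple[float, float], ...]

    def __post_init__(self):
        if not self.thresholds:
            raise ValueError("TierSpec needs at least one tier")
        prev = (float("inf"), float("inf"))
        for t in self.thresholds:
            if not (t[0] < prev[0] and t[1] < prev[1]):
                raise ValueError(
                    "tier thresholds must strictly decrease in both "
                    f"identity and coverage; offending tier {t}")
            prev = t

    @classmethod
    def from_string(cls, text: str) -> "TierSpec":
        """Parse e.g. ``"0.95:0.80,0.90:0.75"``."""
        tiers = []
        for part in text.split(","):
            ident, cov = part.split(":")
            tiers.append((float(ident), float(cov)))
        return cls(tuple(tiers))


DEFAULT_TIERS = TierSpec(((0.95, 0.80), (0.90, 0.75), (0.85, 0.70), (0.80, 0.65)))


@dataclass
class OrthologCatalog:
    """Per-query assignment table for one species.

    ``table`` columns: query_id, klass ("one_to_one"/"one_to_zero"),
    ref_gene ("" for one_to_zero), subgenome, tier_index (0 for
    one_to_zero), identity, coverage.
    """

    species: str
    table: pd.DataFrame

    def assigned(self) -> pd.DataFrame:
        return self.table[self.table["klass"] == "one_to_one"]

    @property
    def reference_genes(self) -> set[str]:
        return set(self.assigned()["ref_gene"])

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, species: str = "") -> "OrthologCatalog":
        table = pd.read_csv(path, sep="\t", dtype={"query_id": str},
                            keep_default_na=False)
        return cls(species=species, table=table)


def read_lengths(path) -> dict[str, int]:
    """Two-column (id, length) TSV without header."""
    frame = pd.read_csv(path, sep="\t", header=None, names=["id", "length"])
    return dict(zip(frame["id"].astype(str), frame["length"].astype(int)))


def parse_hit_table(
    path,
    query_lengths: Mapping[str, int],
    subject_lengths: Mapping[str, int],
    evalue_max: float = DEFAULT_EVALUE_MAX,
) -> list[HitRecord]:
    """Read a 12-column BLAST-tabular file into HitRecords.

    The identity column follows the BLAST convention (percentage) and is
    converted to a fraction. Rows above the e-value cutoff are dropped,
    mirroring the alignment-stage significance threshold.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=12 tab-separated "
                    f"columns, got {len(fields)}")
            qid, sid = fields[0], fields[1]
            if qid not in query_lengths:
                raise KeyError(f"query {qid!r} missing from the length table")
            if sid not in subject_lengths:
                raise KeyError(f"subject {sid!r} missing from the length table")
            e_value = float(fields[10])
            if e_value > evalue_max:
                continue
            records.append(HitRecord(
                query_id=qid, subject_id=sid,
                identity=float(fields[2]) / 100.0,
                align_length=int(fields[3]), mismatches=int(fields[4]),
                gap_opens=int(fields[5]), q_start=int(fields[6]),
                q_end=int(fields[7]), s_start=int(fields[8]),
                s_end=int(fields[9]), e_value=e_value,
                bit_score=float(fields[11]),
                query_length=int(query_lengths[qid]),
                subject_length=int(subject_lengths[sid]),
            ))
    return records


def coverage(hit: HitRecord) -> float:
    """Alignment length over query length, capped at 1 (gapped alignments
    can exceed the query span)."""
    return min(1.0, hit.align_length / hit.query_length)


def _hit_rank(hit: HitRecord) -> tuple:
    # identity desc, coverage desc, bit score desc, subject id asc
    return (-hit.identity, -coverage(hit), -hit.bit_score, hit.subject_id)


def select_best_hit(hits: Sequence[HitRecord]) -> HitRecord:
    """Best hit under (identity, coverage, bit score, subject id) ordering.

    Operationalizes "highest identity and full-length alignment": identity
    first, coverage as the full-length criterion, bit score then subject id
    as deterministic tie-breaks.
    """
    if not hits:
        raise ValueError("select_best_hit requires a non-empty hit list")
    if len({h.query_id for h in hits}) > 1:
        raise ValueError("select_best_hit expects hits of a single query")
    return min(hits, key=_hit_rank)


def _dedup_hsps(hits: Iterable[HitRecord]) -> list[HitRecord]:
    """Keep only the highest-bit-score HSP per (query, subject) pair."""
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        key = (h.query_id, h.subject_id)
        if key not in best or h.bit_score > best[key].bit_score:
            best[key] = h
    return list(best.values())


def assign_orthologs(
    hits: Iterable[HitRecord],
    tiers: TierSpec = DEFAULT_TIERS,
    subgenome_of: Mapping[str, str] | None = None,
    species: str = "",
    all_queries: Iterable[str] | None = None,
) -> OrthologCatalog:
    """Tiered assignment with strict-tier precedence and best-hit resolution.

    For each query the strictest tier leaving at least one surviving hit
    determines its assignment; the winning hit is chosen by
    :func:`select_best_hit`. Because tiers are nested (every hit passing
    tier k also passes tier k+1), assignments made at strict tiers are never
    overwritten during the iterative merge to relaxed tiers. Queries passing
    no tier — and queries listed in ``all_queries`` without hits — are 1:0.
    Finally, reference-side uniqueness is enforced: when several queries
    claim one reference gene, the query with the best winning hit keeps it
    and the rest are demoted to 1:0.
    """
    per_query: dict[str, list[HitRecord]] = {}
    for h in _dedup_hsps(hits):
        per_query.setdefault(h.query_id, []).append(h)

    candidates: dict[str, tuple[HitRecord, int]] = {}
    unassigned: set[str] = set()
    for qid, qhits in per_query.items():
        placed = False
        for tier_index, (min_id, min_cov) in enumerate(tiers.thresholds, start=1):
            surviving = [h for h in qhits
                         if h.identity > min_id and coverage(h) > min_cov]
            if surviving:
                candidates[qid] = (select_best_hit(surviving), tier_index)
                placed = True
                break
        if not placed:
            unassigned.add(qid)
    if all_queries is not None:
        unassigned |= {q for q in all_queries if q not in candidates}

    # reference-side uniqueness: best claimant wins, others demoted to 1:0
    by_ref: dict[str, list[tuple[HitRecord, int, str]]] = {}
    for qid, (hit, tier_index) in candidates.items():
        by_ref.setdefault(hit.subject_id, []).append((hit, tier_index, qid))
    rows = []
    for ref, claims in by_ref.items():
        claims.sort(key=lambda c: (_hit_rank(c[0]), c[2]))
        hit, tier_index, qid = claims[0]
        rows.append((qid, "one_to_one", ref,
                     subgenome_of.get(ref, "") if subgenome_of else "",
                     tier_index, hit.identity, coverage(hit)))
        unassigned.update(c[2] for c in claims[1:])
    rows.extend((qid, "one_to_zero", "", "", 0, float("nan"), float("nan"))
                for qid in unassigned)

    table = pd.DataFrame(rows, columns=[
        "query_id", "klass", "ref_gene", "subgenome", "tier_index",
        "identity", "coverage"])
    table = table.sort_values("query_id", kind="mergesort").reset_index(drop=True)
    return OrthologCatalog(species=species, table=table)
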