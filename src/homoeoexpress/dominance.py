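"""Homoeolog expression quantification and subgenome-dominance testing.

For each A/B homoeolog pair, replicate TPM values are averaged per copy,
the log2(B/A) ratio formed, and the pair classified at a fold threshold:
the copy expressed at least ``fold``-times higher than its counterpart is
dominant. Subgenome bias over a pair set is tested with the equal-split
chi-squared test: observed A- and B-dominant counts against a 50:50
expectation, one degree of freedom, no continuity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .homoeologs import HomoeologPair

__all__ = [
    "ExpressionMatrix",
    "DominanceRecord",
    "ChiSquareResult",
    "load_expression",
    "pair_expression",
    "direction_counts",
    "classify_dominance",
    "chisq_equal_split",
]

CLASSES = ("SubA_dominant", "SubB_dominant", "balanced", "excluded")


@dataclass
class ExpressionMatrix:
    """Genes × samples TPM matrix plus the sample→group map."""

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self):
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicated gene ID {dup!r}")
        if not self.values.columns.is_unique:
            raise ValueError("sample IDs must be unique")
        if (self.values.to_numpy() < 0).any():
            gi, si = np.argwhere(self.values.to_numpy() < 0)[0]
            raise ValueError(
                f"negative TPM at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}")
        unmapped = [s for s in self.values.columns if s not in self.groups.index]
        if unmapped:
            raise ValueError(f"samples not in the group map: {unmapped}")

    def samples_of(self, group: str | None) -> list[str]:
        if group is None:
            return list(self.values.columns)
        chosen = [s for s in self.values.columns if self.groups[s] == group]
        if not chosen:
            raise ValueError(f"no samples in group {group!r}")
        return chosen


def load_expression(path, group_map_path) -> ExpressionMatrix:
    """Read a TPM TSV (first column gene_id, header = samples) and a
    two-column sample→group TSV."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = values.columns[
        [not pd.api.types.is_numeric_dtype(d) for d in values.dtypes]]
    if len(non_numeric):
        col = non_numeric[0]
        bad = values[col][pd.to_numeric(values[col], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric TPM at gene {bad.index[0]!r}, sample {col!r}")
    groups = pd.read_csv(group_map_path, sep="\t", header=None, index_col=0)
    groups = groups.iloc[:, 0]
    groups.index = groups.index.astype(str)
    groups.name = "group"
    return ExpressionMatrix(values=values, groups=groups)


def pair_expression(
    matrix: ExpressionMatrix,
    pairs: Sequence[HomoeologPair],
    samples: Sequence[str] | None = None,
    group: str | None = None,
) -> pd.DataFrame:
    """Per-pair replicate means of the two copies over the chosen samples.

    ``samples`` selects explicit columns; ``group`` selects one group's
    samples; by default all samples are used. Returns a frame with columns
    anchor_id, gene_a, gene_b, mean_tpm_a, mean_tpm_b.
    """
    if samples is None:
        samples = matrix.samples_of(group)
    sub = matrix.values[list(samples)]
    means = sub.mean(axis=1)
    rows = []
    for p in pairs:
        for g in (p.gene_a, p.gene_b):
            if g not in means.index:
                raise KeyError(
                    f"gene {g!r} of pair {p.anchor_id} absent from the matrix")
        rows.append((p.anchor_id, p.gene_a, p.gene_b,
                     float(means[p.gene_a]), float(means[p.gene_b])))
    return pd.DataFrame(rows, columns=[
        "anchor_id", "gene_a", "gene_b", "mean_tpm_a", "mean_tpm_b"])


class DirectionCounts(NamedTuple):
    n_b_higher: int
    n_a_higher: int
    n_tied: int
    n_excluded: int


def direction_counts(pair_means: pd.DataFrame) -> DirectionCounts:
    """Count pairs by the sign of log2(B/A); both-zero pairs are excluded,
    exact nonzero ties counted separately."""
    a = pair_means["mean_tpm_a"].to_numpy()
    b = pair_means["mean_tpm_b"].to_numpy()
    excluded = (a == 0) & (b == 0)
    return DirectionCounts(
        n_b_higher=int(((b > a) & ~excluded).sum()),
        n_a_higher=int(((a > b) & ~excluded).sum()),
        n_tied=int(((a == b) & ~excluded).sum()),
        n_excluded=int(excluded.sum()),
    )


def classify_dominance(
    pair_means: pd.DataFrame, fold_threshold: float = 2.0
) -> pd.DataFrame:
    """Classify each pair at the fold threshold.

    SubB_dominant iff mean_B ≥ fold × mean_A with mean_B > 0 (and
    symmetrically for A; "at least" reads as a non-strict inequality).
    A pair with one silent copy is dominant for the expressed copy; a pair
    with both copies silent is excluded. Everything else is balanced.
    Adds columns log2_ratio (log2 B/A; ±inf for one-sided zeros, NaN for
    excluded pairs) and dominance_class.
    """
    if fold_threshold < 1.0:
        raise ValueError("fold_threshold must be >= 1")
    a = pair_means["mean_tpm_a"].to_numpy(dtype=float)
    b = pair_means["mean_tpm_b"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        log2_ratio = np.log2(b) - np.log2(a)
    excluded = (a == 0) & (b == 0)
    b_dom = (b >= fold_threshold * a) & (b > 0) & ~excluded
    a_dom = (a >= fold_threshold * b) & (a > 0) & ~excluded
    # fold 1 with equal nonzero means satisfies both; call that balanced
    tie = b_dom & a_dom
    b_dom &= ~tie
    a_dom &= ~tie
    klass = np.where(excluded, "excluded",
                     np.where(b_dom, "SubB_dominant",
                              np.where(a_dom, "SubA_dominant", "balanced")))
    out = pair_means.copy()
    out["log2_ratio"] = np.where(excluded, np.nan, log2_ratio)
    out["dominance_class"] = klass
    return out


@dataclass(frozen=True)
class ChiSquareResult:
    """Equal-split chi-squared test of A- vs B-dominant counts."""

    observed_a: int
    observed_b: int
    expected_a: float
    expected_b: float
    statistic: float
    df: int
    p_value: float

    def summary_row(self) -> dict:
        """Counts and the statistic at 4 decimal places, full-precision p."""
        return {
            "observed_a": float(self.observed_a),
            "observed_b": float(self.observed_b),
            "expected_a": self.expected_a,
            "expected_b": self.expected_b,
            "chi2": round(self.statistic, 4),
            "df": self.df,
            "p_value": self.p_value,
        }


def chisq_equal_split(observed_a: int, observed_b: int) -> ChiSquareResult:
    """Pearson goodness-of-fit of (O_A, O_B) against a 50:50 split.

    E = (O_A + O_B)/2 per cell, statistic Σ(O−E)²/E — algebraically
    (O_A − O_B)²/(O_A + O_B) — with 1 df and no continuity correction;
    the p-value is the upper tail of χ²(1), which captures deviation in
    either direction of the two-category split.
    """
    if observed_a < 0 or observed_b < 0:
        raise ValueError("counts must be non-negative")
    total = observed_a + observed_b
    if total < 1:
        raise ValueError("at least one dominant pair is required")
    expected = total / 2.0
    statistic = (observed_a - expected) ** 2 / expected \
        + (observed_b - expected) ** 2 / expected
    p_value = float(stats.chi2.sf(statistic, df=1))
    return ChiSquareResult(
        observed_a=observed_a, observed_b=observed_b,
        expected_a=expected, expected_b=expected,
        statistic=float(statistic), df=1, p_value=p_value)


def dominance_summary(records: pd.DataFrame) -> dict:
    """Direction counts, dominant counts and the equal-split test for a
    classified pair table."""
    counts = direction_counts(records)
    n_a = int((records["dominance_class"] == "SubA_dominant").sum())
    n_b = int((records["dominance_class"] == "SubB_dominant").sum())
    result = chisq_equal_split(n_a, n_b) if n_a + n_b else None
    summary = {
        "n_pairs": int(len(records)),
        "n_b_higher": counts.n_b_higher,
        "n_a_higher": counts.n_a_higher,
        "n_tied": counts.n_tied,
        "n_excluded": counts.n_excluded,
        "n_suba_dominant": n_a,
        "n_subb_dominant": n_b,
    }
    if result is not None:
        summary.update({"chi2": round(result.statistic, 4), "df": result.df,
                        "p_value": result.p_value})
    return summary
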