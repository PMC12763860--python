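"""Weighted co-expression network analysis with trait-associated modules.

The standard weighted-network pipeline: Pearson correlation of log-scale
expression, soft-threshold power chosen by the scale-free topology
criterion, adjacency raised to that power, topological overlap (TOM),
average-linkage clustering on 1−TOM with a static height cut, module
eigengenes (first principal component of the standardized module
submatrix), module–trait Pearson correlation with a |r| and p selection
rule, per-gene gene significance (GS) and module membership (MM), and a
core-gene filter GS > 0.40 & MM > 0.50 split by module direction.

The static height cut replaces the dynamic tree cut of the reference R
implementation; see docs/methods.md for the rationale and the default
height on the 1−TOM scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

__all__ = [
    "NetworkParams",
    "ModuleResult",
    "filter_expressed",
    "pick_soft_power",
    "adjacency",
    "tom_similarity",
    "cluster_modules",
    "module_eigengenes",
    "module_trait_cor",
    "gene_scores",
    "core_genes",
    "run_coexpr",
]


@dataclass(frozen=True)
class NetworkParams:
    """Tunable network construction parameters.

    cut_height is on the 1−TOM dissimilarity scale: module-internal merges
    sit well below it, module-to-background merges above (default 0.90;
    see docs/methods.md).
    """

    soft_power: int = 6
    network_type: str = "unsigned"
    correlation: str = "pearson"
    min_module_size: int = 20
    cut_height: float = 0.90
    r2_target: float = 0.80

    def __post_init__(self):
        if self.soft_power < 1:
            raise ValueError("soft_power must be >= 1")
        if self.min_module_size < 2:
            raise ValueError("min_module_size must be >= 2")
        if not 0.0 < self.cut_height <= 1.0:
            raise ValueError("cut_height must lie in (0, 1]")
        if self.network_type not in ("unsigned", "signed"):
            raise ValueError("network_type must be 'unsigned' or 'signed'")
        if self.correlation != "pearson":
            raise ValueError("only Pearson correlation is supported")


@dataclass
class ModuleResult:
    """Full output of the co-expression stage."""

    labels: pd.Series                 # gene -> module id (0 = unassigned)
    eigengenes: pd.DataFrame          # module x sample
    trait_r: pd.Series                # module -> Pearson r vs trait
    trait_p: pd.Series                # module -> p-value
    selected: pd.Series               # module -> bool (|r| and p rule)
    gs: pd.Series                     # gene -> |cor(expr, trait)|
    mm: pd.Series                     # gene -> cor(expr, own-module eigengene)
    core: dict = field(default_factory=dict)   # "up"/"down" -> list of genes


def filter_expressed(values: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with TPM > 0 in all retained samples (the strict reading
    of a non-zero-expression filter)."""
    keep = (values.to_numpy() > 0).all(axis=1)
    if not keep.any():
        raise ValueError(
            "no gene is expressed in every sample; relax the filter or "
            "check the input matrix")
    return values.loc[keep]


def _check_no_constant(values: np.ndarray) -> None:
    sds = values.std(axis=1)
    if (sds == 0).any():
        raise ValueError(
            f"{int((sds == 0).sum())} constant-expression gene(s) present; "
            "filter before building the network")


def adjacency(values: pd.DataFrame, params: NetworkParams) -> np.ndarray:
    """|cor|^β (unsigned) or ((1+cor)/2)^β (signed) with unit diagonal."""
    x = values.to_numpy(dtype=float)
    _check_no_constant(x)
    corr = np.corrcoef(x)
    if params.network_type == "unsigned":
        a = np.abs(corr) ** params.soft_power
    else:
        a = ((1.0 + corr) / 2.0) ** params.soft_power
    np.fill_diagonal(a, 1.0)
    return a


def pick_soft_power(
    values: pd.DataFrame,
    candidate_powers=tuple(range(1, 21)),
    r2_target: float = 0.80,
    n_bins: int = 10,
    network_type: str = "unsigned",
) -> int:
    """Smallest candidate power whose connectivity distribution fits a
    scale-free law with R² ≥ target.

    For each power: connectivity k_i = Σ_{j≠i} a_ij, log10(k) binned into
    ``n_bins`` equal-width bins, log10(frequency) regressed on log10(mean k
    per bin); the fit R² is the criterion. If no candidate qualifies, the
    best-fitting one is returned with a warning.
    """
    if not candidate_powers:
        raise ValueError("candidate_powers must be non-empty")
    if values.shape[1] < 4:
        raise ValueError("need at least 4 samples to assess scale-free fit")
    best_power, best_r2 = None, -np.inf
    for power in candidate_powers:
        params = NetworkParams(soft_power=int(power), network_type=network_type)
        a = adjacency(values, params)
        k = a.sum(axis=0) - 1.0
        r2 = _scale_free_r2(k, n_bins)
        if r2 >= r2_target:
            return int(power)
        if r2 > best_r2:
            best_power, best_r2 = int(power), r2
    warnings.warn(
        f"no candidate power reached scale-free R^2 {r2_target}; "
        f"returning power {best_power} (R^2 = {best_r2:.3f})")
    return best_power


def _scale_free_r2(k: np.ndarray, n_bins: int) -> float:
    k = k[k > 0]
    if k.size < 2:
        return 0.0
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max() + 1e-12, n_bins + 1)
    idx = np.digitize(logk, edges) - 1
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum()))
    if len(xs) < 3:
        return 0.0
    fit = stats.linregress(xs, ys)
    return float(fit.rvalue ** 2)


def tom_similarity(a: np.ndarray) -> np.ndarray:
    """Topological overlap of a symmetric adjacency with unit diagonal.

    TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij) with
    l_ij = Σ_{u≠i,j} a_iu a_uj and k_i = Σ_{u≠i} a_iu; TOM_ii = 1.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    # (A @ A)_ij counts paths through all u including i and j; both the
    # u = i and u = j terms equal a_ij because the diagonal is 1.
    l = a @ a - 2.0 * a
    k = a.sum(axis=0) - 1.0
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    tom[denom == 0] = 0.0
    np.fill_diagonal(tom, 1.0)
    return np.clip(tom, 0.0, 1.0)


def cluster_modules(tom: np.ndarray, params: NetworkParams,
                    genes: pd.Index | None = None) -> pd.Series:
    """Average-linkage modules from a static cut of the 1−TOM dendrogram.

    Clusters smaller than min_module_size get label 0 (unassigned); the
    rest are renumbered 1..m by decreasing size (ties by smallest member
    index) so labels are stable up to gene order.
    """
    n = tom.shape[0]
    genes = pd.RangeIndex(n) if genes is None else genes
    if n < params.min_module_size:
        warnings.warn("fewer genes than min_module_size; all unassigned")
        return pd.Series(0, index=genes, name="module")
    dism = 1.0 - tom
    np.fill_diagonal(dism, 0.0)
    condensed = squareform(dism, checks=False)
    z = linkage(condensed, method="average")
    raw = fcluster(z, t=params.cut_height, criterion="distance")
    labels = np.zeros(n, dtype=int)
    sizes = pd.Series(raw).value_counts()
    kept = [c for c in sizes.index if sizes[c] >= params.min_module_size]
    # deterministic renumbering: by size desc, then first occurrence
    first_pos = {c: int(np.argmin(np.where(raw == c, np.arange(n), n)))
                 for c in kept}
    kept.sort(key=lambda c: (-sizes[c], first_pos[c]))
    for new, c in enumerate(kept, start=1):
        labels[raw == c] = new
    return pd.Series(labels, index=genes, name="module")


def _standardize(values: np.ndarray) -> np.ndarray:
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    if (sd == 0).any():
        raise ValueError("constant gene encountered while standardizing")
    return (values - mu) / sd


def module_eigengenes(values: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """First principal component scores of each module's standardized
    expression, unit variance, sign-aligned so the eigengene correlates
    non-negatively with the module's mean expression profile."""
    modules = sorted(m for m in labels.unique() if m != 0)
    if not modules:
        raise ValueError("no assigned modules")
    rows = {}
    for m in modules:
        sub = values.loc[labels[labels == m].index].to_numpy(dtype=float)
        z = _standardize(sub)
        # right singular vector of the gene x sample z-matrix = PC scores
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        pc = vt[0]
        pc = pc / pc.std(ddof=1)
        if np.corrcoef(pc, z.mean(axis=0))[0, 1] < 0:
            pc = -pc
        rows[f"M{m}"] = pc
    return pd.DataFrame(rows, index=values.columns).T


def module_trait_cor(
    eigengenes: pd.DataFrame,
    trait: pd.Series,
    r_threshold: float = 0.70,
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Pearson r and two-sided p of each eigengene against the trait, plus
    the selection mask |r| ≥ r_threshold AND p < p_threshold."""
    t = trait.reindex(eigengenes.columns).to_numpy(dtype=float)
    if np.isnan(t).any():
        raise ValueError("trait missing for some samples")
    if np.std(t) == 0:
        raise ValueError("trait is constant")
    if len(t) < 3:
        raise ValueError("need at least 3 samples")
    rows = []
    for m, row in eigengenes.iterrows():
        r, p = stats.pearsonr(row.to_numpy(dtype=float), t)
        rows.append((m, float(r), float(p),
                     abs(r) >= r_threshold and p < p_threshold))
    return pd.DataFrame(rows, columns=["module", "r", "p", "selected"]
                        ).set_index("module")


def gene_scores(
    values: pd.DataFrame,
    trait: pd.Series,
    eigengenes: pd.DataFrame,
    labels: pd.Series,
) -> tuple[pd.Series, pd.Series]:
    """GS_g = |cor(x_g, trait)|; MM_g = cor(x_g, own-module eigengene)
    (NaN for unassigned genes)."""
    t = trait.reindex(values.columns).to_numpy(dtype=float)
    x = values.to_numpy(dtype=float)
    gs = pd.Series(
        [abs(_pearson(x[i], t)) for i in range(len(values))],
        index=values.index, name="GS")
    mm = pd.Series(np.nan, index=values.index, name="MM")
    for m in eigengenes.index:
        mid = int(str(m).lstrip("M"))
        members = labels[labels == mid].index
        e = eigengenes.loc[m].to_numpy(dtype=float)
        for g in members:
            mm[g] = _pearson(values.loc[g].to_numpy(dtype=float), e)
    return gs, mm


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def core_genes(
    gs: pd.Series,
    mm: pd.Series,
    labels: pd.Series,
    trait_table: pd.DataFrame,
    gs_min: float = 0.40,
    mm_min: float = 0.50,
) -> dict[str, list]:
    """Core genes of selected modules: GS > gs_min AND MM > mm_min (strict),
    partitioned into "up"/"down" by the sign of the module's trait r."""
    out: dict[str, list] = {"up": [], "down": []}
    for m, row in trait_table.iterrows():
        if not row["selected"]:
            continue
        mid = int(str(m).lstrip("M"))
        direction = "up" if row["r"] > 0 else "down"
        members = labels[labels == mid].index
        chosen = [g for g in members
                  if gs[g] > gs_min and not np.isnan(mm[g]) and mm[g] > mm_min]
        out[direction].extend(chosen)
    return out


def run_coexpr(
    values: pd.DataFrame,
    trait: pd.Series,
    params: NetworkParams = NetworkParams(),
    r_threshold: float = 0.70,
    p_threshold: float = 0.05,
    gs_min: float = 0.40,
    mm_min: float = 0.50,
    auto_power: bool = False,
) -> ModuleResult:
    """Full co-expression stage on an expression matrix and per-sample trait."""
    expressed = filter_expressed(values)
    log_values = np.log2(expressed + 1.0)
    if auto_power:
        power = pick_soft_power(log_values, r2_target=params.r2_target,
                                network_type=params.network_type)
        params = NetworkParams(
            soft_power=power, network_type=params.network_type,
            correlation=params.correlation,
            min_module_size=params.min_module_size,
            cut_height=params.cut_height, r2_target=params.r2_target)
    a = adjacency(log_values, params)
    tom = tom_similarity(a)
    labels = cluster_modules(tom, params, genes=log_values.index)
    eigengenes = module_eigengenes(log_values, labels)
    trait_table = module_trait_cor(eigengenes, trait, r_threshold, p_threshold)
    gs, mm = gene_scores(log_values, trait, eigengenes, labels)
    core = core_genes(gs, mm, labels, trait_table, gs_min, mm_min)
    return ModuleResult(
        labels=labels, eigengenes=eigengenes,
        trait_r=trait_table["r"], trait_p=trait_table["p"],
        selected=trait_table["selected"], gs=gs, mm=mm, core=core)
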