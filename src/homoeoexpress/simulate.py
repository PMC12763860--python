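"""Synthetic data with planted ground truth for the homoeolog pipeline.

Emulates the three inputs the analysis consumes — a subgenome-resolved
reference panel with A/B anchor pairs, per-species protein alignment hit
tables with controlled identity/coverage tiers and decoy multi-hits, and
TPM expression matrices with planted subgenome-dominance classes, replicate
noise and trait-correlated module blocks — so that every downstream stage
can be tested against known truth.

All generators are deterministic given ``(config, seed)``; per-stream seeds
are derived from ``config.seed`` and a stable CRC of the species label.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .orthologs import DEFAULT_TIERS, TierSpec

__all__ = [
    "SimulationConfig",
    "ReferencePanel",
    "TruthTable",
    "simulate_reference",
    "simulate_hit_table",
    "simulate_expression",
    "write_hit_table",
    "write_lengths",
    "write_expression",
    "write_group_map",
    "write_panel",
    "write_fasta",
]

#: 12-column BLAST tabular (outfmt 6) dialect used throughout.
HIT_COLUMNS = [
    "query_id", "subject_id", "identity_pct", "align_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]


class ConfigError(ValueError):
    """A SimulationConfig field violates its invariant."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic allotetraploid transcriptome.

    Defaults encode the regime the pipeline is designed for: a few hundred
    homoeolog anchor pairs, a tier mix dominated by high-identity orthologs
    with a no-hit tail, a B-biased dominance mix, log-normal baseline TPM
    spanning the bulk dynamic range, modest replicate noise on the log2
    scale, and three co-expression modules of which one is shifted between
    the surface and cave groups.
    """

    n_anchor_pairs: int = 400
    #: P(tier1), P(tier2), P(tier3), P(tier4), P(no hit) per query.
    tier_mix: tuple[float, ...] = (0.4, 0.2, 0.2, 0.1, 0.1)
    decoy_hit_prob: float = 0.3
    n_replicates_per_group: int = 3
    groups: tuple[str, ...] = ("surface", "cave")
    #: P(SubA_dominant), P(SubB_dominant), P(balanced) per anchor pair.
    dominance_mix: tuple[float, float, float] = (0.2, 0.6, 0.2)
    #: Planted |log2 ratio| of dominant pairs: name + parameters. The default
    #: uniform band starts 0.5 log2 units above the classification threshold
    #: so classes are unambiguous noise-free but degradable by noise.
    dominance_fold_distribution: tuple[str, tuple[float, ...]] = (
        "uniform", (math.log2(2.0) + 0.5, math.log2(2.0) + 2.5))
    #: Fold-change threshold the dominant offsets are calibrated against.
    fold_threshold: float = 2.0
    #: Baseline log2-TPM distribution: name + parameters.
    baseline_tpm_distribution: tuple[str, tuple[float, ...]] = ("lognormal", (4.0, 2.0))
    replicate_noise_sd: float = 0.25
    n_modules: int = 3
    module_sizes: tuple[int, ...] = (40, 30, 30)
    #: Per-module log2 shift applied to the second group's samples.
    module_trait_effect: tuple[float, ...] = (2.0, 0.0, 0.0)
    #: Target within-module correlation induced by the shared latent factor.
    module_cor: float = 0.8
    species_labels: tuple[str, ...] = ("surface_sp", "cave_sp1", "cave_sp2")
    seed: int = 0

    def validate(self) -> None:
        if self.n_anchor_pairs < 0:
            raise ConfigError("n_anchor_pairs must be >= 0")
        for name, vec, k in (("tier_mix", self.tier_mix, 5),
                             ("dominance_mix", self.dominance_mix, 3)):
            if len(vec) != k:
                raise ConfigError(f"{name} must have {k} entries")
            if any(p < 0 for p in vec):
                raise ConfigError(f"{name} entries must be >= 0")
            if abs(sum(vec) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {sum(vec)!r})")
        if not 0.0 <= self.decoy_hit_prob <= 1.0:
            raise ConfigError("decoy_hit_prob must lie in [0, 1]")
        if self.n_replicates_per_group < 1:
            raise ConfigError("n_replicates_per_group must be >= 1")
        if len(self.groups) < 1:
            raise ConfigError("groups must be non-empty")
        if self.fold_threshold < 1.0:
            raise ConfigError("fold_threshold must be >= 1")
        if self.replicate_noise_sd < 0:
            raise ConfigError("replicate_noise_sd must be >= 0")
        if not 0.0 <= self.module_cor < 1.0:
            raise ConfigError("module_cor must lie in [0, 1)")
        if self.n_modules != len(self.module_sizes):
            raise ConfigError("module_sizes must have n_modules entries")
        if len(self.module_trait_effect) != self.n_modules:
            raise ConfigError("module_trait_effect must have n_modules entries")
        if any(m < 1 for m in self.module_sizes):
            raise ConfigError("module_sizes entries must be >= 1")
        if sum(self.module_sizes) > 2 * self.n_anchor_pairs:
            raise ConfigError("module_sizes sum exceeds the total gene count")
        lo, hi = self.dominance_fold_distribution[1][:2]
        if self.dominance_fold_distribution[0] == "uniform" and \
                lo < math.log2(self.fold_threshold):
            raise ConfigError(
                "dominance_fold_distribution lower bound must exceed "
                "log2(fold_threshold)")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


@dataclass
class ReferencePanel:
    """Subgenome-resolved reference genes plus A↔B anchor pairs.

    ``genes`` columns: gene_id, subgenome ("A"/"B"), length (aa).
    ``anchors`` columns: anchor_id, ref_a, ref_b.
    """

    genes: pd.DataFrame
    anchors: pd.DataFrame

    @property
    def subgenome_of(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["subgenome"]))

    @property
    def length_of(self) -> dict[str, int]:
        return dict(zip(self.genes["gene_id"], self.genes["length"]))


@dataclass
class TruthTable:
    """Planted truth: one frame per granularity, any of which may be absent.

    queries: query_id, ref_gene ("" if none), tier (0 = no hit), n_hits
    pairs:   anchor_id, dominance_class, log2_ratio (log2 B/A)
    genes:   gene_id, module (0 = none), de_direction ("up"/"down"/"none")
    """

    queries: pd.DataFrame | None = None
    pairs: pd.DataFrame | None = None
    genes: pd.DataFrame | None = None


def _rng(config: SimulationConfig, *streams: str) -> np.random.Generator:
    # CRC-keyed child streams keep species/stage draws independent yet
    # reproducible from the single config seed.
    keys = [zlib.crc32(s.encode()) for s in streams]
    return np.random.default_rng([config.seed & 0x7FFFFFFF, *keys])


def simulate_reference(config: SimulationConfig) -> ReferencePanel:
    """Build a balanced A/B reference panel with one anchor per locus."""
    config.validate()
    rng = _rng(config, "reference")
    n = config.n_anchor_pairs
    lengths = rng.integers(100, 1000, size=2 * n)
    rows, anchors = [], []
    for i in range(n):
        ga, gb = f"refA_{i:05d}", f"refB_{i:05d}"
        rows.append((ga, "A", int(lengths[2 * i])))
        rows.append((gb, "B", int(lengths[2 * i + 1])))
        anchors.append((f"anc_{i:05d}", ga, gb))
    genes = pd.DataFrame(rows, columns=["gene_id", "subgenome", "length"])
    anchors = pd.DataFrame(anchors, columns=["anchor_id", "ref_a", "ref_b"])
    return ReferencePanel(genes=genes, anchors=anchors)


def _tier_bands(tiers: TierSpec) -> list[tuple[float, float, float, float]]:
    """(id_lo, id_hi, cov_lo, cov_hi) per tier; tier 1 capped at 1.0."""
    bands = []
    prev_id, prev_cov = 1.0, 1.0
    for min_id, min_cov in tiers.thresholds:
        bands.append((min_id, prev_id, min_cov, prev_cov))
        prev_id, prev_cov = min_id, min_cov
    return bands


# Margin keeping drawn values strictly inside open tier bands even after the
# 4-decimal percent formatting of the TSV writer.
_BAND_EPS = 1e-4


def simulate_hit_table(
    panel: ReferencePanel,
    config: SimulationConfig,
    species_label: str,
    tiers: TierSpec = DEFAULT_TIERS,
) -> tuple[pd.DataFrame, pd.Series, TruthTable]:
    """Emit a 12-column hit table for one species' queries vs the panel.

    One query per reference gene. The query's true hit draws identity and
    coverage uniformly inside its tier's half-open band, so tier membership
    under strict thresholds is unambiguous; decoy hits have strictly lower
    identity than the true hit and therefore never win best-hit selection.

    Returns (hits frame in BLAST-tabular column layout with identity as a
    percentage, query-length Series, truth table with per-query records).
    """
    config.validate()
    if panel.genes.empty:
        raise ConfigError("panel is degenerate (no genes)")
    bands = _tier_bands(tiers)
    rng = _rng(config, "hits", species_label)

    gene_ids = panel.genes["gene_id"].to_numpy()
    gene_lengths = panel.genes["length"].to_numpy()
    n_q = len(gene_ids)
    tier_draw = rng.choice(len(config.tier_mix), size=n_q, p=config.tier_mix)

    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    qlen = {}
    for i in range(n_q):
        qid = f"{species_label}_q{i:05d}"
        true_ref = gene_ids[i]
        slen = int(gene_lengths[i])
        qlen[qid] = slen
        tier = int(tier_draw[i]) + 1
        if tier == len(config.tier_mix):  # the no-hit slot
            truth_rows.append((qid, "", 0, 0))
            continue
        id_lo, id_hi, cov_lo, cov_hi = bands[tier - 1]
        ident = rng.uniform(id_lo + _BAND_EPS, id_hi - _BAND_EPS)
        cov = rng.uniform(cov_lo + _BAND_EPS, min(cov_hi, 1.0) - _BAND_EPS * (cov_hi < 1.0))
        alen = max(1, math.floor(cov * slen))
        # keep realized coverage strictly above the tier's lower threshold
        while alen / slen <= cov_lo and alen < slen:
            alen += 1
        rows.append(_hit_row(rng, qid, true_ref, ident, alen))
        n_hits = 1
        if rng.random() < config.decoy_hit_prob:
            decoy_ref = _pick_decoy(rng, panel, true_ref)
            d_ident = rng.uniform(0.60, ident - 0.01)
            d_alen = max(1, int(rng.uniform(0.5, 1.0) * slen))
            rows.append(_hit_row(rng, qid, decoy_ref, d_ident, d_alen))
            n_hits = 2
        truth_rows.append((qid, true_ref, tier, n_hits))

    hits = pd.DataFrame(rows, columns=HIT_COLUMNS)
    queries = pd.DataFrame(truth_rows,
                           columns=["query_id", "ref_gene", "tier", "n_hits"])
    lengths = pd.Series(qlen, name="length")
    lengths.index.name = "query_id"
    return hits, lengths, TruthTable(queries=queries)


def _hit_row(rng, qid, sid, identity, alen):
    mism = int(round((1.0 - identity) * alen))
    evalue = 10.0 ** rng.uniform(-30.0, -5.0)
    bits = round(2.0 * alen * identity, 1)
    return (qid, sid, round(identity * 100.0, 4), alen, mism, 0,
            1, alen, 1, alen, evalue, bits)


def _pick_decoy(rng, panel: ReferencePanel, true_ref: str) -> str:
    # Decoys share the true subject's subgenome half the time, to exercise
    # best-hit resolution without corrupting pair-level truth.
    sub = panel.subgenome_of[true_ref]
    want = sub if rng.random() < 0.5 else ("B" if sub == "A" else "A")
    pool = panel.genes.loc[
        (panel.genes["subgenome"] == want) & (panel.genes["gene_id"] != true_ref),
        "gene_id"].to_numpy()
    if len(pool) == 0:
        pool = panel.genes.loc[panel.genes["gene_id"] != true_ref, "gene_id"].to_numpy()
    return str(pool[rng.integers(len(pool))])


def _draw(rng, spec: tuple[str, tuple[float, ...]], size: int) -> np.ndarray:
    name, params = spec
    if name == "uniform":
        return rng.uniform(params[0], params[1], size=size)
    if name == "lognormal":  # parameters on the log2 scale
        return rng.normal(params[0], params[1], size=size)
    raise ConfigError(f"unknown distribution {name!r}")


def simulate_expression(
    panel: ReferencePanel,
    config: SimulationConfig,
    species_label: str = "species",
) -> tuple[pd.DataFrame, pd.Series, TruthTable]:
    """Simulate a TPM matrix (genes × samples) with planted truth.

    Each anchor pair shares a baseline log2 TPM; dominant pairs split a
    planted log2 offset symmetrically between the two copies. Module genes
    share a per-sample latent factor scaled so their pairwise correlation is
    ``module_cor`` given the replicate noise, and the module's trait effect
    shifts the second group's log2 mean. Replicates add N(0, sd) log2 noise.
    """
    config.validate()
    if panel.anchors.empty:
        raise ConfigError("panel has no anchors")
    rng = _rng(config, "expression", species_label)
    n_pairs = len(panel.anchors)
    genes = list(panel.anchors["ref_a"]) + list(panel.anchors["ref_b"])
    # interleave A/B so gene order matches panel reading order
    gene_order = [g for pair in zip(panel.anchors["ref_a"], panel.anchors["ref_b"])
                  for g in pair]

    baseline = _draw(rng, config.baseline_tpm_distribution, n_pairs)
    cls_draw = rng.choice(3, size=n_pairs, p=config.dominance_mix)
    mag = _draw(rng, config.dominance_fold_distribution, n_pairs)
    ratio = np.where(cls_draw == 0, -mag,
                     np.where(cls_draw == 1, mag,
                              rng.uniform(-0.5, 0.5, size=n_pairs)))
    class_names = np.array(["SubA_dominant", "SubB_dominant", "balanced"])

    mean_a = baseline - ratio / 2.0
    mean_b = baseline + ratio / 2.0
    log2_mean = dict(zip(panel.anchors["ref_a"], mean_a))
    log2_mean.update(zip(panel.anchors["ref_b"], mean_b))

    # module memberships drawn without replacement over all genes
    module_of = {g: 0 for g in genes}
    if config.n_modules:
        perm = rng.permutation(len(gene_order))
        pos = 0
        for m, size in enumerate(config.module_sizes, start=1):
            for j in perm[pos:pos + size]:
                module_of[gene_order[j]] = m
            pos += size

    samples = [f"{g}_{r + 1}" for g in config.groups
               for r in range(config.n_replicates_per_group)]
    group_of = pd.Series(
        [g for g in config.groups for _ in range(config.n_replicates_per_group)],
        index=samples, name="group")
    n_s = len(samples)
    is_shifted_group = (group_of == config.groups[-1]).to_numpy().astype(float)

    sd = config.replicate_noise_sd
    rho = config.module_cor
    # The within-module correlation target is marginal: shared variance =
    # trait-shift variance + latent-factor variance. The factor picks up
    # whatever the group shift does not already provide (floored at zero
    # when the shift alone exceeds the target).
    var_t = float(is_shifted_group.var())
    factor_coef = np.zeros(config.n_modules + 1)
    if rho > 0:
        shared_target = sd * sd * rho / (1.0 - rho)
        for m in range(1, config.n_modules + 1):
            eff = config.module_trait_effect[m - 1]
            factor_coef[m] = math.sqrt(
                max(0.0, shared_target - eff * eff * var_t))
    factors = rng.normal(0.0, 1.0, size=(config.n_modules + 1, n_s))

    log2_vals = np.empty((len(gene_order), n_s))
    for gi, g in enumerate(gene_order):
        m = module_of[g]
        mu = log2_mean[g] + is_shifted_group * (
            config.module_trait_effect[m - 1] if m else 0.0)
        shared = factor_coef[m] * factors[m] if m else 0.0
        noise = rng.normal(0.0, sd, size=n_s) if sd > 0 else 0.0
        log2_vals[gi] = mu + shared + noise

    expr = pd.DataFrame(np.exp2(log2_vals), index=pd.Index(gene_order, name="gene_id"),
                        columns=samples)

    pairs_truth = pd.DataFrame({
        "anchor_id": panel.anchors["anchor_id"],
        "dominance_class": class_names[cls_draw],
        "log2_ratio": ratio,
    })
    de_dir = []
    for g in gene_order:
        m = module_of[g]
        eff = config.module_trait_effect[m - 1] if m else 0.0
        de_dir.append("up" if eff > 0 else ("down" if eff < 0 else "none"))
    genes_truth = pd.DataFrame({
        "gene_id": gene_order,
        "module": [module_of[g] for g in gene_order],
        "de_direction": de_dir,
    })
    return expr, group_of, TruthTable(pairs=pairs_truth, genes=genes_truth)


# ---------------------------------------------------------------------------
# plain-text writers


def write_hit_table(hits: pd.DataFrame, path) -> None:
    """12-column tab-separated hit table, no header (outfmt-6 convention)."""
    hits.to_csv(path, sep="\t", header=False, index=False,
                float_format="%.6g")


def write_lengths(lengths: pd.Series, path) -> None:
    lengths.to_csv(path, sep="\t", header=False)


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", float_format="%.6f")


def write_group_map(groups: pd.Series, path) -> None:
    groups.to_csv(path, sep="\t", header=False)


def write_panel(panel: ReferencePanel, genes_path, anchors_path) -> None:
    panel.genes.to_csv(genes_path, sep="\t", index=False)
    panel.anchors.to_csv(anchors_path, sep="\t", index=False)


def write_truth(truth: TruthTable, prefix) -> None:
    for name in ("queries", "pairs", "genes"):
        frame = getattr(truth, name)
        if frame is not None:
            frame.to_csv(f"{prefix}_{name}.tsv", sep="\t", index=False)


def write_fasta(panel: ReferencePanel, path, config: SimulationConfig) -> None:
    """Dummy peptide FASTA for the panel (uniform-random residues)."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    rng = _rng(config, "fasta")
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    records = []
    for gene_id, _, length in panel.genes.itertuples(index=False):
        seq = "".join(rng.choice(alphabet, size=int(length)))
        records.append(SeqRecord(Seq(seq), id=gene_id, description=""))
    seqio_write(records, path, "fasta")
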