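"""Synthetic multi-study data with planted signal.

Generates every input the pipeline consumes: k small two-group miRNA studies
sharing planted effects with between-study heterogeneity and MCAR missing
values; mRNA validation studies whose true DEGs include targets of the planted
miRNAs; a validated-interaction table; GMT gene-set collections with one
planted enriched term; a protein-interaction edge list with a designated hub;
and an exponential survival table with a configurable group log-hazard ratio.

The ground truth of every planted signal is returned alongside the data so
recovery can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SynthConfig
from .studies import ExpressionStudy

SOURCE_DBS = ("mirtarbase", "tarbase", "mirecords")
DECOY_PREFIXES = ("mmu", "rno")

BASELINE_MEAN = 7.0   # typical log2 intensity centre
BASELINE_SD = 1.5     # spread of per-feature baselines


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named, seed-stable substream: one root seed drives every generator."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(stream.encode())])


@dataclass
class GroundTruth:
    """Oracle bookkeeping for planted signal.

    ``de_features`` maps each planted miRNA to its true mean effect (``mu``)
    and the per-study realised effects (``per_study``).  ``target_map`` holds
    the planted miRNA->gene pairs; ``de_genes`` the true DEG set of each mRNA
    study (filled by :func:`generate_mrna_studies`); ``gene_effects`` the true
    signed gene effects.  ``enriched_term_id`` and ``hub_gene`` identify the
    planted enrichment term and network hub.
    """

    de_features: dict = field(default_factory=dict)
    target_map: dict = field(default_factory=dict)
    de_genes: dict = field(default_factory=dict)
    gene_effects: dict = field(default_factory=dict)
    enriched_term_id: str | None = None
    hub_gene: str | None = None

    @property
    def planted_dems(self) -> set:
        return set(self.de_features)

    @property
    def planted_targets(self) -> set:
        return set().union(*self.target_map.values()) if self.target_map else set()

    @property
    def true_deg_union(self) -> set:
        return set().union(*self.de_genes.values()) if self.de_genes else set()


# ---------------------------------------------------------------------------
# miRNA studies
# ---------------------------------------------------------------------------
def _mirna_ids(cfg: SynthConfig, rng: np.random.Generator) -> list[str]:
    n_decoy = int(round(cfg.decoy_fraction * cfg.n_features))
    decoy_idx = set(rng.choice(cfg.n_features, size=n_decoy, replace=False).tolist())
    ids = []
    for i in range(cfg.n_features):
        if i in decoy_idx:
            prefix = DECOY_PREFIXES[i % len(DECOY_PREFIXES)]
        else:
            prefix = "hsa"
        ids.append(f"{prefix}-miR-{i + 1}-5p")
    return ids


def generate_mirna_studies(cfg: SynthConfig) -> tuple[list[ExpressionStudy], GroundTruth]:
    """Simulate ``cfg.k_studies`` two-group miRNA matrices with planted DEMs.

    Null features are N(baseline, sigma2) in both groups.  For each planted
    miRNA the resistant-minus-control shift realised in study *s* is drawn as
    theta_s ~ N(+-mu_effect, tau2), i.e. a random-effects structure with
    between-study variance tau2.  Missing cells are MCAR at ``missing_rate``.
    """
    if cfg.samples_per_group < 2:
        raise ValueError("samples_per_group must be >= 2")
    rng = _rng(cfg.seed, "mirna")
    feature_ids = _mirna_ids(cfg, rng)
    hsa_ids = [f for f in feature_ids if f.startswith("hsa")]
    if cfg.n_true_de > len(hsa_ids):
        raise ValueError("not enough human features to plant n_true_de DEMs")

    planted = list(rng.choice(hsa_ids, size=cfg.n_true_de, replace=False))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_true_de)
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=cfg.n_features)
    baseline_map = dict(zip(feature_ids, baselines))

    truth = GroundTruth()
    for fid, sgn in zip(planted, signs):
        truth.de_features[fid] = {"mu": float(sgn * cfg.mu_effect), "per_study": {}}

    # plant targets now so the miRNA -> gene causal chain exists from the start
    gene_pool = [f"GENE{i + 1}" for i in range(cfg.n_genes)]
    for fid in planted:
        n_targets = max(1, int(rng.poisson(cfg.target_density)))
        genes = rng.choice(gene_pool, size=min(n_targets, cfg.n_genes), replace=False)
        truth.target_map[fid] = set(genes.tolist())

    n = cfg.samples_per_group
    studies = []
    for s in range(cfg.k_studies):
        study_id = f"miR_study_{s + 1}"
        effects = np.zeros(cfg.n_features)
        for i, fid in enumerate(feature_ids):
            if fid in truth.de_features:
                theta = rng.normal(truth.de_features[fid]["mu"], np.sqrt(cfg.tau2))
                truth.de_features[fid]["per_study"][study_id] = float(theta)
                effects[i] = theta
        noise = rng.normal(0.0, np.sqrt(cfg.sigma2), size=(cfg.n_features, 2 * n))
        mat = baselines[:, None] + noise
        mat[:, :n] += effects[:, None]  # first n columns are resistant
        sample_ids = [f"{study_id}_R{j + 1}" for j in range(n)] + [
            f"{study_id}_C{j + 1}" for j in range(n)
        ]
        groups = pd.Series(
            ["resistant"] * n + ["control"] * n, index=sample_ids, name="group"
        )
        if cfg.missing_rate > 0:
            mask = rng.random(mat.shape) < cfg.missing_rate
            # never blank out a feature entirely
            full = mask.all(axis=1)
            mask[full, 0] = False
            mat = np.where(mask, np.nan, mat)
        log_scale = True
        if cfg.raw_scale:
            mat = np.power(2.0, mat)
            log_scale = False
        values = pd.DataFrame(mat, index=feature_ids, columns=sample_ids)
        studies.append(
            ExpressionStudy(
                values=values,
                groups=groups,
                platform=f"SYNTH_PLATFORM_{s + 1}",
                log_scale=log_scale,
                study_id=study_id,
            )
        )
    _ = baseline_map  # kept for clarity; baselines indexed positionally above
    return studies, truth


# ---------------------------------------------------------------------------
# mRNA studies
# ---------------------------------------------------------------------------
def generate_mrna_studies(cfg: SynthConfig, truth: GroundTruth) -> list[ExpressionStudy]:
    """Simulate mRNA validation studies whose DEGs include planted targets.

    A fraction ``target_de_fraction`` of the planted target genes are made
    truly DE with sign opposite the planting miRNA (repression), each in a
    random non-empty subset of the studies; independent DE genes and nulls
    fill out the matrix.
    """
    rng = _rng(cfg.seed, "mrna")
    gene_ids = [f"GENE{i + 1}" for i in range(cfg.n_genes)]
    gene_set = set(gene_ids)
    unknown = truth.planted_targets - gene_set
    if unknown:
        raise ValueError(f"ground truth references unknown gene ids: {sorted(unknown)[:5]}")

    targets = sorted(truth.planted_targets)
    n_de_targets = int(round(cfg.target_de_fraction * len(targets)))
    de_targets = list(rng.choice(targets, size=n_de_targets, replace=False)) if n_de_targets else []

    # sign opposite the (mean) effect of the miRNAs that target the gene
    gene_sign: dict[str, float] = {}
    for g in de_targets:
        mus = [
            truth.de_features[m]["mu"]
            for m, genes in truth.target_map.items()
            if g in genes
        ]
        gene_sign[g] = -np.sign(np.mean(mus)) or -1.0

    non_targets = sorted(gene_set - set(targets))
    indep = list(
        rng.choice(non_targets, size=min(cfg.n_independent_de, len(non_targets)), replace=False)
    )
    for g in indep:
        gene_sign[g] = float(rng.choice([-1.0, 1.0]))

    truth.gene_effects = {g: s * cfg.mrna_effect for g, s in gene_sign.items()}

    study_ids = [f"mRNA_study_{s + 1}" for s in range(cfg.k_mrna_studies)]
    membership: dict[str, list[str]] = {sid: [] for sid in study_ids}
    for g in list(gene_sign):
        include = rng.random(cfg.k_mrna_studies) < cfg.study_inclusion_prob
        if not include.any():
            include[rng.integers(cfg.k_mrna_studies)] = True
        for sid, inc in zip(study_ids, include):
            if inc:
                membership[sid].append(g)
    truth.de_genes = {sid: set(genes) for sid, genes in membership.items()}

    n = cfg.samples_per_group
    baselines = rng.normal(BASELINE_MEAN, BASELINE_SD, size=cfg.n_genes)
    studies = []
    for sid in study_ids:
        effects = np.zeros(cfg.n_genes)
        de_here = truth.de_genes[sid]
        for i, g in enumerate(gene_ids):
            if g in de_here:
                effects[i] = truth.gene_effects[g]
        noise = rng.normal(0.0, np.sqrt(cfg.sigma2), size=(cfg.n_genes, 2 * n))
        mat = baselines[:, None] + noise
        mat[:, :n] += effects[:, None]
        sample_ids = [f"{sid}_R{j + 1}" for j in range(n)] + [
            f"{sid}_C{j + 1}" for j in range(n)
        ]
        groups = pd.Series(
            ["resistant"] * n + ["control"] * n, index=sample_ids, name="group"
        )
        values = pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
        studies.append(
            ExpressionStudy(
                values=values,
                groups=groups,
                platform="SYNTH_MRNA",
                log_scale=True,
                study_id=sid,
            )
        )
    return studies


# ---------------------------------------------------------------------------
# interaction table, gene sets, PPI edges, survival
# ---------------------------------------------------------------------------
def generate_interactions(truth: GroundTruth, cfg: SynthConfig) -> pd.DataFrame:
    """Interaction table containing all planted pairs plus random decoys."""
    rng = _rng(cfg.seed, "interactions")
    rows = []
    for mirna in sorted(truth.target_map):
        for gene in sorted(truth.target_map[mirna]):
            src = SOURCE_DBS[rng.integers(len(SOURCE_DBS))]
            rows.append((mirna, gene, src, 1))
    planted_pairs = {(m, g) for m, g, _, _ in rows}

    mirna_pool = [f"hsa-miR-{i + 1}-5p" for i in range(cfg.n_features)]
    gene_pool = [f"GENE{i + 1}" for i in range(cfg.n_genes)]
    seen = set(planted_pairs)
    added = 0
    while added < cfg.n_decoy_interactions:
        m = mirna_pool[rng.integers(len(mirna_pool))]
        g = gene_pool[rng.integers(len(gene_pool))]
        if (m, g) in seen:
            continue
        seen.add((m, g))
        src = SOURCE_DBS[rng.integers(len(SOURCE_DBS))]
        rows.append((m, g, src, int(rng.random() < 0.7)))
        added += 1
    return pd.DataFrame(rows, columns=["mirna_id", "gene_symbol", "source_db", "validated"])


def generate_genesets(
    cfg: SynthConfig,
    truth: GroundTruth,
    planted_fraction: float = 0.8,
) -> list[tuple[str, str, str, frozenset]]:
    """Gene-set collection with one term enriched for the planted target-DEGs.

    The planted term contains ``planted_fraction`` of the genes that are both
    planted targets and true DEGs, topped up with random genes; decoy terms
    are random subsets of the gene universe.
    """
    rng = _rng(cfg.seed, "genesets")
    gene_pool = [f"GENE{i + 1}" for i in range(cfg.n_genes)]
    overlap_genes = sorted(truth.planted_targets & truth.true_deg_union)
    if not overlap_genes:
        raise ValueError("no planted target-DEGs; generate mRNA studies first")

    n_in = max(1, int(round(planted_fraction * len(overlap_genes))))
    inside = list(rng.choice(overlap_genes, size=n_in, replace=False))
    others = sorted(set(gene_pool) - set(inside))
    filler = list(rng.choice(others, size=min(10, len(others)), replace=False))
    planted_term = ("GO:0000001", "planted resistance response", "BP",
                    frozenset(inside + filler))
    truth.enriched_term_id = planted_term[0]

    categories = ["BP", "MF", "CC", "pathway"]
    terms = [planted_term]
    for t in range(cfg.n_random_terms):
        size = int(rng.integers(10, 51))
        genes = frozenset(rng.choice(gene_pool, size=size, replace=False).tolist())
        cat = categories[t % len(categories)]
        if cat == "pathway":
            tid = f"hsa{t + 2:05d}"
        else:
            tid = f"GO:{t + 2:07d}"
        terms.append((tid, f"synthetic term {t + 2}", cat, genes))
    return terms


def generate_edgelist(cfg: SynthConfig, truth: GroundTruth, edge_prob: float = 0.1) -> pd.DataFrame:
    """STRING-style edge list over the planted target genes with one hub.

    The hub is wired to every other node, so its degree is strictly maximal.
    """
    rng = _rng(cfg.seed, "edges")
    nodes = sorted(truth.planted_targets)
    if len(nodes) < 3:
        raise ValueError("need >= 3 planted target genes to build a network")
    hub = nodes[int(rng.integers(len(nodes)))]
    truth.hub_gene = hub
    others = [g for g in nodes if g != hub]
    rows = [(hub, g, float(np.round(rng.uniform(0.6, 0.999), 3))) for g in others]
    for i in range(len(others)):
        for j in range(i + 1, len(others)):
            if rng.random() < edge_prob:
                rows.append(
                    (others[i], others[j], float(np.round(rng.uniform(0.4, 0.999), 3)))
                )
    df = pd.DataFrame(rows, columns=["node_a", "node_b", "score"])
    # keep the hub strictly maximal even in dense draws
    deg = pd.concat([df["node_a"], df["node_b"]]).value_counts()
    hub_deg = deg[hub]
    for node, d in deg.items():
        if node != hub and d >= hub_deg:
            drop = df[
                (df["node_a"] != hub) & (df["node_b"] != hub)
                & ((df["node_a"] == node) | (df["node_b"] == node))
            ].index[: d - hub_deg + 1]
            df = df.drop(drop)
    return df.reset_index(drop=True)


def generate_survival(
    cfg: SynthConfig,
    truth: GroundTruth | None = None,
    beta: float | None = None,
) -> pd.DataFrame:
    """Exponential survival table with a planted group log-hazard ratio.

    Expression is standard normal; the high-expression half (above the
    median) has hazard ``base_hazard * exp(beta)``; censoring is uniform
    administrative censoring on [0, followup].
    """
    rng = _rng(cfg.seed, "survival")
    beta = cfg.survival_beta if beta is None else beta
    n = cfg.n_survival
    expr = rng.normal(size=n)
    high = expr > np.median(expr)
    hazard = cfg.base_hazard * np.exp(beta * high.astype(float))
    event_time = rng.exponential(1.0 / hazard)
    censor_time = rng.uniform(0.0, cfg.followup, size=n)
    time = np.minimum(event_time, censor_time)
    event = (event_time <= censor_time).astype(int)
    time = np.maximum(time, 1e-6)  # strictly positive times
    return pd.DataFrame(
        {
            "sample_id": [f"patient_{i + 1}" for i in range(n)],
            "time": time,
            "event": event,
            "expression": expr,
        }
    )
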