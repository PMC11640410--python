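"""Configuration dataclasses for the synthetic generator and the pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class SynthConfig:
    """Parameters of the synthetic multi-study generator.

    The defaults describe a small multi-platform miRNA meta-analysis: three
    two-group studies of modest size, strong planted log2 effects with mild
    between-study heterogeneity, moderate array noise, and a low rate of
    completely-at-random missing values.

    Attributes
    ----------
    n_features : number of miRNA features per study.
    n_true_de : number of planted differentially expressed miRNAs (DEMs).
    k_studies : number of miRNA studies (distinct platforms).
    samples_per_group : samples in each of the resistant / control arms.
    mu_effect : mean planted effect, log2 units (sign randomised per feature).
    tau2 : between-study variance of the realised per-study effects (log2^2).
    sigma2 : within-study measurement noise variance (log2^2).
    missing_rate : MCAR missing-cell fraction in the miRNA matrices.
    decoy_fraction : fraction of features given a non-"hsa" species prefix.
    target_density : mean number of planted target genes per planted DEM.
    n_genes : size of the gene vocabulary for the mRNA studies.
    k_mrna_studies : number of mRNA validation studies.
    target_de_fraction : fraction of planted target genes made truly DE.
    n_independent_de : truly DE genes unrelated to any planted miRNA.
    study_inclusion_prob : probability a true DE gene is DE in a given study.
    mrna_effect : |log2 FC| of true DE genes in the mRNA studies.
    n_random_terms : decoy gene-set terms in the synthetic GMT collection.
    n_decoy_interactions : decoy rows in the interaction table.
    n_survival : subjects in the synthetic survival table.
    survival_beta : log hazard ratio of the high-expression group.
    base_hazard : baseline exponential hazard (events per month).
    followup : administrative censoring horizon, months.
    raw_scale : emit 2**x intensities with log_scale False (exercises log2).
    seed : root seed; every generator draws from a named substream of it.
    """

    n_features: int = 300
    n_true_de: int = 20
    k_studies: int = 3
    samples_per_group: int = 10
    mu_effect: float = 2.0
    tau2: float = 0.05
    sigma2: float = 0.25
    missing_rate: float = 0.05
    decoy_fraction: float = 0.10
    target_density: float = 4.0
    n_genes: int = 1000
    k_mrna_studies: int = 3
    target_de_fraction: float = 0.9
    n_independent_de: int = 30
    study_inclusion_prob: float = 0.7
    mrna_effect: float = 2.0
    n_random_terms: int = 50
    n_decoy_interactions: int = 200
    n_survival: int = 200
    survival_beta: float = 0.6931471805599453  # ln 2
    base_hazard: float = 0.02
    followup: float = 120.0
    raw_scale: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_true_de > self.n_features:
            raise ValueError("n_true_de cannot exceed n_features")
        if self.tau2 < 0:
            raise ValueError("tau2 must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not 0 <= self.decoy_fraction < 1:
            raise ValueError("decoy_fraction must lie in [0, 1)")
        if self.samples_per_group < 2:
            raise ValueError("samples_per_group must be >= 2 (variance undefined)")
        if not 0 <= self.target_de_fraction <= 1:
            raise ValueError("target_de_fraction must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SynthConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown synth config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class RunConfig:
    """Thresholds, model policy and stage options for a full pipeline run."""

    synth: SynthConfig = field(default_factory=SynthConfig)
    alpha: float = 0.05
    lfc_cut: float = 1.0
    kappa: float = 0.96
    min_score: float = 0.4
    model: str = "random"          # "random" | "q-gated"
    effect: str = "lfc"            # "lfc" | "smd"
    impute_method: str = "ridge"   # "rf" | "ridge" | "mean"
    enrich_method: str = "bonferroni"
    split_rule: str = "median"
    top_hubs: int = 10
    make_plots: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise ValueError("alpha must lie in [0, 1]")
        if self.lfc_cut is not None and self.lfc_cut < 0:
            raise ValueError("lfc_cut must be >= 0")
        if not -1 <= self.kappa <= 1.01:
            raise ValueError("kappa threshold outside a sensible range")
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must lie in [0, 1]")
        if self.model not in ("random", "q-gated"):
            raise ValueError("model must be 'random' or 'q-gated'")
        if isinstance(self.synth, dict):
            self.synth = SynthConfig.from_dict(self.synth)
        # one root seed drives every stage
        self.synth.seed = self.seed

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
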