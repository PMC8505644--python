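"""Synthetic cohort generator with the statistical structure the pipeline assumes.

No raw cohort data are deposited for this study design, so the generator
builds a stand-in with the same shape: 20 DST non-suppressors vs 73
suppressors, 76 candidate CpG probes spread over transcripts of the six
HPA-axis genes, clinical covariates drawn at the published group means/SDs,
and optional planted hypermethylation on chosen transcripts.

The generative model is logit-normal: per-probe M-values are sampled as
baseline + group effect (cases only) + N(0, noise_sd), then inverse-logit2
transformed, so betas are strictly inside (0, 1) and planted effects are
additive on the M scale — the scale the analysis models. A ground-truth
record accompanies every cohort for parameter-recovery tests. Everything is
reproducible from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MethylationMatrix

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_expression_cohort",
    "generate_paired_cohort",
    "DEFAULT_TRANSCRIPTS",
    "COVARIATE_DEFAULTS",
    "BINARY_DEFAULTS",
]

#: (gene, transcript, probe count) for the candidate panel; 76 probes total.
#: The NR3C1/AJ877169 2-probe and CRHR2/EU012442 14-probe transcripts mirror
#: the structures the enrichment stage must be able to resolve.
DEFAULT_TRANSCRIPTS = [
    ("CRH", "NM_000756", 6),
    ("CRHBP", "NM_001882", 8),
    ("CRHR1", "EU012435", 10),
    ("CRHR1", "NM_004382", 8),
    ("CRHR2", "EU012442", 14),
    ("CRHR2", "NM_001883", 6),
    ("FKBP5", "NM_004117", 12),
    ("NR3C1", "AJ877169", 2),
    ("NR3C1", "NM_000176", 10),
]

#: Continuous clinical covariates: name -> ((case mean, case SD), (control mean, control SD)).
COVARIATE_DEFAULTS = {
    "age": ((37.4, 12.1), (39.0, 11.6)),
    "ctq_total": ((37.2, 13.4), (37.8, 11.2)),
    "tsh_t4": ((0.017, 0.0099), (0.023, 0.02333)),
    "hba1c": ((31.7, 2.9), (33.2, 5.5)),
    "cortisol_baseline": ((515.2, 147.2), (458.5, 133.5)),
    "cortisol_dst": ((225.8, 92.5), (50.6, 34.2)),
    "acth_baseline": ((5.94, 2.32), (6.23, 3.19)),
    "acth_dst": ((3.17, 1.79), (1.45, 1.08)),
    "testosterone": ((13.9, 4.1), (14.1, 5.7)),
    "tnf_alpha": ((6.9, 2.1), (6.7, 2.2)),
    "il6": ((2.03, 0.12), (2.30, 0.98)),
}

#: Binary covariates: name -> (case prevalence, control prevalence).
BINARY_DEFAULTS = {
    "hypersexuality": (0.85, 0.589),
    "depression": (0.15, 0.082),
}

#: Genes outside the candidate panel used for background annotation rows.
_BACKGROUND_GENES = ["BDNF", "OXTR", "SLC6A4", "COMT", "MAOA", "HTR2A"]


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults reproduce the discovery-cohort structure: 20 cases vs 73
    controls, 76 candidate probes, covariates at the published group
    means/SDs, and a residual M-value SD of 0.5 (a typical within-group
    spread for array M-values). ``planted_effects`` maps transcript id to a
    per-probe mean M-shift added to cases.
    """

    n_cases: int = 20
    n_controls: int = 73
    transcripts: list = field(default_factory=lambda: list(DEFAULT_TRANSCRIPTS))
    n_background_transcripts: int = 4
    planted_effects: dict = field(default_factory=dict)
    covariate_spec: dict = field(default_factory=lambda: dict(COVARIATE_DEFAULTS))
    binary_spec: dict = field(default_factory=lambda: dict(BINARY_DEFAULTS))
    noise_sd: float = 0.5
    baseline_m_range: tuple = (-3.0, 3.0)
    background_noise_sd_range: tuple = (1.0, 3.0)
    background_baseline_m_range: tuple = (-1.0, 1.0)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("each group needs at least 2 samples")
        if not self.transcripts:
            raise ValueError("need at least one transcript")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        for name, (pc, pk) in self.binary_spec.items():
            if not (0 <= pc <= 1 and 0 <= pk <= 1):
                raise ValueError(f"prevalence for {name!r} outside [0, 1]")
        unknown = set(self.planted_effects) - {t for _, t, _ in self.transcripts}
        if unknown:
            raise ValueError(f"planted effects on unknown transcripts: {sorted(unknown)}")

    @property
    def n_probes(self) -> int:
        return sum(k for _, _, k in self.transcripts)


@dataclass
class GroundTruth:
    """What was planted: per-probe M-shift, planted transcripts, expression rho."""

    probe_effects: pd.Series
    planted_transcripts: frozenset
    expression_rho: float | None = None


def _candidate_annotation(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    i = 0
    for gene, transcript, k in config.transcripts:
        for _ in range(k):
            rows.append(
                {
                    "probe_id": f"cg{i:08d}",
                    "gene": gene,
                    "transcript": transcript,
                    "tss_distance": int(rng.integers(-2000, 2001)),
                }
            )
            i += 1
    for j in range(config.n_background_transcripts):
        gene = _BACKGROUND_GENES[j % len(_BACKGROUND_GENES)]
        for _ in range(5):
            rows.append(
                {
                    "probe_id": f"cg{i:08d}",
                    "gene": gene,
                    "transcript": f"BG_{gene}_{j:02d}",
                    "tss_distance": int(rng.integers(-5000, 5001)),
                }
            )
            i += 1
    return pd.DataFrame(rows)


def generate_cohort(config: CohortConfig):
    """Draw one synthetic cohort.

    Returns ``(beta, pheno, annotation, truth)``: a beta-scale
    :class:`MethylationMatrix`, a phenotype table indexed by sample id, a
    probe annotation (candidate panel plus background rows) and the
    :class:`GroundTruth`.
    """
    rng = np.random.default_rng(config.seed)
    ann = _candidate_annotation(config, rng)
    n = config.n_cases + config.n_controls
    samples = pd.Index([f"S{i:03d}" for i in range(n)], name="sample_id")
    group = np.array([1] * config.n_cases + [0] * config.n_controls)

    # per-probe effects: planted transcript shifts apply to candidate probes
    probe_ids = ann["probe_id"]
    effects = pd.Series(0.0, index=probe_ids)
    for transcript, shift in config.planted_effects.items():
        effects[ann.loc[ann["transcript"] == transcript, "probe_id"]] = shift

    # candidate rows precede background rows; background probes get wider
    # per-probe variability and mid-range baselines so the genome-wide-style
    # variability filter of the QC stage has probes to work with
    n_cand = config.n_probes
    n_bg = len(probe_ids) - n_cand
    baseline = np.concatenate(
        [
            rng.uniform(*config.baseline_m_range, size=n_cand),
            rng.uniform(*config.background_baseline_m_range, size=n_bg),
        ]
    )
    probe_sd = np.concatenate(
        [
            np.full(n_cand, config.noise_sd),
            rng.uniform(*config.background_noise_sd_range, size=n_bg),
        ]
    )
    noise = rng.normal(0.0, 1.0, size=(len(probe_ids), n)) * probe_sd[:, None]
    m_vals = baseline[:, None] + np.outer(effects.to_numpy(), group) + noise
    beta_vals = np.exp2(m_vals) / (1 + np.exp2(m_vals))
    if config.missing_rate > 0:
        mask = rng.random(beta_vals.shape) < config.missing_rate
        beta_vals = np.where(mask, np.nan, beta_vals)
    beta = MethylationMatrix(
        pd.DataFrame(beta_vals, index=pd.Index(probe_ids, name="probe_id"), columns=samples),
        scale="beta",
    )

    pheno = pd.DataFrame(index=samples)
    pheno["dst_ns"] = group
    for name, (p_case, p_ctrl) in config.binary_spec.items():
        prob = np.where(group == 1, p_case, p_ctrl)
        pheno[name] = (rng.random(n) < prob).astype(int)
    for name, ((mc, sc), (mk, sk)) in config.covariate_spec.items():
        mu = np.where(group == 1, mc, mk)
        sd = np.where(group == 1, sc, sk)
        pheno[name] = rng.normal(mu, sd)

    truth = GroundTruth(
        probe_effects=effects,
        planted_transcripts=frozenset(config.planted_effects),
    )
    return beta, pheno, ann, truth


def generate_expression_cohort(n: int, rho: float, seed: int):
    """Bivariate-normal (M-value, expression) pairs at population correlation rho."""
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if not -1 < rho < 1:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    cov = [[1.0, rho], [rho, 1.0]]
    draws = rng.multivariate_normal([0.0, 0.0], cov, size=n, method="cholesky")
    return draws[:, 0], draws[:, 1]


def generate_paired_cohort(
    annotation: pd.DataFrame,
    n: int,
    rho: float,
    seed: int,
    probe_noise_sd: float = 0.3,
):
    """Paired methylation + expression matrices for the correlation stage.

    Per transcript, a latent per-sample factor and the gene's expression are
    drawn bivariate normal at correlation ``rho``; every probe of the
    transcript is that factor plus its own baseline and N(0, probe_noise_sd)
    noise, so the transcript-average M-value correlates with expression at
    roughly rho (attenuated by the probe noise). Returns an M-scale
    :class:`MethylationMatrix` and a genes x samples expression DataFrame.
    """
    if n < 3:
        raise ValueError("need n >= 3 samples")
    if not -1 < rho < 1:
        raise ValueError("rho must lie strictly inside (-1, 1)")
    rng = np.random.default_rng(seed)
    samples = pd.Index([f"E{i:03d}" for i in range(n)], name="sample_id")
    m_rows, m_index = [], []
    expr: dict = {}
    for gene, gene_grp in annotation.groupby("gene", sort=False):
        e = rng.normal(size=n)
        expr[gene] = e
        for _, grp in gene_grp.groupby("transcript", sort=False):
            latent = rho * e + np.sqrt(1 - rho**2) * rng.normal(size=n)
            for probe in grp["probe_id"]:
                base = rng.uniform(-3, 3)
                m_rows.append(base + latent + rng.normal(0, probe_noise_sd, size=n))
                m_index.append(probe)
    meth = MethylationMatrix(
        pd.DataFrame(np.array(m_rows), index=pd.Index(m_index, name="probe_id"), columns=samples),
        scale="M",
    )
    expr_df = pd.DataFrame(expr, index=samples).T
    expr_df.columns = samples
    return meth, expr_df
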