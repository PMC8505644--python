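"""End-to-end orchestration: simulate -> QC -> table1 -> covariate selection
-> differential methylation -> enrichment -> expression correlation -> post-hoc.

Every stage writes a TSV with a stable column contract and the run manifest
records the counts at each filter step, so a run can be audited from its
output directory alone. All randomness flows from the single seed in the
config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import CandidatePanel, select_candidate_probes, transcript_probe_map
from .cohortstats import table1
from .covselect import DEFAULT_CANDIDATES, forward_select
from .ebayes import run_dmp
from .enrichment import run_enrichment
from .exprcorr import correlate_cohort
from .posthoc import SeparationError, interaction_linear, interaction_logistic
from .preprocess import MethylationMatrix, beta_to_m, pca_outlier_flags
from .synthetic_cohort import CohortConfig, generate_cohort, generate_paired_cohort

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline settings; defaults reproduce the study conditions."""

    out_dir: str = "hpameth_run"
    seed: int = 0
    panel_genes: tuple = ("CRH", "CRHBP", "CRHR1", "CRHR2", "FKBP5", "NR3C1")
    window_bp: int = 2000
    alpha_nominal: float = 0.05
    alpha_covariate: float = 0.10
    sided: str = "two-sided"
    sd_threshold: float = 0.2
    ref_range: float = 0.95
    drop_outliers: bool = True
    planted_effects: dict = field(default_factory=lambda: {"AJ877169": 1.0})
    noise_sd: float = 0.5
    expression_rho: float = 0.7
    expression_cohorts: dict = field(
        default_factory=lambda: {"cohort-A": 11, "cohort-B": 10}
    )

    def __post_init__(self) -> None:
        for a in (self.alpha_nominal, self.alpha_covariate):
            if not 0 < a < 1:
                raise ValueError("alpha levels must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on a synthetic cohort; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    manifest: dict = {"version": __version__, "seed": config.seed, "stages": [], "warnings": []}

    def stage(name: str, **info) -> None:
        manifest["stages"].append({"name": name, **info})

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        # 1. simulate
        cohort_cfg = CohortConfig(
            planted_effects=dict(config.planted_effects),
            noise_sd=config.noise_sd,
            seed=int(rng.integers(2**31)),
        )
        beta, pheno, ann, truth = generate_cohort(cohort_cfg)
        beta.to_tsv(out / "beta.tsv")
        pheno.to_csv(out / "pheno.csv")
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        stage("simulate", n_samples=int(beta.values.shape[1]), n_probes_total=int(beta.values.shape[0]))

        # 2. preprocess: QC then M-values
        report = pca_outlier_flags(beta, config.sd_threshold, config.ref_range)
        report.to_frame().to_csv(out / "outliers.tsv", sep="\t")
        kept = (
            beta.sample_ids[~report.flags.to_numpy()] if config.drop_outliers else beta.sample_ids
        )
        beta_kept = MethylationMatrix(beta.values.loc[:, kept], scale="beta")
        m = beta_to_m(beta_kept)
        m.to_tsv(out / "m_values.tsv")
        pheno = pheno.loc[kept]
        stage(
            "preprocess",
            pc1_variance_pct=report.pc1_variance_pct,
            probes_used=report.probes_used,
            n_flagged=report.n_flagged,
            n_samples_kept=len(kept),
        )

        # 3. candidate selection
        panel = CandidatePanel(frozenset(config.panel_genes), config.window_bp)
        candidates = select_candidate_probes(ann, panel)
        candidates.to_csv(out / "candidates.tsv", sep="\t", index=False)
        m_cand = m.subset_probes(candidates["probe_id"].unique())
        stage("annotation", probes_in=len(ann), candidates=len(candidates))

        # 4. table 1
        t1 = table1(
            pheno,
            "dst_ns",
            continuous=[c for c in pheno.columns if c not in ("dst_ns", "hypersexuality", "depression")],
            categorical=["hypersexuality", "depression"],
        )
        t1.to_csv(out / "table1.tsv", sep="\t", index=False)
        stage("table1", n_variables=len(t1))

        # 5. covariate selection for the DST model
        cand_cols = [c for c in DEFAULT_CANDIDATES if c in pheno.columns]
        trace = forward_select(
            pheno["dst_ns"].to_numpy(float), pheno[cand_cols], alpha=config.alpha_covariate
        )
        trace.steps.to_csv(out / "covselect.tsv", sep="\t", index=False)
        stage("covselect", selected=trace.selected)

        # 6. differential methylation (DST preset)
        dmp = run_dmp(m_cand, None, pheno, preset="dst")
        dmp.to_csv(out / "dmp.tsv", sep="\t", index_label="probe_id")
        n_nominal = int((dmp["p"] < config.alpha_nominal).sum())
        stage(
            "dmp",
            modelled=len(dmp),
            dropped_for_missingness=int(dmp.attrs["n_dropped_missing"]),
            nominally_significant=n_nominal,
            prior_df=float(dmp.attrs["prior_df"]),
        )

        # 7. enrichment
        enr = run_enrichment(dmp, candidates, config.alpha_nominal, config.sided)
        enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        flagged = enr.loc[enr["significant"], "transcript"].tolist()
        stage("enrichment", transcripts_tested=len(enr), flagged_transcripts=flagged)

        # 8. expression correlation in independent synthetic cohorts
        mapping = transcript_probe_map(candidates)
        corr_frames = []
        for label, n in config.expression_cohorts.items():
            meth_e, expr_e = generate_paired_cohort(
                candidates, n, config.expression_rho, int(rng.integers(2**31))
            )
            corr_frames.append(correlate_cohort(meth_e, expr_e, mapping, label))
        corr = pd.concat(corr_frames, ignore_index=True)
        corr.to_csv(out / "exprcorr.tsv", sep="\t", index=False)
        stage("exprcorr", rows=len(corr))

        # 9. post-hoc interaction models on the flagged transcripts' probes
        post_rows = []
        probes_ph = candidates.loc[candidates["transcript"].isin(flagged), "probe_id"].unique()
        for probe in probes_ph:
            cg = m_cand.values.loc[probe].to_numpy(float)
            a = pheno["dst_ns"].to_numpy(float)
            b = pheno["hypersexuality"].to_numpy(float)
            lin = interaction_linear(cg, a, b)
            row = {"probe_id": probe, "linear_interaction_coef": lin.coef["interaction"],
                   "linear_interaction_p": lin.p["interaction"]}
            try:
                log = interaction_logistic(a, cg, b)
                row["logistic_interaction_coef"] = log.coef["interaction"]
                row["logistic_interaction_p"] = log.p["interaction"]
            except SeparationError as err:
                row["logistic_interaction_coef"] = np.nan
                row["logistic_interaction_p"] = np.nan
                manifest["warnings"].append(f"posthoc logistic {probe}: {err}")
            post_rows.append(row)
        posthoc_df = pd.DataFrame(post_rows)
        posthoc_df.to_csv(out / "posthoc.tsv", sep="\t", index=False)
        stage("posthoc", probes=len(posthoc_df))

        manifest["warnings"].extend(str(w.message) for w in caught)

    manifest["counts"] = {
        "probes_in": len(ann),
        "candidates": len(candidates),
        "modelled": len(dmp),
        "nominally_significant": n_nominal,
        "flagged_transcripts": len(flagged),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
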