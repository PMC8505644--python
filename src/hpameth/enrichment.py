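"""Transcript-level binomial enrichment of nominally significant CpGs.

A transcript with n annotated probes of which k reach nominal significance
(raw p < 0.05) is tested against Binomial(n, 0.05): does it carry more
significant probes than the nominal rate predicts? Direction of the
methylation change is ignored. The exact two-sided convention sums the
probabilities of all outcomes no more likely than the observed one (the
minimum-likelihood convention); for k = n the one- and two-sided tails
coincide. Bonferroni adjustment multiplies by the number of transcripts
tested. Probe-probe correlation within a transcript is not modelled, a
known optimism of this test.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["binomial_test", "run_enrichment"]


def binomial_test(k: int, n: int, p0: float = 0.05, sided: str = "two-sided") -> float:
    """Exact binomial tail probability for k successes out of n at rate p0.

    ``sided='greater'`` gives P(X >= k); ``'two-sided'`` uses the
    minimum-likelihood convention.
    """
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if sided not in ("greater", "two-sided"):
        raise ValueError("sided must be 'greater' or 'two-sided'")
    alt = "greater" if sided == "greater" else "two-sided"
    return float(stats.binomtest(int(k), int(n), p0, alternative=alt).pvalue)


def run_enrichment(
    dmp: pd.DataFrame,
    annotation: pd.DataFrame,
    alpha_nominal: float = 0.05,
    sided: str = "two-sided",
) -> pd.DataFrame:
    """Per-transcript binomial test of the count of nominally significant probes.

    ``dmp`` is a moderated-fit table indexed by probe with a raw ``p`` column
    (raw, not FDR-adjusted, p-values are thresholded); ``annotation`` maps
    probes to transcripts, one row per (probe, transcript) pair, so a probe
    contributes to every transcript it is annotated to. Probes absent from
    the annotation are dropped with a warning. The Bonferroni multiplier is
    the number of transcripts tested (those with at least one probe).
    """
    ann = annotation[annotation["probe_id"].isin(dmp.index)]
    n_unannotated = dmp.index.difference(ann["probe_id"]).size
    if ann.empty:
        raise ValueError("no overlap between fit table and annotation")
    if n_unannotated:
        warnings.warn(f"{n_unannotated} probe(s) in the fit table have no annotation; dropped")
    sig = dmp["p"] < alpha_nominal

    rows = []
    for (transcript, gene), grp in ann.groupby(["transcript", "gene"], sort=False):
        probes = grp["probe_id"]
        n = len(probes)
        k = int(sig.loc[probes].sum())
        rows.append((transcript, gene, k, n, binomial_test(k, n, alpha_nominal, sided)))
    out = pd.DataFrame(rows, columns=["transcript", "gene", "k", "n", "p_binomial"])
    m = len(out)
    out["p_bonferroni"] = np.minimum(1.0, out["p_binomial"] * m)
    out["significant"] = out["p_bonferroni"] < 0.05
    out.attrs["bonferroni_multiplier"] = m
    out.attrs["alpha_nominal"] = alpha_nominal
    return out
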