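"""Methylation matrix container, beta/M transforms, and PCA sample QC.

The analysis scale is the M-value, ``M = log2(beta / (1 - beta))``, which is
approximately homoscedastic across the beta range and therefore better suited
to linear modelling than the bounded beta fraction. Beta values are the
measurement scale (fraction methylated, in [0, 1]) and are kept for display.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class ScaleError(ValueError):
    """Raised when an operation receives a matrix on the wrong scale."""


@dataclass
class MethylationMatrix:
    """Probes x samples methylation matrix.

    Parameters
    ----------
    values : pandas.DataFrame
        Probes as rows, samples as columns. Beta scale values must lie in
        [0, 1]; M scale values are unbounded reals.
    scale : {"beta", "M"}
        Which scale ``values`` is on.
    """

    values: pd.DataFrame
    scale: str = "beta"

    def __post_init__(self) -> None:
        if self.scale not in ("beta", "M"):
            raise ValueError(f"scale must be 'beta' or 'M', got {self.scale!r}")
        if self.values.index.has_duplicates:
            raise ValueError("duplicated probe ids")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicated sample ids")
        arr = self.values.to_numpy(dtype=float)
        if self.scale == "beta" and arr.size:
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError("beta values outside [0, 1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @classmethod
    def from_tsv(cls, path, scale: str = "beta") -> "MethylationMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(df, scale=scale)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="probe_id")

    def subset_probes(self, probes) -> "MethylationMatrix":
        return MethylationMatrix(self.values.loc[list(probes)], scale=self.scale)


def beta_to_m(beta: MethylationMatrix, eps: float = 1e-6) -> MethylationMatrix:
    """Logit2 transform: M = log2(b / (1 - b)), clipping b into [eps, 1 - eps].

    The clip keeps fully (un)methylated probes finite; eps defaults to 1e-6,
    far below the noise floor of array beta values.
    """
    if beta.scale != "beta":
        raise ScaleError("input is already on the M scale")
    if not 0 < eps < 0.5:
        raise ValueError("eps must be in (0, 0.5)")
    b = beta.values.clip(lower=eps, upper=1 - eps)
    m = np.log2(b / (1 - b))
    return MethylationMatrix(m, scale="M")


def m_to_beta(m: MethylationMatrix) -> MethylationMatrix:
    """Inverse logit2: b = 2^M / (1 + 2^M)."""
    if m.scale != "M":
        raise ScaleError("input is not on the M scale")
    p = np.exp2(m.values)
    return MethylationMatrix(p / (1 + p), scale="beta")


@dataclass
class OutlierReport:
    """Result of PCA-based sample outlier flagging.

    ``pc1_variance_pct`` is the share of total variance carried by the first
    principal component of the filtered, centered matrix; ``flags`` marks
    samples whose PC1 score falls outside the reference range.
    """

    pc1_variance_pct: float
    scores: pd.Series
    flags: pd.Series
    probes_used: int
    variance_pct: np.ndarray = field(repr=False, default=None)

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pc1_score": self.scores, "outlier": self.flags})


def pca_outlier_flags(
    beta: MethylationMatrix,
    sd_threshold: float = 0.2,
    ref_range: float = 0.95,
) -> OutlierReport:
    """Flag sample outliers on the first principal component.

    Probes whose beta-value standard deviation exceeds ``sd_threshold`` enter
    a PCA of the sample x probe matrix (centered per probe). A sample is
    flagged when its PC1 score lies outside mean +/- z * SD of the scores,
    with z the two-sided normal quantile of ``ref_range`` (1.96 for 0.95).
    Replaces visual inspection of the PC1 display with a reproducible rule.
    """
    if beta.scale != "beta":
        raise ScaleError("PCA QC operates on beta values")
    vals = beta.values.to_numpy(dtype=float)
    if vals.shape[1] < 3:
        raise ValueError("need at least 3 samples for PCA QC")
    sd = vals.std(axis=1, ddof=1)
    keep = sd > sd_threshold
    if not keep.any():
        raise ValueError(
            f"no probe exceeds the SD threshold {sd_threshold}; "
            "lower --sd-threshold or skip outlier QC"
        )
    X = vals[keep].T  # samples x probes
    X = X - X.mean(axis=0)
    # SVD of the centered matrix; singular values give the variance shares
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    variance_pct = 100 * var / var.sum()
    scores = pd.Series(X @ vt[0], index=beta.sample_ids, name="pc1_score")
    z = stats.norm.ppf(0.5 + ref_range / 2)
    mu, sigma = scores.mean(), scores.std(ddof=1)
    if sigma == 0:
        flags = pd.Series(False, index=beta.sample_ids, name="outlier")
    else:
        flags = (scores - mu).abs() > z * sigma
        flags.name = "outlier"
    return OutlierReport(
        pc1_variance_pct=float(variance_pct[0]),
        scores=scores,
        flags=flags,
        probes_used=int(keep.sum()),
        variance_pct=variance_pct,
    )


def regress_out(m: MethylationMatrix, covariates: pd.DataFrame) -> MethylationMatrix:
    """Remove supplied per-sample covariates (e.g. cell fractions) from M-values.

    Per probe, fits OLS of the M-values on an intercept plus the covariates and
    returns intercept + residuals. Generic hook: reference-based cell-type
    deconvolution itself is out of scope.
    """
    if m.scale != "M":
        raise ScaleError("regress_out operates on M-values")
    cov = covariates.reindex(m.sample_ids)
    if cov.isna().any().any():
        raise ValueError("covariates missing for some samples")
    X = np.column_stack([np.ones(len(cov)), cov.to_numpy(dtype=float)])
    Y = m.values.to_numpy(dtype=float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ coef
    adjusted = resid + Y.mean(axis=0)  # keep the per-probe mean level
    if resid.shape[1] and np.linalg.matrix_rank(X) < X.shape[1]:
        warnings.warn("covariate matrix is rank deficient; fit is not unique")
    out = pd.DataFrame(adjusted.T, index=m.probe_ids, columns=m.sample_ids)
    return MethylationMatrix(out, scale="M")
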