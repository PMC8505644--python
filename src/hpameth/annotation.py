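"""Probe-to-gene annotation and TSS-window candidate selection.

Each annotation row links one array probe (a CpG site) to one transcript of a
gene, with the signed base-pair distance to that transcript's transcriptional
start site (negative = upstream). A probe annotated to several transcripts
appears once per transcript, so downstream per-transcript counts include it in
every transcript it maps to.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

REQUIRED_COLUMNS = ("probe_id", "gene", "transcript", "tss_distance")

#: The HPA-axis candidate genes: the CRH ligand, its binding protein and two
#: receptors, the glucocorticoid receptor and its co-chaperone.
DEFAULT_PANEL_GENES = frozenset(
    {"CRH", "CRHBP", "CRHR1", "CRHR2", "FKBP5", "NR3C1"}
)

DEFAULT_WINDOW_BP = 2000


@dataclass(frozen=True)
class CandidatePanel:
    """A gene panel plus the promoter window (bp around the TSS) to keep."""

    genes: frozenset = field(default=DEFAULT_PANEL_GENES)
    window_bp: int = DEFAULT_WINDOW_BP

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel gene set is empty")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        object.__setattr__(self, "genes", frozenset(self.genes))


def load_annotation(path) -> pd.DataFrame:
    """Load a probe annotation TSV/CSV with the four required columns.

    Rows whose ``tss_distance`` does not parse as an integer are dropped with
    a warning naming the offending row numbers (1-based, excluding header).
    Duplicate (probe_id, transcript) pairs are an error.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation file lacks required column(s): {', '.join(missing)}")
    df = df.loc[:, list(REQUIRED_COLUMNS)]
    dist = pd.to_numeric(df["tss_distance"], errors="coerce")
    bad = df.index[dist.isna()]
    if len(bad):
        rows = ", ".join(str(i + 1) for i in bad)
        warnings.warn(f"dropped {len(bad)} row(s) with unparseable tss_distance: row(s) {rows}")
        df = df.drop(index=bad)
        dist = dist.drop(index=bad)
    df = df.assign(tss_distance=dist.astype(int)).reset_index(drop=True)
    if df["probe_id"].eq("").any() or df["probe_id"].isna().any():
        raise ValueError("empty probe_id")
    dup = df.duplicated(subset=["probe_id", "transcript"])
    if dup.any():
        pairs = df.loc[dup, ["probe_id", "transcript"]].apply(tuple, axis=1).tolist()
        raise ValueError(f"duplicate (probe_id, transcript) rows: {pairs}")
    return df


def select_candidate_probes(
    annotation: pd.DataFrame, panel: CandidatePanel | None = None
) -> pd.DataFrame:
    """Keep rows with gene in the panel and |tss_distance| <= window_bp.

    The window is inclusive at both ends, order-preserving and idempotent.
    An empty result is allowed but warned about.
    """
    if panel is None:
        panel = CandidatePanel()
    if annotation.empty:
        raise ValueError("annotation is empty")
    mask = annotation["gene"].isin(panel.genes) & (
        annotation["tss_distance"].abs() <= panel.window_bp
    )
    out = annotation.loc[mask].reset_index(drop=True)
    if out.empty:
        warnings.warn("no probes fall in the candidate panel window")
    return out


def transcript_probe_map(annotation: pd.DataFrame) -> dict:
    """Map transcript -> (gene, list of probe ids), preserving row order."""
    out: dict = {}
    for row in annotation.itertuples(index=False):
        gene, probes = out.setdefault(row.transcript, (row.gene, []))
        probes.append(row.probe_id)
    return out
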