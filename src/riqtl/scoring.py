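"""Weighted multi-criteria candidate-gene prioritization.

Genes inside a QTL support interval are scored against eight evidence
criteria. The first six (founder coding variant, disease GWAS hit for
heart failure, disease GWAS hit for cardiovascular disease, cis
regulation, differential expression, tissue expression above a TPM
threshold) are worth 1 point each; functional relevance and a significant
Mendelian-randomization result are worth 2 each, for a maximum of 10.
Genes scoring at least 30% of the maximum are retained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, fields
from importlib import resources

import numpy as np
import pandas as pd

from .qtl import SupportInterval

__all__ = [
    "CRITERIA",
    "DEFAULT_WEIGHTS",
    "GeneEvidence",
    "ScoreCard",
    "score_gene",
    "score_table",
    "rank_candidates",
    "genes_in_interval",
    "classify_cis",
    "flag_degs",
    "load_example_evidence",
]

# criterion order is load-bearing: weights are positional
CRITERIA = (
    "coding_variant",
    "gwas_cvd",
    "gwas_hf",
    "cis_regulated",
    "deg",
    "expressed",
    "functional_relevance",
    "mr_significant",
)
DEFAULT_WEIGHTS = (1, 1, 1, 1, 1, 1, 2, 2)
DEFAULT_TPM_THRESHOLD = 2.0
DEFAULT_SELECT_FRACTION = 0.30


@dataclass(frozen=True)
class GeneEvidence:
    """Per-gene criterion flags plus the raw expression level."""

    gene: str
    coding_variant: bool = False
    gwas_cvd: bool = False
    gwas_hf: bool = False
    cis_regulated: bool = False
    deg: bool = False
    functional_relevance: bool = False
    mr_significant: bool = False
    expression_tpm: float = 0.0
    chromosome: str = ""
    start_mb: float = math.nan
    end_mb: float = math.nan

    def __post_init__(self) -> None:
        if self.expression_tpm < 0:
            raise ValueError(f"{self.gene}: expression TPM must be non-negative")


@dataclass(frozen=True)
class ScoreCard:
    gene: str
    points: dict[str, int]
    total: int
    max_score: int
    selected: bool
    expression_tpm: float

    def as_row(self) -> dict:
        row = {"gene": self.gene, **self.points,
               "expression_tpm": self.expression_tpm,
               "total": self.total, "selected": self.selected}
        return row


def score_gene(
    evidence: GeneEvidence,
    weights: tuple[int, ...] = DEFAULT_WEIGHTS,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    select_fraction: float = DEFAULT_SELECT_FRACTION,
) -> ScoreCard:
    """Score one gene; the expression criterion is satisfied iff
    TPM > ``tpm_threshold`` (strict). Selection requires the total to reach
    ``ceil(select_fraction * max_score)`` points."""
    if len(weights) != len(CRITERIA):
        raise ValueError(f"expected {len(CRITERIA)} weights, got {len(weights)}")
    flags = {
        "coding_variant": evidence.coding_variant,
        "gwas_cvd": evidence.gwas_cvd,
        "gwas_hf": evidence.gwas_hf,
        "cis_regulated": evidence.cis_regulated,
        "deg": evidence.deg,
        "expressed": evidence.expression_tpm > tpm_threshold,
        "functional_relevance": evidence.functional_relevance,
        "mr_significant": evidence.mr_significant,
    }
    points = {c: int(w) if flags[c] else 0 for c, w in zip(CRITERIA, weights)}
    total = sum(points.values())
    max_score = int(sum(weights))
    cutoff = math.ceil(select_fraction * max_score)
    return ScoreCard(
        gene=evidence.gene,
        points=points,
        total=total,
        max_score=max_score,
        selected=total >= cutoff,
        expression_tpm=evidence.expression_tpm,
    )


def _evidence_from_row(row: pd.Series) -> GeneEvidence:
    kwargs = {"gene": row["gene"], "expression_tpm": float(row.get("expression_tpm", 0.0))}
    for f in fields(GeneEvidence):
        if f.type == "bool" and f.name in row.index:
            kwargs[f.name] = bool(row[f.name])
    for col in ("chromosome", "start_mb", "end_mb"):
        if col in row.index:
            kwargs[col] = row[col]
    return GeneEvidence(**kwargs)


def score_table(
    evidence: pd.DataFrame,
    weights: tuple[int, ...] = DEFAULT_WEIGHTS,
    tpm_threshold: float = DEFAULT_TPM_THRESHOLD,
    select_fraction: float = DEFAULT_SELECT_FRACTION,
) -> list[ScoreCard]:
    """Score every row of an evidence table (missing flags default false)."""
    missing = [c for c in CRITERIA if c != "expressed" and c not in evidence.columns]
    if missing:
        warnings.warn(f"evidence columns absent, treated as false: {missing}", stacklevel=2)
    return [
        score_gene(_evidence_from_row(row), weights, tpm_threshold, select_fraction)
        for _, row in evidence.iterrows()
    ]


def rank_candidates(scorecards: list[ScoreCard]) -> pd.DataFrame:
    """Scorecards as a table sorted by total desc, then TPM desc, then
    gene symbol; tie-break order is a convention recorded here, not an
    externally defined rule."""
    if not scorecards:
        raise ValueError("no scorecards to rank")
    df = pd.DataFrame([s.as_row() for s in scorecards])
    df = df.sort_values(
        ["total", "expression_tpm", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return df


def genes_in_interval(annotation: pd.DataFrame, interval: SupportInterval) -> pd.DataFrame:
    """Genes whose span overlaps the interval (inclusive endpoints).

    ``annotation`` columns: gene, chromosome, start_mb, end_mb.
    """
    if annotation.empty:
        warnings.warn("empty gene annotation", stacklevel=2)
        return annotation
    sel = (
        (annotation["chromosome"].astype(str) == str(interval.chromosome))
        & (annotation["end_mb"] >= interval.start_mb)
        & (annotation["start_mb"] <= interval.end_mb)
    )
    return annotation[sel].sort_values("start_mb").reset_index(drop=True)


def classify_cis(
    gene_chromosome: str,
    gene_start_mb: float,
    gene_end_mb: float,
    peak_chromosome: str,
    peak_mb: float,
    window_mb: float = 5.0,
) -> bool:
    """True iff the gene midpoint lies within ``window_mb`` of the
    expression-QTL peak on the same chromosome."""
    if str(gene_chromosome) != str(peak_chromosome):
        return False
    midpoint = 0.5 * (gene_start_mb + gene_end_mb)
    return abs(midpoint - peak_mb) <= window_mb


def flag_degs(
    results: pd.DataFrame,
    padj_threshold: float = 0.05,
    fc_threshold: float = 1.5,
) -> pd.Series:
    """Differential-expression flags from a results table.

    Accepts either a ``log2_fold_change`` column or a linear ``fold_change``
    column (signed convention: negative = down-regulated; magnitudes in
    (0, 1) are also read as down-regulation). A gene is flagged iff
    padj < ``padj_threshold`` and the linear fold-change magnitude exceeds
    ``fc_threshold``. Rows with missing padj are skipped with a warning.
    """
    if "log2_fold_change" in results.columns:
        magnitude = np.power(2.0, results["log2_fold_change"].abs())
    elif "fold_change" in results.columns:
        fc = results["fold_change"].astype(float).abs()
        magnitude = np.where((fc > 0) & (fc < 1), 1.0 / fc, fc)
        magnitude = pd.Series(magnitude, index=results.index)
    else:
        raise ValueError("need a fold_change or log2_fold_change column")
    padj = results["padj"]
    n_missing = int(padj.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} gene(s) missing adjusted p; not flagged", stacklevel=2)
    flags = (padj < padj_threshold) & (magnitude > fc_threshold)
    return flags.fillna(False).astype(bool)


def load_example_evidence(name: str) -> pd.DataFrame:
    """Bundled example evidence tables: 'bwloss' (22 genes) or 'echo' (9)."""
    fname = {"bwloss": "candidates_bwloss.tsv", "echo": "candidates_echo.tsv"}[name]
    with resources.files("riqtl.data").joinpath(fname).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    for col in df.columns:
        if col not in ("gene", "expression_tpm"):
            df[col] = df[col].astype(bool)
    return df
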