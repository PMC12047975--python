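"""Two-sample Mendelian randomization from summary statistics.

Exposure (eQTL) and outcome (GWAS) effects are harmonized by variant id
and effect allele, then the causal slope is estimated with the Wald ratio
for a single instrument or fixed-effects inverse-variance weighting (IVW)
for two or more. IVW here is algebraically the zero-intercept weighted
regression of outcome betas on exposure betas with weights se_out^-2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "MRInstrumentSet",
    "MRResult",
    "harmonize",
    "wald_ratio",
    "ivw",
    "run_mr",
]

_PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}
_VALID_ALLELES = {"A", "C", "G", "T"}


@dataclass
class MRInstrumentSet:
    """Harmonized instruments for one gene x outcome pair.

    Arrays are aligned per instrument; ``log`` records drop/flip events.
    """

    gene: str
    outcome: str
    variant_ids: tuple[str, ...]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.asarray(self.se_exp) <= 0) or np.any(np.asarray(self.se_out) <= 0):
            raise ValueError("standard errors must be positive")

    @property
    def n_instruments(self) -> int:
        return len(self.variant_ids)


@dataclass(frozen=True)
class MRResult:
    gene: str
    outcome: str
    method: str  # "Wald" or "IVW"
    estimate: float
    se: float
    p_value: float
    n_instruments: int
    flag: str = ""


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    gene: str = "",
    outcome_id: str = "",
) -> MRInstrumentSet:
    """Match exposure and outcome rows by variant id and align effect alleles.

    If the outcome's effect allele equals the exposure's other allele (and
    vice versa) the outcome beta sign is flipped. Palindromic (A/T, C/G)
    variants and variants whose alleles cannot be reconciled are dropped,
    with a log entry each.
    """
    log: list[str] = []
    out_by_id = outcome.set_index("variant_id")
    ids, be, se_e, bo, se_o = [], [], [], [], []
    for _, row in exposure.iterrows():
        vid = row["variant_id"]
        ea, oa = str(row["effect_allele"]).upper(), str(row["other_allele"]).upper()
        if vid not in out_by_id.index:
            log.append(f"{vid}: absent from outcome, dropped")
            continue
        if not ({ea, oa} <= _VALID_ALLELES):
            log.append(f"{vid}: non-ACGT alleles, dropped")
            continue
        if frozenset((ea, oa)) in _PALINDROMIC:
            log.append(f"{vid}: palindromic alleles {ea}/{oa}, dropped")
            continue
        orow = out_by_id.loc[vid]
        oea, ooa = str(orow["effect_allele"]).upper(), str(orow["other_allele"]).upper()
        if (oea, ooa) == (ea, oa):
            beta_out = float(orow["beta"])
        elif (oea, ooa) == (oa, ea):
            beta_out = -float(orow["beta"])
            log.append(f"{vid}: effect allele flipped in outcome, beta sign corrected")
        else:
            log.append(f"{vid}: allele mismatch {ea}/{oa} vs {oea}/{ooa}, dropped")
            continue
        ids.append(vid)
        be.append(float(row["beta"]))
        se_e.append(float(row["se"]))
        bo.append(beta_out)
        se_o.append(float(orow["se"]))
    return MRInstrumentSet(
        gene=gene,
        outcome=outcome_id,
        variant_ids=tuple(ids),
        beta_exp=np.array(be),
        se_exp=np.array(se_e),
        beta_out=np.array(bo),
        se_out=np.array(se_o),
        log=log,
    )


def _normal_p(z: float) -> float:
    return float(min(2.0 * stats.norm.sf(abs(z)), 1.0))


def wald_ratio(instruments: MRInstrumentSet) -> MRResult:
    """Single-instrument causal estimate beta_out / beta_exp with the
    first-order delta-method SE se_out / |beta_exp|."""
    if instruments.n_instruments != 1:
        raise ValueError("Wald ratio requires exactly one instrument")
    bx = float(instruments.beta_exp[0])
    by = float(instruments.beta_out[0])
    so = float(instruments.se_out[0])
    if bx == 0:
        return MRResult(instruments.gene, instruments.outcome, "Wald",
                        np.nan, np.nan, np.nan, 1, flag="zero_exposure_effect")
    est = by / bx
    se = so / abs(bx)
    return MRResult(instruments.gene, instruments.outcome, "Wald",
                    est, se, _normal_p(est / se), 1)


def ivw(instruments: MRInstrumentSet) -> MRResult:
    """Fixed-effects inverse-variance weighted estimate.

    Per-instrument ratios r_i = beta_out,i/beta_exp,i are combined with
    weights w_i = (beta_exp,i / se_out,i)^2; the SE is (sum w_i)^-1/2.
    Instruments with a zero exposure effect are dropped; with one
    instrument remaining this reduces exactly to the Wald ratio.
    """
    keep = instruments.beta_exp != 0
    if not keep.all():
        warnings.warn(
            f"{instruments.gene}/{instruments.outcome}: dropped "
            f"{int((~keep).sum())} instrument(s) with zero exposure effect",
            stacklevel=2,
        )
    sub = MRInstrumentSet(
        instruments.gene, instruments.outcome,
        tuple(np.asarray(instruments.variant_ids)[keep]),
        instruments.beta_exp[keep], instruments.se_exp[keep],
        instruments.beta_out[keep], instruments.se_out[keep],
    )
    if sub.n_instruments == 0:
        return MRResult(sub.gene, sub.outcome, "IVW", np.nan, np.nan, np.nan, 0,
                        flag="no_usable_instruments")
    if sub.n_instruments == 1:
        r = wald_ratio(sub)
        return MRResult(r.gene, r.outcome, "Wald", r.estimate, r.se, r.p_value, 1,
                        flag="fell_back_to_wald" if not keep.all() else "")
    ratios = sub.beta_out / sub.beta_exp
    weights = (sub.beta_exp / sub.se_out) ** 2
    est = float(np.sum(weights * ratios) / np.sum(weights))
    se = float(1.0 / np.sqrt(np.sum(weights)))
    return MRResult(sub.gene, sub.outcome, "IVW", est, se, _normal_p(est / se),
                    sub.n_instruments)


def run_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Estimate one causal effect per (gene, outcome) pair.

    ``exposure`` needs a ``gene`` column, ``outcome`` an ``outcome``
    column; both carry variant_id/effect_allele/other_allele/beta/se.
    Significance is raw p < alpha by default; set ``bh_correct`` for
    Benjamini-Hochberg across the grid.
    Returns (results table, summary counts).
    """
    rows = []
    if not outcome.empty and not exposure.empty:
        for gene, exp_g in exposure.groupby("gene", sort=True):
            for out_id, out_g in outcome.groupby("outcome", sort=True):
                inst = harmonize(exp_g, out_g, gene=gene, outcome_id=out_id)
                if inst.n_instruments == 0:
                    continue
                res = wald_ratio(inst) if inst.n_instruments == 1 else ivw(inst)
                rows.append(res)
    table = pd.DataFrame(
        [
            {
                "gene": r.gene,
                "outcome": r.outcome,
                "n_snps": r.n_instruments,
                "method": r.method,
                "estimate": r.estimate,
                "se": r.se,
                "p_value": r.p_value,
                "flag": r.flag,
            }
            for r in rows
        ],
        columns=["gene", "outcome", "n_snps", "method", "estimate", "se",
                 "p_value", "flag"],
    )
    if not table.empty:
        valid = table["p_value"].notna()
        if bh_correct and valid.any():
            adj = multipletests(table.loc[valid, "p_value"], method="fdr_bh")[1]
            table.loc[valid, "p_adj"] = adj
            table["significant"] = table.get("p_adj", pd.Series(dtype=float)) < alpha
        else:
            table["significant"] = valid & (table["p_value"] < alpha)
    else:
        table["significant"] = pd.Series(dtype=bool)
    sig = table[table["significant"].fillna(False)] if not table.empty else table
    summary = {
        "n_associations": int(len(table)),
        "n_significant": int(len(sig)),
        "n_significant_genes": int(sig["gene"].nunique()) if len(sig) else 0,
        "alpha": alpha,
    }
    return table, summary
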