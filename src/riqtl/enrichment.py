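"""Over-representation analysis with the hypergeometric test and BH FDR.

Categories with fewer than ``min_overlap`` genes overlapping the query
list are removed *before* testing, so the Benjamini-Hochberg denominator
counts only tested categories.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["ora", "read_gmt", "write_gmt"]


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT category file: name <tab> description <tab> gene1 <tab> ..."""
    categories: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        categories[parts[0]] = set(parts[2:])
    return categories


def write_gmt(categories: dict[str, set[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in categories.items():
            fh.write("\t".join([name, name] + sorted(genes)) + "\n")


def ora(
    gene_list: list[str] | set[str],
    categories: dict[str, set[str]],
    background: list[str] | set[str],
    min_overlap: int = 5,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation test per category.

    p = P(X >= k) for k = |list ∩ category| drawn from a population of
    size N = |background| containing K = |category ∩ background| successes
    in n = |list| draws. Enrichment ratio = (k/n)/(K/N). Output is sorted
    by (p, category), so results do not depend on category input order.
    """
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    genes = list(gene_list)
    query = set(genes)
    if len(query) < len(genes):
        warnings.warn(f"deduplicated {len(genes) - len(query)} query gene(s)", stacklevel=2)
    outside = query - background
    if outside:
        warnings.warn(
            f"{len(outside)} query gene(s) absent from background; dropped", stacklevel=2
        )
        query &= background
    N, n = len(background), len(query)

    rows = []
    for name in sorted(categories):
        members = categories[name] & background
        K = len(members)
        k = len(query & members)
        if k < min_overlap:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        ratio = (k / n) / (K / N) if n and K else 0.0
        rows.append(
            {"category": name, "overlap": k, "category_size": K,
             "list_size": n, "background_size": N,
             "enrichment_ratio": ratio, "p_value": min(p, 1.0)}
        )
    result = pd.DataFrame(
        rows,
        columns=["category", "overlap", "category_size", "list_size",
                 "background_size", "enrichment_ratio", "p_value"],
    )
    if result.empty:
        result["fdr"] = pd.Series(dtype=float)
        result["significant"] = pd.Series(dtype=bool)
        return result
    result["fdr"] = multipletests(result["p_value"], method="fdr_bh")[1]
    result["significant"] = result["fdr"] < fdr
    return result.sort_values(["p_value", "category"]).reset_index(drop=True)
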