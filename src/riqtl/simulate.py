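"""Synthetic data with planted ground truth for validating the pipeline.

Generates recombinant-inbred genotypes from two founders (with the
sib-mating map expansion), strain phenotypes with planted additive QTL
effects, and paired exposure/outcome summary statistics linked by a known
causal slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import FounderMap, GenotypeMatrix

__all__ = [
    "QtlSpec",
    "SimConfig",
    "haldane_r",
    "ri_map_expansion",
    "simulate_ri_genotypes",
    "simulate_strain_phenotypes",
    "simulate_mr_statistics",
]

# non-palindromic effect/other allele pairs used for simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class QtlSpec:
    """A planted additive QTL: marker nearest (chromosome, position_cm)
    carries an allele-substitution effect of ``effect`` trait units."""

    chromosome: str
    position_cm: float
    effect: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.effect):
            raise ValueError("QTL effect size must be finite")


@dataclass(frozen=True)
class SimConfig:
    n_strains: int = 60
    n_animals_per_strain: int = 8
    qtl: tuple[QtlSpec, ...] = ()
    heritability: float = 0.5
    replicate_sd: float = 1.0
    causal_effect: float = 0.5
    trait_name: str = "trait"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.heritability <= 1.0:
            raise ValueError(f"heritability must lie in [0, 1], got {self.heritability}")
        if self.n_strains < 2:
            raise ValueError("need at least two strains")
        if self.n_animals_per_strain < 1:
            raise ValueError("need at least one animal per strain")


def haldane_r(d_cm: float | np.ndarray) -> float | np.ndarray:
    """Single-meiosis recombination fraction from map distance (Haldane)."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm) / 100.0))


def ri_map_expansion(r: float | np.ndarray) -> float | np.ndarray:
    """Fixation recombination fraction for sib-mated RI lines: R = 4r/(1+6r)."""
    r = np.asarray(r)
    return 4.0 * r / (1.0 + 6.0 * r)


def simulate_ri_genotypes(
    founder_map: FounderMap,
    n_strains: int,
    seed: int | np.random.Generator = 0,
    *,
    strain_prefix: str = "RIX",
    map_expansion: bool = True,
) -> GenotypeMatrix:
    """Draw fully inbred strain genomes as founder-allele mosaics.

    Each chromosome is a Markov chain along the marker map: the first
    marker's allele is Bernoulli(1/2) and adjacent markers recombine with
    probability ``R = 4r/(1+6r)`` (sib-mating map expansion; pass
    ``map_expansion=False`` for the single-meiosis ``R = r``), where ``r``
    comes from the cM gap via Haldane's map function. Chromosomes are
    independent; only homozygous dosages 0/1 are emitted.
    """
    if n_strains < 2:
        raise ValueError("need at least two strains")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dosages = np.empty((n_strains, founder_map.n_markers), dtype=float)
    for chrom in founder_map.chromosome_names:
        idx = founder_map.chrom_index(chrom)
        cm = np.asarray(founder_map.positions_cm)[idx]
        r = haldane_r(np.diff(cm))
        rec = ri_map_expansion(r) if map_expansion else r
        alleles = np.empty((n_strains, len(idx)), dtype=float)
        alleles[:, 0] = rng.integers(0, 2, size=n_strains)
        for j, rate in enumerate(rec, start=1):
            flip = rng.random(n_strains) < rate
            alleles[:, j] = np.where(flip, 1.0 - alleles[:, j - 1], alleles[:, j - 1])
        dosages[:, idx] = alleles
    strains = tuple(f"{strain_prefix}{i + 1}" for i in range(n_strains))
    return GenotypeMatrix(strains, founder_map, dosages)


def _qtl_marker_index(founder_map: FounderMap, qtl: QtlSpec) -> int:
    idx = founder_map.chrom_index(qtl.chromosome)
    if idx.size == 0:
        raise ValueError(f"QTL chromosome {qtl.chromosome!r} absent from map")
    cm = np.asarray(founder_map.positions_cm)[idx]
    return int(idx[np.argmin(np.abs(cm - qtl.position_cm))])


def simulate_strain_phenotypes(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-animal trait records with planted QTL effects.

    Strain means are ``sum(a_k * dosage_k)`` plus strain-level normal noise
    scaled so the genetic component explains ~``heritability`` of the
    strain-mean variance; each animal adds independent within-strain noise
    with SD ``replicate_sd``. Returns a long table with columns
    ``strain, animal_id, sex, trait, value``.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(
        config.seed if seed is None else seed
    )
    h2 = config.heritability
    genetic = np.zeros(genotypes.n_strains)
    for qtl in config.qtl:
        j = _qtl_marker_index(genotypes.founder_map, qtl)
        genetic += qtl.effect * genotypes.dosages[:, j]
    var_g = float(np.var(genetic))
    if h2 >= 1.0:
        noise_sd = 0.0
    elif var_g > 0 and h2 > 0:
        noise_sd = np.sqrt(var_g * (1.0 - h2) / h2)
    else:
        noise_sd = 1.0  # pure-noise trait; scale is arbitrary
    strain_means = genetic + noise_sd * rng.standard_normal(genotypes.n_strains)

    records = []
    n_rep = config.n_animals_per_strain
    for i, strain in enumerate(genotypes.strains):
        values = strain_means[i] + config.replicate_sd * rng.standard_normal(n_rep)
        if h2 >= 1.0:
            values = np.full(n_rep, strain_means[i])
        for k in range(n_rep):
            records.append(
                {
                    "strain": strain,
                    "animal_id": f"{strain}_{k + 1}",
                    "sex": "F" if k % 2 else "M",
                    "trait": config.trait_name,
                    "value": values[k],
                }
            )
    return pd.DataFrame.from_records(records)


def simulate_mr_statistics(
    n_genes: int,
    n_instruments_per_gene: int,
    theta: float,
    seed: int | np.random.Generator = 0,
    *,
    se_exp: float = 0.05,
    se_out: float = 0.05,
    flip_fraction: float = 0.0,
    outcome: str = "outcome1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Paired exposure/outcome summary-statistic tables with causal slope theta.

    Exposure effects are drawn bounded away from zero; outcome effects are
    ``theta * beta_exp`` plus N(0, se_out) noise. A ``flip_fraction`` of
    instruments is written to the outcome table with effect/other alleles
    swapped and the outcome beta negated, so harmonization must undo the
    flip to recover the generating effects.
    """
    if n_instruments_per_gene < 1:
        raise ValueError("need at least one instrument per gene")
    if not 0.0 <= flip_fraction <= 1.0:
        raise ValueError("flip_fraction must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_total = n_genes * n_instruments_per_gene
    magnitude = rng.uniform(0.2, 0.8, size=n_total)
    sign = rng.choice([-1.0, 1.0], size=n_total)
    beta_exp = magnitude * sign
    beta_out = theta * beta_exp + se_out * rng.standard_normal(n_total)
    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=n_total)
    flipped = rng.random(n_total) < flip_fraction

    exp_rows, out_rows = [], []
    from scipy import stats

    for i in range(n_total):
        gene = f"gene{i // n_instruments_per_gene + 1}"
        variant = f"rs{i + 1}"
        ea, oa = _ALLELE_PAIRS[pair_idx[i]]
        z_exp = beta_exp[i] / se_exp
        exp_rows.append(
            {
                "gene": gene,
                "variant_id": variant,
                "effect_allele": ea,
                "other_allele": oa,
                "beta": beta_exp[i],
                "se": se_exp,
                "pval": 2.0 * stats.norm.sf(abs(z_exp)),
            }
        )
        b_out, ea_out, oa_out = beta_out[i], ea, oa
        if flipped[i]:
            b_out, ea_out, oa_out = -b_out, oa, ea
        out_rows.append(
            {
                "outcome": outcome,
                "variant_id": variant,
                "effect_allele": ea_out,
                "other_allele": oa_out,
                "beta": b_out,
                "se": se_out,
                "pval": 2.0 * stats.norm.sf(abs(b_out / se_out)),
            }
        )
    return pd.DataFrame(exp_rows), pd.DataFrame(out_rows)
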