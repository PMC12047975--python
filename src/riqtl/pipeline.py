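"""End-to-end orchestration: simulate-or-load, derive strain traits, scan,
extract support intervals, score candidates, run MR and enrichment, and
write a manifest that fully determines the outputs."""

from __future__ import annotations

import json
import hashlib
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enrichment import ora, read_gmt
from .genotypes import read_geno_tsv, write_geno_tsv
from .mr import run_mr
from .qtl import hk_scan, lmm_scan, permutation_threshold, support_interval
from .scoring import load_example_evidence, rank_candidates, score_table
from .simulate import (
    FounderMap,
    QtlSpec,
    SimConfig,
    simulate_mr_statistics,
    simulate_ri_genotypes,
    simulate_strain_phenotypes,
)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    # simulation spec (used when no input paths are given)
    n_strains: int = 60
    n_animals_per_strain: int = 8
    n_chromosomes: int = 3
    markers_per_chromosome: int = 20
    cm_spacing: float = 5.0
    mb_per_cm: float = 2.0
    qtl: list = field(default_factory=lambda: [["2", 45.0, 1.0]])
    heritability: float = 0.5
    replicate_sd: float = 1.0
    trait: str = "trait"
    # scan settings
    method: str = "hk"  # hk | lmm | both
    n_perm: int = 1000
    alpha: float = 0.05
    drop: float = 2.0
    # scoring
    evidence: str = "bwloss"  # bundled example name or a TSV path
    tpm_threshold: float = 2.0
    select_fraction: float = 0.30
    # MR
    mr_n_genes: int = 20
    mr_n_instruments: int = 3
    mr_theta: float = 0.5
    mr_alpha: float = 0.05
    # enrichment
    gmt_path: str | None = None
    min_overlap: int = 5
    fdr: float = 0.05
    # inputs (override simulation)
    geno_path: str | None = None
    pheno_path: str | None = None
    exposure_path: str | None = None
    outcome_path: str | None = None
    seed: int = 42

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for attr in ("geno_path", "pheno_path", "exposure_path", "outcome_path", "gmt_path"):
            p = getattr(self, attr)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{attr}: {p}")
        if self.method not in ("hk", "lmm", "both"):
            raise ValueError(f"unknown scan method {self.method!r}")


def _file_checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage and write plain-text artifacts plus a manifest.

    Re-running with the same config reproduces byte-identical outputs.
    Returns the manifest dict.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stages: dict[str, float] = {}
    t0 = time.perf_counter()

    # --- genotypes + per-animal phenotypes -------------------------------
    if config.geno_path:
        geno = read_geno_tsv(config.geno_path)
    else:
        fmap = FounderMap.regular(
            config.n_chromosomes, config.markers_per_chromosome,
            config.cm_spacing, config.mb_per_cm,
        )
        geno = simulate_ri_genotypes(fmap, config.n_strains, rng)
        write_geno_tsv(geno, out / "genotypes.geno.tsv")
    if config.pheno_path:
        animals = pd.read_csv(config.pheno_path, sep="\t")
    else:
        qtl = tuple(QtlSpec(str(c), float(p), float(a)) for c, p, a in config.qtl)
        sim = SimConfig(
            n_strains=geno.n_strains,
            n_animals_per_strain=config.n_animals_per_strain,
            qtl=qtl,
            heritability=config.heritability,
            replicate_sd=config.replicate_sd,
            trait_name=config.trait,
            seed=config.seed,
        )
        animals = simulate_strain_phenotypes(geno, sim, rng)
        _write_tsv(animals, out / "animals.tsv")
    stages["simulate"] = time.perf_counter() - t0

    # --- strain traits ---------------------------------------------------
    t0 = time.perf_counter()
    traits = (
        animals[animals["trait"] == config.trait]
        .groupby("strain")["value"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "value", "size": "n"})
    )
    traits.insert(1, "trait", config.trait)
    _write_tsv(traits, out / "strain_traits.tsv")
    trait_series = traits.set_index("strain")["value"]
    stages["traits"] = time.perf_counter() - t0

    # --- scans + thresholds + intervals ----------------------------------
    t0 = time.perf_counter()
    methods = ("hk", "lmm") if config.method == "both" else (config.method,)
    intervals = {}
    for method in methods:
        scan = (hk_scan if method == "hk" else lmm_scan)(geno, trait_series, config.trait)
        thr = permutation_threshold(
            geno, trait_series, n_perm=config.n_perm,
            alpha=(config.alpha, 0.37), seed=np.random.default_rng(config.seed + 1),
        )
        scan.thresholds = thr
        table = scan.table.copy()
        table["significant_lrs_threshold"] = thr[config.alpha]
        table["suggestive_lrs_threshold"] = thr[0.37]
        _write_tsv(table, out / f"scan_{method}.tsv")
        peak = scan.peak()
        interval = support_interval(scan, peak["chromosome"], drop=config.drop)
        intervals[method] = {
            **interval.to_dict(),
            "peak_marker": peak["marker"],
            "peak_lrs": float(peak["lrs"]),
            "significant_lrs_threshold": thr[config.alpha],
            "suggestive_lrs_threshold": thr[0.37],
        }
    (out / "intervals.json").write_text(json.dumps(intervals, indent=2, sort_keys=True))
    stages["scan"] = time.perf_counter() - t0

    # --- candidate scoring ------------------------------------------------
    t0 = time.perf_counter()
    if config.evidence in ("bwloss", "echo"):
        evidence = load_example_evidence(config.evidence)
    else:
        evidence = pd.read_csv(config.evidence, sep="\t")
    cards = score_table(
        evidence, tpm_threshold=config.tpm_threshold,
        select_fraction=config.select_fraction,
    )
    ranked = rank_candidates(cards)
    _write_tsv(ranked, out / "scorecards.tsv")
    stages["score"] = time.perf_counter() - t0

    # --- Mendelian randomization -----------------------------------------
    t0 = time.perf_counter()
    if config.exposure_path and config.outcome_path:
        exposure = pd.read_csv(config.exposure_path, sep="\t")
        outcome = pd.read_csv(config.outcome_path, sep="\t")
    else:
        exposure, outcome = simulate_mr_statistics(
            config.mr_n_genes, config.mr_n_instruments, config.mr_theta,
            seed=np.random.default_rng(config.seed + 2),
        )
        _write_tsv(exposure, out / "mr_exposure.tsv")
        _write_tsv(outcome, out / "mr_outcome.tsv")
    mr_table, mr_summary = run_mr(exposure, outcome, alpha=config.mr_alpha)
    _write_tsv(mr_table, out / "mr_results.tsv")
    stages["mr"] = time.perf_counter() - t0

    # --- enrichment -------------------------------------------------------
    t0 = time.perf_counter()
    selected = ranked.loc[ranked["selected"], "gene"].tolist()
    if config.gmt_path:
        categories = read_gmt(config.gmt_path)
        background = sorted(set().union(*categories.values()) | set(evidence["gene"]))
    else:
        # synthetic categories over the evidence genes plus filler background
        all_genes = sorted(evidence["gene"])
        background = all_genes + [f"bg{i}" for i in range(200)]
        cat_rng = np.random.default_rng(config.seed + 3)
        categories = {
            f"category_{j + 1}": set(
                cat_rng.choice(background, size=min(30, len(background)), replace=False)
            ) | set(cat_rng.choice(all_genes, size=min(5, len(all_genes)), replace=False))
            for j in range(10)
        }
    enr = ora(selected, categories, background,
              min_overlap=config.min_overlap, fdr=config.fdr)
    _write_tsv(enr, out / "enrichment.tsv")
    stages["enrich"] = time.perf_counter() - t0

    # --- manifest ---------------------------------------------------------
    artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "seed": config.seed,
        "artifacts": {name: _file_checksum(out / name) for name in artifacts},
        "stage_seconds": {k: round(v, 4) for k, v in stages.items()},
        "summary": {
            "intervals": intervals,
            "n_selected_candidates": len(selected),
            "mr": mr_summary,
            "n_enriched_categories": int(enr["significant"].sum()) if len(enr) else 0,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
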