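"""Genotype matrices for two-founder recombinant-inbred panels.

The on-disk dialect is a GeneNetwork-style TSV: ``#chromosome``,
``#position_mb`` and ``#position_cm`` header lines describing the marker
map, then a header row of marker names and one row per strain with cells
in ``{B, D, H, U}`` (or, equivalently, numeric ``0 / 1 / 0.5 / NA``).
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["FounderMap", "GenotypeMatrix", "read_geno_tsv", "write_geno_tsv"]

# founder-allele cell codes -> numeric dosage of the second founder (D)
_CODE_TO_NUM = {"B": 0.0, "D": 1.0, "H": 0.5, "U": np.nan}
_NUM_TO_CODE = {0.0: "B", 1.0: "D", 0.5: "H"}


@dataclass(frozen=True)
class FounderMap:
    """Marker map for a two-founder cross: names, chromosomes, positions.

    Positions must be strictly increasing within each chromosome, in both
    centimorgan and megabase coordinates.
    """

    marker_names: tuple[str, ...]
    chromosomes: tuple[str, ...]
    positions_cm: np.ndarray
    positions_mb: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.marker_names)
        if n == 0:
            raise ValueError("founder map must contain at least one marker")
        if not (len(self.chromosomes) == len(self.positions_cm) == len(self.positions_mb) == n):
            raise ValueError("marker names, chromosomes and positions must have equal length")
        for chrom in dict.fromkeys(self.chromosomes):
            for pos in (self.positions_cm, self.positions_mb):
                p = np.asarray(pos)[self.chrom_index(chrom)]
                if np.any(np.diff(p) <= 0):
                    raise ValueError(
                        f"positions on chromosome {chrom!r} must be strictly increasing"
                    )

    @property
    def n_markers(self) -> int:
        return len(self.marker_names)

    @property
    def chromosome_names(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(self.chromosomes))

    def chrom_index(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.chromosomes) == chrom)

    @classmethod
    def regular(
        cls,
        n_chromosomes: int = 3,
        markers_per_chromosome: int = 20,
        cm_spacing: float = 5.0,
        mb_per_cm: float = 2.0,
    ) -> "FounderMap":
        """Evenly spaced synthetic map (``n_chromosomes`` autosomes)."""
        names, chroms, cms, mbs = [], [], [], []
        for c in range(1, n_chromosomes + 1):
            for m in range(markers_per_chromosome):
                names.append(f"m{c}_{m + 1}")
                chroms.append(str(c))
                cms.append(m * cm_spacing)
                mbs.append(m * cm_spacing * mb_per_cm)
        return cls(tuple(names), tuple(chroms), np.array(cms, float), np.array(mbs, float))


@dataclass
class GenotypeMatrix:
    """Strains x markers dosage matrix with its marker map.

    Cells hold the numeric dosage of the second founder allele:
    0 (first founder), 1 (second founder), 0.5 (heterozygous) or NaN
    (unknown).
    """

    strains: tuple[str, ...]
    founder_map: FounderMap
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.strains), self.founder_map.n_markers):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.strains)} strains x {self.founder_map.n_markers} markers"
            )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return self.founder_map.n_markers

    @property
    def marker_names(self) -> tuple[str, ...]:
        return self.founder_map.marker_names

    def marker_dosage(self, marker: str) -> np.ndarray:
        j = self.marker_names.index(marker)
        return self.dosages[:, j]

    def subset_strains(self, strains: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in strains]
        return GenotypeMatrix(tuple(strains), self.founder_map, self.dosages[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=list(self.strains), columns=list(self.marker_names))


def write_geno_tsv(geno: GenotypeMatrix, path: str | Path) -> None:
    fm = geno.founder_map
    with open(path, "w") as fh:
        fh.write("#chromosome\t" + "\t".join(fm.chromosomes) + "\n")
        fh.write("#position_mb\t" + "\t".join(f"{v:g}" for v in fm.positions_mb) + "\n")
        fh.write("#position_cm\t" + "\t".join(f"{v:g}" for v in fm.positions_cm) + "\n")
        fh.write("strain\t" + "\t".join(fm.marker_names) + "\n")
        for i, strain in enumerate(geno.strains):
            cells = [
                _NUM_TO_CODE.get(v, "U") if not np.isnan(v) else "U" for v in geno.dosages[i]
            ]
            fh.write(strain + "\t" + "\t".join(cells) + "\n")


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    if cell in _CODE_TO_NUM:
        return _CODE_TO_NUM[cell]
    if cell in ("", "NA", "nan", "NaN"):
        return np.nan
    try:
        value = float(cell)
    except ValueError as exc:
        raise ValueError(f"unrecognized genotype cell {cell!r}") from exc
    if value not in (0.0, 0.5, 1.0):
        raise ValueError(f"numeric genotype cell must be 0, 0.5 or 1, got {cell!r}")
    return value


def read_geno_tsv(path: str | Path | io.StringIO) -> GenotypeMatrix:
    """Read the genotype TSV dialect; accepts B/D/H/U or 0/1/0.5/NA cells."""
    if isinstance(path, io.StringIO):
        lines = path.getvalue().splitlines()
    else:
        lines = Path(path).read_text().splitlines()
    header: dict[str, list[str]] = {}
    rows: list[list[str]] = []
    marker_names: list[str] | None = None
    for line in lines:
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if parts[0].startswith("#"):
            header[parts[0][1:]] = parts[1:]
        elif marker_names is None:
            marker_names = parts[1:]
        else:
            rows.append(parts)
    if marker_names is None or not rows:
        raise ValueError("genotype file has no marker header or strain rows")
    n = len(marker_names)
    chroms = header.get("chromosome", ["1"] * n)
    mb = [float(v) for v in header.get("position_mb", [str(i) for i in range(n)])]
    cm = [float(v) for v in header.get("position_cm", [str(i) for i in range(n)])]
    fm = FounderMap(tuple(marker_names), tuple(chroms), np.array(cm), np.array(mb))
    strains, dosages = [], []
    for parts in rows:
        if len(parts) != n + 1:
            raise ValueError(f"strain row {parts[0]!r} has {len(parts) - 1} cells, expected {n}")
        strains.append(parts[0])
        dosages.append([_parse_cell(c) for c in parts[1:]])
    geno = GenotypeMatrix(tuple(strains), fm, np.array(dosages))
    if np.isnan(geno.dosages).any():
        warnings.warn("genotype matrix contains unknown (U/NA) calls", stacklevel=2)
    return geno
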