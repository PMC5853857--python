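"""Readers and writers for the plain-text interchange formats.

Genotypes travel as a tab-delimited dosage matrix (rows = genotypes, first
column ``genotype``, remaining columns = marker ids, entries 0/1/2 or NA)
plus a separate map file (``marker``, ``chromosome``, ``position_cM``).
Markers present in the matrix but absent from the map are retained and
flagged unmapped (they are excluded from LD windows).  Phenotypes travel as
long-format CSV.  All writers mirror their readers so a write -> read
round-trip reproduces the object.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .containers import PLOT_LEVEL, GenotypeMatrix, TraitDataset

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "RunConfig",
    "load_config",
]

_NA = {"", "NA", "NaN", "nan", "na"}


def read_genotypes(path, map_path) -> GenotypeMatrix:
    """Read a dosage matrix + map file into a GenotypeMatrix.

    Raises a parse error naming the line for dosages outside {0, 1, 2, NA}
    and for duplicated marker ids.
    """
    path, map_path = Path(path), Path(map_path)
    with path.open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[0] != "genotype":
            raise ValueError(f"{path}: first column must be 'genotype'")
        marker_ids = header[1:]
        if len(set(marker_ids)) != len(marker_ids):
            dup = [m for m in marker_ids if marker_ids.count(m) > 1][0]
            raise ValueError(f"{path}: duplicated marker id {dup!r}")
        gids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(header):
                raise ValueError(f"{path}:{lineno}: expected {len(header)} fields")
            gids.append(parts[0])
            row = np.empty(len(marker_ids))
            for j, tok in enumerate(parts[1:]):
                if tok in _NA:
                    row[j] = np.nan
                elif tok in ("0", "1", "2"):
                    row[j] = float(tok)
                else:
                    raise ValueError(
                        f"{path}:{lineno}: invalid dosage {tok!r} "
                        f"for marker {marker_ids[j]!r}"
                    )
            rows.append(row)
    dosages = np.vstack(rows) if rows else np.empty((0, len(marker_ids)))

    mp = pd.read_csv(map_path, sep="\t")
    need = {"marker", "chromosome", "position_cM"}
    if not need.issubset(mp.columns):
        raise ValueError(f"{map_path}: must have columns {sorted(need)}")
    mp = mp.set_index("marker")
    extra_map = set(mp.index) - set(marker_ids)
    if extra_map:
        raise ValueError(
            f"{map_path}: markers absent from the matrix: {sorted(extra_map)[:5]}"
        )
    chrom = np.array(
        [str(mp.loc[m, "chromosome"]) if m in mp.index else "NA" for m in marker_ids]
    )
    pos = np.array(
        [float(mp.loc[m, "position_cM"]) if m in mp.index else np.nan
         for m in marker_ids]
    )
    return GenotypeMatrix(
        dosages=dosages,
        marker_ids=marker_ids,
        chromosome=chrom,
        position_cM=pos,
        genotype_ids=gids,
    )


def write_genotypes(geno: GenotypeMatrix, path, map_path) -> None:
    path, map_path = Path(path), Path(map_path)
    with path.open("w") as fh:
        fh.write("genotype\t" + "\t".join(map(str, geno.marker_ids)) + "\n")
        for i, g in enumerate(geno.genotype_ids):
            toks = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno.dosages[i]
            ]
            fh.write(str(g) + "\t" + "\t".join(toks) + "\n")
    mapped = np.isfinite(geno.position_cM)
    pd.DataFrame(
        {
            "marker": [m for m, ok in zip(geno.marker_ids, mapped) if ok],
            "chromosome": geno.chromosome[mapped],
            "position_cM": geno.position_cM[mapped],
        }
    ).to_csv(map_path, sep="\t", index=False)


_PHENO_COLS = ["genotype", "environment", "replicate", "block", "trait", "value"]


def read_phenotypes(path, stage: str = PLOT_LEVEL) -> TraitDataset:
    """Read a long-format phenotype CSV into a TraitDataset.

    Missing required columns and non-numeric values raise parse errors
    naming the offender; single-replicate environments are flagged.
    """
    df = pd.read_csv(path)
    need = _PHENO_COLS if stage == PLOT_LEVEL else ["genotype", "trait", "value"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    vals = pd.to_numeric(df["value"], errors="coerce")
    bad = df.index[vals.isna() & df["value"].notna()]
    if len(bad):
        raise ValueError(
            f"{path}: non-numeric value {df.loc[bad[0], 'value']!r} "
            f"in row {bad[0] + 2}"
        )
    df["value"] = vals
    ds = TraitDataset(df, stage=stage)
    if stage == PLOT_LEVEL:
        single = (
            df.groupby(["trait", "environment"])["replicate"]
            .nunique()
            .pipe(lambda s: s[s < 2])
        )
        if len(single):
            ds.flags["single_replicate"] = [
                tuple(k) for k in single.index.tolist()
            ]
    return ds


def write_phenotypes(ds: TraitDataset, path) -> None:
    ds.data.to_csv(path, index=False)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration loaded from YAML."""

    genotype_path: str
    map_path: str
    phenotype_path: str
    traits: list = field(default_factory=list)
    trait_pairs: list = field(default_factory=list)
    alpha: float = 0.05
    r2_window: float = 0.5
    corrections: list = field(default_factory=lambda: ["fdr"])
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for p in (self.genotype_path, self.map_path, self.phenotype_path):
            if p and not Path(p).exists():
                raise FileNotFoundError(p)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)
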