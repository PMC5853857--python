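"""Core in-memory containers shared across the pipeline.

The substrate of every analysis is a panel of (near-)inbred varieties scored
at mapped bi-allelic markers (allele dosages 0/1/2) together with long-format
multi-environment phenotype records.  These containers are deliberately thin
wrappers around numpy arrays / pandas DataFrames: they validate the invariants
once at construction and the numerical modules then work on the raw arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "KinshipMatrix",
    "LDMatrix",
    "TraitDataset",
]

_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Varieties x markers allele-dosage matrix with a genetic map.

    Parameters
    ----------
    dosages : ndarray, shape (n_genotypes, n_markers)
        Dosage of the minor (second) allele: 0, 1 or 2; NaN encodes missing.
    marker_ids, genotype_ids : sequences of unique labels.
    chromosome : per-marker chromosome label.
    position_cM : per-marker genetic-map coordinate; NaN marks an unmapped
        marker (kept in the matrix but excluded from LD windows).
    """

    dosages: np.ndarray
    marker_ids: list
    chromosome: np.ndarray
    position_cM: np.ndarray
    genotype_ids: list

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.marker_ids = list(self.marker_ids)
        self.genotype_ids = list(self.genotype_ids)
        self.chromosome = np.asarray(self.chromosome)
        self.position_cM = np.asarray(self.position_cM, dtype=float)
        n, m = self.dosages.shape
        if len(self.marker_ids) != m:
            raise ValueError(f"{len(self.marker_ids)} marker ids for {m} columns")
        if len(self.genotype_ids) != n:
            raise ValueError(f"{len(self.genotype_ids)} genotype ids for {n} rows")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicated marker ids")
        if len(set(self.genotype_ids)) != n:
            raise ValueError("duplicated genotype ids")
        if self.chromosome.shape != (m,) or self.position_cM.shape != (m,):
            raise ValueError("map arrays must have one entry per marker")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, _VALID_DOSAGES).all():
            bad = vals[~np.isin(vals, _VALID_DOSAGES)][:5]
            raise ValueError(f"dosages outside {{0,1,2,NaN}}: {bad}")
        self._marker_index = {mk: i for i, mk in enumerate(self.marker_ids)}

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def column(self, marker_id) -> np.ndarray:
        return self.dosages[:, self.index_of(marker_id)]

    def index_of(self, marker_id) -> int:
        try:
            return self._marker_index[marker_id]
        except KeyError:
            raise KeyError(f"unknown marker {marker_id!r}") from None

    def is_mapped(self, marker_id) -> bool:
        return bool(np.isfinite(self.position_cM[self.index_of(marker_id)]))

    def sorted_by_map(self) -> "GenotypeMatrix":
        """Return a copy ordered by (chromosome, cM); unmapped markers last."""
        pos = np.where(np.isfinite(self.position_cM), self.position_cM, np.inf)
        order = np.lexsort((pos, self.chromosome.astype(str)))
        return GenotypeMatrix(
            self.dosages[:, order],
            [self.marker_ids[i] for i in order],
            self.chromosome[order],
            self.position_cM[order],
            self.genotype_ids,
        )

    def map_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "marker": self.marker_ids,
                "chromosome": self.chromosome,
                "position_cM": self.position_cM,
            }
        )


@dataclass
class KinshipMatrix:
    """Genotype relationship matrix A = 2 (J - RD) from Rogers' distances.

    ``A`` is symmetric with entries in [0, 2]; identical inbred lines have
    RD = 0 hence A = 2.  ``A_psd`` is the minimum-eigenvalue-bent copy that
    downstream REML uses (identical to ``A`` when A is already PSD).
    """

    A: np.ndarray
    RD: np.ndarray
    genotype_ids: list
    bending: float = 0.0

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        self.RD = np.asarray(self.RD, dtype=float)
        n = len(self.genotype_ids)
        if self.A.shape != (n, n) or self.RD.shape != (n, n):
            raise ValueError("A/RD must be square with one row per genotype")
        if not np.allclose(self.A, self.A.T, atol=1e-10):
            raise ValueError("A must be symmetric")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def A_psd(self) -> np.ndarray:
        if self.bending > 0.0:
            return self.A + self.bending * np.eye(self.n)
        return self.A

    def eig(self) -> tuple[np.ndarray, np.ndarray]:
        """Cached eigendecomposition of the bent A (clipped to PSD)."""
        if not hasattr(self, "_eig"):
            lam, U = np.linalg.eigh(self.A_psd)
            object.__setattr__(self, "_eig", (np.clip(lam, 0.0, None), U))
        return self._eig


@dataclass
class LDMatrix:
    """Pairwise squared-correlation (r^2) matrix for a set of markers."""

    r2: np.ndarray
    marker_ids: list
    M_eff: int | None = None

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.marker_ids)
        if self.r2.shape != (m, m):
            raise ValueError("r2 must be square, one row per marker")
        if not np.allclose(self.r2, self.r2.T, atol=1e-8):
            raise ValueError("r2 must be symmetric")
        finite = self.r2[np.isfinite(self.r2)]
        if finite.size and (finite.min() < -1e-8 or finite.max() > 1 + 1e-8):
            raise ValueError("r2 entries must lie in [0, 1]")


PLOT_LEVEL = "plot-level"
STAGE1 = "stage1-BLUE"
STAGE2 = "stage2-BLUE"

_STAGE_COLUMNS = {
    PLOT_LEVEL: ["genotype", "environment", "replicate", "block", "trait", "value"],
    STAGE1: ["genotype", "environment", "trait", "value"],
    STAGE2: ["genotype", "trait", "value"],
}


@dataclass
class TraitDataset:
    """Long-format phenotype records with a processing-stage tag.

    stage is one of ``plot-level`` (raw alpha-lattice plots), ``stage1-BLUE``
    (per-environment genotype BLUEs) or ``stage2-BLUE`` (across-environment
    BLUEs).  Key uniqueness is enforced per stage.
    """

    data: pd.DataFrame
    stage: str = PLOT_LEVEL
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.stage not in _STAGE_COLUMNS:
            raise ValueError(f"unknown stage {self.stage!r}")
        cols = _STAGE_COLUMNS[self.stage]
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        self.data = self.data.reset_index(drop=True)
        vals = self.data["value"].to_numpy()
        if not np.issubdtype(np.asarray(vals).dtype, np.number):
            raise ValueError("trait values must be numeric")
        if not np.isfinite(vals[~np.isnan(vals)]).all():
            raise ValueError("trait values must be finite")
        key_cols = [c for c in cols if c != "value"]
        if self.data.duplicated(subset=key_cols).any():
            dup = self.data[self.data.duplicated(subset=key_cols)].iloc[0]
            raise ValueError(f"duplicate record key: {dup[key_cols].to_dict()}")

    @property
    def traits(self) -> list:
        return sorted(self.data["trait"].unique().tolist())

    @property
    def genotypes(self) -> list:
        return sorted(self.data["genotype"].unique().tolist())

    def for_trait(self, trait) -> pd.DataFrame:
        sub = self.data[self.data["trait"] == trait]
        if sub.empty:
            raise KeyError(f"no records for trait {trait!r}")
        return sub.copy()

    def wide(self) -> pd.DataFrame:
        """Genotype x trait table (stage-2 BLUEs only)."""
        if self.stage != STAGE2:
            raise ValueError("wide() is defined for across-environment BLUEs")
        return self.data.pivot(index="genotype", columns="trait", values="value")
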