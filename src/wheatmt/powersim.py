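"""Power and Type I error of the pleiotropy-vs-close-linkage LR test.

Reconstructs the simulation study: two traits are simulated on a synthetic
panel of n inbred genotypes (default 372) at the across-environment BLUE
level (the substrate of the 2D scan), over a grid of minor allele
frequencies, QTL sizes (% of genetic variance) and -- in linkage mode --
r^2 between the two causal positions.

Causal markers are drawn from the panel itself, band-matched to the
requested MAF and r^2 (e.g. MAF "~0.46" means both markers in 0.44-0.48 and
r^2 "~0.55" means 0.53-0.56): only panel-embedded markers experience the
kinship absorption and the surrounding-marker competition that shape the
test, as the study's use of real variety marker profiles did.

* linkage mode: marker 1 carries the QTL for trait 1, marker 2 the QTL for
  trait 2.  The scan's candidate set is the pair plus the r^2 > 0.5 window
  of the target (marker 1).  The rejection proportion is the power to
  detect close linkage.
* pleiotropy mode: a single panel marker (with a non-empty r^2 > 0.5
  window) carries the QTL for both traits.  The rejection proportion is the
  empirical Type I error.

Variance scale.  Everything is parameterized on the REML component scale on
which heritabilities are defined with A = 2 (J - RD) (diagonal 2 for
inbreds): the trait's genetic variance component is fixed at 1, a QTL of
size pct contributes absolute variance pct/100, the polygenic component is
1 - pct/100, and the residual is (1/h2_plot - 1) with plot-basis
heritabilities of 0.44 (trait 1, grain-yield-like) and 0.60 (trait 2,
component-trait-like).  Rejection uses the chi-square(1) reference at a
nominal alpha of 0.05.

Within each replicate the scan estimates (G0, R0) once under the no-marker
null model and re-uses them across the candidate grid (the scan's fast
mode); grid-wise re-estimation agrees within binomial noise but costs two
orders of magnitude more time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import GenotypeMatrix, KinshipMatrix
from .genostats import kinship_from_genotypes, minor_allele_frequency
from .pleioscan2d import LINKAGE, scan_2d
from .synthetic_data import InfeasibleLD, SimPopulationSpec, simulate_genotypes

__all__ = [
    "ScenarioGrid",
    "PowerTable",
    "SimulationPanel",
    "effect_size_from_variance",
    "run_scenario",
    "run_grid",
]

# Table-2-style bands around the nominal grid levels
MAF_BANDS = {
    0.06: (0.06, 0.07),
    0.13: (0.11, 0.14),
    0.22: (0.20, 0.24),
    0.46: (0.44, 0.48),
}
R2_BANDS = {0.55: (0.53, 0.56), 0.70: (0.68, 0.72), 0.91: (0.90, 0.93)}

# residuals on the genetic-variance-component scale: (1/h2_plot - 1) with
# h2_plot = 0.44 (trait 1) and 0.60 (trait 2)
_DEFAULT_RESID = (1.0 / 0.44 - 1.0, 1.0 / 0.60 - 1.0)


def _band(value, table, width):
    if value in table:
        return table[value]
    return (value - width, value + width)


@dataclass
class ScenarioGrid:
    """Simulation grid over MAF x QTL size (x r^2 in linkage mode).

    ``qtl_sizes_pct`` entries may be scalars (balanced: both traits' QTLs
    explain the same share) or (size1, size2) pairs (unbalanced).
    """

    mode: str = "linkage"
    maf_levels: tuple = (0.06, 0.13, 0.22, 0.46)
    qtl_sizes_pct: tuple = (5, 10, 15)
    r2_levels: tuple = (0.55, 0.70, 0.91)
    n_replicates: int = 100
    n_genotypes: int = 372
    alpha: float = 0.05
    seed: int = 0
    resid_var: tuple = _DEFAULT_RESID
    total_genetic_variance: float = 1.0
    window_cap: int = 10
    fast_scan: bool = True

    def __post_init__(self):
        if self.mode not in ("linkage", "pleiotropy"):
            raise ValueError("mode must be 'linkage' or 'pleiotropy'")
        for s in self.qtl_sizes_pct:
            for v in np.atleast_1d(s):
                if not 0 < v < 100:
                    raise ValueError("QTL sizes must be in (0, 100)")

    def cells(self):
        from .genostats import max_r2

        out = []
        for maf in self.maf_levels:
            for size in self.qtl_sizes_pct:
                if self.mode == "linkage":
                    for r2 in self.r2_levels:
                        if r2 > max_r2(maf, maf) + 1e-9:
                            raise InfeasibleLD(f"r^2={r2} infeasible at MAF {maf}")
                        out.append({"maf": maf, "qtl_size": size, "r2": r2})
                else:
                    out.append({"maf": maf, "qtl_size": size, "r2": None})
        return out


@dataclass
class PowerTable:
    """Per-cell rejection proportions with binomial standard errors."""

    table: pd.DataFrame
    mode: str
    n_replicates: int

    @property
    def grand_mean(self) -> float:
        return float(self.table["proportion"].mean())

    @property
    def grand_sd(self) -> float:
        return float(self.table["proportion"].std(ddof=1))

    def pivot(self) -> pd.DataFrame:
        """Table layout: MAF x QTL-size rows, r^2 columns (linkage mode)."""
        t = self.table.copy()
        t["qtl_size"] = t["qtl_size"].astype(str)
        if self.mode != "linkage":
            return t.pivot(index="maf", columns="qtl_size", values="proportion")
        return t.pivot(index=["maf", "qtl_size"], columns="r2", values="proportion")


def effect_size_from_variance(
    pct: float, maf: float, total_genetic_variance: float
) -> float:
    """Additive effect explaining ``pct`` % of the trait's genetic variance.

    Inbred 0/2 dosage coding gives Var(dosage) = 4 p (1 - p), so
    alpha = sqrt(pct/100 * V_G / (4 p (1 - p))).
    """
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    if not 0 < maf <= 0.5:
        raise ValueError("maf must be in (0, 0.5]")
    if total_genetic_variance < 0:
        raise ValueError("total genetic variance must be >= 0")
    var_dosage = 4.0 * maf * (1.0 - maf)
    return float(np.sqrt(pct / 100.0 * total_genetic_variance / var_dosage))


class SimulationPanel:
    """Synthetic genotype panel with cached LD lookups for the simulations.

    Holds the genotypes, the Rogers'-distance kinship, per-chromosome r^2
    matrices, and band-matched eligible causal markers/pairs.
    """

    def __init__(self, geno: GenotypeMatrix, kinship: KinshipMatrix | None = None):
        self.geno = geno
        self.kinship = kinship or kinship_from_genotypes(geno)
        self.D = geno.dosages
        self.n = geno.n_genotypes
        self.mafs = np.array(
            [minor_allele_frequency(self.D[:, j]) for j in range(geno.n_markers)]
        )
        lam, U = self.kinship.eig()
        self._L_A = U * np.sqrt(lam)[None, :]
        self._chrom_cache: dict = {}

    @classmethod
    def default(cls, n_genotypes: int = 372, seed: int = 0) -> "SimulationPanel":
        """The default study panel: 8000 mapped markers on 10 chromosomes.

        Marker density (~5.3 markers/cM) and LD extent (r^2 > 0.5 within
        about 1 cM) are chosen to resemble a mid-density SNP-array panel,
        so r^2 > 0.5 windows hold around ten markers.
        """
        spec = SimPopulationSpec(
            n_genotypes=n_genotypes,
            n_markers_per_chrom=800,
            n_chromosomes=10,
            ld_decay_cM=3.0,
            seed=seed,
        )
        return cls(simulate_genotypes(spec))

    # -- LD lookups ---------------------------------------------------------

    def _chrom_r2(self, chrom):
        if chrom not in self._chrom_cache:
            idx = np.flatnonzero(self.geno.chromosome == chrom)
            X = self.D[:, idx]
            sd = X.std(axis=0)
            keep = sd > 0
            idx = idx[keep]
            Xs = (X[:, keep] - X[:, keep].mean(0)) / sd[keep]
            self._chrom_cache[chrom] = (idx, (Xs.T @ Xs / self.n) ** 2)
        return self._chrom_cache[chrom]

    def eligible_pairs(self, maf_band, r2_band) -> list:
        """Panel marker pairs with both MAFs and their r^2 inside the bands."""
        out = []
        for c in np.unique(self.geno.chromosome):
            idx, R2 = self._chrom_r2(c)
            m = self.mafs[idx]
            inb = (m >= maf_band[0]) & (m <= maf_band[1])
            sel = (
                (R2 >= r2_band[0])
                & (R2 <= r2_band[1])
                & inb[:, None]
                & inb[None, :]
            )
            for a, b in zip(*np.triu(sel, 1).nonzero()):
                out.append((int(idx[a]), int(idx[b])))
        return out

    def eligible_singles(self, maf_band) -> list:
        """Markers in the MAF band that have a non-empty r^2 > 0.5 window."""
        out = []
        for c in np.unique(self.geno.chromosome):
            idx, R2 = self._chrom_r2(c)
            m = self.mafs[idx]
            inb = (m >= maf_band[0]) & (m <= maf_band[1])
            linked = ((R2 > 0.5).sum(axis=1) - 1) > 0
            out.extend(int(j) for j in idx[inb & linked])
        return out

    def window(self, j_target: int, exclude=(), r2_min: float = 0.5, cap: int = 10):
        """Column indices of the r^2 > r2_min window around marker j_target."""
        c = self.geno.chromosome[j_target]
        idx, R2 = self._chrom_r2(c)
        pos = int(np.flatnonzero(idx == j_target)[0])
        r2v = R2[pos]
        order = np.argsort(-r2v)
        out = []
        for t in order:
            j = int(idx[t])
            if j == j_target or j in exclude or r2v[t] <= r2_min:
                continue
            out.append(j)
            if len(out) >= cap:
                break
        return out

    def polygenic(self, s: float, rng) -> np.ndarray:
        """One polygenic draw ~ N(0, s * A)."""
        return self._L_A @ rng.standard_normal(self.n) * np.sqrt(s)


def panel_supports(panel: SimulationPanel, grid: ScenarioGrid) -> bool:
    """True when every grid cell has at least one eligible causal draw."""
    for cell in grid.cells():
        maf_band = _band(cell["maf"], MAF_BANDS, 0.02)
        if grid.mode == "linkage":
            r2_band = _band(cell["r2"], R2_BANDS, 0.02)
            if not panel.eligible_pairs(maf_band, r2_band):
                return False
        elif not panel.eligible_singles(maf_band):
            return False
    return True


def _sizes(cell_size):
    s = np.atleast_1d(cell_size).astype(float)
    return (float(s[0]), float(s[-1]))


def _simulate_traits(panel, grid, markers, sizes_pct, rng) -> pd.DataFrame:
    V_G = grid.total_genetic_variance
    y = np.empty((panel.n, 2))
    for k in range(2):
        mk = markers[k]
        a = effect_size_from_variance(
            sizes_pct[k], minor_allele_frequency(mk), V_G
        )
        s_poly = (1.0 - sizes_pct[k] / 100.0) * V_G
        e = rng.standard_normal(panel.n) * np.sqrt(grid.resid_var[k])
        y[:, k] = a * mk + panel.polygenic(s_poly, rng) + e
    return pd.DataFrame(
        y,
        index=pd.Index(panel.kinship.genotype_ids, name="genotype"),
        columns=["T1", "T2"],
    )


def run_scenario(
    cell: dict, panel: SimulationPanel, grid: ScenarioGrid, seed_seq=None
) -> dict:
    """One grid cell: rejection proportion over ``grid.n_replicates``.

    In linkage mode a rejection is a correct detection of close linkage
    (power); in pleiotropy mode it is a false rejection of pleiotropy
    (Type I error).  Cells with more than 20% failed replicates are marked
    unreliable.
    """
    maf, r2 = cell["maf"], cell.get("r2")
    s1, s2 = _sizes(cell["qtl_size"])
    maf_band = _band(maf, MAF_BANDS, 0.02)
    if grid.mode == "linkage":
        r2_band = _band(r2, R2_BANDS, 0.02)
        pool = panel.eligible_pairs(maf_band, r2_band)
        kind = f"pairs for MAF {maf_band}, r^2 {r2_band}"
    else:
        pool = panel.eligible_singles(maf_band)
        kind = f"windowed markers for MAF {maf_band}"
    if not pool:
        raise InfeasibleLD(f"panel holds no {kind}; regenerate with another seed")
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(grid.seed)
    child = seed_seq.spawn(grid.n_replicates)
    n_rej = n_done = n_failed = 0
    for rep in range(grid.n_replicates):
        rng = np.random.default_rng(child[rep])
        try:
            if grid.mode == "linkage":
                j1, j2 = pool[rng.integers(len(pool))]
                m1, m2 = panel.D[:, j1], panel.D[:, j2]
                blues = _simulate_traits(panel, grid, (m1, m2), (s1, s2), rng)
                cand = {"m1": m1, "m2": m2}
                for j in panel.window(j1, exclude=(j2,), cap=grid.window_cap):
                    cand[f"w{j}"] = panel.D[:, j]
                target = "m1"
            else:
                j = pool[rng.integers(len(pool))]
                m = panel.D[:, j]
                blues = _simulate_traits(panel, grid, (m, m), (s1, s2), rng)
                cand = {"target": m}
                for jw in panel.window(j, cap=grid.window_cap):
                    cand[f"w{jw}"] = panel.D[:, jw]
                target = "target"
            res = scan_2d(
                target,
                ("T1", "T2"),
                blues,
                None,
                panel.kinship,
                alpha=grid.alpha,
                candidates=cand,
                fast=grid.fast_scan,
            )
        except (RuntimeError, ValueError):
            n_failed += 1
            continue
        if res.verdict == "untestable" or not np.isfinite(res.p_value):
            n_failed += 1
            continue
        n_done += 1
        n_rej += int(res.verdict == LINKAGE)
    prop = n_rej / n_done if n_done else float("nan")
    return {
        **cell,
        "proportion": prop,
        "binomial_se": float(np.sqrt(prop * (1 - prop) / n_done))
        if n_done
        else float("nan"),
        "n_done": n_done,
        "n_failed": n_failed,
        "unreliable": n_failed > 0.2 * grid.n_replicates,
    }


def run_grid(grid: ScenarioGrid, panel: SimulationPanel | None = None) -> PowerTable:
    """Run every cell of the grid with independent sub-seeds.

    Fully reproducible from (grid, grid.seed): the panel (when not
    supplied) and each cell derive child seeds from the grid seed.
    """
    root = np.random.SeedSequence(grid.seed)
    panel_seq, cells_seq = root.spawn(2)
    cells = grid.cells()
    if panel is None:
        # a finite panel may by chance hold no band-matched pair for a cell
        # (the rare-MAF x moderate-r^2 corner); regenerate deterministically
        # until every cell is feasible
        for attempt, sub in enumerate(panel_seq.spawn(12)):
            panel = SimulationPanel.default(
                grid.n_genotypes, seed=int(sub.generate_state(1)[0] % (2**31))
            )
            if panel_supports(panel, grid):
                break
        else:
            raise InfeasibleLD(
                "no synthetic panel realization supported every grid cell"
            )
    cell_seqs = cells_seq.spawn(len(cells))
    rows = [
        run_scenario(cell, panel, grid, seed_seq=cell_seqs[i])
        for i, cell in enumerate(cells)
    ]
    table = pd.DataFrame(rows)
    table["qtl_size"] = table["qtl_size"].map(
        lambda s: s if np.isscalar(s) else tuple(np.atleast_1d(s).tolist())
    )
    return PowerTable(table=table, mode=grid.mode, n_replicates=grid.n_replicates)
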