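"""Synthetic genotype panels and multi-environment phenotypes.

The generator emulates the statistical features the downstream analyses rely
on for a panel of ~372 inbred wheat varieties: bi-allelic mapped markers
with a realistic MAF spectrum, intrachromosomal LD decaying with map
distance, a non-trivial kinship structure, and alpha-lattice
multi-environment phenotypes with separate genetic, genotype-x-environment
and plot-error variance components.

Genotypes are built as founder-haplotype mosaics: each inbred line is a
Markov mosaic over a pool of founder haplotypes, switching founders along
the chromosome at a rate set by ``ld_decay_cM``; ``kinship_strength`` is the
probability that a line copies the founder choice of its family's reference
mosaic instead of choosing freely, which induces families of related lines
and hence an informative Rogers'-distance kinship.  Only the first and
second moments of the panel matter downstream, so no attempt is made to
model wheat demography or selection history.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import PLOT_LEVEL, GenotypeMatrix, KinshipMatrix, TraitDataset
from .genostats import max_r2, minor_allele_frequency

__all__ = [
    "SimPopulationSpec",
    "SimTraitSpec",
    "InfeasibleLD",
    "simulate_genotypes",
    "simulate_marker_pair",
    "simulate_linked_neighbors",
    "simulate_phenotypes",
]


class InfeasibleLD(ValueError):
    """Requested (MAF, r^2) combination exceeds the two-locus r^2 bound."""


@dataclass
class SimPopulationSpec:
    """Parameters of the synthetic inbred panel.

    Defaults mirror the study conditions: 372 genotypes, up to 21
    chromosomes.  ``maf_range`` bounds the realized minor allele
    frequencies; ``ld_decay_cM`` is the founder-switch length scale (larger
    values -> slower r^2 decay); ``kinship_strength`` in [0, 1) controls
    founder sharing within families.
    """

    n_genotypes: int = 372
    n_markers_per_chrom: int = 200
    n_chromosomes: int = 10
    maf_range: tuple = (0.05, 0.5)
    ld_decay_cM: float = 2.0
    kinship_strength: float = 0.5
    n_founders: int = 24
    n_families: int = 25
    chrom_length_cM: float = 150.0
    heterozygosity: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_genotypes <= 0 or self.n_markers_per_chrom <= 0:
            raise ValueError("counts must be positive")
        if not 1 <= self.n_chromosomes <= 21:
            raise ValueError("n_chromosomes must be in [1, 21]")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.kinship_strength < 1:
            raise ValueError("kinship_strength must be in [0, 1)")
        if self.ld_decay_cM <= 0:
            raise ValueError("ld_decay_cM must be positive")


@dataclass
class SimTraitSpec:
    """Trait architecture for the phenotype simulator.

    Per-trait polygenic variance ``var_G``, genotype-x-environment variance
    ``var_GxE`` and plot error variance ``var_Error``; ``genetic_corr`` is
    the polygenic correlation matrix among traits.  QTL effects
    (marker, trait, additive effect per dosage unit) add variance on top of
    ``var_G``.  Replicate and incomplete-block effects are i.i.d. normal
    with variances ``var_Rep`` / ``var_Block`` (blocks partition each
    replicate into groups of ``block_size`` plots).
    """

    trait_names: list
    var_G: dict
    var_GxE: dict
    var_Error: dict
    genetic_corr: np.ndarray = None
    n_environments: int = 2
    n_replicates: int = 2
    qtl_effects: list = field(default_factory=list)
    var_Rep: float = 0.3
    var_Block: float = 0.3
    block_size: int = 10
    trait_means: dict = field(default_factory=dict)

    def __post_init__(self):
        t = len(self.trait_names)
        if self.genetic_corr is None:
            self.genetic_corr = np.eye(t)
        C = np.asarray(self.genetic_corr, dtype=float)
        if C.shape != (t, t):
            raise ValueError("genetic_corr must be trait x trait")
        if not np.allclose(C, C.T) or not np.allclose(np.diag(C), 1.0):
            raise ValueError("genetic_corr must be symmetric with unit diagonal")
        if np.linalg.eigvalsh(C)[0] < -1e-10:
            raise ValueError("genetic_corr must be positive semidefinite")
        self.genetic_corr = C
        for name in self.trait_names:
            for dct, lab in (
                (self.var_G, "var_G"),
                (self.var_GxE, "var_GxE"),
                (self.var_Error, "var_Error"),
            ):
                if name not in dct:
                    raise ValueError(f"{lab} missing for trait {name!r}")
                if dct[name] < 0:
                    raise ValueError(f"{lab}[{name!r}] must be >= 0")


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def _founder_haplotypes(m, n_founders, maf_range, p_copy, rng):
    """Founder allele matrix with along-chromosome autocorrelation.

    Each founder haplotype is a Markov chain over markers: with probability
    ``p_copy[j]`` the allele at marker j is copied from marker j-1 (ancestral
    haplotype sharing between adjacent loci), otherwise it is redrawn from
    the marker's target frequency.  This is what makes nearby markers of the
    panel sit in LD blocks once lines inherit founder segments.  Target
    frequencies are block-constant along the chromosome (segments of ~8
    markers share one frequency drawn from ``maf_range``), so rare- and
    common-allele regions are coherent and every MAF class contains marker
    pairs across the whole r^2 range, as on real SNP arrays.
    """
    lo, hi = maf_range
    seg_p = []
    while len(seg_p) < m:
        # L-shaped MAF spectrum: rare-allele segments are over-represented,
        # as on real SNP arrays
        f = lo + (hi - lo) * rng.random() ** 1.7
        if rng.random() < 0.5:
            f = 1.0 - f
        seg_p.extend([f] * int(rng.geometric(1 / 8.0)))
    p = np.asarray(seg_p[:m])
    H = np.empty((n_founders, m), dtype=np.int8)
    H[:, 0] = rng.random(n_founders) < p[0]
    for j in range(1, m):
        copy = rng.random(n_founders) < p_copy[j]
        fresh = rng.random(n_founders) < p[j]
        H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def simulate_genotypes(spec: SimPopulationSpec) -> GenotypeMatrix:
    """Simulate an inbred panel as founder-haplotype mosaics.

    Markers are ordered by (chromosome, cM) with positions uniform on
    [0, chrom_length_cM].  Realized minor allele frequencies are pushed into
    ``spec.maf_range`` by redrawing the founder alleles of violating markers
    (bounded retries), keeping the mosaic structure fixed.
    """
    rng = np.random.default_rng(spec.seed)
    n, m, F = spec.n_genotypes, spec.n_markers_per_chrom, spec.n_founders
    fam = rng.integers(spec.n_families, size=n)

    dosage_cols, chroms, poss, ids = [], [], [], []
    for c in range(spec.n_chromosomes):
        pos = np.sort(rng.uniform(0.0, spec.chrom_length_cM, size=m))
        gaps = np.diff(pos, prepend=pos[0])
        p_stay = np.exp(-gaps / spec.ld_decay_cM)
        founders = _founder_haplotypes(m, F, spec.maf_range, p_stay, rng)

        # family reference mosaics, then per-line mosaics that copy the
        # family reference with probability kinship_strength at each marker
        ref = np.empty((spec.n_families, m), dtype=np.int64)
        ref[:, 0] = rng.integers(F, size=spec.n_families)
        state = np.empty((n, m), dtype=np.int64)
        state[:, 0] = ref[fam, 0]
        fresh0 = rng.random(n) >= spec.kinship_strength
        state[fresh0, 0] = rng.integers(F, size=int(fresh0.sum()))
        for j in range(1, m):
            jump_ref = rng.random(spec.n_families) >= p_stay[j]
            ref[:, j] = np.where(
                jump_ref, rng.integers(F, size=spec.n_families), ref[:, j - 1]
            )
            jump = rng.random(n) >= p_stay[j]
            new = np.where(
                rng.random(n) < spec.kinship_strength,
                ref[fam, j],
                rng.integers(F, size=n),
            )
            state[:, j] = np.where(jump, new, state[:, j - 1])

        hap = founders[state, np.arange(m)[None, :]]
        dos = (2 * hap).astype(float)

        # push realized MAFs into range by flipping single founder alleles
        # (small nudges that leave the LD-block structure intact)
        lo, hi = spec.maf_range
        for j in range(m):
            col = founders[:, j].astype(np.int8).copy()
            for _ in range(4 * F):
                f = float(col[state[:, j]].mean())
                maf = min(f, 1.0 - f)
                if lo - 1e-9 <= maf <= hi + 1e-9:
                    break
                increase_f = (maf < lo) == (f <= 0.5)
                pool = np.flatnonzero(col == (0 if increase_f else 1))
                if pool.size == 0:
                    break
                col[rng.choice(pool)] ^= 1
            dos[:, j] = 2.0 * col[state[:, j]]
            if spec.heterozygosity > 0:
                het = rng.random(n) < spec.heterozygosity
                dos[het, j] = 1.0

        dosage_cols.append(dos)
        chroms.extend([f"{c + 1}"] * m)
        poss.extend(pos.tolist())
        ids.extend([f"chr{c + 1}_m{j}" for j in range(m)])

    return GenotypeMatrix(
        dosages=np.concatenate(dosage_cols, axis=1),
        marker_ids=ids,
        chromosome=np.array(chroms),
        position_cM=np.array(poss),
        genotype_ids=[f"V{i:04d}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# engineered marker pairs / clusters
# ---------------------------------------------------------------------------


def _haplotype_freqs(p: float, q: float, r2: float) -> np.ndarray:
    """Frequencies of haplotypes (11, 10, 01, 00) with positive D."""
    D = np.sqrt(r2 * p * (1 - p) * q * (1 - q))
    f = np.array(
        [p * q + D, p * (1 - q) - D, (1 - p) * q - D, (1 - p) * (1 - q) + D]
    )
    if (f < -1e-12).any():
        raise InfeasibleLD("haplotype frequencies out of range")
    return np.clip(f, 0.0, None) / f.sum()


def simulate_marker_pair(
    maf1: float,
    maf2: float,
    target_r2: float,
    n: int,
    seed: int | np.random.Generator = 0,
    maf_tol: float = 0.02,
    r2_tol: float = 0.03,
    max_attempts: int = 200,
):
    """Two inbred dosage vectors with requested MAFs and r^2.

    Draws per-line two-locus haplotypes from the standard haplotype-frequency
    parameterization (positive D) and rejection-samples until the realized
    MAFs are within ``maf_tol`` and realized r^2 within ``r2_tol`` of the
    request.  Raises :class:`InfeasibleLD` when ``target_r2`` exceeds the
    two-locus bound for the given frequencies.
    """
    bound = max_r2(maf1, maf2)
    if target_r2 > bound + 1e-9:
        raise InfeasibleLD(
            f"r^2={target_r2} infeasible for MAFs ({maf1}, {maf2}): "
            f"upper bound is {bound:.4f}"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if target_r2 >= 1.0 - 1e-12:
        # exact: identical loci
        for _ in range(max_attempts):
            d = 2.0 * (rng.random(n) < maf1)
            f = d.sum() / (2 * n)
            if abs(min(f, 1 - f) - maf1) <= maf_tol and 0 < f < 1:
                return d.copy(), d.copy()
        raise RuntimeError("could not realize requested MAF for r^2=1 pair")
    freqs = _haplotype_freqs(maf1, maf2, target_r2)
    for _ in range(max_attempts):
        hap = rng.choice(4, size=n, p=freqs)
        d1 = 2.0 * np.isin(hap, (0, 1))
        d2 = 2.0 * np.isin(hap, (0, 2))
        try:
            f1 = minor_allele_frequency(d1)
            f2 = minor_allele_frequency(d2)
        except ValueError:
            continue
        if abs(f1 - maf1) > maf_tol or abs(f2 - maf2) > maf_tol:
            continue
        v1, v2 = d1.std(), d2.std()
        if v1 == 0 or v2 == 0:
            continue
        r2 = float(np.corrcoef(d1, d2)[0, 1] ** 2)
        if abs(r2 - target_r2) <= r2_tol:
            return d1, d2
    raise RuntimeError(
        f"no draw met the MAF/r^2 tolerances in {max_attempts} attempts"
    )


def simulate_linked_neighbors(
    target: np.ndarray,
    r2_levels,
    seed: int | np.random.Generator = 0,
):
    """Markers in LD with an existing inbred dosage vector.

    For each requested r^2 level, a neighbour locus with the same allele
    frequency is drawn conditionally on the target's alleles via the
    two-locus haplotype parameterization.  Used to give a simulated causal
    marker a realistic surrounding r^2 > 0.5 window.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    d = np.asarray(target, dtype=float)
    n = d.size
    p = d.sum() / (2 * n)
    p = min(p, 1 - p)
    carrier = d >= 1.0 if d.sum() / (2 * n) <= 0.5 else d < 1.0
    out = []
    for r2 in r2_levels:
        f = _haplotype_freqs(p, p, min(r2, max_r2(p, p)))
        # conditional allele-1 prob for neighbour given target allele
        p_given1 = f[0] / (f[0] + f[1])
        p_given0 = f[2] / (f[2] + f[3])
        prob = np.where(carrier, p_given1, p_given0)
        out.append(2.0 * (rng.random(n) < prob))
    return out


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def _psd_chol(M: np.ndarray) -> np.ndarray:
    if not M.any():
        return np.zeros_like(M)
    lam_min = np.linalg.eigvalsh(M)[0]
    shift = max(0.0, -lam_min) + 1e-12 * float(np.trace(M))
    return np.linalg.cholesky(M + shift * np.eye(M.shape[0]))


def simulate_phenotypes(
    geno: GenotypeMatrix,
    kinship: KinshipMatrix,
    spec: SimTraitSpec,
    seed: int = 0,
) -> TraitDataset:
    """Plot-level alpha-lattice phenotypes with known variance components.

    Per trait k:  y = mean + sum_QTL a * dosage + polygenic + GxE + replicate
    + block + plot error, with polygenic values drawn from
    N(0, G0 (x) A) where G0 = diag(sd) * genetic_corr * diag(sd) and the
    per-trait scale is chosen so the population polygenic variance equals
    ``var_G`` (A's mean diagonal, 2 for inbreds, is divided out).  GxE terms
    are i.i.d. per genotype-environment cell and independent across traits.
    """
    rng = np.random.default_rng(seed)
    n = geno.n_genotypes
    t = len(spec.trait_names)
    for mk, tr, _ in spec.qtl_effects:
        geno.index_of(mk)  # raises on unknown marker
        if tr not in spec.trait_names:
            raise ValueError(f"QTL effect for unknown trait {tr!r}")

    a_scale = float(np.mean(np.diag(kinship.A_psd)))
    sd = np.sqrt(
        np.array([spec.var_G[tr] for tr in spec.trait_names]) / max(a_scale, 1e-12)
    )
    G0 = np.outer(sd, sd) * spec.genetic_corr
    if t > 1 and np.linalg.matrix_rank(spec.genetic_corr) < t and min(sd) > 0:
        pass  # singular correlations are permitted; the Cholesky below shifts
    L_A = _psd_chol(kinship.A_psd)
    polygenic = L_A @ rng.standard_normal((n, t)) @ _psd_chol(G0).T  # (n, t)

    qtl_part = np.zeros((n, t))
    for mk, tr, eff in spec.qtl_effects:
        k = spec.trait_names.index(tr)
        qtl_part[:, k] += eff * geno.column(mk)

    records = []
    n_blocks = max(1, int(np.ceil(n / spec.block_size)))
    for j in range(spec.n_environments):
        env = f"E{j + 1}"
        gxe = rng.normal(
            0.0,
            np.sqrt([spec.var_GxE[tr] for tr in spec.trait_names]),
            size=(n, t),
        )
        for r in range(spec.n_replicates):
            rep = f"R{r + 1}"
            rep_eff = rng.normal(0.0, np.sqrt(spec.var_Rep))
            blocks = rng.permutation(n) // spec.block_size
            block_eff = rng.normal(0.0, np.sqrt(spec.var_Block), size=n_blocks)
            err = rng.normal(
                0.0,
                np.sqrt([spec.var_Error[tr] for tr in spec.trait_names]),
                size=(n, t),
            )
            for k, tr in enumerate(spec.trait_names):
                mu = spec.trait_means.get(tr, 0.0)
                vals = (
                    mu
                    + qtl_part[:, k]
                    + polygenic[:, k]
                    + gxe[:, k]
                    + rep_eff
                    + block_eff[blocks]
                    + err[:, k]
                )
                records.append(
                    pd.DataFrame(
                        {
                            "genotype": geno.genotype_ids,
                            "environment": env,
                            "replicate": rep,
                            "block": [f"{rep}B{b + 1}" for b in blocks],
                            "trait": tr,
                            "value": vals,
                        }
                    )
                )
    return TraitDataset(pd.concat(records, ignore_index=True), stage=PLOT_LEVEL)
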