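"""Marker summary statistics, Rogers' distances / kinship, LD and M_eff.

Conventions
-----------
* Dosages code the count of the minor (second) allele, 0/1/2, NaN = missing.
* Rogers' distance between two individuals is the per-locus Euclidean
  distance between their within-individual allele-frequency vectors averaged
  over loci; for dosage data this reduces to ``mean(|d_i - d_j| / 2)``, so
  fully opposite inbreds are at distance 1 and heterozygotes contribute 0.5.
* The relationship matrix is A = 2 (J - RD).  A is not guaranteed positive
  semidefinite; ``kinship_from_genotypes`` records a minimum-eigenvalue
  "bend" (added to the diagonal only when needed) so REML always receives a
  valid covariance.
* M_eff of an r^2 matrix is the smallest number of leading eigenvalues whose
  cumulative share of the total (negative eigenvalues floored at zero)
  reaches the variance threshold (default 95%); the matrix is not re-centred
  before the eigen-decomposition.
"""

from __future__ import annotations

import math
import warnings

import numpy as np

from .containers import GenotypeMatrix, KinshipMatrix, LDMatrix

__all__ = [
    "minor_allele_frequency",
    "rogers_distance_matrix",
    "kinship_from_genotypes",
    "ld_r2",
    "ld_matrix",
    "m_eff",
    "m_eff_genomewide",
    "ld_window",
    "impute_functional",
    "MarkerExcluded",
    "expand_multiallelic",
]


class MarkerExcluded(Exception):
    """Raised when a marker fails a QC rule (e.g. too much missing data)."""


def minor_allele_frequency(dosage_vector) -> float:
    """Minor allele frequency of a dosage vector, ignoring missing entries."""
    d = np.asarray(dosage_vector, dtype=float)
    obs = d[~np.isnan(d)]
    if obs.size < 2:
        raise ValueError("need at least 2 non-missing dosages for a MAF")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def _pairwise_abs_diff_sums(D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sum over pairwise-complete loci of |d_i - d_l|, and the pair counts.

    Uses indicator-matrix products so the n x n result needs only a handful
    of (n x m) @ (m x n) multiplications even for ~2e4 markers.
    """
    obs = ~np.isnan(D)
    levels = [(D == v) & obs for v in (0.0, 1.0, 2.0)]
    n = D.shape[0]
    total = np.zeros((n, n))
    for a, Ma in enumerate(levels):
        Fa = Ma.astype(float)
        for b, Mb in enumerate(levels):
            if abs(a - b) == 0:
                continue
            total += abs(a - b) * (Fa @ Mb.astype(float).T)
    counts = obs.astype(float) @ obs.astype(float).T
    return total, counts


def rogers_distance_matrix(geno: GenotypeMatrix) -> np.ndarray:
    """Rogers' distance matrix among all genotypes (pairwise-complete loci)."""
    diff, counts = _pairwise_abs_diff_sums(geno.dosages)
    if (counts == 0).any():
        i, l = np.argwhere(counts == 0)[0]
        raise ValueError(
            f"genotypes {geno.genotype_ids[i]!r} and {geno.genotype_ids[l]!r} "
            "share no non-missing markers"
        )
    RD = diff / (2.0 * counts)
    np.fill_diagonal(RD, 0.0)
    return (RD + RD.T) / 2.0


def kinship_from_genotypes(geno: GenotypeMatrix, eps: float = 1e-6) -> KinshipMatrix:
    """A = 2 (J - RD) with minimum-eigenvalue bending when A is indefinite."""
    RD = rogers_distance_matrix(geno)
    A = 2.0 * (1.0 - RD)
    lam_min = float(np.linalg.eigvalsh(A)[0])
    bending = (-lam_min + eps) if lam_min < 0 else 0.0
    return KinshipMatrix(A=A, RD=RD, genotype_ids=list(geno.genotype_ids), bending=bending)


def ld_r2(v1, v2) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Pairwise-complete observations; invariant to allele relabeling
    (v <-> 2 - v).
    """
    a = np.asarray(v1, dtype=float)
    b = np.asarray(v2, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 3:
        raise ValueError("need at least 3 complete dosage pairs for r^2")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise ValueError("monomorphic marker: zero dosage variance")
    r = float(np.corrcoef(a, b)[0, 1])
    return min(r * r, 1.0)


def _corr2_complete(D: np.ndarray) -> np.ndarray:
    X = D - D.mean(axis=0)
    sd = X.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic marker in LD matrix computation")
    C = (X / sd).T @ (X / sd) / D.shape[0]
    return np.clip(C * C, 0.0, 1.0)


def ld_matrix(geno: GenotypeMatrix, chromosome=None, marker_ids=None) -> LDMatrix:
    """r^2 matrix for one chromosome (or an explicit marker subset).

    Only markers with finite (mapped) positions enter a chromosome matrix;
    an explicit ``marker_ids`` list bypasses that filter.
    """
    if marker_ids is not None:
        idx = [geno.index_of(m) for m in marker_ids]
        ids = list(marker_ids)
    else:
        if chromosome is None:
            raise ValueError("give either a chromosome or a marker_ids list")
        mask = (geno.chromosome.astype(str) == str(chromosome)) & np.isfinite(
            geno.position_cM
        )
        idx = np.flatnonzero(mask).tolist()
        ids = [geno.marker_ids[i] for i in idx]
    if not idx:
        raise ValueError("no markers selected for LD matrix")
    D = geno.dosages[:, idx]
    if np.isnan(D).any():
        m = len(idx)
        r2 = np.ones((m, m))
        for a in range(m):
            for b in range(a + 1, m):
                r2[a, b] = r2[b, a] = ld_r2(D[:, a], D[:, b])
    else:
        r2 = _corr2_complete(D)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(r2=r2, marker_ids=ids)


def m_eff(ld: LDMatrix | np.ndarray, variance_threshold: float = 0.95) -> int:
    """Effective number of independent markers from an r^2 matrix.

    Smallest k such that the top-k eigenvalues account for at least
    ``variance_threshold`` of the eigenvalue total.  Negative eigenvalues
    (possible because r^2 of dosages is only approximately Gram) are floored
    at zero before the cumulative sum.
    """
    r2 = ld.r2 if isinstance(ld, LDMatrix) else np.asarray(ld, dtype=float)
    if not np.isfinite(r2).all():
        raise ValueError("non-finite entries in r^2 matrix")
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must be in (0, 1]")
    lam = np.linalg.eigvalsh((r2 + r2.T) / 2.0)[::-1]
    lam = np.maximum(lam, 0.0)
    total = lam.sum()
    if total <= 0:
        raise ValueError("degenerate r^2 matrix: zero eigenvalue mass")
    cum = np.cumsum(lam) / total
    return int(np.searchsorted(cum, variance_threshold - 1e-12) + 1)


def m_eff_genomewide(geno: GenotypeMatrix, variance_threshold: float = 0.95) -> int:
    """Sum of per-chromosome M_eff values over all chromosomes."""
    chroms = np.unique(geno.chromosome[np.isfinite(geno.position_cM)])
    if chroms.size == 0:
        raise ValueError("no mapped markers")
    return sum(
        m_eff(ld_matrix(geno, chromosome=c), variance_threshold) for c in chroms
    )


def ld_window(geno: GenotypeMatrix, target_marker, r2_min: float = 0.5) -> list:
    """Markers on the target's chromosome with r^2 > r2_min to the target.

    The target itself is excluded; only markers with unique mapped positions
    are candidates.  An empty list means the 2D pleiotropy-vs-linkage test
    cannot be run for this target.
    """
    ti = geno.index_of(target_marker)
    if not np.isfinite(geno.position_cM[ti]):
        raise ValueError(f"target marker {target_marker!r} is unmapped")
    chrom = geno.chromosome[ti]
    pos = geno.position_cM
    same = (geno.chromosome == chrom) & np.isfinite(pos)
    target = geno.dosages[:, ti]
    out = []
    for j in np.flatnonzero(same):
        if j == ti:
            continue
        try:
            r2 = ld_r2(target, geno.dosages[:, j])
        except ValueError:
            continue  # monomorphic neighbour cannot be a candidate position
        if r2 > r2_min:
            out.append(geno.marker_ids[j])
    return out


def impute_functional(
    dosage_vector, max_missing: float = 0.10, seed: int | np.random.Generator = 0
):
    """Impute missing dosages from the observed genotype-class frequencies.

    Markers with a missing fraction at or above ``max_missing`` are excluded
    by raising :class:`MarkerExcluded` (the caller decides how to log it).
    """
    d = np.asarray(dosage_vector, dtype=float).copy()
    miss = np.isnan(d)
    frac = miss.mean()
    if frac >= max_missing:
        raise MarkerExcluded(
            f"missing fraction {frac:.2f} >= threshold {max_missing:.2f}"
        )
    if not miss.any():
        return d
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    obs = d[~miss]
    classes, counts = np.unique(obs, return_counts=True)
    d[miss] = rng.choice(classes, size=miss.sum(), p=counts / counts.sum())
    return d


def expand_multiallelic(calls) -> dict:
    """Expand a multi-allelic marker into per-allele bi-allelic dosages.

    ``calls`` is a sequence of per-genotype allele pairs (2-tuples, or
    strings like ``"A/B"``); each observed allele becomes one presence-dosage
    vector and the vectors sum to 2 per genotype (diploid conservation).
    A marker with a single observed allele yields an empty dict with a
    warning.
    """
    pairs = []
    for c in calls:
        if isinstance(c, str):
            parts = c.split("/")
            if len(parts) != 2:
                raise ValueError(f"cannot parse allele call {c!r}")
            pairs.append(tuple(parts))
        else:
            a, b = c
            pairs.append((a, b))
    alleles = sorted({a for p in pairs for a in p})
    if len(alleles) < 2:
        warnings.warn("single-allele marker: nothing to expand", stacklevel=2)
        return {}
    out = {}
    for allele in alleles:
        out[allele] = np.array(
            [float(sum(a == allele for a in p)) for p in pairs]
        )
    return out


def max_r2(p: float, q: float) -> float:
    """Upper bound of r^2 between two loci with minor allele frequencies p, q.

    From the two-locus haplotype parameterization: D_max = min(p(1-q), q(1-p))
    for positive association, so r^2_max = D_max^2 / (p(1-p) q(1-q)).
    """
    for f in (p, q):
        if not 0 < f <= 0.5:
            raise ValueError("allele frequencies must lie in (0, 0.5]")
    d_max = min(p * (1 - q), q * (1 - p))
    return min(1.0, d_max**2 / (p * (1 - p) * q * (1 - q)))
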