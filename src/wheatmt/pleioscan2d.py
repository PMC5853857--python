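"""Two-dimensional likelihood scan: pleiotropy versus close linkage.

For a target marker with a joint two-trait association, the scan contrasts

* the pleiotropy model  y_ki = mu_k + alpha_k * m_i + g_ki + e_ki, in which
  the QTLs for both traits sit at the same position m, with
* the close-linkage model
  y_1i = mu_1 + alpha_1 * m1_i + g_1i + e_1i,
  y_2i = mu_2 + alpha_2 * m2_i + g_2i + e_2i, in which each trait's QTL sits
  at its own position,

both fitted by maximum likelihood on across-environment BLUEs under the
bivariate covariance G0 (x) A + R0 (x) I.  Candidate positions are the
target plus its LD window (markers with r^2 > 0.5).  L0 is the best
log-likelihood on the diagonal of the candidate x candidate grid (same
position for both traits) and L1 the best anywhere on the grid, so
LR = 2 (L1 - L0) >= 0 by construction; LR is referred to chi-square with 1
degree of freedom at a nominal alpha of 0.05, exactly the convention the
test was proposed with (the two models are not strictly nested, a caveat
that is accepted here).

ML, not REML, is mandatory because the two models differ in fixed effects.
Both orderings of each marker pair (which marker carries which trait's
effect) are scanned and the maximum taken.  Variance components are
re-estimated at every grid point by default; ``fast=True`` re-uses the
null-model (no marker) estimates and only re-solves the GLS step, a
documented approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GenotypeMatrix, KinshipMatrix
from .genostats import ld_window
from .mixedmodel import RotatedKernel, fit_kernel

__all__ = ["ScanResult2D", "HaplotypeTable", "scan_2d", "count_haplotypes"]

PLEIOTROPY_NOT_REJECTED = "pleiotropy-not-rejected"
LINKAGE = "linkage"
UNTESTABLE = "untestable"


@dataclass
class ScanResult2D:
    target_marker: object
    window: list
    L0: float = np.nan
    L1: float = np.nan
    LR: float = np.nan
    p_value: float = np.nan
    best_pleiotropy_marker: object = None
    best_linkage_pair: tuple | None = None
    verdict: str = UNTESTABLE
    alpha: float = 0.05
    excluded_points: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "target": self.target_marker,
            "window_size": len(self.window),
            "L0": self.L0,
            "L1": self.L1,
            "LR": self.LR,
            "p_value": self.p_value,
            "best_pleiotropy_marker": self.best_pleiotropy_marker,
            "best_linkage_pair": self.best_linkage_pair,
            "verdict": self.verdict,
        }


def _dosages_for(geno, candidates, target):
    """Resolve candidate dosage vectors from either a dict or a GenotypeMatrix."""
    if isinstance(candidates, dict):
        if target not in candidates:
            raise KeyError("target must be among the candidate dosages")
        return dict(candidates)
    raise TypeError("candidates must be a dict of marker -> dosage vector")


def scan_2d(
    target,
    trait_pair,
    blues_wide: pd.DataFrame,
    geno: GenotypeMatrix | None,
    kinship: KinshipMatrix,
    alpha: float = 0.05,
    r2_min: float = 0.5,
    candidates: dict | None = None,
    fast: bool = False,
) -> ScanResult2D:
    """Run the two-dimensional pleiotropy-vs-linkage scan for one target.

    Parameters
    ----------
    target : marker id (must be in ``geno`` or in ``candidates``).
    trait_pair : the two trait names, columns of ``blues_wide``.
    blues_wide : genotype x trait table of across-environment BLUEs, indexed
        by the kinship's genotype ids.
    geno : genotype matrix used to build the r^2 > ``r2_min`` window; may be
        None when explicit ``candidates`` (marker -> dosage vector) are given.
    candidates : optional explicit candidate set including the target.
    fast : re-use null-model variance components across the grid.

    An empty window yields an ``untestable`` result, mirroring targets that
    must be skipped for lack of surrounding linked markers.
    """
    t1, t2 = trait_pair
    gids = list(kinship.genotype_ids)
    blues = blues_wide.loc[gids, [t1, t2]]
    if blues.isna().any().any():
        raise ValueError("BLUEs must be available for both traits, all genotypes")

    if candidates is not None:
        cand = _dosages_for(geno, candidates, target)
        window = [c for c in cand if c != target]
    else:
        if geno is None:
            raise ValueError("need a GenotypeMatrix when candidates are not given")
        window = ld_window(geno, target, r2_min=r2_min)
        cand = {m: geno.column(m) for m in [target, *window]}
    if not window:
        return ScanResult2D(target_marker=target, window=[], alpha=alpha)

    # one-time rotation by the eigenvectors of A: every grid model then
    # lives in the same block-diagonal likelihood family and differs only
    # in two design columns
    lam, U = kinship.eig()
    n = len(gids)
    y_rot = np.vstack([U.T @ blues[t1].to_numpy(), U.T @ blues[t2].to_numpy()])
    ones_rot = U.T @ np.ones(n)
    names = [target, *window]
    m_rot = {}
    excluded = []
    for c in names:
        v = np.asarray(cand[c], dtype=float)
        if v.std() == 0:
            excluded.append(((c, c), "monomorphic candidate"))
            continue
        m_rot[c] = U.T @ v
    names = [c for c in names if c in m_rot]
    if target not in m_rot:
        warnings.warn(f"monomorphic target {target!r}", stacklevel=2)
        return ScanResult2D(
            target_marker=target, window=window, alpha=alpha,
            excluded_points=excluded,
        )

    def kernel_for(m1_rot, m2_rot):
        p = 2 if m1_rot is None else 4
        X = np.zeros((2, n, p))
        X[0, :, 0] = ones_rot
        X[1, :, 1] = ones_rot
        if m1_rot is not None:
            X[0, :, 2] = m1_rot
            X[1, :, 3] = m2_rot
        return RotatedKernel(y_rot, X, lam)

    # null model (no marker): warm start / fixed (G0, R0) for the grid
    y_resid = blues[[t1, t2]].to_numpy()
    S = np.cov(y_resid.T) / 2.0
    from .mixedmodel import _theta_from_cov

    start0 = np.concatenate(
        [_theta_from_cov(S / max(np.mean(np.diag(kinship.A_psd)), 1e-8)),
         _theta_from_cov(S)]
    )
    null = fit_kernel(kernel_for(None, None), 2, "ml", start=start0)

    llgrid = {}
    for c1 in names:
        for c2 in names:
            kern = kernel_for(m_rot[c1], m_rot[c2])
            if fast:
                out = kern.gls(null.G0, null.R0)
                if out is None:
                    excluded.append(((c1, c2), "invalid covariance"))
                    continue
                logdet, _, _, quad = out
                ll = -0.5 * (kern.N * np.log(2 * np.pi) + logdet + quad)
            else:
                try:
                    fit = fit_kernel(kern, 2, "ml", start=null.theta)
                except RuntimeError:
                    excluded.append(((c1, c2), "non-convergent fit"))
                    continue
                if not fit.converged or not np.isfinite(fit.llf):
                    excluded.append(((c1, c2), "non-convergent fit"))
                    continue
                ll = fit.llf
            llgrid[(c1, c2)] = float(ll)
    diag = {c: llgrid[(c, c)] for c in names if (c, c) in llgrid}
    if not diag:
        warnings.warn(f"no diagonal fit converged for target {target!r}", stacklevel=2)
        return ScanResult2D(
            target_marker=target, window=window, alpha=alpha,
            excluded_points=excluded,
        )
    best_diag = max(diag, key=diag.get)
    L0 = diag[best_diag]
    best_pair = max(llgrid, key=llgrid.get)
    L1 = llgrid[best_pair]
    LR = max(0.0, 2.0 * (L1 - L0))
    p = float(stats.chi2.sf(LR, 1))
    return ScanResult2D(
        target_marker=target,
        window=window,
        L0=float(L0),
        L1=float(L1),
        LR=float(LR),
        p_value=p,
        best_pleiotropy_marker=best_diag,
        best_linkage_pair=best_pair,
        verdict=LINKAGE if p < alpha else PLEIOTROPY_NOT_REJECTED,
        alpha=alpha,
        excluded_points=excluded,
    )


@dataclass
class HaplotypeTable:
    """Two-locus haplotype counts/frequencies across inbred genotypes.

    Haplotypes are indexed by (allele at locus 1, allele at locus 2) with
    allele 1 = the minor (dosage-coded) allele.  ``effect_direction`` maps
    each haplotype to the predicted direction of its joint effect per trait
    given the per-locus additive effect signs (carrying the minor allele
    moves the trait in the direction of that locus's effect sign).
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame
    n_heterozygous_excluded: int
    effect_direction: dict = field(default_factory=dict)
    degenerate: bool = False


def count_haplotypes(m1, m2, effects: tuple | None = None) -> HaplotypeTable:
    """2 x 2 haplotype table for two bi-allelic loci in inbred lines.

    Heterozygous genotypes (dosage 1) at either locus are excluded with a
    count; a monomorphic locus flags the table as degenerate.
    """
    d1 = np.asarray(m1, dtype=float)
    d2 = np.asarray(m2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError("dosage vectors must have equal length")
    ok = np.isin(d1, (0.0, 2.0)) & np.isin(d2, (0.0, 2.0))
    n_het = int((~ok).sum())
    a1 = (d1[ok] / 2).astype(int)
    a2 = (d2[ok] / 2).astype(int)
    counts = np.zeros((2, 2), dtype=int)
    for x, y in zip(a1, a2):
        counts[x, y] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no homozygous genotypes to tabulate")
    freqs = counts / total
    idx = pd.Index([0, 1], name="allele_locus1")
    cols = pd.Index([0, 1], name="allele_locus2")
    degenerate = (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any()
    if degenerate:
        warnings.warn("monomorphic locus: degenerate haplotype table", stacklevel=2)
    directions = {}
    if effects is not None:
        e1, e2 = effects
        for x in (0, 1):
            for y in (0, 1):
                directions[(x, y)] = (
                    int(np.sign(e1) * (1 if x else -1)),
                    int(np.sign(e2) * (1 if y else -1)),
                )
    return HaplotypeTable(
        counts=pd.DataFrame(counts, index=idx, columns=cols),
        frequencies=pd.DataFrame(freqs, index=idx, columns=cols),
        n_heterozygous_excluded=n_het,
        effect_direction=directions,
        degenerate=bool(degenerate),
    )
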