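"""Genome-wide bivariate association scanning and its downstream summaries.

For each marker and trait pair the scan fits the bivariate mixed model on
stage-1 (per-environment) BLUEs,

    y_kji = mu_k + alpha_k * m_i + g_ki + l_kj + (alpha l)_kj * m_i + e_kji,

with polygenic values g ~ N(0, G0 (x) A) and errors R0 (x) I, marker and
marker x environment terms fixed, and tests the marker through a hierarchy
of Wald statistics: a global test of H0: alpha_1 = alpha_2 = 0 (df 2),
post-hoc per-trait tests (df 1), and global / per-trait tests of the
marker x environment interactions.  A marker is declared potentially
pleiotropic only when the global AND both per-trait tests are significant.

Multiple testing is handled by Benjamini-Hochberg FDR on the global
p-values (within a trait pair), Bonferroni, or the effective-marker-number
(M_eff) correction; collinearity among significant markers is summarized by
the effective number of associations (M_eff applied to their r^2 matrix);
explained variance is partitioned sequentially (markers entering by global
Wald p-value) and expressed as a share of genetic variance by dividing
phenotypic R^2 by the entry-mean heritability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import STAGE1, STAGE2, GenotypeMatrix, KinshipMatrix, TraitDataset
from .genostats import m_eff, minor_allele_frequency
from .mixedmodel import MultiTraitMixedModel, WaldResult

__all__ = [
    "AssociationRecord",
    "ScanSummary",
    "scan_bivariate",
    "correct_multiplicity",
    "bh_qvalues",
    "effective_association_count",
    "variance_partition",
    "higher_order_test",
    "stability_ratio",
]


@dataclass
class AssociationRecord:
    """Per-marker bivariate test results."""

    marker_id: object
    trait_pair: tuple
    alpha: dict  # trait -> marker effect (trait units per dosage)
    wald_global: WaldResult
    wald_per_trait: dict  # trait -> WaldResult
    wald_mxe_global: WaldResult | None
    wald_mxe_per_trait: dict
    p_raw: float
    q_fdr: float = np.nan
    significant: dict = field(default_factory=dict)
    covariation_sign: int = 0

    def row(self) -> dict:
        t1, t2 = self.trait_pair
        out = {
            "marker": self.marker_id,
            f"alpha[{t1}]": self.alpha[t1],
            f"alpha[{t2}]": self.alpha[t2],
            "wald_global": self.wald_global.statistic,
            "p_global": self.p_raw,
            f"p[{t1}]": self.wald_per_trait[t1].p_value,
            f"p[{t2}]": self.wald_per_trait[t2].p_value,
            "q_fdr": self.q_fdr,
            "covariation_sign": self.covariation_sign,
        }
        if self.wald_mxe_global is not None:
            out["p_mxe_global"] = self.wald_mxe_global.p_value
        for k, v in self.significant.items():
            out[f"sig_{k}"] = v
        return out


@dataclass
class ScanSummary:
    records: list
    n_significant: dict
    effective_associations: int | None = None


def bh_qvalues(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values: min over the tail of p * m / rank."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def correct_multiplicity(
    p_values, method: str, alpha: float = 0.05, m_eff_count: int | None = None
):
    """Multiple-testing correction of a p-value vector.

    ``method`` is ``fdr`` (returns BH q-values), ``bonferroni`` or ``meff``
    (both return the adjusted per-test threshold alpha / m).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    method = method.lower()
    if method == "fdr":
        return bh_qvalues(p)
    if method == "bonferroni":
        return alpha / p.size
    if method == "meff":
        if not m_eff_count or m_eff_count < 1:
            raise ValueError("meff correction requires a positive M_eff count")
        return alpha / m_eff_count
    raise ValueError(f"unknown correction method {method!r}")


def _fit_marker_model(blues1, kinship, traits, marker_vec, marker_by_env):
    sub = blues1.data[blues1.data["trait"].isin(traits)]
    markers = {tr: marker_vec for tr in traits}
    model = MultiTraitMixedModel(
        sub, kinship, markers=markers, marker_by_env=marker_by_env
    )
    return model.fit("reml")


def scan_bivariate(
    geno: GenotypeMatrix,
    blues1: TraitDataset,
    kinship: KinshipMatrix,
    trait_pair: tuple,
    alpha: float = 0.05,
    posthoc_alpha: float = 0.05,
    m_eff_count: int | None = None,
    markers=None,
    marker_by_env: bool = True,
) -> ScanSummary:
    """Bivariate association scan over markers for one trait pair.

    ``blues1`` holds stage-1 per-environment BLUEs (the scan's observation
    level).  Monomorphic markers are skipped with a log entry.  Significance
    flags: ``fdr`` (BH q < alpha), ``bonferroni`` and ``meff`` (global p
    below the adjusted threshold) -- each additionally gated on both
    per-trait post-hoc tests at ``posthoc_alpha``.
    """
    if blues1.stage != STAGE1:
        raise ValueError("scan_bivariate expects stage-1 BLUEs")
    t1, t2 = trait_pair
    marker_list = list(markers) if markers is not None else list(geno.marker_ids)
    gids = list(kinship.genotype_ids)
    records, skipped = [], []
    for mk in marker_list:
        v = geno.column(mk)
        try:
            if minor_allele_frequency(v) == 0:
                raise ValueError("monomorphic")
        except ValueError:
            skipped.append(mk)
            continue
        try:
            fit = _fit_marker_model(blues1, kinship, (t1, t2), v, marker_by_env)
        except ValueError as exc:
            warnings.warn(f"marker {mk!r} skipped: {exc}", stacklevel=2)
            skipped.append(mk)
            continue
        w_glob = fit.wald_test([f"alpha[{t1}]", f"alpha[{t2}]"])
        w_t = {tr: fit.wald_test([f"alpha[{tr}]"]) for tr in (t1, t2)}
        mxe_names = [n for n in fit.fe_params.index if n.startswith("alpha_env[")]
        w_mxe = None
        w_mxe_t = {}
        if mxe_names:
            w_mxe = fit.wald_test(mxe_names)
            for tr in (t1, t2):
                names_tr = [n for n in mxe_names if n.startswith(f"alpha_env[{tr}:")]
                if names_tr:
                    w_mxe_t[tr] = fit.wald_test(names_tr)
        a = {tr: float(fit.fe_params[f"alpha[{tr}]"]) for tr in (t1, t2)}
        records.append(
            AssociationRecord(
                marker_id=mk,
                trait_pair=(t1, t2),
                alpha=a,
                wald_global=w_glob,
                wald_per_trait=w_t,
                wald_mxe_global=w_mxe,
                wald_mxe_per_trait=w_mxe_t,
                p_raw=w_glob.p_value,
                covariation_sign=int(np.sign(a[t1] * a[t2])),
            )
        )
    if not records:
        return ScanSummary(records=[], n_significant={})
    q = bh_qvalues([r.p_raw for r in records])
    m = len(records)
    bonf_thr = alpha / m
    meff_thr = alpha / m_eff_count if m_eff_count else None
    n_sig = {"fdr": 0, "bonferroni": 0, "meff": 0}
    for r, qi in zip(records, q):
        r.q_fdr = float(qi)
        posthoc = all(
            r.wald_per_trait[tr].p_value < posthoc_alpha for tr in trait_pair
        )
        r.significant["fdr"] = bool(qi < alpha and posthoc)
        r.significant["bonferroni"] = bool(r.p_raw < bonf_thr and posthoc)
        if meff_thr is not None:
            r.significant["meff"] = bool(r.p_raw < meff_thr and posthoc)
        for k in n_sig:
            if r.significant.get(k):
                n_sig[k] += 1
    summary = ScanSummary(records=records, n_significant=n_sig)
    sig = [r.marker_id for r in records if r.significant.get("fdr")]
    if len(sig) >= 1:
        summary.effective_associations = effective_association_count(sig, geno)
    return summary


def effective_association_count(significant_markers, geno: GenotypeMatrix) -> int:
    """Effective number of associations among significant markers.

    M_eff applied to the r^2 matrix of the significant markers (the same
    95%-eigenvalue rule used genome-wide), collapsing collinear hits that
    map to the same region.
    """
    if len(significant_markers) == 0:
        raise ValueError("need at least one significant marker")
    if len(significant_markers) == 1:
        return 1
    D = np.column_stack([geno.column(m) for m in significant_markers])
    sd = D.std(axis=0)
    if (sd == 0).any():
        raise ValueError("monomorphic marker among significant set")
    Z = (D - D.mean(0)) / sd
    r2 = np.clip((Z.T @ Z / D.shape[0]) ** 2, 0.0, 1.0)
    np.fill_diagonal(r2, 1.0)
    return m_eff(r2)


def variance_partition(
    blues2: TraitDataset,
    ordered_markers,
    geno: GenotypeMatrix,
    h2_entry: dict,
) -> pd.DataFrame:
    """Sequential (Type-I) R^2 per marker and per trait.

    Markers enter a per-trait multiple regression on across-environment
    BLUEs in the given order (lowest global Wald p first); each marker's
    incremental R^2 is recorded together with its share of genetic variance
    (R^2 divided by the trait's entry-mean heritability).  Collinear markers
    contribute 0 with a warning.
    """
    if blues2.stage != STAGE2:
        raise ValueError("variance_partition expects across-environment BLUEs")
    wide = blues2.wide()
    rows = []
    for trait, h2 in h2_entry.items():
        if h2 <= 0:
            raise ValueError(f"h2_entry must be positive for {trait!r}")
        y = wide[trait].to_numpy(dtype=float)
        gidx = list(wide.index)
        X = np.ones((len(gidx), 1))
        tss = float(((y - y.mean()) ** 2).sum())
        prev_r2 = 0.0
        for mk in ordered_markers:
            col = geno.column(mk)
            gi = [geno.genotype_ids.index(g) for g in gidx]
            X_new = np.column_stack([X, col[gi]])
            beta, *_ = np.linalg.lstsq(X_new, y, rcond=None)
            rss = float(((y - X_new @ beta) ** 2).sum())
            r2_cum = 1.0 - rss / tss
            inc = max(0.0, r2_cum - prev_r2)
            if inc < 1e-12 and np.linalg.matrix_rank(X_new) < X_new.shape[1]:
                warnings.warn(
                    f"marker {mk!r} collinear with earlier markers: 0 R^2",
                    stacklevel=2,
                )
            rows.append(
                {
                    "trait": trait,
                    "marker": mk,
                    "R2_marker": inc,
                    "R2_cumulative": r2_cum,
                    "genetic_share_marker": inc / h2,
                    "genetic_share_cumulative": r2_cum / h2,
                }
            )
            X = X_new
            prev_r2 = r2_cum
    return pd.DataFrame(rows)


def higher_order_test(
    geno: GenotypeMatrix,
    blues1: TraitDataset,
    kinship: KinshipMatrix,
    marker,
    traits: tuple,
    alpha: float = 0.1,
    correction: str = "meff",
    m_eff_count: int | None = None,
    marker_by_env: bool = True,
) -> dict:
    """Joint t-trait (typically 3) marker test for higher-order candidates.

    Extends the bivariate marker model to ``len(traits)`` traits and
    declares a simultaneous association only when every per-trait Wald test
    passes the corrected threshold (M_eff or Bonferroni at level ``alpha``).
    """
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    v = geno.column(marker)
    fit = _fit_marker_model(blues1, kinship, tuple(traits), v, marker_by_env)
    per_trait = {tr: fit.wald_test([f"alpha[{tr}]"]) for tr in traits}
    if correction == "meff":
        if not m_eff_count:
            raise ValueError("meff correction requires m_eff_count")
        thr = alpha / m_eff_count
    elif correction == "bonferroni":
        thr = alpha / geno.n_markers
    else:
        raise ValueError("correction must be 'meff' or 'bonferroni'")
    declared = all(w.p_value < thr for w in per_trait.values())
    return {
        "marker": marker,
        "traits": tuple(traits),
        "alpha_effects": {tr: float(fit.fe_params[f"alpha[{tr}]"]) for tr in traits},
        "per_trait": per_trait,
        "threshold": thr,
        "declared": declared,
        "fit": fit,
    }


def stability_ratio(
    blues1: TraitDataset, markers, geno: GenotypeMatrix, trait
) -> float:
    """Marker main-effect vs marker-x-environment explained-variance ratio.

    Sequential univariate regression on per-environment BLUEs: environment
    effects enter first, then all marker main effects, then all
    marker x environment interactions; the ratio of the marker to the
    interaction sum-of-squares measures the environmental stability of the
    marker effects (large = stable).  Returns +inf with a flag when the
    interaction term explains (numerically) nothing.
    """
    sub = blues1.for_trait(trait)
    envs = sorted(sub["environment"].unique())
    if len(envs) < 2:
        raise ValueError("stability ratio needs at least 2 environments")
    y = sub["value"].to_numpy(dtype=float)
    gi = [geno.genotype_ids.index(g) for g in sub["genotype"]]
    env_dum = pd.get_dummies(sub["environment"], drop_first=False).to_numpy(float)
    M = np.column_stack([geno.column(mk)[gi] for mk in markers])
    inter = np.column_stack(
        [M * env_dum[:, [j]] for j in range(1, env_dum.shape[1])]
    )

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    rss_env = rss(env_dum)
    rss_mark = rss(np.column_stack([env_dum, M]))
    rss_full = rss(np.column_stack([env_dum, M, inter]))
    ss_marker = rss_env - rss_mark
    ss_inter = rss_mark - rss_full
    tol = 1e-10 * float(((y - y.mean()) ** 2).sum())
    if ss_marker <= tol and ss_inter <= tol:
        raise ValueError("markers explain nothing: stability ratio undefined")
    if ss_inter <= tol:
        warnings.warn("zero interaction variance: ratio = +inf", stacklevel=2)
        return float("inf")
    return float(ss_marker / ss_inter)
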