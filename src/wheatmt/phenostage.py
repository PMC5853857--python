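"""Two-stage phenotypic analysis for multi-environment alpha-lattice trials.

Stage 1 fits, per trait and environment,

    value ~ genotype (fixed) + replicate (random) + block-in-replicate
            (random) + plot error

and returns genotype BLUEs plus the environment error variance.  Stage 2
combines the per-environment BLUEs across environments,

    value ~ genotype (fixed) + environment (random) + residual,

and separates variance components: sigma2_G comes from a parallel
random-genotype fit, while the stage-2 residual mixes genotype-x-environment
and error variance; sigma2_GxE is recovered by subtracting the stage-1
average error variance (of replicated environments) from the stage-2
residual, floored at zero with a flag when the subtraction goes negative.

Heritability is reported on a plot basis,

    h2_plot = s2_G / (s2_G + s2_GxE + s2_Error),

and on an entry-mean basis,

    h2_entry = s2_G / (s2_G + s2_GxE / nEnv + s2_Error / (nRep * nEnv)).

The pipeline is unweighted (no stage-1 precision weights): environments with
a single replicate contribute their raw plot values as stage-1 "BLUEs" and
are excluded from the error-variance average.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import PLOT_LEVEL, STAGE1, STAGE2, TraitDataset

__all__ = [
    "VarianceComponents",
    "stage1_blues",
    "stage2_blues",
    "run_stage1",
    "heritabilities",
    "phenotypic_correlations",
]


@dataclass
class VarianceComponents:
    sigma2_G: float
    sigma2_GxE: float
    sigma2_Error: float
    sigma2_e_stage2: float
    n_env: int
    n_rep: int
    h2_plot: float = np.nan
    h2_entry: float = np.nan
    gxe_floored: bool = False

    def __post_init__(self):
        self.h2_plot, self.h2_entry = heritabilities(self)


def heritabilities(vc: VarianceComponents) -> tuple[float, float]:
    """Plot- and entry-mean-basis heritabilities from variance components."""
    for v in (vc.sigma2_G, vc.sigma2_GxE, vc.sigma2_Error):
        if v < 0:
            raise ValueError("variance components must be non-negative")
    if vc.n_env < 1 or vc.n_rep < 1:
        raise ValueError("environment/replicate counts must be >= 1")
    denom_plot = vc.sigma2_G + vc.sigma2_GxE + vc.sigma2_Error
    denom_entry = (
        vc.sigma2_G
        + vc.sigma2_GxE / vc.n_env
        + vc.sigma2_Error / (vc.n_rep * vc.n_env)
    )
    if denom_plot <= 0 or denom_entry <= 0:
        raise ValueError("all variance components are zero: h2 undefined")
    return vc.sigma2_G / denom_plot, vc.sigma2_G / denom_entry


def _mixedlm(formula, df, vc_formula, reml=True):
    import statsmodels.formula.api as smf

    df = df.copy()
    df["_one_group"] = 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            formula, df, groups="_one_group", vc_formula=vc_formula, re_formula="0"
        )
        return model.fit(reml=reml, method=["lbfgs", "powell"])


def _genotype_blues(result, prefix="C(genotype)") -> pd.Series:
    out = {}
    for name, val in result.fe_params.items():
        if name.startswith(prefix):
            out[name[len(prefix) + 1 : -1]] = float(val)
    return pd.Series(out).sort_index()


def stage1_blues(plots: TraitDataset, trait, environment):
    """Per-genotype BLUEs and error variance for one trait x environment.

    Returns ``(blues: Series indexed by genotype, sigma2_e, flags)``.  A
    single-replicate environment bypasses the mixed model: its plot values
    are passed through as BLUEs with ``sigma2_e = nan`` and a flag.
    """
    if plots.stage != PLOT_LEVEL:
        raise ValueError("stage1_blues expects plot-level data")
    df = plots.data
    sub = df[(df["trait"] == trait) & (df["environment"] == environment)].copy()
    if sub.empty:
        raise KeyError(f"no plots for {trait!r} in {environment!r}")
    if sub["genotype"].nunique() < 2:
        raise ValueError("need at least 2 genotypes")
    flags = {}
    if sub["replicate"].nunique() < 2:
        flags["single_replicate"] = True
        blues = sub.groupby("genotype")["value"].mean().sort_index()
        return blues, float("nan"), flags
    sub["genotype"] = sub["genotype"].astype(str)
    res = _mixedlm(
        "value ~ 0 + C(genotype)",
        sub,
        {"replicate": "0 + C(replicate)", "block": "0 + C(block)"},
    )
    blues = _genotype_blues(res)
    missing = set(sub["genotype"].unique()) - set(blues.index)
    if missing:
        flags["unestimable_genotypes"] = sorted(missing)
    return blues, float(res.scale), flags


def run_stage1(plots: TraitDataset) -> tuple[TraitDataset, dict]:
    """Stage 1 over every trait x environment; returns stage-1 BLUEs.

    The second return value maps trait -> average stage-1 error variance
    over replicated environments (nan when none are replicated).
    """
    rows, err_by_trait = [], {}
    df = plots.data
    for trait in sorted(df["trait"].unique()):
        errs = []
        for env in sorted(df.loc[df["trait"] == trait, "environment"].unique()):
            blues, s2e, flags = stage1_blues(plots, trait, env)
            if not flags.get("single_replicate") and np.isfinite(s2e):
                errs.append(s2e)
            rows.append(
                pd.DataFrame(
                    {
                        "genotype": blues.index,
                        "environment": env,
                        "trait": trait,
                        "value": blues.to_numpy(),
                    }
                )
            )
        err_by_trait[trait] = float(np.mean(errs)) if errs else float("nan")
    return (
        TraitDataset(pd.concat(rows, ignore_index=True), stage=STAGE1),
        err_by_trait,
    )


def stage2_blues(
    stage1: TraitDataset, trait, sigma2_error: float | None = None, n_rep: int = 2
):
    """Across-environment BLUEs plus variance components for one trait.

    ``sigma2_error`` is the stage-1 average error variance for the trait
    (needed to split GxE from error); when None, sigma2_GxE is reported as
    nan with a flag.  Returns ``(blues, VarianceComponents | None, flags)``;
    the components are None for a single-environment trait.
    """
    if stage1.stage != STAGE1:
        raise ValueError("stage2_blues expects stage-1 BLUEs")
    sub = stage1.for_trait(trait)
    sub["genotype"] = sub["genotype"].astype(str)
    flags = {}
    envs = sub["environment"].unique()
    n_env = len(envs)
    if n_env < 2:
        flags["single_environment"] = True
        blues = sub.groupby("genotype")["value"].mean().sort_index()
        return blues, None, flags

    res_f = _mixedlm(
        "value ~ 0 + C(genotype)", sub, {"environment": "0 + C(environment)"}
    )
    blues = _genotype_blues(res_f)
    res_r = _mixedlm(
        "value ~ 1",
        sub,
        {
            "genotype": "0 + C(genotype)",
            "environment": "0 + C(environment)",
        },
    )
    names = list(res_r.model.exog_vc.names)
    sigma2_G = float(res_r.vcomp[names.index("genotype")])
    sigma2_e2 = float(res_r.scale)
    if sigma2_error is None or not np.isfinite(sigma2_error):
        flags["no_stage1_error_variance"] = True
        sigma2_gxe = float("nan")
        sigma2_error = float("nan")
    else:
        sigma2_gxe = sigma2_e2 - sigma2_error
        if sigma2_gxe < 0:
            flags["gxe_floored"] = True
            warnings.warn(
                "stage-2 residual smaller than stage-1 error variance: "
                "sigma2_GxE floored at 0",
                stacklevel=2,
            )
            sigma2_gxe = 0.0
    vc = None
    if np.isfinite(sigma2_gxe):
        vc = VarianceComponents(
            sigma2_G=max(sigma2_G, 0.0),
            sigma2_GxE=sigma2_gxe,
            sigma2_Error=float(sigma2_error),
            sigma2_e_stage2=sigma2_e2,
            n_env=n_env,
            n_rep=n_rep,
            gxe_floored=flags.get("gxe_floored", False),
        )
    return blues, vc, flags


def phenotypic_correlations(blues: TraitDataset):
    """Pearson correlations between stage-2 BLUEs of trait pairs + t-tests.

    Returns ``(r: DataFrame, p: DataFrame)``; a constant trait yields NaN
    entries with a warning.  p-values come from t = r sqrt((n-2)/(1-r^2))
    on n-2 degrees of freedom.
    """
    if blues.stage != STAGE2:
        raise ValueError("phenotypic_correlations expects across-env BLUEs")
    wide = blues.wide()
    traits = list(wide.columns)
    k = len(traits)
    R = np.eye(k)
    P = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide[[traits[i], traits[j]]].dropna()
            n = len(pair)
            if n < 3:
                raise ValueError(
                    f"fewer than 3 genotypes share {traits[i]} and {traits[j]}"
                )
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                warnings.warn(
                    f"constant trait in pair ({traits[i]}, {traits[j]}): "
                    "correlation undefined",
                    stacklevel=2,
                )
                R[i, j] = R[j, i] = np.nan
                P[i, j] = P[j, i] = np.nan
                continue
            r = float(np.corrcoef(x, y)[0, 1])
            if abs(r) >= 1.0:
                p = 0.0
            else:
                tstat = r * np.sqrt((n - 2) / (1.0 - r * r))
                p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
            R[i, j] = R[j, i] = r
            P[i, j] = P[j, i] = p
    return (
        pd.DataFrame(R, index=traits, columns=traits),
        pd.DataFrame(P, index=traits, columns=traits),
    )
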