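"""Multi-trait linear mixed models with Kronecker-structured covariance.

The model for t traits observed on n genotypes (optionally across J
environments) is

    y_kji = (fixed effects)_kji + g_ki + e_kji

with the stacked genetic values g ~ N(0, G0 (x) A) and errors
e ~ N(0, R0 (x) I), where G0 and R0 are the t x t genetic and error
(co)variance matrices among traits and A is a pre-specified genotype
relationship matrix.  Fixed effects can include per-trait intercepts,
environment effects, marker dosage effects (a different marker per trait is
allowed, which is what the close-linkage model needs) and marker x
environment interactions.

Estimation
----------
G0 and R0 are estimated by (restricted) maximum likelihood.  Both matrices
are parameterized through their log-Cholesky factors, which keeps them
positive (semi)definite and lets correlations approach +/-1 smoothly; fixed
effects are profiled out by GLS inside every likelihood evaluation.

For "balanced" layouts (every trait observed on the same genotype x
environment grid) the likelihood is evaluated after a one-time rotation:
with A = U D U' and an orthogonal environment basis whose first vector is
1/sqrt(J), the covariance becomes block diagonal with t x t blocks
d_m * G0 + R0, so each evaluation is O(n t^2) instead of O((ntJ)^3).
Unbalanced layouts (traits measured in different environment sets) fall back
to a dense multivariate-normal likelihood in which errors are shared between
traits only for jointly observed genotype-environment cells.

ML (not REML) must be used whenever two models with different fixed effects
are compared by a likelihood ratio; the 2D pleiotropy-vs-linkage scan relies
on that contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .containers import KinshipMatrix

__all__ = [
    "MultiTraitMixedModel",
    "MultiTraitMixedModelResults",
    "WaldResult",
    "wald_test",
    "fit_kernel",
    "KernelFit",
    "RotatedKernel",
]

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# parameter packing: log-Cholesky factors of (G0, R0)
# ---------------------------------------------------------------------------


def _tri_indices(t: int):
    rows, cols = np.tril_indices(t)
    return rows, cols


def _n_par(t: int) -> int:
    return t * (t + 1) // 2


def _chol_from_theta(theta: np.ndarray, t: int) -> np.ndarray:
    L = np.zeros((t, t))
    rows, cols = _tri_indices(t)
    L[rows, cols] = theta
    d = np.clip(np.diagonal(L).copy(), -12.0, 12.0)
    L[np.diag_indices(t)] = np.exp(d)
    return L


def _theta_from_cov(S: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    t = S.shape[0]
    S = np.asarray(S, dtype=float)
    lam_min = np.linalg.eigvalsh(S)[0]
    if lam_min < floor:
        S = S + (floor - lam_min) * np.eye(t)
    L = np.linalg.cholesky(S)
    L = L.copy()
    L[np.diag_indices(t)] = np.log(np.diagonal(L))
    rows, cols = _tri_indices(t)
    return L[rows, cols]


def _unpack(
    theta: np.ndarray,
    t: int,
    constrain_genetic_cov_zero: bool,
    constrain_error_cov_zero: bool = False,
):
    k = _n_par(t)
    thG = np.asarray(theta[:k], dtype=float).copy()
    thR = np.asarray(theta[k:], dtype=float).copy()
    rows, cols = _tri_indices(t)
    if constrain_genetic_cov_zero:
        thG[rows != cols] = 0.0
    if constrain_error_cov_zero:
        thR[rows != cols] = 0.0
    LG = _chol_from_theta(thG, t)
    LR = _chol_from_theta(thR, t)
    return LG @ LG.T, LR @ LR.T


# ---------------------------------------------------------------------------
# likelihood kernels
# ---------------------------------------------------------------------------


class RotatedKernel:
    """Profile -2 log-likelihood for block covariance  d_m * G0 + R0.

    Data enter as per-trait vectors of common length M (already rotated),
    with a per-index genetic multiplier d (eigenvalues of A, scaled by J for
    the environment-mean component, 0 for the within-environment components).
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, d: np.ndarray):
        # y: (t, M); X: (t, M, p); d: (M,)
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.d = np.asarray(d, dtype=float)
        self.t, self.M = self.y.shape
        self.p = self.X.shape[2]
        self.N = self.t * self.M

    def _weights2(self, G0, R0):
        d = self.d
        s11 = d * G0[0, 0] + R0[0, 0]
        s12 = d * G0[0, 1] + R0[0, 1]
        s22 = d * G0[1, 1] + R0[1, 1]
        det = s11 * s22 - s12 * s12
        if (det <= 0).any() or (s11 <= 0).any() or (s22 <= 0).any():
            return None
        logdet = float(np.log(det).sum())
        W = np.empty((2, 2, self.M))
        W[0, 0] = s22 / det
        W[1, 1] = s11 / det
        W[0, 1] = W[1, 0] = -s12 / det
        return logdet, W

    def _weights_general(self, G0, R0):
        V = self.d[:, None, None] * G0[None] + R0[None]
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet = float(2.0 * np.log(np.diagonal(C, axis1=1, axis2=2)).sum())
        Vinv = np.linalg.inv(V)  # (M, t, t)
        return logdet, np.moveaxis(Vinv, 0, 2)  # (t, t, M)

    def gls(self, G0, R0):
        """Return (logdetV, beta, XtVX, quad_at_beta) or None if invalid."""
        out = self._weights2(G0, R0) if self.t == 2 else self._weights_general(G0, R0)
        if out is None:
            return None
        logdet, W = out
        p = self.p
        XtVX = np.zeros((p, p))
        XtVy = np.zeros(p)
        ytVy = 0.0
        for a in range(self.t):
            for b in range(self.t):
                w = W[a, b]
                XtVX += self.X[a].T @ (w[:, None] * self.X[b])
                XtVy += self.X[a].T @ (w * self.y[b])
                ytVy += float(np.dot(self.y[a] * w, self.y[b]))
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtVX) @ XtVy
        quad = ytVy - float(XtVy @ beta)
        return logdet, beta, XtVX, quad


class _DenseKernel:
    """Dense fallback: arbitrary (trait, genotype, cell) observation lists."""

    def __init__(self, y, X, trait_idx, genotype_idx, cell_idx, A):
        self.y = np.asarray(y, dtype=float)
        self.X = np.asarray(X, dtype=float)
        self.N = self.y.size
        self.p = self.X.shape[1]
        ti = np.asarray(trait_idx)
        gi = np.asarray(genotype_idx)
        ci = np.asarray(cell_idx)
        self.t = int(ti.max()) + 1
        self._Gsel = (ti[:, None], ti[None, :])
        self._Agrid = A[gi[:, None], gi[None, :]]
        self._Egrid = (ci[:, None] == ci[None, :]).astype(float)

    def gls(self, G0, R0):
        V = G0[self._Gsel] * self._Agrid + R0[self._Gsel] * self._Egrid
        try:
            C = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return None
        logdet = float(2.0 * np.log(np.diag(C)).sum())
        from scipy.linalg import cho_solve

        Vi_y = cho_solve((C, True), self.y)
        Vi_X = cho_solve((C, True), self.X)
        XtVX = self.X.T @ Vi_X
        XtVy = self.X.T @ Vi_y
        ytVy = float(self.y @ Vi_y)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
        except np.linalg.LinAlgError:
            beta = np.linalg.pinv(XtVX) @ XtVy
        quad = ytVy - float(XtVy @ beta)
        return logdet, beta, XtVX, quad


def _neg2ll(kernel, G0, R0, reml: bool) -> float:
    out = kernel.gls(G0, R0)
    if out is None:
        return np.inf
    logdet, _, XtVX, quad = out
    val = kernel.N * _LOG2PI + logdet + quad
    if reml:
        sign, ld2 = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        val += ld2 - kernel.p * _LOG2PI
    if not np.isfinite(val):
        return np.inf
    return float(val)


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class WaldResult:
    """Wald test of a subset of estimated fixed effects.

    statistic = theta' Var(theta)^{-1} theta, referred to chi^2 with
    df = rank(Var(theta)); Var(theta) is the corresponding submatrix of the
    C11 block (the GLS covariance of the fixed effects at the variance-
    component estimates).
    """

    theta_hat: np.ndarray
    var_theta: np.ndarray
    statistic: float
    df: int
    p_value: float
    names: list = field(default_factory=list)


def wald_test(theta_hat, var_theta, names=None) -> WaldResult:
    """Closed-form Wald chi-square test (generalized inverse if singular)."""
    theta = np.atleast_1d(np.asarray(theta_hat, dtype=float))
    V = np.atleast_2d(np.asarray(var_theta, dtype=float))
    rank = int(np.linalg.matrix_rank(V))
    if rank < len(theta):
        warnings.warn(
            "singular Var(theta): using generalized inverse, rank-adjusted df",
            stacklevel=2,
        )
        Vinv = np.linalg.pinv(V)
    else:
        Vinv = np.linalg.inv(V)
    W = float(theta @ Vinv @ theta)
    W = max(W, 0.0)
    df = max(rank, 1)
    return WaldResult(
        theta_hat=theta,
        var_theta=V,
        statistic=W,
        df=df,
        p_value=float(stats.chi2.sf(W, df)),
        names=list(names) if names is not None else [],
    )


@dataclass
class KernelFit:
    """Raw variance-component fit of a likelihood kernel."""

    G0: np.ndarray
    R0: np.ndarray
    beta: np.ndarray
    cov_beta: np.ndarray
    llf: float
    theta: np.ndarray
    converged: bool
    n_eval: int


def fit_kernel(
    kernel,
    t: int,
    criterion: str = "reml",
    start: np.ndarray | None = None,
    constrain_genetic_cov_zero: bool = False,
    constrain_error_cov_zero: bool = False,
    maxiter: int = 200,
    gtol: float = 1e-6,
) -> KernelFit:
    """Maximize the profile (restricted) likelihood of a kernel over (G0, R0).

    The log-Cholesky parameters are optimized by L-BFGS-B (numerical
    gradients) with a Nelder-Mead polish when the quasi-Newton run reports
    failure.  ``start`` must be a packed log-Cholesky vector, e.g. from a
    previous fit of a kernel with the same trait count.
    """
    criterion = criterion.lower()
    if criterion not in ("reml", "ml"):
        raise ValueError("criterion must be 'reml' or 'ml'")
    reml = criterion == "reml"
    if start is None:
        raise ValueError("fit_kernel requires explicit start parameters")
    theta0 = np.asarray(start, dtype=float)

    n_eval = 0

    def obj(th):
        nonlocal n_eval
        n_eval += 1
        G0, R0 = _unpack(
            th, t, constrain_genetic_cov_zero, constrain_error_cov_zero
        )
        val = 0.5 * _neg2ll(kernel, G0, R0, reml)
        # large finite penalty instead of inf: L-BFGS-B's line search
        # aborts (spurious "convergence") when it samples an infinity
        return min(val, 1e10)

    res = optimize.minimize(
        obj,
        theta0,
        method="L-BFGS-B",
        bounds=[(-12.0, 12.0)] * theta0.size,
        options={"maxiter": maxiter, "ftol": 1e-11, "gtol": gtol},
    )
    if not res.success:
        res2 = optimize.minimize(
            obj,
            res.x,
            method="Nelder-Mead",
            options={"maxiter": 400 * theta0.size, "xatol": 1e-7, "fatol": 1e-9},
        )
        if res2.fun <= res.fun:
            res = res2
    G0, R0 = _unpack(res.x, t, constrain_genetic_cov_zero, constrain_error_cov_zero)
    out = kernel.gls(G0, R0)
    if out is None:
        raise RuntimeError("likelihood undefined at the optimum")
    _, beta, XtVX, _ = out
    llf = -0.5 * _neg2ll(kernel, G0, R0, reml)
    return KernelFit(
        G0=G0,
        R0=R0,
        beta=beta,
        cov_beta=np.linalg.pinv(XtVX),
        llf=float(llf),
        theta=res.x,
        converged=bool(np.isfinite(llf)) and (res.success or res.fun < np.inf),
        n_eval=n_eval,
    )


class MultiTraitMixedModelResults:
    """Fitted multi-trait mixed model: estimates, likelihood, Wald machinery."""

    def __init__(
        self,
        model: "MultiTraitMixedModel",
        G0: np.ndarray,
        R0: np.ndarray,
        fe_params: pd.Series,
        cov_fe_params: pd.DataFrame,
        llf: float,
        criterion: str,
        converged: bool,
        n_iter: int,
        theta: np.ndarray,
        constrained: bool = False,
    ):
        self.model = model
        self.G0 = G0
        self.R0 = R0
        self.fe_params = fe_params
        self.cov_fe_params = cov_fe_params
        self.llf = llf
        self.criterion = criterion
        self.converged = converged
        self.n_iter = n_iter
        self.theta = theta
        self.constrained = constrained

    # -- inference ----------------------------------------------------------

    def wald_test(self, names) -> WaldResult:
        """Wald test for the named fixed effects (C11 submatrix)."""
        if isinstance(names, str):
            names = [n for n in self.fe_params.index if n.startswith(names)]
        missing = [n for n in names if n not in self.fe_params.index]
        if missing:
            raise KeyError(f"effects not in the model: {missing}")
        theta = self.fe_params.loc[names].to_numpy()
        V = self.cov_fe_params.loc[names, names].to_numpy()
        return wald_test(theta, V, names=names)

    def genetic_correlation(self, traits=(0, 1)) -> dict:
        """Genetic correlation between two traits and its LR test.

        r_g = s_12 / sqrt(s_11 s_22); the LR compares this fit against a
        refit with all genetic covariances constrained to zero and refers
        max(LR, 0) to chi^2_1.
        """
        if not self.converged:
            raise RuntimeError("refusing inference on a non-converged fit")
        a, b = traits
        s_aa, s_bb = self.G0[a, a], self.G0[b, b]
        if s_aa <= 0 or s_bb <= 0:
            raise ValueError("zero genetic variance: correlation undefined")
        r_g = float(self.G0[a, b] / np.sqrt(s_aa * s_bb))
        null = self.model.fit(
            criterion=self.criterion,
            constrain_genetic_cov_zero=True,
            start=self.theta,
        )
        lr = max(0.0, 2.0 * (self.llf - null.llf))
        return {
            "r_g": r_g,
            "lr": lr,
            "p_value": float(stats.chi2.sf(lr, 1)),
            "null_llf": null.llf,
        }

    def summary(self) -> str:
        traits = self.model.trait_names
        lines = [
            "Multi-trait mixed model (G0 (x) A  +  R0 (x) I)",
            f"criterion: {self.criterion.upper()}   logL = {self.llf:.4f}   "
            f"converged: {self.converged} (n_eval={self.n_iter})",
            "",
            "Genetic (co)variance G0:",
            pd.DataFrame(self.G0, index=traits, columns=traits).to_string(
                float_format=lambda x: f"{x: .4f}"
            ),
            "",
            "Error (co)variance R0:",
            pd.DataFrame(self.R0, index=traits, columns=traits).to_string(
                float_format=lambda x: f"{x: .4f}"
            ),
            "",
            "Fixed effects:",
        ]
        se = np.sqrt(np.diag(self.cov_fe_params.to_numpy()))
        tab = pd.DataFrame(
            {"estimate": self.fe_params, "std_err": se}, index=self.fe_params.index
        )
        lines.append(tab.to_string(float_format=lambda x: f"{x: .4f}"))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class MultiTraitMixedModel:
    """t-trait mixed model with genetic covariance G0 (x) A, errors R0 (x) I.

    Parameters
    ----------
    data : long-format DataFrame with columns ``trait``, ``genotype``,
        ``value`` and optionally ``environment``.
    kinship : KinshipMatrix (or a plain PSD ndarray indexed like
        ``genotype_ids``).
    genotype_ids : ordering of genotypes matching the kinship matrix; by
        default the kinship's own ids.
    markers : optional dict mapping trait name -> per-genotype dosage vector
        (aligned with ``genotype_ids``).  Passing the same vector for every
        trait gives the pleiotropic marker model; different vectors give the
        close-linkage model.
    marker_by_env : include fixed marker x environment interaction effects.

    Fixed effects always include a per-trait intercept; environment main
    effects are included per trait whenever more than one environment is
    present (treatment-coded against the first environment).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        kinship,
        genotype_ids=None,
        markers: dict | None = None,
        marker_by_env: bool = False,
    ):
        need = {"trait", "genotype", "value"}
        if not need.issubset(data.columns):
            raise ValueError(f"data must have columns {sorted(need)}")
        data = data.dropna(subset=["value"]).copy()
        if "environment" not in data.columns:
            data["environment"] = "__single__"
        self._kin_eig = None
        if isinstance(kinship, KinshipMatrix):
            A = kinship.A_psd
            kin_ids = list(kinship.genotype_ids)
            self._kin_eig = kinship.eig()
        else:
            A = np.asarray(kinship, dtype=float)
            kin_ids = genotype_ids
            if kin_ids is None:
                raise ValueError("genotype_ids required with a raw kinship array")
        self.genotype_ids = list(kin_ids)
        gset = set(self.genotype_ids)
        extra = set(data["genotype"]) - gset
        if extra:
            raise ValueError(f"genotypes absent from kinship: {sorted(extra)[:5]}")
        self.A = A
        self.trait_names = sorted(data["trait"].unique().tolist())
        self.t = len(self.trait_names)
        if self.t < 2:
            raise ValueError("need at least two traits")
        self.data = data
        self.markers = markers or {}
        self.marker_by_env = marker_by_env
        for tr, v in self.markers.items():
            if tr not in self.trait_names:
                raise KeyError(f"marker given for unknown trait {tr!r}")
            if len(np.asarray(v)) != len(self.genotype_ids):
                raise ValueError("marker vector must align with genotype_ids")
        self._build()

    # -- construction -------------------------------------------------------

    def _env_sets(self):
        out = {}
        for tr in self.trait_names:
            sub = self.data[self.data["trait"] == tr]
            out[tr] = sorted(sub["environment"].unique().tolist())
        return out

    def _is_balanced(self) -> bool:
        envs = self._env_sets()
        ref = envs[self.trait_names[0]]
        if any(envs[tr] != ref for tr in self.trait_names[1:]):
            return False
        need = len(ref) * len(self.genotype_ids) * self.t
        if len(self.data) != need:
            return False
        return True

    def _fe_columns(self, trait, envs):
        """Yield (name, env_or_None, kind) fixed-effect column descriptors."""
        cols = [(f"mu[{trait}]", None, "intercept")]
        for e in envs[1:]:
            cols.append((f"env[{trait}:{e}]", e, "env"))
        if trait in self.markers:
            cols.append((f"alpha[{trait}]", None, "marker"))
            if self.marker_by_env and len(envs) > 1:
                for e in envs[1:]:
                    cols.append((f"alpha_env[{trait}:{e}]", e, "marker_env"))
        return cols

    def _build(self):
        gid_index = {g: i for i, g in enumerate(self.genotype_ids)}
        envs_per_trait = self._env_sets()
        self.balanced = self._is_balanced()

        # global fixed-effect layout
        self.fe_names = []
        self._fe_desc = {}  # name -> (trait, env, kind)
        for tr in self.trait_names:
            for name, env, kind in self._fe_columns(tr, envs_per_trait[tr]):
                self.fe_names.append(name)
                self._fe_desc[name] = (tr, env, kind)
        p = len(self.fe_names)
        name_pos = {n: c for c, n in enumerate(self.fe_names)}

        if self.balanced:
            envs = envs_per_trait[self.trait_names[0]]
            J, n = len(envs), len(self.genotype_ids)
            # data cube y[trait, env, genotype]
            Y = np.full((self.t, J, n), np.nan)
            tpos = {tr: k for k, tr in enumerate(self.trait_names)}
            epos = {e: j for j, e in enumerate(envs)}
            for row in self.data.itertuples(index=False):
                Y[tpos[row.trait], epos[row.environment], gid_index[row.genotype]] = (
                    row.value
                )
            if np.isnan(Y).any():
                raise AssertionError("balanced layout check failed")
            if self._kin_eig is not None:
                lam, U = self._kin_eig
            else:
                lam, U = np.linalg.eigh(self.A)
                lam = np.clip(lam, 0.0, None)
            # orthogonal environment basis, first vector = 1/sqrt(J)
            Q = np.linalg.qr(
                np.column_stack([np.ones(J) / np.sqrt(J), np.eye(J)[:, : J - 1]])
            )[0]
            if Q[0, 0] < 0:
                Q = -Q
            d = np.concatenate([J * lam, np.zeros((J - 1) * n)])
            yr = np.empty((self.t, J * n))
            Xr = np.zeros((self.t, J * n, p))
            for k, tr in enumerate(self.trait_names):
                yr[k] = (Q.T @ Y[k] @ U).ravel()
                for name, (trc, env, kind) in self._fe_desc.items():
                    if trc != tr:
                        continue
                    col = np.zeros((J, n))
                    if kind == "intercept":
                        col[:, :] = 1.0
                    elif kind == "env":
                        col[epos[env], :] = 1.0
                    elif kind == "marker":
                        col[:, :] = np.asarray(self.markers[tr], dtype=float)[None, :]
                    elif kind == "marker_env":
                        col[epos[env], :] = np.asarray(self.markers[tr], dtype=float)
                    Xr[k, :, name_pos[name]] = (Q.T @ col @ U).ravel()
            self._kernel = RotatedKernel(yr, Xr, d)
        else:
            # dense fallback: one row per observation
            rows = self.data.sort_values(["trait", "environment", "genotype"])
            ti = rows["trait"].map(
                {tr: k for k, tr in enumerate(self.trait_names)}
            ).to_numpy()
            gi = rows["genotype"].map(gid_index).to_numpy()
            cell_key = rows["genotype"].astype(str) + "||" + rows[
                "environment"
            ].astype(str)
            _, ci = np.unique(cell_key.to_numpy(), return_inverse=True)
            y = rows["value"].to_numpy(dtype=float)
            X = np.zeros((len(rows), p))
            env_arr = rows["environment"].to_numpy()
            for name, (trc, env, kind) in self._fe_desc.items():
                c = name_pos[name]
                in_trait = ti == self.trait_names.index(trc)
                if kind == "intercept":
                    X[in_trait, c] = 1.0
                elif kind == "env":
                    X[in_trait & (env_arr == env), c] = 1.0
                elif kind == "marker":
                    X[in_trait, c] = np.asarray(self.markers[trc], dtype=float)[
                        gi[in_trait]
                    ]
                elif kind == "marker_env":
                    sel = in_trait & (env_arr == env)
                    X[sel, c] = np.asarray(self.markers[trc], dtype=float)[gi[sel]]
            self._kernel = _DenseKernel(y, X, ti, gi, ci, self.A)

        # guard against rank-deficient fixed design (constant markers etc.)
        Xflat = (
            self._kernel.X.reshape(-1, p)
            if self.balanced
            else self._kernel.X
        )
        if np.linalg.matrix_rank(Xflat) < p:
            raise ValueError(
                "fixed-effect design is rank deficient "
                "(monomorphic marker or constant phenotype?)"
            )

    # -- fitting -------------------------------------------------------------

    def _start_theta(self) -> np.ndarray:
        # moment start: per-trait phenotypic covariance split half/half
        wide = self.data.pivot_table(
            index=["genotype", "environment"], columns="trait", values="value"
        )[self.trait_names]
        S = np.atleast_2d(np.cov(wide.to_numpy().T if wide.shape[0] > 1 else wide))
        S = np.asarray(S, dtype=float)
        S = np.where(np.isfinite(S), S, 0.0)
        dS = np.diag(S).copy()
        dS[dS <= 0] = 1.0
        S[np.diag_indices_from(S)] = dS
        a_scale = float(np.mean(np.diag(self.A)))
        half = S / 2.0
        return np.concatenate(
            [_theta_from_cov(half / max(a_scale, 1e-8)), _theta_from_cov(half)]
        )

    def fit(
        self,
        criterion: str = "reml",
        constrain_genetic_cov_zero: bool = False,
        constrain_error_cov_zero: bool = False,
        start: np.ndarray | None = None,
        maxiter: int = 200,
        gtol: float = 1e-6,
    ) -> MultiTraitMixedModelResults:
        """Estimate (G0, R0) by REML or ML and profile the fixed effects."""
        theta0 = (
            np.asarray(start, dtype=float) if start is not None else self._start_theta()
        )
        kf = fit_kernel(
            self._kernel,
            self.t,
            criterion=criterion,
            start=theta0,
            constrain_genetic_cov_zero=constrain_genetic_cov_zero,
            constrain_error_cov_zero=constrain_error_cov_zero,
            maxiter=maxiter,
            gtol=gtol,
        )
        return MultiTraitMixedModelResults(
            model=self,
            G0=kf.G0,
            R0=kf.R0,
            fe_params=pd.Series(kf.beta, index=self.fe_names),
            cov_fe_params=pd.DataFrame(
                kf.cov_beta, index=self.fe_names, columns=self.fe_names
            ),
            llf=kf.llf,
            criterion=criterion.lower(),
            converged=kf.converged,
            n_iter=kf.n_eval,
            theta=kf.theta,
            constrained=constrain_genetic_cov_zero,
        )

    def loglike_at(self, G0: np.ndarray, R0: np.ndarray, criterion: str = "ml"):
        """Profile log-likelihood at fixed (G0, R0), fixed effects by GLS."""
        val = _neg2ll(self._kernel, np.asarray(G0), np.asarray(R0), criterion == "reml")
        return -0.5 * val

    # -- convenience constructors -------------------------------------------

    @classmethod
    def from_blues(
        cls,
        blues_wide: pd.DataFrame,
        kinship,
        traits=None,
        markers: dict | None = None,
    ) -> "MultiTraitMixedModel":
        """Build a no-environment model from a genotype x trait BLUE table."""
        traits = list(traits) if traits is not None else list(blues_wide.columns)
        long = (
            blues_wide[traits]
            .rename_axis("genotype")
            .reset_index()
            .melt(id_vars="genotype", var_name="trait", value_name="value")
        )
        return cls(long, kinship, markers=markers)
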