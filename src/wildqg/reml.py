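"""Restricted maximum-likelihood mixed models ("animal model").

Supports arbitrary relatedness matrices as random-effect covariances, several
identity random effects (year, nest, permanent environment), fixed covariates
and repeated measures.  Estimation is average-information REML with an
EM-style multiplicative fallback; variance components are constrained
non-negative (boundary fits allowed) unless a component is explicitly marked
as a covariance, in which case it may go negative.

The restricted log-likelihood is, up to an additive constant,

    L = -1/2 [ log|V| + log|X' V^-1 X| + y' P y ],

with V = sum_k sigma_k^2 C_k and P the REML projection.  Likelihood-ratio
tests of a single variance against zero use the 50:50 mixture of a point mass
and chi-square(1) appropriate for a boundary null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .relmat import RelatednessMatrix

_EIG_CACHE: dict = {}


@dataclass
class RandomTerm:
    factor: str
    covariance: RelatednessMatrix | None = None
    name: str | None = None

    def label(self) -> str:
        return self.name or (self.factor if self.covariance is None
                             else f"{self.factor}:{self.covariance.kind}")


@dataclass
class ModelSpec:
    trait: str
    data: object  # TraitDataset or DataFrame of records
    fixed: list[str] = field(default_factory=list)
    random: list[RandomTerm] = field(default_factory=list)

    def records(self) -> pd.DataFrame:
        df = getattr(self.data, "records", self.data)
        if "trait" in df.columns:
            df = df[df["trait"] == self.trait]
        if df.empty:
            raise ValueError(f"no records for trait {self.trait!r}")
        return df.reset_index(drop=True)


@dataclass
class VcFit:
    varcomps: dict[str, float]
    varcomp_se: dict[str, float]
    beta: np.ndarray
    fixed_names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int
    h2: float | None = None
    h2_se: float | None = None
    grad_norm: float | None = None
    extras: dict = field(default_factory=dict)


class RemlError(RuntimeError):
    def __init__(self, msg, trajectory=None):
        super().__init__(msg)
        self.trajectory = trajectory or []


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def build_design(df: pd.DataFrame, fixed: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for term in fixed:
        v = df[term]
        if v.dtype.kind in "OUSb" or isinstance(v.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(v, prefix=term, drop_first=True)
            for c in dummies.columns:
                cols.append(dummies[c].to_numpy(dtype=float))
                names.append(c)
        else:
            cols.append(v.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # name an aliased column: first column whose removal restores rank
        for j in range(X.shape[1] - 1, 0, -1):
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == r:
                raise RemlError(f"singular fixed-effect design; aliased term {names[j]!r}")
        raise RemlError("singular fixed-effect design")
    return X, names


def _term_component(df: pd.DataFrame, term: RandomTerm) -> tuple[np.ndarray, np.ndarray, list]:
    """Observation-level covariance contribution Z K Z' for one random term."""
    levels, inv = np.unique(df[term.factor].astype(str), return_inverse=True)
    n = len(df)
    Z = np.zeros((n, len(levels)))
    Z[np.arange(n), inv] = 1.0
    if term.covariance is None:
        K = np.eye(len(levels))
    else:
        missing = [l for l in levels if l not in set(term.covariance.ids)]
        if missing:
            raise RemlError(
                f"levels of {term.factor!r} absent from {term.covariance.kind} "
                f"matrix: {missing[:5]}")
        K = term.covariance.align(list(levels))
    return Z @ K @ Z.T, Z, list(levels)


# ---------------------------------------------------------------------------
# core optimizers
# ---------------------------------------------------------------------------

def _reml_loglik_parts(y, X, V):
    n, p = X.shape
    cf = linalg.cho_factor(V, lower=True, check_finite=False)
    Vinv = linalg.cho_solve(cf, np.eye(n), check_finite=False)
    logdetV = 2.0 * np.sum(np.log(np.diag(cf[0])))
    VinvX = Vinv @ X
    XtVX = X.T @ VinvX
    sign, logdetX = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtVX, VinvX.T @ y)
    P = Vinv - VinvX @ np.linalg.solve(XtVX, VinvX.T)
    Py = P @ y
    ll = -0.5 * (logdetV + logdetX + float(y @ Py))
    return ll, P, Py, beta, XtVX


def fit_components(y: np.ndarray, X: np.ndarray, components: list[np.ndarray],
                   names: list[str] | None = None,
                   allow_negative: Sequence[int] = (),
                   max_iter: int = 200, tol: float = 1e-6,
                   start: np.ndarray | None = None) -> VcFit:
    """AI-REML over an explicit list of observation-level covariance matrices.

    The last component is typically an identity (residual).  ``allow_negative``
    indexes components interpreted as covariances rather than variances.
    """
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    K = len(components)
    if n <= p:
        raise RemlError("more fixed effects than observations")
    vy = np.var(y)
    if vy <= 0:
        raise RemlError("phenotype has zero variance")
    neg = set(allow_negative)
    theta = np.full(K, vy / K) if start is None else np.array(start, dtype=float)
    for k in neg:
        if start is None:
            theta[k] = 0.0
    floor = 1e-8 * vy
    traj = []
    ll_old = -np.inf
    converged = False
    it = 0
    score = np.zeros(K)
    for it in range(1, max_iter + 1):
        V = sum(theta[k] * components[k] for k in range(K))
        V[np.diag_indices_from(V)] += 1e-6 * vy  # ridge, numerical invertibility
        try:
            ll, P, Py, beta, XtVX = _reml_loglik_parts(y, X, V)
        except np.linalg.LinAlgError as e:
            raise RemlError(f"covariance matrix not positive definite: {e}", traj)
        traj.append((theta.copy(), ll))
        U = np.column_stack([components[k] @ Py for k in range(K)])
        for k in range(K):
            score[k] = -0.5 * (np.sum(P * components[k]) - float(Py @ U[:, k]))
        active = [k for k in range(K)
                  if k in neg or theta[k] > floor or score[k] > 0]
        if abs(ll - ll_old) < tol and it > 1:
            converged = True
            break
        AI = 0.5 * (U.T @ P @ U)
        updated = False
        if active:
            a = np.array(active)
            try:
                delta = np.linalg.solve(AI[np.ix_(a, a)] + 1e-10 * np.eye(len(a)),
                                        score[a])
                step = 1.0
                for _ in range(8):
                    cand = theta.copy()
                    cand[a] = theta[a] + step * delta
                    for k in range(K):
                        if k not in neg:
                            cand[k] = max(cand[k], 0.0)
                    Vc = sum(cand[k] * components[k] for k in range(K))
                    Vc[np.diag_indices_from(Vc)] += 1e-6 * vy
                    try:
                        ll_c, *_ = _reml_loglik_parts(y, X, Vc)
                    except np.linalg.LinAlgError:
                        step *= 0.5
                        continue
                    if ll_c >= ll - 1e-12:
                        theta = cand
                        updated = True
                        break
                    step *= 0.5
            except np.linalg.LinAlgError:
                pass
        if not updated:
            # EM-style multiplicative fallback (positive components only)
            cand = theta.copy()
            for k in active:
                if k in neg:
                    continue
                num = float(Py @ U[:, k])
                den = np.sum(P * components[k])
                if den > 0 and num > 0 and theta[k] > floor:
                    cand[k] = theta[k] * np.sqrt(num / den)
                elif den > 0 and theta[k] <= floor and score[k] > 0:
                    cand[k] = max(theta[k], 1e-4 * vy)
                elif num <= 0:
                    cand[k] = 0.0
            if np.allclose(cand, theta):
                converged = abs(ll - ll_old) < 10 * tol
                break
            theta = cand
        ll_old = ll
    else:
        raise RemlError(f"REML did not converge in {max_iter} iterations", traj)

    V = sum(theta[k] * components[k] for k in range(K))
    V[np.diag_indices_from(V)] += 1e-6 * vy
    ll, P, Py, beta, XtVX = _reml_loglik_parts(y, X, V)
    U = np.column_stack([components[k] @ Py for k in range(K)])
    AI = 0.5 * (U.T @ P @ U)
    try:
        cov = np.linalg.inv(AI + 1e-10 * np.eye(K))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((K, K), np.nan)
        se = np.full(K, np.nan)
    names = names or [f"vc{k}" for k in range(K)]
    grad = np.array([-0.5 * (np.sum(P * components[k]) - float(Py @ U[:, k]))
                     for k in range(K)])
    fit = VcFit(varcomps=dict(zip(names, theta)), varcomp_se=dict(zip(names, se)),
                beta=beta, fixed_names=[], loglik=float(ll), converged=converged,
                n_iter=it, n_obs=n, grad_norm=float(np.max(np.abs(grad))),
                extras={"ai_cov": cov, "theta": theta.copy(), "names": list(names),
                        "P": P, "Py": Py, "V": V})
    return fit


def _eig_cached(values: np.ndarray, key) -> tuple[np.ndarray, np.ndarray]:
    entry = _EIG_CACHE.get(key)
    if entry is not None:
        return entry[1], entry[2]
    w, Q = np.linalg.eigh(values)
    if len(_EIG_CACHE) > 12:
        _EIG_CACHE.clear()
    _EIG_CACHE[key] = (values, w, Q)
    return w, Q


def _fit_two_component(y, X, Kobs, key=None) -> VcFit:
    """Profiled REML for V = s_g^2 K + s_e^2 I via one eigendecomposition."""
    n, p = X.shape
    if key is None:
        key = (Kobs.shape[0], float(Kobs[0, 0]), float(Kobs[-1, -1]),
               float(Kobs.sum()))
    w, Q = _eig_cached(Kobs, key)
    ys = Q.T @ y
    Xs = Q.T @ X

    def neg_profile(gamma: float) -> float:
        wt = gamma * w + 1.0
        if np.any(wt <= 0):
            return np.inf
        Wi = 1.0 / wt
        XtWX = (Xs * Wi[:, None]).T @ Xs
        try:
            cf = linalg.cho_factor(XtWX)
        except np.linalg.LinAlgError:
            return np.inf
        b = linalg.cho_solve(cf, (Xs * Wi[:, None]).T @ ys)
        r = ys - Xs @ b
        quad = float(r @ (Wi * r))
        s2e = quad / (n - p)
        logdetX = 2.0 * np.sum(np.log(np.diag(cf[0])))
        return 0.5 * ((n - p) * np.log(s2e) + np.sum(np.log(wt)) + logdetX
                      + (n - p))

    res = optimize.minimize_scalar(lambda t: neg_profile(np.expm1(t)),
                                   bounds=(np.log1p(0.0), np.log1p(1e4)),
                                   method="bounded",
                                   options={"xatol": 1e-10})
    gamma = float(np.expm1(res.x))
    if neg_profile(0.0) <= res.fun + 1e-10:
        gamma = 0.0
    wt = gamma * w + 1.0
    Wi = 1.0 / wt
    XtWX = (Xs * Wi[:, None]).T @ Xs
    b = np.linalg.solve(XtWX, (Xs * Wi[:, None]).T @ ys)
    r = ys - Xs @ b
    s2e = float(r @ (Wi * r)) / (n - p)
    s2g = gamma * s2e
    ll = -neg_profile(gamma)
    # SEs from the AI matrix in the eigenbasis
    V = s2g * Kobs + s2e * np.eye(n)
    _, P, Py, beta, _ = _reml_loglik_parts(y, X, V)
    U = np.column_stack([Kobs @ Py, Py])
    AI = 0.5 * (U.T @ P @ U)
    try:
        cov = np.linalg.inv(AI + 1e-12 * np.eye(2))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        se = np.full(2, np.nan)
    grad = np.array([-0.5 * (np.sum(P * Kobs) - float(Py @ U[:, 0])),
                     -0.5 * (np.trace(P) - float(Py @ U[:, 1]))])
    return VcFit(varcomps={"genetic": s2g, "residual": s2e},
                 varcomp_se={"genetic": se[0], "residual": se[1]},
                 beta=beta, fixed_names=[], loglik=float(ll), converged=True,
                 n_iter=int(res.nfev), n_obs=n,
                 grad_norm=float(np.max(np.abs(grad))),
                 extras={"ai_cov": cov, "theta": np.array([s2g, s2e]),
                         "names": ["genetic", "residual"], "gamma": gamma})


# ---------------------------------------------------------------------------
# public model interface
# ---------------------------------------------------------------------------

def fit_reml(spec: ModelSpec, max_iter: int = 200, tol: float = 1e-6) -> VcFit:
    """Fit the animal model described by ``spec`` and report variance
    components, h2 (genetic / total) with a delta-method SE, fixed-effect
    solutions and the restricted log-likelihood."""
    df = spec.records()
    y = df["value"].to_numpy(dtype=float)
    X, fixed_names = build_design(df, spec.fixed)
    comps, names = [], []
    Zs = []
    for term in spec.random:
        C, Z, _ = _term_component(df, term)
        comps.append(C)
        Zs.append(Z)
        names.append(term.label())
    genetic_idx = [k for k, t in enumerate(spec.random) if t.covariance is not None]
    # fast path: single correlated term, one observation per level, no others
    if (len(spec.random) == 1 and genetic_idx == [0]
            and Zs[0].shape[0] == Zs[0].shape[1]):
        rm = spec.random[0].covariance
        levels = df[spec.random[0].factor].astype(str)
        key = (id(rm.values), tuple(levels))
        fit = _fit_two_component(y, X, comps[0], key=key)
        fit.fixed_names = fixed_names
        gname = names[0]
        fit.varcomps = {gname: fit.varcomps["genetic"],
                        "residual": fit.varcomps["residual"]}
        fit.varcomp_se = {gname: fit.varcomp_se["genetic"],
                          "residual": fit.varcomp_se["residual"]}
        fit.extras["names"] = [gname, "residual"]
        _attach_h2(fit, gname)
        return fit
    comps.append(np.eye(len(y)))
    names.append("residual")
    fit = fit_components(y, X, comps, names=names, max_iter=max_iter, tol=tol)
    fit.fixed_names = fixed_names
    if genetic_idx:
        _attach_h2(fit, names[genetic_idx[0]])
    return fit


def _attach_h2(fit: VcFit, genetic_name: str) -> None:
    theta = fit.extras["theta"]
    names = fit.extras["names"]
    g = names.index(genetic_name)
    total = float(np.sum(theta))
    if total <= 0:
        fit.h2, fit.h2_se = 0.0, np.nan
        return
    h2 = float(theta[g] / total)
    fit.h2 = min(max(h2, 0.0), 1.0)
    cov = fit.extras.get("ai_cov")
    if cov is not None and np.all(np.isfinite(cov)):
        grad = -theta[g] / total ** 2 * np.ones(len(theta))
        grad[g] += 1.0 / total
        fit.h2_se = float(np.sqrt(max(grad @ cov @ grad, 0.0)))
    else:
        fit.h2_se = np.nan


def lrt_variance(full, reduced) -> tuple[float, float]:
    """Boundary LRT of one variance component: p from the 50:50 mixture of a
    point mass at 0 and chi-square(1)."""
    lf = full.loglik if isinstance(full, VcFit) else fit_reml(full).loglik
    lr = reduced.loglik if isinstance(reduced, VcFit) else fit_reml(reduced).loglik
    lrt = 2.0 * (lf - lr)
    p = 1.0 if lrt <= 0 else 0.5 * stats.chi2.sf(lrt, 1)
    return float(lrt), float(p)


def mixture_pvalue(lrt: float) -> float:
    return 1.0 if lrt <= 0 else float(0.5 * stats.chi2.sf(lrt, 1))


# ---------------------------------------------------------------------------
# cross-population variance-equality test
# ---------------------------------------------------------------------------

def compare_crosspop_variances(trait: str, data, crosspop_G: RelatednessMatrix,
                               fixed: Sequence[str] = (),
                               random: Sequence[RandomTerm] = (),
                               max_iter: int = 200) -> dict:
    """Test equality of additive genetic variances between two populations.

    One-trait model over the merged data with population-masked genetic
    components: sigma1^2 (K o P1) + sigma2^2 (K o P2) + c (K o P12) with the
    cross-population covariance c unconstrained, and per-population residuals.
    The constrained model ties sigma1 = sigma2; the LRT is referred to a full
    chi-square(1) (interior equality constraint).
    """
    spec = ModelSpec(trait=trait, data=data, fixed=list(fixed), random=[])
    df = spec.records()
    pops = sorted(df["population"].unique())
    if len(pops) != 2:
        raise RemlError(f"need exactly 2 populations, found {pops}")
    y = df["value"].to_numpy(dtype=float)
    X, _ = build_design(df, list(fixed))
    term = RandomTerm("individual_id", crosspop_G)
    Kobs, _, _ = _term_component(df, term)
    obs_pop = df["population"].to_numpy()
    m1 = (obs_pop == pops[0]).astype(float)
    m2 = (obs_pop == pops[1]).astype(float)
    B11 = np.outer(m1, m1)
    B22 = np.outer(m2, m2)
    B12 = np.outer(m1, m2) + np.outer(m2, m1)
    comps_extra, names_extra = [], []
    for t in random:
        C, _, _ = _term_component(df, t)
        comps_extra.append(C)
        names_extra.append(t.label())
    n = len(y)
    R1 = np.diag(m1)
    R2 = np.diag(m2)
    full = fit_components(
        y, X,
        [Kobs * B11, Kobs * B22, Kobs * B12] + comps_extra + [R1, R2],
        names=["va_pop1", "va_pop2", "cov12"] + names_extra + ["res1", "res2"],
        allow_negative=(2,), max_iter=max_iter)
    constrained = fit_components(
        y, X,
        [Kobs * (B11 + B22), Kobs * B12] + comps_extra + [R1, R2],
        names=["va_equal", "cov12"] + names_extra + ["res1", "res2"],
        allow_negative=(1,), max_iter=max_iter)
    lrt = 2.0 * (full.loglik - constrained.loglik)
    p = float(stats.chi2.sf(max(lrt, 0.0), 1))
    return {"lrt": float(lrt), "p": p, "full": full, "constrained": constrained,
            "populations": pops}


# ---------------------------------------------------------------------------
# expected phenotypic values
# ---------------------------------------------------------------------------

def compute_EPV(spec: ModelSpec) -> pd.Series:
    """Expected phenotypic value per individual: the per-individual mean of
    (observed value - fitted fixed effects - non-genetic random-effect BLUPs),
    standardized to mean 0 and variance 1.

    The spec must contain no relatedness-based term; the permanent-environment
    term is likewise excluded here (with the genetic term absent it would
    absorb the between-individual genetic signal the EPV is meant to keep).
    """
    for t in spec.random:
        if t.covariance is not None:
            raise RemlError("EPV model must not contain a relatedness-based term")
        if t.factor == "individual_id":
            raise RemlError("EPV model must not contain an individual-level term")
    df = spec.records()
    y = df["value"].to_numpy(dtype=float)
    X, _ = build_design(df, spec.fixed)
    if spec.random:
        comps, Zs, names = [], [], []
        for t in spec.random:
            C, Z, lv = _term_component(df, t)
            comps.append(C)
            Zs.append(Z)
            names.append(t.label())
        comps.append(np.eye(len(y)))
        names.append("residual")
        fit = fit_components(y, X, comps, names=names)
        Py = fit.extras["Py"]
        adjusted = y - X @ fit.beta
        theta = fit.extras["theta"]
        for k, Z in enumerate(Zs):
            u = theta[k] * (Z.T @ Py)  # BLUP for identity covariance
            adjusted = adjusted - Z @ u
    else:
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        adjusted = y - X @ beta
    out = pd.Series(adjusted).groupby(df["individual_id"].astype(str).values).mean()
    sd = out.std(ddof=1) if len(out) > 1 else 0.0
    if sd < 1e-12:
        raise RemlError("EPVs have zero variance (constant phenotype)")
    out = (out - out.mean()) / sd
    out.name = spec.trait
    return out
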