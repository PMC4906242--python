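"""Clustered inference for bouton-level outcomes.

Boutons within an imaged field are correlated, so group comparisons use a
linear mixed model

    y = mu_group + pi_prep + u_field + eps,
    u_field ~ N(0, sigma_f^2),  eps ~ N(0, sigma^2),

fit by restricted maximum likelihood with the variance ratio profiled out in
one dimension.  Companion procedures: Wald tests on group contrasts, a
within-condition field-heterogeneity F test, the field-averaging two-sample
t comparator, and a deliberately naive pooled bouton-level t test kept only
to demonstrate the anticonservatism of ignoring clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "OutcomeTable",
    "MixedModelFit",
    "TestResult",
    "fit_lmm",
    "wald_test",
    "heterogeneity_test",
    "field_average_ttest",
    "naive_pooled_ttest",
]


def _as_outcome_frame(data) -> pd.DataFrame:
    df = pd.DataFrame(data)
    required = {"y", "field_id", "group"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"outcome table missing columns: {sorted(missing)}")
    if "prep_id" not in df.columns:
        df = df.assign(prep_id="prep0")
    df = df.dropna(subset=["y"]).reset_index(drop=True)
    # every field must map to exactly one prep and one group
    for col in ("prep_id", "group"):
        n = df.groupby("field_id")[col].nunique()
        if (n > 1).any():
            raise ValueError(f"field mapped to multiple values of {col}")
    return df


OutcomeTable = pd.DataFrame  # columns: y, field_id, prep_id, group


@dataclass
class MixedModelFit:
    groups: list[str]
    group_means: np.ndarray  # fixed-effect group means (reference-prep scale)
    cov_means: np.ndarray  # covariance of the group-mean estimates
    prep_effects: dict[str, float]
    sigma2_field: float
    sigma2_resid: float
    loglik_reml: float
    converged: bool
    boundary: bool  # True when sigma2_field was truncated at zero
    n_obs: int
    n_fields: int
    used_prep_term: bool
    field_ids: list = field(repr=False, default_factory=list)
    # internals kept for df approximations
    _profile: dict = field(repr=False, default_factory=dict)

    @property
    def icc(self) -> float:
        tot = self.sigma2_field + self.sigma2_resid
        return self.sigma2_field / tot if tot > 0 else 0.0

    def mean(self, group: str) -> float:
        return float(self.group_means[self.groups.index(group)])


@dataclass
class TestResult:
    __test__ = False  # not a pytest class

    statistic: float
    df: float | tuple[float, float] | None
    pvalue: float
    null: str
    method: str

    def __post_init__(self):
        if not (np.isnan(self.pvalue) or 0 <= self.pvalue <= 1):
            raise ValueError("p-value outside [0, 1]")


def _design(df: pd.DataFrame, use_prep: bool):
    groups = sorted(df["group"].unique())
    preps = sorted(df["prep_id"].unique())
    n = len(df)
    Xg = np.zeros((n, len(groups)))
    for j, g in enumerate(groups):
        Xg[df["group"].to_numpy() == g, j] = 1.0
    cols = [f"mu[{g}]" for g in groups]
    X = Xg
    if use_prep and len(preps) > 1:
        Xp = np.zeros((n, len(preps) - 1))
        for j, p in enumerate(preps[1:]):
            Xp[df["prep_id"].to_numpy() == p, j] = 1.0
        X = np.hstack([Xg, Xp])
        cols += [f"prep[{p}]" for p in preps[1:]]
    return X, groups, preps, cols


class _RemlWorkspace:
    """Precomputed sufficient statistics for the profiled REML objective.

    With V = sigma^2 (I + lam Z Z'), one random intercept per field, the
    Woodbury form V_i^-1 = I - c_i J needs only per-field sums of X and y.
    """

    def __init__(self, y, X, field_codes, n_fields):
        self.n, self.p = X.shape
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.nf = np.bincount(field_codes, minlength=n_fields).astype(float)
        self.Sx = np.zeros((n_fields, self.p))
        for j in range(self.p):
            self.Sx[:, j] = np.bincount(field_codes, weights=X[:, j], minlength=n_fields)
        self.Sy = np.bincount(field_codes, weights=y, minlength=n_fields)

    def neg2(self, lam, want_grad=False):
        """-2 restricted log-likelihood (up to constant) and its d/d(lam)."""
        c = lam / (1.0 + lam * self.nf)
        K = self.XtX - (self.Sx.T * c) @ self.Sx
        Xty_w = self.Xty - self.Sx.T @ (c * self.Sy)
        yty_w = self.yty - float(c @ (self.Sy**2))
        try:
            beta = np.linalg.solve(K, Xty_w)
        except np.linalg.LinAlgError:
            return np.inf, None, None
        rss = yty_w - 2.0 * float(beta @ Xty_w) + float(beta @ K @ beta)
        rss = max(rss, 1e-300)
        sign, logdet_k = np.linalg.slogdet(K)
        if sign <= 0:
            return np.inf, None, None
        logdet_v = float(np.sum(np.log1p(lam * self.nf)))
        dof = self.n - self.p
        neg2 = dof * np.log(rss) + logdet_v + logdet_k
        info = {"beta": beta, "sigma2": rss / dof, "XtVinvX": K, "rss": rss}
        if not want_grad:
            return neg2, info, None
        cp = 1.0 / (1.0 + lam * self.nf) ** 2  # d c / d lam
        Kp = -(self.Sx.T * cp) @ self.Sx
        Xty_p = -self.Sx.T @ (cp * self.Sy)
        yty_p = -float(cp @ (self.Sy**2))
        # envelope theorem: d rss / d beta = 0 at the GLS optimum
        rss_p = yty_p - 2.0 * float(beta @ Xty_p) + float(beta @ Kp @ beta)
        grad = (
            dof * rss_p / rss
            + float(np.sum(self.nf / (1.0 + lam * self.nf)))
            + float(np.trace(np.linalg.solve(K, Kp)))
        )
        return neg2, info, grad


def _reml_neg2(lam, y, X, field_codes, n_fields):
    """Convenience wrapper kept for the profile objective's public shape."""
    ws = _RemlWorkspace(y, X, field_codes, n_fields)
    neg2, info, _ = ws.neg2(lam)
    return neg2, info


def _reml_neg2_theta(theta, ws: _RemlWorkspace):
    """-2 restricted log-likelihood in (sigma_f^2, sigma^2), unprofiled."""
    sf2, s2 = theta
    if s2 <= 0 or sf2 < 0:
        return np.inf
    lam = sf2 / s2
    c = lam / (1.0 + lam * ws.nf)
    K = ws.XtX - (ws.Sx.T * c) @ ws.Sx
    Xty_w = ws.Xty - ws.Sx.T @ (c * ws.Sy)
    yty_w = ws.yty - float(c @ (ws.Sy**2))
    try:
        beta = np.linalg.solve(K, Xty_w)
    except np.linalg.LinAlgError:
        return np.inf
    rss = yty_w - 2.0 * float(beta @ Xty_w) + float(beta @ K @ beta)
    sign, logdet_k = np.linalg.slogdet(K / s2)
    if sign <= 0:
        return np.inf
    logdet_v = ws.n * np.log(s2) + float(np.sum(np.log1p(lam * ws.nf)))
    return logdet_v + logdet_k + rss / s2


def _contrast_variance(theta, ws: _RemlWorkspace, c_vec):
    """Variance of a fixed-effect contrast at given variance components."""
    sf2, s2 = theta
    lam = sf2 / s2
    cc = lam / (1.0 + lam * ws.nf)
    K = ws.XtX - (ws.Sx.T * cc) @ ws.Sx
    cov = s2 * np.linalg.inv(K)
    return float(c_vec @ cov @ c_vec)


def _satterthwaite_df(ws: _RemlWorkspace, theta, c_vec):
    """Satterthwaite approximation: df = 2 v^2 / Var(v) with Var(v) from the
    REML observed information of the variance components."""
    theta = np.asarray(theta, dtype=float)
    h = np.maximum(1e-4 * np.maximum(theta, 1e-8), 1e-10)
    # numeric Hessian of -2*loglik (central differences)
    H = np.zeros((2, 2))
    for a in range(2):
        for b in range(a, 2):
            ta = np.array(theta)
            pp = ta.copy(); pp[a] += h[a]; pp[b] += h[b]
            pm = ta.copy(); pm[a] += h[a]; pm[b] -= h[b]
            mp = ta.copy(); mp[a] -= h[a]; mp[b] += h[b]
            mm = ta.copy(); mm[a] -= h[a]; mm[b] -= h[b]
            vals = [_reml_neg2_theta(x, ws) for x in (pp, pm, mp, mm)]
            if not np.all(np.isfinite(vals)):
                return np.inf
            H[a, b] = H[b, a] = (vals[0] - vals[1] - vals[2] + vals[3]) / (4 * h[a] * h[b])
    # gradient of the contrast variance
    g = np.zeros(2)
    for a in range(2):
        tp = theta.copy(); tp[a] += h[a]
        tm = theta.copy(); tm[a] = max(tm[a] - h[a], 0.0 if a == 0 else 1e-12)
        g[a] = (_contrast_variance(tp, ws, c_vec) - _contrast_variance(tm, ws, c_vec)) / (tp[a] - tm[a])
    try:
        cov_theta = 2.0 * np.linalg.inv(H)  # information = H/2 for -2*loglik
    except np.linalg.LinAlgError:
        return np.inf
    v = _contrast_variance(theta, ws, c_vec)
    denom = float(g @ cov_theta @ g)
    if denom <= 0:
        return np.inf
    return 2.0 * v**2 / denom


def fit_lmm(
    data,
    use_prep: bool = True,
    max_iter: int = 200,
) -> MixedModelFit:
    """REML fit of the random-field-intercept model by 1-D profiling.

    The profiled objective depends only on the variance ratio
    lambda = sigma_f^2 / sigma^2; it is minimized on a log grid refined by
    bounded scalar optimization, and the GLS fixed effects are recovered at
    the optimum.  Negative field variance is truncated at zero and flagged.
    """
    df = _as_outcome_frame(data)
    groups_present = df.groupby("group")["field_id"].nunique()
    if (groups_present < 2).any():
        raise ValueError("need >= 2 fields per group")

    if use_prep:
        # a preparation term is droppable when some group lives entirely in
        # one preparation that contains nothing else (perfect confounding)
        tab = pd.crosstab(df["prep_id"], df["group"])
        for g in tab.columns:
            preps_of_g = tab.index[tab[g] > 0]
            if len(preps_of_g) == 1 and (tab.loc[preps_of_g[0]] > 0).sum() == 1:
                warnings.warn(
                    f"group {g!r} perfectly confounded with preparation "
                    f"{preps_of_g[0]!r}; dropping preparation term"
                )
                use_prep = False
                break

    y = df["y"].to_numpy(dtype=float)
    X, groups, preps, cols = _design(df, use_prep)
    field_ids = sorted(df["field_id"].unique())
    field_codes = df["field_id"].map({f: i for i, f in enumerate(field_ids)}).to_numpy()
    n_fields = len(field_ids)

    ws = _RemlWorkspace(y, X, field_codes, n_fields)

    def objective(log_lam):
        val, _, _ = ws.neg2(np.exp(log_lam))
        return val

    # coarse grid, bounded refinement, then a gradient root-finding polish
    # (a derivative-free minimizer localizes the optimum only to ~sqrt(eps))
    grid = np.linspace(-12.0, 8.0, 41)
    vals = np.array([objective(g) for g in grid])
    j = int(np.argmin(vals))
    lo = grid[max(0, j - 1)]
    hi = grid[min(len(grid) - 1, j + 1)]
    res = optimize.minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": 1e-8, "maxiter": max_iter},
    )
    lam = float(np.exp(res.x))
    for width in (0.05, 0.5, 2.0):
        a, b = lam * np.exp(-width), lam * np.exp(width)
        ga = ws.neg2(a, want_grad=True)[2]
        gb = ws.neg2(b, want_grad=True)[2]
        if ga is not None and gb is not None and ga < 0 < gb:
            lam = float(
                optimize.brentq(
                    lambda l: ws.neg2(l, want_grad=True)[2], a, b,
                    xtol=1e-300, rtol=8.9e-16, maxiter=max_iter,
                )
            )
            break
    neg2_opt, info, _ = ws.neg2(lam)
    neg2_zero, info_zero, _ = ws.neg2(0.0)
    boundary = False
    if neg2_zero <= neg2_opt + 1e-10:
        lam, neg2_opt, info = 0.0, neg2_zero, info_zero
        boundary = True
    if info is None:
        raise np.linalg.LinAlgError("singular design in mixed-model fit")

    sigma2 = info["sigma2"]
    beta = info["beta"]
    cov_beta = sigma2 * np.linalg.inv(info["XtVinvX"])
    k = len(groups)
    fit = MixedModelFit(
        groups=groups,
        group_means=beta[:k].copy(),
        cov_means=cov_beta[:k, :k].copy(),
        prep_effects=(
            {p: float(b) for p, b in zip(preps[1:], beta[k:])} if X.shape[1] > k else {}
        ),
        sigma2_field=lam * sigma2,
        sigma2_resid=sigma2,
        loglik_reml=-0.5 * (neg2_opt + (len(y) - X.shape[1]) * (1 + np.log(2 * np.pi / max(len(y) - X.shape[1], 1)))),
        converged=bool(res.success or boundary),
        boundary=boundary,
        n_obs=len(y),
        n_fields=n_fields,
        used_prep_term=X.shape[1] > k,
        field_ids=field_ids,
        _profile={"lambda": lam, "neg2": neg2_opt, "ws": ws, "n_cols": X.shape[1]},
    )
    return fit


def wald_test(
    fit: MixedModelFit,
    contrast: tuple[str, str] | list[tuple[str, str]],
    df_method: str = "satterthwaite",
) -> TestResult:
    """Wald test of group contrasts on a converged mixed-model fit.

    A single (a, b) pair tests mu_a - mu_b; a list of pairs gives a joint
    chi-square test (df = number of pairs).  The default t reference uses
    Satterthwaite degrees of freedom from the REML information (calibrated
    at small field counts); ``df_method='z'`` gives the plain normal
    reference and ``'between_field'`` a t with fields-minus-groups df.
    """
    if not fit.converged:
        raise ValueError("fit did not converge")
    pairs = [contrast] if isinstance(contrast, tuple) else list(contrast)
    k = len(fit.groups)
    C = np.zeros((len(pairs), k))
    for i, (a, b) in enumerate(pairs):
        for g in (a, b):
            if g not in fit.groups:
                raise ValueError(f"unknown group {g!r}")
        C[i, fit.groups.index(a)] = 1.0
        C[i, fit.groups.index(b)] -= 1.0
    est = C @ fit.group_means
    cov = C @ fit.cov_means @ C.T

    if len(pairs) == 1:
        se = float(np.sqrt(cov[0, 0]))
        if se == 0:  # degenerate zero contrast (group vs itself)
            return TestResult(0.0, None, 1.0, f"mu[{pairs[0][0]}] = mu[{pairs[0][1]}]", "lmm_wald")
        z = float(est[0] / se)
        null = f"mu[{pairs[0][0]}] = mu[{pairs[0][1]}]"
        if df_method == "between_field":
            dof = max(fit.n_fields - k, 1)
            p = 2.0 * stats.t.sf(abs(z), dof)
            return TestResult(z, float(dof), float(p), null, "lmm_wald")
        if df_method == "satterthwaite":
            dof = np.inf
            ws = fit._profile.get("ws")
            if ws is not None and not fit.boundary:
                c_full = np.zeros(fit._profile["n_cols"])
                c_full[:k] = C[0]
                dof = _satterthwaite_df(
                    ws, (fit.sigma2_field, fit.sigma2_resid), c_full
                )
            if np.isfinite(dof):
                p = 2.0 * stats.t.sf(abs(z), dof)
                return TestResult(z, float(dof), float(p), null, "lmm_wald")
            # boundary or degenerate information: normal reference
            p = 2.0 * stats.norm.sf(abs(z))
            return TestResult(z, None, float(p), null, "lmm_wald")
        p = 2.0 * stats.norm.sf(abs(z))
        return TestResult(z, None, float(p), null, "lmm_wald")

    if np.allclose(est, 0) and np.allclose(cov, 0):
        return TestResult(0.0, float(len(pairs)), 1.0, "all contrasts zero", "lmm_wald")
    stat = float(est @ np.linalg.solve(cov, est))
    dof = len(pairs)
    p = float(stats.chi2.sf(stat, dof))
    null = "; ".join(f"mu[{a}] = mu[{b}]" for a, b in pairs)
    return TestResult(stat, float(dof), p, null, "lmm_wald")


def heterogeneity_test(data, condition: str | None = None) -> TestResult:
    """F test of equal field means within one condition (field as fixed factor).

    A small p-value indicates intra-field correlation that bouton-level
    pooling would ignore.  Fields with fewer than 2 boutons are dropped.
    """
    df = _as_outcome_frame(data)
    if condition is not None:
        df = df[df["group"] == condition]
    elif df["group"].nunique() > 1:
        raise ValueError("pass condition= when the table has multiple groups")
    sizes = df.groupby("field_id").size()
    small = sizes[sizes < 2].index
    if len(small):
        warnings.warn(f"dropping fields with < 2 boutons: {sorted(small)}")
        df = df[~df["field_id"].isin(small)]
    fields = df["field_id"].unique()
    if len(fields) < 2:
        raise ValueError("need >= 2 fields with >= 2 boutons")
    y = df["y"].to_numpy(dtype=float)
    grand = y.mean()
    ssb = ssw = 0.0
    for f in fields:
        yf = df.loc[df["field_id"] == f, "y"].to_numpy(dtype=float)
        ssb += yf.size * (yf.mean() - grand) ** 2
        ssw += float(((yf - yf.mean()) ** 2).sum())
    df1 = len(fields) - 1
    df2 = y.size - len(fields)
    fstat = (ssb / df1) / (ssw / df2)
    p = float(stats.f.sf(fstat, df1, df2))
    return TestResult(float(fstat), (float(df1), float(df2)), p,
                      "equal field means within condition", "heterogeneity_wald")


def field_average_ttest(data, groups: tuple[str, str] | None = None) -> TestResult:
    """Two-sample pooled t test on per-field mean responses.

    Collapses each field to one observation; valid under clustering but less
    efficient than the mixed model.
    """
    df = _as_outcome_frame(data)
    gs = sorted(df["group"].unique()) if groups is None else list(groups)
    if len(gs) != 2:
        raise ValueError("field_average_ttest compares exactly two groups")
    means = df.groupby(["group", "field_id"])["y"].mean()
    a = means.loc[gs[0]].to_numpy()
    b = means.loc[gs[1]].to_numpy()
    if min(a.size, b.size) < 2:
        raise ValueError("need >= 2 fields per group")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    dof = a.size + b.size - 2
    return TestResult(float(t), float(dof), float(p),
                      f"mu[{gs[0]}] = mu[{gs[1]}] (field means)", "field_avg_ttest")


def naive_pooled_ttest(data, groups: tuple[str, str] | None = None) -> TestResult:
    """Bouton-level two-sample t test ignoring clustering (diagnostic only)."""
    df = _as_outcome_frame(data)
    gs = sorted(df["group"].unique()) if groups is None else list(groups)
    if len(gs) != 2:
        raise ValueError("naive_pooled_ttest compares exactly two groups")
    a = df.loc[df["group"] == gs[0], "y"].to_numpy(dtype=float)
    b = df.loc[df["group"] == gs[1], "y"].to_numpy(dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("need >= 2 boutons per group")
    warnings.warn("naive pooled t-test is anticonservative under clustering")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    dof = a.size + b.size - 2
    return TestResult(float(t), float(dof), float(p),
                      f"mu[{gs[0]}] = mu[{gs[1]}] (pooled boutons)", "naive_pooled_ttest")
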