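"""Boltzmann fits for voltage-clamp data.

Two model forms:

* I-V curve: ``I(V) = Gmax * (Erev - V) / (1 + exp((V_half - V) / k))`` —
  a linear driving force times a Boltzmann activation gate.
* Tail-current activation: ``I(V) = I_min + (I_max - I_min) / (1 + exp((V_half - V) / k))``.

Both are fit by trust-region nonlinear least squares with analytic Jacobians
and seeded multistart on non-convergence.  Group comparisons operate on
per-cell values (peak densities or fitted parameters) with Welch tests; a
summary-statistics Welch path covers published mean/SEM/n triplets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "IVFitParams",
    "ActivationFitParams",
    "iv_model",
    "activation_model",
    "fit_iv",
    "fit_activation",
    "simulate_iv",
    "simulate_tail",
    "compare_groups",
    "welch_from_summary",
]

DEFAULT_IV_GRID = np.arange(-50.0, 41.0, 10.0)
DEFAULT_TAIL_GRID = np.arange(-60.0, 61.0, 10.0)


@dataclass
class IVFitParams:
    gmax: float  # nS/pF
    erev: float  # mV
    v_half: float  # mV (printed symbol: V1/2act)
    k: float  # mV slope factor (printed symbol: kact)
    residual_norm: float
    converged: bool
    sign_flipped: bool = False

    def predict(self, v: np.ndarray) -> np.ndarray:
        return iv_model(v, self.gmax, self.erev, self.v_half, self.k)


@dataclass
class ActivationFitParams:
    i_min: float
    i_max: float
    v_half: float  # mV (printed symbol: V1/2inact)
    k: float  # mV (printed symbol: kinact)
    residual_norm: float
    converged: bool

    def predict(self, v: np.ndarray) -> np.ndarray:
        return activation_model(v, self.i_min, self.i_max, self.v_half, self.k)

    def normalized(self, v: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp((self.v_half - v) / self.k))


def iv_model(v, gmax, erev, v_half, k):
    return gmax * (erev - v) / (1.0 + np.exp((v_half - v) / k))


def activation_model(v, i_min, i_max, v_half, k):
    return i_min + (i_max - i_min) / (1.0 + np.exp((v_half - v) / k))


def _iv_jac(p, v):
    gmax, erev, v_half, k = p
    e = np.exp((v_half - v) / k)
    denom = 1.0 + e
    base = (erev - v) / denom
    d_g = base
    d_e = gmax / denom
    d_vh = -gmax * (erev - v) * e / (denom**2 * k)
    d_k = gmax * (erev - v) * e * (v_half - v) / (denom**2 * k**2)
    return np.column_stack([d_g, d_e, d_vh, d_k])


def _act_jac(p, v):
    i_min, i_max, v_half, k = p
    e = np.exp((v_half - v) / k)
    denom = 1.0 + e
    d_min = 1.0 - 1.0 / denom
    d_max = 1.0 / denom
    d_vh = -(i_max - i_min) * e / (denom**2 * k)
    d_k = (i_max - i_min) * e * (v_half - v) / (denom**2 * k**2)
    return np.column_stack([d_min, d_max, d_vh, d_k])


def _check_grid(v, i, min_points):
    v = np.asarray(v, dtype=float)
    i = np.asarray(i, dtype=float)
    if v.size != i.size or v.size < min_points:
        raise ValueError(f"need >= {min_points} matched (V, I) points")
    order = np.argsort(v)
    v, i = v[order], i[order]
    if np.any(np.diff(v) <= 0):
        raise ValueError("potentials must be distinct")
    return v, i


def fit_iv(v_mv, i_density, max_nfev: int = 2000) -> IVFitParams:
    """Fit the driving-force Boltzmann I-V model to peak current densities.

    Currents supplied in the inward-negative raw convention are flipped so
    that the model's positive driving-force product applies (recorded in
    ``sign_flipped``).
    """
    v, i = _check_grid(v_mv, i_density, 6)
    if np.allclose(i, 0):
        raise ValueError("all-zero currents")
    flipped = False
    if i[np.argmax(np.abs(i))] < 0:
        i = -i
        flipped = True

    # initialization: Erev from the descending zero-crossing beyond the peak,
    # V_half at half-maximal current, Gmax from the peak amplitude
    jpk = int(np.argmax(i))
    erev0 = v[-1] + 10.0
    if jpk < v.size - 1:
        seg_v, seg_i = v[jpk:], i[jpk:]
        cross = np.nonzero(np.diff(np.sign(seg_i)) < 0)[0]
        if cross.size:
            j = cross[0]
            erev0 = seg_v[j] - seg_i[j] * (seg_v[j + 1] - seg_v[j]) / (seg_i[j + 1] - seg_i[j])
    half = i[jpk] / 2.0
    rising = np.nonzero(i[: jpk + 1] >= half)[0]
    vhalf0 = v[rising[0]] if rising.size else v[jpk] - 10.0
    gmax0 = i[jpk] / max(erev0 - v[jpk], 1.0)

    def resid(p):
        return iv_model(v, *p) - i

    def jac(p):
        return _iv_jac(p, v)

    lb = [1e-9, v[0] - 100.0, v[0] - 100.0, 0.1]
    ub = [np.inf, v[-1] + 200.0, v[-1] + 100.0, 30.0]
    starts = [np.clip([gmax0, erev0, vhalf0, 5.0], lb, ub)]
    rng = np.random.default_rng(12345)
    for _ in range(3):
        starts.append(np.clip(starts[0] * rng.uniform(0.5, 1.5, 4), lb, ub))
    best = None
    for x0 in starts:
        sol = optimize.least_squares(
            resid, x0, jac=jac, bounds=(lb, ub), method="trf", max_nfev=max_nfev
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < 1e-20:
            break
    return IVFitParams(
        gmax=float(best.x[0]),
        erev=float(best.x[1]),
        v_half=float(best.x[2]),
        k=float(best.x[3]),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
        sign_flipped=flipped,
    )


def fit_activation(v_mv, i_tail, max_nfev: int = 2000) -> ActivationFitParams:
    """Fit the single-Boltzmann activation curve to tail-current amplitudes."""
    v, i = _check_grid(v_mv, i_tail, 6)
    span = i.max() - i.min()
    if span <= 1e-12 * max(1.0, np.abs(i).max()):
        raise ValueError("flat input: no activation range to fit")
    imin0, imax0 = i[0], i[-1]
    if imin0 > imax0:  # decreasing curve: swap roles, k stays positive
        imin0, imax0 = i.min(), i.max()
    half = imin0 + 0.5 * (imax0 - imin0)
    above = np.nonzero(i >= half)[0]
    vhalf0 = v[above[0]] if above.size else v[v.size // 2]

    def resid(p):
        return activation_model(v, *p) - i

    def jac(p):
        return _act_jac(p, v)

    lb = [-np.inf, -np.inf, v[0] - 100.0, 0.1]
    ub = [np.inf, np.inf, v[-1] + 100.0, 30.0]
    starts = [np.clip([imin0, imax0, vhalf0, 5.0], lb, ub)]
    rng = np.random.default_rng(54321)
    for _ in range(3):
        jitter = rng.uniform(0.8, 1.2, 4)
        starts.append(np.clip(starts[0] * jitter + rng.normal(0, 1, 4), lb, ub))
    best = None
    for x0 in starts:
        sol = optimize.least_squares(
            resid, x0, jac=jac, bounds=(lb, ub), method="trf", max_nfev=max_nfev
        )
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success and sol.cost < 1e-20:
            break
    return ActivationFitParams(
        i_min=float(best.x[0]),
        i_max=float(best.x[1]),
        v_half=float(best.x[2]),
        k=float(best.x[3]),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
    )


def simulate_iv(
    gmax: float,
    erev: float,
    v_half: float,
    k: float,
    grid: np.ndarray = DEFAULT_IV_GRID,
    noise_frac: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Model-exact I-V sweep with optional multiplicative Gaussian noise."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty voltage grid")
    i = iv_model(grid, gmax, erev, v_half, k)
    if noise_frac > 0:
        if rng is None:
            raise ValueError("pass rng for noisy simulation")
        i = i * (1.0 + noise_frac * rng.standard_normal(grid.size))
    return grid, i


def simulate_tail(
    i_min: float,
    i_max: float,
    v_half: float,
    k: float,
    grid: np.ndarray = DEFAULT_TAIL_GRID,
    noise_frac: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty voltage grid")
    i = activation_model(grid, i_min, i_max, v_half, k)
    if noise_frac > 0:
        if rng is None:
            raise ValueError("pass rng for noisy simulation")
        i = i * (1.0 + noise_frac * rng.standard_normal(grid.size))
    return grid, i


@dataclass
class GroupComparison:
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int
    percent_change: float  # 100 * (mean_b - mean_a) / mean_a
    percent_change_percell: float | None  # mean of per-cell changes vs mean_a
    t_stat: float
    df: float
    pvalue: float


def compare_groups(values_a, values_b) -> GroupComparison:
    """Welch comparison of per-cell values between two groups.

    Reports both percent-change conventions (ratio of means, and mean of
    per-cell percent changes relative to the group-A mean).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("need >= 3 cells per group")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite df
    va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
    df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
    ma = a.mean()
    pct = 100.0 * (b.mean() - ma) / ma if ma != 0 else np.nan
    pct_cell = float(np.mean(100.0 * (b - ma) / ma)) if ma != 0 else None
    return GroupComparison(
        mean_a=float(ma),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        n_a=int(a.size),
        mean_b=float(b.mean()),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_b=int(b.size),
        percent_change=float(pct),
        percent_change_percell=pct_cell,
        t_stat=float(t),
        df=float(df),
        pvalue=float(p),
    )


def welch_from_summary(mean_a, sem_a, n_a, mean_b, sem_b, n_b):
    """Welch t statistic, df and two-sided p from published mean/SEM/n."""
    va, vb = sem_a**2, sem_b**2
    t = (mean_b - mean_a) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def read_sweeps(path) -> pd.DataFrame:
    """Read per-cell sweeps (cell_id, group, V_mV, I_pA[, Cm_pF]) from CSV.

    When capacitance is present, adds an ``I_density`` column (pA/pF).
    """
    df = pd.read_csv(path)
    required = {"cell_id", "group", "V_mV", "I_pA"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sweep file missing columns: {sorted(missing)}")
    if "Cm_pF" in df.columns:
        df["I_density"] = df["I_pA"] / df["Cm_pF"]
    return df
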