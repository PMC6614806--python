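"""Binding time-course assembly and saturating-exponential kinetic fitting.

The binding of probes to unwound plasmid sites, with probes in excess and
negligible site re-closure, follows

    B(t) = U0 * (1 - exp(-K * t)),        K = k * (P0 - U0)

where B is the bound-complex count per 100 probes, U0 the initial number of
unwound (open) sites per 100 probes, P0 the probe count in the same units,
K the observed pseudo-first-order rate and k the underlying second-order
rate constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.special import expit, logit

__all__ = [
    "KineticParams",
    "BindingTimeCourse",
    "KineticFit",
    "binding_model",
    "assemble_time_course",
    "fit_eq1",
    "derive_rate_constant",
]


class FitError(RuntimeError):
    """Kinetic fit failed to converge."""


@dataclass(frozen=True)
class KineticParams:
    """Ground-truth kinetic parameters, in per-100-probe units.

    ``K = k * (P0 - U0)`` links the observed rate to the second-order rate
    constant; either may be supplied, the other is derived.
    """

    P0: float
    U0: float
    K: float | None = None
    k: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.U0 <= self.P0):
            raise ValueError("require 0 <= U0 <= P0")
        if self.K is None and self.k is None:
            raise ValueError("one of K or k must be given")
        excess = self.P0 - self.U0
        if self.K is None:
            object.__setattr__(self, "K", self.k * excess)
        elif self.k is None:
            if excess <= 0:
                raise ValueError("P0 must exceed U0 to derive k")
            object.__setattr__(self, "k", self.K / excess)
        else:
            if not np.isclose(self.K, self.k * excess, rtol=1e-6):
                raise ValueError("inconsistent K and k: K must equal k*(P0-U0)")
        if self.K < 0 or self.k < 0:
            raise ValueError("rates must be non-negative")

    def bound_at(self, t: np.ndarray | float) -> np.ndarray | float:
        """Expected bound count per 100 probes at time t (seconds)."""
        return binding_model(t, self.U0, self.K)


def binding_model(
    t: np.ndarray | float, u0: float, rate: float
) -> np.ndarray | float:
    """Saturating exponential B(t) = u0 * (1 - exp(-rate*t))."""
    return u0 * -np.expm1(-rate * np.asarray(t, dtype=float))


@dataclass
class BindingTimeCourse:
    """Mean binding level per 100 probes vs time, with SEM over replicates."""

    times: np.ndarray
    mean_bound: np.ndarray
    sem_bound: np.ndarray
    sem_time: np.ndarray
    n_videos: int
    #: optional (n_replicates, n_timepoints) matrix of per-replicate counts,
    #: column order matching ``times``; enables the replicate-level sandwich
    #: covariance in the kinetic fit (counts at successive times are
    #: correlated because bound molecules persist).
    replicate_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_bound = np.asarray(self.mean_bound, dtype=float)
        self.sem_bound = np.asarray(self.sem_bound, dtype=float)
        self.sem_time = np.asarray(self.sem_time, dtype=float)
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.sem_bound < 0) or np.any(self.sem_time < 0):
            raise ValueError("SEM values must be non-negative")
        if self.n_videos < 1:
            raise ValueError("n_videos must be >= 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_s": self.times,
                "mean_bound_per_100": self.mean_bound,
                "sem_bound_per_100": self.sem_bound,
                "sem_t_s": self.sem_time,
                "n_videos": self.n_videos,
            }
        )


@dataclass
class KineticFit:
    """Result of fitting the saturating-exponential binding model."""

    U0_hat: float
    K_hat: float
    se_U0: float
    se_K: float
    covariance: np.ndarray
    residuals: np.ndarray
    converged: bool
    identifiable: bool = True
    k_hat: float | None = None
    se_k: float | None = None
    message: str = ""
    n_points: int = 0

    def predict(self, t: np.ndarray | float) -> np.ndarray | float:
        return binding_model(t, self.U0_hat, self.K_hat)

    def confidence_interval(self, z: float = 1.96) -> dict[str, tuple[float, float]]:
        return {
            "U0": (self.U0_hat - z * self.se_U0, self.U0_hat + z * self.se_U0),
            "K": (self.K_hat - z * self.se_K, self.K_hat + z * self.se_K),
        }

    def to_dict(self) -> dict:
        return {
            "U0_hat": self.U0_hat,
            "se_U0": self.se_U0,
            "K_hat": self.K_hat,
            "se_K": self.se_K,
            "k_hat": self.k_hat,
            "se_k": self.se_k,
            "covariance": self.covariance.tolist(),
            "converged": self.converged,
            "identifiable": self.identifiable,
            "n_points": self.n_points,
            "message": self.message,
        }


def assemble_time_course(
    counts: pd.DataFrame,
    replicate_col: str = "replicate",
    time_col: str = "t_s",
    value_col: str = "bound_per_100",
    group_col: str = "video_index",
) -> BindingTimeCourse:
    """Aggregate per-video binding counts into a mean +/- SEM time course.

    ``counts`` must carry one row per (replicate, video); rows sharing a
    ``group_col`` value are replicate observations of the same nominal time
    point.  SEM of the measurement times is reported alongside SEM of the
    counts, matching the two-axis error model of the binding figures.
    """
    required = {time_col, value_col, group_col}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"counts table missing columns: {sorted(missing)}")
    grouped = counts.groupby(group_col)
    n_rep = grouped[value_col].count()
    if (n_rep == 1).any():
        warnings.warn(
            "single replicate at one or more time points; SEM reported as 0",
            stacklevel=2,
        )
    mean_b = grouped[value_col].mean()
    sem_b = grouped[value_col].sem().fillna(0.0)
    mean_t = grouped[time_col].mean()
    sem_t = grouped[time_col].sem().fillna(0.0)
    order = np.argsort(mean_t.to_numpy())
    n_videos = int(n_rep.max())
    replicate_values = None
    if replicate_col in counts.columns:
        pivot = counts.pivot_table(
            index=replicate_col, columns=group_col, values=value_col
        )
        if not pivot.isna().any().any():
            cols = mean_t.index.to_numpy()[order]
            replicate_values = pivot[cols].to_numpy(dtype=float)
    return BindingTimeCourse(
        times=mean_t.to_numpy()[order],
        mean_bound=mean_b.to_numpy()[order],
        sem_bound=sem_b.to_numpy()[order],
        sem_time=sem_t.to_numpy()[order],
        n_videos=n_videos,
        replicate_values=replicate_values,
    )


def _initial_guesses(
    t: np.ndarray, b: np.ndarray, p0_cap: float, rng: np.random.Generator
) -> list[tuple[float, float]]:
    """Primary start: U0 = max(B); K from a log-linear fit of the residual
    saturation; plus jittered restarts."""
    u0_start = float(np.clip(np.max(b), 1e-6, p0_cap))
    frac = np.clip(b / (u0_start * 1.05), 1e-9, 1 - 1e-9)
    mask = (t > 0) & (b > 0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], -np.log1p(-frac[mask]), 1)[0]
        k_start = float(max(slope, 1e-8))
    else:
        k_start = 1.0 / max(t.max(), 1.0)
    guesses = [(u0_start, k_start)]
    for _ in range(5):
        guesses.append(
            (
                float(np.clip(u0_start * rng.uniform(0.5, 1.5), 1e-6, p0_cap)),
                k_start * float(rng.uniform(0.2, 5.0)),
            )
        )
    return guesses


def fit_eq1(
    tc: BindingTimeCourse,
    p0_cap: float = 100.0,
    condition_number_limit: float = 1e8,
    seed: int = 0,
) -> KineticFit:
    """Weighted nonlinear least-squares fit of B(t) = U0*(1 - exp(-K t)).

    Weights are inverse-variance (1/sem^2); unit weights are used if any
    SEM is zero.  Parameters are constrained to U0 in [0, p0_cap] and
    K >= 0 via a smooth reparameterization (logit/log), not clipping.
    Multi-start initialization guards against local minima.  Identifiability
    of (U0, K) is checked through the condition number of the weighted
    Jacobian at the optimum.
    """
    t = tc.times
    b = tc.mean_bound
    if len(t) < 4:
        raise ValueError("need >= 4 time points to fit")
    if np.any(tc.sem_bound <= 0):
        w = np.ones_like(b)
    else:
        w = 1.0 / tc.sem_bound
    rng = np.random.default_rng(seed)

    if np.allclose(b, 0.0):
        cov = np.zeros((2, 2))
        return KineticFit(
            U0_hat=0.0,
            K_hat=0.0,
            se_U0=0.0,
            se_K=0.0,
            covariance=cov,
            residuals=np.zeros_like(b),
            converged=True,
            identifiable=False,
            message="all-zero time course: U0=0, K unidentifiable",
            n_points=len(t),
        )

    # theta = (logit(U0/p0_cap), log K): bounds enforced by the transform.
    def unpack(theta):
        return p0_cap * expit(theta[0]), np.exp(theta[1])

    def resid(theta):
        u0, rate = unpack(theta)
        return w * (binding_model(t, u0, rate) - b)

    best = None
    for u0_g, k_g in _initial_guesses(t, b, p0_cap, rng):
        theta0 = np.array(
            [logit(np.clip(u0_g / p0_cap, 1e-9, 1 - 1e-9)), np.log(k_g)]
        )
        try:
            sol = least_squares(resid, theta0, method="lm", max_nfev=5000)
        except Exception:
            continue
        if sol.success and (best is None or sol.cost < best.cost):
            best = sol
    if best is None:
        raise FitError("kinetic fit failed to converge from all starts")

    u0_hat, k_hat_rate = unpack(best.x)

    # Jacobian in natural (U0, K) space for covariance and identifiability.
    jac = np.column_stack(
        [
            w * -np.expm1(-k_hat_rate * t),
            w * u0_hat * t * np.exp(-k_hat_rate * t),
        ]
    )
    jtj = jac.T @ jac
    svals = np.linalg.svd(jac, compute_uv=False)
    cond = svals[0] / svals[-1] if svals[-1] > 0 else np.inf
    identifiable = bool(cond < condition_number_limit)
    if not identifiable:
        warnings.warn(
            f"(U0, K) poorly identified: Jacobian condition number {cond:.2e}",
            stacklevel=2,
        )
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full((2, 2), np.nan)
        identifiable = False
    residuals = binding_model(t, u0_hat, k_hat_rate) - b
    if np.all(w == 1.0):
        # unit weights: scale covariance by the residual variance
        dof = max(len(t) - 2, 1)
        cov = cov * float(residuals @ residuals) / dof
    if tc.replicate_values is not None and tc.replicate_values.shape[0] >= 3:
        # counts at successive times share molecules, so errors are
        # correlated; replace the independent-error covariance with the
        # replicate-level sandwich  A^-1 (J'W S W J) A^-1, where S is the
        # empirical covariance of the replicate mean.
        n_rep = tc.replicate_values.shape[0]
        sigma = np.cov(tc.replicate_values, rowvar=False) / n_rep
        wj = w[:, None] * jac  # = W @ J_natural with W = diag(w^2)
        try:
            a_inv = np.linalg.inv(jtj)
            cov = a_inv @ (wj.T @ sigma @ wj) @ a_inv
        except np.linalg.LinAlgError:  # pragma: no cover
            pass
    return KineticFit(
        U0_hat=float(u0_hat),
        K_hat=float(k_hat_rate),
        se_U0=float(np.sqrt(max(cov[0, 0], 0.0))),
        se_K=float(np.sqrt(max(cov[1, 1], 0.0))),
        covariance=cov,
        residuals=residuals,
        converged=True,
        identifiable=identifiable,
        n_points=len(t),
    )


def derive_rate_constant(fit: KineticFit, p0: float) -> tuple[float, float]:
    """Second-order rate constant k = K/(P0 - U0) with first-order error
    propagation through the (U0, K) covariance.

    Returns (k_hat, se_k) and records them on ``fit``.
    """
    excess = p0 - fit.U0_hat
    if excess <= 0:
        raise ValueError("P0 must exceed fitted U0 (excess-probe assumption)")
    k_hat = fit.K_hat / excess
    grad = np.array([fit.K_hat / excess**2, 1.0 / excess])
    var_k = float(grad @ fit.covariance @ grad)
    se_k = float(np.sqrt(max(var_k, 0.0)))
    fit.k_hat = float(k_hat)
    fit.se_k = se_k
    return float(k_hat), se_k
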