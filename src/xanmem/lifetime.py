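"""Returns-allowed interaction-lifetime decay curves and constrained
multi-exponential decomposition.

The decay statistic: at an origin time t0 the interactions present are
recorded; C(tau) is the number of those interactions that are *also*
present at t0 + tau, re-formed bonds counted again (returns allowed, no
absorbing break).  Averaging over many origins gives a smooth curve that
is modelled as

    C(tau) = C0 * sum_i (A_i / 100) * exp(-tau / T_i),

with non-negative percentage contributions A_i summing to 100 and time
constants T_i sorted ascending.  Four components describe hydroxyl-water
H-bond decay in the bilayer interface well; the fit is unweighted least
squares on the linear scale with NNLS-seeded amplitudes and log-spaced
multi-start over the time constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .contacts import BondEventMatrix

__all__ = [
    "DecayConfig", "DecayCurve", "MultiExpFit", "FitFailure",
    "decay_curve", "fit_multiexp", "fit_residuals", "multiexp_model",
]


class FitFailure(RuntimeError):
    """All restarts of the multi-exponential fit failed to converge."""

    def __init__(self, msg, diagnostics=None):
        super().__init__(msg)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class DecayConfig:
    """Origin layout for the returns-allowed decay statistic (all ps)."""

    lag: float = 5000.0
    origin_stride: float = 1000.0
    origin_count: int | None = None
    spacing: float = 1.0
    first_origin: float = 0.0

    def __post_init__(self):
        if self.lag <= 0 or self.origin_stride <= 0 or self.spacing <= 0:
            raise ValueError("lag, origin_stride and spacing must be positive")
        if self.origin_stride < self.spacing:
            raise ValueError("origin stride must be >= sample spacing")


@dataclass
class DecayCurve:
    lags: np.ndarray        # ps
    counts: np.ndarray      # mean surviving count C(tau)
    n_origins: int
    interaction: str = ""

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.lags.shape != self.counts.shape:
            raise ValueError("lags and counts must have equal length")


def decay_curve(matrix: BondEventMatrix, cfg: DecayConfig = DecayConfig()) -> DecayCurve:
    """Multi-origin returns-allowed decay curve of a bond event matrix.

    C(tau) = (1/N_origins) sum_origins sum_pairs 1[on at t0] * 1[on at t0+tau].
    """
    dt = matrix.dt
    times = matrix.times
    span = times[-1] - times[0]
    n_lag = int(round(cfg.lag / dt))
    if n_lag < 1 or span < cfg.lag:
        raise ValueError(
            f"trajectory span {span} ps cannot accommodate lag {cfg.lag} ps"
        )
    stride = max(1, int(round(cfg.origin_stride / dt)))
    first = int(round(cfg.first_origin / dt))
    last_origin = matrix.matrix.shape[1] - n_lag - 1
    if last_origin < first:
        raise ValueError("no admissible origins: lag too long for trajectory span")
    origins = np.arange(first, last_origin + 1, stride)
    if cfg.origin_count is not None:
        origins = origins[: cfg.origin_count]
    m = matrix.matrix
    acc = np.zeros(n_lag + 1)
    for i0 in origins:
        on = np.flatnonzero(m[:, i0])
        if on.size:
            acc += m[on, i0 : i0 + n_lag + 1].sum(axis=0)
    acc /= len(origins)
    lags = np.arange(n_lag + 1) * dt
    return DecayCurve(lags, acc, len(origins), matrix.interaction)


def multiexp_model(lags, amplitudes, taus) -> np.ndarray:
    """sum_i B_i exp(-tau / T_i) with absolute amplitudes B_i."""
    lags = np.asarray(lags, dtype=float)
    out = np.zeros_like(lags)
    for b, t in zip(amplitudes, taus):
        out += b * np.exp(-lags / t)
    return out


@dataclass
class MultiExpFit:
    """Constrained sum-of-exponentials decomposition of a decay curve.

    fractions are percentages of the total amplitude (sum exactly 100);
    taus ascend.  Standard errors come from the Gauss-Newton covariance at
    the optimum.
    """

    n_components: int
    fractions: np.ndarray      # A_i, %
    taus: np.ndarray           # T_i, ps
    c0: float                  # total amplitude at tau = 0
    sse: float
    fraction_se: np.ndarray
    tau_se: np.ndarray
    residuals: np.ndarray = field(repr=False, default=None)
    degenerate: bool = False   # two time constants within 5% of each other

    def model(self, lags) -> np.ndarray:
        return multiexp_model(lags, self.c0 * self.fractions / 100.0, self.taus)


def _single_fit(lags, counts, log_tau0, max_tau):
    n = len(log_tau0)

    def residual(p):
        b = p[:n] ** 2  # squared parameterisation keeps amplitudes >= 0
        taus = np.exp(p[n:])
        return multiexp_model(lags, b, taus) - counts

    # NNLS seed for the amplitudes at the starting time constants
    design = np.exp(-lags[:, None] / np.exp(log_tau0)[None, :])
    b0, _ = nnls(design, counts)
    b0 = np.maximum(b0, 1e-6 * max(counts.max(), 1.0))
    p0 = np.concatenate([np.sqrt(b0), log_tau0])
    lower = np.concatenate([np.full(n, 0.0), np.full(n, np.log(1e-3))])
    upper = np.concatenate(
        [np.full(n, np.inf), np.full(n, np.log(max_tau))]
    )
    sol = least_squares(
        residual, p0, bounds=(lower, upper), xtol=1e-13, ftol=1e-13, gtol=1e-13,
        max_nfev=1500,
    )
    return sol


def fit_multiexp(
    curve: DecayCurve,
    n: int = 4,
    restarts: int = 16,
    rng: np.random.Generator | int | None = 0,
    max_tau_factor: float = 20.0,
) -> MultiExpFit:
    """Best-of-multi-start constrained fit of ``n`` decaying exponentials.

    Initial time constants are log-spaced over [sample spacing, lag] with
    multiplicative jitter across restarts; amplitudes are seeded by
    non-negative least squares at each start.  Raises :class:`FitFailure`
    if no restart converges.
    """
    lags, counts = curve.lags, curve.counts
    if len(lags) < 4 * n:
        raise ValueError(f"need at least {4 * n} curve points to fit {n} components")
    if counts[0] <= 0:
        raise ValueError("C(0) must be positive")
    rng = np.random.default_rng(rng)
    spacing = max(lags[1] - lags[0], 1e-6) if len(lags) > 1 else 1.0
    lag_span = max(lags[-1], spacing * 2)
    base = np.linspace(np.log(spacing), np.log(lag_span), n + 2)[1:-1]
    max_tau = lag_span * max_tau_factor

    best = None
    failures = []
    for k in range(restarts):
        jitter = rng.normal(0.0, 0.4, size=n) if k else np.zeros(n)
        try:
            sol = _single_fit(lags, counts, base + jitter, max_tau)
        except Exception as exc:  # singular NNLS design etc.
            failures.append(str(exc))
            continue
        if not sol.success and not np.isfinite(sol.cost):
            failures.append(sol.message)
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise FitFailure("multi-exponential fit failed on all restarts", failures)

    b = best.x[:n] ** 2
    taus = np.exp(best.x[n:])
    order = np.argsort(taus)
    b, taus = b[order], taus[order]
    c0 = float(b.sum())
    fractions = 100.0 * b / c0

    # Gauss-Newton covariance in (B_i, T_i) space via the delta method
    resid = multiexp_model(lags, b, taus) - counts
    sse = float(np.sum(resid**2))
    J = np.empty((len(lags), 2 * n))
    for i in range(n):
        e = np.exp(-lags / taus[i])
        J[:, i] = e
        J[:, n + i] = b[i] * e * lags / taus[i] ** 2
    dof = max(len(lags) - 2 * n, 1)
    sigma2 = sse / dof
    try:
        cov = sigma2 * np.linalg.pinv(J.T @ J)
        b_se = np.sqrt(np.maximum(np.diag(cov)[:n], 0.0))
        tau_se = np.sqrt(np.maximum(np.diag(cov)[n:], 0.0))
    except np.linalg.LinAlgError:
        b_se = np.full(n, np.nan)
        tau_se = np.full(n, np.nan)
    frac_se = 100.0 * b_se / c0
    gaps = np.diff(taus) / taus[:-1] if n > 1 else np.array([1.0])
    return MultiExpFit(
        n_components=n,
        fractions=fractions,
        taus=taus,
        c0=c0,
        sse=sse,
        fraction_se=frac_se,
        tau_se=tau_se,
        residuals=-resid,
        degenerate=bool(np.any(gaps < 0.05)),
    )


def fit_residuals(fit: MultiExpFit, curve: DecayCurve) -> dict:
    """Residual series and graphical-check summaries for a converged fit.

    Returns the residual r(tau) = C(tau) - model(tau), the maximum
    |r|/C(0), and a Wald-Wolfowitz runs-test z statistic on the residual
    signs (|z| >> 2 flags structured misfit).
    """
    r = curve.counts - fit.model(curve.lags)
    signs = np.sign(r)
    signs = signs[signs != 0]
    n_pos = int((signs > 0).sum())
    n_neg = int((signs < 0).sum())
    runs = 1 + int(np.sum(signs[1:] != signs[:-1])) if signs.size else 0
    if n_pos > 0 and n_neg > 0:
        n_tot = n_pos + n_neg
        mean_runs = 2.0 * n_pos * n_neg / n_tot + 1.0
        var_runs = (
            2.0 * n_pos * n_neg * (2.0 * n_pos * n_neg - n_tot)
            / (n_tot**2 * (n_tot - 1.0))
        )
        z = (runs - mean_runs) / np.sqrt(var_runs) if var_runs > 0 else 0.0
    else:
        z = 0.0
    return {
        "residuals": r,
        "max_rel_residual": float(np.max(np.abs(r)) / curve.counts[0]),
        "runs_z": float(z),
        "sse": float(np.sum(r**2)),
    }
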