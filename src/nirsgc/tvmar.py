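"""Time-varying multivariate autoregressive (tvMAR) estimation across
trials with a self-tuning Kalman filter.

The model is ``x(t) = sum_k A(k, t) x(t-k) + eps(t)`` with the coefficient
matrices following a random walk over trial time.  All trials at a given
trial time enter one Kalman update as a batch of observations, so the fit
is exactly invariant to trial ordering.  The random-walk noise covariance
is never estimated explicitly: its effect is absorbed into a self-tuning
adaptation constant driven by the ratio of the current to the recent
across-trial innovation magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .datasets import TrialDataset

__all__ = ["StokOptions", "TvMARFit", "fit_stok", "residual_variance"]


@dataclass(frozen=True)
class StokOptions:
    """Tuning parameters of the self-tuning Kalman estimator.

    adapt_init : baseline adaptation constant (state-covariance inflation
        per step at steady innovation magnitude).
    adapt_min, adapt_max : bounds of the self-tuned adaptation constant.
    prior_scale : initial state covariance = ``prior_scale * I``.
    sigma_halflife_s : half-life (seconds) of the exponential smoothing of
        the innovation covariance estimate.
    eig_floor : relative eigenvalue floor of the regularized inversion of
        the innovation/regressor covariance.
    var_floor : relative floor on the diagonal of the innovation covariance
        (times the per-channel data variance) so GC log-ratios stay finite.
    burnin_s : initial stretch treated as estimator burn-in; recorded on
        the fit so downstream reporting can exclude it.
    """

    adapt_init: float = 0.05
    adapt_min: float = 1e-4
    adapt_max: float = 0.5
    prior_scale: float = 10.0
    sigma_halflife_s: float = 0.5
    eig_floor: float = 1e-8
    var_floor: float = 1e-12
    burnin_s: float = 3.0


@dataclass
class TvMARFit:
    """Fitted tvMAR model.

    coeffs : (p, T, n, n) with ``coeffs[k-1, t][j, i]`` the lag-``k``
        coupling from channel ``i`` into channel ``j`` at fitted time ``t``.
    innovation_cov : (T, n, n) symmetric PSD innovation covariance.
    times : (T,) seconds relative to trial onset.
    trace : per-time adaptation diagnostics (adaptation constant,
        innovation magnitude, regularization events).
    """

    order: int
    dt: float
    times: np.ndarray
    coeffs: np.ndarray
    innovation_cov: np.ndarray
    opts: StokOptions
    channel_names: list[str] = field(default_factory=list)
    trace: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_times(self) -> int:
        return self.coeffs.shape[1]

    @property
    def burnin_mask(self) -> np.ndarray:
        """True for fitted times past the estimator burn-in."""
        return self.times >= self.times[0] + self.opts.burnin_s - 1e-9

    def coeff_stack(self, t: int) -> np.ndarray:
        """Coefficient stack (p, n, n) at fitted time index ``t``."""
        return self.coeffs[:, t]

    def residual_variance(self, target: int, t: int) -> float:
        return residual_variance(self, target, t)

    # ------------------------------------------------------------------ I/O
    def to_hdf5(self, target) -> None:
        if isinstance(target, (str, Path)):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        target.create_dataset("coeffs", data=self.coeffs)
        target.create_dataset("innovation_cov", data=self.innovation_cov)
        target.create_dataset("times", data=self.times)
        for key, val in self.trace.items():
            target.create_dataset(f"trace/{key}", data=val)
        target.attrs["order"] = self.order
        target.attrs["dt"] = self.dt
        target.attrs["channel_names"] = [str(c) for c in self.channel_names]
        for key, val in vars(self.opts).items():
            target.attrs[f"opts_{key}"] = val

    @classmethod
    def from_hdf5(cls, source) -> "TvMARFit":
        if isinstance(source, (str, Path)):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        opts = StokOptions(
            **{
                k[len("opts_") :]: float(v)
                for k, v in source.attrs.items()
                if k.startswith("opts_")
            }
        )
        trace = {}
        if "trace" in source:
            trace = {k: source[f"trace/{k}"][()] for k in source["trace"]}
        names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in source.attrs["channel_names"]
        ]
        return cls(
            order=int(source.attrs["order"]),
            dt=float(source.attrs["dt"]),
            times=source["times"][()],
            coeffs=source["coeffs"][()],
            innovation_cov=source["innovation_cov"][()],
            opts=opts,
            channel_names=names,
            trace=trace,
        )


def residual_variance(fit: TvMARFit, target: int, t: int) -> float:
    """Full-model residual variance of ``target`` at fitted time index ``t``
    (the (target, target) entry of the innovation covariance)."""
    if not 0 <= t < fit.n_times:
        raise IndexError(f"time index {t} outside fitted window [0, {fit.n_times})")
    if not 0 <= target < fit.n_channels:
        raise IndexError("target channel out of range")
    return float(fit.innovation_cov[t, target, target])


def _floored_solve(mat: np.ndarray, rhs: np.ndarray, rel_floor: float) -> tuple[np.ndarray, int]:
    """Solve a symmetric system via eigendecomposition with a relative
    eigenvalue floor; returns the solution and the number of floored modes."""
    w, v = np.linalg.eigh(mat)
    floor = rel_floor * max(w[-1], 1e-300)
    n_floored = int(np.sum(w < floor))
    w = np.maximum(w, floor)
    return v @ ((v.T @ rhs) / w[:, None]), n_floored


def fit_stok(
    data: TrialDataset,
    order: int = 15,
    fit_window_s: tuple[float, float] | None = None,
    opts: StokOptions | None = None,
) -> TvMARFit:
    """Fit a tvMAR model across trials with the self-tuning Kalman filter.

    Parameters
    ----------
    data : trial-epoched dataset; trials act as repeated realizations.
    order : AR order ``p`` (the standard analysis uses 15, i.e. 1.95 s at
        a 0.13 s sampling interval).
    fit_window_s : closed time window (seconds, onset-relative) to fit;
        default is every epoch time with ``order`` preceding samples.
    opts : estimator tuning parameters.

    Returns
    -------
    TvMARFit with one coefficient stack and innovation covariance per
    fitted time point.  Deterministic given data and options.
    """
    opts = opts or StokOptions()
    x = data.data  # (n, T, R)
    n, t_total, r = x.shape
    if r < 2:
        raise ValueError("need at least 2 trials")
    times = data.times
    if fit_window_s is None:
        candidates = np.arange(order, t_total)
    else:
        lo, hi = fit_window_s
        candidates = np.where((times >= lo - 1e-9) & (times <= hi + 1e-9))[0]
        candidates = candidates[candidates >= order]
    if candidates.size < order + 1:
        raise ValueError("fewer usable samples than order + 1 in the fit window")

    m = n * order
    # lagged design per fitted time: (T_fit, R, m), columns [x(t-1); ...; x(t-p)]
    lag_design = np.concatenate(
        [x[:, candidates - k, :].transpose(1, 2, 0) for k in range(1, order + 1)],
        axis=2,
    )
    targets = x[:, candidates, :].transpose(1, 2, 0)  # (T_fit, R, n)

    chan_var = x.var(axis=(1, 2))
    sigma_floor = opts.var_floor * np.maximum(chan_var, 1e-300)
    lam_sigma = 0.5 ** (data.dt / opts.sigma_halflife_s)

    b = np.zeros((m, n))
    p_cov = opts.prior_scale * np.eye(m)
    ema_ms = float(chan_var.mean())
    sigma = None

    t_fit = candidates.size
    coeffs = np.empty((order, t_fit, n, n))
    innovation_cov = np.empty((t_fit, n, n))
    trace_c = np.empty(t_fit)
    trace_ms = np.empty(t_fit)
    trace_floored = np.zeros(t_fit, dtype=int)
    eye_r = np.eye(r)

    for step in range(t_fit):
        z = lag_design[step]  # (R, m)
        y = targets[step]  # (R, n)
        innov = y - z @ b  # prior one-step prediction errors
        ms = float(np.mean(innov**2))

        c = opts.adapt_init if ema_ms <= 0 else opts.adapt_init * ms / ema_ms
        c = float(np.clip(c, opts.adapt_min, opts.adapt_max))
        p_cov = (1.0 + c) * p_cov
        r_obs = max(ema_ms, 1e-300)

        if r <= m:
            s = z @ p_cov @ z.T + r_obs * eye_r
            k_gain_t, n_floor = _floored_solve(s, z @ p_cov, opts.eig_floor)
            k_gain = k_gain_t.T  # (m, R)
        else:
            # Woodbury form in coefficient space: (I + P Z'Z / r) K = P Z' / r.
            # The identity term (observation noise) keeps this invertible even
            # for a rank-deficient regressor covariance.
            gram = z.T @ z
            k_gain = np.linalg.solve(
                np.eye(m) + p_cov @ gram / r_obs, p_cov @ z.T / r_obs
            )
            n_floor = 0
        b = b + k_gain @ innov
        p_cov = p_cov - k_gain @ (z @ p_cov)
        p_cov = 0.5 * (p_cov + p_cov.T)
        w, v = np.linalg.eigh(p_cov)
        if w[0] < 0:
            p_cov = (v * np.maximum(w, 0.0)) @ v.T

        centered = innov - innov.mean(axis=0)
        sigma_raw = centered.T @ centered / (r - 1)
        sigma = sigma_raw if sigma is None else lam_sigma * sigma + (1 - lam_sigma) * sigma_raw
        sig = 0.5 * (sigma + sigma.T)
        d = np.arange(n)
        sig[d, d] = np.maximum(sig[d, d], sigma_floor)
        innovation_cov[step] = sig

        coeffs[:, step] = b.T.reshape(n, order, n).transpose(1, 0, 2)
        trace_c[step] = c
        trace_ms[step] = ms
        trace_floored[step] = n_floor
        ema_ms = lam_sigma * ema_ms + (1 - lam_sigma) * ms

    return TvMARFit(
        order=order,
        dt=data.dt,
        times=times[candidates],
        coeffs=coeffs,
        innovation_cov=innovation_cov,
        opts=opts,
        channel_names=list(data.channel_names),
        trace={"adaptation": trace_c, "innovation_ms": trace_ms, "floored": trace_floored},
    )
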