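"""Time-varying conditional Granger causality from a fitted tvMAR model.

For every ordered channel pair (i, j) and fitted time t,

    GC_{i->j}(t) = ln( sigma_{j\\i}(t) / sigma_j(t) )

where sigma_j(t) is the full-model innovation variance of target j and
sigma_{j\\i}(t) is the residual variance of j when channel i's influence is
excluded.  The efficient path never refits on data: it treats the fitted
model at time t as locally stationary, computes its exact autocovariance
sequence (companion-form Lyapunov equation, solved by doubling and batched
over time), and solves the reduced Yule-Walker system for the non-source
channels.  In exact arithmetic sigma_{j\\i} >= sigma_j, so the index is
non-negative; values that fail by numerical error are clipped to zero and
counted in the diagnostics.

A definitional oracle that *does* refit the reduced model on data is
provided for validation (``conditional_gc_reduced_refit``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import _var
from .datasets import TrialDataset
from .tvmar import StokOptions, TvMARFit, fit_stok

__all__ = [
    "GCTensor",
    "count_ordered_pairs",
    "conditional_gc",
    "conditional_gc_reduced_refit",
]

logger = logging.getLogger(__name__)


def count_ordered_pairs(n: int) -> int:
    """Number of directed connections, i.e. ordered channel pairs (i, j),
    i != j: ``n * (n - 1)``."""
    if n < 2:
        raise ValueError("need at least 2 channels")
    return n * (n - 1)


@dataclass
class GCTensor:
    """Non-negative GC values over ordered channel pairs and time.

    gc : (n, n, T) with ``gc[i, j, t] = GC_{i->j}``; the diagonal is NaN
        (undefined), as are time points where the reduction failed.
    diagnostics : clipped fraction, raw minimum before clipping, number of
        missing time points, reduction settings.
    """

    gc: np.ndarray
    times: np.ndarray
    channel_names: list[str] = field(default_factory=list)
    method: str = "efficient"
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_channels(self) -> int:
        return self.gc.shape[0]

    def pair(self, source: int, target: int) -> np.ndarray:
        return self.gc[source, target]

    def to_frame(self) -> pd.DataFrame:
        """Long-format table (source, target, time_s, gc)."""
        n, _, t = self.gc.shape
        src, tgt, ti = np.meshgrid(np.arange(n), np.arange(n), np.arange(t), indexing="ij")
        mask = src != tgt
        return pd.DataFrame(
            {
                "source": src[mask],
                "target": tgt[mask],
                "time_s": self.times[ti[mask]],
                "gc": self.gc[src[mask], tgt[mask], ti[mask]],
            }
        )

    def to_hdf5(self, target) -> None:
        if isinstance(target, (str, Path)):
            with h5py.File(target, "w") as fh:
                self.to_hdf5(fh)
            return
        target.create_dataset("gc", data=self.gc)
        target.create_dataset("times", data=self.times)
        target.attrs["method"] = self.method
        target.attrs["channel_names"] = [str(c) for c in self.channel_names]
        for key, val in self.diagnostics.items():
            target.attrs[f"diag_{key}"] = val

    @classmethod
    def from_hdf5(cls, source) -> "GCTensor":
        if isinstance(source, (str, Path)):
            with h5py.File(source, "r") as fh:
                return cls.from_hdf5(fh)
        names = [
            c.decode() if isinstance(c, bytes) else str(c)
            for c in source.attrs["channel_names"]
        ]
        diags = {
            k[len("diag_") :]: v for k, v in source.attrs.items() if k.startswith("diag_")
        }
        return cls(
            gc=source["gc"][()],
            times=source["times"][()],
            channel_names=names,
            method=str(source.attrs["method"]),
            diagnostics=diags,
        )


def conditional_gc(
    fit: TvMARFit,
    window_s: tuple[float, float] | None = None,
    time_stride: int = 1,
    reduced_order: int | None = None,
) -> GCTensor:
    """Compute time-varying conditional GC for every ordered channel pair.

    Parameters
    ----------
    fit : fitted tvMAR model.
    window_s : closed reporting window in seconds (default: all fitted
        times past the estimator burn-in).
    time_stride : evaluate GC every ``time_stride``-th fitted sample.
    reduced_order : AR order of the reduced Yule-Walker solve; defaults to
        ``max(3 * order, 8)``.

    Time points with an unstable or non-convergent local model are marked
    missing (NaN) and logged, never silently zeroed.
    """
    n = fit.n_channels
    if n < 2:
        raise ValueError("need at least 2 channels for GC")
    q = reduced_order if reduced_order is not None else max(3 * fit.order, 8)

    if window_s is None:
        sel = np.where(fit.burnin_mask)[0]
        if sel.size == 0:
            sel = np.arange(fit.n_times)
    else:
        lo, hi = window_s
        sel = np.where((fit.times >= lo - 1e-9) & (fit.times <= hi + 1e-9))[0]
        if sel.size == 0:
            raise ValueError("reporting window outside the fitted time axis")
    sel = sel[::time_stride]

    coeffs = fit.coeffs[:, sel].transpose(1, 0, 2, 3)  # (T, p, n, n)
    sigma = fit.innovation_cov[sel]
    t_sel = sel.size

    gammas, converged = _var.stationary_autocov(coeffs, sigma, n_lags=q)
    n_missing = int(np.sum(~converged))
    if n_missing:
        level = logging.WARNING if n_missing > 0.1 * t_sel else logging.DEBUG
        logger.log(
            level,
            "%d of %d time points have a non-convergent local model; marked missing",
            n_missing,
            t_sel,
        )

    gc = np.full((n, n, t_sel), np.nan)
    ok = np.where(converged)[0]
    sigma_full = np.maximum(np.einsum("tjj->tj", sigma[ok]), 1e-300)  # (T_ok, n)
    n_neg = 0
    raw_min = 0.0
    total = 0
    for src in range(n):
        keep = np.array([c for c in range(n) if c != src])
        resid = _var.reduced_innovation_cov(gammas[ok], keep, order=q)
        sig_red = np.einsum("tjj->tj", resid)  # (T_ok, n-1)
        vals = np.log(np.maximum(sig_red, 1e-300) / sigma_full[:, keep])
        n_neg += int(np.sum(vals < 0))
        total += vals.size
        if vals.size:
            raw_min = min(raw_min, float(vals.min()))
        gc[src, keep[:, None], ok[None, :]] = np.maximum(vals, 0.0).T
    return GCTensor(
        gc=gc,
        times=fit.times[sel],
        channel_names=list(fit.channel_names),
        method="efficient",
        diagnostics={
            "clipped_fraction": n_neg / max(total, 1),
            "raw_min": raw_min,
            "n_missing": n_missing,
            "reduced_order": q,
        },
    )


def conditional_gc_reduced_refit(
    data: TrialDataset,
    source: int,
    order: int = 15,
    fit_window_s: tuple[float, float] | None = None,
    opts: StokOptions | None = None,
    target: int | None = None,
    full_fit: TvMARFit | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Definitional GC oracle: refit the tvMAR without the source channel.

    Fits the reduced model on the data excluding ``source`` and returns
    ``ln(sigma_reduced(t) / sigma_full(t))`` for the target channel(s).
    O(n) times slower than the efficient path; intended as a correctness
    reference.  Values are returned unclipped.

    Returns
    -------
    times : (T,) fitted times.
    series : (T,) if ``target`` given, else (n-1, T) over the non-source
        channels in ascending channel order.
    """
    n = data.n_channels
    if not 0 <= source < n:
        raise ValueError("source channel out of range")
    if full_fit is None:
        full_fit = fit_stok(data, order=order, fit_window_s=fit_window_s, opts=opts)
    keep = np.array([c for c in range(n) if c != source])
    reduced_fit = fit_stok(
        data.select_channels(keep), order=order, fit_window_s=fit_window_s, opts=opts
    )
    sig_full = np.einsum("tjj->tj", full_fit.innovation_cov)[:, keep]
    sig_red = np.einsum("tjj->tj", reduced_fit.innovation_cov)
    series = np.log(np.maximum(sig_red, 1e-300) / np.maximum(sig_full, 1e-300)).T
    if target is not None:
        if target == source or not 0 <= target < n:
            raise ValueError("target must be a channel different from source")
        j = int(np.where(keep == target)[0][0])
        return full_fit.times, series[j]
    return full_fit.times, series
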