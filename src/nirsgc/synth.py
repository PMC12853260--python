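"""Synthetic trial-structured signals from ground-truth time-varying VAR
networks, with a closed-form Granger-causality oracle for stationary cases.

The generator emulates trial-epoched hemodynamic-band multichannel signals:
each trial is an independent realization of

    x(t) = A(1, t) x(t-1) + ... + A(p, t) x(t-p) + eps(t)

with a piecewise-constant coefficient schedule shared by all trials,
optional i.i.d. Gaussian measurement noise, and a burn-in so trials start
near the stationary distribution.  Pre/post condition pairs with known
directed coupling changes provide ground truth for the full pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _var
from .datasets import ChannelMap, TrialDataset

__all__ = [
    "Modulation",
    "GroundTruthNetwork",
    "ScenarioConfig",
    "generate_trials",
    "make_condition_pair",
    "analytic_gc_stationary",
    "demo_condition_pair",
]


@dataclass(frozen=True)
class Modulation:
    """Piecewise-constant override of one coupling coefficient.

    Sets ``A(lag)[target, source] = value`` for epoch sample indices in
    ``[t_start, t_stop)``; ``t_stop=None`` means until the end of the epoch.
    Burn-in samples use the schedule at the first epoch index.
    """

    source: int
    target: int
    value: float
    lag: int = 1
    t_start: int = 0
    t_stop: int | None = None


@dataclass
class GroundTruthNetwork:
    """Time-varying VAR ground truth: base coefficients plus modulations.

    Parameters
    ----------
    base : (p, n, n) coefficient stack; ``base[k-1][j, i]`` couples channel
        ``i`` at lag ``k`` into channel ``j``.
    noise_cov : (n, n) symmetric positive-definite innovation covariance.
    modulations : piecewise-constant coefficient overrides.
    labels : optional channel-to-ROI map.
    """

    base: np.ndarray
    noise_cov: np.ndarray
    modulations: list[Modulation] = field(default_factory=list)
    labels: ChannelMap | None = None

    def __post_init__(self) -> None:
        self.base = np.asarray(self.base, dtype=float)
        if self.base.ndim != 3 or self.base.shape[1] != self.base.shape[2]:
            raise ValueError("base must be (p, n, n)")
        if not np.all(np.isfinite(self.base)):
            raise ValueError("coefficients must be finite")
        self.noise_cov = np.asarray(self.noise_cov, dtype=float)
        n = self.base.shape[1]
        if self.noise_cov.shape != (n, n):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(self.noise_cov, self.noise_cov.T):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(self.noise_cov).min() <= 0:
            raise ValueError("noise_cov must be positive definite")

    @property
    def n_channels(self) -> int:
        return self.base.shape[1]

    @property
    def order(self) -> int:
        return self.base.shape[0]

    @property
    def is_stationary(self) -> bool:
        return not self.modulations

    def breakpoints(self, n_times: int) -> np.ndarray:
        """Epoch sample indices at which the coefficient schedule changes."""
        pts = {0}
        for m in self.modulations:
            pts.add(max(m.t_start, 0))
            if m.t_stop is not None and m.t_stop < n_times:
                pts.add(m.t_stop)
        return np.array(sorted(p for p in pts if p < n_times))

    def coeffs_at(self, t: int) -> np.ndarray:
        """Coefficient stack ``(p, n, n)`` active at epoch sample ``t``."""
        out = self.base.copy()
        for m in self.modulations:
            stop = np.inf if m.t_stop is None else m.t_stop
            if m.t_start <= t < stop:
                out[m.lag - 1, m.target, m.source] = m.value
        return out

    def check_stable(self, n_times: int, max_radius: float = 1.0) -> None:
        """Raise if the companion spectral radius reaches 1 anywhere."""
        for t in self.breakpoints(n_times):
            rho = float(_var.spectral_radius(self.coeffs_at(int(t))[None])[0])
            if rho >= max_radius:
                raise ValueError(
                    f"unstable coefficient schedule at epoch sample {int(t)}: "
                    f"spectral radius {rho:.4f} >= 1"
                )


@dataclass
class ScenarioConfig:
    """Simulation settings for one condition.

    Defaults emulate the study conditions: a 0.13 s sampling interval,
    epochs of [-5, 15] s around onset, and trial counts in the hundreds.
    """

    n_trials: int = 300
    n_times: int = 154          # 20 s at 0.13 s, half-open [-5, 15)
    dt: float = 0.13
    onset_index: int = 38       # sample at 0 s
    noise_scale: float = 0.1    # measurement-noise standard deviation
    amplitude_cv: float = 0.0   # trial-to-trial amplitude variability knob
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")
        if not 0 <= self.onset_index < self.n_times:
            raise ValueError("onset index must lie within the epoch")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


def generate_trials(
    network: GroundTruthNetwork,
    config: ScenarioConfig,
    phase: str | None = None,
    hand: str | None = None,
) -> TrialDataset:
    """Simulate independent trials from a (time-varying) VAR network.

    A burn-in of ``10 * order`` samples generated under the schedule at the
    first epoch index is discarded, so trials start near the stationary
    distribution.  Deterministic given ``config.seed``.
    """
    network.check_stable(config.n_times)
    p, n = network.order, network.n_channels
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=int(config.seed), spawn_key=(hash_tag(phase, hand),))
    )
    burn = 10 * p
    total = burn + config.n_times
    chol = np.linalg.cholesky(network.noise_cov)
    r = config.n_trials

    x = np.zeros((total + p, r, n))
    eps = rng.standard_normal((total, r, n)) @ chol.T
    coeffs_first = network.coeffs_at(0)
    for step in range(total):
        t_epoch = max(step - burn, 0)
        a = coeffs_first if step < burn else network.coeffs_at(t_epoch)
        acc = eps[step]
        for k in range(1, p + 1):
            acc = acc + x[p + step - k] @ a[k - 1].T
        x[p + step] = acc

    data = x[p + burn :].transpose(2, 0, 1)  # (n, T, R)
    if config.amplitude_cv > 0:
        sigma = np.sqrt(np.log1p(config.amplitude_cv**2))
        amps = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=r)
        data = data * amps[None, None, :]
    if config.noise_scale > 0:
        data = data + config.noise_scale * rng.standard_normal(data.shape)
    return TrialDataset(
        data=data, dt=config.dt, onset_index=config.onset_index, phase=phase, hand=hand
    )


def hash_tag(phase: str | None, hand: str | None) -> int:
    """Small deterministic stream key for a condition tag pair."""
    phases = {None: 0, "pre": 1, "post": 2}
    hands = {None: 0, "unaffected": 1, "affected": 2}
    return phases.get(phase, 3) * 4 + hands.get(hand, 3)


def make_condition_pair(
    network_pre: GroundTruthNetwork,
    network_post: GroundTruthNetwork,
    config: ScenarioConfig,
    hand: str | None = None,
) -> tuple[TrialDataset, TrialDataset, pd.DataFrame]:
    """Generate pre/post datasets plus the ground-truth coupling change map.

    The change map lists every ordered channel pair whose net coupling
    (summed over lags, averaged over epoch time) differs between the two
    networks, tagged as ``increase`` or ``decrease``.
    """
    if network_pre.n_channels != network_post.n_channels:
        raise ValueError("pre and post networks must have the same channel count")
    pre = generate_trials(network_pre, config, phase="pre", hand=hand)
    post = generate_trials(network_post, config, phase="post", hand=hand)

    n_times = config.n_times
    mean_pre = _schedule_mean(network_pre, n_times)
    mean_post = _schedule_mean(network_post, n_times)
    net = (mean_post - mean_pre).sum(axis=0)  # (n, n), target x source
    rows = []
    nch = network_pre.n_channels
    for tgt in range(nch):
        for src in range(nch):
            d = net[tgt, src]
            if abs(d) > 1e-12:
                rows.append(
                    {
                        "source": src,
                        "target": tgt,
                        "direction": "increase" if d > 0 else "decrease",
                        "magnitude": abs(d),
                    }
                )
    change_map = pd.DataFrame(rows, columns=["source", "target", "direction", "magnitude"])
    return pre, post, change_map


def _schedule_mean(network: GroundTruthNetwork, n_times: int) -> np.ndarray:
    pts = list(network.breakpoints(n_times)) + [n_times]
    acc = np.zeros_like(network.base)
    for a, b in zip(pts[:-1], pts[1:]):
        acc += network.coeffs_at(int(a)) * (b - a)
    return acc / n_times


def analytic_gc_stationary(
    network: GroundTruthNetwork,
    source: int,
    target: int,
    reduced_order: int = 60,
) -> float:
    """Closed-form conditional Granger causality for a stationary network.

    Computes ``ln(sigma_reduced / sigma_full)`` for the target channel,
    where the reduced autoregression (all channels except the source) is
    solved from the model's exact autocovariance sequence via Yule-Walker.
    Only defined for time-invariant networks.
    """
    if not network.is_stationary:
        raise ValueError("analytic GC oracle is defined only for stationary networks")
    if source == target:
        raise ValueError("source and target must differ")
    n = network.n_channels
    if not (0 <= source < n and 0 <= target < n):
        raise ValueError("channel index out of range")
    gammas, ok = _var.stationary_autocov(
        network.base[None], network.noise_cov[None], n_lags=reduced_order
    )
    if not ok[0]:
        raise ValueError("network is not stable; autocovariance did not converge")
    keep = np.array([c for c in range(n) if c != source])
    resid = _var.reduced_innovation_cov(gammas, keep, order=reduced_order)[0]
    j = int(np.where(keep == target)[0][0])
    sigma_red = resid[j, j]
    sigma_full = network.noise_cov[target, target]
    return float(np.log(sigma_red / sigma_full))


def demo_condition_pair(
    seed: int = 0,
    n_trials: int = 100,
    n_times: int = 70,
    onset_index: int = 15,
    increase: tuple[int, int] = (0, 2),
    pre_strength: float = 0.0,
    post_strength: float = 0.3,
    noise_scale: float = 0.1,
) -> tuple[TrialDataset, TrialDataset, pd.DataFrame, ChannelMap]:
    """Five-channel, three-ROI demo scenario with one planted coupling
    increase between ROIs (used by the CLI fixtures and end-to-end tests)."""
    n = 5
    base = np.zeros((1, n, n))
    np.fill_diagonal(base[0], 0.3)
    base[0, 3, 2] = 0.2   # within-ROI-B coupling present in both conditions
    src, tgt = increase
    pre_net_base = base.copy()
    pre_net_base[0, tgt, src] = pre_strength
    post_net_base = base.copy()
    post_net_base[0, tgt, src] = post_strength
    noise = np.eye(n)
    cmap = ChannelMap.from_assignments(
        rois={"ip-PMv": [0, 1], "ip-M1": [2, 3], "co-M1": [4]},
        hemispheres={"ip-PMv": "ip", "ip-M1": "ip", "co-M1": "co"},
        n_channels=n,
        seeds=[0],
    )
    net_pre = GroundTruthNetwork(pre_net_base, noise, labels=cmap)
    net_post = GroundTruthNetwork(post_net_base, noise, labels=cmap)
    config = ScenarioConfig(
        n_trials=n_trials,
        n_times=n_times,
        onset_index=onset_index,
        noise_scale=noise_scale,
        seed=seed,
    )
    pre, post, change_map = make_condition_pair(net_pre, net_post, config)
    return pre, post, change_map, cmap
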