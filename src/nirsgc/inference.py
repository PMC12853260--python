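"""Trial-label permutation inference with FDR control.

Significance of any GC-change quantity is assessed by randomly permuting
the pre/post labels of the pooled trials (within each hand condition
separately, preserving group sizes), refitting the full pipeline statistic
on every surrogate, and computing

    p = #( |surrogate| >= |observed| ) / B .

All scalar quantities of one analysis form a single family, flagged
jointly by the Benjamini-Hochberg step-up rule at the stated FDR level.
Surrogate random streams are counter-based (keyed by the surrogate index),
so results are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .datasets import TrialDataset

__all__ = ["PermutationResult", "permutation_test", "bh_fdr"]

logger = logging.getLogger(__name__)


def bh_fdr(p_values, q: float = 0.1) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < q < 1:
        raise ValueError("q must lie in (0, 1)")
    flags, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags


@dataclass
class PermutationResult:
    """Observed statistics, surrogate distributions, p-values, FDR flags."""

    table: pd.DataFrame       # columns: id, observed, p, significant
    surrogates: np.ndarray    # (B, n_statistics)
    B: int
    q: float
    seed: int
    n_retries: int = 0

    def __getitem__(self, stat_id: str) -> pd.Series:
        return self.table.set_index("id").loc[stat_id]


def _as_dict(ds) -> dict:
    return dict(ds) if isinstance(ds, dict) else {"": ds}


def _shuffle_pair(
    pre: dict[str, TrialDataset], post: dict[str, TrialDataset], rng: np.random.Generator
) -> tuple[dict, dict]:
    """Permute pre/post labels within each hand condition, preserving
    group sizes."""
    new_pre, new_post = {}, {}
    for key in pre:
        a, b = pre[key], post[key]
        pooled = np.concatenate([a.data, b.data], axis=2)
        perm = rng.permutation(pooled.shape[2])
        new_pre[key] = TrialDataset(
            pooled[:, :, perm[: a.n_trials]], a.dt, a.onset_index,
            phase=a.phase, hand=a.hand, channel_names=list(a.channel_names),
        )
        new_post[key] = TrialDataset(
            pooled[:, :, perm[a.n_trials :]], b.dt, b.onset_index,
            phase=b.phase, hand=b.hand, channel_names=list(b.channel_names),
        )
    return new_pre, new_post


def permutation_test(
    pre,
    post,
    statistic,
    B: int = 1000,
    q: float = 0.1,
    seed: int = 0,
    plus_one: bool = False,
    max_retries: int = 3,
) -> PermutationResult:
    """Permutation test of pre-vs-post statistics with BH-FDR flags.

    Parameters
    ----------
    pre, post : TrialDataset or mapping hand -> TrialDataset.  Labels are
        permuted within each hand condition separately.
    statistic : callable taking the same (pre, post) structure and
        returning an ordered mapping id -> scalar; any pipeline
        composition ending in scalars works.
    B : number of surrogates (1000 in the standard analysis).
    q : FDR level for the collective flags.
    plus_one : if True, use the conservative (r + 1) / (B + 1) p-value
        estimator instead of r / B.
    max_retries : surrogate failures are retried on the next sub-stream
        and counted; exhausted retries re-raise.

    Deterministic given ``seed``; surrogates may be evaluated in any order.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    pre_d, post_d = _as_dict(pre), _as_dict(post)
    if set(pre_d) != set(post_d):
        raise ValueError("pre and post must share hand conditions")
    for key in pre_d:
        if pre_d[key].data.shape[:2] != post_d[key].data.shape[:2]:
            raise ValueError("pre and post datasets must share channels and epoch axes")

    unwrap = not isinstance(pre, dict)

    def run(p_d, q_d):
        if unwrap:
            return statistic(p_d[""], q_d[""])
        return statistic(p_d, q_d)

    observed = run(pre_d, post_d)
    ids = list(observed.keys())
    obs = np.array([float(observed[k]) for k in ids])

    surr = np.empty((B, len(ids)))
    n_retries = 0
    for b in range(B):
        for attempt in range(max_retries + 1):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=int(seed), spawn_key=(b, attempt))
            )
            try:
                sp, spo = _shuffle_pair(pre_d, post_d, rng)
                vals = run(sp, spo)
                surr[b] = [float(vals[k]) for k in ids]
                break
            except Exception:  # noqa: BLE001 - surrogate-level robustness
                if attempt == max_retries:
                    raise
                n_retries += 1
                logger.warning("surrogate %d failed; retrying on next stream", b)

    exceed = (np.abs(surr) >= np.abs(obs)[None, :]).sum(axis=0)
    p = (exceed + 1) / (B + 1) if plus_one else exceed / B
    flags = bh_fdr(p, q=q)
    table = pd.DataFrame({"id": ids, "observed": obs, "p": p, "significant": flags})
    return PermutationResult(
        table=table, surrogates=surr, B=B, q=q, seed=seed, n_retries=n_retries
    )
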