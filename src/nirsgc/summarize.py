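"""Region-level summaries of pre-to-post changes in directed connectivity.

Given channel-level GC tensors for a pre and a post condition, the
summaries are built from the element-wise difference ``post - pre``:

* region-level increase ``dGC+`` = largest positive channel-level change
  between two ROIs (0 if all changes are non-positive), and decrease
  ``dGC-`` = smallest negative change (0 if all are non-negative), either
  per time point or after summing the positive/negative parts over a time
  window;
* relative affected-vs-unaffected changes;
* hemisphere means over significant connections, with medial ROIs (SMA)
  counted in both hemispheres;
* weighted-graph views (seed-channel nodes, degree centralities).

Integration windows are half-open in sample time, ``[a, b)``, so the five
standard 4 s windows [-2,2], [0,4], [2,6], [4,8], [6,10] are exactly
half-overlapping and their union equals the whole [-2, 10] window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ChannelMap
from .gc import GCTensor

__all__ = [
    "DeltaGC",
    "delta_gc",
    "window_indices",
    "region_change_timeresolved",
    "region_change_integrated",
    "region_summary_table",
    "relative_change",
    "hemisphere_means",
    "degree_centrality",
    "channel_increase_matrix",
    "seed_channel_view",
    "edges_to_dot",
    "STANDARD_WINDOWS",
    "WHOLE_WINDOW",
]

#: Half-overlapping 4 s windows centered at 0, 2, 4, 6 and 8 s.
STANDARD_WINDOWS = ((-2.0, 2.0), (0.0, 4.0), (2.0, 6.0), (4.0, 8.0), (6.0, 10.0))
#: Whole reporting window for total (time-integrated) changes.
WHOLE_WINDOW = (-2.0, 10.0)


@dataclass
class DeltaGC:
    """Channel-level GC change (post - pre) per ordered pair and time."""

    diff: np.ndarray  # (n, n, T), NaN on the diagonal
    times: np.ndarray
    hand: str | None = None
    channel_names: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.diff.shape[0]


def delta_gc(pre: GCTensor, post: GCTensor, hand: str | None = None) -> DeltaGC:
    """Element-wise post - pre difference of two GC tensors."""
    if pre.gc.shape != post.gc.shape:
        raise ValueError("pre and post GC tensors must share channels and times")
    if pre.times.shape != post.times.shape or not np.allclose(pre.times, post.times):
        raise ValueError("pre and post time axes differ")
    return DeltaGC(
        diff=post.gc - pre.gc,
        times=pre.times.copy(),
        hand=hand,
        channel_names=list(pre.channel_names),
    )


def window_indices(times: np.ndarray, window_s: tuple[float, float]) -> np.ndarray:
    """Indices of time samples in the half-open window [a, b)."""
    a, b = window_s
    idx = np.where((times >= a - 1e-9) & (times < b - 1e-9))[0]
    if idx.size == 0:
        raise ValueError(f"window {window_s} lies outside the time axis")
    return idx


def _pair_diffs(d: DeltaGC, chans_a: np.ndarray, chans_b: np.ndarray) -> np.ndarray:
    """Channel-level differences for all ordered pairs (i in A, j in B),
    shaped (n_pairs, T)."""
    if len(chans_a) == 0 or len(chans_b) == 0:
        raise ValueError("empty ROI")
    ii, jj = np.meshgrid(chans_a, chans_b, indexing="ij")
    mask = ii != jj
    return d.diff[ii[mask], jj[mask], :]


def region_change_timeresolved(
    d: DeltaGC, cmap: ChannelMap, roi_a: str, roi_b: str, t: int | None = None
):
    """Largest positive / smallest negative channel-level change from
    ``roi_a`` to ``roi_b`` per time point (zero-clipped).

    Returns arrays (increase, decrease) over time, or scalars at ``t``.
    """
    if roi_a == roi_b:
        raise ValueError("source and target ROI must differ")
    diffs = _pair_diffs(d, cmap.channels_in(roi_a), cmap.channels_in(roi_b))
    inc = np.maximum(np.nanmax(diffs, axis=0), 0.0)
    dec = np.minimum(np.nanmin(diffs, axis=0), 0.0)
    if t is not None:
        return float(inc[t]), float(dec[t])
    return inc, dec


def region_change_integrated(
    d: DeltaGC, cmap: ChannelMap, roi_a: str, roi_b: str, window_s: tuple[float, float]
) -> tuple[float, float]:
    """Time-integrated region-level change over a half-open window.

    Per channel pair the positive and negative parts of the change are
    summed over the window; the region increase/decrease is the largest
    positive / smallest negative of those sums (zero-clipped).
    """
    if roi_a == roi_b:
        raise ValueError("source and target ROI must differ")
    idx = window_indices(d.times, window_s)
    diffs = _pair_diffs(d, cmap.channels_in(roi_a), cmap.channels_in(roi_b))[:, idx]
    pos = np.nansum(np.maximum(diffs, 0.0), axis=1)
    neg = np.nansum(np.minimum(diffs, 0.0), axis=1)
    return float(max(pos.max(), 0.0)), float(min(neg.min(), 0.0))


def region_summary_table(
    d: DeltaGC, cmap: ChannelMap, windows=None
) -> pd.DataFrame:
    """Integrated increases/decreases for every ordered ROI pair and window.

    ``windows=None`` uses the whole window plus the five standard ones.
    """
    if windows is None:
        windows = (WHOLE_WINDOW,) + STANDARD_WINDOWS
    rows = []
    for roi_a, roi_b in permutations(cmap.rois(), 2):
        for win in windows:
            inc, dec = region_change_integrated(d, cmap, roi_a, roi_b, win)
            rows.append(
                {
                    "source_roi": roi_a,
                    "target_roi": roi_b,
                    "window": f"[{win[0]:g},{win[1]:g})",
                    "win_lo": win[0],
                    "win_hi": win[1],
                    "hand": d.hand or "",
                    "increase": inc,
                    "decrease": dec,
                }
            )
    return pd.DataFrame(rows)


def relative_change(affected: pd.DataFrame, unaffected: pd.DataFrame) -> pd.DataFrame:
    """Relative (affected minus unaffected) total changes per ROI pair.

    ``rel_increase = dGC+_aff - dGC+_unaff`` and
    ``rel_decrease = |dGC-_aff| - |dGC-_unaff|``; both are positive when
    the change is more pronounced for affected-hand use.
    """
    keys = ["source_roi", "target_roi", "window"]
    a = affected.set_index(keys)
    u = unaffected.set_index(keys)
    if not a.index.equals(u.index):
        raise ValueError("affected and unaffected summaries cover different pairs")
    out = pd.DataFrame(
        {
            "rel_increase": a["increase"] - u["increase"],
            "rel_decrease": a["decrease"].abs() - u["decrease"].abs(),
        }
    )
    return out.reset_index()


def hemisphere_means(
    summary: pd.DataFrame, cmap: ChannelMap, significant: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Mean total increases/decreases within and between hemispheres.

    Averages over all ordered ROI pairs in each group (ip-ip, co-co,
    ip-co); non-significant entries contribute zero.  Medial ROIs (the
    SMA) count toward both within-hemisphere groups; pairs of two medial
    ROIs are ambiguous and rejected.
    """
    sig_inc = sig_dec = None
    if significant is not None:
        keys = ["source_roi", "target_roi"]
        sig = significant.set_index(keys)
        sig_inc = sig["sig_increase"]
        sig_dec = sig["sig_decrease"]

    groups: dict[str, dict[str, list[float]]] = {
        g: {"increase": [], "decrease": []} for g in ("ip-ip", "co-co", "ip-co")
    }
    for _, row in summary.iterrows():
        ha = cmap.hemisphere_of(row["source_roi"])
        hb = cmap.hemisphere_of(row["target_roi"])
        if ha == "unassigned" or hb == "unassigned":
            raise ValueError("ROI without a hemisphere assignment")
        inc, dec = row["increase"], row["decrease"]
        if sig_inc is not None:
            key = (row["source_roi"], row["target_roi"])
            inc = inc if bool(sig_inc.loc[key]) else 0.0
            dec = dec if bool(sig_dec.loc[key]) else 0.0
        tags = []
        if ha == "medial" and hb == "medial":
            raise ValueError("cannot assign a hemisphere group to a medial-medial pair")
        if "medial" in (ha, hb):
            other = hb if ha == "medial" else ha
            tags.append(f"{other}-{other}")  # SMA counts within both hemispheres
        elif ha == hb:
            tags.append(f"{ha}-{ha}")
        else:
            tags.append("ip-co")
        for tag in tags:
            groups[tag]["increase"].append(inc)
            groups[tag]["decrease"].append(dec)
    rows = []
    for tag, vals in groups.items():
        rows.append(
            {
                "group": tag,
                "mean_increase": float(np.mean(vals["increase"])) if vals["increase"] else 0.0,
                "mean_decrease": float(np.mean(vals["decrease"])) if vals["decrease"] else 0.0,
                "n_pairs": len(vals["increase"]),
            }
        )
    return pd.DataFrame(rows)


def degree_centrality(weights) -> pd.DataFrame:
    """In-, out- and total degree of each node of a weighted directed graph.

    ``weights`` is an (n, n) adjacency matrix (``weights[i, j]`` = edge
    i -> j) or a DataFrame with columns source, target, weight.  Weights
    must be non-negative (the increases graph).
    """
    if isinstance(weights, pd.DataFrame):
        n = int(max(weights["source"].max(), weights["target"].max())) + 1
        mat = np.zeros((n, n))
        mat[weights["source"], weights["target"]] = weights["weight"]
    else:
        mat = np.array(weights, dtype=float)
        mat[np.isnan(mat)] = 0.0
    if (mat < 0).any():
        raise ValueError("degree centrality of an increases graph needs non-negative weights")
    out_deg = mat.sum(axis=1)
    in_deg = mat.sum(axis=0)
    return pd.DataFrame(
        {
            "node": np.arange(mat.shape[0]),
            "in_degree": in_deg,
            "out_degree": out_deg,
            "total": in_deg + out_deg,
        }
    )


def channel_increase_matrix(
    d: DeltaGC, cmap: ChannelMap, window_s: tuple[float, float] = WHOLE_WINDOW
) -> np.ndarray:
    """Total channel-level GC increases (positive parts summed over the
    window) across all ordered pairs of ROI-assigned channels; other
    entries (and the diagonal) are zero."""
    idx = window_indices(d.times, window_s)
    pos = np.nansum(np.maximum(d.diff[:, :, idx], 0.0), axis=2)
    assigned = np.concatenate([cmap.channels_in(r) for r in cmap.rois()]) if cmap.rois() else []
    mask = np.zeros_like(pos, dtype=bool)
    a = np.asarray(assigned, dtype=int)
    mask[np.ix_(a, a)] = True
    np.fill_diagonal(mask, False)
    return np.where(mask, pos, 0.0)


def seed_channel_view(
    d: DeltaGC,
    cmap: ChannelMap,
    seeds,
    window_s: tuple[float, float] = WHOLE_WINDOW,
) -> pd.DataFrame:
    """Region-level total increases with each seed channel as its own node.

    All seed channels must belong to one ROI; that ROI is split into
    per-channel nodes (named ``roi:ch<k>``) while other ROIs stay intact.
    Only increases are reported (edges with zero increase are kept with
    weight 0 for completeness of the node set).
    """
    seeds = [int(s) for s in seeds]
    seed_rois = {cmap.roi_of(s) for s in seeds}
    if len(seed_rois) != 1 or "unassigned" in seed_rois:
        raise ValueError("seed channels must all belong to one ROI")
    seed_roi = seed_rois.pop()
    nodes: dict[str, np.ndarray] = {}
    for roi in cmap.rois():
        if roi == seed_roi:
            rest = [c for c in cmap.channels_in(roi) if c not in seeds]
            for s in seeds:
                nodes[f"{roi}:ch{s}"] = np.array([s])
            if rest:
                nodes[roi] = np.array(rest)
        else:
            nodes[roi] = cmap.channels_in(roi)
    idx = window_indices(d.times, window_s)
    pos = np.nansum(np.maximum(d.diff[:, :, idx], 0.0), axis=2)
    rows = []
    for na, ca in nodes.items():
        for nb, cb in nodes.items():
            if na == nb:
                continue
            ii, jj = np.meshgrid(ca, cb, indexing="ij")
            m = ii != jj
            if not m.any():
                continue
            rows.append(
                {"source": na, "target": nb, "increase": float(pos[ii[m], jj[m]].max())}
            )
    return pd.DataFrame(rows)


def edges_to_dot(edges: pd.DataFrame, source="source", target="target",
                 weight="increase", name="G") -> str:
    """Render a weighted edge list as DOT-dialect text via networkx."""
    graph = nx.DiGraph(name=name)
    for _, row in edges.iterrows():
        graph.add_edge(str(row[source]), str(row[target]), weight=float(row[weight]))
    lines = [f"digraph {name} {{"]
    for node in graph.nodes:
        lines.append(f'    "{node}";')
    for u, v, data in graph.edges(data=True):
        lines.append(f'    "{u}" -> "{v}" [weight={data["weight"]:.6g}];')
    lines.append("}")
    return "\n".join(lines)
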