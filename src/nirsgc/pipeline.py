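"""End-to-end orchestration: preprocess -> fit -> GC -> delta -> summaries
-> permutation -> reports, from a single configuration.

Defaults reproduce the standard analysis settings: 0.02-0.3 Hz 4th-order
zero-phase bandpass, epochs [-5, 15) s with baseline [-5, 0) s, tvMAR
order 15 fitted on [-5, 10] s, GC reported on [-2, 10] s, the five
half-overlapping 4 s summary windows plus the whole window, 1000
surrogates and FDR 0.1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import summarize
from .datasets import ChannelMap, TrialDataset
from .gc import conditional_gc
from .inference import permutation_test
from .tvmar import StokOptions, fit_stok

__all__ = ["AnalysisConfig", "run_full_analysis"]

logger = logging.getLogger(__name__)

HANDS = ("unaffected", "affected")
PHASES = ("pre", "post")


@dataclass
class AnalysisConfig:
    """Settings of one full analysis run.

    ``inputs`` maps ``"<phase>_<hand>"`` (e.g. ``"pre_affected"``) to a
    TrialDataset HDF5/CSV path; ``channel_map`` is a channel-map CSV.
    """

    inputs: dict[str, str] = field(default_factory=dict)
    channel_map: str = ""
    output_dir: str = "nirsgc-out"
    low_hz: float = 0.02
    high_hz: float = 0.3
    filter_order: int = 4
    epoch_window_s: tuple[float, float] = (-5.0, 15.0)
    baseline_window_s: tuple[float, float] = (-5.0, 0.0)
    fit_window_s: tuple[float, float] = (-5.0, 10.0)
    report_window_s: tuple[float, float] = (-2.0, 10.0)
    ar_order: int = 15
    windows: tuple = summarize.STANDARD_WINDOWS
    B: int = 1000
    q: float = 0.1
    seed: int = 0
    gc_time_stride: int = 1
    stok: StokOptions = field(default_factory=StokOptions)

    def __post_init__(self) -> None:
        if not 0 < self.q < 1:
            raise ValueError("q must lie in (0, 1)")
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.ar_order < 1:
            raise ValueError("ar_order must be >= 1")

    @classmethod
    def from_json(cls, path) -> "AnalysisConfig":
        raw = json.loads(Path(path).read_text())
        if "stok" in raw:
            raw["stok"] = StokOptions(**raw["stok"])
        for key in ("epoch_window_s", "baseline_window_s", "fit_window_s", "report_window_s"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "windows" in raw:
            raw["windows"] = tuple(tuple(w) for w in raw["windows"])
        return cls(**raw)

    def to_json(self, path) -> None:
        raw = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(raw, indent=2, default=list))


def _load_dataset(path: str) -> TrialDataset:
    p = Path(path)
    if p.suffix in (".h5", ".hdf5"):
        return TrialDataset.from_hdf5(p)
    return TrialDataset.from_csv(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_analysis(
    config: AnalysisConfig,
    datasets: dict[str, TrialDataset] | None = None,
    cmap: ChannelMap | None = None,
) -> dict:
    """Run the full pipeline and write a report bundle to the output dir.

    ``datasets``/``cmap`` may be passed directly (e.g. synthetic data);
    otherwise they are loaded from the paths in the config.  Produces GC
    tensors per condition, per-hand channel-level changes, region
    summaries (time-resolved, windowed, whole-window, relative),
    hemisphere means, seed-channel graphs, permutation tables, and a
    manifest with content digests.  Idempotent for a fixed seed.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        result = _run(config, datasets, cmap, out)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    manifest = {
        "seed": config.seed,
        "files": {
            str(p.relative_to(out)): _sha256(p)
            for p in sorted(out.rglob("*"))
            if p.is_file() and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    result["manifest"] = manifest
    return result


def _run(config, datasets, cmap, out: Path) -> dict:
    if cmap is None:
        cmap = ChannelMap.from_csv(config.channel_map)
    if datasets is None:
        datasets = {key: _load_dataset(path) for key, path in config.inputs.items()}
    hands = sorted({k.split("_", 1)[1] for k in datasets})
    logger.info("stage fit: %d conditions, order %d", len(datasets), config.ar_order)

    fits, gcs = {}, {}
    for key, ds in datasets.items():
        fit = fit_stok(ds, order=config.ar_order, fit_window_s=config.fit_window_s,
                       opts=config.stok)
        fit.to_hdf5(out / f"fit_{key}.h5")
        gct = conditional_gc(fit, window_s=config.report_window_s,
                             time_stride=config.gc_time_stride)
        gct.to_hdf5(out / f"gc_{key}.h5")
        gct.to_frame().to_csv(out / f"gc_{key}.csv", index=False)
        fits[key], gcs[key] = fit, gct

    logger.info("stage delta/summaries")
    deltas = {}
    summaries = {}
    for hand in hands:
        d = summarize.delta_gc(gcs[f"pre_{hand}"], gcs[f"post_{hand}"], hand=hand)
        deltas[hand] = d
        whole_win = tuple(config.report_window_s)
        table = summarize.region_summary_table(
            d, cmap, windows=(whole_win,) + tuple(config.windows)
        )
        table.to_csv(out / f"region_summary_{hand}.csv", index=False)
        summaries[hand] = table
        inc_mat = summarize.channel_increase_matrix(d, cmap, whole_win)
        summarize.degree_centrality(inc_mat).to_csv(
            out / f"degree_centrality_{hand}.csv", index=False
        )
        seeds = cmap.seeds()
        if seeds.size:
            view = summarize.seed_channel_view(d, cmap, seeds, whole_win)
            view.to_csv(out / f"seed_view_{hand}.csv", index=False)
            (out / f"seed_view_{hand}.dot").write_text(summarize.edges_to_dot(view))

    relative = None
    whole_win = tuple(config.report_window_s)
    if set(hands) >= {"unaffected", "affected"}:
        whole = {
            h: s[np.isclose(s["win_lo"], whole_win[0]) & np.isclose(s["win_hi"], whole_win[1])]
            for h, s in summaries.items()
        }
        relative = summarize.relative_change(whole["affected"], whole["unaffected"])
        relative.to_csv(out / "relative_change.csv", index=False)

    logger.info("stage permutation: B=%d", config.B)
    perm_results = {}
    hem_means = {}
    for hand in hands:
        pre, post = datasets[f"pre_{hand}"], datasets[f"post_{hand}"]

        def stat(p_ds, q_ds, _cfg=config, _cmap=cmap):
            return _whole_window_statistic(p_ds, q_ds, _cfg, _cmap)

        res = permutation_test(pre, post, stat, B=config.B, q=config.q, seed=config.seed)
        res.table.to_csv(out / f"permutation_{hand}.csv", index=False)
        perm_results[hand] = res

        sig = _significance_frame(res.table)
        whole = summaries[hand]
        whole = whole[
            np.isclose(whole["win_lo"], whole_win[0])
            & np.isclose(whole["win_hi"], whole_win[1])
        ]
        hm = summarize.hemisphere_means(whole, cmap, significant=sig)
        hm.to_csv(out / f"hemisphere_means_{hand}.csv", index=False)
        hem_means[hand] = hm

    return {
        "fits": fits,
        "gc": gcs,
        "deltas": deltas,
        "summaries": summaries,
        "relative": relative,
        "permutation": perm_results,
        "hemisphere_means": hem_means,
        "channel_map": cmap,
    }


def _whole_window_statistic(pre: TrialDataset, post: TrialDataset,
                            config: AnalysisConfig, cmap: ChannelMap) -> dict[str, float]:
    """Whole-window region-level increases and decreases for every ordered
    ROI pair — the family tested by the permutation stage."""
    vals = {}
    for phase, ds in (("pre", pre), ("post", post)):
        fit = fit_stok(ds, order=config.ar_order, fit_window_s=config.fit_window_s,
                       opts=config.stok)
        vals[phase] = conditional_gc(fit, window_s=config.report_window_s,
                                     time_stride=config.gc_time_stride)
    d = summarize.delta_gc(vals["pre"], vals["post"])
    stats: dict[str, float] = {}
    from itertools import permutations as _perms

    for roi_a, roi_b in _perms(cmap.rois(), 2):
        inc, dec = summarize.region_change_integrated(
            d, cmap, roi_a, roi_b, tuple(config.report_window_s)
        )
        stats[f"{roi_a}->{roi_b}:increase"] = inc
        stats[f"{roi_a}->{roi_b}:decrease"] = dec
    return stats


def _significance_frame(table: pd.DataFrame) -> pd.DataFrame:
    rows = {}
    for _, row in table.iterrows():
        pair, kind = row["id"].rsplit(":", 1)
        src, tgt = pair.split("->")
        rows.setdefault((src, tgt), {})[f"sig_{kind}"] = bool(row["significant"])
    out = [
        {"source_roi": s, "target_roi": t,
         "sig_increase": v.get("sig_increase", False),
         "sig_decrease": v.get("sig_decrease", False)}
        for (s, t), v in rows.items()
    ]
    return pd.DataFrame(out)
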