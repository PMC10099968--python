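"""End-to-end orchestration and group statistics.

Reads a session bundle (real or synthetic), runs trial filtering, per-unit
z-profiles and modulation detection, per-class population PETHs, the
cluster/ARI correspondence analysis and the named group comparisons, and
writes tabular/JSON outputs plus a run manifest.  Significance is α = 0.05
throughout and no multiple-testing correction is applied (each comparison is
reported as a separate named contrast; interpret families of tests
accordingly).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__
from .cluster import run_cluster_analysis
from .peth import (
    PethSpec,
    ZProfile,
    build_zprofile,
    class_population_peth,
    detect_modulation,
    fast_slow_compare,
    filter_trials,
)
from .rf_atlas import ReceptiveField, overlap_report
from .synth import TrialEvents, UnitRecord

__all__ = ["GroupStatsRecord", "group_compare", "read_bundle", "run_all"]

logger = logging.getLogger("microreach")

ALPHA = 0.05
DISTAL_CLASSES = frozenset({1, 2, 6})
PROXIMAL_CLASSES = frozenset({8, 9, 10})

DESIGNS = ("one_way_anova", "mann_whitney", "paired_t", "unpaired_t", "pearson")
_PARAMETRIC = ("one_way_anova", "paired_t", "unpaired_t", "pearson")


@dataclass
class GroupStatsRecord:
    """One named group comparison: test, statistic, p-value, group summaries."""

    comparison: str
    design: str
    groups: dict  # name -> {n, mean, sd}
    statistic: float
    p_value: float
    shapiro: dict | None = None  # name -> {statistic, p_value}; parametric designs


def _summaries(groups: Mapping[str, Sequence[float]]) -> dict:
    out = {}
    for name, vals in groups.items():
        v = np.asarray(vals, dtype=float)
        out[name] = {
            "n": int(v.size),
            "mean": float(v.mean()) if v.size else float("nan"),
            "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        }
    return out


def group_compare(
    groups: Mapping[str, Sequence[float]],
    design: str,
    comparison: str = "",
) -> GroupStatsRecord:
    """Run a named standard test on grouped values.

    ``groups`` maps group name to values.  ``paired_t`` and ``pearson``
    expect exactly two equal-length groups; ``one_way_anova`` two or more.
    For parametric designs a Shapiro–Wilk normality check per group is
    recorded alongside the test (not used to switch tests automatically).
    """
    if design not in DESIGNS:
        raise ValueError(f"design must be one of {DESIGNS}")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    vals = list(arrays.values())
    if design in ("mann_whitney", "paired_t", "unpaired_t", "pearson") and len(vals) != 2:
        raise ValueError(f"{design} requires exactly two groups")
    if design in ("paired_t", "pearson") and len(vals[0]) != len(vals[1]):
        raise ValueError(f"{design} requires equal-length groups")
    if design == "one_way_anova":
        if len(vals) < 2:
            raise ValueError("one_way_anova requires at least two groups")
        res = stats.f_oneway(*vals)
    elif design == "mann_whitney":
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
    elif design == "paired_t":
        res = stats.ttest_rel(vals[0], vals[1])
    elif design == "unpaired_t":
        res = stats.ttest_ind(vals[0], vals[1])
    else:  # pearson
        res = stats.pearsonr(vals[0], vals[1])
    shapiro = None
    if design in _PARAMETRIC:
        shapiro = {}
        for name, v in arrays.items():
            if v.size >= 3 and np.ptp(v) > 0:
                sw = stats.shapiro(v)
                shapiro[name] = {"statistic": float(sw.statistic), "p_value": float(sw.pvalue)}
            else:
                shapiro[name] = {"statistic": float("nan"), "p_value": float("nan")}
    return GroupStatsRecord(
        comparison=comparison or design,
        design=design,
        groups=_summaries(arrays),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        shapiro=shapiro,
    )


# --- bundle I/O --------------------------------------------------------------


def read_bundle(bundle_dir: str | Path):
    """Read a session bundle written by the generator (or hand-assembled).

    Returns ``(units, trials, rf_maps)``; ``rf_maps`` is None when
    ``rf_maps.json`` is absent (it is optional).  Missing required files are
    reported together in one error.
    """
    d = Path(bundle_dir)
    required = ["units.tsv", "spikes.tsv", "trials.tsv"]
    missing = [f for f in required if not (d / f).exists()]
    if missing:
        raise FileNotFoundError(f"session bundle at {d} is missing: {', '.join(missing)}")
    units_df = pd.read_csv(d / "units.tsv", sep="\t", dtype={"unit_id": str})
    spikes_df = pd.read_csv(d / "spikes.tsv", sep="\t", dtype={"unit_id": str})
    trials_df = pd.read_csv(d / "trials.tsv", sep="\t")
    spikes_by_unit = {uid: g["spike_time_s"].to_numpy() for uid, g in spikes_df.groupby("unit_id")}
    units = []
    for row in units_df.itertuples(index=False):
        rf = None if pd.isna(row.rf_class) else int(row.rf_class)
        units.append(
            UnitRecord(
                unit_id=row.unit_id,
                cat_id=str(row.cat_id),
                cell_type=row.cell_type,
                rf_class=rf,
                # unique: duplicate timestamps can arise from the µs text precision
                spike_times=np.unique(spikes_by_unit.get(row.unit_id, np.empty(0))),
            )
        )
    trials = [
        TrialEvents(int(r.trial_id), r.door_open_s, r.paw_lift_s, r.tube_entry_s, r.paw_down_s)
        for r in trials_df.itertuples(index=False)
    ]
    rf_maps = None
    if (d / "rf_maps.json").exists():
        with open(d / "rf_maps.json", encoding="utf-8") as fh:
            records = json.load(fh)
        rf_maps = {}
        for rec in records:
            rf_maps.setdefault(rec["unit_id"], []).append(
                {"spike_type": rec["spike_type"], "regions": rec["regions"]}
            )
    return units, trials, rf_maps


def _rf_from_regions(regions: Sequence[Mapping[str, str]]) -> ReceptiveField:
    return ReceptiveField([(r["region"], r["intensity"]) for r in regions])


def _config_hash(config: Mapping) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# --- orchestration -----------------------------------------------------------


def run_all(
    bundle_dir: str | Path,
    out_dir: str | Path,
    spec: PethSpec | None = None,
    min_units_per_class: int = 4,
    n_perm: int = 1000,
    restarts: int = 50,
    seed: int = 0,
    fast_slow_min_trials: int = 60,
) -> dict:
    """Run the full analysis on a session bundle and write all outputs.

    Pipeline: trial filtering → per-unit z-profiles and modulation table →
    per-class population PETHs → cluster/ARI correspondence (skipped with a
    logged reason when fewer than two classes reach ``min_units_per_class``)
    → group comparisons (baseline rate / onset / peak latency by class,
    pooled distal {1,2,6} vs proximal {8,9,10} latencies, paired
    peak-vs-baseline for increasing and decreasing units, fast/slow quartile
    comparison for units with enough trials, CS/SS field overlap when maps
    are present).  Outputs are deterministic bytes for a fixed bundle, spec
    and seed; the manifest records every seed and a config hash.
    """
    spec = spec or PethSpec()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    units, trials, rf_maps = read_bundle(bundle_dir)
    kept, excluded = filter_trials(trials)
    logger.info(
        "trials: %d kept, %d excluded (%.1f%%)",
        len(kept),
        len(excluded),
        100.0 * len(excluded) / len(trials),
    )
    if not kept:
        raise ValueError("no trials survive the exclusion rules")

    profiles: list[ZProfile] = []
    mod_rows = []
    for u in units:
        zp = build_zprofile(u, kept, spec)
        profiles.append(zp)
        m = detect_modulation(zp, spec)
        mod_rows.append(
            {
                "unit_id": u.unit_id,
                "rf_class": "" if u.rf_class is None else u.rf_class,
                "cell_type": u.cell_type,
                "flagged": zp.flagged,
                "significant": m.significant,
                "direction": m.direction or "",
                "onset_ms": "" if m.onset_latency is None else f"{m.onset_latency:.1f}",
                "peak_ms": "" if m.peak_latency is None else f"{m.peak_latency:.1f}",
                "baseline_hz": f"{m.baseline_rate:.3f}",
                "peak_hz": "" if m.peak_rate is None else f"{m.peak_rate:.3f}",
            }
        )
    mod_df = pd.DataFrame(mod_rows)
    mod_df.to_csv(out / "unit_modulation.tsv", sep="\t", index=False)

    by_class: dict[int, list[ZProfile]] = {}
    for zp in profiles:
        if zp.rf_class is not None and not zp.flagged:
            by_class.setdefault(zp.rf_class, []).append(zp)
    pop = class_population_peth(by_class, spec)
    pop_rows = []
    for cid, zp in pop.items():
        for left, z in zip(zp.bin_lefts, zp.z):
            pop_rows.append({"class": cid, "bin_left_ms": f"{left:.1f}", "mean_z": f"{z:.6f}"})
    pd.DataFrame(pop_rows).to_csv(out / "class_peth.tsv", sep="\t", index=False)

    cluster_rep = None
    cluster_skip_reason = None
    try:
        cluster_rep = run_cluster_analysis(
            profiles,
            min_units_per_class=min_units_per_class,
            n_perm=n_perm,
            restarts=restarts,
            seed=seed,
        )
    except ValueError as err:
        cluster_skip_reason = str(err)
        logger.warning("cluster stage skipped: %s", cluster_skip_reason)
    if cluster_rep is not None:
        with open(out / "cluster_report.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(cluster_rep, fh, indent=1, sort_keys=True)
            fh.write("\n")
        conf = pd.DataFrame(
            cluster_rep["confusion_counts"],
            index=[f"cluster_{c}" for c in cluster_rep["cluster_ids"]],
            columns=[f"class_{c}" for c in cluster_rep["class_ids"]],
        )
        conf.to_csv(out / "confusion.tsv", sep="\t")

    # group comparisons
    stats_records: list[GroupStatsRecord] = []
    det = {zp.unit_id: detect_modulation(zp, spec) for zp in profiles if not zp.flagged}

    def _per_class(extract) -> dict[str, list[float]]:
        g: dict[str, list[float]] = {}
        for zp in profiles:
            if zp.flagged or zp.rf_class is None:
                continue
            v = extract(zp)
            if v is not None:
                g.setdefault(f"class_{zp.rf_class}", []).append(v)
        return {k: v for k, v in sorted(g.items()) if len(v) >= 2}

    def _maybe(rec_args):
        try:
            stats_records.append(group_compare(*rec_args[:-1], comparison=rec_args[-1]))
        except ValueError as err:
            logger.warning("comparison %s skipped: %s", rec_args[-1], err)

    base_by_class = _per_class(lambda zp: zp.baseline_mean)
    if len(base_by_class) >= 2:
        _maybe((base_by_class, "one_way_anova", "baseline_rate_by_class"))
    onset_by_class = _per_class(lambda zp: det[zp.unit_id].onset_latency)
    if len(onset_by_class) >= 2:
        _maybe((onset_by_class, "one_way_anova", "onset_latency_by_class"))
    peak_by_class = _per_class(lambda zp: det[zp.unit_id].peak_latency)
    if len(peak_by_class) >= 2:
        _maybe((peak_by_class, "one_way_anova", "peak_latency_by_class"))

    def _pooled(latency_attr: str) -> dict[str, list[float]] | None:
        pools: dict[str, list[float]] = {"distal": [], "proximal": []}
        for zp in profiles:
            if zp.flagged or zp.rf_class is None:
                continue
            v = getattr(det[zp.unit_id], latency_attr)
            if v is None:
                continue
            if zp.rf_class in DISTAL_CLASSES:
                pools["distal"].append(v)
            elif zp.rf_class in PROXIMAL_CLASSES:
                pools["proximal"].append(v)
        if min(len(v) for v in pools.values()) >= 2:
            return pools
        return None

    for attr, name in (("onset_latency", "onset"), ("peak_latency", "peak")):
        pools = _pooled(attr)
        if pools:
            _maybe((pools, "mann_whitney", f"distal_vs_proximal_{name}_latency"))

    for direction in ("increase", "decrease"):
        sel = [
            (m.baseline_rate, m.peak_rate)
            for m in det.values()
            if m.significant and m.direction == direction
        ]
        if len(sel) >= 2:
            base, peak = zip(*sel)
            _maybe(
                (
                    {"baseline": list(base), "peak": list(peak)},
                    "paired_t",
                    f"peak_vs_baseline_{direction}",
                )
            )

    fast_slow = []
    for u, zp in zip(units, profiles):
        if zp.flagged:
            continue
        try:
            fs = fast_slow_compare(u, trials, spec, min_trials=fast_slow_min_trials)
        except ValueError:
            continue
        fast_slow.append(fs)
    if len(fast_slow) >= 2:
        fast_base = [fs.fast.baseline_rate for fs in fast_slow]
        slow_base = [fs.slow.baseline_rate for fs in fast_slow]
        _maybe(({"fast": fast_base, "slow": slow_base}, "unpaired_t", "fast_vs_slow_baseline_rate"))
        peaks = [
            (fs.fast.peak_rate, fs.slow.peak_rate)
            for fs in fast_slow
            if fs.fast.peak_rate is not None and fs.slow.peak_rate is not None
        ]
        if len(peaks) >= 2:
            f, s = zip(*peaks)
            _maybe(({"fast": list(f), "slow": list(s)}, "unpaired_t", "fast_vs_slow_peak_rate"))

    overlap = None
    if rf_maps:
        pairs = []
        for uid, maps in sorted(rf_maps.items()):
            ss = [m for m in maps if m["spike_type"] == "ss"]
            cs = [m for m in maps if m["spike_type"] == "cs"]
            if ss and cs:
                pairs.append((_rf_from_regions(cs[0]["regions"]), _rf_from_regions(ss[0]["regions"])))
        if pairs:
            overlap = overlap_report(pairs).summary()

    with open(out / "group_stats.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump([asdict(r) for r in stats_records], fh, indent=1, sort_keys=True)
        fh.write("\n")

    manifest = {
        "package_version": __version__,
        "alpha": ALPHA,
        "multiple_testing_correction": "none (comparisons reported individually)",
        "seed": seed,
        "n_perm": n_perm,
        "restarts": restarts,
        "spec": asdict_spec(spec),
        "config_hash": _config_hash(asdict_spec(spec) | {"seed": seed, "n_perm": n_perm}),
        "n_units": len(units),
        "n_trials_input": len(trials),
        "n_trials_kept": len(kept),
        "n_trials_excluded": len(excluded),
        "exclusion_reasons": sorted(r for _, r in excluded),
        "cluster_skipped": cluster_skip_reason,
        "overlap": overlap,
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w", encoding="utf-8", newline="\n") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "manifest": manifest,
        "modulation": mod_df,
        "population": pop,
        "cluster": cluster_rep,
        "group_stats": stats_records,
        "fast_slow": fast_slow,
        "overlap": overlap,
    }


def asdict_spec(spec: PethSpec) -> dict:
    return {
        "align_event": spec.align_event,
        "window": list(spec.window),
        "bin_width": spec.bin_width,
        "kernel_sd": spec.kernel_sd,
        "baseline": list(spec.baseline),
        "z_threshold": spec.z_threshold,
        "min_run_bins": spec.min_run_bins,
        "peak_on_rate": spec.peak_on_rate,
    }
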