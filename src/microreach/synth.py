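"""Synthetic reach-session generator.

Emulates a single-unit recording session of the cat cerebellar C3 zone during
a reach-to-retrieve task: a sequence of trials with behavioural event markers
(door open → paw lift → tube entry → paw down), and per-unit spike trains from
an inhomogeneous Poisson process whose rate is a constant baseline plus
Gaussian-bump modulations anchored to trial events.  Class presets encode the
study conditions reported for the six receptive-field classes with four or
more units: printed baseline rates, printed between-unit onset-latency
statistics relative to paw lift, and multi-peak modulation for the distal
classes (1, 2, 6) versus single-peak for the proximal ones (8, 9, 10).

Times for events and spikes are seconds; profile parameters are milliseconds
and Hz.  Everything is reproducible from a single master seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import norm, truncnorm

from .rf_atlas import CLASS_TEMPLATES, REGION_ADJACENCY, ReceptiveField

__all__ = [
    "ClassProfile",
    "SessionConfig",
    "TrialEvents",
    "UnitRecord",
    "CELL_TYPES",
    "default_class_profiles",
    "class_determined_profiles",
    "simulate_session",
    "generate_rf_map",
    "simulate_cs_ss_pairs",
    "write_bundle",
]

CELL_TYPES = ("purkinje_simple", "purkinje_complex", "mossy_fibre", "interneuron")

#: Events a modulation bump may be anchored to.
ANCHOR_EVENTS = ("door_open", "paw_lift", "tube_entry", "paw_down")


@dataclass(frozen=True)
class ClassProfile:
    """Firing-rate profile of one receptive-field class.

    The primary modulation is a Gaussian bump of SD ``response_width / 2``
    anchored to paw lift; its 2-SD leading edge defines the injected onset.
    ``secondary_peaks`` are further bumps (anchor event, offset ms,
    amplitude Hz) of the same width; negative amplitudes model suppression.
    """

    class_id: int
    baseline_rate: float  # Hz
    onset_mean: float  # ms relative to paw lift
    onset_sd: float  # ms, between-unit spread
    amplitude: float = 50.0  # Hz, signed
    response_width: float = 100.0  # ms; bump SD = response_width / 2
    n_peaks: int = 1
    secondary_peaks: tuple[tuple[str, float, float], ...] = ()

    def __post_init__(self):
        if not 1 <= self.class_id <= 10:
            raise ValueError("class_id must be 1..10")
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be positive")
        if self.response_width <= 0:
            raise ValueError("response_width must be positive")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")
        if self.n_peaks != 1 + len(self.secondary_peaks):
            raise ValueError("n_peaks must equal 1 + len(secondary_peaks)")
        neg = min(0.0, self.amplitude) + sum(min(0.0, a) for _, _, a in self.secondary_peaks)
        if self.baseline_rate + neg < 0:
            raise ValueError("suppression deeper than baseline: rate would go negative")
        for anchor, _, _ in self.secondary_peaks:
            if anchor not in ANCHOR_EVENTS:
                raise ValueError(f"unknown anchor event: {anchor!r}")


@dataclass(frozen=True)
class SessionConfig:
    """Session-level simulation parameters.

    Defaults reproduce the study conditions: the six analysable classes at
    their reported unit counts, 40 trials per session, reach durations
    320 ± 131 ms and reaction times drawn so that only a small fraction
    falls below the 150 ms exclusion cut.
    """

    units_per_class: Mapping[int, int] = field(
        default_factory=lambda: {1: 8, 2: 4, 6: 5, 8: 7, 9: 10, 10: 4}
    )
    trials_per_unit: int = 40
    reach_duration_mean: float = 320.0  # ms
    reach_duration_sd: float = 131.0  # ms
    reaction_time_mean: float = 300.0  # ms
    reaction_time_sd: float = 80.0  # ms
    inter_trial_interval: float = 10.0  # s
    rng_seed: int = 0
    stratified_onsets: bool = True
    cs_maps: bool = True
    rf_jitter: float = 0.2

    def __post_init__(self):
        if not self.units_per_class:
            raise ValueError("units_per_class must be non-empty")
        for cid, n in self.units_per_class.items():
            if not 1 <= cid <= 10:
                raise ValueError(f"class id out of range: {cid}")
            if n < 1:
                raise ValueError("unit counts must be >= 1")
        if self.trials_per_unit < 1:
            raise ValueError("trials_per_unit must be >= 1")
        if self.reach_duration_mean <= 0:
            raise ValueError("reach_duration_mean must be positive")
        for name in ("reach_duration_sd", "reaction_time_mean", "reaction_time_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.inter_trial_interval <= 0:
            raise ValueError("inter_trial_interval must be positive")


@dataclass(frozen=True)
class TrialEvents:
    """Behavioural event timestamps of one trial (seconds, session clock)."""

    trial_id: int
    door_open: float
    paw_lift: float
    tube_entry: float
    paw_down: float

    def __post_init__(self):
        if not self.door_open < self.paw_lift < self.tube_entry < self.paw_down:
            raise ValueError(
                "events must be ordered door_open < paw_lift < tube_entry < paw_down"
            )

    def event_time(self, name: str) -> float:
        if name not in ANCHOR_EVENTS:
            raise ValueError(f"unknown event: {name!r}")
        return getattr(self, name)


@dataclass(frozen=True)
class UnitRecord:
    """One recorded unit: identity, cell type, class label, spike times (s)."""

    unit_id: str
    cat_id: str
    cell_type: str
    rf_class: int | None
    spike_times: np.ndarray

    def __post_init__(self):
        if self.cell_type not in CELL_TYPES:
            raise ValueError(f"cell_type must be one of {CELL_TYPES}")
        spikes = np.asarray(self.spike_times, dtype=float)
        if spikes.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if spikes.size > 1 and not np.all(np.diff(spikes) > 0):
            raise ValueError("spike_times must be strictly increasing")
        object.__setattr__(self, "spike_times", spikes)


# --- class presets -----------------------------------------------------------

# Printed per-class conditions: (baseline Hz, onset mean ms, onset SD ms).
_CLASS_STATS = {
    1: (32.4, -110.0, 63.0),
    2: (22.6, 0.0, 165.0),
    6: (37.6, -152.0, 83.0),
    8: (31.6, 41.0, 159.0),
    9: (33.9, -8.0, 180.0),
    10: (36.7, 180.0, 164.0),
}
_DISTAL_CLASSES = (1, 2, 6)
_PROXIMAL_CLASSES = (8, 9, 10)


def default_class_profiles() -> list[ClassProfile]:
    """Presets for the six classes with four or more recorded units.

    Baseline rates and onset statistics are the printed per-class values.
    Distal classes (1, 2, 6) carry a secondary bump anchored to tube entry,
    giving the multi-peak modulation typical of distal receptive fields;
    proximal classes (8, 9, 10) are single-peaked.
    """
    profiles = []
    for cid in sorted(_CLASS_STATS):
        base, mu, sd = _CLASS_STATS[cid]
        secondary = (("tube_entry", 0.0, 20.0),) if cid in _DISTAL_CLASSES else ()
        profiles.append(
            ClassProfile(
                class_id=cid,
                baseline_rate=base,
                onset_mean=mu,
                onset_sd=sd,
                n_peaks=1 + len(secondary),
                secondary_peaks=secondary,
            )
        )
    return profiles


def class_determined_profiles() -> list[ClassProfile]:
    """Default presets with zero between-unit onset spread.

    Every unit of a class then carries the class-mean onset, so activity
    profiles are fully determined by class (up to Poisson noise).  This is
    the configuration for testing cluster–class correspondence: with the
    printed between-unit spreads (SD up to 180 ms), onset distributions of
    different classes overlap and correspondence is not identifiable from a
    38-unit session by construction.
    """
    return [replace(p, onset_sd=0.0) for p in default_class_profiles()]


# --- trial and spike generation ---------------------------------------------


def _truncnorm_ms(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Truncated-normal draws (> 0), in ms."""
    if sd == 0:
        return np.full(size, mean)
    a = -mean / sd  # truncate at 0
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _generate_trials(config: SessionConfig, rng: np.random.Generator) -> list[TrialEvents]:
    n = config.trials_per_unit
    rts = _truncnorm_ms(rng, config.reaction_time_mean, config.reaction_time_sd, n) / 1000.0
    durs = _truncnorm_ms(rng, config.reach_duration_mean, config.reach_duration_sd, n) / 1000.0
    holds = _truncnorm_ms(rng, 500.0, 100.0, n) / 1000.0  # tube entry -> paw down
    trials = []
    for i in range(n):
        door = (i + 1) * config.inter_trial_interval
        lift = door + rts[i]
        entry = lift + durs[i]
        down = entry + holds[i]
        trials.append(TrialEvents(i, door, lift, entry, down))
    return trials


def _unit_onsets(profile: ClassProfile, n_units: int, config: SessionConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Per-unit true onsets (ms) for one class.

    Stratified mode places the units at midpoint quantiles of
    N(onset_mean, onset_sd), so a class of 4-10 units carries the reported
    between-unit mean and spread rather than a noisy i.i.d. realisation of it.
    """
    if config.stratified_onsets:
        q = (np.arange(n_units) + 0.5) / n_units
        onsets = profile.onset_mean + profile.onset_sd * norm.ppf(q)
        return rng.permutation(onsets)
    return rng.normal(profile.onset_mean, profile.onset_sd, size=n_units)


def _bump_centers_amps(profile: ClassProfile, onset_ms: float,
                       trials: Sequence[TrialEvents]) -> tuple[np.ndarray, np.ndarray]:
    """Centers (s, session clock) and amplitudes (Hz) of all modulation bumps."""
    sigma_ms = profile.response_width / 2.0
    centers, amps = [], []
    # primary bump: 2-SD leading edge at the unit's true onset, paw-lift anchored
    center_offset_s = (onset_ms + 2.0 * sigma_ms) / 1000.0
    for tr in trials:
        centers.append(tr.paw_lift + center_offset_s)
        amps.append(profile.amplitude)
        for anchor, offset_ms, amp in profile.secondary_peaks:
            centers.append(tr.event_time(anchor) + offset_ms / 1000.0)
            amps.append(amp)
    return np.asarray(centers), np.asarray(amps)


def _simulate_spikes(profile: ClassProfile, onset_ms: float, trials: Sequence[TrialEvents],
                     t_end: float, rng: np.random.Generator) -> np.ndarray:
    """Inhomogeneous-Poisson spike train by thinning at the rate ceiling."""
    sigma_s = profile.response_width / 2000.0
    centers, amps = _bump_centers_amps(profile, onset_ms, trials)
    lam_max = profile.baseline_rate + float(np.sum(amps[amps > 0])) if amps.size else profile.baseline_rate
    n_cand = rng.poisson(lam_max * t_end)
    t = np.sort(rng.uniform(0.0, t_end, size=n_cand))
    lam = np.full(t.shape, profile.baseline_rate)
    for c, a in zip(centers, amps):
        # bumps are narrow; only candidates within 5 SD contribute
        lo, hi = np.searchsorted(t, [c - 5 * sigma_s, c + 5 * sigma_s])
        if hi > lo:
            lam[lo:hi] += a * np.exp(-((t[lo:hi] - c) ** 2) / (2 * sigma_s**2))
    np.clip(lam, 0.0, None, out=lam)
    keep = rng.uniform(0.0, lam_max, size=t.shape) < lam
    spikes = t[keep]
    return np.unique(spikes)  # strictly increasing


def _cell_type_cycle(i: int) -> str:
    # roughly half Purkinje simple-spike units, the rest mossy fibres and
    # putative interneurons, as in the recorded sample
    cycle = ("purkinje_simple", "mossy_fibre", "purkinje_simple", "interneuron", "mossy_fibre")
    return cycle[i % len(cycle)]


def simulate_session(
    config: SessionConfig,
    profiles: Sequence[ClassProfile] | None = None,
) -> tuple[list[UnitRecord], list[TrialEvents], dict[str, list[dict]]]:
    """Simulate one session: trial events, unit spike trains and RF maps.

    Returns ``(units, trials, rf_maps)`` where ``rf_maps`` maps unit_id to a
    list of map records ``{"spike_type": "ss"|"cs", "regions": [...]}``.
    Every unit shares the session's trial sequence; each unit's true onset is
    drawn once and held fixed across trials.  Fully reproducible from
    ``config.rng_seed`` (per-unit child seeds are derived deterministically
    from the master seed, class id and within-class index).
    """
    if profiles is None:
        profiles = default_class_profiles()
    by_class = {p.class_id: p for p in profiles}
    missing = sorted(set(config.units_per_class) - set(by_class))
    if missing:
        raise ValueError(f"no ClassProfile provided for requested classes: {missing}")

    master = np.random.SeedSequence(config.rng_seed)
    trial_rng = np.random.default_rng(master.spawn(1)[0])
    trials = _generate_trials(config, trial_rng)
    t_end = trials[-1].paw_down + config.inter_trial_interval

    units: list[UnitRecord] = []
    rf_maps: dict[str, list[dict]] = {}
    unit_index = 0
    for cid in sorted(config.units_per_class):
        n_units = config.units_per_class[cid]
        profile = by_class[cid]
        class_seq = np.random.SeedSequence(config.rng_seed, spawn_key=(cid,))
        onset_rng = np.random.default_rng(class_seq)
        onsets = _unit_onsets(profile, n_units, config, onset_rng)
        for j in range(n_units):
            unit_seq = np.random.SeedSequence(config.rng_seed, spawn_key=(cid, j))
            rng = np.random.default_rng(unit_seq)
            spikes = _simulate_spikes(profile, float(onsets[j]), trials, t_end, rng)
            cell_type = _cell_type_cycle(unit_index)
            unit_id = f"u{unit_index:03d}_c{cid}"
            units.append(UnitRecord(unit_id, "cat01", cell_type, cid, spikes))
            maps = [
                {
                    "spike_type": "ss",
                    "regions": _rf_regions(
                        generate_rf_map(cid, config.rf_jitter, seed=(config.rng_seed, cid, j, 1))
                    ),
                }
            ]
            if config.cs_maps and cell_type == "purkinje_simple":
                # two thirds of dual-field Purkinje cells have concordant
                # complex-spike fields; the rest map to a different class
                concordant = rng.random() < 2.0 / 3.0
                cs_class = cid if concordant else _discordant_class(cid, rng)
                maps.append(
                    {
                        "spike_type": "cs",
                        "regions": _rf_regions(
                            generate_rf_map(cs_class, config.rf_jitter, seed=(config.rng_seed, cid, j, 2))
                        ),
                    }
                )
            rf_maps[unit_id] = maps
            unit_index += 1
    return units, trials, rf_maps


def _discordant_class(cid: int, rng: np.random.Generator) -> int:
    others = [c for c in sorted(CLASS_TEMPLATES) if c != cid]
    return int(others[rng.integers(len(others))])


def _rf_regions(rf: ReceptiveField) -> list[dict]:
    return [{"region": r, "intensity": i} for r, i in sorted(rf.regions)]


# --- receptive-field map generation -----------------------------------------


def generate_rf_map(class_id: int, jitter: float = 0.0, seed=0) -> ReceptiveField:
    """A receptive-field map for a class, with jittered borders.

    Starts from the class template (core regions strong, the rest of the full
    extent weak).  With probability ``jitter`` each non-core template region
    is dropped, and with probability ``jitter / 2`` each anatomically
    adjacent outside region is added (weak).  ``jitter = 0`` returns the
    template exactly; the core is never removed, so the map stays non-empty
    and classifies back to its own class at moderate jitter.
    """
    if class_id not in CLASS_TEMPLATES:
        raise ValueError(f"unknown receptive-field class: {class_id}")
    if not 0.0 <= jitter <= 1.0:
        raise ValueError("jitter must be in [0, 1]")
    template = CLASS_TEMPLATES[class_id]
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    kept = set(template.core_regions)
    for r in sorted(template.full_regions - template.core_regions):
        if rng.random() >= jitter:
            kept.add(r)
    border = sorted(
        {n for r in template.full_regions for n in REGION_ADJACENCY[r]} - template.full_regions
    )
    added = {r for r in border if rng.random() < jitter / 2.0}
    return ReceptiveField(
        [(r, "strong") for r in sorted(template.core_regions)]
        + [(r, "weak") for r in sorted((kept - template.core_regions) | added)]
    )


def simulate_cs_ss_pairs(
    n_concordant: int,
    n_discordant: int,
    jitter: float = 0.35,
    seed: int = 0,
) -> list[tuple[ReceptiveField, ReceptiveField]]:
    """Synthetic (complex-spike, simple-spike) field pairs for overlap analysis.

    Concordant pairs are two jittered maps of one class; discordant pairs take
    the two fields from well-separated classes (distal vs. proximal), giving
    the high-versus-near-zero overlap split seen in dual-field Purkinje cells.
    """
    rng = np.random.default_rng(seed)
    pairs = []
    classes = sorted(CLASS_TEMPLATES)
    for i in range(n_concordant):
        cid = classes[rng.integers(len(classes))]
        pairs.append(
            (
                generate_rf_map(cid, jitter, seed=(seed, i, 0)),
                generate_rf_map(cid, jitter, seed=(seed, i, 1)),
            )
        )
    for i in range(n_discordant):
        cs, ss = (1, 10) if i % 2 == 0 else (2, 8)
        pairs.append(
            (
                generate_rf_map(cs, jitter, seed=(seed, n_concordant + i, 0)),
                generate_rf_map(ss, jitter, seed=(seed, n_concordant + i, 1)),
            )
        )
    return pairs


# --- session bundle I/O ------------------------------------------------------


def write_bundle(
    out_dir: str | Path,
    units: Sequence[UnitRecord],
    trials: Sequence[TrialEvents],
    rf_maps: Mapping[str, list[dict]] | None = None,
) -> None:
    """Write the standard session bundle.

    ``units.tsv``, ``spikes.tsv``, ``trials.tsv`` (tab-separated, header row,
    times in seconds) and ``rf_maps.json``.  Output bytes depend only on the
    data, so identical sessions serialize identically.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "units.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("unit_id\tcat_id\tcell_type\trf_class\n")
        for u in units:
            rf = "" if u.rf_class is None else str(u.rf_class)
            fh.write(f"{u.unit_id}\t{u.cat_id}\t{u.cell_type}\t{rf}\n")
    with open(out / "spikes.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("unit_id\tspike_time_s\n")
        for u in units:
            for t in u.spike_times:
                fh.write(f"{u.unit_id}\t{t:.6f}\n")
    with open(out / "trials.tsv", "w", encoding="utf-8", newline="\n") as fh:
        fh.write("trial_id\tdoor_open_s\tpaw_lift_s\ttube_entry_s\tpaw_down_s\n")
        for tr in trials:
            fh.write(
                f"{tr.trial_id}\t{tr.door_open:.6f}\t{tr.paw_lift:.6f}"
                f"\t{tr.tube_entry:.6f}\t{tr.paw_down:.6f}\n"
            )
    if rf_maps is not None:
        records = [
            {"unit_id": uid, "spike_type": m["spike_type"], "regions": m["regions"]}
            for uid in sorted(rf_maps)
            for m in rf_maps[uid]
        ]
        with open(out / "rf_maps.json", "w", encoding="utf-8", newline="\n") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)
            fh.write("\n")
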