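# microreach

Spike-train analysis of cerebellar C3-zone microzone activity during skilled
reaching.

Single units in the C3 zone of the cat cerebellar cortex (Purkinje cells,
mossy fibres and cortical interneurons) carry cutaneous receptive fields that
fall into ten canonical forelimb classes, from the digits (class 1) to the
medial shoulder and upper arm (class 10).  During a reach-to-retrieve task,
units belonging to the same receptive-field class modulate their firing with
similar timing relative to paw lift-off — distal classes before the lift,
proximal classes after it.  `microreach` implements the full analysis chain
used to establish that correspondence, plus a synthetic session generator so
every stage is testable without the recorded data:

- **Trial filtering** — exclude reaches with reaction time < 150 ms to the
  door opening, or reach duration (paw lift → tube entry) deviating more than
  2.5 SD from the session mean.
- **PETH / z-score latency analysis** — 10 ms-bin peri-event histograms
  aligned to paw lift, smoothed with a 10 ms Gaussian kernel, z-scored
  against the −1000..−500 ms baseline, with modulation onset at the leading
  edge of the first sustained crossing of ±2 baseline SDs and peak latency at
  the maximal |z|.
- **Receptive-field atlas** — class templates on a 15-region forelimb
  lattice, area-weighted Jaccard classification, and overlap between two
  fields (e.g. complex-spike vs simple-spike fields of one Purkinje cell) as
  100·|A∩B|/|A∪B| of their total extents.
- **Cluster–class correspondence** — each unit's z-PETH as a vector, PCA to
  3 components, k-means with k = number of analysable classes (≥ 4 units),
  a confusion matrix with a diagonal-maximising cluster→class matching, the
  Adjusted Rand Index

  ARI = (Σᵢⱼ C(nᵢⱼ,2) − E) / (½[Σᵢ C(aᵢ,2) + Σⱼ C(bⱼ,2)] − E),
  E = Σᵢ C(aᵢ,2)·Σⱼ C(bⱼ,2)/C(n,2),

  and its permutation significance: the percentile of the observed ARI among
  1000 ARIs recomputed under random reassignment of class labels (class
  sizes preserved); > 95% indicates a non-chance correspondence.
- **Synthetic sessions** — inhomogeneous-Poisson spike trains (thinning)
  whose rate is a class baseline plus Gaussian-bump modulations anchored to
  trial events; class presets encode the reported per-class baseline rates
  and onset-latency statistics, reach durations 320 ± 131 ms, multi-peak
  modulation for distal classes.

## Worked example

```python
import numpy as np
import microreach as mr

cfg = mr.SessionConfig(rng_seed=1)          # 6 classes × printed unit counts, 40 trials
units, trials, rf_maps = mr.simulate_session(cfg, mr.default_class_profiles())
kept, excluded = mr.filter_trials(trials)

spec = mr.PethSpec()                        # 10 ms bins, ±2 SD, −1000..−500 ms baseline
onsets = {}
for u in units:
    zp = mr.build_zprofile(u, kept, spec)
    m = mr.detect_modulation(zp, spec)
    if m.significant:
        onsets.setdefault(u.rf_class, []).append(m.onset_latency)
for cid in sorted(onsets):
    print(f"class {cid:>2}: n={len(onsets[cid])}  mean onset {np.mean(onsets[cid]):+6.1f} ms")
```

```
class  1: n=8  mean onset -112.5 ms
class  2: n=4  mean onset   -7.5 ms
class  6: n=5  mean onset -144.0 ms
class  8: n=7  mean onset  +42.9 ms
class  9: n=10  mean onset   -2.0 ms
class 10: n=4  mean onset +182.5 ms
```

The estimated class means recover the injected (reported) onset statistics:
distal classes 1 and 6 modulate ~110–150 ms before paw lift, classes 2 and 9
around lift-off, proximal classes 8 and 10 after it.  Clustering a session
whose profiles are fully determined by class then ties activity pattern to
receptive-field identity:

```python
units, trials, _ = mr.simulate_session(cfg, mr.class_determined_profiles())
kept, _ = mr.filter_trials(trials)
profiles = [mr.build_zprofile(u, kept, spec) for u in units]
rep = mr.run_cluster_analysis(profiles, n_perm=1000, restarts=50, seed=1)
print(f"k={rep['k']}  ARI={rep['ari']:.3f}  percentile={rep['percentile']:.1f}%  "
      f"diagonal {rep['diagonal_count']}/{rep['n_units']}")
```

```
k=6  ARI=0.824  percentile=100.0%  diagonal 35/38
```

35 of 38 units land in the cluster matched to their receptive-field class,
and the observed ARI exceeds all 1000 label-shuffled ARIs (percentile 100%,
i.e. far beyond the 95% significance bar).

## Command line

```
microreach simulate --config config.yaml --seed 1 --out session/
microreach analyze  --in session/ --align paw_lift --out results/
microreach cluster  --in session/ --min-class-size 4 [--purkinje-only] --seed 1 --out results/
microreach run      --in session/ --config peth.yaml --seed 1 --out results/
```

`simulate` writes the session bundle (`units.tsv`, `spikes.tsv`,
`trials.tsv`, `rf_maps.json`); `run` produces the modulation table
(`unit_modulation.tsv`), per-class population PETHs (`class_peth.tsv`), the
cluster report (`cluster_report.json`, `confusion.tsv`), group statistics
(`group_stats.json`) and a run manifest with all seeds and a config hash.

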