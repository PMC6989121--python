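# ninsync

Analysis pipeline for dual-region miniature-microscope (miniscope)
recordings in freely moving mice: cross-region **synchronous pattern (SP)
detection** from calcium-event onsets, **SP-triggered behavioral
acceleration** classification from a head-mounted IMU, **rearing and turn
parsing** from individual accelerometer channels, and **optogenetic
stimulus-response classification** — together with a fully ground-truthed
synthetic session generator so every stage can be validated without in
vivo data.

The intended user images two brain regions at once (e.g. cerebellar
Purkinje cell dendrites and motor cortex) at 30 frames/s, logs a 3-axis
accelerometer at 104 Hz, and has already extracted per-cell fluorescence
traces upstream (motion correction + source extraction). This package
takes it from there.

## The core quantities

**Kernel-sum synchrony.** Per-cell event onset times $\{t_{ij}\}$ are
detected at sub-frame resolution by matched filtering. Each onset is
convolved with a unit-peak Epanechnikov kernel of half-width $h$ (default
0.1 s) and summed over all cells:

$$S(t) = \sum_i \sum_j \max\!\Big(0,\; 1 - \big(\tfrac{t - t_{ij}}{h}\big)^2\Big).$$

Intervals where $S(t) > \mu_S + 2\sigma_S$ are **global synchronous
events**. Two cells that both fire inside the same synchronous event
co-fire once; pairs co-firing **at least 5 times** are synchronous pairs
(SPs), labeled within-region or across-region and assembled into a
degree-sorted arc-diagram graph.

**Behavioral coupling.** From the compound acceleration
$a_{xyz} = \sqrt{x^2+y^2+z^2}$, each SP is classified by where the
acceleration first exceeds a baseline mean+2σ threshold: *pre*, *post*,
*around* (±150 ms), or *no change*; a random-trigger control compares
SP-triggered against randomly triggered threshold crossings.

**Stimulus responses.** Cells are *responders* if the trial-averaged
post-stimulus signal exceeds the pre-stimulus baseline mean+2σ, with
onset latency from a 4-parameter logistic fit (crossing of mean+1σ); a
paired t-test of per-trial mean activity pre vs during stimulation splits
cells into *decreased / unchanged / increased*, with per-cluster calcium
event rates.

## Worked example

```sh
python examples/02_detect_sps.py
```

```
kernel sum: mean 1.95, sd 1.53, threshold 5.01
global synchronous events: 72 (planted: 37)
SP pairs (co-fired >= 5x): 87 of 507 co-firing pairs
  within-region: {'CBL': 26, 'CTX': 15}, across-region: 46
participation (fraction of cells with >= 1 across-SP): {'CBL': 0.55, 'CTX': 0.3}
highest-degree cell: CBL_001 (17 SP partners, radius 2.00)
```

A 5-minute simulated session (20 cerebellar + 20 cortical cells, a
12-cell ensemble planted across both regions) yields 72 supra-threshold
intervals of the kernel sum. The 46 across-region SP pairs are cell pairs
— one per region — that repeatedly fired inside the same synchronous
event; the "participation" line is the fraction of each region's cells
with at least one across-region SP partner, and node radii in the
arc-diagram layout scale with SP partner count.

The other examples cover session simulation (`01`), SP-triggered
acceleration and rearing (`03`), stimulus-response classification (`04`),
and the end-to-end pipeline with its JSON report (`05`). Each prints the
numbers it computes and a line on what they mean.

## Layout

```
src/ninsync/
  io.py        CSV session artifacts, IMU count->g conversion, stream alignment
  synth.py     synthetic session generator with ground truth
  events.py    onset detection, event rates, half-decay times, Z-scoring
  sync.py      kernel sum, synchronous events, SP graph, scope labels
  behavior.py  compound acceleration, SP-trigger classes, rearing, turns
  stim.py      trial tensor, responders, sigmoid onsets, modulation classes
  graph.py     arc-diagram layout, GraphML / edge-list export
  pipeline.py  config-driven end-to-end runs with a JSON report
```

`docs/methods.md` documents the models, parameter choices and known
limitations.

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch on a
default synthetic session (simulate → detect onsets → SPs → behavior →
stimulus response → report):

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The seed controls every source of randomness; identical seeds reproduce
identical runs.
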