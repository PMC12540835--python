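# congresskit

Quantification of **chromosome congression** from tracked spindle-pole and
kinetochore trajectories, with a ground-truth synthetic-data generator.

During early mitosis, chromosomes positioned near the spindle poles ("polar"
chromosomes) must be carried to the spindle equator — the metaphase plate —
before anaphase can begin safely. Live-cell experiments that perturb the
kinetochore motor CENP-E produce time-lapse trajectories of the two spindle
poles and of sister-kinetochore pairs; turning those trajectories into
biology requires a reproducible chain of geometry, event detection and
statistics. `congresskit` implements that chain for cell biologists who
track poles and kinetochores (positions in µm, time in minutes) and want
per-pair congression events, per-cell summaries and the associated group
statistics without hand-tuned spreadsheets.

## The quantities

With pole positions **a**, **b** per frame, the spindle frame is the
midpoint **m** = (**a**+**b**)/2 and unit axis **û** = (**b**−**a**)/‖**b**−**a**‖;
the equatorial plane passes through **m** perpendicular to **û**. For a
sister pair with center **c**:

- distance to the plane `d_plane = |(c − m)·û|`, distance to the nearest
  pole `d_pole = min(‖c−a‖, ‖c−b‖)`, interkinetochore distance
  `d_KT = ‖p₁−p₂‖`, and two acute angles (pair-center-to-pole line vs
  spindle axis; sister axis vs spindle axis);
- a pair is **polar** when `d_pole < d_plane`, **aligned-ever** when
  `d_plane ≤ 3 µm` on any frame;
- the **plate crossing** is the first frame with `d_plane < 2 µm`, and the
  **congression velocity** is
  `v = (d_plane(t_c − w) − d_plane(t_c)) / w` over the `w = 6 min`
  (4 min U2OS preset) window before the crossing, positive toward the plate;
- **alignment success** means an initially polar pair reaches `d_plane ≤ 2 µm`
  within 30 min of the reference event; polar pairs are counted at 12 min
  after mitosis onset and every 6 min thereafter; cells are categorised as
  tight / low (1–4 outside) / high (≥5 outside) misalignment or no plate.

Fluorescence is quantified on sum projections: integrated spot intensity
minus cytoplasmic background × area, divided by the number of z-planes, then
normalised to the CENP-A reference channel and, when requested, to the
aligned-group mean within each cell. The statistical battery is one-way
ANOVA + two-sided Tukey HSD, pooled two-proportion z-tests with a chi-square
test of independence, OLS with a two-tailed slope t-test, and mean ± s.d.
with 95% confidence intervals of both.

The synthetic module generates all of the above with known ground truth:
exponential initiation times (condition-specific rate λ), a biphasic
slow-then-fast approach to the plate, a logistic interkinetochore-distance
rise, Mad2-like intensity decay that begins *before* fast movement, a latent
correlation between per-pair speed and Mad2 decay, and pixel-integrated 3D
Gaussian image stacks.

## Worked example

```python
from congresskit.synthetic import SimulationConfig, simulate_experiment
from congresskit.cli import run_analyze, run_stats, PipelineConfig, loss_speed_table

cfg = SimulationConfig(n_cells=3, pairs_per_cell=8, master_seed=1)
tracks, truth, mad2 = simulate_experiment(cfg)
res = run_analyze(tracks, PipelineConfig())
loss = loss_speed_table(res["pair_kinematics"], mad2)
report, text = run_stats(res["events"], res["summary"], loss)
print(text)
```

prints

```
Congression velocity ANOVA: F=7.509, p=0.0114
  Tukey inhibited vs reactivated: dmean=-0.165 um/min, p_adj=0.0114
30-min success inhibited (5/18) vs reactivated (17/18): z=-4.103, p=4.09e-05
Success chi-square: chi2=16.831, df=1, p=4.09e-05
Speed vs Mad2 loss OLS: slope=0.114 um/min per unit loss, R2=0.757, p=9.58e-16 (n=48)
```

The two simulated conditions share the same fast-phase velocity but differ
10-fold in initiation rate, so the success proportions separate decisively
(17/18 vs 5/18 initially polar pairs aligned within 30 min, z = −4.1) while
velocity differences are modest and window-driven. The positive OLS slope
recovers the programmed coupling between Mad2 loss and plate-approach speed.
`res["summary"]` carries the per-cell view — e.g. `reactivated_c0` aligned
100% of its 6 polar pairs and shows a tight plate, while `inhibited_c0`
aligned 17% with low misalignment and a 6.8 µm maximum chromosome spread.

The same pipeline is available from a shell:

```bash
congresskit simulate --out sim --seed 1
congresskit analyze --tracks sim/tracks.csv --out analysis
congresskit stats --events analysis/events.csv --summary analysis/summary.csv --out report
```

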