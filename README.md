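# epsigraph

Network analysis of time series via **ε-regular graphs**, with an
application to early warning of ventricular tachyarrhythmia (VT) from
R-R interval (heart-beat interval) recordings.

The ε-regular graph is a quantitative time-series-to-network transform:
every sample *p<sub>i</sub>* of a series becomes a vertex, and two
vertices are joined iff

&nbsp;&nbsp;&nbsp;&nbsp;|*p<sub>i</sub>* − *p<sub>j</sub>*| ≤ ε

for a fixed threshold ε ≥ 0 in the units of the data.  Unlike the
(qualitative, shape-based) natural visibility graph, adjacency depends
only on sample *values*: equal or near-equal values always form complete
subgraphs, and a genuine outlier is exiled to its own connected
component rather than becoming a hub.  Varying ε spans a graph family
from edgeless (ε = 0, distinct values) to complete (ε ≥ range), and the
mean graph degree inside a sliding window becomes a time-resolved
measure of how tightly the signal's values cluster.

The package provides, as a library plus a thin `epsigraph` command-line
tool:

- **`epsigraph.core`** — ε-regular graph construction with O(n log n)
  degree/component/completeness queries (no edge materialization needed),
  edge-list/GraphML export;
- **`epsigraph.visibility`** — natural visibility graphs (strict
  line-of-sight convention), the qualitative comparator;
- **`epsigraph.dfa`** — first-order detrended fluctuation analysis with
  a two-regime log-log slope fit split at box size 15, the linear-method
  baseline for heart-rate variability;
- **`epsigraph.pipeline`** — the VT early-warning analysis: crop paired
  pre-event (VT) and control (CR) records to their last 985 samples,
  slide 60-sample windows (stride 1), compute mean graph degree per
  window at ε = 0.04 s, average per group, subtract CR from VT per
  subject pair, and detect the warning as the difference-curve global
  minimum followed by the first local maximum; the lead time is the sum
  of R-R intervals from the warning window to the event onset;
- **`epsigraph.io_rr`** — plain-text RR files and CSV cohort manifests;
- **`epsigraph.simulate`** — seeded generators: standard-normal series,
  Brownian motion, and synthetic paired RR cohorts with a transient
  pre-event dynamics change for download-free testing.

## Worked example

A 10-point series with three repeated levels and three high outliers, at
ε = 0.1 (`examples/01_epsilon_graph_basics.py`):

```python
import epsigraph as eg

series = [0.2, 0.29, 0.7, 0.29, 0.38, 0.7, 0.2, 0.38, 0.7, 0.2]
g = eg.build_epsilon_graph(series, epsilon=0.1)
```

prints

```
vertices: 10, edges: 18, mean degree: 3.6
raw degrees:        [4, 6, 2, 6, 3, 2, 4, 3, 2, 4]
components: [[0, 1, 3, 4, 6, 7, 9], [2, 5, 8]]
the three 0.7 points form a complete subgraph: True
```

The 0.2/0.29/0.38 levels chain together into one 7-vertex component
(consecutive levels differ by ≤ 0.1) while the 0.7 outliers form their
own complete component — the outlier-isolating behaviour that makes the
transform useful for detecting regime changes in value distributions.

The full early-warning pipeline on a synthetic 81-pair cohort with a
transient dynamics change injected at sample 300
(`examples/05_early_warning_pipeline.py`):

```
windows analyzed per record: 926 (985 samples, w=60, stride 1)
difference-curve global minimum: -23.76 at window 300
following local maximum:         16.56 at window 361
mean lead time before the event: 548.8 s (9.1 min)
injected change was at sample 300 -> detection error 0 windows
```

The minimum marks the window of turbulent (high-variance) rhythm, where
scattered values have few ε-neighbours; the following maximum marks
abnormally regular rhythm, where tightly packed values inflate the
degree above the control records.  `examples/06_epsilon_sweep.py` shows
the detected window is stable across ε ∈ [0.01, 0.06].

## Command line

```bash
epsigraph graph series.rr -e 0.1 --out-edges edges.tsv     # one graph
epsigraph simulate --out-dir cohort --seed 42              # synthetic cohort
epsigraph analyze cohort/manifest.csv --out-dir results    # early-warning report
epsigraph sweep cohort/manifest.csv --epsilons 0.02,0.04   # ε sensitivity
epsigraph dfa series.rr --crossover 15                     # scaling exponents
```

`analyze` writes `curves.tsv` (per-window group means and the VT−CR
difference) and `report.json` (warning windows, values, per-subject and
mean lead times).

## Analyzing the clinical cohorts

The package reads plain-text RR files only.  To reproduce the clinical
analysis, download the Spontaneous Ventricular Tachyarrhythmia Database
(v1.0) and, for healthy subjects, the MIT-BIH Normal Sinus Rhythm
Database from PhysioNet, convert each record to text RR intervals in
seconds (e.g. `ann2rr -r <record> -a <annotator> -i s`, one interval per
line), place the files under `data/mvtdb-rr/` with a `manifest.csv`
(columns `subject_id,group,path,units`; group `VT`, `CR` or `HS`), and
run `epsigraph analyze data/mvtdb-rr/manifest.csv`.  When that directory
is present, the test suite additionally checks the cohort's headline
numbers (difference-curve minimum −2.12 at window 276, local maximum
5.59 at window 393, mean lead time 514.625 s ≈ 8:30 min, and the
long-scale DFA slopes of the group curves).

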