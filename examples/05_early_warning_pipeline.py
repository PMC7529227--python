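"""The full early-warning analysis on a synthetic paired RR cohort.

81 pre-event (VT) / control (CR) record pairs of 985 R-R intervals are
generated; each VT record carries a transient dynamics change starting at
sample 300 — one window of tripled variability followed by abnormally
regular rhythm.  The pipeline slides 60-sample windows (stride 1) over
each record, computes the mean epsilon-graph degree per window at
eps = 0.04 s, averages within groups, subtracts CR from VT per pair, and
locates the warning: the difference-curve global minimum and the local
maximum that follows.  The lead time sums the remaining R-R intervals
from the warning window to the event onset at the final sample.
"""

import epsigraph as eg

spec = eg.CohortSpec(
    n_pairs=81, length=985,
    change_index=300, change_sd_scale=3.0, change_duration=60, post_sd_scale=0.5,
    seed=42,
)
records = eg.gen_rr_cohort(spec)
curves, report = eg.analyze_cohort(records, eg.AnalysisConfig(seed=42))

print(f"windows analyzed per record: {len(curves.diff)} (985 samples, w=60, stride 1)")
print(f"difference-curve global minimum: {report.min_value:.2f} at window {report.min_index}")
print(f"following local maximum:         {report.max_value:.2f} at window {report.max_index}")
print(f"mean lead time before the event: {report.mean_lead_seconds:.1f} s "
      f"({report.mean_lead_seconds / 60:.1f} min)")
print(f"injected change was at sample 300 -> detection error "
      f"{abs(report.min_index - 300)} windows")

# The minimum marks the window fully inside the turbulent burst (degree
# collapses because widely scattered values have few eps-neighbours); the
# maximum marks the stabilized phase (abnormally regular rhythm packs
# values within eps, inflating degree above the control records).
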