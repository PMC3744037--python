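"""Compare the two collecting vessels across animals.

One of the two rat-tail collecting vessels ("dominant") shows fluorescence
first and pumps harder.  This script quantifies several simulated animals
and runs the paired, two-tail Bonferroni-corrected comparison between the
dominant and non-dominant vessel per metric and segment.
"""

import lymphnir as ln
from lymphnir.synth import session_rois

sessions = []
for i in range(4):
    cfg = ln.preset("healthy", seed=40 + i, duration_s=720)
    stack, _ = ln.simulate_video(cfg)
    sessions.append(ln.analyze_session(stack, session_rois(cfg),
                                       animal_id=f"rat{i:02d}"))

table = ln.compile_timecourse(sessions)
for r in ln.compare_design(table, "vessel_paired"):
    star = "*" if r.significant else " "
    print(f"{star} {r.comparison:55s} t={r.t_statistic:6.2f} "
          f"p_adj={r.p_adjusted:.4f} (m={r.m_comparisons})")

print("\n'*' marks comparisons significant at alpha=0.05 after Bonferroni")
print("correction across the metric-segment family; the dominant vessel")
print("shows shorter transport times and higher frequencies/velocities.")
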