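"""Week-0 vs week-1 follow-up: functional deficits and node enlargement.

Simulates four animals at baseline and one week after tracer injection
(function degraded in both vessels), fixes dominance labels from week 0,
and runs the paired one-tail timecourse tests plus node morphometry.
"""

import lymphnir as ln
from lymphnir.synth import session_rois

sessions, nodes = [], []
for i in range(4):
    wk0 = wk1 = None
    for week, name in ((0, "healthy"), (1, "icg_week1")):
        cfg = ln.preset(name, seed=1000 * week + i, duration_s=720)
        stack, _ = ln.simulate_video(cfg)
        res = ln.analyze_session(stack, session_rois(cfg), week0_result=wk0,
                                 animal_id=f"rat{i:02d}", week=week, group="icg")
        if week == 0:
            wk0 = res
        sessions.append(res)

node_cfg = ln.SimConfig(seed=5)
for week in (0, 1):
    img, _ = ln.simulate_node_image(week, "icg", node_cfg)
    area = ln.node_area(img, node_cfg.node_pixel_size_mm)
    nodes.append(ln.NodeMeasurement(f"rat00", week, "icg", area))

table = ln.compile_timecourse(sessions, nodes)
print("paired one-tail tests, week 1 vs week 0 (functional-loss direction):")
for r in ln.compare_design(table[table["vessel"] != "node"], "timecourse_one_tail"):
    star = "*" if r.significant else " "
    print(f"{star} {r.comparison:58s} p={r.p_raw:.4f}")

a0, a1 = (n.area_mm2 for n in nodes)
print(f"\nsciatic node area: week 0 {a0:.2f} mm2 -> week 1 {a1:.2f} mm2 "
      f"({ln.percent_change(a0, a1):+.0f}%)")
print("\nEvery metric degrades significantly one week after injection, and")
print("the draining node enlarges several-fold — the tracer itself perturbs")
print("the lymphatic function it is used to measure.")
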