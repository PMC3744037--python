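"""Track tracer retention at the injection site over four weeks.

Indocyanine green stays in the tissue space for weeks after an intradermal
injection.  The retention series images the injection site every 2 days;
the tracer counts as visible while its SNR exceeds 3 dB.
"""

import lymphnir as ln
from lymphnir.synth import SimConfig, retention_rois

cfg = SimConfig(seed=3)
series, truth = ln.simulate_retention_series(cfg)
inj, bg = retention_rois(cfg)
points, last_day = ln.retention_curve(series, inj, bg)

print("day   SNR (dB)  visible")
for p in points:
    print(f"{p.day:3d}   {p.snr_db:7.2f}  {'yes' if p.visible else 'no'}")
print(f"\nlast visible day: {last_day}")
print(f"analytic 3 dB crossing of the configured decay: "
      f"day {truth.retention_crossing_day:.1f}")
print("\nThe tracer remains visible for more than two weeks — repeat")
print("injections inside this window measure a perturbed lymphatic system.")
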