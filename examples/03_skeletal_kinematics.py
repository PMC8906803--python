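"""Gape, hyoid depression, opercula abduction — and their peak ordering.

During the intake the head expands as an anterior-to-posterior wave: peak
gape first, then peak hyoid depression, then peak opercula abduction.
During reverse flow the wave (and hence the peak order) inverts. This
script computes the three traces from jaw/hyoid/operculum locators in the
anatomical frame and classifies the peak order per phase.
"""

import oroflow as of

world = of.generate_feeding_sequence(of.CARP, n_cycles=2, seed=7)
anat, _, phases = of.analyze_world(world)

approach = phases.of_label("approach")[0]
rest_window = (approach.start_time, approach.end_time)  # pre-strike posture
traces = [
    of.gape_trace(anat.points["upper_jaw"], anat.points["lower_jaw"], anat.frame_rate),
    of.hyoid_depression_trace(anat.points["hyoid"], anat.frame_rate, rest_window),
    of.opercula_abduction_trace(anat.points["operculum"], anat.frame_rate, rest_window),
]

for phase in ("intake", "rf"):
    out = of.peak_sequence(traces, phases, phase)
    order = " -> ".join(f"{var} @ {t:.3f}s" for var, t in out["order"])
    print(f"{phase}: {order}")
    print(f"   classified: {out['label']}")

print("\n'intake_like' = gape, hyoid, opercula (expansion wave travelling")
print("backward); 'rf_like' is the inverted wave that pushes water forward.")
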