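"""Segment a suction-feeding sequence into phases from water-tracer motion.

Generates a carp-like synthetic recording (15 water tracers, one food
tracer, bone markers, 750 frames/s), expresses everything in the
cranium-bound anatomical frame, and segments the sequence by the mean
anteroposterior water velocity: approach, intake, stasis, and alternating
reverse-flow (rf) / backflow (bf) handling phases.
"""

import oroflow as of

world = of.generate_feeding_sequence(of.CARP, n_cycles=3, seed=42)
anat, velocity, phases = of.analyze_world(world)

print(f"{'phase':<9} {'start (s)':>9} {'end (s)':>9} {'peak v (cm/s)':>14}")
for iv in phases:
    print(f"{iv.label:<9} {iv.start_time:9.3f} {iv.end_time:9.3f} "
          f"{iv.peak_ap_velocity:14.1f}")

intake = phases.intake()
period = of.transition_periodicity(phases)
print(f"\nintake duration: {intake.end_time - intake.start_time:.3f} s "
      f"(peak {intake.peak_ap_velocity:.1f} cm/s, posterior flow is negative)")
print(f"rf/bf periodicity: {period['mean']:.3f} +/- {period['sd']:.3f} s "
      f"over {period['n']} reversals")
print("\nNegative peaks mark posterior (intake-like) flow; positive peaks mark")
print("anterior reverse flow. The periodicity is the rhythm of intraoral food")
print("handling (published: 0.58 +/- 0.12 s in carp).")
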