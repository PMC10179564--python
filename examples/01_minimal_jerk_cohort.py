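"""Simulate a small reach-lift cohort and write it to disk as TRC + manifest.

The generator produces four-marker upper-limb recordings whose point-to-
point segments follow the minimal-jerk law (bell-shaped velocity, zero
endpoint velocity), with still rest frames framing the lift so that the
crop stage has work to do.
"""

import numpy as np

import reachkin as rk

cfg = rk.SimulationConfig(n_stroke_participants=3, n_control_participants=2,
                          recordings_per_limb=2, seed=7)
recordings, manifest = rk.simulate_cohort(cfg)
manifest_out = rk.write_cohort(recordings, "scratch_cohort", format="trc")

print("recordings per class:", rk.class_counts(manifest))
rec = recordings[0]
fnz = rec.axis("FN", "z")
print(f"first recording: {rec.recording_id}  class={rec.class_label} "
      f"side={rec.side}  frames={rec.n_frames}")
print(f"FN vertical excursion: {np.ptp(fnz):.3f} m "
      f"(ACR: {np.ptp(rec.axis('ACR', 'z')):.3f} m)")
# Each post-stroke participant contributes both limbs (G0 non-affected,
# G1 affected); controls contribute both limbs as G2.  The distal
# fingertip marker travels farthest, the shoulder marker least.
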