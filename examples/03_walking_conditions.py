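"""Classify walking conditions on a U-turn trial and a step trial.

Curvilinear walking (CW) is found from the pelvis heading (>= 45 degrees
of rotation at >= 15 deg/s peak, 0.5-10 s); step negotiation (SN) from a
heel-height change > 0.15 m between consecutive same-side initial
contacts.  Everything else is straight walking (SW).
"""

from collections import Counter

from gaitevents import (Kinematics, StepSpec, SyntheticGaitSpec, TurnSpec,
                        classify_trial, detect_events, simulate_trial)

# --- 180-degree U-turn over 2 s in the middle of the walk ---------------
spec = SyntheticGaitSpec(n_strides=10, seed=3)
mid = 0.5 * sum(spec.walk_window())
spec.turns = (TurnSpec(angle_deg=180.0, start_s=round(mid - 1.0, 2),
                       duration_s=2.0),)
trial, truth = simulate_trial(spec)
kin = Kinematics(trial)
events = detect_events(trial, "M10", kin=kin)
labeled, segments = classify_trial(trial, events, kin)
for s in segments:
    print(f"{s.label}: {s.start:.2f}-{s.end:.2f} s, "
          f"net yaw {s.total_yaw_deg:.0f} deg, "
          f"peak rate {s.peak_yaw_rate_deg_s:.0f} deg/s")
print("event labels:", dict(Counter(e.condition for e in labeled)))

# --- 0.20 m step half-way along the path --------------------------------
spec2 = SyntheticGaitSpec(n_strides=10, seed=3)
spec2.steps = (StepSpec(height_m=0.20,
                        position_m=round(spec2.total_arc_length() / 2, 2)),)
trial2, _ = simulate_trial(spec2)
kin2 = Kinematics(trial2)
labeled2, segments2 = classify_trial(trial2, detect_events(trial2, "M10",
                                                           kin=kin2), kin2)
for s in segments2:
    print(f"{s.label} ({s.side}): {s.start:.2f}-{s.end:.2f} s, "
          f"height change {s.height_change_m:+.2f} m")
print("event labels:", dict(Counter(e.condition for e in labeled2)))

# One CW segment covers the turn and one SN segment per side covers the
# stride that crosses the step; events inside them inherit the label.
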