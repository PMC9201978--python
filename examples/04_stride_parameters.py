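"""Compute spatio-temporal stride parameters and their error propagation.

Strides are delimited by consecutive same-side initial contacts; the
intervening final contact splits stance and swing.  Length is the
horizontal heel displacement between the bounding contacts, speed is
length over duration.  Detection timing errors propagate into the
parameters; the error table quantifies bias (ME), precision (IQRE) and
accuracy (MAE), absolute and relative.
"""

from gaitevents import (Kinematics, SyntheticGaitSpec, build_stride_table,
                        classify_trial, detect_events, simulate_trial,
                        stride_param_errors, summarize_stride_errors)

trial, truth = simulate_trial(SyntheticGaitSpec(n_strides=10, seed=21))
kin = Kinematics(trial)
labeled, _ = classify_trial(trial, detect_events(trial, "M10", kin=kin), kin)
table = build_stride_table(trial, labeled, kin, method="M10")

print(table[["side", "t_ic_start", "duration_s", "stance_s", "swing_s",
             "length_m", "speed_mps"]].head(6).to_string(index=False))

errors = stride_param_errors(table, truth.strides)
summary = summarize_stride_errors(errors)
print("\nerror summary (detected - reference):")
print(summary[["parameter", "n", "ME", "IQRE", "MAE",
               "MAE_pct"]].to_string(index=False))

# MAE_pct is the median absolute relative error: ~0% for duration/length/
# speed means the one-frame event-timing errors barely reach the stride
# level; stance/swing are more sensitive because the final-contact error
# does not cancel between the two bounding initial contacts.
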