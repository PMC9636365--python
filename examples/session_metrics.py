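"""Session-level metrics from one synthetic interval-training session.

Generates a 10-min 100 W warm-up followed by five 4-min intervals with 3-min
rests, then computes the quantities the diagnostic parameters are built from:
the highest 30-s heart-rate mean, per-interval VO2 plateaus, heart-rate
recovery, substrate oxidation and efficiency ratios.
"""

import overreach as ov
from overreach.sessions import brouwer_substrates, gross_efficiency, guarded_ratio

session, markers = ov.generate_session(seed=1)
intervals, summary = ov.summarize_session(session, markers)

print("Per-interval summary:")
print(intervals.round(2).to_string(index=False))

print(f"\nSession HR_max (peak 30-s mean): {summary['hr_max_bpm']:.1f} bpm")
print(f"Session-mean HRR at 30 s: {summary['hrr_30s_mean']:.1f} bpm")
print(f"Session-mean HRR at 60 s: {summary['hrr_60s_mean']:.1f} bpm")

# substrate use at a steady point of the warm-up (last 7 min analysis mask)
warm = session[(session.time_s >= 180) & (session.time_s <= 599)]
vo2, vco2 = warm.vo2_lmin.mean(), warm.vco2_lmin.mean()
rep = brouwer_substrates(vo2, vco2)
print(f"\nWarm-up (100 W, last 7 min): VO2 {vo2:.2f} L/min, RER {rep.rer:.2f}")
print(f"  carbohydrate oxidation {rep.cho_g_min:.2f} g/min, fat {rep.fat_g_min:.2f} g/min")
print(f"  gross efficiency {gross_efficiency(100.0, vo2, vco2):.1f} %")

w_per_hr, _ = guarded_ratio(intervals.power_mean_w.mean(), intervals.hr_mean_bpm.mean())
print(f"\nHIIT power per heart rate: {w_per_hr:.2f} W/bpm")
print(
    "\nA falling power-per-HR or HR-per-RPE ratio across training phases is"
    "\none of the qualitative signs accompanying maladaptation."
)
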