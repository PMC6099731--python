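"""Bench probe calibration: recovery by gain and loss, pooling, stability.

Simulates the standard bench design (4 replicate dialysate samples per
perfusion flow rate, gain and loss directions) and summarizes it.  Recovery
falls as flow rises because the perfusate spends less time at the membrane;
gain/loss agreement is what justifies using in vivo retrodialysis loss as
the recovery estimate.
"""

from micropkpd import (
    generate_recovery_experiment,
    generate_stability_series,
    grand_mean,
    stability_check,
    summarize_recovery,
)

measurements = generate_recovery_experiment(noise_cv=0.0)
gains = [m for m in measurements if m.method == "gain"]
losses = [m for m in measurements if m.method == "loss"]

print("flow rate   recovery(gain)   loss")
for g, l in zip(
    sorted(summarize_recovery(gains, by="flow_rate"), key=lambda s: float(s.condition)),
    sorted(summarize_recovery(losses, by="flow_rate"), key=lambda s: float(s.condition)),
):
    print(f"{g.condition:>6} uL/min   {g.mean_rr:6.2f}%      {l.mean_rr:6.2f}%  (n={g.n})")

print(f"pooled recovery by gain: {grand_mean(summarize_recovery(gains)):.2f}%")
print("(gain and loss agree because the membrane transfer fraction is symmetric)")

series = generate_stability_series(seed=1)
verdict = stability_check(series)
print(
    f"in vivo retrodialysis over 8 h: mean loss {verdict.mean:.2f}%, "
    f"CV {100 * verdict.cv:.1f}% -> {'stable' if verdict.passed else 'unstable'} "
    f"(threshold {100 * verdict.threshold:.0f}%)"
)
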