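"""Warmup-scheduled augmentation probabilities over a training run.

The warmup factor P ramps linearly from 0 and reaches 1 at exactly one
fifth of the epochs; every augmentation's base probability is scaled by P,
so early epochs see raw data and later epochs the full default pipeline.
"""

from strawdet import ScheduleState, effective_plan, warmup_probability

BASE = {"mosaic": 1.0, "fliplr": 0.5, "hsv": 0.5}
TOTAL = 100

print(f"epoch    P     " + "  ".join(f"{k:>7s}" for k in BASE))
for epoch in (0, 5, 10, 15, 20, 50, 99):
    plan = effective_plan(ScheduleState(epoch, TOTAL), BASE)
    eff = "  ".join(f"{plan.effective_probabilities[k]:7.2f}" for k in BASE)
    print(f"{epoch:5d}  {plan.warmup_factor:4.2f}  {eff}")

print()
print("P is the warmup factor of the schedule; each column is an effective")
print("firing probability (base probability x P). Full augmentation starts at")
print(f"epoch {next(e for e in range(TOTAL) if warmup_probability(ScheduleState(e, TOTAL)) == 1.0)} "
      f"= 1/5 of {TOTAL} epochs.")
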