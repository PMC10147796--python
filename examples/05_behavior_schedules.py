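"""Behavioral scheduling: rotational schemes, criterion, habituation."""

import numpy as np

from ps6quant import (HabituationSchedule, count_valid_schemes, criterion_met,
                      generate_scheme, schedule_sessions, simulate_learner)

rng = np.random.default_rng(5)
schemes = [generate_scheme(rng) for _ in range(4)]
print("four rotational schemes (5 L / 5 R, runs <= 2):",
      ", ".join(map(str, schemes)))
print("valid schemes of this kind:", count_valid_schemes(10, 5, 2), "of 252")

plan = schedule_sessions(schemes, n_sessions=8)
print("\nsession plan (two sessions per day, schemes cycled):")
print(plan.to_string(index=False))

# a learner improving from chance to 85% correct
sessions = simulate_learner([0.5, 0.6, 0.7, 0.8, 0.85, 0.85, 0.85], seed=2)
print("\nper-session correct:", [s.n_correct for s in sessions])
met = criterion_met(sessions)
print("learning criterion (>=7/10 three sessions running) met at session:",
      met)

hab = HabituationSchedule()
print(f"\nhabituation: {hab.total_sessions} sessions / {hab.total_trials} "
      f"trials over {hab.n_days} days (last day a single session)")
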