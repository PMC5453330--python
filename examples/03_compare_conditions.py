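"""Compare rhythmic gene sets across three conditions.

Simulates a control cohort, an amplitude-damped / phase-advanced cohort
(emulating around-the-clock feeding), and a cohort that loses most
rhythms (emulating a clock knockout); partitions the rhythmic sets,
and summarises the phase shift of the genes shared with control.
"""

from dielfit import (
    ConditionSpec,
    SimulationConfig,
    call_rhythmic,
    fit_all,
    generate_expression,
    partition_sets,
    phase_histogram,
    phase_shift,
)

PHASES = [(z, 1 / 6) for z in (2, 6, 10, 14, 18, 22)]
cfg = SimulationConfig(
    n_features=800,
    conditions=[
        ConditionSpec("control", 0.25, (0.6, 1.4), PHASES),
        ConditionSpec("constant_fed", 0.25, amplitude_damping=0.7,
                      phase_shift_h=-1.5),
        ConditionSpec("clock_ko", 0.05, amplitude_damping=0.3),
    ],
    noise_sd=0.2,
    seed=3,
)
tc, truth = generate_expression(cfg)

fits, calls = {}, {}
for cond in tc.conditions:
    fits[cond] = fit_all(tc.subset_condition(cond))
    calls[cond] = set(call_rhythmic(fits[cond], 1e-4).feature_ids)

part = partition_sets(calls)
print("rhythmic-set partition (non-empty regions):")
for region, members in part.regions.items():
    if members:
        print(f"  {' & '.join(region):40s} {len(members):4d} genes")

shared = calls["control"] & calls["constant_fed"]
shift = phase_shift(fits["control"], fits["constant_fed"], sorted(shared))
print(f"\ncircular mean phase shift control -> constant_fed: "
      f"{shift.mean_shift_h:+.2f} h (planted: -1.5 h)")

hist = phase_histogram(fits["control"].loc[sorted(calls['control']), "phase"]
                       .dropna() % 24)
print("\ncontrol phase histogram (top 3 bins):")
print(hist.sort_values(ascending=False).head(3).to_string())
# The partition mirrors the planted overlap structure and the circular
# mean recovers the planted phase advance of the shared oscillators.
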