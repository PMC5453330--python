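"""Plant known 24-h rhythms and recover them with the cosinor fit.

Generates 200 genes (half rhythmic) sampled at 6 ZT timepoints over two
days with 3 replicates per timepoint, fits the harmonic regression to
each, and compares fitted amplitude/phase to the planted truth.
"""

import numpy as np

from dielfit import ConditionSpec, SimulationConfig, fit_all, generate_expression

cfg = SimulationConfig(
    n_features=200,
    conditions=[ConditionSpec(
        "control",
        rhythmic_fraction=0.5,
        amplitude_range=(0.5, 1.5),
        phase_distribution=[(z, 1 / 6) for z in (2, 6, 10, 14, 18, 22)],
    )],
    noise_sd=0.2,
    seed=1,
)
tc, truth = generate_expression(cfg)
res = fit_all(tc)

truth = truth.set_index("feature_id")
rhythmic = truth["rhythmic"]
amp_err = (res["amplitude"] - truth["amplitude"])[rhythmic].abs()
dphi = (res["phase"] - truth["phase"])[rhythmic].abs() % 24
phase_err = np.minimum(dphi, 24 - dphi)

print(f"{tc.n_features} genes x {tc.n_samples} samples, noise sd 0.2 log2 units")
print(f"median |amplitude error| (rhythmic genes): {amp_err.median():.3f} log2")
print(f"median |phase error|     (rhythmic genes): {phase_err.median():.2f} h")
print(f"rhythmic genes with p < 1e-4: {(res['p_value'][rhythmic] < 1e-4).mean():.0%}")
print(f"arrhythmic genes with p < 1e-4: {(res['p_value'][~rhythmic] < 1e-4).mean():.1%}")
# Small errors and near-total separation of the two groups show the fit
# recovers the planted rhythm parameters at realistic array noise.
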