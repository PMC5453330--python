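"""PAM-cluster rhythmic genes by the shape of their daily profile.

Genes are planted in three phase groups (peaks at ZT2, ZT10, ZT18);
their z-scored per-ZT mean profiles are clustered with PAM and the
number of clusters is selected by the best mean silhouette width.
"""

import numpy as np

from dielfit import ConditionSpec, SimulationConfig, generate_expression
from dielfit.cluster import profile_matrix, select_k

cfg = SimulationConfig(
    n_features=300,
    conditions=[ConditionSpec(
        "control", 1.0, (0.8, 1.2),
        phase_distribution=[(2.0, 1 / 3), (10.0, 1 / 3), (18.0, 1 / 3)],
    )],
    noise_sd=0.15,
    seed=4,
)
tc, truth = generate_expression(cfg)
profiles, _ = profile_matrix(tc, condition="control")
model = select_k(profiles, k_range=range(2, 11))

print("mean silhouette by k:")
for k, s in model.silhouette_by_k.items():
    marker = " <- selected" if k == model.k else ""
    print(f"  k={k:2d}: {s:.3f}{marker}")

print(f"\nselected k = {model.k}")
for c in range(model.k):
    members = np.where(model.labels == c)[0]
    peak_zt = profiles.columns[profiles.iloc[members].mean(axis=0).argmax()]
    print(f"  cluster {c}: {len(members):3d} genes, mean profile peaks at {peak_zt}")
# Three clusters whose mean profiles peak at the three planted phases
# show the clustering is phase-driven, as intended by the z-scoring.
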