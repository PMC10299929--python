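"""Pose-normalize a cohort and fit the PCA statistical shape model.

Each aligned case becomes a 404-long feature vector (x, y, z, radius for
101 points); PCA yields ranked anatomical modes of variation, and a
two-sample t-test per mode flags where the outcome groups differ.
"""

import archssm as a
from archssm import shape_model as sm

cohort = a.generate_cohort(a.SyntheticCohortSpec(n_cases=100,
                                                 prevalence=0.4, seed=2))
aligned = [a.align(arch) for arch in cohort.arches]
X = sm.assemble_features(aligned)
print(f"feature matrix: {X.shape[0]} cases x {X.shape[1]} features")

model = sm.fit_pca(X, case_ids=cohort.case_ids)
evr = model.explained_variance_ratio()
print(f"first 3 modes explain {100 * evr[:3].sum():.1f}% of variance; "
      f"first 10 modes {100 * evr[:10].sum():.1f}%")

ttest = sm.mode_group_ttest(model, cohort.labels)
sig = ttest.loc[ttest["significant"], "mode"].tolist()
print(f"modes differing between groups at p<0.01: {sig}")
print("(low-order significant modes carry the group shape contrast; "
      "high modes are noise)")

rmse10 = sm.reconstruction_rmse(model, 0, 10, "ALL")
rmse_nb = sm.reconstruction_rmse(model, 0, 10, "NEAR_BIFURCATION")
print(f"case 0 reconstruction RMSE with 10 modes: {rmse10:.2f} mm overall, "
      f"{rmse_nb:.2f} mm near the bifurcation")
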