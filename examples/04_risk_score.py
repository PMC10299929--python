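"""Fisher discriminant shape risk score and the mode-count sweep.

A Fisher LDA over the first k PCA coefficients gives each anatomy one
standardized score (Z-score; higher = more coarctation-like).  Sweeping
k = 1..25 shows resubstitution AUC creeping upward while leave-one-out
AUC plateaus: the growing gap is the overfitting signature used to pick
the working mode count.
"""

import archssm as a
from archssm import descriptors as de
from archssm import discriminant as dd
from archssm import shape_model as sm
from archssm.synthetic import attenuated_contrast

# attenuated class contrast so performance is not saturated at 1.0
p0, p1 = attenuated_contrast(0.35)
cohort = a.generate_cohort(a.SyntheticCohortSpec(
    n_cases=120, prevalence=0.4, class0_means=p0, class1_means=p1, seed=4))
aligned = [a.align(x) for x in cohort.arches]
model = sm.fit_pca(sm.assemble_features(aligned), case_ids=cohort.case_ids)

sweep = dd.sweep_modes(model, cohort.labels, k_max=25)
print("k  AUC(RS) AUC(LOOCV)")
for k in (1, 3, 5, 10, 15, 20, 25):
    print(f"{k:2d}  {sweep.auc_rs[k - 1]:.3f}   {sweep.auc_loocv[k - 1]:.3f}")
print(f"selected k = {sweep.selected_k} "
      "(largest k near the LOOCV optimum without an RS-LOOCV gap)")

k = 10
axis = dd.fit_lda(model.coefficients[:, :k], cohort.labels)
z = dd.risk_scores(axis, model.coefficients[:, :k])
print(f"risk score: mean {z.mean():+.2e}, sd {z.std(ddof=1):.3f} "
      "(cohort-standardized Z)")
print(f"group means: coarctation-like {z[cohort.labels == 1].mean():+.2f}, "
      f"false-positive-like {z[cohort.labels == 0].mean():+.2f}")

minus, plus = dd.lda_extreme_shapes(model, axis, sd_multiple=3.0)
ang_m = de.compute_descriptors(minus).ang_vert_deg
ang_p = de.compute_descriptors(plus).ang_vert_deg
print(f"extreme phenotypes at Z=-3 / Z=+3: insertion angle "
      f"{ang_m:.0f} deg -> {ang_p:.0f} deg")
print("(the high-risk phenotype shows the steeper, near-perpendicular "
      "isthmus insertion)")
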