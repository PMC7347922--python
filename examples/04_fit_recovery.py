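"""Fit the hierarchical model to a synthetic cohort and test the learning bias.

Generates an asymmetric-model cohort, fits it with empirical-Bayes EM, and
compares the recovered group means with the generating values; the z-test
asks whether the group-level learning bias alpha+ - alpha- is positive.
"""

from mvtlearn import CohortSpec, default_group, em_fit, generate_cohort, learning_bias_ztest

dist = default_group("exp1", "asymmetric")
spec = CohortSpec(
    n_subjects=16,
    experiment="exp2",
    allocation={"RichPoor": 8, "PoorRich": 8},
    dist=dist,
    seed=11,
)
logs = generate_cohort(spec)

post, fits = em_fit(logs, "asymmetric", restarts=3, seed=0)
true = dist.mean_params().as_dict()
fitted = post.mean_params().as_dict()
print(f"EM converged in {post.n_iter} iterations\n")
print(f"{'parameter':10s} {'true':>9s} {'recovered':>10s}")
for name in true:
    print(f"{name:10s} {true[name]:9.4f} {fitted[name]:10.4f}")

z = learning_bias_ztest(post)
print(f"\nlearning bias (alpha+ - alpha-): z = {z.value:.2f}, p = {z.p:.2g}")
print("\nA positive z recovers the generating asymmetry: reward-driven updates")
print("outweigh omission-driven ones at the population level.")
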