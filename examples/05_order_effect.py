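"""Why only the asymmetric learner shows a block-order effect.

Runs reduced replicate counts of the cohort simulation under both models and
prints the mean poor-minus-rich difference score per order condition.  With
alpha+ > alpha-, subjects who start rich keep an inflated rho in the poor
block (slow unlearning), muting their behavioral change; symmetric learners
adjust equally in both directions, so block order should not matter.
"""

from mvtlearn import order_effect_experiment

for model in ("asymmetric", "symmetric"):
    rep = order_effect_experiment(model=model, n_sims=20, n_subjects=40, seed=3)
    s = rep.summary
    print(f"{model:10s}  RichPoor {s['mean_diff_RichPoor']:+.3f}  "
          f"PoorRich {s['mean_diff_PoorRich']:+.3f}  "
          f"order effect {s['order_effect']:+.3f}")
print("\nOnly the asymmetric model separates the two conditions: that asymmetric")
print("signature is what the model comparison picks up in choice data.")
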