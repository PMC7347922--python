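"""Task structure and the normative (MVT) policy for each environment.

Prints each option's profitability and, per environment, the acceptance set
that maximises the long-run reward rate.  Under the Marginal Value Theorem an
option is worth accepting only if its reward beats the opportunity cost of
its handling time, so the rich environment (best option abundant) supports a
much more selective policy than the poor one.
"""

from mvtlearn import (
    DEFAULT_OPTIONS,
    SessionDesign,
    hdlr_environment,
    mvt_optimal_policy,
    poor_environment,
    profitability,
    rich_environment,
)

design = SessionDesign("exp1", "RichPoor")

print("Options (reward pts, handling s -> profitability pts/s):")
for label, opt in DEFAULT_OPTIONS.items():
    print(f"  {label}: {opt.reward_points:>4.0f} pts / {opt.handling_seconds} s"
          f" -> {profitability(opt):.1f} pts/s")

print("\nOptimal policy per environment (accept set, long-run rate):")
for env in (rich_environment(900), poor_environment(900), hdlr_environment(600)):
    sol = mvt_optimal_policy(env, design)
    accept = ", ".join(sorted(sol.accept_set))
    print(f"  {env.name:10s} accept {{{accept}}} at {sol.long_run_rate:.2f} pts/s")

print("\nA higher long-run rate raises the opportunity cost of handling, so the")
print("rich environment's optimal forager accepts only the best option.")
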