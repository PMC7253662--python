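"""Baseline go/no-decision ratios and 90%-target prize sizes.

Runs the baseline campaign at a reduced sample count (500 projects per
indication), printing the share of projects a private developer would
pursue unaided and the entry-reward sizes the fitted response models say
would convert 90% of no-decisions into go-decisions.
"""

from abxfund import load_parameters, run_baseline

specs = load_parameters()
base = run_baseline(specs, n_samples=500, seed=1, target_pgo=0.9)

print("go-decision probability without intervention (%):")
print((base.go_ratios["Go"] * 100).round(1).sort_values(ascending=False).to_string())
print()
print("prize (million USD) yielding P(go) = 90%, by entry phase:")
print(base.prizes.round(0).to_string())
print()
print("Later rewards must be far larger: a market entry reward is paid only")
print("on success and after many discounted years, so it buys less")
print("go-probability per dollar than a phase-1 reward.")
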