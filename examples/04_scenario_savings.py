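"""Cost savings of direct funding in the 50%-inefficiency scenario.

Prices 300 projects per indication under the packaged reference schedule
of 90%-target entry rewards and prints the mean cost savings of funding
development at-cost (with a 50% inefficiency mark-up) instead of paying
the reward, per observed market approval.
"""

from abxfund import load_parameters, run_scenario
from abxfund.parameters import load_reference_prizes

specs = load_parameters()
res = run_scenario(specs, n_samples=300, inefficiency=0.5, seed=1,
                   prizes=load_reference_prizes())

print("mean cost savings of direct funding (million USD per market approval):")
print(res.mean_savings.round(0).to_string())
print()
print("Positive means paying at-cost is cheaper than the reward; negative")
print("means the reward is cheaper.  Early-phase rewards beat direct funding,")
print("late-phase and market entry rewards cost the benefactor more.")
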