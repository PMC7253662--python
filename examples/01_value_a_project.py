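"""Sample one antibiotic project and value it from all four perspectives.

Draws a single project realization for the CUTI indication, expands it
into its yearly cashflow schedule with a 500-million-USD market entry
reward attached, and prints the four expected-net-present-value
perspectives.
"""

from abxfund import EconomyConfig, load_parameters
from abxfund.sampling import PrizeDraw, project_rng, sample_project
from abxfund.schedule import build_schedule
from abxfund.valuation import evaluate

specs = load_parameters()
cfg = EconomyConfig()
rng = project_rng(seed=7, stream=0, index=0)

real = sample_project(specs["CUTI"], cfg, rng)
sched = build_schedule(real, extra=specs["CUTI"].extra_costs,
                       prize=PrizeDraw("M1", 500.0))
res = evaluate(sched, r=real.private_rate, r_social=real.social_rate,
               inefficiency=0.5)

print(f"development time: {real.total_development_years:.1f} years, "
      f"P(reach market) = {sched.p_reach_market:.3f}")
print(f"private ENPV            {res.private:10.1f} MUSD  -> "
      f"{'go' if res.go_without else 'no-go'} without intervention")
print(f"intervened private ENPV {res.intervened_private:10.1f} MUSD  -> "
      f"{'go' if res.go_with else 'no-go'} with the 500 MUSD reward")
print(f"indirect (prize) cost   {res.indirect:10.1f} MUSD")
print(f"direct (at-cost) cost   {res.direct:10.1f} MUSD at 50% inefficiency")
print()
print("The developer decides on the first two numbers; the public benefactor")
print("pays the (negative) third when funding via the prize, or the fourth")
print("when funding development at-cost.")
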