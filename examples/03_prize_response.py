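"""Fit and invert the prize-response model for one indication and phase.

Simulates ABOM projects, fits the logistic model of post-prize
go-decisions on log10 prize size over the no-decision subset, and inverts
it at a few go-probability targets.
"""

from abxfund import EconomyConfig, load_parameters
from abxfund.experiments import simulate_batch
from abxfund.incentive import fit_pgo, predict_pgo, solve_prize

specs = load_parameters()
evs = simulate_batch(specs["ABOM"], EconomyConfig(), seed=1, stream=0, n=2000)

nogo = [(e.prize_size, e.intervened("P1", e.prize_size) >= 0)
        for e in evs if not e.go_without]
fit = fit_pgo(nogo, indication="ABOM", prize_phase="P1")

print(f"logistic fit on {fit.n_obs} no-decision projects: "
      f"b0 = {fit.beta0:.2f}, b1 = {fit.beta1:.2f} "
      f"(max p-value {fit.max_p_value:.1e})")
for target in (0.5, 0.75, 0.9):
    z = solve_prize(fit, target)
    print(f"  P(go) = {target:.0%} needs a phase-1 reward of {z:7.1f} MUSD "
          f"(check: predict -> {predict_pgo(fit, z):.3f})")
print()
print("b1 > 0: larger prizes convert more no-decisions; the analytic")
print("inversion returns the reward size hitting any go-probability target.")
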