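# abxfund

Monte Carlo comparison of **direct (at-cost) versus indirect (prize-based)
public funding of antibiotic development**.

New antibiotics are commercially unattractive: development is long, risky
and expensive, while sales of a novel antibiotic are deliberately held
back by stewardship. Policy proposals therefore either *pull* private
developers with lump-sum rewards — phase entry rewards or (partially
delinked) market entry rewards (MERs) — or *push* by paying development
costs directly. This package quantifies, for hypothetical antibiotics
against six indications (ABOM, ABSSSI, CABP, CIAI, CUTI, HABP/VABP),
which option costs a public benefactor less per approved drug, as a
function of how strongly the prize must convert developer no-decisions
into go-decisions and how inefficiently a plan-based direct funder
operates.

It is intended for health-economics and pharmaceutical-policy researchers
who want a reproducible, parameter-table-driven implementation of the
comparison, with every modelling stage exposed as a library function.

## Model

A project is a staged pipeline PC → P1 → P2 → P3 → P4 → 20 market years.
Phase durations, costs and success probabilities, market size, launch
success, generic entry and discount rates are drawn from triangular (or
uniform) distributions shipped as CSV tables. Each realization is
periodized into yearly steps *t* (fractional across phase boundaries) and
valued as a risk-adjusted discounted cashflow from four perspectives:

    private      ENPV = Σ_t (R_t − C_t)        · (P0/P_t) / (1+r)^t
    intervened   ENPV = Σ_t (R_t − C_t + Z_t)  · (P0/P_t) / (1+r)^t
    indirect     ENPV = Σ_t (−Z_t)             · (P0/P_t) / (1+r′)^t
    direct       ENPV = Σ_t (−(1+i) C_t)       · (P0/P_t) / (1+r′)^t

where R, C, Z are revenue, cost and prize at step *t*; P0/P_t is the
probability of surviving to step *t* from the pre-clinical outset; P0 is
the technical probability of reaching the market; *r* is the private and
*r′* the social discount rate; and *i* is the direct funder's
inefficiency. A developer goes ahead iff its (intervened) private ENPV ≥ 0.
Indirect and direct ENPV are pure benefactor costs (always ≤ 0).

The conditional probability that a prize of size *z* (million USD) turns a
no-decision into a go-decision is modelled per indication × prize phase by

    logit P(go) = β0 + β1 · log10 z,

fitted on simulated projects, and inverted analytically,
z\*(p) = 10^[(logit p − β0)/β1], to size a reward for any go-target.
Benefactor costs are normalised per observed market approval (divide by
P0), and the *cost savings of direct funding* is direct − indirect ENPV
per approval on the subset of projects the prize actually stimulates.

## Worked example

```bash
python examples/02_baseline_decisions.py
```

prints (500 projects per indication, seed 1):

```
go-decision probability without intervention (%):
CUTI         87.4
ABSSSI       82.4
ABOM         75.6
CABP         74.6
CIAI         72.8
HABP/VABP    59.0

prize (million USD) yielding P(go) = 90%, by entry phase:
              P1     P2      P3      P4      M1
ABOM        95.0  221.0   811.0  1385.0  2207.0
...
```

Unaided, most projects already clear the private hurdle — except the
hospital pneumonia indication (HABP/VABP), whose small market and heavy
phase-3 costs leave 41% of projects abandoned. Converting 90% of the
remaining no-decisions requires a ~95 MUSD reward if paid at phase-1
entry, but over 2 billion USD if paid at market entry: a market reward is
received only on success and a decade later, so a developer with a high
discount rate values each promised dollar at a few cents.

The other examples value a single project (`01`), fit and invert the
prize-response model (`03`), and price the 50%-inefficiency scenario
(`04`), each printing a short interpretation. The same campaigns are
available from the shell:

```bash
abxfund baseline --seed 1 --out runs/base
abxfund grid     --seed 1 --out runs/grid      # P(go) × inefficiency sweep
abxfund scenario --seed 1 --reference-prizes --out runs/scen
```

Every run writes CSV tables plus a `manifest.json` (config, seed, fixture
checksum) that makes it reproducible byte-for-byte.

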