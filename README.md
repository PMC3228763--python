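# clonecascade

Dynamics of mutant cell clones in hierarchically organized tissues.

Renewing tissues such as blood, skin and the colonic crypt are organized as
a differentiation hierarchy: a small, constant pool of stem cells feeds a
chain of progressively more differentiated, progressively faster-dividing
cell compartments. `clonecascade` implements the linear multi-compartment
model of this architecture and uses it to answer a clinically motivated
question: **when a mutant clone appears in the blood, where in the
hierarchy did it arise, and how long will it persist?** The flagship worked
example is the kinetics of PIG-A mutant (GPI-negative, PNH-phenotype)
clones, which are detectable by flow cytometry in virtually every healthy
adult and typically vanish within months.

## Model

Compartment 0 is a stem-cell pool of constant size N₀ whose cells divide
asymmetrically at rate r₀, exporting one cell per division into compartment
1. In each downstream compartment k (k = 1…K) cells divide at rate rₖ; a
division produces two daughters in compartment k+1 with probability εₖ
(symmetric differentiation), kills the cell with probability dₖ, or
produces two daughters in compartment k (self-renewal) otherwise. The mean
occupancies Nₖ(t) obey the linear cascade

    dN₁/dt = φ − b₁N₁,      dNₖ/dt = aₖNₖ₋₁ − bₖNₖ   (k ≥ 2)

with stem flux φ = r₀N₀, inflow coefficients aₖ = 2εₖ₋₁rₖ₋₁, net-loss
parameters γₖ = 2(εₖ + dₖ) − 1 and decay coefficients bₖ = γₖrₖ. The
package provides:

* **closed-form solutions** — hypoexponential (Bateman-type) sums of
  exponentials for stem-driven filling (with the homeostatic equilibrium
  N\*ₖ as t → ∞), for transient mutant clones founded in a downstream
  compartment (washed out whenever all γ > 0), and for "stem-like" mutants
  with γ_c = 0, evaluated stably to 31 compartments via log-magnitude
  bookkeeping with an arbitrary-precision fallback;
* **an ODE oracle** — direct high-accuracy integration of the cascade, used
  to cross-check every closed form and to evaluate degenerate (confluent
  decay-rate) cases;
* **a Gillespie simulator** — individual-based stochastic simulation of the
  first compartments with ensemble summaries and empirical extinction
  times; the deterministic cascade is the exact mean of this branching
  process;
* **extinction times** — the slowest-decay-mode approximation
  τ = ln(A)/b_min and exact root-finding on the full exponential sum, with
  extinction defined as the average count dropping below one cell;
* **the PIG-A analysis** — per-million mutant frequencies in the
  circulating compartment, detection/extinction reports at flow-cytometry
  observation levels, and a scan ranking candidate compartments of origin
  against observed clone sizes and persistence times.

The default human hematopoiesis parameterization uses the standard
compartmental estimates (N₀ = 400 active stem cells dividing about once
per year, ε = 0.85, d = 0, rₖ = 1.26ᵏ per year, K = 31 with compartment 31
representing circulating cells); PIG-A mutants share the healthy rates but
carry a slightly lower differentiation probability ε = 0.765.

## Worked example: a PIG-A clone born in compartment 10

```python
from clonecascade import CloneInit, frequency_trajectory, detection_report
from clonecascade.presets import human_hematopoiesis, piga_mutant

healthy = human_hematopoiesis()          # 31 compartments, eps=0.85, r_k = 1.26**k
mutant = piga_mutant()                   # same rates, eps = 0.765
freq = frequency_trajectory(healthy, mutant, CloneInit(origin=10))

t_peak, peak = freq.peak()
print(f"peak frequency: {peak:.1f} per million at day {t_peak * 365:.0f}")
for level in (51.0, 21.0):
    rep = detection_report(freq, sample_level=level, detection_limit=7.5)
    print(
        f"level {level:.0f}/million: sampled on the decay at day "
        f"{rep.time_at_sample_level_decaying:.0f}, below the detection limit at day "
        f"{rep.time_below_limit:.0f} -> extinction {rep.extinction_time:.0f} days"
    )
```

prints

```
peak frequency: 60.8 per million at day 282
level 51/million: sampled on the decay at day 345, below the detection limit at day 556 -> extinction 211 days
level 21/million: sampled on the decay at day 461, below the detection limit at day 556 -> extinction 96 days
```

A single mutant cell arising in compartment 10 grows to a peak of about 61
GPI-negative cells per million circulating cells some nine months after the
mutation. If it is sampled when it has decayed back to 51 per million (the
largest clone size measured in vivo), it stays detectable above the
7.5-per-million flow-cytometry limit for another ~211 days; sampled at 21
per million (the average measured clone size), for another ~96 days. Clones
born deeper than compartment 12 never reach the detection limit at all,
which is why observed PNH-phenotype clones in healthy adults point to an
origin among early progenitor compartments — `origin_scan` automates
exactly this inference.

A command-line interface exposes the same analyses
(`clonecascade equilibrium | fill | mutant | simulate | extinction | piga |
fixtures`), reading YAML scenario configs and writing tidy CSV results plus
a resolved config and log per run; see `clonecascade --help`.

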