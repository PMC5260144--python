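# macpol — multiscale simulation of macrophage M1/M2 polarization

`macpol` simulates how macrophages decide between the classically activated
(M1, pro-inflammatory, NOS2-marked) and alternatively activated (M2,
anti-inflammatory, Arg1-marked) phenotypes when that decision is driven not
by a fixed stimulus but by an evolving immune response.  It is aimed at
computational immunologists and systems biologists who want a small,
fully-inspectable multiscale model: every macrophage agent carries a signed
Boolean gene-regulatory network, and the cell population around it supplies
the network's inputs.

## The model

**Microscopic scale.**  An 18-node signed Boolean network (inputs IFN-γ,
IL-10, IL-4, LPS; receptors TLR4, IFNγR, IL-4Rα, IL-10R; internal nodes
NF-κB, STAT1, SOCS3, NOS2, STAT6, PPARγ, SOCS1, KLF4, Arg1, STAT3) with the
synchronous update map

    x_i(t+1) = ( ∨_{j∈E+_i} x_j(t) ) ∧ ¬( ∨_{j∈E-_i} x_j(t) )

— a gene switches on iff some activating parent is on and no inhibiting
parent is.  Inputs are clamped to the locally sensed stimulus vector
I = (IFNg, IL10, IL4, LPS).  A macrophage commits when its state reaches a
fixed point of the clamped dynamics expressing the M1 marker NOS2 or the
M2 marker Arg1; commitment is terminal, and no reachable state expresses
both markers (verified exhaustively over all 2^18 states).

**Mesoscopic scale.**  A reactive lattice-gas automaton on a periodic
L×L×L lattice: macrophages, B cells, Th1/Th2/Treg helper cells and discrete
tokens of antigen, antibody, IFN-γ, IL-4 and IL-10 diffuse with equal speed
(one of seven von-Neumann moves per step) and react through 15 local
stochastic rules — macrophage activation by IFN-γ, phagocytosis and
antigen presentation, helper priming by presenting macrophages, cytokine
secretion on cell–cell contact, Th-driven B-cell proliferation with
antibody release, and antibody–antigen neutralization.  Each step, every
active or presenting undifferentiated macrophage gets one chance to commit
by advancing its network under the local inputs (rules M0 → M1 with
probability f1, M0 → M2 with f2, where f1/f2 indicate attractor hits and
f1 + f2 ≤ 1).

**Experiments.**  Three challenge scenarios are bundled: a replicating
LPS-bearing bacterium (expected M1-polarized, controlled infection); a
non-replicating vaccine followed by daily IL-4 from day 3 for a week
(expected M2 polarization); and the bacterium followed by daily IL-10 on
the same schedule, in which a seed-dependent fraction of replicates fails
to control the infection — the dampened immune response.  The ensemble
layer runs seeded replicates, aggregates mean ± sd kinetics and classifies
each replicate controlled/dampened.

## Worked example

```python
from macpol import run_scenario, gram_negative, total

result = run_scenario(gram_negative(), n_replicates=5, base_seed=1)
for seed, ts in zip(result.seeds, result.replicates):
    print(seed,
          int(total(ts, "M1").iloc[-1]),
          int(total(ts, "M2").iloc[-1]),
          int(total(ts, "Ag").iloc[-1]),
          result.outcomes[seed - 1])
```

prints one line per replicate — seed, final M1 count, final M2 count,
final antigen count, outcome:

```
1 498 0 24932 dampened
2 500 0 0 controlled
3 500 0 0 controlled
4 500 0 0 controlled
5 500 0 0 controlled
```

Essentially all 500 macrophages end M1-committed (the NOS2-active
attractor) and the bacterium is usually cleared; in an occasional
replicate (seed 1 here) the response ignites too late to control the
infection within the run.  Replacing `gram_negative()` with
`vaccine_il4()` reverses the polarization (tens of M2 commitments,
essentially no M1); with `bacterium_il10()` roughly four in ten
replicates end with the antigen at carrying capacity instead of zero.

The same experiments run from the shell:

```sh
macpol simulate gram_negative --replicates 20 --seed 0 --out out/gn
macpol attractors                 # fixed points of all 16 input regimes
macpol validate-network           # exhaustive commitment-structure check
macpol calibrate-dampening --doses 2000,4000,8000,16000,32000 --replicates 24 --seed 0
```

`simulate` writes per-replicate CSV time series (one row per step, one
column per cell-state/molecule census series), aggregate `mean.csv` /
`sd.csv`, an `outcomes.csv`, a JSON summary and a run manifest with the
seed and the config/network/rule-table hashes.  Identical config and seed
reproduce every output byte for byte.

## Layout

- `src/macpol/grn.py` — Boolean network, attractor machinery, classification
- `src/macpol/network_io.py` — signed edge-list format + bundled network
- `src/macpol/rules.py` — the 15 reaction rules, rule-table text format,
  per-site and per-agent update surfaces
- `src/macpol/engine.py` — lattice engine (vectorized), census, audit
- `src/macpol/scenarios.py` — scenarios, ensembles, outcome classification,
  dose calibration
- `src/macpol/config.py`, `cli.py`, `fixtures.py`, `rng.py` — configuration,
  command line, test fixtures, seeded RNG streams
- `docs/methods.md` — modelling assumptions, parameter choices, limitations
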