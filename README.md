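# timeco

Ecological dynamics of the tumor-immune microenvironment (TIME) with
tumor-induced immune cell conversion.

Tumors do not merely evade the immune system — they actively reshape it,
converting anti-tumor immune cells (e.g. M1 macrophages) into pro-tumor
phenotypes (e.g. M2 macrophages). `timeco` implements a minimal
generalized Lotka–Volterra model of this interaction and the analysis
toolchain a dynamical-systems study of it needs: steady states, invasion
growth rates, linear stability with numerical resolution of marginal
cases, bifurcation detection, two-parameter regime maps, and basins of
attraction. It is aimed at mathematical oncologists and theoretical
ecologists exploring how conversion reshapes the possible fates of a
tumor-immune ecosystem.

## Model

Densities of tumor cells `T`, pro-tumor immune (PTI) cells `P`, and
anti-tumor immune (ATI) cells `A` evolve as

```
dT/dt = T (r_T − (r_T/K_T) T + α_TP P − α_TA A)
dP/dt = P (−d_P P + α_PT T) + ω A T
dA/dt = A (r_A − (r_A/K_A) A + α_AT T − α_AP P) − ω A T
```

with all parameters non-negative; `α_XY` is the per-capita effect of type
`Y` on the growth of type `X`, and `ω A T` is the tumor-catalyzed
conversion of ATI into PTI cells — the model's distinguishing ingredient.
Three binary structural switches (quadratic vs. linear PTI
self-limitation, PTI tumor-growth term on/off, logistic vs.
source-recruitment ATI dynamics) span eight model variants sharing one
implementation.

Key derived quantities:

* invasion growth rates `Ω_{X→S}`, e.g. `Ω_{T→A} = r_T − α_TA K_A`
  (tumor invading the cancer-free state);
* net negative feedbacks `Γ_{X→Y;S}`, e.g.
  `Γ_{T→T;TP} = r_T/K_T − α_TP α_PT/d_P`, whose positivity is exactly
  the feasibility condition of the tumor-PTI state — violated, the
  tumor→PTI→tumor positive feedback loop permits unbounded growth;
* the transcritical threshold
  `ω_TC = Γ_{T→T;TP} · r_A/r_T + α_AT − α_AP α_PT/d_P`, where the
  coexistence branch collides with the tumor-PTI state and they exchange
  stability.

The central phenomenon: when the tumor cannot invade the cancer-free
state (`Ω_{T→A} < 0`), a positive conversion rate past a saddle-node
value creates bistability between the cancer-free state and a cancer
state — a strong Allee effect with a threshold initial tumor density.

## Worked example

Steady states at the reference parameter set (all rates and capacities 1,
`α_TP = 0.95`, `α_TA = 1.5`, `α_PT = 0.15`, `α_AT = 0.05`,
`α_AP = 0.5`) with conversion rate `ω = 1`:

```python
from timeco import all_equilibria, classify_stability, load_fixture, steady_states_to_frame

params = load_fixture("basin_ref").parameters.replace(omega=1.0)
states = all_equilibria(params)
verdicts = [classify_stability(params, s) for s in states]
print(steady_states_to_frame(states, verdicts)[
    ["label", "T", "P", "A", "feasible", "verdict"]
].round(6).to_string(index=False))
```

```
  label        T        P        A  feasible                     verdict
TRIVIAL 0.000000 0.000000 0.000000      True                    unstable
      T 1.000000 0.000000 0.000000      True                    unstable
      A 0.000000 0.000000 1.000000      True marginal_numerically_stable
     TP 1.166181 0.174927 0.000000      True                      stable
    TPA 0.090031 0.271610 0.778666      True                    unstable
```

At this conversion rate the system is bistable: the cancer-free state
`A = (0, 0, 1)` (linearly marginal — its PTI-direction eigenvalue is
structurally zero — but attracting, as the perturbation trials confirm)
coexists with the stable cancer state `TP ≈ (1.166, 0.175, 0)`, and the
unstable coexistence state sits on the basin boundary between them.
Since `ω = 1` exceeds `ω_TC = 0.8325`, the stable coexistence branch has
already merged into TP.

The same analyses run from the shell:

```
timeco equilibria --fixture basin_ref -p omega=1
timeco sweep --fixture fold_sweep --omega-min 0.3 --omega-max 1.2   # logs ω_TC, fold
timeco basins --fixture basin_ref -p omega=2 --points 9
timeco phase-diagram --fixture regime_ref
timeco simulate --fixture basin_ref --init 0.01 0 1
```

Parameter fixtures `killing_sweep` … `runaway_ref` encode the reference parameter
sets; any config file (YAML/JSON) with all eleven parameters spelled
out works in their place.

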