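# coldchain

Two-stage decision support for last-mile vaccine cold-chain logistics:

1. **Route optimization** — a heterogeneous-fleet capacitated vehicle routing
   problem over one depot/DC and a set of vaccination centers.  Capacity can
   be read as a per-tour stop budget (default 10 stops, the responsive
   "milk-run" setting) or as dose volume against vehicle capacity.  An exact
   set-partitioning solver (provably optimal up to 15 customers) and a
   Clarke–Wright + 2-opt/relocate heuristic are provided, plus a Weiszfeld
   center-of-gravity routine for greenfield DC siting.
2. **Discrete-event + Monte-Carlo simulation** — executes the planned milk
   runs over a multi-week horizon with weekly Monday orders, a Monday–Friday
   06:00–15:00 shipping window, uniform processing-time draws, triangular
   vehicle speeds, LTL dispatch, capacity-driven trip repetition and
   total-backorder semantics.  Scenarios (network model × fleet composition)
   are scored on ELT service level, lead time, transportation cost and CO2
   emissions, aggregated over replications with t confidence intervals,
   stability checks and optional common-random-number pairing.

Because the studied region's weekly demand database and road-network
distances are not public, the `synth` module generates statistically similar
instances: 46 municipalities (adult population 301,975) with supply-driven
weekly dose totals allocated proportionally to adult population (+20% uplift
for high-infection municipalities) and geodesic × circuity road distances.
The three-vehicle catalogue (e-NV200 / NV200 / VW Transporter) and the ten
fleet scenarios over three network models are packaged as fixtures.

## CLI

```sh
coldchain synth    --out inst/ --seed 1                   # generate an instance
coldchain optimize --instance inst/ --model 2 --gfa --out plan.json
coldchain simulate --instance inst/ --plan plan.json --fleet "e-NV200=3,NV200=2"
coldchain run      --instance inst/ --scenario 7 --reps 30 --seed 1 --out runout/
coldchain compare  --instance inst/ --scenarios 1,2,3 --reps 30 --seed 1 --paired
```

Network models: 1 = Oslo DC, EV for the near customer group; 2 = relocated
DC (Hamar, or greenfield with `--gfa`), 1-day lead-time target for all
customers; 3 = Oslo DC, combustion-only fleet.

## Python API

```python
from coldchain import SynthConfig, generate_instance, Scenario, run_two_stage

instance = generate_instance(SynthConfig(seed=1))
scenario = Scenario(id=2, model_id=1, fleet={"e-NV200": 3, "NV200": 2})
result = run_two_stage(instance, scenario, n_reps=30, base_seed=0)
print(result.summary.mean["elt_service_level"])
```

## Layout

```
src/coldchain/instance.py   domain types, file I/O, distances, conversions
src/coldchain/synth.py      synthetic instance generator + fixtures
src/coldchain/routing.py    stage 1: exact & heuristic CVRP, greenfield DC
src/coldchain/sim.py        stage 2: discrete-event replication engine
src/coldchain/kpi.py        indicators, Monte-Carlo aggregation, stability
src/coldchain/scenarios.py  pipeline orchestration and scenario comparison
src/coldchain/cli.py        click command group
```
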