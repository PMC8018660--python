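# emobook

An event-driven, agent-based simulator of **emotional bookkeeping** in a
primate-like social group, with the parameter-sweep machinery and the
relationship-differentiation / stability analysis needed to study how the
*dynamics* and *speed* of internal relationship updating shape a group's
affiliative network.

## The scientific problem

Primates form differentiated affiliative relationships — a few strong
"friendships" against a background of weak ties — and a leading proximate
explanation is emotional bookkeeping: each individual integrates the
emotional effects of received grooming into a single partner-specific
valuation, the **LIKE** attitude, which then biases its own future grooming
choices. How such a bookkeeping rule must look for realistic, stable,
differentiated networks to emerge is an open question that this kind of
simulation addresses.

Twenty individuals move on a continuous 300 x 300 toroidal arena (1 grid
unit = 1 m, 1 time step = 1 min, a 12-h active day, a 350-day year).  Each
has a fixed dominance rank (dominance 1.00 down to 0.05), a fixed
partner-specific **FEAR** attitude proportional to the dominance gap, three
dynamic emotional states (arousal, anxiety, satisfaction) and a directed
row of LIKE attitudes.  Grooming raises the *receiver's* LIKE toward the
groomer; time erodes LIKE; agonism never touches it.

The bookkeeping core compares four update rules (the package's central
object of study):

| dynamics      | increase (grooming)   | decrease (idle)        |
|---------------|-----------------------|------------------------|
| original      | linear, `LIKE = a x`  | exponential, `0.5^(x/LHW)` |
| alternative   | logistic `1/(1+e^-kx)`| logistic `1 - 1/(1+e^-kx)` |
| dynamics3     | linear                | logistic               |
| dynamics4     | logistic              | exponential            |

calibrated against two speed contracts: **LINC** — uninterrupted grooming
drives LIKE from minimum to maximum in 10 / 30 / 60 min (fast /
intermediate / slow); **LHW** — exponential decay halves LIKE every LHW
minutes, and logistic decay from the upper bound first crosses 0.5 after
LHW minutes (LHW = 0 is a special rule that empties the full range in
50 min).  **LPS** in [0, 1] sets how strongly LIKE biases grooming-partner
choice.  The study grid crosses 2 dynamics x 3 LINC x 6 LHW x 4 LPS = 144
cells (2 replicates each) plus a 4-cell probe of the mixed dynamics.

The analysis stage categorizes second-year mean LIKE values into high
(>= 0.75) / intermediate / low (<= 0.25) dyads, and scores temporal
stability as the mean squared Pearson correlation (R^2) of the 380 directed
dyad values between five snapshots taken half a simulated year apart.

## A worked example

```python
import emobook as eb

cfg = eb.RunConfig(dynamics="alternative", linc="slow", lhw=2880, lps=0.99,
                   seed=7, scale=0.05)          # desk-scale run (~seconds)
record = eb.run_simulation(cfg)
mean = eb.second_year_mean(record.like_samples, record.like_sample_times,
                           cfg.recording_minutes)
summary = eb.categorize(mean)
stability = eb.stability_score(record.snapshots, record.snapshot_times)
print(f"high/intermediate/low dyads: {summary.n_high}/"
      f"{summary.n_intermediate}/{summary.n_low}")
print(f"stability (mean R^2):        {stability.mean_r2:.2f}")
```

prints

```
high/intermediate/low dyads: 16/2/362
mean LIKE in high dyads:     0.986
mean LIKE in low dyads:      0.012
transition R^2:              0.54, 0.86, 0.98, 0.87
stability (mean R^2):        0.81
```

Read: under the alternative (logistic) dynamics with slow increase,
intermediate decrease (LHW = 2880 min) and near-maximal partner selectivity
(LPS = 0.99), the group splits almost categorically into a few strong
bonds (16 dyads near the 0.99 ceiling) and many near-floor ties, with
almost no intermediate relationships, and the bond pattern is largely
conserved across half-year transitions.  Dropping `scale` (or omitting it)
runs the full two-year protocol.

## Command line

```bash
emobook curves --out curves.csv              # LIKE(t) tables for all dynamics
emobook run --dynamics original --linc fast --lhw 720 --lps 0.99 \
            --seed 1 --scale 0.05 --out run_out
emobook analyze run_out --plot               # categories + stability (+ plots)
emobook sweep --config sweep.yaml --out sweep_out
emobook fixtures --n 20 --n-high 2 --out fx  # synthetic analysis fixtures
```

All outputs are CSV/JSON with a manifest recording the full configuration
and seed; identical configuration and seed reproduce bit-identical outputs.

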