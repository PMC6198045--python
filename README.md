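# bphce

A Markov cost-effectiveness model of oral dutasteride/tamsulosin
**combination therapy** versus tamsulosin **monotherapy** for men (≥50 y)
with lower urinary tract symptoms from benign prostatic hyperplasia
(BPH), from a healthcare payer perspective (direct costs only, 2018
US$). It is aimed at health-economics researchers and students who want
a transparent, scriptable and fully testable implementation of this
class of decision-analytic model.

## The model

Patients start in the BPH state of a seven-state chain

```
BPH → AUR → TURP → {repeat TURP, medical intervention, recovery} → death
```

with acute urinary retention (AUR) and the first transurethral
resection of the prostate (TURP) as one-cycle tunnel states, at most two
TURP procedures per patient, and death absorbing both 30-day surgical
mortality and age-specific background mortality (a calibrated Gompertz
stand-in, combined with disease transitions as competing risks).
Combination therapy acts through relative risk reductions (RRR) on the
BPH→AUR and BPH→TURP transitions:

    p_comb = p_mono × (1 − RRR),   RRR_AUR = 0.676, RRR_TURP = 0.706

Discounted costs `C` and quality-adjusted life years `E` (3%/yr on both)
are accumulated over annual cycles by a deterministic cohort engine or a
seeded individual-level microsimulation, and compared as

    ICER = (C_comb − C_mono) / (E_comb − E_mono)   [US$/QALY]

with net-monetary-benefit decision rules `NMB = λ·E − C` at
willingness-to-pay `λ`. One-way sensitivity analysis (tornado) and
second-order probabilistic sensitivity analysis (beta/gamma parameter
distributions → CE-plane scatter → CEAC) are built in.

## Worked example

```sh
bphce basecase --horizon 4 --out out4
```

prints the two-arm cost decomposition, episode counts, QALYs and the
ICER over the 4-year horizon:

```
        section                  row Combination therapy Monotherapy Difference
Cost (US$ 2018)                 Drug               1,728       202.2      1,526
Cost (US$ 2018)                  BPH               1,751       1,707      43.19
Cost (US$ 2018)                  AUR                4.74       14.06     -9.323
Cost (US$ 2018)                 TURP               123.2       408.8     -285.6
Cost (US$ 2018) Medical intervention              0.3538       1.527     -1.173
       Episodes                  BPH                3.88       3.782    0.09828
       Episodes                  AUR             0.00376     0.01141  -0.007647
       Episodes                 TURP             0.02067     0.06853   -0.04786
       Episodes                Death             0.05546     0.05652   -0.00106
        Outcome                 QALY               3.277       3.246    0.03097
        Outcome           Total cost               3,607       2,334      1,273

ICER (cost per QALY gained): 41,111 US$/QALY [icer]
```

Reading it: over 4 years combination therapy costs US$1,273 more per
patient (almost entirely drug acquisition), prevents about 0.05 TURPs
and 0.008 AUR episodes per patient, and yields 0.031 extra discounted
QALYs — US$41,111 per QALY gained under this parameterisation.
`--horizon lifetime` runs 35 years; `--engine microsim --seed 1` swaps
in the individual-level engine. `bphce owsa` and `bphce psa --n 10000
--seed 1` produce the tornado table and the CE-plane/CEAC outputs, and
every parameter can be overridden through a flat YAML config
(`src/bphce/data/basecase.config` is the shipped reference; see
`docs/methods.md` and `docs/parameter_mapping.md` for modelling
conventions).

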