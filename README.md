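# lhsdrive

Simulation and scoring toolkit for evaluating **learning health systems
(LHS)** with the *engine–drivetrain* model: a translational science hub
(e.g. a CTSA center) is the engine, community empowerment is the variable
transmission, and four coupled learning cycles — clinical care, education,
research, governance — are the wheels that convert institutional capacity
into translational motion.

It is written for health-system evaluators, translational-science program
staff, and methods researchers who want to (a) score community empowerment
with a structured multi-rater instrument, (b) explore how empowerment,
resources, friction, and cross-cycle learning spillovers jointly shape
translational velocity and return on investment, and (c) stress-test those
conclusions under parameter uncertainty with a seeded Monte Carlo sweep.

## The model

**Community Transmission Index (CTI).** Each project is scored quarterly
on eight domains (shared governance, bidirectional accountability, data
transparency, participatory data governance, feedback closure,
co-production depth, trust capital, equity integration) on a 0–4 rubric by
three raters (academic, health system, community). Ratings are normalized
(`s = r/4`), averaged over raters, and weighted:

```
CTI_p = Σ_d w_d S_{p,d},   Σ_d w_d = 1,   CTI ∈ [0, 1]
```

with maturity bands Transactional `[0, .25)`, Advisory `[.25, .50)`,
Collaborative `[.50, .70)`, Shared-Governance `[.70, .85)`, and
Community-Anchored `[.85, 1]`. Inter-rater reliability uses weighted
Cohen's κ (target ≥ 0.75); any domain where raters spread ≥ 2 rubric
points is flagged for consensus review.

**Drivetrain.** CTI maturity `M` sets transmission efficiency and
friction reduction,

```
T(M) = 1 / (1 + exp(−a (M − m0)))        (logistic)
R(M) = r_max · M^η / (M^η + c^η)          (Hill)
```

and each wheel's direct drive saturates in the engine/friction balance:

```
f_j = v_max,j · E_j T(M) / (E_j T(M) + F_j (1 − R(M)))
```

Cross-cycle learning spillovers `K` (4×4, zero diagonal, spectral radius
< 1; rows receive, columns influence) couple the wheels:

```
v = (I − K)^{-1} f
```

**Efficiency and economics.** The gain index `TEI-G = ‖v‖_W / ‖f‖_W`
measures spillover amplification; the bottleneck index
`TEI-B = min_j v_j / Σ_j α_j v_j` measures drivetrain balance; the global
index is `TEI = TEI-G × TEI-B`. Systems classify into four states on the
(TEI-G, TEI-B) plane: Fragmented, Emerging, Functional, Fully Integrated.
Innovation counts are linear in velocity, revenues and costs are
parameterized per wheel, and `ROI = R/E` per wheel and globally.

## Worked example

Generate a small synthetic rater file and score it:

```
$ lhsdrive fixtures --projects 2 --periods 1 --agreement high --seed 11 --out ratings.csv
$ lhsdrive score-cti --ratings ratings.csv --out cti.csv
$ cat cti.csv
project_id,period,S1,S2,S3,S4,S5,S6,S7,S8,cti,band
P001,2026-Q1,0.083333,0.083333,0.916667,0.500000,0.666667,0.583333,0.666667,0.083333,0.448333,Advisory
P002,2026-Q1,0.500000,0.916667,0.583333,0.333333,0.916667,0.916667,1.000000,0.500000,0.711667,SharedGovernance
```

Project P002's composite 0.712 places it in the Shared-Governance band:
community partners hold formal decision roles but the system is not yet
community-anchored. Pushing a CTI of 0.62 through the default drivetrain:

```python
import numpy as np, lhsdrive as L
p = L.TransmissionParams(a=10, m0=0.5, r_max=0.6, eta=2, c=0.5)
alloc = L.WheelAllocation((1,1,1,1), (1,1,1,1), (1.33, 1.05, 1.34, 1.11))
f = L.wheel_drive(0.62, alloc, p)            # [0.7275 0.5744 0.733  0.6072]
v = L.coupled_velocities(f, L.default_config().coupling)
                                             # [1.0448 0.8223 1.0079 0.8372]
s = L.efficiency_scores(v, f)
print(s.tei_g, s.tei_b, s.tei)               # 1.4050  0.8861  1.2449
```

At this maturity the transmission passes 77 % of engine capacity
(`T = 0.7685`) and removes 36 % of contextual friction (`R = 0.3636`);
spillovers amplify the weighted velocity norm by 40 % (TEI-G 1.405), and
the slowest wheel (education, 0.822 month⁻¹) holds the system at 89 % of
its mission-weighted mean speed (TEI-B 0.886).

A full Monte Carlo sweep (hyperparameters re-sampled each iteration,
per-project CTI and resources re-drawn, 95 % simulation intervals across
iterations):

```
$ lhsdrive montecarlo --iterations 500 --seed 1 --out mc/
$ lhsdrive report --projects mc/projects.csv --out report/
```

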