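# pomnet

Analysis pipeline for microbial communities during simulated particle
sinking: DNA stable-isotope-probing (SIP) incorporator identification,
particle-attached (PA) vs free-living (FL) lifestyle classification,
alpha diversity, and random-matrix-theory (RMT) thresholded
co-occurrence networks with module and keystone (Zi–Pi) analysis.

It is written for microbial ecologists working with 16S OTU tables from
density-gradient SIP experiments who want the full analysis chain —
rarefaction → diversity → incorporator calls → lifestyle odds ratios →
ecological networks — as tested, scriptable Python, with a synthetic-data
generator that plants known modules, hubs, incorporators and lifestyle
preferences so every stage can be validated end to end without sequencing
data.

## The statistics at the core

- **Incorporator ("active" OTU) rule.** After pooling gradient fractions
  inside a heavy buoyant-density window (default 1.730–1.746 g/mL,
  densities from refractometer readings via
  ρ = −75.9318 + 99.2031x − 31.2551x²), an OTU is active when
  RA(¹³C heavy) − RA(¹²C heavy) ≥ δ* = 0.01.
- **Lifestyle odds ratio.** log10(RA_PA / RA_FL) on replicate means;
  > 0 is PA preference, < 0 FL preference, a sign switch across pressure
  levels is a dual lifestyle, and zeros in one fraction give exclusive
  calls.
- **RMT threshold.** The correlation cutoff t* is where the eigenvalue
  nearest-neighbour spacing distribution of the thresholded Pearson
  matrix transitions from GOE (Wigner–Dyson, correlated noise) to
  Poisson e^(−s) statistics; edges are pairs with |r| ≥ t*, signed by r.
- **Topology and keystones.** avgK = 2L/N, average clustering, mean
  geodesic distance over connected pairs; greedy-modularity modules with
  Newman's Q; per-node Zi (within-module degree z-score) and Pi
  (participation, 1 − Σ (k_m/k)²) with roles at the 2.5 / 0.62
  thresholds; Maslov–Sneppen degree-preserving rewired nulls.

See `docs/methods.md` for the full model description and numerical
choices.

## Worked example

Run the numbered analysis scripts (or `pomnet simulate --out run --seed 1`
for the same thing in one step):

```bash
python analysis/01_simulate.py
python analysis/02_diversity.py
python analysis/03_sip_incorporators.py
python analysis/05_network.py
```

which prints, for seed 1:

```
community table: 100 OTUs × 60 samples (depth 10475)
planted: 4 modules, 4 hubs, 10 incorporators
...
heavy window (1.73, 1.746) g/mL; 10 active OTUs called
vs planted incorporators: recall 1.00, precision 1.00
...
t* = 0.30; 100 nodes, 1310 links (677+/633-), 4 modules, Q = 0.537
null Q = 0.123 ± 0.005 (p = 0.039)
```

Reading: the ten OTUs that took up the labeled substrate are exactly the
ten whose heavy-fraction abundance rose by ≥ 1 percentage point under
¹³C; the co-occurrence network splits into the four planted modules, and
its modularity (0.537) sits far above the degree-preserving null
(0.123 ± 0.005), the signature of non-random ecological structure.
Intermediate tables (diversity per sample, active calls, lifestyle
records, edge list, Zi–Pi roles, network statistics) land in
`results/`, and `analysis/06_report.py` consolidates them.

The same stages are available as a CLI (`pomnet simulate | rarefy |
diversity | sip-call | lifestyle | network | report`) and as library
functions (`pomnet.rarefy`, `pomnet.identify_active_otus`,
`pomnet.classify_lifestyles`, `pomnet.rmt_threshold`, …).

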