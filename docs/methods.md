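# Methods

pomnet analyzes microbial communities from simulated particle-sinking
incubations along four axes: alpha diversity of rarefied OTU tables,
identification of substrate-incorporating ("active") taxa from DNA
stable-isotope-probing (SIP) density gradients, particle-attached (PA) vs
free-living (FL) lifestyle classification by abundance odds ratios, and
co-occurrence network analysis with a random-matrix-theory (RMT)
correlation threshold, greedy-modularity modules, Zi–Pi keystone roles and
degree-preserving random nulls. A synthetic-data generator with planted
ground truth makes every stage testable end to end.

## Table handling and diversity

Counts are rarefied to a common depth by multivariate-hypergeometric
subsampling (without replacement) per sample; the study-anchored default
depth is 10,475 reads. OTUs that become all-zero are dropped (flagged in
the log) because constant rows have undefined correlations downstream.
"Detected" for the prevalence filter means count > 0; the network-input
default of ≥ 7 samples encodes the more-than-six-samples rule.

Diversity indices are computed after rarefaction. Shannon entropy is
reported in nats by default with the log base recorded in the output
table (toolchains differ in their base conventions, so it is explicit).
Simpson evenness is E = (1/D)/S_obs with D = Σ p_i²; a finite-sample
variant using Σ n_i(n_i−1)/(N(N−1)) is available by flag because the
index name alone does not pin down the estimator. Chao1 uses the classic
form S_obs + n1²/(2·n2), switching to the bias-corrected form
S_obs + n1(n1−1)/(2(n2+1)) when there are no doubletons. ACE uses the
standard coverage estimator with rare cutoff 10 and falls back to Chao1
(with a warning) when every rare read is a singleton, where its coverage
term is undefined.

## SIP incorporator calling

Refractometer readings convert to CsCl buoyant density by the empirical
quadratic ρ = −75.9318 + 99.2031·x − 31.2551·x², valid (and strictly
monotone) on the refractometer range x ∈ [1.33, 1.46]; inputs outside
that range raise, which catches density/RI unit mix-ups.

"Heavy" fractions are those inside a configured buoyant-density window,
default [1.730, 1.746] g/mL following common full-labeling SIP practice;
the window is a required, logged analysis choice recorded in every run
manifest. When several fractions fall in the window their OTU
relative-abundance vectors are pooled by weighted mean — weights are
qPCR copy numbers when available (fractions differ in DNA mass),
otherwise equal.

An OTU is called active when its relative abundance in the pooled ¹³C
heavy fraction exceeds that in the ¹²C heavy fraction by at least
δ* = 0.01, i.e. one percentage point of the community; the rule operates
on the *difference* of relative abundances, not a ratio, and a negative
difference never passes. Missing OTUs count as zero. The calls are
deterministic given the profiles; inputs that do not sum to one are
rejected so raw counts cannot slip through.

## Lifestyle odds ratios

The lifestyle odds ratio of an OTU at a pressure level is
log10(RA_PA / RA_FL) computed on replicate-mean relative abundances;
replicates are averaged before the ratio because one ratio per OTU per
pressure is the unit of interpretation. Positive values mark PA
preference, negative FL preference. No pseudocount is added: an OTU with
zero abundance in exactly one fraction is an *exclusive* call rather than
a number (an optional pseudo-abundance flag exists for sensitivity
analysis). Calls are made only where the OTU reaches the 1 % abundance
floor in at least one fraction at that pressure. An OTU whose numeric
ratio changes sign across pressures is *dual*; mixed patterns that
involve only exclusives on one side stay unclassified because no sign
switch of the numeric ratio was observed.

## Network inference

The association matrix is pairwise Pearson correlation between OTU rows
of the prevalence-filtered, rarefied relative-abundance table, computed
on untransformed proportions with zeros kept as zeros (a log10(x + ε)
flag exists; no blank-filling or imputation is applied, for determinism).
Constant rows are excluded with a warning.

The edge threshold is selected by the RMT transition of the eigenvalue
nearest-neighbour spacing distribution (NNSD): correlated noise produces
GOE (Wigner–Dyson) spacing statistics, while a decoupled
signal-plus-blocks matrix produces Poisson spacings P(s) = e^(−s). For
each candidate threshold on the grid 0.30–0.99 (step 0.01) entries with
|r| below the threshold are zeroed, rows with no surviving off-diagonal
entry are removed, and the spectrum of the remaining matrix is unfolded
with a cubic smoothing spline of the cumulative spectral density
(smoothing parameter n^1.25, which tracks the global density shape while
leaving level fluctuations intact; exact degeneracies are collapsed
before fitting, and non-monotone spline wiggles are clipped at zero).
Spacings are binned into ⌈√m⌉ equal-probability bins of the unit
exponential and chi-square tested. A threshold is Poisson-consistent when
the exponential fits at p > α (default 0.05) *or* fits strictly better
than the Wigner surmise (π/2)·s·e^(−πs²/4) scored on the same bins — the
model-comparison arm makes the scan robust to the occasional false
rejection expected when testing ~70 grid points at α = 0.05. The
selected t* is the smallest grid value that is Poisson-consistent and
stays consistent for the rest of the grid. Spectra with fewer than 10
surviving rows or spacings are treated as Poisson-degenerate (a
near-diagonal matrix carries no level repulsion by construction); scans
on matrices below 20 OTUs are refused outright.

The network has an edge for every pair with |r| ≥ t*, signed by the sign
of r. Isolated OTUs are excluded from the node set, which is why "total
OTUs" and "total nodes" differ. All topology statistics are computed on
the sign-ignored simple graph: average connectivity avgK = 2L/N, average
clustering coefficient (Watts–Strogatz local clustering averaged over
nodes), and average geodesic distance over *connected* node pairs only —
these networks are typically disconnected, so an all-pairs mean would be
infinite. Sign affects only the positive/negative link tallies.

Modules come from greedy agglomerative modularity maximization
(Clauset–Newman–Moore, via networkx) on the unweighted sign-ignored
graph; nodes and edges are inserted in sorted order and module ids
assigned by size then lexicographic smallest member, so partitions are
reproducible. Q is Newman's Σ_s (l_s/L − (d_s/2L)²); its mathematical
range is [−1/2, 1) even though it is often loosely described as 0-to-1.

Zi is the z-score of a node's within-module degree against its module's
members (defined as 0 when the module's within-degrees have zero
spread); Pi = 1 − Σ_m (k_i,m/k_i)². Roles follow the four-quadrant rule
with thresholds Zi = 2.5 and Pi = 0.62, both hub-side comparisons
inclusive: network hub (Zi ≥ 2.5, Pi ≥ 0.62), module hub (Zi ≥ 2.5,
Pi < 0.62), connector (Zi < 2.5, Pi ≥ 0.62), peripheral otherwise.

Random nulls are Maslov–Sneppen double-edge swaps with attempted-swap
semantics (default 100 × L attempts per rewire, 100 rewires); each
rewired graph preserves the degree sequence exactly. Empirical two-sided
p-values use the (r+1)/(n+1) correction. Graphs that admit no swap (a
star) yield a null equal to the observed network, with a warning.

## Synthetic data: what it emulates, and what it does not

`generate_modular_table` plants block correlation: OTU i in module m has
latent z_i = √b·g + s_i·√(a_i − b)·f_m + √(1 − a_i)·ε_i per sample, with
a = within-module and b = between-module correlation and s_i ∈ {+1, −1}
alternating within each module. The sign alternation means same-module
pairs correlate at |r| = a with both signs — as real co-occurrence
modules do — and makes the module factor cancel from sample totals,
which stops compositional closure from leaking module structure into
between-module correlations. Hub OTUs (first member(s) of each module)
load more strongly (a_hub = a + 0.6(1 − a)). Latent log-abundances are
μ_i + 0.6·z_i with per-OTU means μ_i ~ N(0, 0.6²); counts are
multinomial at the sequencing depth on the per-sample softmax
composition. One global seed drives deterministic per-operation
sub-streams.

`generate_lifestyle_pairs` produces paired PA/FL multinomial samples in
which each OTU's expected PA:FL relative-abundance ratio equals
10^effect *exactly*. Both compositions must sum to one, which is only
possible when effects are mixed-sign (or zero); a one-parameter
exponential tilt, solved with Brent's method, equalizes the two
normalizers. Exclusive OTUs (effect ±∞) carry mass on one side only,
with the two exclusive totals equalized since they are free generator
choices. All-same-sign nonzero effect maps are rejected as infeasible —
that configuration has no valid pair of compositions.

`generate_sip_profiles` models each OTU's across-fraction abundance as a
Gaussian over buoyant density centered at an OTU-specific base density,
with the 15-fraction grid spanning 1.755 down to 1.615 g/mL and a small
lognormal measurement noise (σ = 0.02) per fraction. Incorporators shift
by heavy_density_shift × 0.717 (the ¹³C atom fraction of the labeled
substrate) in the ¹³C incubation; the ¹²C control's 1.3 atom % is
effectively natural abundance and is treated as the unshifted baseline,
so the planted ¹³C-vs-¹²C center difference is exactly the product of
the configured shift and atom fraction. Base densities are uniform on
[1.718, 1.726] g/mL. That spread (0.008 g/mL) is deliberately kept below
the labeling shift (0.0143 g/mL at the default 0.02 g/mL full-labeling
shift): in real full-labeling SIP the density shift exceeds the
within-community GC-driven spread, and that ordering is what makes a
fixed heavy window informative. With a spread much wider than the shift,
labeled and unlabeled peak densities interleave and no window can
recover rare incorporators under the absolute one-percentage-point rule
— scaled-down shift therefore implies scaled-down spread.

The generator does **not** emulate: read-level sequencing error or
chimeras, 16S copy-number variation, overdispersion beyond multinomial
sampling, fraction-to-fraction DNA recovery variation beyond the
lognormal noise, or taxonomic structure. Passing recovery tests
demonstrate that the estimators invert the generator's planted
mechanisms at realistic depths and sample sizes; they do not certify
performance under real-data artifacts such as batch effects or
compositional zeros at low depth.

## Problem sizes and numerical tolerances

Default study conditions: 100 OTUs, sequencing depth 10,475, 15 gradient
fractions, ¹³C/¹²C atom fractions 0.717/0.013, heavy window
[1.730, 1.746] g/mL, δ* = 0.01, lifestyle floor 0.01, prevalence ≥ 7
samples, threshold grid 0.30:0.99:0.01, α = 0.05, 100 nulls.

Recovery analyses use: module recovery on 200 OTUs × 4 modules × 60
samples (within r = 0.9, between 0); incorporator recovery at the
100-OTU default over replicate seeds; lifestyle sign recovery on 200
OTUs at |effect| ≥ 0.5 over 10 replicate pairs; modularity-vs-null on
80-OTU tables with 20 rewires at 20 × L attempted swaps each. Sixty
samples per group reflect the triplicate × condition × fraction scale of
gradient-resolved amplicon designs while giving the NNSD scan spectra
large enough to test.

Tolerances: fraction normalization 1e-9; relative-abundance column sums
1e-9 (inputs to incorporator calling 1e-6); density inversion 1e-6 (via
Brent); Pearson oracle agreement 1e-12. Ties in active-call sorting
break by OTU id; greedy-modularity ties are fixed by sorted insertion
order.

## Known limitations

- The NNSD scan has limited power below ~100 surviving OTUs; on small
  planted matrices it tends to accept at the low end of the grid, where
  weak compositional correlations may remain as edges. Module detection
  is robust to these extra edges, but edge lists at low t* should not be
  read as curated interactions.
- Greedy modularity is a heuristic; on adversarial small graphs its Q
  can sit slightly below the exhaustive optimum (bounded at 0.05 in the
  test suite).
- The exact-ratio construction for lifestyle pairs fixes expected
  ratios, not per-replicate biological variability; replicate scatter is
  purely multinomial.
- Rewired nulls preserve degrees but not sign structure; positive and
  negative links are rewired as one population, matching the
  sign-ignored topology statistics they are compared against.
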