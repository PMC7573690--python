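# Methods

## The quantity under study

For each organism we consider the proteins whose homo-oligomer state is
annotated: a protein either acts as a monomer (k = 1) or assembles into a
complex of k identical subunits. The frequency of state k is

    f_s(k) = N_k / N_T,

with N_k the number (or summed abundance) of proteins in state k and N_T the
denominator. Two denominator conventions are implemented because published
frequency plots are ambiguous between them:

- `all-known` (default): N_T = all proteins with any known homo-oligomer
  state, monomers included. Frequencies over the full support sum to 1.
- `parity-subset`: N_T = the proteins in the selected parity class only, so
  even-k frequencies renormalize to 1 before model fitting.

Subunit numbers above `k_max` (default 24) are pooled into an overflow bin
that stays in the denominator but is excluded from per-k frequencies; extreme
annotations are sparse and unstable, and no fit uses them.

## The resource–precision model

Two ingredients, both per protein complex:

- synthesis energy E(k) = a · L · k, with a = 4.5 ATP per amino acid and L
  the average protein length (defaults 270 aa bacterial, 360 aa eukaryotic).
  The function returns the absolute ATP count with these constants;
  downstream use treats it as a relative cost.
- reaction precision: each subunit carries one binary occupancy state, so a
  k-mer supports M^k = 2^k statistical arrangements and Prec ∝ 2^(−k). The
  general M is a parameter of `n_arrangements`, not a separate model.

Balancing cost against precision yields the predicted frequency
f_s(k) ∝ k / 2^k. The fit (`fit_resource_model`) has two modes:

- `scaled` (default): one-parameter least squares, A = Σ f·w / Σ w² with
  w(k) = k/2^k — the closed form of min_A Σ (f_emp − A·w)².
- `normalized`: A fixed so the prediction is a probability distribution on
  the fitted support.

Both are exposed because a fitted curve on a frequency plot does not reveal
which normalization was used. The default support is the four even points
{2, 4, 6, 8}; R² is computed against the empirical mean over the support.
The capacity statistic c(k) = f_s(k)·k follows pointwise; for a normalized
distribution Σ c(k) equals the mean subunit number, which the tests use as an
identity.

For cyclic complexes, the arrangement count modulo rotation is the binary
necklace number (1/k) Σ_{d|k} φ(d)·2^(k/d); both it and the Euler totient are
computed in exact integer arithmetic (divisor enumeration, trial-division
factorization) and are property-tested against rotation-orbit enumeration and
gcd counting.

The Hill response is implemented exactly as H = s^n / (s^n + Kd). Note the
dimensional inconsistency: Kd is not raised to n, so the formula is only
scale-consistent when concentrations are expressed in units of the
half-maximal point. The conventional form s^n / (s^n + Kd^n) is available via
`kd_power=True`.

## Power-law fitting

Two estimators for two data regimes:

- **Small frequency tables** (a handful of even-k points): ordinary least
  squares of log f on log k (natural logs; the base affects neither the
  exponent nor R²). The slope's p value is the two-sided t test with n−2
  degrees of freedom — with n = 4 points this is the only standard reading
  of a reported (exponent, R², p) triple.
- **Degree sequences**: the discrete power law p(k) = k^(−γ)/ζ(γ, k_min) on
  k ≥ k_min, with ζ the Hurwitz zeta. γ̂ maximizes the likelihood; the
  negative log-likelihood is convex in γ (exponential family), so a
  golden-section search on (1+1e−6, 12) to 1e−6 suffices and is vectorized
  across candidate cutoffs. The scan over k_min candidates (every distinct
  observed value whose tail keeps ≥ `min_tail` = 10 observations and ≥ 2
  distinct values) refits γ at each candidate and picks the one minimizing
  the KS distance D = max_k |F_emp(k) − F_model(k)| over observed tail
  values; exact ties go to the smallest k_min (largest tail).

On discrete data with heavy ties, the fitted KS distance is nearly flat
across nested correct cutoffs (all candidates above the true k_min describe
the same tail), so the selected k_min jitters upward in a minority of runs
while γ̂ stays accurate. The recovery tests assert what the method actually
delivers: mode at the true cutoff, no dips into the head, and γ within tight
bands.

The goodness-of-fit p is a semiparametric bootstrap in which each replicate
resamples the empirical head (values below k_min) and regenerates the tail
from the fitted power law in data proportions, then is refit from scratch —
its own k_min scan and γ. Refitting replicates is essential: fixing k_min
anticonservatively deflates the replicate KS distances and inflates p.
p = fraction of replicates with D at least the observed D; p > 0.1 means the
power law cannot be rejected. Tail samples are drawn by inverse CDF from a
table truncated at max(10⁶, 10·max observed); the residual mass beyond the
table is below ~10⁻⁴ even for γ near 1.9 and is renormalized away.

## The synthetic-data generator

The generator emulates what the analysis needs from an annotation extract,
not the biology that produced it:

- **Proteome** (`ProteomeSimParams`): n proteins; a `known_fraction` (default
  0.3 — annotation coverage of oligomer state is small in real proteomes)
  carry a state drawn from weights w(k) ∝ k/2^k for even k,
  `odd_suppression`·k/2^k for odd k > 1 (default 0.3 — the observed even/odd
  asymmetry, imposed as a single multiplier because the analysis only
  observes it), and a free `monomer_weight` (default 0.5, comparable to the
  dimer weight; monomers sit outside the even-k fit). Lengths are log-normal
  (σ = 0.45) around `mean_length_aa` = 270; abundances log-normal with
  dispersion σ = 1.5 (a few orders of magnitude, as in real copy-number
  data). Category labels are assigned independently of k.
- **Network** (`NetworkSimParams`): each node is in the power-law tail with
  probability `tail_fraction` (default 0.5), drawing its degree from
  p(k) ∝ k^(−γ) truncated at `k_max` = 10 000 with γ = 2.5, k_min = 5;
  otherwise from a Poisson head (mean 2.0) truncated below k_min by
  rejection. The degree sum is forced even by incrementing the largest
  entry, preserving the tail's truncation boundary. Edges are realized by
  stub matching with rejection of self-loops and duplicate edges; unmatched
  stubs are discarded after 100·E pairing attempts and reported
  (`G.graph["discarded_stubs"]`), so the realized degree sequence
  underestimates hub degrees slightly (~1–2 % of stubs at these densities).

What the generator does **not** emulate: correlations between oligomer state
and degree, between abundance and state, hetero-oligomers, splice variants,
annotation biases (well-studied proteins are annotated more often), or
degree–degree correlations beyond what stub matching induces. Passing tests
therefore demonstrate that the estimators recover the structure they assume,
not that real proteomes satisfy those assumptions.

## Annotation parsing

Free-text subunit annotations are mapped by vocabulary: Greek-numeral names
(monomer → 1 … homododecamer → 12) and numeric "homo-N-mer" forms. An
annotation naming several homo states takes the first-mentioned one (the
primary-description convention of curated subunit text), recording all states
in an ambiguity note; "min"/"max" policies are available. Hetero-only
annotations are excluded; a bare "Homooligomer" with no number is flagged
homo-oligomeric but carries no k and is excluded from distributions.
Unparseable text yields unknown, never an exception.

## Problem sizes and numerical choices

- Distribution convergence checks: n = 100 000 proteins, total-variation
  tolerance 0.02.
- γ/k_min recovery: 50 seeded degree sequences of n = 10 000 at the
  generator defaults (γ = 2.5, k_min = 5, Poisson(2) head on half the
  nodes); bands γ ± 0.05, k_min ± 2, required in ≥ 90 % of runs.
- Bootstrap calibration: 20 runs of n = 2 000 pure-tail samples at
  n_boot = 200 — sizes chosen so the full-refit bootstrap stays desk-scale
  while the per-run p retains ~0.005 resolution.
- MLE tolerance 1e−6; the estimator is verified against a brute-force
  likelihood grid at step 1e−4 and against the continuous approximation
  1 + n/Σ ln(x_i/(k_min − ½)) within 0.1 for γ ∈ [2, 3].
- Degenerate inputs: an all-identical tail raises a divergent-estimate
  error (the likelihood increases without bound); empty filters raise
  empty-input errors; malformed table rows are counted and skipped.

## Limitations

- The KS-minimizing cutoff selection inherits the flat-landscape jitter
  described above; report k_min with its scan table, not as a point fact.
- The bootstrap p is approximate for very heavy tails (γ < 2) where the
  truncated sampling table carries non-negligible residual mass.
- Stub matching is not a uniform sampler of simple graphs with the given
  degree sequence; for the degree statistics computed here the bias is
  immaterial, but clustering-sensitive quantities should not be read off
  these graphs.
- Abundance-weighted frequencies treat missing abundance as zero weight,
  which underrepresents poorly quantified proteins.
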