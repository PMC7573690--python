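# oligodist

Most proteins do not act alone: a large share of any proteome assembles into
homo-oligomers — complexes of *k* identical subunits. Across organisms the
frequency of *k*-mers falls off steeply and unevenly: dimers and tetramers are
common, large and odd-numbered complexes are rare. `oligodist` is an analysis
package for studying that distribution. It computes subunit-number frequency
distributions from annotated proteome tables, fits power laws to frequency
tables and to protein–protein interaction (PPI) degree data, and fits a
**resource–precision model** that explains the distribution as a trade-off
between synthesis cost and reaction precision.

## The model

For a protein of *k* identical subunits, each of average length *L* amino
acids:

- **Energy cost** of synthesis, at 4.5 ATP per amino acid:
  `E(k) ∝ 4.5 · L · k` — linear in *k*.
- **Precision** of the binding reactions a *k*-mer can implement: each subunit
  contributes a binary occupancy state, giving `2^k` statistical arrangements
  (`M^k` in general), so `Prec ∝ 1/2^k`.
- Balancing the two predicts the proteome frequency of *k*-mers:

  ```
  f_s(k) ∝ k / 2^k,   f_s = N_k / N_T
  ```

  where `N_k` counts proteins with *k* subunits and `N_T` is the total number
  of proteins with a known homo-oligomer state.
- The **capacity** statistic `c(k) = f_s(k) · k` reads *k* as a bit count
  (`M = 2^k` signal levels); normalized over even support {2,4,6,8} the model
  gives `c(2) = c(4) = 8/7`.
- For cyclic complexes the arrangement count modulo rotation is the **binary
  necklace number** `(1/k) Σ_{d|k} φ(d) · 2^{k/d}` (Euler totient φ).

On the network side, PPI degree sequences are fitted with the discrete
power law `p(k) ∝ k^(−γ)` for `k ≥ k_min` (Hurwitz-zeta normalization,
maximum likelihood), with `k_min` chosen by minimizing the Kolmogorov–Smirnov
distance and a semiparametric bootstrap goodness-of-fit *p* (each replicate
refit from scratch; `p > 0.1` means the power law cannot be rejected).

A synthetic-data module generates annotation tables and degree sequences with
exactly this structure, so the whole pipeline is testable without downloading
UniProt/STRING extracts; the readers accept the real formats (tab-separated
annotation tables with free-text subunit descriptions; STRING-style edge
lists) when you have them.

## Worked example

Running the numbered analysis scripts on the simulated study data:

```sh
python analysis/01_simulate_datasets.py
python analysis/02_oligomer_distributions.py
python analysis/03_fit_resource_model.py
python analysis/04_ppi_degree_analysis.py
```

prints, among other output:

```
even-k renormalized f_s: {2: 0.562, 4: 0.274, 6: 0.112, 8: 0.036} (model k/2^k predicts {2: 0.571, 4: 0.286, 6: 0.107, 8: 0.036})
log-log OLS on 6 even-k points: exponent -2.725, R^2 0.886, p 0.0051
resource-precision fit f_s = A*k/2^k: A = 1.1202, R^2 = 0.9995
power-law tail: gamma = 2.520, k_min = 5, n_tail = 5034, KS D = 0.0052, bootstrap p = 0.815 (p > 0.1: power law not rejected)
```

Reading: the even-subunit frequencies of a 20 000-protein simulated proteome
(30 % annotated) renormalize to within a few hundredths of the `k/2^k`
prediction; the least-squares scale fit explains 99.9 % of their variance; and
the degree sequence of the companion 10 000-node network is recovered with
γ = 2.52 and cutoff k_min = 5 (simulated at γ = 2.5, k_min = 5), with a
non-rejecting bootstrap *p*. Tables land under `results/`.

The same computations run on real extracts via the CLI
(`oligodist freq`, `oligodist fit-model`, `oligodist fit-powerlaw`,
`oligodist ppi`, `oligodist run-all`); the pipeline emits every headline
statistic of the study design — mean degree 2E/N, per-class average degrees,
the γ/k_min/n_tail/p of the degree fit, and the OLS exponent/R²/p of the
even-k fit — so comparing against a curated dataset is one command once the
files are fetched.

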