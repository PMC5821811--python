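# avalanches

Statistics of neuronal avalanches for spike-raster data: avalanche
extraction with data-driven time binning, rigorous truncated power-law
inference for the size and duration distributions, the three-exponent
scaling relation, and surrogate-based analysis of memory between avalanche
sizes. A critical branching-process simulator with known ground truth backs
every stage, so the whole pipeline is testable without recordings.

## Who this is for

Groups analyzing population spike data — calcium imaging of dissociated
cultures, MEA recordings, spike-inferred rasters — who want to ask whether
the activity is consistent with critical, scale-free avalanche dynamics and
*which* critical exponents it carries, without hand-picking fit ranges.

## The science in brief

Pool all spikes, bin time at the mean inter-spike interval, and call every
maximal run of occupied bins an avalanche with size *S* (spikes) and
duration *T* (bins). Near a critical point,

    f(S) ~ S^(−τ),   f(T) ~ T^(−α),   ⟨T⟩(S) ~ S^γ,

and the exponents obey the scaling relation **(α − 1)/(τ − 1) = 1/γ**. A
critical branching process (branching ratio m = 1, the mean-field class)
has τ = 1.5, α = 2.0, γ = 0.5; different exponent sets that still satisfy
the relation indicate different universality classes.

τ and α are estimated by maximum likelihood on a truncated discrete power
law, with Kolmogorov–Smirnov goodness of fit (a fast analytic p-value and
an accurate surrogate-resampling p-value), scanned over *all* admissible
cutoff intervals; the reported fit is the widest interval — in decades —
whose power-law hypothesis is not rejected, and a flat exponent plateau
across intervals is the signature of genuine scale-free behavior. γ comes
from least squares of log mean duration against log size. Memory between
avalanche sizes is quantified by δP(λ): the difference between the
empirical CDF of the size ratio S_{i+j}/S_i and its expectation under
random reshuffling, with uncertainty bands from the surrogate ensemble, a
clustering excess on λ ∈ (1/3, 3), and a memory length j* — the lag at
which the correlations disappear. Quasi-synchronous network bursts
(system-size events) are screened out before any fit.

See `docs/methods.md` for conventions, calibration details and measured
finite-size accuracy.

## Worked example

Simulate a critical branching process and run the full inference:

```python
from avalanches import (BranchingConfig, simulate_branching_avalanches,
                        scan_intervals, fit_gamma, scaling_relation_check)

truth = simulate_branching_avalanches(BranchingConfig(m=1.0, n_avalanches=50_000, seed=7))
cat = truth.catalog
keep = cat.fit_mask  # drop cascades truncated at the absorbing size cap

tau = scan_intervals(cat.sizes[keep], n_surrogates=1000, seed=1).selected
alpha = scan_intervals(cat.durations[keep], n_surrogates=1000, seed=2).selected
gamma = fit_gamma(cat, tau.model.x_low, tau.model.x_high)

chk = scaling_relation_check(
    (tau.exponent, tau.uncertainty_2sigma),
    (alpha.exponent, alpha.uncertainty_2sigma),
    (gamma.gamma, gamma.gamma_2sigma),
)
```

which prints (formatted):

```
tau   = 1.493 +- 0.006  on [2, 659400], p_surrogate = 0.02
alpha = 1.947 +- 0.026  on [14, 3138], p_surrogate = 0.04
gamma = 0.532 +- 0.007
gamma predicted from (tau, alpha): 0.521 +- 0.015; consistent: True
```

Reading: the size exponent lands on the mean-field 1.5 almost exactly over
nearly six decades; the duration exponent and γ sit a few percent off 2.0
and 0.5 — the documented slow corrections to scaling of the branching
process at this sample size (see `docs/methods.md`), already far smaller
than the ±0.1–0.4 uncertainties typical of real recordings — and the three
exponents are mutually consistent with the scaling relation. The surrogate
p-values are the stricter of the two goodness-of-fit measures; small values
at this very large sample size reflect those same detectable finite-size
corrections, not a failure of scale-freeness over the fitted range.

The same pipeline runs from the shell on raster CSVs
(`neuron_id,frame` rows; see `avalanches --help`):

```
avalanches report recording1.csv recording2.csv --seed 1 --out results/
avalanches extract recording1.csv --out catalog.tsv
avalanches scan catalog.tsv --variable size --surrogates 1000 --seed 1
avalanches correlate catalog.tsv --jmax 10 --seed 1
```

`report` chains ISI → binning → extraction → SSE screening → interval scans
→ γ fit → scaling check → δP, writes a JSON report with every seed,
selected interval and rule id recorded, and regenerates bit-identically
from the same config and inputs.

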