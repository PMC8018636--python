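# Methods

## Model and procedure

The package treats a published pair of per-group mean OTU-frequency vectors
as the attack surface of a membership-inference test.  The target's profile
is binary presence/absence; abundance information is deliberately discarded
(binary calls are less sensitive to protocol and sequencing-depth variation
than relative frequencies, and a frequency-valued query does not reliably
gain power because the accumulated small differences inflate the sample
variance along with the mean).

Given the query `y`, reference summary `r` and case summary `c` over the
same `t` OTUs, the per-OTU distance is `d_j = |y_j − r_j| − |y_j − c_j|`,
which for binary `y` reduces to `(1 − 2 y_j)(r_j − c_j)`.  The test
statistic is `Z = (d̄ − μ₀) / (s/√t)` with `s` the sample standard
deviation of the `d_j` (the `t−1` denominator is used; at the OTU counts
where the test is meaningful the difference from `t` is negligible).  The
normality of `Z` under the null rests on the central limit theorem across
OTUs, so `t ≤ 50` triggers a warning rather than an error — the
approximation degrades gradually.  If every `d_j` is identical (`s = 0`,
e.g. the two summaries coincide on every OTU), the statistic is undefined
and a `DegenerateVarianceError` is raised rather than returning ±∞: such a
query/summary combination carries no membership signal.

The decision is a pair of one-sided tests, each at level α: `Z` above the
upper critical value flags a case member, below the lower one a reference
member.  The total size against the outsider hypothesis is therefore 2α;
this is stated explicitly to avoid silent size confusion.  α must lie in
(0, 0.5).

### Critical values

Two null specifications are supported.  `"normal"` uses exact N(0, 1)
quantiles (the α = 0.05 threshold is 1.6449; the commonly quoted 1.65 is a
rounding).  When simulation context exists, empirical critical values from
percentiles of simulated outsider statistics (`Z^P`) are preferred, because
the finite-sample null deviates from N(0, 1): conditional on one realized
pair of group samples, the outsider statistics carry a random location and
scale (the summaries are themselves noisy at small `n`).  Quantiles use the
linear-interpolation ("type 7") definition throughout.  At least 20 null
draws are required for empirical criticals; the power machinery defaults to
far more.

## Synthetic populations

The simulation framework generates the study conditions the test is
evaluated under.  Per-OTU presence probabilities are i.i.d.
`p_j ~ Beta(π₁, π₂)`; individuals are independent `Bernoulli(p)` vectors;
group summaries are column means of materialized samples (marginally
`Binomial(n, p_j)/n`; a direct binomial sampler is provided for when no
member queries are needed, and the two routes are tested for distributional
equivalence).  Four Beta parameterizations cover the plausible shapes of a
community's frequency spectrum: (1, 1) — uniform, the indifference prior;
(0.1, 1) — few high-frequency taxa; (1, 0.1) — many high-frequency taxa;
(0.1, 0.1) — a U-shaped mix of constitutive and opportunistic taxa.  The
benchmark design points are `t = 2000` OTUs (roughly the species count of
the human gut community) with `n_R = n_C = 10`, and `t = 20000`
(strain-level resolution, ~10 strains per species) with `n = 100`.

What the generator does **not** emulate: correlated OTU occurrences (real
communities are ecologically structured; correlation is handled analytically
only, see below), within-individual abundance structure, sequencing noise or
detection thresholds, and systematic case/control composition differences
(handled analytically via the shifted null).  Passing tests therefore
demonstrate the statistic's behavior under independent Beta-Bernoulli
communities, a lower bound on realism that the robustness across the four
Beta shapes partially mitigates.

### Randomness

Every sampler is a pure function of its parameters and a seed.  A root seed
spawns named, order-independent substreams (population, sample-R, sample-C,
null queries, true-positive selection; one set per replicate, one per grid
cell), so changing one knob — say, the number of null draws — never
perturbs unrelated draws, and grids rerun bit-for-bit identically.

## Power estimation

Per replicate the simulator draws one population, materializes both group
samples, and computes three families of statistics with μ₀ = 0: `Z^P` from
fresh outsiders, and `Z^{R+}`, `Z^{C+}` from uniformly selected member rows
of the respective samples — the member's own profile is inside the summary
it is tested against, which is the literal membership scenario.  Default
draw counts are 100 per family per replicate, matching the original
simulation design; β estimates at 100 draws cannot resolve thresholds like
0.01, so binomial Monte-Carlo standard errors `√(β(1−β)/n)` are always
reported and the verification suites use ≥ 1000 draws.  Degenerate-variance
draws (possible at tiny `t`) are dropped and counted, never imputed.

`β^C` is the fraction of `Z^{C+}` below the upper empirical critical value;
`β^R` the fraction of `Z^{R+}` above the lower one — each cell is judged
against its own simulated null, not against ±1.6449.

**Single population vs. pooled replicates.**  By default one population
underlies all draws of a run (`n_reps = 1`), which is the per-panel design
the benchmark β values use.  Conditional on one sample pair, however, the
outsider statistics carry a random offset comparable to their spread, so
the *marginal* null distribution — the thing that is approximately
N(0, 1) — must be measured by pooling across fresh populations
(`n_reps > 1`).  The calibration check uses 100 replicates × 10 draws; the
monotonicity grid pools 25 replicates × 50 draws per cell so that the
binomial standard error is an honest uncertainty measure for cell
comparisons.  Problem sizes in the test suite (3 × 3 grid over
n ∈ {10, 100, 1000}, t ∈ {20, 1000, 20000}, 1250 draws per cell) are chosen
to resolve the orderings of interest while keeping a full run of the suite
in the minutes range; the full published-style sweep
(n = 10…1000, t = 20…20000, finer steps) runs through the same
`power_grid` entry point.

KDE density curves of the statistic distributions use a Gaussian kernel
with Scott's-rule bandwidth (the bandwidth is a free choice; Scott is the
standard default and is recorded in the output).  Curves are exported as
(grid, density) tables; rendered plots are a convenience layer behind an
optional matplotlib extra.

## Analytic corrections

**Correlated OTUs.**  With average pairwise correlation ρ̃ among the
distances, `V(d̄) = V(d)/t · (1 + ρ̃(t−1))`, equivalently an effective
independent-OTU count `t_e = t / (1 + ρ̃(t−1))`.  ρ̃ is admissible on
`[−1/(t−1), 1]`; at the lower endpoint `t_e` is infinite, below it the
variance would be negative and a parameter error is raised.  Small negative
correlations inflate `t_e` dramatically (t = 1000, ρ̃ = −0.001 → t_e = 10⁶)
while equally small positive ones halve it (ρ̃ = +0.001 → t_e ≈ 500).
Because ρ̃ cannot be read off published summaries, `t_e` is exposed as a
diagnostic, not folded into the main test.

**Divergent source populations.**  If the groups' underlying populations
differ systematically so that `E(Δ) = E(r − c) ≠ 0`, an outsider's expected
distance shifts to `μ₀* = E(Δ) − 2E(Δ)E(p)`, bounded in [−1, 1] and
vanishing as the mean presence probability approaches 0.5.  `μ₀*` can be
passed as the `mu0` parameter of the test to apply the correction.

## Numerical and design choices

- Binarization: presence iff frequency strictly > 0 by default; the
  detection threshold is exposed because real pipelines differ, but no
  principled default other than 0 exists for presence/absence calls.
- Sample variance: `t − 1` denominator (unbiasedness convention).
- Quantiles: numpy's linear interpolation everywhere.
- Degenerate inputs: identical-distance vectors raise; empty inputs raise;
  grid cells that fail are flagged in the output table rather than aborting
  the sweep.
- The s = 0 test compares `max(d) == min(d)` in addition to the computed
  standard deviation, because identical entries can leave a rounding-level
  nonzero sd.
- OTU identifiers are positional and synthetic; no taxonomy database is
  consulted, and profiles/summaries are aligned by position with an
  identifier cross-check when ids are present on both sides.

## Limitations

- Independence across OTUs is assumed by the simulator; correlated binary
  communities are not generated, so the ρ̃ correction is analytic only.
- β estimates at the default 100 draws are coarse; use the draw-count and
  replicate options for decisions near a threshold.
- The test's calibration against real (non-Beta-Bernoulli) communities is
  untested here; the uniform prior gives a conservative "minimal power"
  estimate to use at study-design time.
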