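# Methods

This package infers the optimal growth temperature (OGT) of organisms — in
particular Asgard archaea and reconstructed ancestral Asgard proteins — from
the temperature dependence of GDP binding by the translation elongation
factor EF-1A (bacterial EF-Tu). The binding optimum of EF-1A/EF-Tu tracks
the OGT of the host organism closely across prokaryotes, so a fitted binding
optimum, measured on a purified (extant or resurrected ancestral) protein,
serves as a thermometer for the organism or ancestor that carried it.

## The peak model

Binding fluorescence as a function of assay temperature t is modelled as a
skewed Gaussian-like bell curve

    F'(t) = F0 + (F* − F0) · exp(−((t − t*) / s(t))²)
    s(t)  = sL + (sR − sL) / (1 + exp(−(t − t*) / w))

with baseline fluorescence F0, peak fluorescence F*, peak temperature t*,
and a width that interpolates logistically from the left width sL to the
right width sR around t* at rate w. The five parameters (F0, F*, t*, sL,
sR) are estimated by least squares on the individual replicate datapoints
(33 residuals on the standard design of 3 replicates × 11 temperatures);
w is a fixed constant, 5 °C by default, configurable but never optimised.

The asymmetry matters because thermal activation (rising binding with
temperature) and unfolding (collapsing binding) act on different
temperature scales, so the curve need not fall as fast as it rises.

### Fitting

The sum of squared residuals is minimised with a derivative-free
Nelder–Mead simplex on the transformed coordinates

    (F0, log(F* − F0), t*, log(sL − s_min), log(sR − s_min)),

which enforces F* ≥ F0 and sL, sR > s_min by construction. The floor
s_min = 3 °C reflects an identifiability limit of the assay design: with
measurements every 10 °C, widths much below the grid spacing are not
resolvable, and without the floor the objective admits degenerate minima in
which one width collapses to a spike passing through a single datapoint
(we observed such minima on roughly 1 in 10 random 2 %-noise instances).
Three degrees is well below any plausible binding-curve width on this assay
while excluding the spike solutions.

Initialisation takes t* at the grid temperature of the maximal replicate
mean, F0/F* at the minimal/maximal mean, and both widths at 10 °C. Because
the objective is multimodal on sparse grids, the fit is multi-started: five
random restarts jittering t* by ±10 °C and the log-widths by roughly a
factor e^±1.5, plus two deterministic "narrow-flank" starts with one width
near the floor, keeping the lowest-SSE solution. Convergence tolerances
scale with the magnitude of the objective; a stalled simplex is restarted
once from its last point (Nelder–Mead can wander along flat valleys
without formally converging even when the optimum is found).

A fit is reported as non-identifiable when the fitted amplitude F* − F0 is
below 3× the pooled replicate standard deviation (a flat curve has no
meaningful peak), or when the fitted t* falls outside the fitted
temperature interval — the latter occurs genuinely when a protein's stable
range truncates the data on one side of the optimum so that the restricted
curve is monotone.

## Stable range and fit restriction

In the ThermoFluor (thermal shift) assay, dye fluorescence rises as the
protein unfolds; the grid temperature with the highest replicate-mean
intensity marks the transition from partial to complete unfolding. The
protein is treated as stable from the lowest assayed temperature up to one
grid step below that transition (ties at the maximum resolve to the lowest
tied temperature; the grid step is the minimal spacing of consecutive
assayed temperatures). The upper bound is therefore resolution-limited —
an approximate upper temperature limit rather than a fitted melting
temperature — and binding fits are restricted to this range, since binding
measured on an unfolded protein is not informative about the optimum.

## Bootstrap confidence intervals

Uncertainty in t* is quantified by a nonparametric bootstrap that mirrors
the replicate structure: for each of n_boot = 1000 bootstrap datasets, the
three replicate values at every temperature are independently resampled
with replacement, the model is refit, and the 90 % confidence interval is
taken as the 5th and 95th percentiles of the resulting peak-temperature
distribution. Percentiles use linear interpolation between order statistics
(index 1 + p·(n−1) on the sorted sample — numpy's default rule; at
n = 1000 the choice among standard conventions moves the bounds by less
than 0.1 percentile).

Implementation choices: the point estimate always comes from the full,
un-resampled data; bootstrap refits warm-start at the full-data solution
with a relaxed parameter tolerance (10⁻⁴ °C — far finer than the CI
resolution); refits that fail or are non-identifiable are dropped and
counted, and more than 10 % failures raises an error rather than reporting
a silently biased interval. Randomness derives from one root seed expanded
into per-replicate substreams (numpy SeedSequence), so results are
reproducible and independent of execution order. Percentile intervals from
3 replicates are only approximately calibrated; in our simulations at 2 %
relative noise the 90 % interval covers the generating optimum in roughly
80–97 % of runs.

The percentile interval need not contain the full-data point estimate, and
no such constraint is imposed.

## From binding optimum to OGT

The fitted binding optimum is used directly as the OGT estimate (identity
proxy), with the bootstrap interval carried through unchanged. The
supporting calibration — organisms of known OGT versus their measured
binding optima — is summarised by the Pearson product-moment correlation.
An optional linear-calibration mode maps optima through the least-squares
line fitted to the calibration table, but it is off by default: with the
identity proxy, estimates remain directly comparable to published binding
optima.

Known issue: for the four-organism calibration table shipped with the
package (MK-D1 20/19.9, S. cerevisiae 28/32.2, H. sapiens 37/33.5,
E. coli 37/43.4 °C), the product-moment formula gives r ≈ 0.889, and on the
alternative optima quoted in the narrative of the original study
(20.5, 34.6, 40.1, 40.2 °C) it gives r ≈ 0.967; the correlation of 0.9906
published alongside these numbers is not reproducible from either set. Both
datasets ship as fixtures and a test documents the discrepancy; the
standard formula is used throughout.

Thermal lifestyles are classified by thresholds at 45 °C
(mesophile / moderate thermophile) and 80 °C (moderate thermophile /
hyperthermophile). The literature draws these lines variously; these
defaults are configurable and reproduce the published class assignments
for all optima between 20 and 85 °C that we checked.

## Ancestral-sequence consensus

Ancestral sequences inferred by different reconstruction engines (e.g.
empirical-Bayes ASR in IQ-TREE, FastML, PAML) for the same node mostly
agree but differ at a minority of sites. The consensus is built per aligned
column: a unanimous state is kept; otherwise the state with the most votes
wins, with the gap character a votable state. Vote ties break toward the
state with the highest posterior probability (PP) among the methods
carrying it; since gap columns carry no PP, a gap candidate counts as PP 0
in this comparison, so residues with any evidence beat gaps. Remaining
ties fall back to lexicographic order of the state character (gap first) —
an arbitrary but deterministic final rule that makes the consensus
invariant to the input order of the reconstructions. An optional reference
("neighbor") sequence mode instead resolves any disagreement toward the
state that a supplied closely-related sequence carries at the column,
emulating curation against extant relatives.

The reported per-column PP of the consensus is the maximum PP among the
inputs carrying the chosen state (for unanimous columns likewise the
maximum across methods — the closest order statistic available from the
inputs alone), and the mean PP averages over non-gap consensus columns.
Columns where the consensus state is a gap are removed from the unaligned
export.

## Trait mapping

OGT estimates attach to tree nodes by label (leaves via taxon labels,
internal nodes via node labels; labels must be unique). The trajectory
table lists, for every annotated node, the OGT difference to its *nearest
annotated ancestor* — unannotated intermediate nodes are skipped so the
difference is always defined — and these differences telescope exactly
along any fully annotated path. Only measured or fitted values are mapped;
there is no model-based interpolation (e.g. Brownian-motion ancestral state
reconstruction) for unmeasured nodes, because the method's point is that
ancestral values are measured on resurrected proteins rather than inferred
from a trait model. Newick I/O goes through dendropy; annotations are
exported both inline as `[&ogt=…]` hot comments and as a sidecar TSV, the
sidecar being authoritative since comment dialects vary across toolchains.

## Synthetic data

All pipeline inputs can be generated with known ground truth. The binding
generator draws each datapoint from the peak model plus additive
homoscedastic Gaussian noise, by default parameterised relative to peak
fluorescence (2 % of F*) because fluorescence is in arbitrary units; values
are clipped at zero. The default design is the study design: temperatures
0–100 °C in 10 °C steps, 3 replicates (33 datapoints). The ThermoFluor
generator produces a logistic rise to a peak followed by a linear decay —
only the argmax is consumed downstream, so any unimodal shape with
controlled peak placement suffices. The ASR generator plants a truth
sequence and corrupts each method's copy independently at its error rate,
drawing per-site PPs from Beta distributions concentrated near 1 at correct
sites and lower at erroneous sites. The trait-tree generator builds a
random topology by sequential joins and evolves OGT from the root by
independent Gaussian steps per branch (truncated to 5–95 °C so optima stay
on the assay grid), attaching to every node a binding profile whose
generating optimum equals its OGT — Brownian-style evolution is a test
harness here, not a scientific claim.

What the generators do *not* emulate: temperature-dependent (heteroscedastic)
noise, instrument drift, unbound-probe background, two-transition melts,
alignment errors or among-site rate variation in the ASR inputs. Passing
parameter-recovery tests therefore demonstrates correctness of the
estimation machinery under the stated noise model, not robustness to every
artefact of real assay data.

## Problem sizes and numerical conventions

Simulation-based checks use sizes chosen to exercise the statistics
meaningfully while keeping a full test run fast: 100 seeded assays per
parameter-recovery check, 60 simulated assays × 200 bootstrap replicates
for the CI coverage check, 50 seeds for consensus-accuracy comparisons, and
20 random instances for the fit-versus-oracle agreement check (the oracle
profiles t* on a 0.1 °C grid, refitting the other four parameters at each
point from three independent warm-start chains). Analysis drivers default
to the full n_boot = 1000.

Degenerate inputs are rejected with specific errors rather than guessed at:
profiles with fewer than 6 datapoints or 3 distinct temperatures, flat melt
curves, transitions at the lowest assayed temperature, stable ranges
retaining fewer than 3 binding temperatures, empty percentile samples,
all-gap consensus columns, unequal aligned lengths, and estimates referring
to labels absent from the tree.

## Known limitations

- The stable-range upper bound inherits the 10 °C grid resolution.
- A binding optimum within ~10 °C of the stable-range edge can be genuinely
  non-identifiable from the restricted data; the fit flags this rather than
  extrapolating.
- Percentile-bootstrap coverage with 3 replicates is approximate (see
  above), and intervals can exclude the point estimate.
- The identity OGT proxy ignores any systematic offset between binding
  optimum and growth optimum; the calibration table quantifies, but does
  not correct, this relationship unless the linear mode is enabled.
- Consensus PPs are derived from the input methods' PPs only; no joint
  reassessment of the consensus sequence under a substitution model is
  performed.
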