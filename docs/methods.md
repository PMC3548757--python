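# Methods

This note records the model as implemented, the conventions chosen where
the physics admits more than one reading, the scales at which the test
suite exercises it, and what those tests do and do not establish.

## Duplex free energy

Stability of a gapless probe/fragment duplex is additive over
nearest-neighbor (NN) dinucleotide steps:

    dG = sum(step dH) - T * sum(step dS) + initiation terms + salt term
    K_eq = exp(-dG / RT),  R = 8.314462618 J/(mol K)

* **Tables.**  `data/nn_unified.tsv` bundles the unified Watson–Crick set
  (10 steps), the 51 published mismatch values (48 single internal
  mismatches plus the three tandem G·T contexts) and the GC/AT
  initiation terms, in J/mol and J/(K·mol).  Steps are written
  `XY/WZ` = 5'-XY-3' over 3'-WZ-5'; the strand-swapped presentation
  `ZW/YX` resolves to the same entry.  A *single*-mismatch context absent
  from a user table raises an explicit error; adjacent-double-mismatch
  contexts (for which no literature values exist beyond the tandem G·T
  set) contribute (0, 0) and are only counted in diagnostics.
* **Initiation.**  Each maximal run of ≥ 2 consecutively paired bases
  contributes two initiation terms.  A terminal pair is GC-class if either
  of its bases is G or C, else AT-class.  For Watson–Crick terminals this
  is the standard rule; keying on the pair rather than on one strand keeps
  duplex energy exactly invariant under swapping the strand presentation.
  An isolated single pair (between an abasic site and a helix end)
  contributes nothing: one base pair does not nucleate a stable stack.
* **Abasic sites.**  An abasic probe position (backbone present, base
  lost) cannot pair; the duplex is treated as two sub-helices joined at a
  nick, each run scored with its own stacking and initiation terms.  This
  is the most conservative reading of a backbone-only position; no
  literature value exists for the nick itself.
* **Terminal mismatches** are scored with the internal-mismatch values;
  the known extra stabilization of mismatches in the last bases is not
  modelled.
* **Salt.**  dG gains `salt_coeff * n_steps * ln[Na+]` with
  `salt_coeff = -476.976 J/mol` (the unified −0.114 kcal/mol per phosphate
  pair) and `n_steps` counting every backbone step inside paired runs,
  including unparameterized ones (phosphates exist regardless of whether
  stacking data do).  At the 1 M default the term vanishes, which is also
  the regime in which the model was found to fit best.
* **Overflow.**  K_eq exponents are clamped to ±700 with a warning; the
  clamp is never reached for realistic oligo lengths.

Two independent code paths compute dG: a scalar per-alignment reference
(`delta_g`) and a vectorized anti-diagonal "window cube" used everywhere
performance matters (`score_windows`).  They are cross-checked against
each other on hundreds of randomized cases, including abasic variants and
non-unit salt.

## Fragment enumeration and concentrations

Targets are user-supplied segments (PCR products, transcripts, ...).
Fragmentation cuts every inter-base junction independently with
probability p = 1/μ (μ = mean fragment length in bases; the p = 1/μ mapping
is the geometric mean-length identity).  Concentrations per fragment
class:

| class      | meaning                                   | concentration        |
|------------|-------------------------------------------|----------------------|
| both_cut   | cuts at both ends of the paired window     | C·p²·q^(j−1)         |
| right/left_open | one end cut, other runs past a probe end | C·p·q^j·(1 − q^E) |
| both_open  | both ends run past the probe               | C·q^(j+1)·(1−q^El)(1−q^Er) |

`j` is the paired-window length and `E` the number of segment bases
actually available for the unseen extension.  The `(1 − q^E)` factors are
a finite-segment refinement: with them, the collapsed table equals an
exhaustive enumeration of every concrete fragment at every offset
*exactly*, which the oracle tests verify to 1e−10 on ≥ 200 random
instances; as E → ∞ the published tail forms are recovered.  Enumeration
is per paired window on each strand (the reverse presentation is the
segment's reverse complement), with ≥ 2 paired non-abasic bases required.
Coordinates in all files are 1-based inclusive on the presented strand.

`prune` drops table entries whose K_eq falls below a relative threshold
(default 1e−12 of the table maximum).  It is applied to K_eq rather than
C·K_eq because the fragmentation weight depends on μ, a fitted quantity
unknown at table-build time; `prune = 0` is exactly exhaustive and is used
in every oracle test.  The fit engine never prunes: it reduces whole
window sets to per-segment sums.

## Occupancy, wash, synthesis errors, scanner

Competition is per spot: α = Σ C·K_eq(washed) / (Σ C·K_eq + 1), the
numerator restricted to K_eq ≥ K_eqW, the denominator unrestricted — the
wash as printed removes weak complexes after equilibrium without
re-equilibrating.  Wash K_eqW = 0 disables the wash.  Note that for spots
with a perfect-match target the C·K_eq spectrum is dominated by a few
near-full-overlap complexes, so at realistic settings intermediate wash
thresholds barely move α; the wash grid is then resolved by the
deterministic tie-break (smaller K_eqW, then smaller μ).

Synthesis proceeds from the 3' end (base 1 = 3'-most).  The one-error
mixture comprises the full-length probe (p_F = Π S_b B_b), each
single truncation (Π_{b<m} S_b B_b · (1 − S_m); the 3'-anchored prefix),
and each single abasic variant (p_F(1 − B_m)/B_m, computed in the direct
product form so B_m = 0 is well-defined).  The residual mass is the
≥ 2-error class with occupancy zero; emitted + residual = 1 exactly.
"Truncation plus abasic" combinations are two errors and land in the
residual.  Spot occupancy is α = Σ p_x α_x, and intensity
I(α) = MAX·exp(ln(MIN/MAX)·exp(−α·GOMP)) with natural logarithm (the
choice that makes I(0) = MIN exact).  MIN/MAX/GOMP are configuration, not
fitted (defaults 100 / 65536 / 7).

A consequence worth knowing: with realistic rates (S·B ≈ 0.9 per base)
only ~7 % of 25-mers are error-free, so spot occupancies top out near the
total emitted one-error mass (~0.25), and most intensity variation between
spots comes from sequence composition through p_F and the fragment
coverage of the probe — this is precisely how the model generates
forward/reverse brightness differences and chip effects.

## Per-chip fitting

The objective is the sum of squared differences between observed and
expected intensities over all spots with observations (missing values are
skipped, never imputed; a log-scale objective is available by flag but raw
is the default).  Free parameters: 8 synthesis rates (logit scale) and one
concentration per segment (log scale).  Fragmentation mean and wash
threshold are discrete grid dimensions; the grid winner is the highest raw
Pearson correlation, ties broken toward smaller K_eqW then smaller μ.

The minimizer is Powell's direction-set method, staged: since p_F
constrains only the *products* S_b·B_b, a first Powell pass fits the four
products (even split) plus concentrations after a coarse log-spaced
concentration scan, and a second pass opens the split into all eight
rates, re-run up to three times to reset Powell's direction set.  Seeded
jittered restarts guard the weakly identified split directions, and a
restart loop exits early once the data are reproduced to machine
precision.  The staging matters: the joint 10-dimensional surface has a
long curved product/concentration valley with shallow local dips in which
a cold-started Powell reliably stalls, while the staged search recovers
generating parameters exactly on noiseless data.  Everything is
deterministic given the config seed.

The 1-D NN search scales one step's dH by a grid of ratios, rebuilds the
K_eq forests, and reports the mean (over chips) of each chip's best
correlation across the wash/fragmentation combinations, normalized to the
ratio-1 value.  It evaluates at the supplied parameter point rather than
refitting per ratio.

## Synthetic chips

`make_design` emulates a resequencing design: random segments (default
two of 56 bp) tiled by forward/reverse 25-mer pairs at sampled loci,
optional replicate spots under shared replicate groups.  Loci are sampled
without replacement while distinct windows remain, then with replacement —
a 2000-spot chip over two short PCR products necessarily repeats
sequences, as real designs tiling a handful of products do, and the
distinct-sequence caching in the engine makes this the tractable regime.

Defaults are the modelled protocol: 42 °C, 1 M Na⁺, scanner 100/65536/7,
synthesis rates at the FMR1-design point estimates
(incorporation A/C/G/T = 0.967/0.944/0.908/0.950, retention
0.959/0.941/0.953/0.962), fragmentation mean 50 bases, wash K_eqW = 1e6
(the stability of roughly a weak 10-mer), and per-segment concentration
1e−17 in the table's K_eq units — chosen once so that C·K_eq of a
full-length perfect duplex is of order one, i.e. spots sit mid-way up the
scanner's range and stay concentration-sensitive rather than saturated.

Noise is multiplicative log-normal with unit mean, independent per spot
(replicates included), clamped to [0, MAX].  The experimental anchor is the
replicate-spot correlation: `calibrate_sigma` inverts
ρ = Var(I)/(Var(I) + E[I²](e^{σ²} − 1)) for the replicated spots'
noiseless intensities, and 62 simulated chips reproduce ρ = 0.906 within
±0.02.  The model is exact in the many-replicate limit; small replicate
sets bias the per-chip Pearson estimate upward, so the calibration test
uses ~90 replicate pairs.

What the simulator does *not* emulate: spatial artifacts, feature
bleed-through, sequence-biased fragmentation, position-dependent synthesis
efficiency, probe surface density, secondary structure, and real scanner
quantization.  Passing recovery tests therefore show that the estimation
machinery is correct and well-conditioned under the model's own
assumptions — not that real chips satisfy those assumptions.

## Problem sizes in the test suite

Chosen as the package's own desk-scale study conditions: oracle
equivalence on ≥ 200 instances with segments ≤ 30 bp and probes ≤ 12 bp
(exhaustive brute force is exact there); parameter recovery on a
2000-spot, two-segment chip (noiseless: rates recovered within ±0.02 with
correlation > 0.999; with replicate-calibrated noise: within ±0.05); the
mismatch positional scan on 25-mers over a 56-bp segment; the NN search
over all ten Watson–Crick steps at ratios 0.7–1.3 on five noisy chips of a
30-bp segment containing all sixteen dinucleotides.

## Known limitations

* Strand symmetry of forward/reverse probe pairs is exact only for the
  perfect-match duplex: complementing both bases of a mismatch changes its
  chemical identity (A·C ↔ T·G), so the cross-hybridization forests of
  the two strands differ slightly even with error-free synthesis, and
  truncation variants (3'-anchored) add a small asymmetry under uniform
  imperfect rates.  Both effects are orders of magnitude below the
  base-specific-rate effects the strand-ratio analysis targets.
* The wash threshold is weakly identified on perfect-match-dominated
  designs (see above); its machinery is nevertheless fully exercised by
  the oracle tests at thresholds that bite.
* Concentrations and synthesis rates are partially confounded through the
  occupancy scale; the staged fit resolves this on clean data, but on
  small noisy chips the incorporation/retention split within one base
  remains the least certain quantity, as the worked example in the README
  shows.
* Dangling-end stabilization, terminal-mismatch bonuses, RNA tables and
  ≥ 2-error binding are out of scope; the NN table format would accept
  RNA/DNA values but none are bundled.
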