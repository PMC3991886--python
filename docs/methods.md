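# Methods

This note documents the models, conventions and numerical choices behind
ssbkit, in the spirit of a package methods appendix: what is computed, under
which assumptions, which defaults were genuinely open choices, and what the
synthetic-data tests do and do not establish.

## Composition and count reconstruction

Published characterization tables print per-residue percentages at one
decimal. Given a row and the chain length `L`, integer counts are recovered
by rounding `pct·L/100` to the nearest integer and repairing any
deficit/surplus against `L` by largest-remainder adjustment (ties broken by
descending fractional part, then alphabetically by residue). For a
self-consistent row the result is the unique assignment whose re-rounded
percentages reproduce the row; for `L ≤ 500` this round-trip is exercised as
a property test over random sequences.

Printed rows are not always self-consistent. In the packaged ten-protein
panel, the FpsSSB row sums to 102.1% and the EcoSSB row's Thr percentage
admits no integer count at the published length (9/178 → 5.1, 8/178 → 4.5
against a printed 5.0). Reconstruction therefore never hard-fails by
default: it returns counts that sum exactly to `L` and reports the
irreconcilable residues in `mismatches` (a `strict=True` flag upgrades this
to an error). Rows are kept verbatim — percentages are never renormalized —
and the table reader's default row-sum slack is [99.0, 102.5] so the
panel loads as printed; a stricter rounding-only slack of [99.0, 101.0]
is available.

Two panel rows (the thermophilic comparators) have no published chain
length. TmaSSB's length (141) is the unique value below 250 whose
reconstruction round-trips exactly. No length in 80–300 round-trips the
TteSSB3 row (it sums to 99.3%); 150 is used as the closest-consistent
value. Neither row feeds any headline quantity.

**Group statistics.** Group percentages are sums of the member residues'
one-decimal percentages — the convention used when such figures are quoted
next to printed tables — so a printed row and its reconstructed counts give
identical values. The hydrophobic set {A,I,L,V,M,G,P,F,W} is the
classification that reproduces the quoted hydrophobic contents of this
panel exactly and is fixed; charged {D,E,K,H,R}, polar {N,Q,S,T,Y} and
aromatic {F,W,Y} are standard. The "tiny+small" index defaults to Taylor's
tiny+small set {A,C,G,S,T,D,N,P,V}; no standard set reproduces the
panel's quoted tiny+small figures, so this index is regarded as
non-reproduced and the set is configurable. The Arg/(Arg+Lys) ratio is
reported at two decimals and flagged undefined when Arg+Lys = 0.

## Physicochemical indices

*Monomer mass* is the count-weighted sum of average (isotope-weighted)
residue masses plus one water (18.0153 Da), reported in kDa at one decimal.
*Aliphatic index* follows Ikai: `100(n_A + 2.9 n_V + 3.9(n_I + n_L))/L`,
two decimals. *Isoelectric point* is the root of the Henderson–Hasselbalch
net-charge function over D, E, C, Y, H, K, R plus one N- and one C-terminus,
found by bisection on [0, 14] to 10⁻³ (the charge is strictly decreasing in
pH, so the root is unique), reported at two decimals. The Bjellqvist pKₐ
set is the default — the set behind the common web calculators, hence the
appropriate one for comparing against tabulated pI values — with the table
exposed as an argument. Cys is treated as fully reduced. The test suite
cross-checks the bisection against Biopython's independent implementation
to ±0.05.

Because reconstructed counts carry ±1-count ambiguity wherever the printed
row was rounded (or inconsistent), sequence-derived quantities recovered
from print can differ from the true-sequence values: in the packaged panel
the masses of FpsSSB and EcoSSB land one 0.1-kDa step from the tabulated
values, and the pI of FpsSSB (inconsistent row) and PinSSB (pI in the flat
near-neutral region of the charge curve, where ±1 count moves the root by
~0.2) miss the ±0.05 band. These are properties of the printed inputs, not
of the algorithms; the corresponding acceptance tests are left failing
rather than widened.

## Alignment, identity and similarity

Global (end-to-end) alignment uses affine gap penalties (default
BLOSUM62, gap open 10, extend 0.5; PAM matrices selectable) via Biopython's
`PairwiseAligner`; among co-optimal alignments the aligner's first
deterministic traceback is taken. Percent identity counts identical
columns; percent similarity additionally counts columns whose residues
co-occupy at least one similarity group — {V,L,I,M}, {W,F,Y}, {E,D}, {K,R},
{Q,D}, {S,T}, with D intentionally in two groups. The default denominator
is the full alignment length; the shorter-sequence length is available.
Both percentages are symmetric and printed as integers.

The aligner is validated against brute-force enumeration of every
affine-gap alignment: exhaustively for all sequence pairs of lengths 1–3
over a three-letter alphabet, and on seeded random pairs of lengths 4–7
over a four-letter alphabet (full enumeration over all length-≤7 pairs is
combinatorially out of reach; the mixed exhaustive/sampled design covers
the same code paths).

MSA conservation shading classifies each column by the largest similarity
cluster: the maximum over residues present of the fraction of sequences
carrying a residue similar to it (gaps never similar). Bands are 100%,
≥80% and ≥60% — the conventional editor bands; threshold captions that
read "<80%" in figure legends are interpreted as these bands.

Exact reproduction of any published pairwise identity/similarity table is
not promised: such tables rarely state the program, matrix, gap costs or
denominator used, so comparisons are tolerance-based (±5 points). The
panel's own records are public database sequences and are not bundled;
sequence-level comparisons require a user-supplied FASTA.

## Titration model and fitting

The forward model treats an `L`-nt oligonucleotide as carrying `L/n`
tetramer-equivalents of binding capacity, where `n` is the site size
(nt occluded per tetramer at saturation). Free tetramer and free capacity
equilibrate with a single observed association constant `K`; the bound
fraction solves the resulting quadratic, and relative fluorescence is
`1 − Qθ` with `Q` the saturation quench. As `K → ∞` this reduces to the
stoichiometric limit: a line from (0, 1) reaching the plateau `1 − Q` at
`D_b = nP/L`. Cooperative overlap-lattice statistics are deliberately out
of scope — the estimands are `n` and `Q`, for which the capacity
approximation suffices; `K` is a nuisance parameter.

The default "breakpoint" fit is least squares on the continuous two-segment
model (parameters `D_b` and plateau), giving `n = L·D_b/P` and
`Q = 1 − plateau`; `ci_n` is the 1.96σ half-width propagated from the fit
covariance. The "equilibrium" mode fits `(n, Q, log₁₀K)` on the full model
and converges to the breakpoint estimate for tight binding. A titration is
declared unsaturated — and refused — when the fitted breakpoint falls at or
beyond the penultimate point, i.e. the data contain no plateau to pin `Q`;
this post-fit criterion is robust to noise where a "last two points still
declining" rule is not.

Across salt conditions, fits are declared salt-independent when every pair
of site sizes agrees within the sum of their uncertainties; otherwise a
binding-mode transition is reported with the lowest- and highest-salt
estimates.

**Recovery performance.** With the study geometry (1.5 nmol tetramer,
(dT)76, amounts in nmol per fixed volume) and 2% Gaussian signal noise, the
breakpoint estimator is unbiased; its spread is set by how densely the
decline is sampled. The replicate-recovery test uses 51 aliquots spanning
1.6× the breakpoint — a realistic fluorimeter titration — which keeps the
estimator's σ(n̂) near 0.8 nt even at n = 65, so ±2 nt is a ≈2.5σ window
and recovery succeeds in ≥95% of 50 seeded replicates for every
(n, Q) ∈ {30, 32, 45, 65} × {0.53, 0.81, 0.93}.

## Melting curves and half-lives

UV melting curves are modeled as two-state: linear lower/upper baselines
bridged by a logistic transition of half-width `w` (default 2 °C) at `tm`,
on a 25–95 °C grid at 0.5 °C (a 1 °C/min scan sampled twice a degree).
The default midpoint extractor first locates the transition (derivative
peak; width estimated from amplitude/4·max-slope), fits baselines only to
points beyond ±5 widths, normalizes, and interpolates the 0.5 crossing.
This two-pass design removes the bias a fixed-fraction baseline window
incurs when it clips a transition tail; residual error is below 0.03 °C at
zero noise (the round-trip is exact at the 0.1 °C precision at which Tm
values are printed) and below 0.5 °C at 1% noise across 100 seeds.
The midpoint is invariant to affine rescaling of the signal. A derivative
read-off (3-point smoothing, centred differences) and a DSC peak-maximum
read-off are available; "no transition" is raised when the fitted baselines
are indistinguishable (amplitude under 4× the baseline residual) or the
normalized signal never crosses 0.5. ΔTm is a plain difference,
positive for destabilization.

Inactivation time courses use the standard grid
{0, 1, 2.5, 5, 10, 15, 30, 45, 60} min, with fraction bound normalized to 1
at t = 0. The half-life is the linearly interpolated first crossing of 0.5;
a course that never crosses is a first-class censored value printed as
">60 min" (the grid tops out there); a course starting below 0.5 is an
error. The synthetic generator uses exponential decay `2^(−t/t½)`, which
crosses 0.5 exactly at `t½`; between grid points the linear interpolation
of an exponential carries a small convexity bias, which is why zero-noise
round-trips are asserted at grid times.

## Gel filtration

Calibration is ordinary least squares of log₁₀(mass) on retention time
(≥3 standards with distinct retention times; slope negative by the physics).
Native masses are read off at one decimal, with retention times outside the
standards' range flagged as extrapolated. Oligomeric state is called from
the native/monomer ratio against bands 4 ± 0.5 (homotetramer), 2 ± 0.5
(dimer), 1 ± 0.5 (monomer), else ambiguous; the ±0.5 window covers the
panel's observed tetramer ratios (3.8–4.4) and the systematic bias typical
of gel-filtration masses, and is configurable. The default synthetic
column (slope −0.076 log₁₀kDa/min, intercept 3.9) resolves the four
standard proteins (29–200 kDa) between ~21 and ~32 min.

## Synthetic data: scope of the claims

The generators emulate idealized instrument outputs: homoscedastic Gaussian
noise, no drift, no photobleaching or inner-filter effects, exact two-state
melting, a single binding mode per condition, and exact log-linearity of
the gel-filtration column. Passing the recovery tests therefore
demonstrates that the analyzers are correct inverses of the stated models
at realistic noise levels — not that those models capture every behaviour
of real traces (multi-transition melts, sloping titration plateaus,
column non-ideality). Every generator takes an explicit integer seed and
one `numpy` Generator per call; identical parameters and seed give
identical output, and runs of the pipeline are byte-reproducible.

## Defaults worth knowing

| Parameter | Default | Why |
|---|---|---|
| Row-sum slack | [99.0, 102.5] | loads the panel verbatim incl. its inconsistent row |
| Rounding | half away from zero | matches printed tables (1 dp; ratio 2 dp; percentages integer for alignment) |
| pKₐ set | Bjellqvist | comparability with tabulated pI values |
| Matrix / gaps | BLOSUM62, 10/0.5 | well-defined modern standard; PAM selectable |
| Similarity denominator | alignment length | symmetric, conventional |
| Titration geometry | P = 1.5 nmol, L = 76 nt | the panel's assay geometry |
| Tetramer window | ratio 4 ± 0.5 | contains all observed tetramer ratios |
| Melting grid | 25–95 °C, 0.5 °C | 1 °C/min scan, two readings per degree |
| Time grid | 0…60 min (9 points) | the panel's inactivation schedule |
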