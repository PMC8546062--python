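# Methods

This note records the model implemented by `nmrsearch`, the choices made
where the design was genuinely open, what the synthetic generator does and
does not emulate, and the package's known limitations. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Problem and model

A query 1D NMR spectrum S = (x, y) is given on a strictly ascending,
uniform ppm grid (the canonical digitization for ¹³C work here is 0.05
ppm). Each candidate molecule G contributes only a vector of predicted or
annotated chemical shifts Δ = [δ₁ ≤ … ≤ δ_m]. The matching score of G
against S is computed by a three-step estimation procedure — align the
shifts onto the spectrum's peaks, fit a parametric lineshape model,
penalize the total shift movement — and candidates are ranked by score.

### Lineshape model

The estimated spectrum is a kernel-density-style sum of unit-height peaks,

    f(x) = Σᵢ k((x − μᵢ)/σᵢ; λᵢ),
    k(z; λ) = (1 − λ)·exp(−(4 ln 2)·z²) + λ/(1 + 4z²).

Both components equal 1 at z = 0 and ½ at z = ±½, so σᵢ is exactly the
full width at half maximum of peak i (ppm) and λᵢ ∈ [0, 1] interpolates
between a Gaussian (λ = 0) and a Lorentzian (λ = 1) of the same FWHM.
Peaks have no amplitude parameter: chemically equivalent nuclei appear as
duplicated shifts whose kernels stack additively. Duplicates are therefore
never deduplicated anywhere in the package.

### Alignment

Above-threshold support: x_τ = {xⱼ : yⱼ > τ}, with strict inequality. The
smallest shift is pinned to min x_τ, the largest to max x_τ, interior
shifts go to their nearest support frequency. Open points resolved here:

- m = 1: the two endpoint rules would name different targets; the single
  shift goes to its nearest support element (least displacement,
  consistent with the interior rule).
- Exact midpoint ties take the lower frequency (deterministic output).
- The aligned vector is not re-sorted. The nearest-value rule can invert
  close interior shifts; the ordering hinge in the objective is the
  mechanism that discourages inversions, so the inversion is left visible
  to it.

### Objective and optimizer

    J(μ, σ, λ) = cossim(y, ŷ)
               − ‖ y/‖y‖₁ − ŷ/‖ŷ‖₁ ‖²
               − Σᵢ (μᵢ − δ′ᵢ)²  − Σᵢ σᵢ²
               − Σᵢ max{μᵢ − μᵢ₊₁ + ε, 0}².

All five terms carry unit weight (configurable, default 1). The second
term is the squared Euclidean distance between the L1-normalized spectra;
the norm exponent is not printed more explicitly in the method's
definition, and squared-Euclidean is the reading adopted here. Two
consequences of the literal unit weights are worth stating because they
shape everything downstream:

- The anchor and width terms are in ppm² while the similarity terms are
  unitless. A 1 ppm displacement of one center costs about the entire
  dynamic range of the cosine term, so μ stays close to the aligned
  anchors and σ is driven well below its initialization h = 1 ppm.
- Because the anchors δ′ are grid frequencies, μ inherits a quantization
  pull of up to half a grid step, and endpoint peaks — whose anchors sit
  at the edge of the above-threshold support rather than at the peak
  center — inherit a pull of order the support half-width.

Maximization uses L-BFGS-B with box constraints σᵢ ≥ 10⁻³ ppm and
λᵢ ∈ [0, 1] (μ unbounded), initialized at μ = Δ′, σ = h, λ = ½.
Convergence: projected-gradient tolerance 10⁻⁸, at most 500 iterations;
these are cheap, dense, small problems. If the iteration cap is reached
the best iterate is returned with a `converged=False` flag, never an
exception, and the returned objective never falls below its value at the
initialization. Iterates that underflow the model to exactly zero (ultra-
narrow pure-Gaussian peaks between grid points) are given a large penalty
so the line search backtracks.

Gradients are analytic by default, cross-checked against finite
differences in the test suite; the squared hinge is C¹ so the objective is
differentiable everywhere. Finite differences remain available
(`gradient: fd`) and give the same optima; the analytic path is roughly
30× cheaper per iteration at m ≈ 10 and is why a 220-molecule pool scores
in seconds.

### Filters and score

Before fitting, a candidate abstains (score −C) if its alignment moved
some shift by more than θ, or if some above-threshold frequency is farther
than θ from every aligned shift. Both comparisons are strictly
greater-than at the boundary. C is not pinned down by the method's
definition beyond "large"; C = 10⁶ is used, which dominates any attainable
score (|score| ≤ 1 + α·‖Δ* − Δ‖ and displacements are bounded by θ√m for
fitted candidates). Unpredictable or empty shift sets also score −C so one
bad candidate cannot abort a pool run. Fitted candidates score

    score(G; S) = cossim(y, ŷ) − α·‖Δ* − Δ‖,

with ‖·‖ read as the Euclidean norm (an L1 option is exposed). When a
molecule carries several shift sets (different predictors), each is scored
and the best wins; exact ties fall back to a fixed provenance order
(table, hose, mpnn, other). Rankings break score ties by molecule id, so
results are deterministic and independent of pool order; parallel scoring
(process pool) preserves serial results exactly.

### Hyperparameters

| name | default | units | role |
|------|---------|-------|------|
| τ | 0.05 | normalized intensity | peak-picking threshold for alignment |
| θ | 10 | ppm | filter tolerance (both criteria) |
| α | 0.05 | 1/ppm | strength of the displacement penalty |
| h | 1.0 | ppm | initial σ for the fit |
| ε | 0.01 | ppm | ordering margin in the hinge |

τ = 0.05 presumes max-normalized intensities; `read_spectrum` therefore
max-normalizes by default (flag-controlled), since the threshold is
otherwise meaningless across instruments. θ, h, ε mainly affect
efficiency, not accuracy; α trades off spectral similarity against
prediction error and is the one knob worth tuning per nucleus.

## Synthetic data: what it emulates and what it does not

The generator produces the regime the method is designed for: sparse ¹³C
spectra on a 0.05 ppm grid over 0–220 ppm, 4–16 peaks per molecule at
least 1 ppm apart (uniformly placed via order statistics, exact and
rejection-free), per-peak FWHM σ ~ U[0.03, 0.10] ppm, mixing
λ ~ U[0.2, 0.8], additive Gaussian baseline noise (sd 0.01) clipped at
zero, max-normalization. Benchmarks expose the pool to the true shifts
only through i.i.d. Gaussian jitter (sd 1 ppm), the typical error scale of
empirical ¹³C shift predictors; decoys are independent draws from the same
molecular model.

The linewidth range deserves its own justification, because both bounds
are set by the method, not by taste. Proton-decoupled ¹³C singlets are
narrow — a few Hz, so after decimation to a 0.05 ppm grid their effective
FWHM is between a fraction of a grid step and about two grid steps. Below
σ ≈ 0.03 ppm a peak centered between grid points can leave *no* sample
above τ = 0.05, violating the method's own premise that τ sit below the
lowest peak intensity (the peak is then invisible to alignment, and the
true molecule can be mis-aligned or filtered). Above σ ≈ 0.10 ppm the
above-threshold support extends far enough beyond endpoint peaks that the
ppm²-weighted anchor term pins their fitted centers visibly off-center.
U[0.03, 0.10] is the band in which the generator's stated consistency
properties hold: with zero noise and jitter, scoring the generating shift
set against its own spectrum recovers every center to within two grid
steps (worst observed 0.085 ppm over the committed 50-spectrum suite) with
‖Δ* − Δ‖₂ ≤ 0.1 ppm, and the self-match score lands at 0.92–0.99. The
residual gap to the theoretical score of 1 is exactly the quantization and
endpoint pull described above and is not recoverable under literal unit
weights; it is shared by all candidates and therefore does not affect
ranking.

Not emulated: chemically realistic shift distributions by functional
group, multiplet structure, solvent/referencing offsets, phase or baseline
artifacts, intensity distortions from relaxation or NOE. Passing the
synthetic suite therefore demonstrates the pipeline's correctness and its
robustness to prediction error and baseline noise — not performance on any
particular instrument's data, where τ and α would need adjustment.

## Numerical choices and degenerate inputs

- Grid uniformity is enforced to 10⁻⁶ relative; non-uniform inputs must go
  through `resample_to_grid` explicitly (linear interpolation), never
  silently.
- Spectrum files are delimited text, delimiter auto-detected, single
  header line tolerated, descending-ppm input reversed on read. The writer
  emits 6 decimal places by default; precision is a parameter where
  lossless round-trips matter.
- An empty peak support (no intensity above τ) aborts the whole query with
  a distinct error — it is a property of the query, not of any candidate.
- All-zero vectors make the cosine undefined and raise explicitly.
- The benchmark's jittered shift lists are re-sorted ascending after
  jittering, preserving the shift-set invariant.

## Known limitations

- The units imbalance in J is implemented faithfully; as a consequence σ*
  is biased low and endpoint centers inherit a small systematic pull
  toward the support edge. On noiseless data the worst fitted-center error
  is typically two grid steps or less, but the extreme over many random
  draws can reach ~0.12 ppm.
- The alignment is not an assignment: several shifts may map to one
  support frequency, and order inversions are only discouraged by the
  hinge, not forbidden.
- Scores are comparable within one query, not across queries; no
  confidence calibration is attempted.
- HOSE-code and neural shift predictors are out of scope; the predictor
  contract is the extension point, and the table-backed predictor mirrors
  the annotated-database pathway.
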