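# Methods

## Model and assumptions

The correction targets lateral spillover: membrane-marker signal from one
cell measured inside the segment of an adjacent cell because their membranes
interleave at the shared boundary. Two assumptions underlie the equations:

1. a membrane marker's signal is distributed roughly uniformly along the
   originating cell's boundary, so the amount spilling into a particular
   neighbor scales with the shared fraction of the boundary;
2. segmentation is good enough that a marker's signal is higher inside its
   own cell than in the neighbors it spills into.

The mask contract is a labeled integer image: pixels of cell k carry label
k ≥ 1, and a one-pixel-wide band of zeros separates cells (it also marks
plain background; the algorithm needs no distinction). Loading validates
that no two 8-connected pixels carry different positive labels.

### Adjacency

Every zero pixel's 3×3 neighborhood is scanned for positive labels. The
perimeter P_A counts zero pixels 8-adjacent to cell A; the shared boundary
b_AK counts zero pixels 8-adjacent to both A and K. A pixel adjacent to
m ≥ 3 cells contributes to all C(m, 2) pairs — each pairwise path is
physical and triple junctions are rare but real. Windows are cropped at the
image edge. Perimeters are pixel counts, not geometric lengths: the
compensation coefficients are the ratios b_AK / P, and both numerator and
denominator are defined in the same pixel currency.

One wrinkle in the coefficient definition deserves a note: the subtraction
coefficient divides the shared boundary by the perimeter of the *donor*
cell K (b_AK / P_K), the reinforcement coefficient by the *receiving* cell's
own perimeter (b_AK / P_A). This pairing is what makes the correction
globally conservative (see below).

### Border signals

A cell pixel is a border pixel when a structuring-element offset from it
lands on an in-bounds zero pixel. The star element is the L1 ball of radius
d (2·d·(d+1) offsets: 12 at d = 2, 40 at d = 4); the sudoku element is the
L∞ ball ((2d+1)² − 1 offsets). Star at d = 2 is the default and works well
at MIBI-like resolution (~0.8 µm/px); finer-pitched immunofluorescence data
needs d = 4 to span the same physical membrane width. Offsets falling
outside the image are not treated as boundary — the image edge is not a
cell–cell interface. Any zero pixel, inter-cell boundary or background,
triggers border membership: background-facing membrane carries signal worth
reinforcing, and the subtraction term only ever involves *shared* boundary.

### The correction

For each compensated channel and cell A, with Y the region signal (border
total X_0b, or whole-cell total X_0 for the whole-cell variants):

    subtraction:      X_Acomp = X_A0 − Σ_K Y_K · b_AK / P_K
    full correction:  X_Acomp = X_A0 + Y_A · (Σ_K b_AK) / P_A
                                     − Σ_K Y_K · b_AK / P_K

The implementation keeps the explicit neighbor sums with the actual b_AK
and P values rather than the simplification that assumes full enclosure
(Σ_K b_AK = P_A): cells at the image edge or facing background then simply
receive partial reinforcement instead of being over-reinforced. Clipping of
negative results to zero happens once, after both terms are combined.
Accumulation order is fixed (ascending neighbor label), so output is
deterministic to the bit.

Two algebraic consequences are tested rather than assumed:

* **Conservation.** Before clipping, the full correction only moves signal:
  Σ_A reinforcement(A) = Σ_A subtraction(A) for any mask, because both
  double sums run over the same symmetric b_AK with matching denominators.
  Total compensated signal equals total original signal to 1e-6 relative.
* **Monotonicity.** Reinforcement is non-negative, so the subtraction-only
  result never exceeds the full correction; clipping can only raise totals.

### Whole-cell variants

How the whole-cell region should enter the reinforcement term is not
derivable from first principles; this package substitutes whole-cell totals
symmetrically into both terms. This reproduces the expected qualitative
behavior — whole-cell subtraction over-removes signal and inflates the
double-negative population relative to border correction — and keeps the
conservation identity intact for the whole-cell full correction.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `element.shape` | `star` | search neighborhood geometry (star = diamond, sudoku = square) |
| `element.size` | 2 | element radius in pixels; sets the membrane band width |
| `method` | `redsea` | `subtraction` omits the reinforcement term |
| `region` | `border` | which totals feed the correction terms |
| manifest `compensate` | — | per-channel flag; nuclear channels must stay `false` |

The display transform for before/after comparisons is
`sqrt(asinh((x/size)/cofactor))` with cofactor 1. The inverse hyperbolic
sine is the standard cytometry "arcsinh with cofactor" variance-stabilizing
transform; a true arcsine is undefined for counts above 1. The clustering
normalization divides each marker by the per-field-of-view median of a
reference nuclear channel, then min-max rescales each marker over all cells
pooled; a column constant at rescale time maps to zeros rather than
erroring.

Positivity in all evaluation statistics is strict (value > threshold, ties
negative) with default threshold 0, matching the "> 0 counts" convention;
thresholds are user-settable because real gates are drawn per dataset.
Undefined ratios (empty denominators in enrichment or accuracy) are
reported as missing values with a reason string, never as 0 or infinity.

## Synthetic scenes

`redsea.synth` generates the test substrate: seed pixels are
rejection-sampled with a minimum separation, the canvas is tiled by their
Voronoi regions (Euclidean distance transform), and a one-pixel boundary is
carved by zeroing every pixel that has an 8-neighbor of greater label — a
one-sided rule that provably leaves no two distinct labels 8-adjacent.
Cell types are drawn uniformly; defaults give two mutually exclusive marker
pairs (CD3/CD20, CD4/CD8) plus a shared nuclear dsDNA channel at 10
expected counts per border pixel.

Markers are deposited uniformly on each cell's border pixels (star, d = 2).
Spillover then moves the fraction `spillover · b_AK / P_A` of donor A's
total onto neighbor K's border pixels, uniformly; signal is moved, never
created, so global totals are conserved exactly at every spillover level
before optional per-pixel Poisson resampling. The whole scene is a pure
function of the spec (one seeded generator).

What passing tests on these scenes do *not* show: behavior under realistic
morphology, nucleus/cytoplasm compartmentalization, point-spread blur, or
segmentation errors — none of which the generator emulates.

## The over-correction regime

The correction equations carry no spillover-magnitude parameter: the
subtraction term removes the neighbor's *full* boundary-signal share
b_AK / P_K, implicitly assuming that boundary signal participates fully in
the exchange between adjacent cells. When the true spill fraction is small,
this over-corrects per-cell totals — measured on 96×96 scenes of 30 cells
(no noise), compensated totals have higher mean absolute error against
ground truth than uncompensated totals for spillover fractions below about
0.22, and lower above it. The binary readout is far more forgiving: false
double-positives are removed at every spillover level in [0.05, 0.4],
because over-subtraction on an already-contaminated channel still clips to
zero, while genuinely positive cells stay far above threshold. In short:
trust the correction for gating and cell-type calling; treat corrected
*totals* quantitatively only where spillover is substantial.

## Problem sizes and numerics

The test suite runs brute-force per-pixel reference implementations against
the vectorized code on 100 random masks up to 32×32 with up to 12 cells
(integer quantities match exactly, reals to 1e-9 absolute), and the
full-scale spillover-removal check uses a 256×256 scene of 200 cells with
Poisson noise and spillover 0.3 — large enough for stable quadrant
fractions, small enough to run in seconds. Gates there are set at 10% of
the per-channel median positive-cell ground-truth total, the synthetic
analogue of drawing a gate between populations. FCS output stores float32
(round-trips to ≤ 1e-5 relative); CSV output round-trips exactly.

## Known limitations

* Strictly 2-D: no through-plane (3-D) spillover, and physically
  overlapping cells cannot be resolved — the mask format itself assigns
  each pixel to one cell.
* Only adjacency-mediated spillover is modeled; autofluorescence, spectral
  or isotopic crosstalk and imaging artifacts are out of scope.
* The correction assumes membrane-localized markers; compensating nuclear
  or cytoplasmic channels violates its assumptions and is disabled by
  default.
* Totals (not images) are corrected: per-pixel output images are not
  produced.
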