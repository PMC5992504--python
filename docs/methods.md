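# Methods

## The parameter space

An image line is parameterized by orientation θ ∈ [0, π) and signed
distance d ∈ [−R, +R] from the image center, with R half the image
diagonal. The third coordinate p ∈ [−R, +R] is the signed position of a
point along the line (the y-coordinate in a frame rotated by θ). A cell
H(θ, d, p) represents the segment of line (θ, d) from the lowest position
−R up to p; after the two-stage voting it holds the number of edge points
of that line at positions ≤ p, so H(p_i) − H(p_j) counts the points
strictly between two positions on the discrete line.

Pixel coordinates map to centered coordinates with (width−1)/2 offsets and
image-native y (growing downward); this keeps integer grids symmetric and
round trips exact. θ bins are left-closed; d and p round half away from
zero for platform determinism, with indices clipped at the extremes
(|d| = R occurs exactly on the diagonal). Columns keep one row per pixel
of p; the pattern stage reads every Δp-th row. `n_rows` is rounded up to
a multiple of Δp so that strided cells tile the column exactly.

## Patterns

A piece of segment spanning rows (p−l, p] is **full** when
H(p) − H(p−l) > τ_F and **empty** when it is < τ_E. A non-intersection
endpoint is a full central run of η cells with empty cells just beyond the
end in all three columns (center and both laterals) and no full run in the
lateral columns; a corner half-pattern is a full central run with at least
one empty lateral run of η−1 cells (the cell at the end is excluded, and
the run above the anchor is deliberately unconstrained so that crossing
segments do not mask corners). Both come in a flipped version covering the
opposite line direction. A corner requires half-patterns on two layers
whose angular offset (mod π) lies in the corner range, mapping to the same
image position within max(Δd, Δp) pixels. Defaults: τ_F = ηΔp − 2,
τ_E = 1, corner range 35–145°; all configurable, as is the lateral-run
length (η vs η−1 cells). Pattern anchors whose pieces would overrun the
column or lack a lateral column are skipped rather than zero-padded.

## The neuron model

Linear-leak integrate-and-fire: the potential is updated only on input,
decaying toward zero from either sign at rate λ per tick before the
same-tick inputs (summed across synapses) are added; the neuron fires at
P ≥ Θ and resets to zero with no refractory period. Synapses carry real
weights of either sign and integer tick delays. The simulator is
event-driven and fully vectorized; ties within a tick resolve by ascending
neuron id, so runs are bit-reproducible. With Θ = 4 and λ = 0.2, unit
spikes at consecutive ticks trace 1, 1.8, 2.6, 3.4, 4.2 — firing on the
fifth input; generally k consecutive unit spikes reach 0.8k + 0.2.

## Network construction

Per orientation layer: n_d × n_rows Hough neurons (threshold w_cE, decay
λ), with feedforward column synapses of delay one tick per one-pixel row;
3 subpattern neurons per strided cell (u/s/c spans Δp, (η−1)Δp, ηΔp rows),
each with an excitatory synapse from its anchor row and an inhibitory one
of equal magnitude from span rows below, delayed by exactly the span so
common votes cancel; and the pattern stage per cell. Derived weights:
w_uI = −ηΔp·w_cE (a single vote above a candidate end vetoes the
pattern within its integration window), w_cI = −ρ_p1·w_cE and
w_sI = −ρ_p2·w_cE (weak lateral penalization). Defaults mirror the
reference operating point: w_cE = 1, ρ = 0.25, Θ_p1 = 6.5, Θ_p2 = 8,
λ = 0.2/tick, Δd = Δp = 2, Δθ = 0.04, η = 6.

The corner combination stage deviates from a naive reading in three
deliberate ways, each forced by the event timing:

* p2 responses are pooled per cell over a one-cell cross neighborhood
  (±1 in d or the p-stride) before the cross-layer sum. The cross-layer
  "same position" correspondence is only exact to the cell resolution;
  without the neighborhood, anchors that quantize one cell apart on the
  two layers (routinely observed on oblique corners) never meet.
* The cross-layer sum neuron nΣ carries a strong delayed self-inhibition
  (−4·n_rows·w_cE), making it fire at most once per run. Several in-range
  layers responding to the same structure otherwise make nΣ spike
  repeatedly, and any pair of those spikes within the coincidence window
  would confirm a corner without the local layer's own half-pattern
  (observed as false corners in the middle of straight edges).
* The coincidence neuron nΠ has unit-weight inputs from its own layer's
  p2 (delayed to match the pooled path) and from nΣ, threshold 1.5·w_cE
  and decay w_cE/(2ηΔp): exactly two inputs within ηΔp ticks fire it, one
  never can. A threshold of two with unit inputs would admit zero skew
  under any leak.

nΣ pooling synapses are instantiated only for cells whose image-window
center lies inside the image; out-of-image cells cannot host a corner, and
the restriction halves the largest synapse group. At 128×128 and default
resolutions the network has ≈8.5 million neurons and ≈46 million synapses
and builds in well under a minute.

## Vote injection: exact counts versus sharp timing

A vote entering first-stage row r reaches every higher row r′ of its
column at tick (r′ − r) + const; its arrival phase is constant along the
column. Two votes of one column with equal phases merge into a single
spike at every shared row. The package supports both resolutions of this
conflict:

* **Simultaneous injection** (default for detection): every edge pixel
  fires at tick 0. Phases equal −r and are automatically distinct within
  a column except for pixels sharing a first-stage cell, whose votes merge
  once at that cell. Spike counts equal the accumulated transform of the
  *binarized* first-stage votes — the near-one-to-one regime — and the
  temporal pattern the subpattern stage integrates stays sharp.
* **Serialized injection**: each pixel is greedily assigned the smallest
  firing tick whose phase is free in all of its columns across layers, so
  no votes ever merge and spike counts equal the reference transform
  exactly. On dense contiguous structures free phases are scarce and
  offsets grow to tens of ticks, dispersing the spike trains and defeating
  leaky integration, so this mode is for sparse inputs and oracle
  comparisons, not detection.

The simulation horizon is n_rows + ηΔp + 16 ticks plus the largest
injection offset (column propagation plus the deepest synaptic path).

## Readout

Endpoint-layer neurons integrate without leak (evidence for one feature
arrives spread over many ticks across layers; any leak would privilege
whichever layer happens to respond last) and do not fire during the run.
Winners are selected greedily by descending final potential with
suppression in a w × w window (w = 2·max(Δd, Δp) + 1) and raster-order
ties — the deterministic equivalent of the lateral reset wiring. A winner
needs potential ≥ Θ_e (default 2: support from at least two orientation
layers, which is why Δθ defaults to half the angular bound) and, with edge
gating on (default), must be an edge pixel. A winner is labeled a corner
when its coincidence-neuron evidence alone reaches Θ_e, else an endpoint.

The regular implementation localizes detections in the intensity image by
maximizing the minimum eigenvalue of the gradient covariance (3×3 Sobel
derivatives, 5×5 summation window) inside the window implied by the cell
resolutions, falling back to the window center on featureless windows,
then applies the same greedy suppression.

## Synthetic scenes

Generators rasterize one-pixel-wide digital lines (midpoint algorithm,
no anti-aliasing) for segments, polylines, polygons and two-armed corners,
annotate exact vertex/endpoint ground truth, optionally degrade scenes
with seeded random gaps and spurious pixels, and render filled intensity
images for the localization stage. They emulate an idealized edge
detection stage: no noise in edge position, no thickness variation, no
texture or curvature. Passing tests on these scenes validate the
transform, the network dynamics and the readout; they do not measure
robustness to the edge-detector artifacts of natural images.

## Parameter interplay and known limitations

* **Gap tolerance.** With consecutive-tick spikes, k inputs reach
  0.8k + 0.2 (λ = 0.2), so Θ_p1 = 6.5 needs 8 of the ηΔp = 12 votes of a
  full piece: up to 4 missing pixels are tolerated, fewer if the gaps also
  spread the spike train in time. The nominal budget ηΔp − Θ_p1 = 5.5 is
  shared between gaps, leak and lateral penalization, so the pure gap
  tolerance is smaller than that number suggests.
* **Oblique lines.** A digital line with direction ψ places
  max(|cos ψ|, |sin ψ|)⁻¹ ≈ 0.71–1.0 votes per p-row; near 45° a
  12-row window holds only ~8–9 votes and the staircase splits them across
  two d-columns, so segment endpoints at directions within roughly ±10° of
  the diagonals fall below Θ_p1 and are missed — by both implementations,
  as a property of the operating point, not of the spiking realization.
  Corners remain detectable as long as each arm is within the angular
  capture range of some layer.
* **Satellite detections.** On long straight edges the suppression window
  (5 px) can admit a secondary winner ~3 px from a true corner along each
  edge; these stay inside the rounded 3-px matching rule but inflate the
  detection count. A larger window trades them against resolving close
  feature pairs.
* **Coarse angular steps.** With Δθ above the bound arctan(1/(ηΔp)) a
  feature is generally seen by a single layer; the evidence threshold must
  then be lowered to 1, and oblique features mid-way between layers drift
  out of their column within a pattern span and are lost. The test-suite
  fixtures at coarse Δθ therefore use axis-aligned scenes.
* **Problem sizes.** The test suite and the acceptance script run the full
  architecture at 128×128 (one shared build) and property checks at
  31–64 px; these sizes exercise every code path while keeping a complete
  run around a minute.
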