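"""The HT3D spiking architecture: Hough layers, subpattern/pattern neurons,
corner combiners and the endpoint detection layer.

Signal flow
-----------
Edge-layer neurons fire once per edge pixel and excite, in every
orientation layer, the Hough neuron of the first segment the pixel could
terminate.  Feedforward synapses up each column (one tick per one-pixel
row) propagate the votes, so each Hough neuron's spike train encodes the
accumulated vote count of its cell.  Subpattern neurons (u/s/c types)
difference two Hough cells a fixed span apart using a paired excitatory and
delayed inhibitory synapse: common votes cancel tick for tick, and the
remaining spikes count the edge points inside a piece of segment of length
``delta_p``, ``(eta-1)*delta_p`` or ``eta*delta_p`` rows.  Pattern neurons
combine subpattern outputs: p1 fires for a complete non-intersection
endpoint pattern (full central run, empty top/bottom cells, vetoed by any
vote above the end), p2 for a corner half-pattern.  A per-cell pooling
neuron relays p2 responses to the corner combiners of other layers; the
coincidence neuron confirms a corner only when its own layer's p2 and a
pooled response from a layer at a corner-range angular offset arrive within
one pattern length of each other.  Finally, p1 and coincidence spikes are
projected back onto the image-registered endpoint layer, whose neurons
integrate evidence without leak; winners after surround suppression are the
detected corners and endpoints.

Vote serialization
------------------
Two edge pixels may fall into the same first-stage cell of some layer;
their simultaneous spikes would merge into a single Hough spike and break
the one-to-one spike/vote correspondence.  ``inject_edges`` therefore
offsets the firing tick of each edge pixel by a small color chosen so that
no two pixels sharing a first-stage cell in any layer fire together.  A
pixel's entire vote pattern shifts rigidly in time, so all subpattern
cancellations are preserved, and Hough/subpattern spike counts match the
reference transform exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .geometry import HoughSpec, hough_to_image_center
from .reference import Detection
from .snn import RunResult, SpikeEvent, SpikingNetwork

__all__ = [
    "SnnParams",
    "NetworkLayout",
    "build",
    "inject_edges",
    "hough_spike_counts",
    "subpattern_spike_counts",
    "count_neurons",
    "Ht3dSnnDetector",
]

U, S, C = 0, 1, 2                     # subpattern neuron types
P1N, P1F, P2N, P2F = 0, 1, 2, 3       # pattern neuron types
NORMAL, FLIPPED = 0, 1


@dataclass(frozen=True)
class SnnParams:
    """Synaptic weights, thresholds and decay of the HT3D network.

    Defaults follow the reference operating point: decay 0.2 per tick,
    unit excitatory weight, penalization factors 0.25, pattern thresholds
    6.5 (endpoint) and 8 (corner half-pattern), corner angle range
    35-145 degrees.
    """

    w_cE: float = 1.0
    rho_p1: float = 0.25
    rho_p2: float = 0.25
    theta_p1: float = 6.5
    theta_p2: float = 8.0
    lambda_: float = 0.2
    corner_angle_min: float = 35.0    # degrees
    corner_angle_max: float = 145.0
    inhibition_window: int | None = None
    edge_gating: bool = True
    endpoint_threshold: float = 2.0
    strict_threshold: bool = False
    serialize_votes: bool = False

    def derived_weights(self, spec: HoughSpec) -> dict[str, float]:
        """Inhibitory weights implied by ``w_cE`` and the pattern geometry.

        ``w_uI = -eta*delta_p*w_cE`` makes a single vote above a candidate
        endpoint veto the whole pattern window; ``w_cI``/``w_sI`` are the
        mild lateral penalizations.
        """
        return {
            "w_uI": -spec.eta * spec.delta_p * self.w_cE,
            "w_cI": -self.rho_p1 * self.w_cE,
            "w_sI": -self.rho_p2 * self.w_cE,
        }

    def nms_window(self, spec: HoughSpec) -> int:
        if self.inhibition_window is not None:
            return int(self.inhibition_window)
        return 2 * int(max(spec.delta_d, spec.delta_p)) + 1


class NetworkLayout:
    """Id bookkeeping plus the pixel/cell geometry shared by build and readout.

    Populations are laid out in contiguous id blocks:
    edge, hough, subpattern, pattern, p2-pool, corner-sum, corner-product,
    endpoint.  Helper methods map structured indices to flat neuron ids.
    """

    def __init__(self, spec: HoughSpec, params: SnnParams) -> None:
        self.spec = spec
        self.params = params
        w, h = spec.width, spec.height
        nt, nd, nr, npp = spec.n_theta, spec.n_d, spec.n_rows, spec.n_p
        self.n_pix = w * h

        sizes = {
            "edge": self.n_pix,
            "hough": nt * nd * nr,
            "sub": nt * nd * npp * 3,
            "pattern": nt * nd * npp * 4,
            "p2pool": nt * nd * npp,
            "nsigma": nt * nd * npp,
            "npi": nt * nd * npp * 2,
            "endpoint": self.n_pix,
        }
        self.offsets: dict[str, int] = {}
        off = 0
        for name, size in sizes.items():
            self.offsets[name] = off
            off += size
        self.sizes = sizes
        self.n_neurons = off
        for k, v in params.derived_weights(spec).items():
            setattr(self, k, v)

        # per-layer first-stage cell of every pixel
        px = np.arange(w) - (w - 1) / 2.0
        py = np.arange(h) - (h - 1) / 2.0
        X = np.tile(px, h)
        Y = np.repeat(py, w)
        self.pix_didx = np.empty((nt, self.n_pix), np.int32)
        self.pix_row = np.empty((nt, self.n_pix), np.int32)
        for t, theta in enumerate(spec.theta_values):
            ct, st = math.cos(theta), math.sin(theta)
            d = X * ct + Y * st
            p = -X * st + Y * ct
            self.pix_didx[t] = np.clip(
                np.floor((d + spec.R) / spec.delta_d + 0.5), 0, nd - 1
            ).astype(np.int32)
            self.pix_row[t] = np.clip(np.floor(p + spec.R + 0.5), 0, nr - 1).astype(np.int32)
        self.pix_cell = self.pix_row // spec.delta_p

        # centers of strided cells (image pixel coordinates), per layer
        d_c = np.arange(nd) * spec.delta_d - spec.R
        p_c = spec.anchor_rows - (spec.delta_p - 1) / 2.0 - spec.R
        D, P = np.meshgrid(d_c, p_c, indexing="ij")       # (nd, np)
        self.cell_x = np.empty((nt, nd, npp))
        self.cell_y = np.empty((nt, nd, npp))
        for t, theta in enumerate(spec.theta_values):
            xc, yc = hough_to_image_center(theta, D, P)
            self.cell_x[t] = xc + (w - 1) / 2.0
            self.cell_y[t] = yc + (h - 1) / 2.0
        self.cell_in_image = (
            (self.cell_x > -0.5) & (self.cell_x < w - 0.5)
            & (self.cell_y > -0.5) & (self.cell_y < h - 0.5)
        )

    # ---- id helpers -----------------------------------------------------
    def edge_id(self, px, py):
        return self.offsets["edge"] + np.asarray(py) * self.spec.width + np.asarray(px)

    def hough_id(self, t, d, r):
        nd, nr = self.spec.n_d, self.spec.n_rows
        return self.offsets["hough"] + (np.asarray(t) * nd + np.asarray(d)) * nr + np.asarray(r)

    def sub_id(self, t, d, k, typ):
        nd, npp = self.spec.n_d, self.spec.n_p
        return (
            self.offsets["sub"]
            + ((np.asarray(t) * nd + np.asarray(d)) * npp + np.asarray(k)) * 3
            + typ
        )

    def pattern_id(self, t, d, k, typ):
        nd, npp = self.spec.n_d, self.spec.n_p
        return (
            self.offsets["pattern"]
            + ((np.asarray(t) * nd + np.asarray(d)) * npp + np.asarray(k)) * 4
            + typ
        )

    def p2pool_id(self, t, d, k):
        nd, npp = self.spec.n_d, self.spec.n_p
        return self.offsets["p2pool"] + (np.asarray(t) * nd + np.asarray(d)) * npp + np.asarray(k)

    def nsigma_id(self, t, d, k):
        nd, npp = self.spec.n_d, self.spec.n_p
        return self.offsets["nsigma"] + (np.asarray(t) * nd + np.asarray(d)) * npp + np.asarray(k)

    def npi_id(self, t, d, k, version):
        nd, npp = self.spec.n_d, self.spec.n_p
        return (
            self.offsets["npi"]
            + ((np.asarray(t) * nd + np.asarray(d)) * npp + np.asarray(k)) * 2
            + version
        )

    def endpoint_id(self, px, py):
        return self.offsets["endpoint"] + np.asarray(py) * self.spec.width + np.asarray(px)

    def block(self, name) -> slice:
        return slice(self.offsets[name], self.offsets[name] + self.sizes[name])

    def horizon(self, max_stagger: int = 0) -> int:
        """Settling horizon: column propagation plus the deepest synaptic path."""
        return self.spec.n_rows + self.spec.full_piece_rows + 16 + int(max_stagger)

    # ---- valid pattern cells -------------------------------------------
    def pattern_valid(self):
        """Boolean (4, n_p) validity of each pattern version per cell index,
        plus the valid d range; patterns whose pieces would overrun the
        column or lack a lateral column are not wired."""
        spec = self.spec
        k = np.arange(spec.n_p)
        anchors = spec.anchor_rows
        ok_n = (anchors >= spec.full_piece_rows) & (k + 1 <= spec.n_p - 1)
        ok_f = (k >= 1) & (k + spec.eta - 1 <= spec.n_p - 1)
        valid = np.zeros((4, spec.n_p), bool)
        valid[P1N] = ok_n
        valid[P1F] = ok_f
        valid[P2N] = ok_n & (k >= 1)
        valid[P2F] = ok_f
        return valid


def count_neurons(spec: HoughSpec) -> dict[str, int]:
    """Per-layer-type neuron counts of the architecture.

    Hough orientation layers keep one neuron per one-pixel row
    (``n_d * n_p * delta_p`` each), subpattern layers three neurons per
    strided cell, pattern layers eight (two pattern types plus the corner
    combination units, in normal and flipped versions), and the endpoint
    layer one neuron per pixel.
    """
    per_pos = spec.n_d * spec.n_p
    counts = {
        "hough": spec.n_theta * per_pos * spec.delta_p,
        "subpattern": spec.n_theta * per_pos * 3,
        "pattern": spec.n_theta * per_pos * 8,
        "endpoint": spec.width * spec.height,
    }
    counts["total"] = sum(counts.values())
    return counts


def build(spec: HoughSpec, params: SnnParams | None = None):
    """Construct the full spiking network for ``spec``.

    Returns ``(network, layout)``.  Raises ``ValueError`` for parameter
    combinations with no valid pattern support (columns shorter than a
    pattern, or fewer than three d-columns).
    """
    params = params or SnnParams()
    if spec.full_piece_rows >= spec.n_rows:
        raise ValueError("pattern span eta*delta_p must be shorter than the column")
    if spec.n_d < 3:
        raise ValueError("need at least three d-columns for lateral pattern checks")
    layout = NetworkLayout(spec, params)
    valid = layout.pattern_valid()
    if not valid.any():
        raise ValueError("no valid pattern cells for this parameter combination")

    w = params.w_cE
    lam = params.lambda_
    net = SpikingNetwork(strict_threshold=params.strict_threshold)
    nt, nd, nr, npp = spec.n_theta, spec.n_d, spec.n_rows, spec.n_p
    eta, dp = spec.eta, spec.delta_p

    net.add_neurons(layout.sizes["edge"], threshold=1.0, decay=0.0)
    net.add_neurons(layout.sizes["hough"], threshold=w, decay=lam)
    net.add_neurons(layout.sizes["sub"], threshold=w, decay=lam)
    thr_pattern = np.tile([params.theta_p1, params.theta_p1,
                           params.theta_p2, params.theta_p2], nt * nd * npp)
    net.add_neurons(layout.sizes["pattern"], threshold=thr_pattern, decay=lam)
    net.add_neurons(layout.sizes["p2pool"], threshold=w, decay=lam)
    net.add_neurons(layout.sizes["nsigma"], threshold=w, decay=lam)
    # coincidence: one input is sub-threshold, two within eta*delta_p ticks fire
    net.add_neurons(layout.sizes["npi"], threshold=1.5 * w,
                    decay=w / (2.0 * spec.full_piece_rows))
    net.add_neurons(layout.sizes["endpoint"], threshold=1e30, decay=0.0)

    T = np.arange(nt)[:, None, None]
    D = np.arange(nd)[None, :, None]
    K = np.arange(npp)[None, None, :]

    # (a) edge layer -> first-stage Hough cells, every orientation layer
    pix = np.arange(layout.n_pix)
    edge_ids = layout.offsets["edge"] + pix
    for t in range(nt):
        net.add_synapses(edge_ids, layout.hough_id(t, layout.pix_didx[t], layout.pix_row[t]),
                         w, 1)

    # (b) vote propagation up each column, one tick per one-pixel row
    R_ = np.arange(nr - 1)[None, None, :]
    pre = layout.hough_id(T, D, R_).ravel()
    net.add_synapses(pre, pre + 1, w, 1)

    # (c) subpattern differencing: excitation from the anchor row, delayed
    # inhibition of equal magnitude from ``span`` rows below
    anchors = spec.anchor_rows
    for typ, span in ((U, dp), (S, (eta - 1) * dp), (C, eta * dp)):
        post = layout.sub_id(T, D, K, typ).ravel()
        net.add_synapses(layout.hough_id(T, D, anchors[None, None, :]).ravel(), post, w, 1)
        low = anchors - span
        m = (low[None, None, :] >= 0) & np.ones((nt, nd, 1), bool)
        net.add_synapses(
            layout.hough_id(T, D, np.maximum(low, 0)[None, None, :])[m],
            layout.sub_id(T, D, K, typ)[m], -w, 1 + span,
        )

    # (d) pattern neurons; lateral columns require 1 <= d <= n_d - 2
    w_uI, w_cI, w_sI = layout.w_uI, layout.w_cI, layout.w_sI
    Dl = np.arange(1, nd - 1)[None, :, None]

    def wire(post_typ, k_mask, inputs):
        m = np.broadcast_to(k_mask[None, None, :], (nt, nd - 2, npp))
        post = layout.pattern_id(T, Dl, K, post_typ)
        post_m = np.broadcast_to(post, m.shape)[m]
        for src_id, weight in inputs:
            net.add_synapses(np.broadcast_to(src_id, m.shape)[m], post_m, weight, 1)

    wire(P1N, valid[P1N], [
        (layout.sub_id(T, Dl, K, C), w),
        (layout.sub_id(T, Dl - 1, np.clip(K + 1, 0, npp - 1), U), w_uI),
        (layout.sub_id(T, Dl, np.clip(K + 1, 0, npp - 1), U), w_uI),
        (layout.sub_id(T, Dl + 1, np.clip(K + 1, 0, npp - 1), U), w_uI),
        (layout.sub_id(T, Dl - 1, K, C), w_cI),
        (layout.sub_id(T, Dl + 1, K, C), w_cI),
    ])
    Kup = np.clip(K + eta - 1, 0, npp - 1)
    Kdn = np.clip(K - 1, 0, npp - 1)
    wire(P1F, valid[P1F], [
        (layout.sub_id(T, Dl, Kup, C), w),
        (layout.sub_id(T, Dl - 1, Kdn, U), w_uI),
        (layout.sub_id(T, Dl, Kdn, U), w_uI),
        (layout.sub_id(T, Dl + 1, Kdn, U), w_uI),
        (layout.sub_id(T, Dl - 1, Kup, C), w_cI),
        (layout.sub_id(T, Dl + 1, Kup, C), w_cI),
    ])
    wire(P2N, valid[P2N], [
        (layout.sub_id(T, Dl, K, C), w),
        (layout.sub_id(T, Dl - 1, Kdn, S), w_sI),
        (layout.sub_id(T, Dl + 1, Kdn, S), w_sI),
    ])
    wire(P2F, valid[P2F], [
        (layout.sub_id(T, Dl, Kup, C), w),
        (layout.sub_id(T, Dl - 1, Kup, S), w_sI),
        (layout.sub_id(T, Dl + 1, Kup, S), w_sI),
    ])

    # (e) corner combination: per-cell pooling of the two p2 versions over a
    # one-cell cross neighborhood (the cross-layer "same image position"
    # correspondence is only exact to the cell resolution, so pattern
    # anchors may jitter by one cell in d or p), then cross-layer summation
    # over the corner angle range, then coincidence
    for dd, dk in ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0)):
        d_lo, d_hi = max(dd, 0), nd + min(dd, 0)
        k_lo, k_hi = max(dk, 0), npp + min(dk, 0)
        Dn = np.arange(d_lo, d_hi)[None, :, None]
        Kn = np.arange(k_lo, k_hi)[None, None, :]
        pool = layout.p2pool_id(T, Dn - dd, Kn - dk).ravel()
        net.add_synapses(layout.pattern_id(T, Dn, Kn, P2N).ravel(), pool, w, 1)
        net.add_synapses(layout.pattern_id(T, Dn, Kn, P2F).ravel(), pool, w, 1)

    phi_min = math.radians(params.corner_angle_min)
    phi_max = math.radians(params.corner_angle_max)
    in_img = layout.cell_in_image
    halfw, halfh = (spec.width - 1) / 2.0, (spec.height - 1) / 2.0
    for t in range(nt):
        d_sel, k_sel = np.nonzero(in_img[t])
        if d_sel.size == 0:
            continue
        x = layout.cell_x[t, d_sel, k_sel] - halfw
        y = layout.cell_y[t, d_sel, k_sel] - halfh
        post = layout.nsigma_id(t, d_sel, k_sel)
        for t2 in range(nt):
            if t2 == t:
                continue
            delta = abs(t2 - t) * spec.delta_theta
            if not (phi_min <= delta <= phi_max
                    or phi_min <= math.pi - delta <= phi_max):
                continue
            th2 = spec.theta_values[t2]
            d2 = x * math.cos(th2) + y * math.sin(th2)
            p2 = -x * math.sin(th2) + y * math.cos(th2)
            d2i = np.clip(np.floor((d2 + spec.R) / spec.delta_d + 0.5), 0, nd - 1).astype(int)
            k2 = np.clip(np.floor(p2 + spec.R + 0.5), 0, nr - 1).astype(int) // dp
            net.add_synapses(layout.p2pool_id(t2, d2i, k2), post, w, 1)
        # strong delayed self-inhibition: the cross-layer sum neuron reports
        # "a corner-range half-pattern exists here" at most once per run, so
        # the coincidence neuron below cannot fire from pooled evidence
        # alone when several in-range layers respond to the same structure.
        # The magnitude outweighs any possible pooled excitation plus leak
        # recovery within the simulation horizon.
        net.add_synapses(post, post, -4.0 * spec.n_rows * w, 1)

    for version, ptyp in ((NORMAL, P2N), (FLIPPED, P2F)):
        npi = layout.npi_id(T, D, K, version).ravel()
        # the direct path is delayed to match p2 -> pool -> sum -> product
        net.add_synapses(layout.pattern_id(T, D, K, ptyp).ravel(), npi, w, 3)
        net.add_synapses(layout.nsigma_id(T, D, K).ravel(), npi, w, 1)

    # (f) reverse voting: each detector cell excites the endpoint neurons of
    # exactly the pixels whose discrete Hough position it represents
    for t in range(nt):
        ep = layout.offsets["endpoint"] + pix
        for typ_id in (
            layout.pattern_id(t, layout.pix_didx[t], layout.pix_cell[t], P1N),
            layout.pattern_id(t, layout.pix_didx[t], layout.pix_cell[t], P1F),
            layout.npi_id(t, layout.pix_didx[t], layout.pix_cell[t], NORMAL),
            layout.npi_id(t, layout.pix_didx[t], layout.pix_cell[t], FLIPPED),
        ):
            net.add_synapses(typ_id, ep, w, 1)

    net.finalize()
    return net, layout


def inject_edges(edge_image: np.ndarray, layout: NetworkLayout,
                 serialize: bool = True) -> list[SpikeEvent]:
    """Input events for an edge map.

    With ``serialize=False`` every edge pixel fires at tick 0 (simultaneous
    excitation).  A vote entering first-stage row ``r`` then reaches every
    higher row ``r'`` of its column at tick ``r' - r + const`` — its arrival
    phase ``-r`` is distinct within the column except for pixels sharing a
    first-stage cell, whose coincident votes merge into a single spike.
    Spike counts then equal the accumulated transform of the *binarized*
    first-stage votes (the near-one-to-one regime), and spike timing is
    exactly the clean propagation pattern.

    With ``serialize=True`` each pixel is assigned, greedily in raster
    order, the smallest firing tick whose phase differs from every
    already-assigned vote in each of the pixel's columns across all
    orientation layers, so no two votes ever merge and spike counts equal
    the reference transform exactly.  The price is temporal dispersion:
    on dense contiguous structures free phases are scarce and offsets grow,
    smearing the spike trains the pattern stage integrates.  Exact counting
    therefore suits sparse inputs and oracle comparisons; detection on
    dense scenes uses simultaneous injection.
    """
    spec = layout.spec
    if edge_image.shape != (spec.height, spec.width):
        raise ValueError("edge image dimensions do not match the network spec")
    ys, xs = np.nonzero(edge_image)
    pids = ys.astype(np.int64) * spec.width + xs
    if not serialize:
        return [SpikeEvent(0, int(layout.offsets["edge"] + pid), 1.0) for pid in pids]
    nt = spec.n_theta
    col_phases: dict[tuple[int, int], set[int]] = {}
    events = []
    for pid in pids:
        forbidden: set[int] = set()
        keys = []
        for t in range(nt):
            row = int(layout.pix_row[t, pid])
            key = (t, int(layout.pix_didx[t, pid]))
            keys.append((key, row))
            phases = col_phases.get(key)
            if phases:
                forbidden.update(ph + row for ph in phases)
        color = 0
        while color in forbidden:
            color += 1
        for key, row in keys:
            col_phases.setdefault(key, set()).add(color - row)
        events.append(SpikeEvent(color, int(layout.offsets["edge"] + pid), 1.0))
    return events


def hough_spike_counts(result: RunResult, layout: NetworkLayout) -> np.ndarray:
    """Total output spikes of every Hough neuron, accumulator-shaped.

    Contract: identical to the reference transform's accumulated votes.
    """
    spec = layout.spec
    return result.spike_counts[layout.block("hough")].reshape(
        spec.n_theta, spec.n_d, spec.n_rows
    )


def subpattern_spike_counts(result: RunResult, layout: NetworkLayout) -> np.ndarray:
    """Spikes of u/s/c neurons as an array (theta, d, cell, type).

    Contract: equals the reference vote difference over each neuron's span.
    """
    spec = layout.spec
    return result.spike_counts[layout.block("sub")].reshape(
        spec.n_theta, spec.n_d, spec.n_p, 3
    )


class Ht3dSnnDetector:
    """Build once, detect many: the spiking HT3D corner/endpoint detector."""

    def __init__(self, spec: HoughSpec, params: SnnParams | None = None) -> None:
        self.spec = spec
        self.params = params or SnnParams()
        self.network, self.layout = build(spec, self.params)

    def run(self, edge_image: np.ndarray, record=(), serialize: bool | None = None) -> RunResult:
        """Simulate to quiescence on one edge map (network state is reset)."""
        if serialize is None:
            serialize = self.params.serialize_votes
        events = inject_edges(edge_image, self.layout, serialize=serialize)
        max_color = max((ev.time for ev in events), default=0)
        self.network.reset()
        result = self.network.run(events, self.layout.horizon(max_color), record=record)
        if not result.complete:
            raise RuntimeError(
                f"simulation horizon exceeded with {result.dropped_deliveries} pending deliveries"
            )
        return result

    def endpoint_potential_map(self, result: RunResult) -> np.ndarray:
        """Endpoint-layer membrane potentials as an (height, width) image."""
        return result.potentials[self.layout.block("endpoint")].reshape(
            self.spec.height, self.spec.width
        ).copy()

    def detect(self, edge_image: np.ndarray) -> list[Detection]:
        """Detected corners and endpoints in image space.

        Endpoint-layer neurons integrate pattern evidence without leak;
        pixels reaching the endpoint threshold compete under greedy
        surround suppression (descending potential, raster-order ties)
        within the inhibition window.  With edge gating enabled only edge
        pixels may win, which pins detections to the drawn contour.
        """
        result = self.run(edge_image)
        layout, spec, params = self.layout, self.spec, self.params
        h, w = spec.height, spec.width
        counts = result.spike_counts

        ep_ev = np.zeros(layout.n_pix)
        co_ev = np.zeros(layout.n_pix)
        best_count = np.zeros(layout.n_pix, np.int64)
        best_info = np.full((layout.n_pix, 4), -1, np.int64)  # t, d, k, flip

        def accumulate(ids, kind_map, flip_arr_info):
            fired = np.nonzero(counts[ids.ravel()])[0]
            for f in fired:
                idx = np.unravel_index(f, ids.shape)
                nid = int(ids[idx])
                cnt = int(counts[nid])
                t, d, k, flip = flip_arr_info(idx)
                sel = np.nonzero(
                    (layout.pix_didx[t] == d) & (layout.pix_cell[t] == k)
                )[0]
                if sel.size == 0:
                    continue
                kind_map[sel] += cnt
                upd = sel[best_count[sel] < cnt]
                best_count[upd] = cnt
                best_info[upd] = (t, d, k, flip)

        nt, nd, npp = spec.n_theta, spec.n_d, spec.n_p
        pat = np.arange(layout.offsets["pattern"],
                        layout.offsets["pattern"] + layout.sizes["pattern"]).reshape(
            nt, nd, npp, 4)
        accumulate(pat[..., P1N], ep_ev, lambda i: (i[0], i[1], i[2], 0))
        accumulate(pat[..., P1F], ep_ev, lambda i: (i[0], i[1], i[2], 1))
        npi = np.arange(layout.offsets["npi"],
                        layout.offsets["npi"] + layout.sizes["npi"]).reshape(
            nt, nd, npp, 2)
        accumulate(npi[..., NORMAL], co_ev, lambda i: (i[0], i[1], i[2], 0))
        accumulate(npi[..., FLIPPED], co_ev, lambda i: (i[0], i[1], i[2], 1))

        total = result.potentials[layout.block("endpoint")].copy()
        cand = total >= params.endpoint_threshold
        if params.edge_gating:
            cand &= edge_image.ravel() > 0
        order = np.lexsort((np.arange(layout.n_pix), -total))
        order = order[cand[order]]
        suppressed = np.zeros((h, w), bool)
        half = params.nms_window(spec) // 2
        detections: list[Detection] = []
        for pid in order:
            py, px = divmod(int(pid), w)
            if suppressed[py, px]:
                continue
            suppressed[max(py - half, 0): py + half + 1,
                       max(px - half, 0): px + half + 1] = True
            kind = "corner" if co_ev[pid] >= params.endpoint_threshold else "endpoint"
            t, d, k, flip = best_info[pid]
            row = int(spec.anchor_rows[k]) if k >= 0 else -1
            detections.append(
                Detection(kind, bool(flip == 1), int(t), int(d), row,
                          float(px), float(py), float(total[pid]))
            )
        return detections
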