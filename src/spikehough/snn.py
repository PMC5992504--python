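"""Deterministic event-driven simulation of leaky integrate-and-fire networks.

The neuron model is the linear-leak LIF unit: the membrane potential is
updated only when input arrives; between inputs it decays linearly toward
zero from either sign,

    P'(t) = sign(P) * max(|P| - lambda * dt, 0),
    P(t)  = P'(t) + sum of same-tick weighted inputs,

and the neuron emits a spike and resets to zero when P reaches its
threshold.  Time is an integer tick (the minimum interval between two
consecutive spikes); synapses carry a real weight of either sign and an
integer delay in ticks.

The simulator is fully vectorized: all inputs scheduled for one tick are
summed per neuron before the threshold test, active neurons are updated
with numpy, and output spikes schedule downstream deliveries at
``t + delay``.  Identical inputs always produce identical spike trains;
ties within a tick are resolved by ascending neuron id.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LIFNeuron", "SpikeEvent", "RunResult", "SpikingNetwork", "dump_raster"]


def dump_raster(result: "RunResult", path) -> None:
    """Write recorded spikes as CSV ``neuron_id,time_tick`` (debug aid)."""
    with open(path, "w") as fh:
        fh.write("neuron_id,time_tick\n")
        for nid in sorted(result.spike_times):
            for t in result.spike_times[nid]:
                fh.write(f"{nid},{t}\n")


@dataclass
class LIFNeuron:
    """Scalar LIF neuron; reference form of the update rule.

    The vectorized network applies exactly this arithmetic; keeping the
    scalar version around lets tests check the two paths against each
    other spike for spike.
    """

    threshold: float
    decay_rate: float
    potential: float = 0.0
    last_update: int = 0
    strict: bool = False

    def integrate(self, summed_weighted_input: float, t: int) -> bool:
        """Apply leak up to tick ``t``, add the input, fire if at threshold."""
        if t < self.last_update:
            raise ValueError("time must not run backwards")
        dt = t - self.last_update
        p = self.potential
        p = np.sign(p) * max(abs(p) - self.decay_rate * dt, 0.0)
        p += summed_weighted_input
        self.last_update = t
        fired = p > self.threshold if self.strict else p >= self.threshold
        self.potential = 0.0 if fired else p
        return bool(fired)


@dataclass(frozen=True)
class SpikeEvent:
    """External input: deliver ``weight`` to ``neuron`` at ``time`` ticks."""

    time: int
    neuron: int
    weight: float = 1.0


@dataclass
class RunResult:
    spike_counts: np.ndarray
    spike_times: dict[int, list[int]]
    potentials: np.ndarray
    horizon: int
    dropped_deliveries: int = 0

    @property
    def complete(self) -> bool:
        """True when no scheduled delivery fell beyond the horizon."""
        return self.dropped_deliveries == 0


class SpikingNetwork:
    """A population of LIF neurons with weighted, delayed synapses.

    Build with :meth:`add_neurons` / :meth:`add_synapses`, then
    :meth:`finalize` (which compiles synapses into CSR adjacency), then
    :meth:`run`.  ``reset`` restores the resting state so one network can
    be reused across inputs.
    """

    def __init__(self, strict_threshold: bool = False) -> None:
        self.strict = strict_threshold
        self._thr: list[np.ndarray] = []
        self._dec: list[np.ndarray] = []
        self._pre: list[np.ndarray] = []
        self._post: list[np.ndarray] = []
        self._w: list[np.ndarray] = []
        self._dl: list[np.ndarray] = []
        self.n_neurons = 0
        self._finalized = False

    # ---- construction ---------------------------------------------------
    def add_neurons(self, count: int, threshold, decay) -> tuple[int, int]:
        """Append ``count`` neurons; returns their id range ``[start, stop)``."""
        if self._finalized:
            raise RuntimeError("network already finalized")
        start = self.n_neurons
        self._thr.append(np.broadcast_to(np.asarray(threshold, float), (count,)).copy())
        self._dec.append(np.broadcast_to(np.asarray(decay, float), (count,)).copy())
        self.n_neurons += count
        return start, self.n_neurons

    def add_synapses(self, pre, post, weight, delay) -> None:
        pre = np.asarray(pre, dtype=np.int64).ravel()
        n = pre.size
        if n == 0:
            return
        self._pre.append(pre)
        self._post.append(np.broadcast_to(np.asarray(post, np.int64).ravel(), (n,)).copy())
        self._w.append(np.broadcast_to(np.asarray(weight, np.float64).ravel(), (n,)).copy())
        dl = np.broadcast_to(np.asarray(delay, np.int64).ravel(), (n,)).copy()
        if np.any(dl < 0):
            raise ValueError("synaptic delays must be >= 0")
        self._dl.append(dl)

    def finalize(self) -> None:
        """Compile synapse lists to CSR adjacency keyed by presynaptic id."""
        if self._finalized:
            return
        self.threshold = np.concatenate(self._thr) if self._thr else np.zeros(0)
        self.decay = np.concatenate(self._dec) if self._dec else np.zeros(0)
        if self._pre:
            pre = np.concatenate(self._pre)
            order = np.argsort(pre, kind="stable")
            pre = pre[order]
            self.syn_post = np.concatenate(self._post)[order].astype(np.int32)
            self.syn_weight = np.concatenate(self._w)[order].astype(np.float64)
            self.syn_delay = np.concatenate(self._dl)[order].astype(np.int32)
            counts = np.bincount(pre, minlength=self.n_neurons)
        else:
            self.syn_post = np.zeros(0, np.int32)
            self.syn_weight = np.zeros(0)
            self.syn_delay = np.zeros(0, np.int32)
            counts = np.zeros(self.n_neurons, np.int64)
        self.indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        self._pre = self._post = self._w = self._dl = None
        self._thr = self._dec = None
        self.potential = np.zeros(self.n_neurons)
        self.last_update = np.zeros(self.n_neurons, np.int64)
        self._finalized = True

    def reset(self) -> None:
        self.potential[:] = 0.0
        self.last_update[:] = 0

    # ---- simulation ------------------------------------------------------
    def _fanout(self, fired_ids: np.ndarray):
        """Flat synapse indices of all outgoing synapses of ``fired_ids``."""
        starts = self.indptr[fired_ids]
        stops = self.indptr[fired_ids + 1]
        counts = stops - starts
        total = int(counts.sum())
        if total == 0:
            return np.zeros(0, np.int64)
        idx = np.repeat(starts - np.concatenate([[0], np.cumsum(counts)[:-1]]), counts)
        return idx + np.arange(total)

    def run(self, initial_events, horizon: int, record=()) -> RunResult:
        """Process events in time order up to ``horizon`` ticks (inclusive).

        ``initial_events`` is an iterable of :class:`SpikeEvent`; same-tick
        inputs to one neuron are summed before the threshold test.  Each
        output spike schedules its synaptic deliveries at ``t + delay``;
        deliveries falling beyond the horizon are dropped and counted.
        ``record`` is an iterable of neuron ids whose spike times are kept
        (``record="all"`` keeps every neuron's).
        """
        if not self._finalized:
            self.finalize()
        pending: dict[int, list[tuple[np.ndarray, np.ndarray]]] = {}
        dropped = 0
        for ev in initial_events:
            if ev.time > horizon:
                dropped += 1
                continue
            pending.setdefault(int(ev.time), []).append(
                (np.asarray([ev.neuron], np.int64), np.asarray([ev.weight], float))
            )
        record_all = isinstance(record, str) and record == "all"
        record_set = None if record_all else set(int(r) for r in record)
        spike_counts = np.zeros(self.n_neurons, np.int64)
        spike_times: dict[int, list[int]] = {}

        t = 0
        while pending and t <= horizon:
            t = min(pending)
            batch = pending.pop(t)
            posts = np.concatenate([b[0] for b in batch])
            weights = np.concatenate([b[1] for b in batch])
            order = np.argsort(posts, kind="stable")
            posts, weights = posts[order], weights[order]
            ids, starts = np.unique(posts, return_index=True)
            sums = np.add.reduceat(weights, starts)

            dt = (t - self.last_update[ids]).astype(float)
            p = self.potential[ids]
            p = np.sign(p) * np.maximum(np.abs(p) - self.decay[ids] * dt, 0.0)
            p = p + sums
            thr = self.threshold[ids]
            fired = (p > thr) if self.strict else (p >= thr)
            self.potential[ids] = np.where(fired, 0.0, p)
            self.last_update[ids] = t
            fired_ids = ids[fired]
            if fired_ids.size:
                spike_counts[fired_ids] += 1
                if record_all:
                    for nid in fired_ids:
                        spike_times.setdefault(int(nid), []).append(t)
                elif record_set:
                    for nid in fired_ids:
                        if int(nid) in record_set:
                            spike_times.setdefault(int(nid), []).append(t)
                sidx = self._fanout(fired_ids)
                if sidx.size:
                    dls = self.syn_delay[sidx]
                    for dl in np.unique(dls):
                        m = dls == dl
                        tt = t + int(dl)
                        if tt > horizon:
                            dropped += int(m.sum())
                            continue
                        pending.setdefault(tt, []).append(
                            (self.syn_post[sidx[m]].astype(np.int64), self.syn_weight[sidx[m]])
                        )
        return RunResult(spike_counts, spike_times, self.potential, horizon, dropped)
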