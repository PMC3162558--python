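"""Spiking-neuron realization of path evolution.

A grid of regular-spiking Izhikevich neurons (10 rows x 10 phenotype
columns, plus one shared start neuron) carries paths as chains of
single-spike propagation: winner-take-all (WTA) competition lets each spike
drive exactly one downstream synapse, chosen with probability proportional
to its weight, so the spike route plays the role of a traversed path and the
weight distribution the role of transition probabilities.  Each neuron
carries a phenotype bit; the network's phenotype for a trial is the ordered
bits of the first ten distinct neurons to spike after the start neuron is
stimulated, and its fitness the number of ones (the 10-bit all-ones task).

Selection acts through dopamine-modulated STDP with eligibility traces:
pre-before-post spike pairings tag the delivering synapse's trace, a global
dopamine signal (positive for above-average fitness, negative for
below-average) converts traces into weight change, silent neurons' outgoing
weights decay linearly, and sub-minimum synapses are removed.  Structural
plasticity forms new synapses from active neurons to adjacent neurons of the
next column (with a second hop that reconnects to the original row a third
of the time — a bypass mutation — and diverges otherwise), and long-silent
neurons flip their phenotype bit, so variation never dries up.

Weights are in millivolts of delivered depolarization; one synaptic delay
everywhere (1 ms); time step 1 ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RS_A", "RS_B", "RS_C", "RS_D",
    "SpikingConfig", "SpikingTrace", "SpikingNet",
    "izhikevich_step", "reward_rule", "readout_phenotype",
    "run_spiking_pea", "calibrate_background",
]

# regular-spiking Izhikevich constants
RS_A, RS_B, RS_C, RS_D = 0.02, 0.2, -65.0, 8.0
V_PEAK = 30.0
V_REST, U_REST = -70.0, -14.0


def izhikevich_step(v: float, u: float, current: float, dt: float = 1.0
                    ) -> tuple[float, float, bool]:
    """One step of the two-variable quadratic neuron (two half-steps for v).

    Returns ``(v, u, spiked)``; on reaching 30 mV the spike is registered
    and the reset v <- c, u <- u + d applied.
    """
    for _ in range(2):
        v = v + 0.5 * dt * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        if v >= V_PEAK:
            v = V_PEAK     # clamp the overshoot so u stays well-behaved
    u = u + dt * RS_A * (RS_B * v - u)
    if v >= V_PEAK:
        return RS_C, u + RS_D, True
    return v, u, False


@dataclass
class SpikingConfig:
    rows: int = 10
    cols: int = 10                    # phenotype columns
    trial_ms: int = 1000
    stim_ms: int = 10                 # stimulation offset within a trial
    reward_ms: int = 50               # reward offset within a trial
    da_per_bit: float = 0.5
    decay_rate: float = 0.00002       # mV/ms, silent-presynaptic decay
    silent_ms: float = 1000.0         # silence needed before decay applies
    struct_prob: float = 0.01         # per-spike synaptogenesis probability
    max_out: int = 3                  # per-neuron output cap (start exempt)
    outflow_cap: float = 60.0         # mV, total outflow triggering removal
    w_min: float = 15.0
    w_max: float = 60.0
    new_weight: float = 30.0          # initial weight of structural synapses
    trace_tau: float = 100.0          # ms (cited model's 1 s, 10x faster)
    da_tau: float = 50.0              # ms (cited model's 200 ms, 4x faster)
    stdp_plus: float = 0.10
    stdp_minus: float = 0.12
    stdp_window_tau: float = 20.0     # ms, pairing window time constant
    stdp_gain: float = 0.05           # mV per unit trace x DA per ms
    avg_coeffs: tuple[float, float] = (0.01, 0.99)   # (old, new), as printed
    flip_ms: float = 60000.0          # silent-neuron bit-flip interval
    noise_rate_hz: float = 0.06       # Poisson kick rate per neuron
    kick_mv: float = 30.0
    stim_mv: float = 30.0
    trials: int = 5000
    seed: int = 0
    plastic: bool = True              # master switch for all plasticity
    stop_at_target: bool = False

    def __post_init__(self):
        if abs(sum(self.avg_coeffs) - 1.0) > 1e-9:
            raise ValueError("avg_coeffs must sum to 1")
        if not self.w_min < self.w_max:
            raise ValueError("need w_min < w_max")

    @property
    def n_neurons(self) -> int:
        return 1 + self.rows * self.cols


@dataclass
class SpikingTrace:
    phenotypes: list[str] = field(default_factory=list)
    fitness: list[float] = field(default_factory=list)
    running_avg: list[float] = field(default_factory=list)
    da_delivered: list[float] = field(default_factory=list)
    n_synapses: list[int] = field(default_factory=list)
    first_hit_trial: int | None = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "trial": range(len(self.fitness)),
            "phenotype": self.phenotypes,
            "fitness": self.fitness,
            "running_avg": self.running_avg,
            "da_delivered": self.da_delivered,
            "n_synapses": self.n_synapses,
        })

    def to_csv(self, path: str) -> None:
        self.to_dataframe().to_csv(path, index=False)


def reward_rule(fitness: float, running_avg: float, da_per_bit: float = 0.5,
                n_bits: int = 10, avg_coeffs: tuple[float, float] = (0.01, 0.99)
                ) -> tuple[float, float]:
    """Dopamine delta and updated running average for one trial.

    Above-average fitness rewards +``da_per_bit`` per correct (1) bit;
    below-average punishes -``da_per_bit`` per incorrect bit, counting every
    non-1 readout slot (including slots never produced) among ``n_bits``;
    exact equality delivers nothing.
    """
    if fitness > running_avg:
        da = da_per_bit * fitness
    elif fitness < running_avg:
        da = -da_per_bit * (n_bits - fitness)
    else:
        da = 0.0
    new_avg = avg_coeffs[0] * running_avg + avg_coeffs[1] * fitness
    return da, new_avg


def readout_phenotype(spike_log, stim_time: float, reward_time: float,
                      bits: np.ndarray, start_id: int = 0, n_bits: int = 10
                      ) -> tuple[str, float]:
    """Phenotype and fitness from a spike log.

    The first ``n_bits`` distinct non-start neurons spiking in
    ``[stim_time, reward_time)`` contribute their bits in spike order; the
    string may be shorter if activity dies out, and fitness is the count of
    ones in whatever was produced.
    """
    seen: list[int] = []
    for t, n in spike_log:
        if t < stim_time or t >= reward_time:
            continue
        if n == start_id or n in seen:
            continue
        seen.append(n)
        if len(seen) == n_bits:
            break
    phenotype = "".join(str(int(bits[n])) for n in seen)
    return phenotype, float(phenotype.count("1"))


class SpikingNet:
    """State container + elementary operations of the spiking PEA.

    Neuron ids: 0 is the start neuron; neuron (row r, column c) with
    r in [0, rows) and c in [0, cols) has id ``1 + c*rows + r``.
    """

    def __init__(self, cfg: SpikingConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.rng = rng
        n = cfg.n_neurons
        self.v = np.full(n, V_REST)
        self.u = np.full(n, U_REST)
        self.bits = np.zeros(n, dtype=np.int64)
        self.bits[1:] = rng.integers(0, 2, size=n - 1)
        self.last_spike = np.full(n, -1e12)
        self.last_flip = np.zeros(n)
        # synapse arrays
        self.syn_pre = np.zeros(0, dtype=np.int64)
        self.syn_post = np.zeros(0, dtype=np.int64)
        self.syn_w = np.zeros(0)
        self.syn_trace = np.zeros(0)
        self.syn_last_deliver = np.zeros(0)
        self.da = 0.0
        self._build_initial_synapses()
        self._reindex()

    # ------------------------------------------------------------------
    def neuron_id(self, row: int, col: int) -> int:
        return 1 + col * self.cfg.rows + row

    def row_col(self, nid: int) -> tuple[int, int]:
        return (nid - 1) % self.cfg.rows, (nid - 1) // self.cfg.rows

    @property
    def n_synapses(self) -> int:
        return len(self.syn_pre)

    def _build_initial_synapses(self) -> None:
        """Start fans out to every row of column 0; each neuron chains to the
        same row of the next column; weights uniform in [w_min, w_max]."""
        cfg = self.cfg
        pre, post = [], []
        for r in range(cfg.rows):
            pre.append(0)
            post.append(self.neuron_id(r, 0))
            for c in range(cfg.cols - 1):
                pre.append(self.neuron_id(r, c))
                post.append(self.neuron_id(r, c + 1))
        m = len(pre)
        self.syn_pre = np.asarray(pre, dtype=np.int64)
        self.syn_post = np.asarray(post, dtype=np.int64)
        self.syn_w = self.rng.uniform(cfg.w_min, cfg.w_max, size=m)
        self.syn_trace = np.zeros(m)
        self.syn_last_deliver = np.full(m, -1e12)

    def _reindex(self) -> None:
        n = self.cfg.n_neurons
        self.out_idx: list[list[int]] = [[] for _ in range(n)]
        self.in_idx: list[list[int]] = [[] for _ in range(n)]
        for s, (p, q) in enumerate(zip(self.syn_pre, self.syn_post)):
            self.out_idx[p].append(s)
            self.in_idx[q].append(s)

    def add_synapse(self, pre: int, post: int, w: float) -> int:
        self.syn_pre = np.append(self.syn_pre, pre)
        self.syn_post = np.append(self.syn_post, post)
        self.syn_w = np.append(self.syn_w, w)
        self.syn_trace = np.append(self.syn_trace, 0.0)
        self.syn_last_deliver = np.append(self.syn_last_deliver, -1e12)
        self._reindex()
        return len(self.syn_pre) - 1

    def remove_synapses(self, idx) -> None:
        if len(idx) == 0:
            return
        keep = np.ones(len(self.syn_pre), dtype=bool)
        keep[np.asarray(idx, dtype=np.int64)] = False
        self.syn_pre = self.syn_pre[keep]
        self.syn_post = self.syn_post[keep]
        self.syn_w = self.syn_w[keep]
        self.syn_trace = self.syn_trace[keep]
        self.syn_last_deliver = self.syn_last_deliver[keep]
        self._reindex()

    def has_synapse(self, pre: int, post: int) -> bool:
        return any(self.syn_post[s] == post for s in self.out_idx[pre])

    # ------------------------------------------------------------------
    def wta_choose(self, neuron: int) -> int | None:
        """Pick at most one outgoing synapse, probability proportional to
        weight; None when the neuron has no outputs."""
        outs = self.out_idx[neuron]
        if not outs:
            return None
        if len(outs) == 1:
            return outs[0]
        ws = self.syn_w[outs]
        r = self.rng.random() * ws.sum()
        acc = 0.0
        for s, w in zip(outs, ws):
            acc += w
            if r < acc:
                return s
        return outs[-1]

    def _enforce_out_caps(self, neuron: int) -> None:
        """Keep <= max_out outputs and total outflow <= outflow_cap by
        removing synapses with probability inversely proportional to weight.
        The start neuron's initial fan-out is exempt from the count cap."""
        cfg = self.cfg
        while True:
            outs = self.out_idx[neuron]
            over_count = neuron != 0 and len(outs) > cfg.max_out
            over_weight = len(outs) > 1 and \
                self.syn_w[outs].sum() > cfg.outflow_cap
            if not (over_count or over_weight):
                return
            inv = 1.0 / self.syn_w[outs]
            k = self.rng.choice(len(outs), p=inv / inv.sum())
            self.remove_synapses([outs[k]])

    def _adjacent_next(self, neuron: int) -> int | None:
        """Uniform adjacent-row neuron in the next column (None past the
        final column)."""
        cfg = self.cfg
        r, c = self.row_col(neuron)
        if c + 1 >= cfg.cols:
            return None
        rows = [rr for rr in (r - 1, r, r + 1) if 0 <= rr < cfg.rows]
        return self.neuron_id(rows[self.rng.integers(len(rows))], c + 1)

    def structural_step(self, neuron: int, force: bool = False) -> list[int]:
        """Activity-dependent synaptogenesis for one spiking neuron.

        With probability ``struct_prob`` the neuron grows a synapse to an
        adjacent-row neuron of the next column; that target immediately
        grows one onward synapse to an adjacent-row neuron of *its* next
        column, so the two-hop route returns to the original row (a bypass
        mutant) a third of the time and diverges otherwise.  Output caps are
        enforced after each addition.  Returns the new synapse indices.
        """
        cfg = self.cfg
        if neuron == 0:
            return []
        if not force and self.rng.random() >= cfg.struct_prob:
            return []
        target = self._adjacent_next(neuron)
        if target is None:
            return []
        created = []
        if not self.has_synapse(neuron, target):
            created.append(self.add_synapse(neuron, target, cfg.new_weight))
            self._enforce_out_caps(neuron)
        onward = self._adjacent_next(target)
        if onward is not None and not self.has_synapse(target, onward):
            created.append(self.add_synapse(target, onward, cfg.new_weight))
            self._enforce_out_caps(target)
        return created

    def flip_silent_bits(self, now: float) -> int:
        """Flip the phenotype bit of every neuron that has been silent for a
        full flip interval since its last spike or flip."""
        cfg = self.cfg
        ref = np.maximum(self.last_spike[1:], self.last_flip[1:])
        mask = (now - ref) >= cfg.flip_ms
        idx = np.nonzero(mask)[0] + 1
        self.bits[idx] = 1 - self.bits[idx]
        self.last_flip[idx] = now
        return len(idx)


def calibrate_background(cfg: SpikingConfig, sim_ms: int = 200_000,
                         seed: int = 0) -> float:
    """Measured mean firing rate (Hz per neuron) under background noise with
    all plasticity frozen; used to pick ``noise_rate_hz`` so the grid sits in
    the 0.1-1 Hz band (each kick triggers a WTA cascade down the columns, so
    the realized rate exceeds the kick rate severalfold)."""
    c = SpikingConfig(**{**cfg.__dict__, "plastic": False,
                         "trials": max(1, sim_ms // cfg.trial_ms),
                         "stim_mv": 0.0, "seed": seed})
    sim = _Simulator(c)
    sim.run()
    return sim.total_spikes / (c.n_neurons * (c.trials * c.trial_ms) / 1000.0)


class _Simulator:
    """Per-millisecond event loop with closed-form fast-forward through
    quiet stretches (no pending deliveries, no recent spikes: trace/DA decay,
    their weight-change integral, and silent-synapse decay all have exact
    closed forms between events)."""

    QUIET_AFTER = 60.0   # ms since last spike before fast-forward engages

    def __init__(self, cfg: SpikingConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.net = SpikingNet(cfg, self.rng)
        self.trace = SpikingTrace()
        self.running_avg = 0.0
        self.total_spikes = 0
        self._trace_decay = math.exp(-1.0 / cfg.trace_tau)
        self._da_decay = math.exp(-1.0 / cfg.da_tau)
        self._tau_eff = 1.0 / (1.0 / cfg.trace_tau + 1.0 / cfg.da_tau)
        self._noise_scale = (1000.0 / (cfg.noise_rate_hz * cfg.n_neurons)
                             if cfg.noise_rate_hz > 0 else math.inf)
        self._next_noise = self._draw_noise(0.0)
        self._pending: list[tuple[int, float]] = []   # (syn, weight) next ms
        self._last_activity = -1e12

    def _draw_noise(self, now: float) -> float:
        if not math.isfinite(self._noise_scale):
            return math.inf
        return now + self.rng.exponential(self._noise_scale)

    # ------------------------------------------------------------------
    def run(self) -> SpikingTrace:
        cfg = self.cfg
        net = self.net
        for trial in range(cfg.trials):
            t0 = trial * cfg.trial_ms
            stim_t = t0 + cfg.stim_ms
            reward_t = t0 + cfg.reward_ms
            spike_log: list[tuple[float, int]] = []
            t = t0
            rewarded = False
            while t < t0 + cfg.trial_ms:
                if self._can_skip(t):
                    horizon = min(self._next_noise,
                                  stim_t if t <= stim_t else math.inf,
                                  reward_t if not rewarded else math.inf,
                                  t0 + cfg.trial_ms)
                    if horizon > t + 1:
                        self._skip_to(t, math.floor(horizon))
                        t = math.floor(horizon)
                        continue
                self._step_ms(t, stim_t, spike_log)
                t += 1
                if not rewarded and t >= reward_t:
                    self._deliver_reward(spike_log, stim_t, reward_t, trial)
                    rewarded = True
            if not rewarded:
                self._deliver_reward(spike_log, stim_t, reward_t, trial)
            if cfg.plastic:
                net.flip_silent_bits(t0 + cfg.trial_ms)
            if cfg.stop_at_target and self.trace.first_hit_trial is not None:
                break
        return self.trace

    # ------------------------------------------------------------------
    def _can_skip(self, t: float) -> bool:
        return (not self._pending
                and t - self._last_activity >= self.QUIET_AFTER)

    def _skip_to(self, t: float, t2: float) -> None:
        """Advance from t to t2 through a quiet stretch in closed form."""
        cfg = self.cfg
        net = self.net
        dt = t2 - t
        if dt <= 0:
            return
        if cfg.plastic and net.n_synapses:
            if abs(net.da) > 1e-12:
                factor = self._tau_eff * (1.0 - math.exp(-dt / self._tau_eff))
                net.syn_w += cfg.stdp_gain * net.syn_trace * net.da * factor
                np.clip(net.syn_w, None, cfg.w_max, out=net.syn_w)
            net.syn_trace *= math.exp(-dt / cfg.trace_tau)
            net.da *= math.exp(-dt / cfg.da_tau)
            # silent-presynaptic linear decay, piecewise-exact per synapse
            eligible_from = np.maximum(
                t, net.last_spike[net.syn_pre] + cfg.silent_ms)
            decay_ms = np.clip(t2 - eligible_from, 0.0, None)
            net.syn_w -= cfg.decay_rate * decay_ms
            self._cull_weak()
        # membrane relaxation toward rest (u decays at rate a, v follows)
        net.u = U_REST + (net.u - U_REST) * math.exp(-RS_A * dt)
        disc = np.clip(25.0 - 0.16 * (140.0 - net.u), 0.0, None)
        net.v = (-5.0 - np.sqrt(disc)) / 0.08

    def _cull_weak(self) -> None:
        net = self.net
        weak = np.nonzero(net.syn_w < self.cfg.w_min)[0]
        if len(weak):
            net.remove_synapses(weak)

    # ------------------------------------------------------------------
    def _step_ms(self, t: float, stim_t: float, spike_log) -> None:
        cfg = self.cfg
        net = self.net
        current = np.zeros(cfg.n_neurons)
        # scheduled WTA deliveries from last ms arrive now
        delivered = self._pending
        self._pending = []
        for s, w in delivered:
            if s >= net.n_synapses:      # synapse vanished meanwhile
                continue
            post = net.syn_post[s]
            current[post] += w
            net.syn_last_deliver[s] = t
            # post-before-pre pairing depresses the trace
            dt_post = t - net.last_spike[post]
            if 0.0 < dt_post <= 5 * cfg.stdp_window_tau:
                net.syn_trace[s] -= cfg.stdp_minus * math.exp(
                    -dt_post / cfg.stdp_window_tau)
            self._last_activity = t
        # background noise kicks (Poisson, one neuron per event)
        while t >= self._next_noise:
            n = int(self.rng.integers(cfg.n_neurons))
            current[n] += cfg.kick_mv
            self._next_noise = self._draw_noise(self._next_noise)
            self._last_activity = t
        if t == stim_t and cfg.stim_mv > 0.0:
            current[0] += cfg.stim_mv
            self._last_activity = t
        # integrate all neurons
        v, u = net.v, net.u
        for _ in range(2):
            v += 0.5 * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
            np.clip(v, -90.0, V_PEAK, out=v)
        u += RS_A * (RS_B * v - u)
        spiked = np.nonzero(v >= V_PEAK)[0]
        v[spiked] = RS_C
        u[spiked] += RS_D
        for n in spiked:
            n = int(n)
            net.last_spike[n] = t
            spike_log.append((t, n))
            self.total_spikes += 1
            self._last_activity = t
            # pre-before-post pairing potentiates recently delivering inputs
            for s in net.in_idx[n]:
                dt_pre = t - net.syn_last_deliver[s]
                if 0.0 <= dt_pre <= 5 * cfg.stdp_window_tau:
                    net.syn_trace[s] += cfg.stdp_plus * math.exp(
                        -dt_pre / cfg.stdp_window_tau)
            # WTA: exactly one delivery scheduled for t+1
            s = net.wta_choose(n)
            if s is not None:
                self._pending.append((s, float(net.syn_w[s])))
            if cfg.plastic:
                net.structural_step(n)
        if cfg.plastic and net.n_synapses:
            if abs(net.da) > 1e-9:
                net.syn_w += cfg.stdp_gain * net.syn_trace * net.da
                np.clip(net.syn_w, None, cfg.w_max, out=net.syn_w)
            net.syn_trace *= self._trace_decay
            net.da *= self._da_decay
            silent = (t - net.last_spike[net.syn_pre]) >= cfg.silent_ms
            if silent.any():
                net.syn_w[silent] -= cfg.decay_rate
            self._cull_weak()

    # ------------------------------------------------------------------
    def _deliver_reward(self, spike_log, stim_t, reward_t, trial) -> None:
        cfg = self.cfg
        phenotype, fitness = readout_phenotype(
            spike_log, stim_t, reward_t, self.net.bits, n_bits=cfg.cols)
        da_delta = 0.0
        if cfg.plastic:
            da_delta, self.running_avg = reward_rule(
                fitness, self.running_avg, cfg.da_per_bit, cfg.cols,
                cfg.avg_coeffs)
            self.net.da += da_delta
        else:
            _, self.running_avg = reward_rule(
                fitness, self.running_avg, 0.0, cfg.cols, cfg.avg_coeffs)
        tr = self.trace
        tr.phenotypes.append(phenotype)
        tr.fitness.append(fitness)
        tr.running_avg.append(self.running_avg)
        tr.da_delivered.append(da_delta)
        tr.n_synapses.append(self.net.n_synapses)
        if tr.first_hit_trial is None and phenotype == "1" * cfg.cols:
            tr.first_hit_trial = trial


def run_spiking_pea(cfg: SpikingConfig) -> SpikingTrace:
    """Run the spiking path-evolution experiment; reproducible from the seed."""
    return _Simulator(cfg).run()
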