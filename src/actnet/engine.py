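"""Event-driven simulation kernel.

A model is compiled to flat numpy arrays and advanced one event at a
time: every non-clamped node accumulates a signed net rate from its
incoming edges; the node with the earliest timeout

    t_next(v) = t_ref(v) + (1/levels_v) / |net_rate(v)|

moves by +/-1 and global time jumps to that timeout.  ``t_ref(v)`` is
the time of v's last move (or the moment v last became movable), so the
discrete system tracks the normalized rate equations dx/dt = net_rate.
Ties between simultaneous timeouts break toward the lower node index,
making the whole loop a pure function of (model, init, max_events).

Termination is by quiescence (fixed point), by recurrence of the
activity vector within a sliding window (limit cycle; the first
recurrence closes the cycle), or by the event budget (unresolved).
The kernel is identical pure-Python/numba code; numba just makes the
Monte-Carlo screens tractable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if len(args) == 1 and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


STATUS_FIXED_POINT = 0
STATUS_CYCLE = 1
STATUS_TRUNCATED = 2

_RATE_EPS = 1e-12  # net rates below this are treated as exactly zero


@njit(cache=True)
def _kernel(
    a,
    levels,
    clamped,
    e_scn,
    e_sign,
    e_k,
    e_r1,
    e_r2,
    e_tgt,
    max_events,
    zob,
    W,
    ring_states,
    ring_times,
    ring_hash,
    ring_phase,
    ev_node,
    ev_level,
    ev_time,
    mean_out,
):
    n = a.shape[0]
    E = e_k.shape[0]
    t = 0.0
    tref = np.zeros(n)
    rho = np.zeros(n)
    blocked = np.zeros(n, dtype=np.bool_)

    h = np.int64(0)
    for i in range(n):
        h ^= zob[i, a[i]]
    ring_states[0] = a
    ring_times[0] = 0.0
    ring_hash[0] = h
    for q in range(n):
        ring_phase[0, q] = 0.0

    c = 0
    status = STATUS_TRUNCATED
    cyc_start = np.int64(-1)
    period = np.int64(0)

    while c < max_events:
        for i in range(n):
            rho[i] = 0.0
        for j in range(E):
            r1 = e_r1[j]
            act = a[r1] / levels[r1]
            scn = e_scn[j]
            if scn == 1:
                rate = e_k[j] * act
            elif scn == 2:
                tg = e_tgt[j]
                s = a[tg] / levels[tg]
                if e_sign[j] > 0:
                    rate = e_k[j] * act * (1.0 - s)
                else:
                    rate = e_k[j] * act * s
            else:
                r2 = e_r2[j]
                rate = e_k[j] * act * (a[r2] / levels[r2])
            if e_sign[j] > 0:
                rho[e_tgt[j]] += rate
            else:
                rho[e_tgt[j]] -= rate

        best_i = -1
        best_t = 0.0
        for i in range(n):
            if clamped[i]:
                continue
            ri = rho[i]
            movable = (ri > _RATE_EPS and a[i] < levels[i]) or (
                ri < -_RATE_EPS and a[i] > 0
            )
            if not movable:
                # saturated / quiescent nodes schedule no event; their
                # clock restarts when conditions change
                blocked[i] = True
                continue
            if blocked[i]:
                tref[i] = t
                blocked[i] = False
            ti = tref[i] + (1.0 / levels[i]) / abs(ri)
            if ti < t:
                ti = t  # overdue timeout fires immediately
            if best_i == -1 or ti < best_t:
                best_i = i
                best_t = ti

        if best_i == -1:
            status = STATUS_FIXED_POINT
            break

        i = best_i
        old = a[i]
        if rho[i] > 0.0:
            a[i] = old + 1
        else:
            a[i] = old - 1
        t = best_t
        tref[i] = t
        h ^= zob[i, old] ^ zob[i, a[i]]
        ev_node[c] = i
        ev_level[c] = a[i]
        ev_time[c] = t
        c += 1

        idx = c % W
        for q in range(n):
            ring_states[idx, q] = a[q]
            # per-node clock phase; 0 for clamped/blocked nodes
            if clamped[q] or blocked[q]:
                ring_phase[idx, q] = 0.0
            else:
                ring_phase[idx, q] = t - tref[q]
        ring_times[idx] = t
        ring_hash[idx] = h

        phase_tol = 1e-6 * (1.0 + t)
        dmax = c if c < W else W - 1
        found = False
        for d in range(1, dmax + 1):
            jdx = (c - d) % W
            if ring_hash[jdx] != h:
                continue
            same = True
            for q in range(n):
                if ring_states[jdx, q] != a[q]:
                    same = False
                    break
            if same:
                # a genuine cycle must also recur in clock phase,
                # otherwise slow background dynamics is still running
                for q in range(n):
                    if abs(ring_phase[jdx, q] - ring_phase[idx, q]) > phase_tol:
                        same = False
                        break
            if not same:
                continue
            # recurrence closes a cycle of d states; report the
            # time-weighted mean activity over one period
            total = t - ring_times[jdx]
            for q in range(n):
                mean_out[q] = 0.0
            if total > 0.0:
                for m in range(d):
                    s_idx = (c - d + m) % W
                    nx_idx = (c - d + m + 1) % W
                    dt = ring_times[nx_idx] - ring_times[s_idx]
                    for q in range(n):
                        mean_out[q] += ring_states[s_idx, q] * dt
                for q in range(n):
                    mean_out[q] /= total
            else:
                for m in range(d):
                    s_idx = (c - d + m) % W
                    for q in range(n):
                        mean_out[q] += ring_states[s_idx, q]
                for q in range(n):
                    mean_out[q] /= d
            status = STATUS_CYCLE
            cyc_start = c - d
            period = d
            found = True
            break
        if found:
            break

    if status != STATUS_CYCLE:
        for q in range(n):
            mean_out[q] = a[q]
    return status, c, cyc_start, period, t


@dataclass
class RunResult:
    """Raw kernel output for one simulation run."""

    status: int
    n_events: int
    cycle_start: int
    period: int
    final_time: float
    final_state: np.ndarray  # int64 activities after the last event
    mean_levels: np.ndarray  # float64; cycle mean, else final state
    ev_node: np.ndarray | None = None
    ev_level: np.ndarray | None = None
    ev_time: np.ndarray | None = None


class CompiledModel:
    """A NetworkModel flattened to arrays for the kernel."""

    def __init__(self, model):
        model.validate()
        self.model = model
        self.node_names = tuple(n.name for n in model.nodes)
        self.index = {name: i for i, name in enumerate(self.node_names)}
        n = len(model.nodes)
        self.n = n
        self.levels = np.array([nd.levels for nd in model.nodes], dtype=np.int64)
        self.clamped = np.array(
            [nd.clamp is not None for nd in model.nodes], dtype=np.bool_
        )
        self.clamp_values = np.array(
            [-1 if nd.clamp is None else nd.clamp for nd in model.nodes],
            dtype=np.int64,
        )
        self.initial = np.array(
            [nd.clamp if nd.clamp is not None else nd.initial for nd in model.nodes],
            dtype=np.int64,
        )
        E = len(model.edges)
        self.e_scn = np.empty(E, dtype=np.int64)
        self.e_sign = np.empty(E, dtype=np.int64)
        self.e_k = np.empty(E, dtype=np.float64)
        self.e_r1 = np.empty(E, dtype=np.int64)
        self.e_r2 = np.empty(E, dtype=np.int64)
        self.e_tgt = np.empty(E, dtype=np.int64)
        for j, e in enumerate(model.edges):
            self.e_scn[j] = e.scenario
            self.e_sign[j] = 1 if e.sign == "activation" else -1
            self.e_k[j] = e.k
            self.e_r1[j] = self.index[e.regulators[0]]
            self.e_r2[j] = (
                self.index[e.regulators[1]] if len(e.regulators) > 1 else -1
            )
            self.e_tgt[j] = self.index[e.target]
        # deterministic Zobrist table for incremental state hashing
        rng = np.random.default_rng(0x5EED_ACE)
        max_lv = int(self.levels.max()) if n else 1
        self.zobrist = rng.integers(
            np.iinfo(np.int64).min, np.iinfo(np.int64).max, size=(max(n, 1), max_lv + 1), dtype=np.int64
        )
        self.window = int(max(128, 4 * n + 4))

    def default_max_events(self) -> int:
        lv = int(self.levels.max()) if self.n else 100
        return 10 * lv * max(self.n, 1)

    def make_init(self, overrides=None) -> np.ndarray:
        a = self.initial.copy()
        if overrides is not None:
            for name, level in overrides.items():
                i = self.index[name]
                if not (0 <= level <= self.levels[i]):
                    raise ValueError(
                        f"initial level {level} for {name!r} outside bounds"
                    )
                a[i] = level
        a[self.clamped] = self.clamp_values[self.clamped]
        return a

    def run(self, a0: np.ndarray, max_events: int | None = None,
            record: bool = False) -> RunResult:
        if max_events is None:
            max_events = self.default_max_events()
        n = self.n
        a = np.array(a0, dtype=np.int64, copy=True)
        if n == 0:
            return RunResult(
                STATUS_FIXED_POINT, 0, -1, 0, 0.0, a,
                np.zeros(0, dtype=np.float64),
            )
        a[self.clamped] = self.clamp_values[self.clamped]
        W = self.window
        ring_states = np.zeros((W, n), dtype=np.int64)
        ring_times = np.zeros(W, dtype=np.float64)
        ring_hash = np.zeros(W, dtype=np.int64)
        ring_phase = np.zeros((W, n), dtype=np.float64)
        ev_node = np.empty(max_events, dtype=np.int64)
        ev_level = np.empty(max_events, dtype=np.int64)
        ev_time = np.empty(max_events, dtype=np.float64)
        mean_out = np.zeros(n, dtype=np.float64)
        status, c, cyc_start, period, t = _kernel(
            a,
            self.levels,
            self.clamped,
            self.e_scn,
            self.e_sign,
            self.e_k,
            self.e_r1,
            self.e_r2,
            self.e_tgt,
            max_events,
            self.zobrist,
            W,
            ring_states,
            ring_times,
            ring_hash,
            ring_phase,
            ev_node,
            ev_level,
            ev_time,
            mean_out,
        )
        res = RunResult(
            int(status), int(c), int(cyc_start), int(period), float(t), a, mean_out
        )
        if record:
            res.ev_node = ev_node[:c].copy()
            res.ev_level = ev_level[:c].copy()
            res.ev_time = ev_time[:c].copy()
        return res
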