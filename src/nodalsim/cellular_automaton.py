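"""Three-state cellular-automaton conduction model.

Each node is resting, excited or refractory.  A resting node accumulates an
excitation counter e_i (gain x number of currently excited neighbours per
step) and fires when e_i reaches the threshold theta; it then stays excited
for E steps (exciting its neighbours), refractory for R steps, and returns
to rest.  The counter resets on firing and on leaving refractoriness.
Updates are synchronous.

Conduction velocity is controlled by the firing delay (steps of
supra-threshold input required, theta/gain) and the neighbourhood reach
(lattice radius over which excited nodes are counted); the refractory
period by (E + R) * dt.  ``ca_tune_cv`` searches these integers against a
measured 1-D fibre velocity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import convolve

from .geometry import CODE_TISSUE, Geometry

__all__ = [
    "CAParams",
    "CAState",
    "CAModel",
    "ca_step",
    "ca_refractory_period",
    "ca_cv_1d",
    "ca_tune_cv",
    "CARangeError",
    "REST",
    "EXCITED",
    "REFRACTORY",
]

REST, EXCITED, REFRACTORY = 0, 1, 2


class CARangeError(ValueError):
    """Requested conduction velocity outside the automaton's range."""


@dataclass(frozen=True)
class CAParams:
    """Per-tissue automaton constants.

    theta: excitation threshold (counter units); gain: counter increment
    per excited neighbour per step; excited / refractory: state durations
    in time steps; reach: neighbourhood radius (Euclidean, in nodes);
    neighborhood: 'face' (6/4-connected at reach 1) or 'moore'.
    """

    theta: float
    gain: float = 1.0
    excited: int = 12
    refractory: int = 60
    reach: int = 1
    neighborhood: str = "face"

    def __post_init__(self):
        if self.theta <= 0 or self.excited < 1 or self.refractory < 0:
            raise ValueError("CAParams requires theta > 0, E >= 1, R >= 0")
        if self.reach < 1:
            raise ValueError("neighbourhood reach must be >= 1")


@dataclass
class CAState:
    """Lattice state: per-node phase type, phase counter and excitation
    counter, plus the global step index."""

    state: np.ndarray    # int8: REST / EXCITED / REFRACTORY
    phase: np.ndarray    # int32 steps spent in the current state
    counter: np.ndarray  # float64 excitation counter e_i
    step: int = 0

    @classmethod
    def resting(cls, shape):
        return cls(
            state=np.zeros(shape, dtype=np.int8),
            phase=np.zeros(shape, dtype=np.int32),
            counter=np.zeros(shape, dtype=np.float64),
        )

    def copy(self):
        return CAState(self.state.copy(), self.phase.copy(),
                       self.counter.copy(), self.step)


def _kernel(reach: int, neighborhood: str) -> np.ndarray:
    n = 2 * reach + 1
    z, y, x = np.mgrid[-reach:reach + 1, -reach:reach + 1,
                       -reach:reach + 1]
    if neighborhood == "moore":
        k = np.ones((n, n, n), dtype=np.float64)
    elif neighborhood == "face":
        if reach == 1:
            k = (np.abs(x) + np.abs(y) + np.abs(z) <= 1).astype(np.float64)
        else:
            k = (x * x + y * y + z * z <= reach * reach).astype(np.float64)
    else:
        raise ValueError(f"unknown neighbourhood {neighborhood!r}")
    k[reach, reach, reach] = 0.0
    return k


_KERNEL_CACHE: dict = {}


def _cached_kernel(reach, neighborhood):
    key = (reach, neighborhood)
    if key not in _KERNEL_CACHE:
        _KERNEL_CACHE[key] = _kernel(reach, neighborhood)
    return _KERNEL_CACHE[key]


def ca_step(st: CAState, labels: np.ndarray, params: dict) -> CAState:
    """One synchronous automaton update; pure function of the old state.

    ``params`` maps label codes to CAParams.  Background (code 0) voxels
    never participate.
    """
    tissue = labels != 0
    excited = (st.state == EXCITED) & tissue
    new = st.copy()
    new.step = st.step + 1

    # neighbour counts, one convolution per distinct neighbourhood
    counts = np.zeros(st.state.shape, dtype=np.float64)
    if excited.any():
        exc_f = excited.astype(np.float64)
        flat2d = st.state.shape[2] == 1
        by_hood: dict = {}
        for code, p in params.items():
            by_hood.setdefault((p.reach, p.neighborhood), []).append(code)
        for (reach, hood), codes in by_hood.items():
            m = np.isin(labels, codes) & (labels != 0)
            if not m.any():
                continue
            k = _cached_kernel(reach, hood)
            if flat2d:
                k = k[:, :, reach:reach + 1]  # exact on single-layer grids
            c = convolve(exc_f, k, mode="constant", cval=0.0)
            counts[m] = c[m]

    gain = np.zeros_like(counts)
    theta = np.full_like(counts, np.inf)
    e_dur = np.zeros(st.state.shape, dtype=np.int32)
    r_dur = np.zeros(st.state.shape, dtype=np.int32)
    for code, p in params.items():
        m = labels == code
        gain[m] = p.gain
        theta[m] = p.theta
        e_dur[m] = p.excited
        r_dur[m] = p.refractory

    resting = (st.state == REST) & tissue
    acc = st.counter + gain * counts
    fire = resting & (acc >= theta)
    hold = resting & ~fire
    new.counter[hold] = acc[hold]
    new.state[fire] = EXCITED
    new.phase[fire] = 0
    new.counter[fire] = 0.0

    exc = (st.state == EXCITED) & tissue
    done_e = exc & (st.phase + 1 >= e_dur)
    new.phase[exc & ~done_e] = st.phase[exc & ~done_e] + 1
    # entering refractoriness; R = 0 falls straight through to rest
    to_rest = done_e & (r_dur == 0)
    to_refr = done_e & (r_dur > 0)
    new.state[to_refr] = REFRACTORY
    new.phase[to_refr] = 0
    new.state[to_rest] = REST
    new.phase[to_rest] = 0
    new.counter[to_rest] = 0.0

    refr = (st.state == REFRACTORY) & tissue
    done_r = refr & (st.phase + 1 >= r_dur)
    new.phase[refr & ~done_r] = st.phase[refr & ~done_r] + 1
    new.state[done_r] = REST
    new.phase[done_r] = 0
    new.counter[done_r] = 0.0
    return new


class CAModel:
    """Cellular-automaton engine over a labelled geometry.

    Shares the geometry / probe / stimulus interfaces of the
    reaction-diffusion engine so the same measurements apply.
    """

    def __init__(self, geom: Geometry, params: dict, dt_ms: float = 1.0):
        geom.validate()
        self.geom = geom
        self.labels = geom.labels
        codes = {int(c) for c in np.unique(self.labels) if c != 0}
        missing = codes - set(params)
        if missing:
            raise ValueError(f"no CA parameters for codes {sorted(missing)}")
        self.params = {int(k): v for k, v in params.items()}
        self.dt = float(dt_ms)
        self.state = CAState.resting(self.labels.shape)

    @classmethod
    def from_config(cls, geom: Geometry, cfg_ca: dict):
        """Build from the config's ``ca`` section (per-tissue entries)."""
        dt = float(cfg_ca.get("dt_ms", 1.0))
        by_tissue = {
            name: CAParams(
                theta=float(e["theta"]), gain=float(e.get("gain", 1.0)),
                excited=int(e["excited"]), refractory=int(e["refractory"]),
                reach=int(e.get("reach", 1)),
                neighborhood=e.get("neighborhood", "face"),
            )
            for name, e in cfg_ca["tissues"].items()
        }
        params = {}
        for code in np.unique(geom.labels):
            code = int(code)
            if code == 0:
                continue
            tissue = CODE_TISSUE[code]
            if tissue in ("atrial", "san", "block"):
                t = "atrial"
            else:
                t = tissue
            if t not in by_tissue:
                raise ValueError(f"config lacks CA parameters for {t!r}")
            params[code] = by_tissue[t]
        return cls(geom, params, dt)

    def stimulate(self, region_mask: np.ndarray):
        """Excite resting nodes in the region (refractory nodes ignored)."""
        m = region_mask & (self.labels != 0) & (self.state.state == REST)
        self.state.state[m] = EXCITED
        self.state.phase[m] = 0
        self.state.counter[m] = 0.0

    def step(self, n: int = 1):
        for _ in range(n):
            self.state = ca_step(self.state, self.labels, self.params)
        return self.state

    def trace_value(self, idx) -> float:
        """Triangular pseudo-potential at a node: 1 while excited, linear
        decline through refractoriness, 0 at rest."""
        s = self.state.state[idx]
        if s == EXCITED:
            return 1.0
        if s == REFRACTORY:
            r = max(1, int(self.params[int(self.labels[idx])].refractory))
            return 1.0 - (self.state.phase[idx] + 1) / (r + 1)
        return 0.0

    def run(self, n_steps: int, stimuli=(), probes: dict | None = None):
        """Advance the automaton; ``stimuli`` is a list of (step, mask).

        Returns probe traces as APTrace objects (time in ms).
        """
        from .measurements import APTrace

        probes = dict(probes if probes is not None else self.geom.probes)
        stim = {}
        for s, m in stimuli:
            stim.setdefault(int(s), []).append(m)
        times = np.arange(n_steps + 1) * self.dt
        data = {k: np.zeros(n_steps + 1) for k in probes}
        for i in range(n_steps + 1):
            for m in stim.get(self.state.step, []):
                self.stimulate(m)
            for k, idx in probes.items():
                data[k][i] = self.trace_value(tuple(idx))
            if i < n_steps:
                self.step()
        return {k: APTrace(name=k, t=times, u=v) for k, v in data.items()}


# ---------------------------------------------------------------------------
# 1-D fibre characterization
# ---------------------------------------------------------------------------

def _fibre(n_nodes: int, code: int = 1, dx_um: float = 60.0) -> Geometry:
    from .geometry import Geometry, LabelVolume

    labels = np.full((n_nodes, 1, 1), code, dtype=np.int8)
    return Geometry(LabelVolume(labels, dx_um=dx_um))


def ca_cv_1d(p: CAParams, dx_um: float = 60.0, dt_ms: float = 1.0,
             n_nodes: int = 300) -> float:
    """Steady-state wavefront speed on a uniform 1-D fibre (m/s)."""
    geom = _fibre(n_nodes)
    model = CAModel(geom, {1: p}, dt_ms)
    m = np.zeros(geom.shape, dtype=bool)
    m[0] = True
    model.stimulate(m)
    first = np.full(n_nodes, -1)
    for step in range(1, 40 * n_nodes):
        model.step()
        exc = model.state.state[:, 0, 0] == EXCITED
        newly = exc & (first < 0)
        first[newly[:n_nodes]] = step
        if first[-1] >= 0:
            break
    i0, i1 = n_nodes // 3, 2 * n_nodes // 3
    if first[i1] < 0 or first[i1] <= first[i0]:
        raise CARangeError("wavefront did not propagate along the fibre")
    nodes_per_step = (i1 - i0) / (first[i1] - first[i0])
    return nodes_per_step * (dx_um / 1000.0) / dt_ms


def ca_refractory_period(p: CAParams, dt_ms: float = 1.0,
                         n_nodes: int = 120, dx_um: float = 60.0) -> float:
    """Effective refractory period from an S1-S2 scan on a 1-D fibre (ms).

    Returns the shortest S1-to-S2 interval (in dt steps) for which the
    premature wave reaches the distal probe.
    """
    def propagates(ci_steps: int) -> bool:
        geom = _fibre(n_nodes)
        model = CAModel(geom, {1: p}, dt_ms)
        m = np.zeros(geom.shape, dtype=bool)
        m[:2] = True
        far = n_nodes - 2
        model.stimulate(m)
        n_acts = 0
        prev = False
        total = ci_steps + 6 * (p.excited + p.refractory) + 20 * n_nodes
        for step in range(1, total):
            if step == ci_steps:
                model.stimulate(m)
            exc = model.state.state[far, 0, 0] == EXCITED
            if exc and not prev:
                n_acts += 1
                if n_acts >= 2:
                    return True
            prev = exc
            model.step()
        return False

    lo = 1
    hi = 4 * (p.excited + p.refractory) + 10
    if not propagates(hi):
        raise CARangeError("S2 never propagates; fibre cannot recover")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if propagates(mid):
            hi = mid
        else:
            lo = mid
    return hi * dt_ms


def ca_tune_cv(target_cv: float, dx_um: float = 60.0, dt_ms: float = 1.0,
               neighborhood: str = "face", max_reach: int = 8,
               max_delay: int = 30, rp_ms: float | None = None,
               tol: float = 0.10) -> CAParams:
    """Find automaton constants whose 1-D fibre CV matches the target.

    Searches the neighbourhood reach and the firing delay (theta at gain 1).
    Raises CARangeError listing the achievable bounds when the target is
    outside ``tol`` (fractional).  If ``rp_ms`` is given, the refractory
    duration is set so E + R = rp_ms / dt.
    """
    v_node = dx_um / 1000.0 / dt_ms     # one node per step, m/s
    v_min = v_node / max_delay
    v_max = v_node * max_reach
    best = None
    for reach in range(1, max_reach + 1):
        for delay in range(1, max_delay + 1):
            p = CAParams(theta=float(delay), gain=1.0,
                         excited=max(12, delay + 2), refractory=60,
                         reach=reach, neighborhood=neighborhood)
            try:
                cv = ca_cv_1d(p, dx_um, dt_ms)
            except CARangeError:
                continue
            err = abs(cv - target_cv) / target_cv
            if best is None or err < best[0]:
                best = (err, p, cv)
            if err < 0.005:
                break
        if best is not None and best[0] < 0.005:
            break
    if best is None or best[0] > tol:
        raise CARangeError(
            f"target {target_cv:g} m/s unreachable; achievable range is "
            f"about [{v_min:g}, {v_max:g}] m/s at dx={dx_um} um, "
            f"dt={dt_ms} ms"
        )
    p = best[1]
    if rp_ms is not None:
        total = int(round(rp_ms / dt_ms))
        p = replace(p, refractory=max(0, total - p.excited))
    return p
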