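"""Scenario drivers: strand characterization and the three nodal experiments.

* ``measure_strand`` runs the 50x5x5 strand protocol (first-three-layer
  stimulus, conduction velocity over layers 10-40, mid-strand APD90 and
  upstroke, S1-S2 refractory period) for any tissue.
* ``run_sinus`` lets the idealized atrium free-run from the sinoatrial node.
* ``run_af`` induces an atrial-fibrillation-like reentry with a premature
  planar stimulus at the superior-caval margin.
* ``run_echo`` reproduces the ventricular-echo-beat sequence on the
  dual-pathway ring with the cellular-automaton engine.

All scenarios are deterministic; a config hash is recorded in every result.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from . import measurements as ms
from .cellular_automaton import CAModel
from .geometry import (Geometry, make_dual_pathway_ring,
                       make_idealized_right_atrium, make_strand)
from .solver import Simulation
from .tissue_kinetics import ModelConfig, default_config, san_limit_cycle

__all__ = [
    "StrandResult",
    "measure_strand",
    "san_holding_state",
    "san_cycle_length",
    "run_sinus",
    "run_af",
    "run_echo",
    "find_echo_window",
    "SinusResult",
    "AFResult",
    "EchoResult",
    "DEFAULT_AF_S2_MS",
    "DEFAULT_AF_COUPLING_SCALE",
]

#: Premature-stimulus time for the desk-scale AF scenario (ms after start);
#: midpoint of the vulnerable window found by ``scan`` in scripts/calibrate.py.
DEFAULT_AF_S2_MS = 170.0

#: Diffusion (coupling) scale applied in the AF scenario so the atrial
#: wavelength fits the desk-scale sheet.
DEFAULT_AF_COUPLING_SCALE = 1.0 / 16.0


def config_hash(cfg: ModelConfig) -> str:
    payload = json.dumps(
        {name: vars(p) for name, p in cfg.tissues.items()}
        | {"unit": cfg.diffusion_unit, "rho": cfg.recovery_boost,
           "ratio": cfg.anisotropy_ratio},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# SAN single-cell utilities
# ---------------------------------------------------------------------------

def san_holding_state(cfg: ModelConfig | None = None,
                      fraction: float | None = None):
    """Diastolic holding state for paced SAN protocols.

    Integrates an isolated SAN element to its limit cycle and returns
    ``(cycle_length_ms, u0, v0)`` where (u0, v0) is the state a given
    fraction of the way through diastole (maximum diastolic potential ->
    next activation onset).
    """
    cfg = cfg or default_config()
    frac = cfg.san_hold_fraction if fraction is None else fraction
    t, u, v, cl = san_limit_cycle(cfg.tissues["san"], cfg)
    imdp = int(np.argmin(u))
    ihold = imdp + int(frac * (len(u) - imdp))
    ihold = min(ihold, len(u) - 1)
    return cl, float(u[ihold]), float(v[ihold])


def san_cycle_length(cfg: ModelConfig | None = None,
                     use_strand: bool = True) -> float:
    """Spontaneous cycle length (ms) of the free-running SAN model."""
    cfg = cfg or default_config()
    if not use_strand:
        return san_holding_state(cfg)[0]
    geom = make_strand(tissue="san")
    sim = Simulation(geom, cfg)
    res = sim.run(1500.0, probes={"mid": geom.probes["mid"]})
    return ms.cycle_length(res.traces["mid"], cfg.activation_threshold)


# ---------------------------------------------------------------------------
# strand characterization (the published-table protocol)
# ---------------------------------------------------------------------------

@dataclass
class StrandResult:
    tissue: str
    cv: float            # m/s, layers 10 -> 40
    apd90: float         # ms, mid-strand
    upstroke: float      # 1/ms, mid-strand
    rp: float | None     # ms, S1-S2 at 1 ms resolution
    cycle_length: float | None = None   # ms, pacemaking tissue only
    dt: float = 0.0


def _strand_sim(tissue: str, cfg: ModelConfig, dt=None) -> Simulation:
    geom = make_strand(tissue=tissue)
    sim = Simulation(geom, cfg, dt=dt)
    if tissue == "san":
        _, u0, v0 = san_holding_state(cfg)
        sim.set_uniform_state(u0, v0)
    return sim


_RUN_T = {"san": 280.0, "atrial": 160.0, "ine": 120.0, "pb": 260.0}


def measure_strand(tissue: str, cfg: ModelConfig | None = None,
                   dt: float | None = None, measure_rp: bool = True,
                   rp_resolution: float = 1.0) -> StrandResult:
    """Run the 50x5x5 strand protocol for one tissue and measure it.

    The strand is stimulated over its first three element layers; for the
    pacemaking SAN the strand is held at a mid-diastolic phase of the limit
    cycle (so the paced wave propagates into partially recovered tissue, as
    in the node).  The refractory period is the shortest S1-S2 coupling
    interval whose premature wave reaches the distal probe.
    """
    cfg = cfg or default_config()
    thr = cfg.activation_threshold
    sim = _strand_sim(tissue, cfg, dt)
    stim = sim.strand_stim_region()
    sim.add_stimulus(0.0, stim, "set-u", 1.0, 1.0)
    res = sim.run(_RUN_T[tissue], probes={
        "mid": sim.geom.probes["mid"], "far": sim.geom.probes["far"]})
    cv = ms.conduction_velocity(res.activation, 10, 40)
    apd = ms.apd90(res.traces["mid"], thr)
    ups = ms.max_upstroke(res.traces["mid"])
    cl = None
    if tissue == "san":
        cl = san_holding_state(cfg)[0]

    rp = None
    if measure_rp:
        # S1 transit time to the distal probe, from the baseline run, so
        # the S1 wave's own arrival is never mistaken for an S2 response
        t_far_s1 = float(ms.activation_times(res.traces["far"], thr)[0])

        def propagates(ci: float) -> bool:
            s2 = _strand_sim(tissue, cfg, dt)
            region = s2.strand_stim_region()
            s2.add_stimulus(0.0, region, "set-u", 1.0, 1.0)
            s2.add_stimulus(ci, region, "set-u", 1.0, 1.0)
            horizon = ci + t_far_s1 + 40.0
            r = s2.run(horizon, probes={"far": s2.geom.probes["far"]})
            acts = ms.activation_times(r.traces["far"], thr)
            lo_t = max(ci, t_far_s1 + 10.0)
            return bool(np.any((acts > lo_t) & (acts <= horizon)))

        hi = {"san": 310.0, "atrial": 200.0, "ine": 260.0,
              "pb": 260.0}[tissue]
        rp = ms.rp_scan(propagates, lo=20.0, hi=hi,
                        resolution=rp_resolution)
    return StrandResult(tissue=tissue, cv=cv, apd90=apd, upstroke=ups,
                        rp=rp, cycle_length=cl, dt=res.dt)


# ---------------------------------------------------------------------------
# sinus rhythm on the idealized atrium
# ---------------------------------------------------------------------------

@dataclass
class SinusResult:
    map_cycle1: ms.ActivationMap
    map_cycle2: ms.ActivationMap
    traces: dict
    cycle_length: float
    config_hash: str = ""


def run_sinus(geom: Geometry | None = None, cfg: ModelConfig | None = None,
              dt: float | None = None, settle_ms: float = 150.0,
              coupling_scale: float = DEFAULT_AF_COUPLING_SCALE,
              discard_beats: int = 3) -> SinusResult:
    """Free-running sinus rhythm; returns activation maps of two steady
    cycles.

    The scenario runs at the documented desk-scale coupling (shared with
    the arrhythmia scenario): at full coupling the idealized node, which
    lacks the real exit architecture (transitional interdigitations,
    insulating connective tissue), is electrotonically silenced by the
    atrial sheet.  The first spontaneous beat starts from the synchronized
    initial state and is discarded as transient; the maps cover the second
    and third beats (the sheet is traversed well within ``settle_ms`` of a
    nodal activation).  Raises a diagnostic error if the node does not
    activate spontaneously within two intrinsic cycle lengths.
    """
    cfg = cfg or default_config()
    geom = geom if geom is not None else make_idealized_right_atrium()
    if not np.any(geom.labels == 3):
        raise ValueError("sinus protocol requires a geometry with an SAN")
    cl0 = san_holding_state(cfg)[0]
    sim = Simulation(geom, cfg, dt=dt, diffusion_scale=coupling_scale)
    sc = geom.probes["san_centre"]
    thr = cfg.activation_threshold

    chunk = 20.0
    t_max = (7.0 + 2.0 * discard_beats) * cl0
    beats: list[float] = []
    maps: list[ms.ActivationMap] = []
    parts: dict[str, list] = {}
    next_capture = None
    last_u = None
    while sim.state.t < t_max and len(maps) < 2:
        res = sim.run(chunk)
        for k, tr in res.traces.items():
            t_arr, u_arr = tr.t, tr.u
            if parts.get(k):
                keep = t_arr > parts[k][-1][0][-1]
                t_arr, u_arr = t_arr[keep], u_arr[keep]
            parts.setdefault(k, []).append((t_arr, u_arr))
        tr = res.traces["san_centre"]
        u = tr.u if last_u is None else np.concatenate([[last_u], tr.u])
        tt = tr.t if last_u is None else np.concatenate([[tr.t[0] - 1],
                                                         tr.t])
        for t_cross in ms.activation_times(
                ms.APTrace("sc", tt, u), thr):
            if not beats or t_cross > beats[-1] + 50.0:
                beats.append(float(t_cross))
                if len(beats) <= discard_beats:
                    # settling beats: discard their activation record
                    next_capture = ("discard", t_cross + settle_ms)
                elif next_capture is None:
                    next_capture = ("keep", t_cross + settle_ms)
        last_u = float(tr.u[-1])
        if len(beats) == 0 and sim.state.t > 2.0 * cl0 + 60.0:
            raise RuntimeError(
                "no spontaneous SAN activation within two cycles; "
                f"probe u({sc}) never crossed threshold"
            )
        if next_capture and sim.state.t >= next_capture[1]:
            mode = next_capture[0]
            if mode == "keep":
                maps.append(ms.ActivationMap(
                    times=np.where(sim.activation >= 0.0,
                                   sim.activation, np.nan),
                    threshold=thr, dx_um=geom.dx_um))
            sim.reset_activation()
            next_capture = None
    if len(maps) < 2:
        raise RuntimeError(
            "fewer than three spontaneous beats within "
            f"{t_max:.0f} ms; beats at {beats}"
        )
    traces = {}
    for k, pieces in parts.items():
        traces[k] = ms.APTrace(
            name=k, t=np.concatenate([p[0] for p in pieces]),
            u=np.concatenate([p[1] for p in pieces]))
    clm = float(beats[discard_beats + 1] - beats[discard_beats])
    return SinusResult(map_cycle1=maps[0], map_cycle2=maps[1],
                       traces=traces, cycle_length=clm,
                       config_hash=config_hash(cfg))


# ---------------------------------------------------------------------------
# AF-like arrhythmia
# ---------------------------------------------------------------------------

@dataclass
class AFResult:
    reentry: bool
    traces: dict
    san_ratio: ms.ConductionRatio | None
    avn_ratio: ms.ConductionRatio | None
    atrial_cl: float | None
    window: tuple
    config_hash: str = ""


def run_af(geom: Geometry | None = None, cfg: ModelConfig | None = None,
           s2_time: float = DEFAULT_AF_S2_MS,
           coupling_scale: float = DEFAULT_AF_COUPLING_SCALE,
           duration: float = 1100.0, dt: float | None = None) -> AFResult:
    """Premature planar stimulation at the superior-caval margin.

    S1 is the spontaneous sinus beat; S2 a planar premature stimulus along
    the cranial edge.  Coupling is scaled down (documented default) so the
    atrial wavelength fits the desk-scale sheet; failure to induce reentry
    is reported in the result, not raised.
    """
    cfg = cfg or default_config()
    geom = geom if geom is not None else make_idealized_right_atrium()
    sim = Simulation(geom, cfg, dt=dt, diffusion_scale=coupling_scale)
    svc = geom.meta["stim_regions"]["svc"]
    mask = np.zeros(geom.shape, dtype=bool)
    mask[:, int(svc["y_min"]):, :] = True
    mask &= geom.labels == svc["label"]
    sim.add_stimulus(s2_time, mask, "set-u", 1.0, 1.0)
    probes = {k: geom.probes[k] for k in
              ("san_centre", "crista", "septum", "pb_distal", "junction")}
    res = sim.run(duration, probes=probes, record_dt=0.25)
    thr = cfg.activation_threshold
    window = (s2_time + 150.0, duration)
    atr = res.traces["crista"]
    acts = ms.activation_times(atr, thr)
    acts = acts[(acts >= window[0]) & (acts <= window[1])]
    cl_intrinsic = san_holding_state(cfg)[0]
    reentry = len(acts) >= 3 and np.mean(np.diff(acts)) < 0.75 * cl_intrinsic
    san_ratio = avn_ratio = None
    atrial_cl = None
    if reentry:
        atrial_cl = float(np.mean(np.diff(acts)))
        try:
            san_ratio = ms.conduction_ratio(
                atr, res.traces["san_centre"], window, thr)
        except ms.MeasurementError:
            pass
        try:
            avn_ratio = ms.conduction_ratio(
                atr, res.traces["pb_distal"], window, thr)
        except ms.MeasurementError:
            pass
    return AFResult(reentry=reentry, traces=res.traces,
                    san_ratio=san_ratio, avn_ratio=avn_ratio,
                    atrial_cl=atrial_cl, window=window,
                    config_hash=config_hash(cfg))


# ---------------------------------------------------------------------------
# ventricular echo beat (cellular-automaton engine)
# ---------------------------------------------------------------------------

@dataclass
class EchoResult:
    echo: bool
    s2_captured: bool
    fast_blocked: bool
    slow_conducted: bool
    events: dict = field(default_factory=dict)
    log: list = field(default_factory=list)


def _pb_stub_params(cfg: ModelConfig):
    """Cellular-automaton parameters for the stimulus stub.

    The distal stub recovers faster than the nodal pathways (the premature
    ventricular-side activation arises below the node), so couplings inside
    the limbs' vulnerable window can engage it.
    """
    from .cellular_automaton import CAParams

    e = cfg.ca["tissues"]["pb"]
    return CAParams(theta=float(e["theta"]), gain=float(e.get("gain", 1.0)),
                    excited=int(e["excited"]), refractory=40,
                    reach=int(e.get("reach", 1)))


def run_echo(ring: Geometry | None = None, s1_s2_interval: float = 110.0,
             cfg: ModelConfig | None = None,
             duration_ms: float = 700.0) -> EchoResult:
    """S1-S2 at the penetrating-bundle stub of the dual-pathway ring.

    Labels every limb traversal with its direction and reports whether a
    reentrant echo (anterograde re-activation of the penetrating bundle
    after the retrograde premature beat) occurred.
    """
    cfg = cfg or default_config()
    ring = ring if ring is not None else make_dual_pathway_ring()
    model = CAModel.from_config(ring, cfg.ca)
    # distal stub: faster-recovering tissue below the node
    stub = _pb_stub_params(cfg)
    sr = ring.meta["stim_regions"]["pb_tip"]
    stub_mask = np.zeros(ring.shape, dtype=bool)
    stub_mask[sr["x"][0]:sr["x"][1], sr["y"][0]:sr["y"][1], :] = True
    # the whole bundle of the echo preparation recovers distally fast;
    # the limbs keep their published refractory periods
    model.params = dict(model.params)
    model.params[8] = stub

    dt = model.dt
    s1 = 5
    s2 = s1 + int(round(s1_s2_interval / dt))
    nsteps = int(round(duration_ms / dt))
    traces = model.run(nsteps, stimuli=[(s1, stub_mask), (s2, stub_mask)])
    thr = 0.5
    ev = {k: ms.activation_times(v, thr) for k, v in traces.items()}

    t_s1, t_s2 = s1 * dt, s2 * dt

    def acts_after(name, t0, t1=np.inf):
        a = ev[name]
        return a[(a > t0) & (a < t1)]

    s2_captured = len(acts_after("pb_tip", t_s2 - 1.5 * dt,
                                 t_s2 + 3 * dt)) > 0
    slow_conducted = len(acts_after("slow_mid", t_s2, t_s2 + 300)) > 0
    # a retrograde response reaches the fast-limb entrance promptly; the
    # anterograde (echo) wave arrives there much later, from above
    fast_retro = acts_after("fast_entry", t_s2, t_s2 + 30)
    fast_blocked = s2_captured and len(fast_retro) == 0
    echo_acts = acts_after("pb_junction", t_s2 + 20)
    echo = bool(s2_captured and fast_blocked and slow_conducted
                and len(echo_acts) > 0)

    log = []
    for limb, lo_p, hi_p in (("fast", "fast_entry", "fast_top"),
                             ("slow", "slow_entry", "slow_top")):
        for t_lo in ev.get(lo_p, []):
            his = [t for t in ev.get(hi_p, []) if abs(t - t_lo) < 300]
            if not his:
                continue
            t_hi = min(his, key=lambda t: abs(t - t_lo))
            direction = "retrograde" if t_hi > t_lo else "anterograde"
            log.append({"limb": limb, "t_enter": float(min(t_lo, t_hi)),
                        "t_exit": float(max(t_lo, t_hi)),
                        "direction": direction})
    log.sort(key=lambda e: e["t_enter"])
    return EchoResult(echo=echo, s2_captured=s2_captured,
                      fast_blocked=fast_blocked,
                      slow_conducted=slow_conducted, events=ev, log=log)


def find_echo_window(ring: Geometry | None = None,
                     cfg: ModelConfig | None = None,
                     lo: float = 60.0, hi: float = 200.0,
                     step: float = 2.0):
    """Scan S1-S2 intervals; return (first, last) interval producing an echo,
    or None if none does."""
    ring = ring if ring is not None else make_dual_pathway_ring()
    cfg = cfg or default_config()
    hits = []
    ci = lo
    while ci <= hi:
        if run_echo(ring, ci, cfg).echo:
            hits.append(ci)
        ci += step
    if not hits:
        return None
    return (min(hits), max(hits))
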