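"""Calibration of the free model constants against the strand protocol.

The published per-tissue table fixes (D, c1, c2, b, d) but not the
excitation thresholds (alpha), the SAN recovery-nullcline offset (q), the
global diffusion unit, or the sub-threshold recovery boost (rho).  This
script measures the 50x5x5 strand battery over small parameter ranges and
prints the operating point frozen into data/default_params.yaml.

Run stages separately:

    python scripts/calibrate.py unit        # diffusion unit from atrial CV
    python scripts/calibrate.py battery     # full four-tissue battery
    python scripts/calibrate.py san         # SAN (alpha, q) neighbourhood
    python scripts/calibrate.py anisotropy  # slab CV ratio check
    python scripts/calibrate.py af-window   # AF vulnerable-window scan
"""

from __future__ import annotations

import copy
import sys
import time

import numpy as np

from nodalsim import (default_config, make_anisotropic_slab, measure_strand,
                      san_cycle_length, san_holding_state)
from nodalsim.measurements import conduction_velocity
from nodalsim.solver import Simulation
from nodalsim.tissue_kinetics import TissueParams

TARGETS = {  # published simulation column of the strand table
    "san": dict(cv=0.0673, up=0.124, apd=185.0, rp=283.0),
    "atrial": dict(cv=0.5333, up=1.583, apd=75.05, rp=82.0),
    "ine": dict(cv=0.0949, up=0.1578, apd=93.7, rp=91.0),
    "pb": dict(cv=0.1413, up=0.3755, apd=118.07, rp=154.0),
}


def with_tissue(cfg, name, **kw):
    cfg = copy.deepcopy(cfg)
    p = cfg.tissues[name]
    cfg.tissues[name] = TissueParams(**{**vars(p), **kw})
    return cfg


def stage_unit():
    cfg = default_config()
    for _ in range(3):
        r = measure_strand("atrial", cfg, measure_rp=False)
        unit = cfg.diffusion_unit * (TARGETS["atrial"]["cv"] / r.cv) ** 2
        print(f"unit={cfg.diffusion_unit:.5f} -> CV={r.cv:.4f} "
              f"APD={r.apd90:.2f}  => next unit={unit:.5f}")
        cfg = copy.deepcopy(cfg)
        cfg.diffusion_unit = unit


def stage_battery():
    cfg = default_config()
    for tissue in ("atrial", "ine", "pb", "san"):
        t0 = time.time()
        r = measure_strand(tissue, cfg)
        tg = TARGETS[tissue]

        def pct(x, t):
            return 100.0 * (x - t) / t

        print(f"{tissue:7s} CV={r.cv:.4f} ({pct(r.cv, tg['cv']):+5.1f}%)  "
              f"APD={r.apd90:7.2f} ({pct(r.apd90, tg['apd']):+5.1f}%)  "
              f"up={r.upstroke:.4f} ({pct(r.upstroke, tg['up']):+5.1f}%)  "
              f"RP={r.rp:.0f} ({pct(r.rp, tg['rp']):+5.1f}%)  "
              f"[{time.time() - t0:.0f} s, dt={r.dt:.4f}]")
    cl = san_cycle_length(cfg)
    print(f"SAN strand cycle length = {cl:.1f} ms (target 330, "
          f"{100 * (cl - 330) / 330:+.1f}%)")


def stage_san():
    cfg0 = default_config()
    for a, q in [(0.16, 0.49), (0.18, 0.495), (0.18, 0.50), (0.18, 0.505),
                 (0.20, 0.515)]:
        cfg = with_tissue(cfg0, "san", alpha=a, q=q)
        cl = san_holding_state(cfg)[0]
        r = measure_strand("san", cfg)
        print(f"a={a:.2f} q={q:.3f} CL={cl:6.1f} CV={r.cv:.4f} "
              f"APD={r.apd90:6.1f} RP={r.rp:.0f}")


def stage_anisotropy():
    cfg = default_config()
    geom = make_anisotropic_slab(dims=(72, 48, 8), fiber_axis=(1, 0, 0))
    cvs = {}
    for axis in (0, 1):
        sim = Simulation(geom, cfg)
        mask = np.zeros(geom.shape, dtype=bool)
        if axis == 0:
            mask[:3] = True
        else:
            mask[:, :3] = True
        sim.add_stimulus(0.0, mask, "set-u", 1.0, 1.0)
        sim.run(40.0 if axis == 0 else 90.0, probes={})
        amap = sim.run(0.0, probes={}).activation
        n = geom.shape[axis]
        cvs[axis] = conduction_velocity(amap, n // 4, 3 * n // 4, axis=axis)
        print(f"axis {axis}: CV = {cvs[axis]:.4f} m/s")
    print(f"anisotropy CV ratio = {cvs[0] / cvs[1]:.3f} "
          f"(sqrt(10) = {np.sqrt(10):.3f})")


def stage_af_window():
    from nodalsim.protocols import run_af

    cfg = default_config()
    for s2 in np.arange(120.0, 230.0, 10.0):
        t0 = time.time()
        r = run_af(s2_time=s2, duration=1100.0)
        print(f"s2={s2:5.0f}  reentry={r.reentry}  "
              f"atrial CL={r.atrial_cl}  san={r.san_ratio}  "
              f"avn={r.avn_ratio}  [{time.time() - t0:.0f} s]")


if __name__ == "__main__":
    stage = sys.argv[1] if len(sys.argv) > 1 else "battery"
    {"unit": stage_unit, "battery": stage_battery, "san": stage_san,
     "anisotropy": stage_anisotropy, "af-window": stage_af_window}[stage]()
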