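"""Point (reaction) dynamics for every tissue class of the atrial model.

All tissues share the cubic excitation non-linearity of the Rogers-modified
FitzHugh-Nagumo model, with the excitation variable ``u`` normalized so that
u = 0 is the resting potential and u = 1 the overshoot:

Working myocardium, inferior nodal extension and penetrating bundle
(non-pacemaking form)::

    du/dt = c1 * u * (u - alpha) * (1 - u) - c2 * u * v
    dv/dt = b * (1 + rho * sigma(u)) * (d * u - v)

where ``sigma`` is a logistic switch that accelerates recovery at
sub-threshold voltages (recovery is slow during the plateau, fast after
repolarization), giving refractory periods commensurate with action
potential duration.

Sinoatrial node (pacemaking form)::

    du/dt = c1 * u * (u - alpha) * (1 - u) - c2 * v
    dv/dt = b * (d * (u - q) - v)

The recovery-nullcline offset ``q`` places the unique equilibrium on the
unstable middle branch of the cubic nullcline, so an isolated element is a
relaxation oscillator: slow diastolic depolarization from a hyperpolarized
maximum diastolic potential, regenerative upstroke, long plateau.

The passive block zone has no recovery variable and no regenerative term::

    du/dt = -u / Rb        (plus diffusion)

The four named parameter columns (D, c1, c2, b, d) reproduce the published
table verbatim; ``alpha`` and ``q`` are calibrated once on the 50x5x5 strand
(see scripts/calibrate.py) and frozen in the shipped default config.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "TissueParams",
    "VoltageScale",
    "PeripheryRule",
    "BlockZoneParams",
    "ModelConfig",
    "default_config",
    "load_config",
    "reaction_rogers",
    "reaction_san",
    "reaction_passive",
    "blend_periphery",
    "u_to_vm",
    "vm_to_u",
    "InvalidStateError",
]


class InvalidStateError(ValueError):
    """Raised when reaction terms are evaluated on non-finite state."""


@dataclass(frozen=True)
class TissueParams:
    """One column of the per-tissue parameter table.

    D is the diffusion coefficient in table units (scaled to mm^2/ms by the
    global ``diffusion_unit``); c1 the excitation rate, c2 the
    recovery-coupling strength, b the recovery time-scale (1/ms), d the
    recovery gain, alpha the excitation threshold in normalized-voltage
    units.  ``q`` (recovery-nullcline offset) is non-zero only for the
    pacemaking sinoatrial form.
    """

    D: float
    c1: float
    c2: float
    b: float
    d: float
    alpha: float
    q: float = 0.0
    pacemaker: bool = False

    def __post_init__(self):
        if not (self.c1 > 0 and self.b > 0 and self.d > 0 and self.D >= 0):
            raise ValueError(
                "TissueParams requires c1 > 0, b > 0, d > 0, D >= 0"
            )


@dataclass(frozen=True)
class VoltageScale:
    """Affine map between normalized voltage u and membrane potential (mV)."""

    Vr: float = -80.0   # resting potential
    Vos: float = 20.0   # overshoot potential
    Vth: float = -67.0  # threshold potential

    def __post_init__(self):
        if not (self.Vos > self.Vth > self.Vr):
            raise ValueError("voltage scale requires Vos > Vth > Vr")


@dataclass(frozen=True)
class PeripheryRule:
    """Linear blend of c1 across the SAN border band toward the atrium."""

    band_width: int = 4      # elements (0.24 mm at 60 um)
    c1S: float = 1.0         # SAN core value
    c1A_ref: float = 12.7    # atrial value the gradient trends toward

    def __post_init__(self):
        if self.band_width < 1:
            raise ValueError("periphery band width must be >= 1")


@dataclass(frozen=True)
class BlockZoneParams:
    """Passive block zone: pure leak with resistivity Rb."""

    Rb: float = 0.5

    def __post_init__(self):
        if self.Rb <= 0:
            raise ValueError("block-zone resistivity Rb must be positive")


@dataclass
class ModelConfig:
    """Full parameter set: tissue columns plus global model constants."""

    tissues: dict                      # name -> TissueParams
    dx_um: float = 60.0
    diffusion_unit: float = 0.0234     # mm^2/ms per table unit of D
    anisotropy_ratio: float = 10.0     # D_l / D_t on anisotropic tissues
    recovery_boost: float = 4.0        # rho in the non-pacemaking form
    recovery_switch_u: float = 0.3
    recovery_switch_width: float = 0.05
    activation_threshold: float = 0.5
    san_hold_fraction: float = 0.5     # paced-protocol diastolic phase
    voltage: VoltageScale = field(default_factory=VoltageScale)
    block_zone: BlockZoneParams = field(default_factory=BlockZoneParams)
    periphery: PeripheryRule | None = None
    ca: dict = field(default_factory=dict)   # cellular-automaton parameters

    def __post_init__(self):
        if self.periphery is None:
            self.periphery = PeripheryRule(
                c1S=self.tissues["san"].c1,
                c1A_ref=self.tissues["atrial"].c1,
            )

    def tissue(self, name: str) -> TissueParams:
        return self.tissues[name]


def _as_tissue(name, entry) -> TissueParams:
    return TissueParams(
        D=float(entry["D"]), c1=float(entry["c1"]), c2=float(entry["c2"]),
        b=float(entry["b"]), d=float(entry["d"]),
        alpha=float(entry.get("alpha", 0.13)),
        q=float(entry.get("q", 0.0)),
        pacemaker=bool(entry.get("pacemaker", False)),
    )


def load_config(path=None) -> ModelConfig:
    """Load a parameter config (YAML/JSON dialect); default = shipped file."""
    if path is None:
        text = (
            resources.files("nodalsim.data") / "default_params.yaml"
        ).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    tissues = {k: _as_tissue(k, v) for k, v in raw["tissues"].items()}
    vs = raw.get("voltage_scale", {})
    per = raw.get("periphery", {})
    cfg = ModelConfig(
        tissues=tissues,
        dx_um=float(raw.get("dx_um", 60.0)),
        diffusion_unit=float(raw["diffusion_unit"]),
        anisotropy_ratio=float(raw.get("anisotropy_ratio", 10.0)),
        recovery_boost=float(raw.get("recovery_boost", 0.0)),
        recovery_switch_u=float(raw.get("recovery_switch_u", 0.3)),
        recovery_switch_width=float(raw.get("recovery_switch_width", 0.05)),
        activation_threshold=float(raw.get("activation_threshold", 0.5)),
        san_hold_fraction=float(raw.get("san_hold_fraction", 0.5)),
        voltage=VoltageScale(**vs) if vs else VoltageScale(),
        block_zone=BlockZoneParams(
            **raw.get("block_zone", {"Rb": 0.5})
        ),
        periphery=PeripheryRule(
            band_width=int(per.get("band_width", 4)),
            c1S=float(tissues["san"].c1),
            c1A_ref=float(tissues["atrial"].c1),
        ),
        ca=raw.get("ca", {}),
    )
    return cfg


_DEFAULT_CACHE: list = []


def default_config() -> ModelConfig:
    """The shipped default configuration (cached)."""
    if not _DEFAULT_CACHE:
        _DEFAULT_CACHE.append(load_config(None))
    return _DEFAULT_CACHE[0]


# ---------------------------------------------------------------------------
# reaction terms
# ---------------------------------------------------------------------------

def _check_finite(*arrs):
    for a in arrs:
        if not np.all(np.isfinite(a)):
            raise InvalidStateError("non-finite state passed to reaction term")


def _sigma(u, u_sw, width):
    return 1.0 / (1.0 + np.exp((np.asarray(u, float) - u_sw) / width))


def reaction_rogers(u, v, p: TissueParams, cfg: ModelConfig | None = None):
    """Non-pacemaking reaction rates (atrial muscle, INE, penetrating bundle).

    Returns (du_dt, dv_dt) excluding diffusion.  The resting state (0, 0) is
    a stable fixed point; a supra-threshold perturbation produces a single
    action potential.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_finite(u, v)
    cfg = cfg or default_config()
    du = p.c1 * u * (u - p.alpha) * (1.0 - u) - p.c2 * u * v
    vp = np.maximum(v, 0.0)
    boost = (cfg.recovery_boost
             * _sigma(u, cfg.recovery_switch_u, cfg.recovery_switch_width)
             * vp / (vp + 0.1))
    dv = p.b * (1.0 + boost) * (p.d * u - v)
    return du, dv


def reaction_san(u, v, p: TissueParams, cfg: ModelConfig | None = None):
    """Pacemaking reaction rates for the sinoatrial node.

    Linear recovery coupling with an offset recovery nullcline: the unique
    equilibrium is unstable and every trajectory converges to the
    pacemaking limit cycle.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    _check_finite(u, v)
    du = p.c1 * u * (u - p.alpha) * (1.0 - u) - p.c2 * v
    dv = p.b * (p.d * (u - p.q) - v)
    return du, dv


def reaction_passive(u, bz: BlockZoneParams):
    """Passive block-zone decay: du/dt = -u / Rb (no recovery variable)."""
    if bz.Rb <= 0:
        raise ValueError("block-zone resistivity Rb must be positive")
    u = np.asarray(u, dtype=float)
    _check_finite(u)
    return -u / bz.Rb


def blend_periphery(disSA, rule: PeripheryRule):
    """Graded c1 across the SAN periphery band.

    ``disSA`` is the minimum lattice distance (elements) from an SAN element
    to the nearest atrial element.  The blend is linear over the band:
    c1 equals the SAN core value for disSA >= band_width and trends toward
    the atrial value as disSA decreases (the extrapolated disSA = 0 endpoint
    is the atrial value itself; the shallowest SAN voxel, disSA = 1, carries
    the atrial-side endpoint of the blend).
    """
    dis = np.asarray(disSA, dtype=float)
    if np.any(dis < 0):
        raise ValueError("disSA must be non-negative")
    w = float(rule.band_width)
    s = np.clip(dis, 0.0, w) / w
    out = rule.c1A_ref + (rule.c1S - rule.c1A_ref) * s
    if out.ndim == 0:
        return float(out)
    return out


def u_to_vm(u, s: VoltageScale):
    """Map normalized voltage to membrane potential: u=0 -> Vr, u=1 -> Vos."""
    if s.Vos <= s.Vr:
        raise ValueError("voltage scale requires Vos > Vr")
    return s.Vr + np.asarray(u, dtype=float) * (s.Vos - s.Vr)


def vm_to_u(vm, s: VoltageScale):
    """Inverse of :func:`u_to_vm`."""
    if s.Vos <= s.Vr:
        raise ValueError("voltage scale requires Vos > Vr")
    return (np.asarray(vm, dtype=float) - s.Vr) / (s.Vos - s.Vr)


def threshold_vm(p: TissueParams, s: VoltageScale) -> float:
    """Membrane potential corresponding to the excitation threshold alpha."""
    return float(u_to_vm(p.alpha, s))


def _integrate_san(n, dt, c1, c2, b, d, a, q):
    from numba import njit

    global _integrate_san_jit
    if "_integrate_san_jit" not in globals():
        @njit(cache=True)
        def _impl(n, dt, c1, c2, b, d, a, q):
            u = 0.0
            v = 0.0
            us = np.empty(n)
            vs = np.empty(n)
            for i in range(n):
                du = c1 * u * (u - a) * (1.0 - u) - c2 * v
                dv = b * (d * (u - q) - v)
                u += dt * du
                v += dt * dv
                us[i] = u
                vs[i] = v
            return us, vs

        _integrate_san_jit = _impl
    return _integrate_san_jit(n, dt, c1, c2, b, d, a, q)


def san_limit_cycle(p: TissueParams, cfg: ModelConfig | None = None,
                    T: float = 4000.0, dt: float = 0.005):
    """Integrate an isolated SAN element and return its limit cycle.

    Returns (t, u, v) arrays covering the final full cycle, and the cycle
    length in ms, as ``(t, u, v, cl)``.  Used by the paced-strand protocol
    to construct diastolic holding states.
    """
    n = int(T / dt)
    us, vs = _integrate_san(n, dt, p.c1, p.c2, p.b, p.d, p.alpha, p.q)
    thr = (cfg or default_config()).activation_threshold
    cross = np.where((us[:-1] < thr) & (us[1:] >= thr))[0]
    if len(cross) < 3:
        raise InvalidStateError(
            "SAN parameters do not produce sustained oscillation"
        )
    cl = float(np.diff(cross)[-2:].mean() * dt)
    i0, i1 = cross[-2], cross[-1]
    t = np.arange(i1 - i0) * dt
    return t, us[i0:i1].copy(), vs[i0:i1].copy(), cl
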