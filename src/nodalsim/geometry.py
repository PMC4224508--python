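"""Voxelized tissue geometries for the nodal conduction models.

The simulation domain is a 3D integer lattice of tissue codes on a uniform
grid (default voxel edge 60 um).  Codes follow the right-atrium labelling
convention used throughout the package:

====  =======================  =========================================
code  name                     notes
====  =======================  =========================================
0     background               non-tissue, excluded from the domain
1     atrial                   atrial wall, isotropic working myocardium
2     ine                      inferior nodal extension (slow AV pathway)
3     san                      sinoatrial node, anisotropic
4     crista                   crista terminalis, anisotropic bundle
5     roof                     roof bundle, anisotropic (3D only)
6     main_branch              main branch, anisotropic (3D only)
7     block                    passive block zone (inexcitable barrier)
8     pb                       penetrating bundle of the AV node
9     tz                       transitional zone (fast AV pathway,
                               cellular-automaton scenarios)
====  =======================  =========================================

Anisotropic tissues carry a per-voxel unit fibre direction.  Generators are
deterministic: the same arguments always produce bit-identical geometries.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TISSUE_CODES",
    "CODE_TISSUE",
    "ANISOTROPIC_CODES",
    "GeometryError",
    "LabelVolume",
    "FiberField",
    "Geometry",
    "make_strand",
    "make_anisotropic_slab",
    "make_idealized_right_atrium",
    "make_dual_pathway_ring",
    "read_geometry",
    "write_geometry",
    "read_s2_ascii",
]

TISSUE_CODES = {
    0: "background",
    1: "atrial",
    2: "ine",
    3: "san",
    4: "crista",
    5: "roof",
    6: "main_branch",
    7: "block",
    8: "pb",
    9: "tz",
}

#: map a label code onto the electrophysiological tissue class it uses
CODE_TISSUE = {
    1: "atrial",
    2: "ine",
    3: "san",
    4: "atrial",
    5: "atrial",
    6: "atrial",
    7: "block",
    8: "pb",
    9: "tz",
}

ANISOTROPIC_CODES = frozenset({3, 4, 5, 6})

_NAME_CODE = {v: k for k, v in TISSUE_CODES.items()}


class GeometryError(ValueError):
    """Raised for invalid label volumes or generator arguments."""


@dataclass
class LabelVolume:
    """3D integer lattice of tissue codes with uniform voxel spacing."""

    labels: np.ndarray          # int array, shape (nx, ny, nz)
    dx_um: float = 60.0
    code_table: dict = field(default_factory=lambda: dict(TISSUE_CODES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise GeometryError("label volume must be 3-dimensional")
        if self.dx_um <= 0:
            raise GeometryError("voxel size must be positive")

    @property
    def shape(self):
        return self.labels.shape

    @property
    def dx_mm(self) -> float:
        return self.dx_um / 1000.0

    def validate(self) -> dict:
        """Check all codes against the code table; return voxel counts per code.

        Raises GeometryError listing offending values for unknown codes, or
        if the volume contains no tissue at all.
        """
        codes, counts = np.unique(self.labels, return_counts=True)
        unknown = [int(c) for c in codes if int(c) not in self.code_table]
        if unknown:
            raise GeometryError(f"unknown tissue codes in volume: {unknown}")
        table = {int(c): int(n) for c, n in zip(codes, counts)}
        if sum(n for c, n in table.items() if c != 0) == 0:
            raise GeometryError("label volume contains no tissue voxels")
        return table


@dataclass
class FiberField:
    """Per-voxel unit fibre direction (direction cosines l, m, n).

    Defined (non-zero) only on anisotropic tissues; zero vectors mark voxels
    where no orientation is assigned.
    """

    lx: np.ndarray
    ly: np.ndarray
    lz: np.ndarray

    def norm(self) -> np.ndarray:
        return np.sqrt(self.lx ** 2 + self.ly ** 2 + self.lz ** 2)

    def validate(self, labels: np.ndarray | None = None):
        n = self.norm()
        defined = n > 0
        if not np.allclose(n[defined], 1.0, atol=1e-6):
            raise GeometryError("fibre directions must be unit vectors")
        if labels is not None:
            aniso = np.isin(labels, list(ANISOTROPIC_CODES))
            if np.any(aniso & ~defined):
                raise GeometryError(
                    "fibre orientation missing on anisotropic voxels"
                )


@dataclass
class Geometry:
    """Label volume plus optional fibre field and named probe sites."""

    volume: LabelVolume
    fibers: FiberField | None = None
    probes: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    @property
    def labels(self) -> np.ndarray:
        return self.volume.labels

    @property
    def shape(self):
        return self.volume.shape

    @property
    def dx_um(self) -> float:
        return self.volume.dx_um

    def validate(self) -> dict:
        counts = self.volume.validate()
        if self.fibers is not None:
            self.fibers.validate(self.labels)
        else:
            if np.any(np.isin(self.labels, list(ANISOTROPIC_CODES))):
                raise GeometryError(
                    "geometry contains anisotropic tissue but no fibre field"
                )
        for name, idx in self.probes.items():
            if len(idx) != 3 or not all(
                0 <= i < s for i, s in zip(idx, self.shape)
            ):
                raise GeometryError(f"probe {name!r} outside lattice: {idx}")
        return counts

    def content_hash(self) -> str:
        """Stable hash of labels, spacing, fibres and probes."""
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.labels, dtype=np.int16).tobytes())
        h.update(np.float64(self.volume.dx_um).tobytes())
        if self.fibers is not None:
            for a in (self.fibers.lx, self.fibers.ly, self.fibers.lz):
                h.update(np.ascontiguousarray(a, dtype=np.float32).tobytes())
        h.update(json.dumps(sorted(self.probes.items())).encode())
        return h.hexdigest()


def _code_of(tissue) -> int:
    if isinstance(tissue, (int, np.integer)):
        code = int(tissue)
    else:
        code = _NAME_CODE.get(str(tissue), None)
    if code is None or code not in TISSUE_CODES or code == 0:
        raise GeometryError(f"unknown tissue {tissue!r}")
    return code


def _constant_fibers(shape, direction, where):
    d = np.asarray(direction, dtype=float)
    n = np.linalg.norm(d)
    if n == 0:
        raise GeometryError("fibre direction must be non-zero")
    d = d / n
    lx = np.zeros(shape, dtype=np.float32)
    ly = np.zeros(shape, dtype=np.float32)
    lz = np.zeros(shape, dtype=np.float32)
    lx[where], ly[where], lz[where] = d
    return FiberField(lx, ly, lz)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def make_strand(n_long: int = 50, n_cross: int = 5, tissue="atrial",
                dx_um: float = 60.0) -> Geometry:
    """Uniform single-tissue strand (default 50 x 5 x 5 elements).

    The stimulus region is the first three element layers along x; probe
    sites mark the 10th and 40th layers (conduction-velocity interval), the
    mid-strand element and a far element near the distal end.
    """
    if n_long < 3 or n_cross < 1:
        raise GeometryError("strand dimensions too small")
    code = _code_of(tissue)
    labels = np.full((n_long, n_cross, n_cross), code, dtype=np.int8)
    c = n_cross // 2
    probes = {
        "layer10": (9, c, c),
        "layer40": (min(39, n_long - 1), c, c),
        "mid": (n_long // 2, c, c),
        "far": (n_long - 3, c, c),
    }
    vol = LabelVolume(labels, dx_um=dx_um)
    fib = None
    if code in ANISOTROPIC_CODES:
        # bundle strands run along their fibres; the nodal strand is cut
        # across them (SAN conduction is characterized in the slow,
        # centre-to-crista direction, transverse to the nodal myocytes)
        direction = (0, 1, 0) if code == 3 else (1, 0, 0)
        fib = _constant_fibers(labels.shape, direction, labels == code)
    meta = {"kind": "strand", "stim_layers": 3, "tissue": TISSUE_CODES[code]}
    return Geometry(vol, fib, probes, meta)


def make_anisotropic_slab(dims=(60, 40, 40), fiber_axis=(1, 0, 0),
                          tissue="crista", dx_um: float = 60.0) -> Geometry:
    """Uniform slab with a constant fibre field (anisotropy test bed)."""
    dims = tuple(int(d) for d in dims)
    if any(d < 3 for d in dims):
        raise GeometryError("slab dimensions too small")
    code = _code_of(tissue)
    labels = np.full(dims, code, dtype=np.int8)
    fib = _constant_fibers(dims, fiber_axis, labels == code)
    probes = {
        "x0": (dims[0] // 4, dims[1] // 2, dims[2] // 2),
        "x1": (3 * dims[0] // 4, dims[1] // 2, dims[2] // 2),
        "y0": (dims[0] // 2, dims[1] // 4, dims[2] // 2),
        "y1": (dims[0] // 2, 3 * dims[1] // 4, dims[2] // 2),
    }
    meta = {"kind": "slab", "fiber_axis": tuple(np.asarray(fiber_axis, float)
                                                / np.linalg.norm(fiber_axis))}
    return Geometry(LabelVolume(labels, dx_um=dx_um), fib, probes, meta)


def make_idealized_right_atrium(nx: int = 200, ny: int = 150,
                                three_d: bool = False,
                                dx_um: float = 60.0) -> Geometry:
    """Idealized 2D right-atrial sheet (3D variant available).

    Emulates the topology of the real preparation: an SAN ellipse abutting
    the crista terminalis, a passive block zone interposed between the SAN
    and the septal side (so septal activation must detour around it), an
    insulated inferior-nodal-extension / penetrating-bundle chain entered
    upstream from the crista side and downstream (compact-node junction)
    from the septal side, and an atrial sheet everywhere else.

    In the 2D reduction the roof bundle and main branch (codes 5 and 6, 3D
    supra-atrial bundles) are absent; this is recorded in ``meta``.
    Coordinates: x runs septal (low x) to lateral/crista (high x), y runs
    caudal (low y) to cranial (high y).
    """
    if nx < 120 or ny < 100:
        raise GeometryError("idealized atrium requires nx >= 120, ny >= 100")
    nz = 8 if three_d else 1
    L = np.zeros((nx, ny, nz), dtype=np.int8)
    L[:, :, :] = 1  # atrial sheet

    # scale anchor points to the requested sheet
    def sx(x):
        return int(round(x * nx / 200.0))

    def sy(y):
        return int(round(y * ny / 150.0))

    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    # crista terminalis: vertical fast bundle near the lateral edge
    ct = (xs >= sx(152)) & (xs < sx(160)) & (ys >= sy(12)) & (ys < sy(140))
    L[ct] = 4

    # SAN ellipse left of (and touching) the crista
    # radii have a floor: a node too small relative to the voxel size
    # is suppressed by the diffusive load of the atrial sheet
    cx, cy, rx, ry = sx(136), sy(95), max(16, sx(16)), max(32, sy(32))
    san = ((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0
    L[san & ~ct] = 3

    # passive block zone interposed between SAN and the septal side,
    # spanning the SAN's full cranio-caudal extent
    # the zone must span the node's full cranio-caudal extent so the
    # septal side is reachable only around it
    bz_lo = min(sy(62), cy - ry - 2)
    bz_hi = max(sy(130), cy + ry + 3)
    bz = (xs >= sx(112)) & (xs < sx(122)) & \
         (ys >= bz_lo) & (ys < bz_hi)
    keep = np.isin(L, (3, 4))
    L[bz[..., None] & ~keep] = 7

    # AV-nodal chain along the caudal margin: INE strip (slow pathway)
    y0, y1 = sy(18), sy(24)
    ine = (ys >= y0) & (ys < y1) & (xs >= sx(64)) & (xs < sx(152))
    L[ine] = 2
    # penetrating bundle continues septally from the compact-node junction
    pb = (ys >= y0) & (ys < y1) & (xs >= sx(40)) & (xs < sx(64))
    L[pb] = 8

    # insulation around the nodal chain: non-tissue gaps above and below,
    # open only at the crista end (upstream) and the junction (downstream)
    above = (ys >= y1) & (ys < sy(27)) & (xs >= sx(40)) & (xs < sx(148))
    opening = (xs >= sx(64)) & (xs < sx(72))
    L[above & ~opening] = 0
    below = (ys >= sy(15)) & (ys < y0) & (xs >= sx(40)) & (xs < sx(152))
    L[below] = 0
    # distal cap beyond the penetrating bundle (His exit, not modelled)
    cap = (ys >= sy(15)) & (ys < sy(27)) & (xs >= sx(36)) & (xs < sx(40))
    L[cap] = 0

    if three_d:
        # supra-atrial bundles in the upper z half: roof bundle crossing the
        # cranial margin, main branch leaving the crista medially
        roof = (ys >= sy(138)) & (ys < sy(144)) & (xs >= sx(40)) & \
               (xs < sx(160))
        main = (ys >= sy(95)) & (ys < sy(101)) & (xs >= sx(100)) & \
               (xs < sx(152))
        for z in range(nz // 2, nz):
            lz = L[:, :, z]
            lz[roof] = 5
            lz[main & (lz != 3) & (lz != 4)] = 6

    # fibre field: vertical along the crista and SAN; horizontal on the
    # 3D bundles
    aniso = np.isin(L, list(ANISOTROPIC_CODES))
    lx = np.zeros(L.shape, dtype=np.float32)
    ly = np.zeros(L.shape, dtype=np.float32)
    lz = np.zeros(L.shape, dtype=np.float32)
    ly[np.isin(L, (3, 4))] = 1.0
    lx[np.isin(L, (5, 6))] = 1.0
    fib = FiberField(lx, ly, lz)

    zc = nz // 2 if three_d else 0
    probes = {
        "san_centre": (cx, cy, zc),
        "crista": (sx(156), cy, zc),
        "septum": (sx(20), cy, zc),
        "ine_entry": (sx(148), sy(21), zc),
        "junction": (sx(66), sy(21), zc),
        "pb_distal": (sx(44), sy(21), zc),
    }
    # probe line perpendicular to the crista through the SAN centre
    x_line = np.linspace(sx(122), sx(176), 19).round().astype(int)
    for i, x in enumerate(x_line, start=1):
        probes[f"san_line_{i:02d}"] = (int(x), cy, zc)
    # AV-nodal axis from the upstream INE entrance to the distal bundle
    x_axis = np.linspace(sx(148), sx(44), 21).round().astype(int)
    for i, x in enumerate(x_axis, start=1):
        probes[f"avn_axis_{i:02d}"] = (int(x), sy(21), zc)

    meta = {
        "kind": "atrium3d" if three_d else "atrium2d",
        "codes_absent_2d": [] if three_d else [5, 6],
        "stim_regions": {
            # superior-caval margin strip used for premature planar stimuli
            "svc": {"y_min": ny - 6, "label": 1},
        },
        "san_centre": (cx, cy, zc),
    }
    geom = Geometry(LabelVolume(L, dx_um=dx_um), fib, probes, meta)
    geom.validate()
    return geom


def make_dual_pathway_ring(dx_um: float = 60.0, width: int = 3,
                           slow_extra: int = 0) -> Geometry:
    """Dual-pathway AV-nodal ring for the echo-beat experiment.

    A penetrating-bundle stub at the caudal end connects to two limbs that
    rejoin through an atrial segment at the cranial end: a short fast limb
    (transitional zone, long refractory period) and a long, meandering slow
    limb (inferior nodal extension, short refractory period).  S1/S2 stimuli
    are applied at the penetrating-bundle tip.
    """
    w = int(width)
    if w < 1:
        raise GeometryError("corridor width must be >= 1")
    nx, ny = 120, 100
    L = np.zeros((nx, ny, 1), dtype=np.int8)

    def box(x0, x1, y0, y1, code):
        L[x0:x1, y0:y1, 0] = code

    # penetrating bundle stub, bottom centre, pointing caudally
    box(58, 58 + w, 6, 26 + w, 8)
    # fast limb (transitional zone): bottom-right corridor + right vertical
    box(58 + w, 92, 26, 26 + w, 9)
    box(92 - w, 92, 26, 66, 9)
    # slow limb (INE): bottom-left corridor, left vertical, and a serpentine
    # detour that lengthens the path (slow_extra controls the detour size)
    box(14, 58, 26, 26 + w, 2)
    box(14, 14 + w, 26, 50 + w, 2)
    box(14, 14 + min(slow_extra, 36) + w, 50, 50 + w, 2)
    xr = 14 + min(slow_extra, 36)
    box(xr, xr + w, 50, 66, 2)
    # atrial bridge across the top joining both limbs
    box(xr, 92, 66, 66 + w, 1)

    probes = {
        "pb_tip": (59, 8, 0),
        "pb_junction": (59, 24, 0),
        "fast_entry": (92 - w + 1, 28, 0),
        "slow_entry": (30, 27, 0),
        "fast_mid": (92 - w + 1, 46, 0),
        "slow_mid": (14 + 1, 40, 0),
        "fast_top": (92 - w + 1, 64, 0),
        "slow_top": (xr + 1, 64, 0),
        "atrium": ((xr + 92) // 2, 67, 0),
    }
    meta = {
        "kind": "ring",
        "stim_regions": {"pb_tip": {"x": (58, 58 + w), "y": (6, 10)}},
    }
    geom = Geometry(LabelVolume(L, dx_um=dx_um), None, probes, meta)
    geom.validate()
    return geom


# ---------------------------------------------------------------------------
# file I/O: compressed array container with an embedded JSON header
# ---------------------------------------------------------------------------

_FORMAT_VERSION = 1


def write_geometry(geom: Geometry, path) -> None:
    """Write a geometry to ``path`` (.npz container, JSON header embedded)."""
    geom.validate()
    header = {
        "format": "nodalsim-geometry",
        "version": _FORMAT_VERSION,
        "dims": list(geom.shape),
        "dx_um": geom.dx_um,
        "code_table": {str(k): v for k, v in geom.volume.code_table.items()},
        "probes": {k: list(map(int, v)) for k, v in geom.probes.items()},
        "meta": _jsonable(geom.meta),
        "has_fibers": geom.fibers is not None,
    }
    arrays = {
        "header": np.frombuffer(
            json.dumps(header, sort_keys=True).encode(), dtype=np.uint8
        ),
        "labels": geom.labels.astype(np.int8),
    }
    if geom.fibers is not None:
        arrays["fiber_l"] = geom.fibers.lx.astype(np.float32)
        arrays["fiber_m"] = geom.fibers.ly.astype(np.float32)
        arrays["fiber_n"] = geom.fibers.lz.astype(np.float32)
    np.savez_compressed(path, **arrays)


def read_geometry(path) -> Geometry:
    """Read a geometry written by :func:`write_geometry` and validate it."""
    with np.load(path) as z:
        try:
            header = json.loads(bytes(z["header"].tobytes()).decode())
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise GeometryError(f"not a nodalsim geometry file: {exc}")
        if header.get("format") != "nodalsim-geometry":
            raise GeometryError("not a nodalsim geometry file")
        labels = z["labels"]
        fib = None
        if header.get("has_fibers"):
            fib = FiberField(z["fiber_l"], z["fiber_m"], z["fiber_n"])
    vol = LabelVolume(
        labels,
        dx_um=float(header["dx_um"]),
        code_table={int(k): v for k, v in header["code_table"].items()},
    )
    geom = Geometry(
        vol, fib,
        probes={k: tuple(v) for k, v in header.get("probes", {}).items()},
        meta=header.get("meta", {}),
    )
    geom.validate()
    return geom


def read_s2_ascii(path, dims, dx_um: float = 60.0) -> Geometry:
    """Import a plain-text label matrix using the supplementary integer
    coding (codes 1-8), whitespace-separated, x fastest / z slowest.

    Optional convenience loader; generated geometries are the primary route.
    """
    flat = np.loadtxt(path, dtype=np.int16).ravel()
    nx, ny, nz = dims
    if flat.size != nx * ny * nz:
        raise GeometryError(
            f"label count {flat.size} does not match dims {dims}"
        )
    labels = flat.reshape((nz, ny, nx)).transpose(2, 1, 0).astype(np.int8)
    geom = Geometry(LabelVolume(labels, dx_um=dx_um))
    geom.validate()
    return geom


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
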