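"""Ball-and-stick rendering of 3D molecules over a rotation grid.

Each molecule is depicted as a CPK-colored ball-and-stick model and
captured once per orientation of a three-axis rotation grid: for a
per-axis increment ``a`` the per-axis angle set is {0, a, 2a, ...} below
360 degrees and the grid is its three-fold Cartesian product, giving
ceil(360/a)**3 images.  Rendering is a deterministic software rasterizer
(orthographic projection, painter's algorithm) so snapshot ensembles are
byte-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from .chemio import Molecule3D

__all__ = [
    "Orientation",
    "RenderConfig",
    "SnapshotSet",
    "rotation_grid",
    "rotation_matrix",
    "render",
    "snapshot_ensemble",
    "save_ensemble",
    "save_ensembles",
]

#: CPK-like element colors (RGB 0-255); unknown elements fall back to magenta.
CPK_COLORS: dict[str, tuple[int, int, int]] = {
    "C": (144, 144, 144),
    "H": (255, 255, 255),
    "O": (255, 13, 13),
    "N": (48, 80, 248),
    "S": (255, 255, 48),
    "Cl": (31, 240, 31),
    "Br": (166, 41, 41),
    "I": (148, 0, 148),
    "P": (255, 128, 0),
}
DEFAULT_COLOR = (255, 0, 255)

#: Covalent radii in Angstrom (single-bond, common organic elements).
COVALENT_RADII: dict[str, float] = {
    "H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "P": 1.07,
    "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
DEFAULT_RADIUS = 0.90


@dataclass(frozen=True)
class Orientation:
    """Rotation angles in degrees about the fixed x, y and z world axes."""

    rx: float
    ry: float
    rz: float

    def __post_init__(self) -> None:
        for name, a in (("rx", self.rx), ("ry", self.ry), ("rz", self.rz)):
            if not (0 <= a < 360):
                raise ValueError(f"{name}={a} outside [0, 360)")


@dataclass(frozen=True)
class RenderConfig:
    """Raster parameters of the ball-and-stick depiction.

    ``sphere_scale`` multiplies the element covalent radius to give the
    displayed ball radius; ``stick_fraction`` gives the stick radius as a
    fraction of the mean displayed bond length.  ``margin`` is the blank
    border fraction left around the molecule's bounding sphere, so every
    orientation of the molecule fits the frame at the same zoom.
    """

    width: int = 256
    height: int = 256
    background: tuple[int, int, int] = (0, 0, 0)
    atom_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(CPK_COLORS)
    )
    sphere_scale: float = 0.55
    stick_fraction: float = 0.08
    margin: float = 0.10

    def __post_init__(self) -> None:
        if self.width < 8 or self.height < 8:
            raise ValueError("image dimensions must be at least 8 px")
        if self.sphere_scale <= 0 or self.stick_fraction <= 0:
            raise ValueError("radius scales must be positive")
        if not (0 <= self.margin < 1):
            raise ValueError("margin must be in [0, 1)")

    def color_of(self, element: str) -> tuple[int, int, int]:
        return self.atom_colors.get(element, DEFAULT_COLOR)


@dataclass
class SnapshotSet:
    """Ordered snapshots of one molecule: one RGB image per grid orientation."""

    molecule_id: str
    increment: float
    items: list[tuple[Orientation, np.ndarray]]

    def __post_init__(self) -> None:
        expected = len(rotation_grid(self.increment))
        if len(self.items) != expected:
            raise ValueError(
                f"{self.molecule_id}: {len(self.items)} images, grid expects {expected}"
            )
        shapes = {img.shape for _, img in self.items}
        if len(shapes) > 1:
            raise ValueError(f"{self.molecule_id}: inconsistent image dimensions")

    def __len__(self) -> int:
        return len(self.items)

    def images(self) -> np.ndarray:
        """All images stacked as a (n, H, W, 3) uint8 array, grid order."""
        return np.stack([img for _, img in self.items])


def rotation_grid(increment_deg: float) -> list[Orientation]:
    """All grid orientations for a per-axis angle increment.

    Per-axis angles are {0, a, 2a, ...} intersected with [0, 360); the
    grid is the Cartesian product over x, y, z in lexicographic order
    (rx slowest, rz fastest), hence ceil(360/a)**3 orientations.
    """
    a = float(increment_deg)
    if not (0 < a <= 360):
        raise ValueError(f"increment {increment_deg} outside (0, 360]")
    n = math.ceil(360.0 / a)
    axis = [k * a for k in range(n)]
    return [Orientation(rx, ry, rz) for rx in axis for ry in axis for rz in axis]


def rotation_matrix(orientation: Orientation) -> np.ndarray:
    """Extrinsic rotation about fixed world axes: x first, then y, then z."""
    ax, ay, az = (math.radians(v) for v in (orientation.rx, orientation.ry, orientation.rz))
    cx, sx = math.cos(ax), math.sin(ax)
    cy, sy = math.cos(ay), math.sin(ay)
    cz, sz = math.cos(az), math.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _display_radii(elements: Sequence[str], config: RenderConfig) -> np.ndarray:
    return config.sphere_scale * np.array(
        [COVALENT_RADII.get(el, DEFAULT_RADIUS) for el in elements]
    )


def _draw_disk(buf: np.ndarray, cx: float, cy: float, r: float,
               color: tuple[int, int, int]) -> None:
    """Shaded sphere impostor: Lambert-lit disk, light toward the camera."""
    h, w, _ = buf.shape
    x0, x1 = max(0, int(cx - r) - 1), min(w, int(cx + r) + 2)
    y0, y1 = max(0, int(cy - r) - 1), min(h, int(cy + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2
    mask = d2 <= r * r
    if not mask.any():
        return
    nz = np.sqrt(np.clip(1.0 - d2[mask] / (r * r), 0.0, 1.0))
    shade = 0.35 + 0.65 * nz
    buf[y0:y1, x0:x1][mask] = np.clip(
        np.asarray(color, dtype=float)[None, :] * shade[:, None], 0, 255
    )


_STICK_COLOR = (180, 180, 180)


def _draw_stick(buf: np.ndarray, p: np.ndarray, q: np.ndarray, r: float) -> None:
    """Flat-shaded capsule between two projected bond endpoints."""
    h, w, _ = buf.shape
    x0 = max(0, int(min(p[0], q[0]) - r) - 1)
    x1 = min(w, int(max(p[0], q[0]) + r) + 2)
    y0 = max(0, int(min(p[1], q[1]) - r) - 1)
    y1 = min(h, int(max(p[1], q[1]) + r) + 2)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    px = xx + 0.5 - p[0]
    py = yy + 0.5 - p[1]
    vx, vy = q[0] - p[0], q[1] - p[1]
    seg2 = vx * vx + vy * vy
    t = np.clip((px * vx + py * vy) / seg2, 0.0, 1.0) if seg2 > 1e-12 else 0.0
    d2 = (px - t * vx) ** 2 + (py - t * vy) ** 2
    mask = d2 <= r * r
    if not mask.any():
        return
    edge = np.sqrt(np.clip(1.0 - d2[mask] / (r * r), 0.0, 1.0))
    shade = 0.45 + 0.55 * edge
    buf[y0:y1, x0:x1][mask] = np.clip(
        np.asarray(_STICK_COLOR, dtype=float)[None, :] * shade[:, None], 0, 255
    )


def render(molecule: Molecule3D, orientation: Orientation,
           config: RenderConfig = RenderConfig()) -> np.ndarray:
    """Rasterize one orientation of a molecule to an (H, W, 3) uint8 array.

    The molecule is centered at its centroid, rotated, and projected
    orthographically; the per-molecule zoom makes the bounding sphere
    (atom radii included) fill ``1 - margin`` of the frame, so the scale
    is identical at every orientation.  Atoms are depth-sorted together
    with bonds and drawn back-to-front (painter's algorithm).
    """
    coords = molecule.coords - molecule.coords.mean(axis=0)
    radii = _display_radii(molecule.elements, config)
    extent = float(np.max(np.linalg.norm(coords, axis=1) + radii))
    if extent <= 0:
        extent = 1.0

    rot = rotation_matrix(orientation)
    xyz = coords @ rot.T

    half = 0.5 * min(config.width, config.height)
    scale = half * (1.0 - config.margin) / extent
    cx, cy = config.width / 2.0, config.height / 2.0
    # screen coords: x right, y down; camera looks along -z (larger z = nearer)
    pts = np.column_stack([cx + scale * xyz[:, 0], cy - scale * xyz[:, 1]])
    depth = xyz[:, 2]

    if molecule.bonds:
        blen = [np.linalg.norm(xyz[i] - xyz[j]) for i, j, _ in molecule.bonds]
        stick_r = max(config.stick_fraction * scale * float(np.mean(blen)), 0.5)
    else:
        stick_r = 1.0

    prims: list[tuple[float, str, int]] = []
    for i in range(molecule.n_atoms):
        prims.append((float(depth[i]), "atom", i))
    for b, (i, j, _) in enumerate(molecule.bonds):
        prims.append((float(0.5 * (depth[i] + depth[j])), "bond", b))
    prims.sort(key=lambda t: (t[0], t[1], t[2]))  # far to near, stable ties

    buf = np.empty((config.height, config.width, 3), dtype=float)
    buf[:] = np.asarray(config.background, dtype=float)
    for _, kind, idx in prims:
        if kind == "atom":
            _draw_disk(buf, pts[idx, 0], pts[idx, 1],
                       max(scale * radii[idx], 1.0),
                       config.color_of(molecule.elements[idx]))
        else:
            i, j, _ = molecule.bonds[idx]
            _draw_stick(buf, pts[i], pts[j], stick_r)
    return np.clip(np.rint(buf), 0, 255).astype(np.uint8)


def snapshot_ensemble(molecule: Molecule3D, increment: float,
                      config: RenderConfig = RenderConfig()) -> SnapshotSet:
    """Render the molecule at every orientation of the rotation grid."""
    items = []
    for orient in rotation_grid(increment):
        try:
            items.append((orient, render(molecule, orient, config)))
        except Exception as exc:
            raise RuntimeError(
                f"{molecule.id}: render failed at ({orient.rx}, {orient.ry}, "
                f"{orient.rz}): {exc}"
            ) from exc
    return SnapshotSet(molecule.id, increment, items)


def _snapshot_name(molecule_id: str, orient: Orientation) -> str:
    return (f"{molecule_id}_rx{round(orient.rx):03d}"
            f"_ry{round(orient.ry):03d}_rz{round(orient.rz):03d}.png")


def save_ensemble(snapshots: SnapshotSet, directory: str | Path) -> list[Path]:
    """Write each snapshot as an RGB PNG; returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for orient, img in snapshots.items:
        p = directory / _snapshot_name(snapshots.molecule_id, orient)
        Image.fromarray(img, mode="RGB").save(p, format="PNG")
        paths.append(p)
    return paths


def save_ensembles(ensembles: Iterable[SnapshotSet], directory: str | Path) -> list[Path]:
    """Save many ensembles into one directory; duplicate molecule ids error."""
    ensembles = list(ensembles)
    ids = [e.molecule_id for e in ensembles]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate molecule ids would collide on disk: {dupes}")
    paths: list[Path] = []
    for e in ensembles:
        paths.extend(save_ensemble(e, directory))
    return paths
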