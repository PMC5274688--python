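"""Geometry of the layered long-bone model with an oblique crack.

The 2D model is a stack of horizontal layers (soft tissue over cortical
bone over marrow) sampled on a square cell-centered grid. Coordinates:
``y`` increases downward from the free soft-tissue surface at y = 0, ``z``
runs along the bone axis with z = 0 at the crack mid-line. The crack is a
parallelogram-shaped band through the full cortical thickness: at each
depth the axial gap has constant width ``w`` and its mid-line is displaced
by (y − y_top)·tan θ, where θ is the fracture angle measured from the
y-axis (θ = 0 is a transverse fracture).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .materials import ElasticMaterial, SOFT_TISSUE, lame_from_velocities

__all__ = [
    "GeometryError",
    "LayerSpec",
    "CrackSpec",
    "MaterialGrid",
    "build_layered_grid",
    "carve_crack",
    "default_layers",
]


class GeometryError(ValueError):
    """Layer stack or crack does not fit the grid."""


@dataclass(frozen=True)
class LayerSpec:
    name: str
    thickness: float  # mm
    material: ElasticMaterial

    def __post_init__(self) -> None:
        if self.thickness <= 0:
            raise GeometryError(f"layer {self.name!r}: thickness must be > 0")


@dataclass(frozen=True)
class CrackSpec:
    """Axial gap width ``width_w`` (mm), fracture angle ``angle_theta``
    (degrees from the y-axis; 0 = transverse), fill material (soft tissue by
    default — a fresh, unhealed fracture) and axial position of the crack
    mid-line at the top of the cortical layer."""

    width_w: float
    angle_theta: float = 0.0
    fill: ElasticMaterial = SOFT_TISSUE
    center_z: float = 0.0

    def __post_init__(self) -> None:
        if self.width_w < 0:
            raise GeometryError(f"width_w must be >= 0, got {self.width_w}")
        if not 0.0 <= self.angle_theta < 90.0:
            raise GeometryError(f"angle_theta must be in [0, 90), got {self.angle_theta}")


@dataclass
class MaterialGrid:
    """Cell-centered 2D property fields, indexed ``[iz, iy]``.

    Cell (iz, iy) is centered at z = z0 + iz·dx, y = (iy + ½)·dx. The
    ``damping`` field is an amplitude decay rate in 1/µs (zero until the
    solver attaches attenuation). ``layer_index`` labels cells by layer
    (order in the stack); crack cells keep their layer label.
    """

    dx: float
    nz: int
    ny: int
    z0: float  # z of the first column of cell centers (mm)
    density: np.ndarray
    lame_lambda: np.ndarray
    lame_mu: np.ndarray
    damping: np.ndarray
    layer_index: np.ndarray
    attenuation: np.ndarray = None  # dB·cm⁻¹·MHz⁻¹ per cell
    layers: list[LayerSpec] = field(default_factory=list)
    crack: CrackSpec | None = None

    def __post_init__(self) -> None:
        if self.attenuation is None:
            self.attenuation = np.zeros((self.nz, self.ny))
        shape = (self.nz, self.ny)
        for name in ("density", "lame_lambda", "lame_mu", "damping", "layer_index", "attenuation"):
            arr = getattr(self, name)
            if arr.shape != shape:
                raise GeometryError(f"field {name} has shape {arr.shape}, expected {shape}")
        if np.any(self.density <= 0) or np.any(self.lame_lambda <= 0):
            raise GeometryError("density and lame_lambda must be strictly positive")
        if np.any(self.lame_mu < 0) or np.any(self.damping < 0):
            raise GeometryError("lame_mu and damping must be non-negative")

    @property
    def z_centers(self) -> np.ndarray:
        return self.z0 + self.dx * np.arange(self.nz)

    @property
    def y_centers(self) -> np.ndarray:
        return self.dx * (np.arange(self.ny) + 0.5)

    @property
    def v_long_max(self) -> float:
        return float(np.sqrt(((self.lame_lambda + 2 * self.lame_mu) / self.density).max()))

    def layer_y_range(self, index: int) -> tuple[float, float]:
        """(y_top, y_bottom) of a layer in mm."""
        tops = np.cumsum([0.0] + [l.thickness for l in self.layers])
        return tops[index], tops[index + 1]

    def copy(self) -> "MaterialGrid":
        return MaterialGrid(
            self.dx, self.nz, self.ny, self.z0,
            self.density.copy(), self.lame_lambda.copy(), self.lame_mu.copy(),
            self.damping.copy(), self.layer_index.copy(), self.attenuation.copy(),
            list(self.layers), self.crack,
        )


def default_layers() -> list[LayerSpec]:
    """The reference stack: 2 mm soft tissue, 4 mm cortical bone, 10 mm marrow."""
    from .materials import CORTICAL_BONE, MARROW, SOFT_TISSUE as TISSUE

    return [
        LayerSpec("soft_tissue", 2.0, TISSUE),
        LayerSpec("cortical_bone", 4.0, CORTICAL_BONE),
        LayerSpec("marrow", 10.0, MARROW),
    ]


def build_layered_grid(
    layers: list[LayerSpec], length_z: float, dx: float
) -> MaterialGrid:
    """Sample a horizontal layer stack onto a square-cell grid.

    The grid spans z ∈ [−length_z/2, length_z/2] and y ∈ [0, Σ thickness].
    Each cell takes the properties of the layer containing its center.
    ``dx`` must tile every thickness and the length to within one cell.
    """
    if dx <= 0:
        raise GeometryError(f"dx must be > 0, got {dx}")
    if not layers:
        raise GeometryError("at least one layer required")
    total = sum(l.thickness for l in layers)
    for l in layers:
        if abs(l.thickness / dx - round(l.thickness / dx)) > 1e-6:
            raise GeometryError(f"dx={dx} does not tile layer {l.name!r} ({l.thickness} mm)")
    if abs(length_z / dx - round(length_z / dx)) > 1e-6:
        raise GeometryError(f"dx={dx} does not tile length_z={length_z}")
    nz = int(round(length_z / dx))
    ny = int(round(total / dx))

    density = np.empty((nz, ny))
    lam = np.empty((nz, ny))
    mu = np.empty((nz, ny))
    att = np.empty((nz, ny))
    layer_index = np.empty((nz, ny), dtype=np.int32)
    y = dx * (np.arange(ny) + 0.5)
    y_top = 0.0
    for idx, layer in enumerate(layers):
        sel = (y >= y_top) & (y < y_top + layer.thickness)
        l_lam, l_mu = lame_from_velocities(layer.material)
        density[:, sel] = layer.material.density
        lam[:, sel] = l_lam
        mu[:, sel] = l_mu
        att[:, sel] = layer.material.attenuation
        layer_index[:, sel] = idx
        y_top += layer.thickness
    # cells whose center falls exactly on the bottom boundary (rounding)
    tail = y >= y_top
    if tail.any():
        l_lam, l_mu = lame_from_velocities(layers[-1].material)
        density[:, tail] = layers[-1].material.density
        lam[:, tail] = l_lam
        mu[:, tail] = l_mu
        att[:, tail] = layers[-1].material.attenuation
        layer_index[:, tail] = len(layers) - 1

    return MaterialGrid(
        dx=dx, nz=nz, ny=ny, z0=-0.5 * length_z + 0.5 * dx,
        density=density, lame_lambda=lam, lame_mu=mu,
        damping=np.zeros((nz, ny)), layer_index=layer_index,
        attenuation=att, layers=list(layers),
    )


def carve_crack(
    grid: MaterialGrid, crack: CrackSpec, cortical_index: int = 1
) -> MaterialGrid:
    """Replace cortical-layer cells inside the tilted crack band by the fill.

    A cell belongs to the crack when its center satisfies
    ``|z − center_z − (y − y_top)·tan θ| ≤ w/2`` and it lies in the cortical
    layer. Zero width returns an identical copy (intact model); the
    operation is idempotent. Raises :class:`GeometryError` when the tilted
    band leaves the axial extent of the grid.
    """
    out = grid.copy()
    out.crack = crack
    if crack.width_w == 0:
        return out

    y_top, y_bot = grid.layer_y_range(cortical_index)
    tan_t = math.tan(math.radians(crack.angle_theta))
    z_lo, z_hi = grid.z0, grid.z0 + (grid.nz - 1) * grid.dx
    for y_edge in (y_top, y_bot):
        for sgn in (-1.0, 1.0):
            z_face = crack.center_z + y_edge_offset(y_edge, y_top, tan_t) + sgn * crack.width_w / 2
            if not (z_lo <= z_face <= z_hi):
                raise GeometryError(
                    f"crack band exits the axial domain (face at z={z_face:.2f} mm)"
                )

    z = grid.z_centers[:, None]
    y = grid.y_centers[None, :]
    in_layer = grid.layer_index == cortical_index
    band = np.abs(z - crack.center_z - (y - y_top) * tan_t) <= crack.width_w / 2
    sel = in_layer & band
    f_lam, f_mu = lame_from_velocities(crack.fill)
    out.density[sel] = crack.fill.density
    out.lame_lambda[sel] = f_lam
    out.lame_mu[sel] = f_mu
    out.attenuation[sel] = crack.fill.attenuation
    return out


def y_edge_offset(y_edge: float, y_top: float, tan_t: float) -> float:
    return (y_edge - y_top) * tan_t


def crack_cell_count(grid: MaterialGrid, intact: MaterialGrid) -> int:
    """Number of cells whose properties differ from the intact reference."""
    return int(np.count_nonzero(grid.density != intact.density))
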