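"""Rayleigh–Lamb dispersion of a free elastic plate.

Solves the characteristic equations of the symmetric (S) and antisymmetric
(A) Lamb-wave families for phase-velocity branches, differentiates them into
group velocity, counts propagating modes below a frequency–thickness bound,
and predicts direct and mode-converted packet arrival times for the
axial-transmission geometry.

The characteristic residual is kept real and continuous through the bulk
velocities by the substitution tan(x)/x → tanh(|x|)/|x| when a squared
through-thickness wavenumber (p² = ω²/V_L² − k², q² = ω²/V_T² − k²) turns
negative, which lets ordinary bracketed root refinement work on every
velocity interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .materials import ElasticMaterial, ElasticPlate

__all__ = [
    "DispersionError",
    "NoRootError",
    "ModeBranch",
    "ArrivalPlan",
    "lamb_characteristic",
    "solve_phase_velocity",
    "trace_branch",
    "count_propagating_modes",
    "predict_arrivals",
    "rayleigh_velocity",
    "thin_plate_s0_velocity",
    "fundamental_branches",
    "group_velocities_at",
]

_SYMMETRIC = ("s", "sym", "symmetric")
_ANTISYMMETRIC = ("a", "anti", "antisymmetric")

#: Upper end of the phase-velocity scan window, as a multiple of V_L. Roots of
#: higher-order branches just above their cutoff (v_phase → ∞) fall outside
#: any finite window; the scan ceiling bounds which near-cutoff roots are seen.
_SCAN_VMAX_FACTOR = 6.0
_SCAN_POINTS = 3000
#: Relative residual below which a refined bracket is accepted as a root
#: (rejects the tan-pole sign changes of the characteristic function).
_RESIDUAL_TOL = 1e-6


class DispersionError(RuntimeError):
    """Branch tracing failed (discontinuity / mislabeled root)."""


class NoRootError(DispersionError):
    """The requested mode does not exist at this frequency–thickness."""


def _normalize_family(family: str) -> str:
    f = family.lower()
    if f in _SYMMETRIC:
        return "symmetric"
    if f in _ANTISYMMETRIC:
        return "antisymmetric"
    raise ValueError(f"unknown Lamb family {family!r}")


def _ct(x2: float, half_h: float) -> float:
    """cos(sqrt(x2)·half_h) for x2 ≥ 0; 1 in the evanescent region x2 < 0.

    The evanescent cosh(sqrt(−x2)·half_h) is factored out of the residual
    (a positive scale that cannot hold a root), which bounds the function
    and keeps it continuous across x2 = 0.
    """
    if x2 > 0.0:
        return math.cos(math.sqrt(x2) * half_h)
    return 1.0


def _st(x2: float, half_h: float) -> float:
    """sin(sqrt(x2)·half_h)/sqrt(x2), continued to tanh(r·half_h)/r for
    x2 < 0 (the same cosh factor removed as in :func:`_ct`); half_h at 0."""
    if x2 > 0.0:
        r = math.sqrt(x2)
        return math.sin(r * half_h) / r
    if x2 < 0.0:
        r = math.sqrt(-x2)
        return math.tanh(r * half_h) / r
    return half_h


def _characteristic_terms(
    family: str, fh: float, v_phase: float, plate: ElasticPlate
) -> tuple[float, float]:
    mat = plate.material
    h = plate.thickness_h
    f = fh / h  # MHz
    w = 2.0 * math.pi * f  # rad/µs
    k2 = (w / v_phase) ** 2
    p2 = (w / mat.v_long) ** 2 - k2
    q2 = (w / mat.v_shear) ** 2 - k2
    hh = 0.5 * h
    if family == "symmetric":
        return (
            (q2 - k2) ** 2 * _ct(p2, hh) * _st(q2, hh),
            4.0 * k2 * p2 * _st(p2, hh) * _ct(q2, hh),
        )
    return (
        4.0 * k2 * q2 * _st(q2, hh) * _ct(p2, hh),
        (q2 - k2) ** 2 * _st(p2, hh) * _ct(q2, hh),
    )


def lamb_characteristic(
    family: str, fh: float, v_phase: float, plate: ElasticPlate
) -> float:
    """Real residual of the Rayleigh–Lamb equation; zero on a dispersion branch.

    The pole-free product form is used: for the symmetric family
    ``(q²−k²)²·cos(ph/2)·sin(qh/2)/q + 4k²p·sin(ph/2)·q·cos(qh/2)/q`` (and
    the mirrored expression for the antisymmetric family), with
    k = ω/v_phase, p² = ω²/V_L² − k², q² = ω²/V_T² − k². Evanescent
    (negative-squared) wavenumbers are continued via cosh/sinh with the
    common exponential growth factored out, so the residual is real,
    continuous and bounded on the whole phase-velocity axis and every sign
    change brackets a root.
    """
    family = _normalize_family(family)
    if fh <= 0 or v_phase <= 0:
        raise ValueError(f"fh and v_phase must be > 0 (got fh={fh}, v_phase={v_phase})")
    t1, t2 = _characteristic_terms(family, fh, v_phase, plate)
    return t1 + t2


def _relative_residual(family: str, fh: float, v: float, plate: ElasticPlate) -> float:
    t1, t2 = _characteristic_terms(family, fh, v, plate)
    scale = max(abs(t1), abs(t2), 1e-300)
    return abs(t1 + t2) / scale


def _refine(family: str, fh: float, a: float, b: float, plate: ElasticPlate) -> float | None:
    """Brentq on a sign-change bracket; None if it refines onto a tan pole."""
    root = brentq(
        lambda v: lamb_characteristic(family, fh, v, plate), a, b, xtol=1e-14, rtol=1e-12
    )
    if _relative_residual(family, fh, root, plate) < _RESIDUAL_TOL:
        return root
    return None


def _scan_roots(
    family: str,
    fh: float,
    plate: ElasticPlate,
    v_lo: float | None = None,
    v_hi: float | None = None,
    n: int = _SCAN_POINTS,
) -> list[float]:
    mat = plate.material
    if v_lo is None:
        v_lo = 1e-3 * mat.v_shear if mat.v_shear > 0 else 1e-3
    if v_hi is None:
        v_hi = _SCAN_VMAX_FACTOR * mat.v_long
    grid = np.linspace(v_lo, v_hi, n)
    vals = np.array([lamb_characteristic(family, fh, v, plate) for v in grid])
    roots: list[float] = []
    sign_change = np.nonzero(np.sign(vals[:-1]) * np.sign(vals[1:]) < 0)[0]
    for i in sign_change:
        r = _refine(family, fh, grid[i], grid[i + 1], plate)
        if r is not None:
            roots.append(r)
    return roots


def solve_phase_velocity(
    family: str, order: int, fh: float, plate: ElasticPlate
) -> float:
    """Phase velocity (mm/µs) of the order-th branch of a family at one f·h.

    Roots of the characteristic equation are collected by a dense
    phase-velocity scan with bracketed refinement and returned in ascending
    order; ``order`` indexes into that list. Raises :class:`NoRootError`
    below a higher-order mode's cutoff (fh_cutoff = n·V_T/2 or n·V_L/2).
    """
    family = _normalize_family(family)
    if fh <= 0:
        raise ValueError(f"fh must be > 0, got {fh}")
    if order < 0:
        raise ValueError(f"order must be >= 0, got {order}")
    roots = _scan_roots(family, fh, plate)
    if len(roots) <= order:
        raise NoRootError(
            f"{family} branch of order {order} has no root at fh={fh} MHz·mm "
            f"(found {len(roots)} root(s) in the scan window)"
        )
    return roots[order]


@dataclass
class ModeBranch:
    """One traced Lamb-mode dispersion branch.

    ``fh_samples`` (MHz·mm) strictly increase; ``v_phase`` and ``v_group``
    (mm/µs) are the sampled phase and group velocities. Group velocity is
    dω/dk by finite differences along the branch.
    """

    family: str
    order: int
    fh_samples: np.ndarray
    v_phase: np.ndarray
    v_group: np.ndarray
    plate: ElasticPlate = field(repr=False, default=None)

    def v_phase_at(self, fh: float) -> float:
        return float(np.interp(fh, self.fh_samples, self.v_phase))

    def v_group_at(self, fh: float) -> float:
        return float(np.interp(fh, self.fh_samples, self.v_group))

    @property
    def name(self) -> str:
        return ("S" if self.family == "symmetric" else "A") + str(self.order)


def _rebracket(
    family: str, fh: float, v_prev: float, plate: ElasticPlate
) -> float | None:
    """Find the root nearest v_prev by expanding relative brackets."""
    f = lambda v: lamb_characteristic(family, fh, v, plate)
    for delta in (0.02, 0.05, 0.1, 0.2, 0.35):
        a = v_prev * (1.0 - delta)
        b = v_prev * (1.0 + delta)
        # sub-scan inside the bracket so a pole+root pair is not missed
        grid = np.linspace(a, b, 40)
        vals = [f(v) for v in grid]
        for i in range(len(grid) - 1):
            if np.sign(vals[i]) * np.sign(vals[i + 1]) < 0:
                r = _refine(family, fh, grid[i], grid[i + 1], plate)
                if r is not None:
                    return r
    return None


def trace_branch(
    family: str,
    order: int,
    fh_grid: np.ndarray,
    plate: ElasticPlate,
    max_jump: float = 0.05,
) -> ModeBranch:
    """Trace one branch over a strictly increasing f·h grid.

    Continuation: the first grid point is solved by a full scan, each
    subsequent one by local re-bracketing around the previous root (this
    prevents hopping onto a neighbouring branch near mode crossings). An
    adjacent-sample jump above ``max_jump`` (relative) raises
    :class:`DispersionError`. Group velocity is dω/dk via central
    differences on the traced (ω, k) samples, one-sided at the endpoints.
    """
    family = _normalize_family(family)
    fh_grid = np.asarray(fh_grid, dtype=float)
    if fh_grid.ndim != 1 or len(fh_grid) < 3:
        raise ValueError("fh_grid must be a 1-D array with at least 3 samples")
    if not np.all(np.diff(fh_grid) > 0):
        raise ValueError("fh_grid must be strictly increasing")

    vp = np.empty_like(fh_grid)
    vp[0] = solve_phase_velocity(family, order, fh_grid[0], plate)
    for i in range(1, len(fh_grid)):
        r = _rebracket(family, fh_grid[i], vp[i - 1], plate)
        if r is None:
            r = solve_phase_velocity(family, order, fh_grid[i], plate)
        # allowed jump: max_jump in flat regions, widened where the branch
        # itself is steep (A0 phase velocity grows like sqrt(fh) near 0)
        if i >= 2:
            local = abs(vp[i - 1] / vp[i - 2] - 1.0)
            allowed = max(max_jump, 2.5 * local)
        else:
            allowed = max(max_jump, 0.5)
        if abs(r - vp[i - 1]) > allowed * vp[i - 1]:
            raise DispersionError(
                f"branch {family}{order} jumps {vp[i-1]:.4f} -> {r:.4f} mm/µs "
                f"at fh={fh_grid[i]:.4f} MHz·mm (grid too coarse or mode crossing)"
            )
        vp[i] = r

    h = plate.thickness_h
    omega = 2.0 * math.pi * fh_grid / h  # rad/µs
    k = omega / vp  # rad/mm
    vg = np.gradient(omega, k)  # central differences, one-sided at ends
    if not (np.all(np.isfinite(vg)) and np.all(vg > 0)):
        raise DispersionError(f"non-finite or non-positive group velocity on {family}{order}")
    return ModeBranch(family, order, fh_grid, vp, vg, plate)


def count_propagating_modes(fh_max: float, plate: ElasticPlate) -> int:
    """Number of Lamb modes with cutoff below ``fh_max`` (MHz·mm).

    The two fundamentals S0/A0 have no cutoff; each higher-order mode cuts
    on at f·h = n·V_T/2 or n·V_L/2 (n ≥ 1, both families interleaved), so
    the count is 2 plus the number of such cutoffs strictly below fh_max.
    """
    if fh_max <= 0:
        raise ValueError(f"fh_max must be > 0, got {fh_max}")
    mat = plate.material
    count = 2
    for v in (mat.v_shear, mat.v_long):
        if v > 0:
            # n·v/2 < fh_max  ->  n < 2·fh_max/v
            count += max(0, math.ceil(2.0 * fh_max / v) - 1)
    return count


@dataclass(frozen=True)
class ArrivalPlan:
    """Predicted packet delays (µs) for source→crack distance z1 and
    crack→receiver distance z2: the direct S0 and A0 arrivals and the two
    mode-converted paths (S0 on one leg, A0 on the other)."""

    t_S0: float
    t_A0: float
    t_conv_A0S0: float
    t_conv_S0A0: float


def predict_arrivals(z1: float, z2: float, v_S0: float, v_A0: float) -> ArrivalPlan:
    """Direct and converted-mode delays over the split path z1 + z2.

    t_S0 = (z1+z2)/v_S0, t_A0 = (z1+z2)/v_A0; a packet converted at the
    crack travels one leg at each group velocity:
    t_conv_A0S0 = z1/v_S0 + z2/v_A0 and t_conv_S0A0 = z1/v_A0 + z2/v_S0.
    Both converted delays lie between the direct ones and coincide when
    z1 = z2 (the converted packets merge).
    """
    if min(z1, z2) < 0 or z1 + z2 <= 0:
        raise ValueError(f"distances must be >= 0 with z1+z2 > 0 (got {z1}, {z2})")
    if v_S0 <= 0 or v_A0 <= 0:
        raise ValueError("velocities must be > 0")
    if v_S0 <= v_A0:
        raise ValueError(f"expected v_S0 > v_A0, got {v_S0} <= {v_A0}")
    return ArrivalPlan(
        t_S0=(z1 + z2) / v_S0,
        t_A0=(z1 + z2) / v_A0,
        t_conv_A0S0=z1 / v_S0 + z2 / v_A0,
        t_conv_S0A0=z1 / v_A0 + z2 / v_S0,
    )


def rayleigh_velocity(material: ElasticMaterial) -> float:
    """Rayleigh surface-wave velocity: root of the Rayleigh equation
    (2−c²/V_T²)² = 4·sqrt(1−c²/V_L²)·sqrt(1−c²/V_T²) in (0, V_T)."""
    vl, vt = material.v_long, material.v_shear

    def f(c: float) -> float:
        x = (c / vt) ** 2
        return (2.0 - x) ** 2 - 4.0 * math.sqrt(1.0 - (c / vl) ** 2) * math.sqrt(1.0 - x)

    return brentq(f, 1e-6 * vt, vt * (1.0 - 1e-12))


def thin_plate_s0_velocity(material: ElasticMaterial) -> float:
    """Low-frequency S0 (plate) velocity 2·V_T·sqrt(1 − V_T²/V_L²)."""
    vt, vl = material.v_shear, material.v_long
    return 2.0 * vt * math.sqrt(1.0 - (vt / vl) ** 2)


def fundamental_branches(
    plate: ElasticPlate,
    fh_max: float = 1.0,
    fh_step: float = 0.005,
) -> tuple[ModeBranch, ModeBranch]:
    """Trace the S0 and A0 branches from low f·h up to ``fh_max``."""
    grid = np.arange(fh_step, fh_max + 0.5 * fh_step, fh_step)
    s0 = trace_branch("symmetric", 0, grid, plate)
    a0 = trace_branch("antisymmetric", 0, grid, plate)
    return s0, a0


def group_velocities_at(
    plate: ElasticPlate, fh: float, fh_step: float = 0.005
) -> tuple[float, float]:
    """(v_group(S0), v_group(A0)) at one f·h, from freshly traced branches."""
    s0, a0 = fundamental_branches(plate, fh_max=max(1.0, fh * 1.25), fh_step=fh_step)
    return s0.v_group_at(fh), a0.v_group_at(fh)
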