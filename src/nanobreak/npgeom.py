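"""Nanoparticle-loaded water phantom geometry.

A microscopic water sphere carries a dilute, homogeneous suspension of
non-overlapping core-shell nanoparticles (gold cores with gold or platinum
shells). This module builds that phantom by hard-sphere rejection sampling
and provides the bookkeeping conversions between metal concentration,
atoms per particle, and particle number.

Internal length unit is the nanometre; the phantom volume is accepted in
µm³ and sample volumes in litres at the interface.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

AVOGADRO = 6.02214076e23  # mol^-1

#: hard cap on placement attempts per particle before the phantom is
#: declared overcrowded
MAX_PLACEMENT_RETRIES = 100_000


@dataclass(frozen=True)
class CoreShellNP:
    """A spherical core-shell nanoparticle.

    Parameters
    ----------
    center : (3,) array_like
        Particle centre in nm, phantom-centred coordinates.
    core_diameter : float
        Metal core diameter in nm (> 0).
    shell_thickness : float
        Shell thickness in nm (>= 0; 0 means a bare monometallic particle).
    core_material, shell_material : str
        Material labels; ``"Au"`` cores with ``"Au"`` or ``"Pt"`` shells in
        the systems modelled here.
    """

    center: np.ndarray
    core_diameter: float
    shell_thickness: float
    shell_material: str = "Au"
    core_material: str = "Au"

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        if center.shape != (3,):
            raise ValueError(f"center must be a 3-vector, got shape {center.shape}")
        object.__setattr__(self, "center", center)
        if self.core_diameter <= 0:
            raise ValueError("core_diameter must be positive")
        if self.shell_thickness < 0:
            raise ValueError("shell_thickness must be non-negative")

    @property
    def core_radius(self) -> float:
        return self.core_diameter / 2.0

    @property
    def outer_radius(self) -> float:
        """Core radius plus shell thickness, nm."""
        return self.core_diameter / 2.0 + self.shell_thickness


@dataclass
class Phantom:
    """Water sphere with embedded non-overlapping core-shell nanoparticles.

    ``sphere_volume`` is in µm³; the radius is derived as (3V/4π)^(1/3).
    """

    sphere_volume: float  # µm³
    particles: list[CoreShellNP] = field(default_factory=list)
    water_density: float = 1000.0  # kg/m³
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sphere_volume <= 0:
            raise ValueError("sphere_volume must be positive")

    @property
    def sphere_radius(self) -> float:
        """Sphere radius in µm."""
        return (3.0 * self.sphere_volume / (4.0 * math.pi)) ** (1.0 / 3.0)

    @property
    def sphere_radius_nm(self) -> float:
        return self.sphere_radius * 1e3

    @property
    def n_particles(self) -> int:
        return len(self.particles)

    def centers_nm(self) -> np.ndarray:
        """(n, 3) array of particle centres in nm (empty (0, 3) if none)."""
        if not self.particles:
            return np.empty((0, 3))
        return np.stack([p.center for p in self.particles])

    def water_mass_kg(self) -> float:
        """Mass of the water in the sphere, excluding particle volume."""
        v_sphere_m3 = self.sphere_volume * 1e-18
        v_np_m3 = sum(
            4.0 / 3.0 * math.pi * p.outer_radius**3 for p in self.particles
        ) * 1e-27
        return self.water_density * (v_sphere_m3 - v_np_m3)


class PlacementError(RuntimeError):
    """Raised when hard-sphere placement fails: the phantom is overcrowded."""


def _uniform_in_sphere(rng: np.random.Generator, radius: float) -> np.ndarray:
    """One point uniform in a sphere of given radius (direction × r·u^(1/3))."""
    direction = rng.normal(size=3)
    norm = np.linalg.norm(direction)
    while norm == 0.0:  # pragma: no cover - probability zero
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
    r = radius * rng.random() ** (1.0 / 3.0)
    return direction / norm * r


def build_phantom(
    n_particles: int,
    sphere_volume: float = 50.0,
    core_diameter: float = 3.0,
    shell_thickness: float = 2.0,
    shell_material: str = "Pt",
    seed: int = 0,
    core_material: str = "Au",
    water_density: float = 1000.0,
    max_retries: int = MAX_PLACEMENT_RETRIES,
) -> Phantom:
    """Place ``n_particles`` identical core-shell particles uniformly in a
    water sphere, with hard-sphere non-overlap.

    Centres are sampled uniformly in the sphere interior shrunk by the
    particle outer radius so every particle lies fully inside; a candidate
    is rejected if it would overlap any already-placed particle (centre
    distance <= sum of outer radii). Deterministic for a fixed seed.

    Raises
    ------
    PlacementError
        If a particle cannot be placed within ``max_retries`` attempts.
    """
    if n_particles < 0:
        raise ValueError("n_particles must be non-negative")
    phantom = Phantom(
        sphere_volume=sphere_volume, water_density=water_density, seed=seed
    )
    outer = core_diameter / 2.0 + shell_thickness
    if core_diameter <= 0:
        raise ValueError("core_diameter must be positive")
    allowed_radius = phantom.sphere_radius_nm - outer
    if n_particles > 0 and allowed_radius <= 0:
        raise PlacementError(
            f"particle outer radius {outer} nm exceeds sphere radius "
            f"{phantom.sphere_radius_nm:.3f} nm"
        )
    rng = np.random.default_rng(seed)
    centers = np.empty((n_particles, 3))
    min_sep2 = (2.0 * outer) ** 2
    for i in range(n_particles):
        for _ in range(max_retries):
            candidate = _uniform_in_sphere(rng, allowed_radius)
            if i:
                d2 = np.sum((centers[:i] - candidate) ** 2, axis=1)
                if np.min(d2) <= min_sep2:
                    continue
            centers[i] = candidate
            break
        else:
            raise PlacementError(
                f"could not place particle {i + 1}/{n_particles} after "
                f"{max_retries} attempts; phantom too crowded"
            )
    phantom.particles = [
        CoreShellNP(
            center=c,
            core_diameter=core_diameter,
            shell_thickness=shell_thickness,
            shell_material=shell_material,
            core_material=core_material,
        )
        for c in centers
    ]
    return phantom


def atoms_per_particle(core_diameter: float, atomic_density: float) -> int:
    """Number of metal atoms in a spherical core.

    ``(π/6)·d³·ρ`` rounded to the nearest integer, with ``d`` in nm and
    ``ρ`` in atoms/nm³ (bulk Au: ~59 atoms/nm³).
    """
    if core_diameter <= 0 or atomic_density <= 0:
        raise ValueError("core_diameter and atomic_density must be positive")
    return round(math.pi / 6.0 * core_diameter**3 * atomic_density)


def particles_from_concentration(
    metal_concentration: float, atoms_per_particle: float, volume: float
) -> int:
    """Particle count from total metal concentration.

    Parameters are the metal concentration in mol/L, atoms per particle,
    and the sample volume in litres. A zero volume gives zero particles.
    """
    if metal_concentration <= 0 or atoms_per_particle <= 0:
        raise ValueError("metal_concentration and atoms_per_particle must be positive")
    if volume < 0:
        raise ValueError("volume must be non-negative")
    return round(metal_concentration * AVOGADRO * volume / atoms_per_particle)


def write_phantom(phantom: Phantom, path: str | Path) -> None:
    """Serialize a phantom to columnar text (one particle per row)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# seed={phantom.seed}\n")
        fh.write(f"# sphere_volume_um3={phantom.sphere_volume!r}\n")
        fh.write(f"# water_density={phantom.water_density!r}\n")
        fh.write("# columns=cx_nm cy_nm cz_nm core_d_nm shell_t_nm shell_material core_material\n")
        for p in phantom.particles:
            fh.write(
                f"{p.center[0]:.17g}\t{p.center[1]:.17g}\t{p.center[2]:.17g}\t"
                f"{p.core_diameter:.17g}\t{p.shell_thickness:.17g}\t"
                f"{p.shell_material}\t{p.core_material}\n"
            )


def read_phantom(path: str | Path) -> Phantom:
    """Read a phantom written by :func:`write_phantom`."""
    path = Path(path)
    header: dict[str, str] = {}
    particles: list[CoreShellNP] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    header[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if len(fields) != 7:
                raise ValueError(f"{path}:{lineno}: expected 7 fields, got {len(fields)}")
            try:
                cx, cy, cz, core_d, shell_t = (float(v) for v in fields[:5])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed number") from exc
            particles.append(
                CoreShellNP(
                    center=np.array([cx, cy, cz]),
                    core_diameter=core_d,
                    shell_thickness=shell_t,
                    shell_material=fields[5],
                    core_material=fields[6],
                )
            )
    if "sphere_volume_um3" not in header:
        raise ValueError(f"{path}: missing sphere_volume_um3 header")
    seed = None if header.get("seed", "None") == "None" else int(header["seed"])
    return Phantom(
        sphere_volume=float(header["sphere_volume_um3"]),
        particles=particles,
        water_density=float(header.get("water_density", 1000.0)),
        seed=seed,
    )
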