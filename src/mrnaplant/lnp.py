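"""Lipid-nanoparticle shell composition and molecular packing.

The vaccine particle is a ~250 Angstrom lipid nanosphere encapsulating the
mRNA payload.  Its lipid budget follows area-per-lipid (APL) bookkeeping:
the number of surface-occupying lipids is the sphere surface divided by the
APL.  Cholesterol intercalates between the phospholipid headgroups by
default and therefore consumes no surface area of its own; its count is
carried as a ratio to the surface-occupying pool.

The spatial seed configuration for the molecules is posed as an
unconstrained penalty minimisation: the objective accumulates a squared
hinge for every inter-molecular atom pair closer than a tolerance d_tol
(2 Angstrom by default) plus squared hinges for region constraints, and
vanishes exactly when the configuration is feasible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from ._units import angstrom2_to_nm2
from .errors import InvalidInputError

SHELL_SPECIES = ("DSPC", "CHOL", "DDAB", "PEG", "DOPE")


@dataclass
class ShellSpec:
    """LNP shell composition problem.

    ``composition`` holds relative mole amounts per species (any positive
    scale); ``apl`` is the average area per lipid in nm^2; the particle
    diameter is in Angstrom.
    """

    particle_diameter: float = 250.0
    apl: float = 0.65
    composition: dict[str, float] = field(
        default_factory=lambda: {"DSPC": 620, "CHOL": 2876, "DDAB": 2280,
                                 "PEG": 124, "DOPE": 0})
    rna_copies: int = 22
    cholesterol_intercalates: bool = True

    def __post_init__(self) -> None:
        if self.particle_diameter <= 0:
            raise InvalidInputError("particle_diameter must be > 0")
        unknown = set(self.composition) - set(SHELL_SPECIES)
        if unknown:
            raise InvalidInputError(f"unknown shell species: {sorted(unknown)}")
        if any(v < 0 for v in self.composition.values()):
            raise InvalidInputError("composition entries must be >= 0")

    def surface_area_nm2(self) -> float:
        r = self.particle_diameter / 2.0
        return angstrom2_to_nm2(4.0 * math.pi * r * r)


def area_per_lipid(diameter: float, surface_lipid_count: float) -> float:
    """APL (nm^2) = sphere surface / number of surface lipids; diameter in
    Angstrom."""
    if surface_lipid_count <= 0:
        raise InvalidInputError("surface_lipid_count must be > 0")
    r = diameter / 2.0
    return angstrom2_to_nm2(4.0 * math.pi * r * r) / surface_lipid_count


def _largest_remainder(targets: np.ndarray, total: int) -> np.ndarray:
    """Round non-negative reals to integers preserving their (rounded) sum."""
    floors = np.floor(targets).astype(int)
    remainder = int(total - floors.sum())
    order = np.argsort(-(targets - floors))
    out = floors.copy()
    for i in order[:remainder]:
        out[i] += 1
    return out


def shell_counts(spec: ShellSpec) -> dict[str, int]:
    """Per-species molecule counts covering the particle surface.

    The surface-occupying count is surface area / APL.  When cholesterol
    intercalates it is excluded from the surface budget: the surface pool is
    apportioned over the non-cholesterol species (largest-remainder
    rounding, preserving the pool total) and the cholesterol count follows
    its mole ratio to that pool.
    """
    if spec.apl <= 0:
        raise InvalidInputError("apl must be > 0")
    n_surface = spec.surface_area_nm2() / spec.apl
    comp = {s: spec.composition.get(s, 0.0) for s in SHELL_SPECIES}
    total_comp = sum(comp.values())
    if total_comp <= 0:
        raise InvalidInputError("composition must have a positive total")
    counts: dict[str, int] = {}
    if spec.cholesterol_intercalates:
        surf_species = [s for s in SHELL_SPECIES
                        if s != "CHOL" and comp[s] > 0]
        surf_total = sum(comp[s] for s in surf_species)
        if surf_total <= 0:
            raise InvalidInputError(
                "cholesterol-only composition cannot cover the surface")
        pool = int(round(n_surface))
        targets = np.array([n_surface * comp[s] / surf_total
                            for s in surf_species])
        ints = _largest_remainder(targets, pool)
        counts = dict.fromkeys(SHELL_SPECIES, 0)
        counts.update(dict(zip(surf_species, (int(v) for v in ints))))
        counts["CHOL"] = int(round(n_surface * comp["CHOL"] / surf_total))
    else:
        species = [s for s in SHELL_SPECIES if comp[s] > 0]
        pool = int(round(n_surface))
        targets = np.array([n_surface * comp[s] / total_comp for s in species])
        ints = _largest_remainder(targets, pool)
        counts = dict.fromkeys(SHELL_SPECIES, 0)
        counts.update(dict(zip(species, (int(v) for v in ints))))
    return counts


# ---------------------------------------------------------------------------
# packing problem

ConstraintFn = Callable[[np.ndarray], float]


@dataclass
class Molecule:
    """Rigid molecule template: atom coordinates (n_atoms, 3) Angstrom,
    given relative to the barycenter."""

    name: str
    atoms: np.ndarray

    def __post_init__(self) -> None:
        self.atoms = np.asarray(self.atoms, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.atoms)):
            raise InvalidInputError("atom coordinates must be finite")


@dataclass
class PackingProblem:
    """Configuration of rigid molecules with overlap and region penalties.

    ``barycenters`` (n_mol, 3) and ``angles`` (n_mol, 3; extrinsic xyz Euler,
    radians) place each template.  ``constraints`` maps molecule index (or
    None = all molecules) to a list of per-atom region functions g(p) <= 0.
    ``squared_distance_variant`` switches the overlap hinge from the
    typeset d_tol^2 - ||dp|| argument to the conventional d_tol^2 - ||dp||^2.
    """

    molecules: list[Molecule]
    barycenters: np.ndarray
    angles: np.ndarray
    d_tol: float = 2.0
    constraints: dict[int | None, list[ConstraintFn]] = field(
        default_factory=dict)
    squared_distance_variant: bool = False

    def __post_init__(self) -> None:
        if self.d_tol <= 0:
            raise InvalidInputError("d_tol must be > 0")
        n = len(self.molecules)
        self.barycenters = np.asarray(self.barycenters,
                                      dtype=float).reshape(n, 3)
        self.angles = np.asarray(self.angles, dtype=float).reshape(n, 3)

    def placed_atoms(self) -> list[np.ndarray]:
        """World coordinates p_ij = c_i + R(theta_i) a_ij per molecule."""
        out = []
        for mol, c, th in zip(self.molecules, self.barycenters, self.angles):
            rot = Rotation.from_euler("xyz", th).as_matrix()
            out.append(c + mol.atoms @ rot.T)
        return out

    def molecule_constraints(self, i: int) -> list[ConstraintFn]:
        return list(self.constraints.get(None, [])) \
            + list(self.constraints.get(i, []))


def packing_objective(problem: PackingProblem) -> float:
    """Penalty objective f(c, theta) >= 0; zero iff feasible.

    Overlap term: sum over atom pairs of distinct molecules of
    max(0, d_tol^2 - ||dp||)^2 (or the squared-distance variant).
    Constraint term: sum over atoms of max(0, g(p))^2 for every region
    function attached to the molecule.
    """
    placed = problem.placed_atoms()
    d2tol = problem.d_tol ** 2
    total = 0.0
    n = len(placed)
    for i in range(n):
        for k in range(i + 1, n):
            diff = placed[i][:, None, :] - placed[k][None, :, :]
            dist2 = np.einsum("ijk,ijk->ij", diff, diff)
            if problem.squared_distance_variant:
                arg = d2tol - dist2
            else:
                arg = d2tol - np.sqrt(dist2)
            hinge = np.maximum(arg, 0.0)
            total += float(np.sum(hinge * hinge))
    for i in range(n):
        fns = problem.molecule_constraints(i)
        for fn in fns:
            for p in placed[i]:
                g = fn(p)
                if g > 0:
                    total += g * g
    return total


# built-in spherical region constraints -------------------------------------

def inside_sphere(radius: float,
                  center: Sequence[float] = (0.0, 0.0, 0.0)) -> ConstraintFn:
    c = np.asarray(center, dtype=float)

    def g(p: np.ndarray) -> float:
        return float(np.linalg.norm(p - c) - radius)
    return g


def outside_sphere(radius: float,
                   center: Sequence[float] = (0.0, 0.0, 0.0)) -> ConstraintFn:
    c = np.asarray(center, dtype=float)

    def g(p: np.ndarray) -> float:
        return float(radius - np.linalg.norm(p - c))
    return g


def between_radii(r_inner: float, r_outer: float,
                  center: Sequence[float] = (0.0, 0.0, 0.0)) -> ConstraintFn:
    c = np.asarray(center, dtype=float)

    def g(p: np.ndarray) -> float:
        r = float(np.linalg.norm(p - c))
        return max(r_inner - r, r - r_outer)
    return g


def inside_box(half_extent: float) -> ConstraintFn:
    """Axis-aligned cube [-h, h]^3 around the origin."""

    def g(p: np.ndarray) -> float:
        return float(np.max(np.abs(p)) - half_extent)
    return g


@dataclass
class PackingResult:
    problem: PackingProblem
    objective: float
    feasible: bool
    restarts_used: int


def minimize_packing(problem: PackingProblem, seed: int,
                     restarts: int = 10, box_half_extent: float | None = None,
                     tol: float = 1e-6) -> PackingResult:
    """Seeded multi-start local minimisation of the packing objective.

    Each restart samples barycenters uniformly (inside the sampling box,
    inferred from the constraints' scale when not given) and angles
    uniformly over [0, 2 pi), then polishes with a gradient-free local
    search (Powell).  Deterministic for a fixed seed.  Always returns the
    best configuration found; ``feasible`` reports whether f <= tol.
    """
    rng = np.random.default_rng(seed)
    n = len(problem.molecules)
    if box_half_extent is None:
        # scale the sampling box to hold the molecules loosely
        box_half_extent = max(5.0, 2.0 * problem.d_tol * n ** (1.0 / 3.0))

    def unpack(x: np.ndarray) -> PackingProblem:
        c = x[:3 * n].reshape(n, 3)
        th = x[3 * n:].reshape(n, 3)
        return PackingProblem(problem.molecules, c, th, problem.d_tol,
                              problem.constraints,
                              problem.squared_distance_variant)

    def fun(x: np.ndarray) -> float:
        return packing_objective(unpack(x))

    best_x = np.concatenate([problem.barycenters.ravel(),
                             problem.angles.ravel()])
    best_f = fun(best_x)
    used = 0
    for used in range(1, restarts + 1):
        if best_f <= tol:
            break
        c0 = rng.uniform(-box_half_extent, box_half_extent, size=(n, 3))
        th0 = rng.uniform(0.0, 2.0 * math.pi, size=(n, 3))
        x0 = np.concatenate([c0.ravel(), th0.ravel()])
        f0 = fun(x0)
        if f0 > tol:
            res = minimize(fun, x0, method="Powell",
                           options={"maxiter": 100, "maxfev": 20000,
                                    "xtol": 1e-6, "ftol": 1e-10})
            x0, f0 = res.x, float(res.fun)
        if f0 < best_f:
            best_x, best_f = x0, f0
    solved = unpack(np.asarray(best_x))
    return PackingResult(solved, best_f, best_f <= tol, used)


# ---------------------------------------------------------------------------
# coordinate I/O (XYZ and minimal PDB, Angstrom)

def write_xyz(path, problem: PackingProblem, comment: str = "") -> None:
    placed = problem.placed_atoms()
    n_atoms = sum(len(p) for p in placed)
    with open(path, "w") as fh:
        fh.write(f"{n_atoms}\n{comment}\n")
        for mol, coords in zip(problem.molecules, placed):
            for x, y, z in coords:
                fh.write(f"{mol.name[:2]:<2s} {x:12.6f} {y:12.6f} {z:12.6f}\n")


def read_xyz(path) -> list[tuple[str, np.ndarray]]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    n = int(lines[0].split()[0])
    out = []
    for line in lines[2:2 + n]:
        parts = line.split()
        out.append((parts[0], np.array([float(v) for v in parts[1:4]])))
    return out


def write_pdb(path, problem: PackingProblem) -> None:
    placed = problem.placed_atoms()
    serial = 0
    with open(path, "w") as fh:
        for resid, (mol, coords) in enumerate(
                zip(problem.molecules, placed), start=1):
            resname = mol.name[:3].upper().ljust(3)
            for x, y, z in coords:
                serial += 1
                fh.write(
                    f"ATOM  {serial:5d}  C   {resname} A{resid:4d}    "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n")
        fh.write("END\n")
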