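"""Synthetic fixtures with known ground truth for every analysis stage.

Generators cover (a) ion coordination sites with prescribed ion–oxygen
distances, (b) trajectories with prescribed per-atom Gaussian fluctuation
and two-state (bound/unbound) salt-bridge occupancy, (c) ideal-gas frames
for RDF normalisation oracles, and (d) Hill-type activity curves with
additive Gaussian noise. Everything is bit-reproducible given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kinetics import ActivityCurve
from .structio import AtomRecord, Structure, Trajectory

__all__ = [
    "SiteSpec",
    "TwoStateSpec",
    "TrajSpec",
    "make_coordination_site",
    "make_trajectory",
    "make_ideal_gas",
    "make_activity_curve",
    "fibonacci_directions",
]

MIN_LIGAND_SEPARATION = 1.5  # Å; closer ligand pairs are a geometry error


@dataclass(frozen=True)
class SiteSpec:
    """An ion at the origin plus oxygens at prescribed distances.

    ``ligands`` maps labels (e.g. ``"V341 O"``) to ion–oxygen distances in
    Å. Directions are assigned by a deterministic spherical Fibonacci rule,
    which keeps ligands well separated; the geometry is irrelevant to bond
    valence, which depends only on the distances.
    """

    ion_element: str = "K"
    ligands: tuple[tuple[str, float], ...] = ()
    seed: int = 0


@dataclass(frozen=True)
class TwoStateSpec:
    """Bernoulli bound/unbound distances for one mobile atom.

    The atom at ``atom_index`` is placed at ``d_bound`` Å (probability
    ``p_bound``) or ``d_unbound`` Å from the anchor atom, independently per
    frame, along the anchor→atom reference direction.
    """

    atom_index: int
    anchor_index: int
    d_bound: float
    d_unbound: float
    p_bound: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_bound <= 1.0):
            raise ValueError("p_bound must lie in [0, 1]")


@dataclass(frozen=True)
class TrajSpec:
    """Stationary Gaussian fluctuation about a reference structure.

    ``sigma`` is either one isotropic per-coordinate standard deviation in
    Å for all atoms or a per-atom array; ``two_state`` optionally overrides
    one atom with bound/unbound hopping.
    """

    reference: Structure
    sigma: float | np.ndarray = 0.0
    n_frames: int = 100
    seed: int = 0
    two_state: TwoStateSpec | None = None


def fibonacci_directions(n: int) -> np.ndarray:
    """n approximately evenly spread unit vectors (spherical Fibonacci)."""
    if n < 1:
        raise ValueError("need n >= 1")
    i = np.arange(n, dtype=float)
    golden = (1.0 + math.sqrt(5.0)) / 2.0
    z = 1.0 - 2.0 * (i + 0.5) / n
    theta = 2.0 * math.pi * i / golden
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def _ligand_atom(label: str, serial: int, pos: np.ndarray) -> AtomRecord:
    """Build an oxygen AtomRecord from a ``"V341 O"``-style label."""
    parts = label.split()
    name = parts[-1] if parts else "O"
    resname, resid = "LIG", serial
    if parts and len(parts) >= 2:
        head = parts[0]
        alpha = head.rstrip("0123456789")
        digits = head[len(alpha):]
        if alpha and digits:
            resname, resid = alpha.upper(), int(digits)
    return AtomRecord(
        serial=serial,
        name=name,
        element="O",
        resname=resname,
        resid=resid,
        chain="A",
        x=float(pos[0]),
        y=float(pos[1]),
        z=float(pos[2]),
    )


def make_coordination_site(spec: SiteSpec) -> Structure:
    """Ion at the origin; one oxygen per ligand at its exact distance.

    Raises a geometry error if any two ligands end up closer than 1.5 Å.
    Deterministic given the spec (the seed only rotates nothing here; the
    Fibonacci directions are themselves deterministic).
    """
    if not spec.ligands:
        raise ValueError("site spec needs at least one ligand")
    dirs = fibonacci_directions(len(spec.ligands))
    atoms = [
        AtomRecord(
            serial=1,
            name=spec.ion_element.upper(),
            element=spec.ion_element,
            resname=spec.ion_element.upper(),
            resid=1,
            chain="I",
            x=0.0,
            y=0.0,
            z=0.0,
        )
    ]
    positions = []
    for k, (label, dist) in enumerate(spec.ligands):
        if dist <= 0:
            raise ValueError(f"ligand distance must be positive, got {dist}")
        pos = dirs[k] * dist
        positions.append(pos)
        atoms.append(_ligand_atom(label, serial=k + 2, pos=pos))
    pos_arr = np.array(positions)
    for a in range(len(pos_arr)):
        for b in range(a + 1, len(pos_arr)):
            if np.linalg.norm(pos_arr[a] - pos_arr[b]) < MIN_LIGAND_SEPARATION:
                raise ValueError(
                    f"ligand clash: atoms {a} and {b} closer than "
                    f"{MIN_LIGAND_SEPARATION} Å"
                )
    return Structure(atoms, source="synthetic coordination site")


def make_trajectory(spec: TrajSpec) -> Trajectory:
    """Frames = reference + isotropic Gaussian displacements per atom.

    With a two-state spec, that atom is instead placed at d_bound/d_unbound
    from its (reference) anchor position along the reference direction, by
    an independent Bernoulli(p_bound) draw per frame; Gaussian jitter is
    then added on top of the chosen centre.
    """
    rng = np.random.default_rng(spec.seed)
    ref = spec.reference.coords
    n_atoms = ref.shape[0]
    sigma = np.asarray(spec.sigma, dtype=float)
    if sigma.ndim == 0:
        sigma = np.full(n_atoms, float(sigma))
    if sigma.shape != (n_atoms,):
        raise ValueError(f"sigma must be scalar or shape ({n_atoms},)")
    if np.any(sigma < 0):
        raise ValueError("sigma must be non-negative")

    frames = ref[None, :, :] + rng.standard_normal(
        (spec.n_frames, n_atoms, 3)
    ) * sigma[None, :, None]

    if spec.two_state is not None:
        ts = spec.two_state
        direction = ref[ts.atom_index] - ref[ts.anchor_index]
        nrm = np.linalg.norm(direction)
        if nrm < 1e-12:
            raise ValueError("two-state atom and anchor coincide in the reference")
        direction = direction / nrm
        bound = rng.random(spec.n_frames) < ts.p_bound
        d = np.where(bound, ts.d_bound, ts.d_unbound)
        centers = ref[ts.anchor_index][None, :] + d[:, None] * direction[None, :]
        jitter = rng.standard_normal((spec.n_frames, 3)) * sigma[ts.atom_index]
        frames[:, ts.atom_index, :] = centers + jitter

    return Trajectory(spec.reference, frames, source="synthetic trajectory")


def make_ideal_gas(
    n_particles: int, box: float | tuple[float, float, float], n_frames: int, seed: int = 0
) -> Trajectory:
    """Uniform i.i.d. particle positions per frame, with box metadata.

    The reference oracle for shell-normalised RDFs: a homogeneous system
    has g(r) = 1 for r well below half the box length.
    """
    if n_particles < 2:
        raise ValueError("need at least 2 particles")
    if isinstance(box, (int, float)):
        box = (float(box),) * 3
    rng = np.random.default_rng(seed)
    frames = rng.random((n_frames, n_particles, 3)) * np.asarray(box)[None, None, :]
    atoms = [
        AtomRecord(
            serial=i + 1,
            name="AR",
            element="Ar",
            resname="GAS",
            resid=i + 1,
            chain="A",
            x=float(frames[0, i, 0]),
            y=float(frames[0, i, 1]),
            z=float(frames[0, i, 2]),
        )
        for i in range(n_particles)
    ]
    return Trajectory(
        Structure(atoms, source="synthetic ideal gas"),
        frames,
        box=box,
        source="synthetic ideal gas",
    )


def make_activity_curve(
    n: float,
    K_half: float,
    v0: float,
    v_max: float,
    mode: str,
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> ActivityCurve:
    """Exact Hill values plus additive Gaussian noise (seeded)."""
    if mode not in ("activation", "inhibition"):
        raise ValueError(f"unknown mode {mode!r}")
    c = np.asarray(concentrations, dtype=float)
    cn = np.power(np.maximum(c, 0.0), n)
    Kn = K_half**n
    frac = Kn / (Kn + cn) if mode == "inhibition" else cn / (Kn + cn)
    v = v0 + (v_max - v0) * frac
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return ActivityCurve(c, v)
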