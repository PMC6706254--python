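"""Distance-based interaction analyses on structures and trajectories.

Contacts (H-bond / electrostatic distance criterion), salt-bridge distance
series with bound-state occupancy, radial distribution functions between a
single atom and a group centre of mass, and RMSD series after rigid-body
superposition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np

from .structio import Selection, Structure, Trajectory, select, select_one

__all__ = [
    "ContactList",
    "RDFResult",
    "RMSDSeries",
    "SaltBridgeSeries",
    "contacts",
    "saltbridge_series",
    "rdf",
    "rdf_pair_distances",
    "superpose",
    "rmsd_series",
]

#: Default H-bond / electrostatic contact criterion in Å.
CONTACT_THRESHOLD = 3.5
#: Default salt-bridge bound-state criterion (N to carboxylate-O COM) in Å.
SALTBRIDGE_CUTOFF = 4.0


@dataclass
class ContactList:
    pairs: list[tuple[str, str, float]]  # (label_a, label_b, distance Å)
    threshold: float

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SaltBridgeSeries:
    distances: np.ndarray  # per-frame N–COM distance, Å
    bound_cutoff: float
    occupancy: float  # fraction of frames with distance <= cutoff


@dataclass
class RDFResult:
    bin_edges: np.ndarray  # Å
    g: np.ndarray
    mode: str  # "probability_density" | "shell_normalized"
    n_frames: int
    unit: str = "angstrom"

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def in_nm(self) -> "RDFResult":
        """Same result with the distance axis in nm (densities rescaled)."""
        if self.unit == "nm":
            return self
        g = self.g * 10.0 if self.mode == "probability_density" else self.g
        return RDFResult(self.bin_edges / 10.0, g, self.mode, self.n_frames, "nm")


@dataclass
class RMSDSeries:
    per_frame: np.ndarray  # Å
    mean: float
    sd: float
    reference: str
    n_fit_atoms: int


def _atom_masses(structure: Structure, indices: list[int]) -> np.ndarray:
    return np.array(
        [gemmi.Element(structure.atoms[i].element or "X").weight for i in indices]
    )


def contacts(
    structure: Structure,
    sel_a: Selection | str,
    sel_b: Selection | str,
    threshold: float = CONTACT_THRESHOLD,
) -> ContactList:
    """All cross pairs between two selections within ``threshold`` Å.

    Each pair is reported once; self-pairs (the same atom in both
    selections) are skipped. Heavy-atom, distance-only criterion.
    """
    ia = select(structure, sel_a)
    ib = select(structure, sel_b)
    coords = structure.coords
    pairs: list[tuple[str, str, float]] = []
    seen: set[tuple[int, int]] = set()
    for i in ia:
        for j in ib:
            if i == j:
                continue
            key = (min(i, j), max(i, j))
            if key in seen:
                continue
            d = float(np.linalg.norm(coords[i] - coords[j]))
            if d <= threshold:
                seen.add(key)
                pairs.append(
                    (structure.atoms[i].label, structure.atoms[j].label, d)
                )
    pairs.sort(key=lambda t: t[2])
    return ContactList(pairs, threshold)


def _group_com_positions(traj: Trajectory, indices: list[int]) -> np.ndarray:
    """(n_frames, 3) centre of mass of an atom group, per frame."""
    masses = _atom_masses(traj.topology, indices)
    pos = traj.frames[:, indices, :]
    return (pos * masses[None, :, None]).sum(axis=1) / masses.sum()


def saltbridge_series(
    trajectory: Trajectory,
    basic_sel: Selection | str,
    acidic_sel: Selection | str,
    bound_cutoff: float = SALTBRIDGE_CUTOFF,
) -> SaltBridgeSeries:
    """Per-frame salt-bridge distance and bound-state occupancy.

    The distance runs from a single basic nitrogen (e.g. Lys NZ) to the
    centre of mass of the two carboxylate oxygens of an acidic side chain;
    occupancy is the fraction of frames at or below ``bound_cutoff``.
    """
    i_n = select_one(trajectory.topology, basic_sel)
    acidic = select(trajectory.topology, acidic_sel)
    if len(acidic) != 2:
        raise ValueError(
            f"acidic selection must resolve to the 2 carboxylate oxygens, got {len(acidic)}"
        )
    com = _group_com_positions(trajectory, acidic)
    n_pos = trajectory.frames[:, i_n, :]
    dists = np.linalg.norm(n_pos - com, axis=1)
    occupancy = float(np.mean(dists <= bound_cutoff))
    return SaltBridgeSeries(dists, bound_cutoff, occupancy)


def _minimum_image(vec: np.ndarray, box: tuple[float, float, float]) -> np.ndarray:
    b = np.asarray(box, dtype=float)
    return vec - b * np.round(vec / b)


def rdf(
    trajectory: Trajectory,
    sel_a: Selection | str,
    sel_b_com: Selection | str,
    bin_width: float = 0.1,
    r_max: float = 10.0,
    mode: str = "probability_density",
    density: float | None = None,
) -> RDFResult:
    """Distance histogram between one atom and a group centre of mass.

    ``probability_density`` (default) normalises the histogram to unit
    integral over [0, r_max] — the natural normalisation for an
    intramolecular pair. ``shell_normalized`` divides bin counts by the
    ideal-gas expectation 4πr²Δr·ρ per frame (ρ from the box volume when the
    trajectory carries a box, else ``density``), so g(r) → 1 for a
    homogeneous system. Minimum-image distances are used when a box is
    present. Bins are half-open [lo, hi), last bin closed.
    """
    if not (r_max > bin_width > 0):
        raise ValueError("need r_max > bin_width > 0")
    if mode not in ("probability_density", "shell_normalized"):
        raise ValueError(f"unknown RDF mode {mode!r}")
    i_a = select_one(trajectory.topology, sel_a)
    group = select(trajectory.topology, sel_b_com)
    if not group:
        raise ValueError("empty group selection")
    if len(group) == 1:
        com = trajectory.frames[:, group[0], :]
    else:
        com = _group_com_positions(trajectory, group)
    vec = com - trajectory.frames[:, i_a, :]
    if trajectory.box is not None:
        vec = _minimum_image(vec, trajectory.box)
    dists = np.linalg.norm(vec, axis=1)

    n_bins = int(round(r_max / bin_width))
    edges = np.linspace(0.0, n_bins * bin_width, n_bins + 1)
    counts, _ = np.histogram(dists, bins=edges)
    n_frames = trajectory.frame_count

    if mode == "probability_density":
        total = counts.sum()
        if total == 0:
            g = np.zeros(n_bins)
        else:
            g = counts / (total * bin_width)
    else:
        if trajectory.box is not None:
            volume = float(np.prod(trajectory.box))
            rho = len(group) / volume if len(group) > 1 else 1.0 / volume
        elif density is not None:
            rho = density
        else:
            raise ValueError("shell_normalized mode needs a box or an explicit density")
        centers = 0.5 * (edges[:-1] + edges[1:])
        shell = 4.0 * math.pi * centers**2 * bin_width
        g = counts / (n_frames * shell * rho)
    return RDFResult(edges, np.asarray(g, dtype=float), mode, n_frames)


def rdf_pair_distances(
    trajectory: Trajectory,
    sel_a: Selection | str,
    sel_b: Selection | str,
) -> np.ndarray:
    """All per-frame cross distances between two selections (flattened).

    Helper for shell-normalised RDFs over many equivalent pairs (e.g. the
    ideal-gas oracle), using minimum-image distances when a box is present.
    """
    ia = select(trajectory.topology, sel_a)
    ib = select(trajectory.topology, sel_b)
    out = []
    for f in range(trajectory.frame_count):
        pa = trajectory.frames[f, ia, :]
        pb = trajectory.frames[f, ib, :]
        vec = pb[None, :, :] - pa[:, None, :]
        if trajectory.box is not None:
            vec = _minimum_image(vec, trajectory.box)
        d = np.linalg.norm(vec, axis=2)
        mask = ~np.eye(len(ia), len(ib), dtype=bool) if ia == ib else np.ones_like(d, bool)
        out.append(d[mask])
    return np.concatenate(out)


def superpose(
    mobile: np.ndarray, reference: np.ndarray, weights: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Least-squares rigid-body superposition (Kabsch, no reflection).

    Returns ``(transformed, rotation, translation, rmsd)`` such that
    ``transformed = mobile @ rotation.T + translation`` minimises the RMSD
    to ``reference`` over proper rotations (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 atoms for superposition")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    mu_m = (w[:, None] * mobile).sum(axis=0)
    mu_r = (w[:, None] * reference).sum(axis=0)
    A = mobile - mu_m
    B = reference - mu_r
    H = (w[:, None] * A).T @ B
    U, s, Vt = np.linalg.svd(H)
    # collinearity check: fewer than 2 significant singular values
    if s[1] < 1e-10 * max(s[0], 1e-30):
        raise ValueError("degenerate (collinear) fit atoms")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_r - R @ mu_m
    transformed = mobile @ R.T + t
    rmsd = float(np.sqrt((w * ((transformed - reference) ** 2).sum(axis=1)).sum()))
    return transformed, R, t, rmsd


def rmsd_series(
    trajectory: Trajectory,
    analysis_sel: Selection | str,
    reference: Structure,
    fit_sel: Selection | str,
) -> RMSDSeries:
    """Per-frame RMSD of ``analysis_sel`` after superposing each frame on
    ``reference`` over ``fit_sel``.

    Selections must resolve to the same atoms (by index) in the trajectory
    topology and the reference structure. The fit is unweighted.
    """
    fit_t = select(trajectory.topology, fit_sel)
    fit_r = select(reference, fit_sel)
    ana_t = select(trajectory.topology, analysis_sel)
    ana_r = select(reference, analysis_sel)
    if len(fit_t) != len(fit_r) or len(ana_t) != len(ana_r):
        raise ValueError("selections resolve to different atom counts in trajectory and reference")
    if not ana_t:
        raise ValueError("empty analysis selection")
    ref_coords = reference.coords
    per_frame = np.empty(trajectory.frame_count)
    for f in range(trajectory.frame_count):
        frame = trajectory.frames[f]
        _, R, t, _ = superpose(frame[fit_t], ref_coords[fit_r])
        moved = frame[ana_t] @ R.T + t
        diff = moved - ref_coords[ana_r]
        per_frame[f] = math.sqrt(float((diff**2).sum() / len(ana_t)))
    return RMSDSeries(
        per_frame,
        float(per_frame.mean()),
        float(per_frame.std(ddof=1)) if len(per_frame) > 1 else 0.0,
        reference.source or "reference",
        len(fit_t),
    )
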