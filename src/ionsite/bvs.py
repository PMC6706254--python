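"""Bond-valence analysis of cation coordination.

The bond-valence sum (BVS) is an empirical measure of how well an ion is
coordinated: each ligand atom at distance r contributes a partial valence
that decays with distance, and the sum over the coordination shell should
match the ion's formal charge (1.00 for K⁺) when coordination is ideal.

Two standard functional forms are supported:

* power:        v(r) = (r / r0) ** (-N)
* exponential:  v(r) = exp((R0 - r) / b)

Both equal 1 at r = r0 and decrease monotonically. The default K⁺–O
parameterisation is the classic alkali–oxygen power law (r0 = 2.276 Å,
N = 9.1); parameters for other cations (e.g. Rb⁺–O) can be calibrated from
(distance, valence) pairs with :func:`calibrate_bv`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structio import Selection, Structure, Trajectory, select, select_one

__all__ = [
    "BVPair",
    "K_O_POWER",
    "CoordinationShell",
    "ValenceReport",
    "TrajectoryValenceResult",
    "pair_valence",
    "coordination_shell",
    "valence_report",
    "valence_from_distances",
    "calibrate_bv",
    "trajectory_valence",
]

WATER_RESNAMES = {"HOH", "WAT", "H2O", "SOL", "TIP3"}


@dataclass(frozen=True)
class BVPair:
    """Cation–ligand bond-valence parameters.

    ``r0`` is the unit-valence reference distance (power form) or R0
    (exponential form); ``exponent`` is the dimensionless power N or, for the
    exponential form, the softness parameter b in Å. ``cutoff`` is the shell
    inclusion radius; contacts beyond it contribute zero (closed interval at
    the cutoff).
    """

    cation: str = "K+"
    ligand_element: str = "O"
    form: str = "power"
    r0: float = 2.276
    exponent: float = 9.1
    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if self.form not in ("power", "exponential"):
            raise ValueError(f"unknown bond-valence form {self.form!r}")
        if self.r0 <= 0:
            raise ValueError("r0 must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent (N or b) must be positive")
        if self.cutoff <= self.r0:
            raise ValueError("cutoff must exceed r0")


#: Classic alkali–oxygen power-law parameters for K⁺, with the 4 Å shell rule.
K_O_POWER = BVPair()


@dataclass
class CoordinationShell:
    """Ligand atoms within the cutoff of one ion, sorted by distance."""

    ion_index: int
    ion_label: str
    ligands: list[tuple[int, str, float]]  # (atom index, label, distance Å)
    cutoff: float
    ligand_element: str = "O"

    def __len__(self) -> int:
        return len(self.ligands)

    @property
    def distances(self) -> np.ndarray:
        return np.array([d for *_, d in self.ligands], dtype=float)

    @property
    def labels(self) -> list[str]:
        return [lbl for _, lbl, _ in self.ligands]


@dataclass
class ValenceReport:
    """Per-ligand partial valences and their total for one structure."""

    rows: list[tuple[str, float, float]]  # (label, distance Å, valence)
    total: float
    params: BVPair

    def as_table(self) -> str:
        lines = ["ligand\tdistance_A\tvalence"]
        for label, d, v in self.rows:
            lines.append(f"{label}\t{d:.2f}\t{v:.2f}")
        lines.append(f"Total valence\t\t{self.total:.2f}")
        return "\n".join(lines)


@dataclass
class TrajectoryValenceResult:
    """Frame-averaged valences: per-ligand and total mean ± SEM."""

    per_ligand: dict[str, tuple[float, float]]  # label -> (mean, SEM)
    total_mean: float
    total_sem: float
    frames_used: int
    params: BVPair


def pair_valence(r: float, params: BVPair) -> float:
    """Partial valence of a single cation–ligand contact at distance ``r`` Å.

    Returns 0 beyond ``params.cutoff``; the cutoff itself is included.
    """
    if r <= 0:
        raise ValueError(f"distance must be positive, got {r}")
    if r > params.cutoff:
        return 0.0
    if params.form == "power":
        return float((r / params.r0) ** (-params.exponent))
    return float(math.exp((params.r0 - r) / params.exponent))


def coordination_shell(
    structure: Structure,
    ion: Selection | str,
    ligand_element: str = "O",
    cutoff: float = 4.0,
    include_waters: bool = False,
) -> CoordinationShell:
    """All ``ligand_element`` atoms within ``cutoff`` Å of the ion.

    Water oxygens are excluded by default (set ``include_waters`` to keep
    them). Ties at exactly the cutoff are included; the list is sorted
    ascending by distance.
    """
    ion_idx = select_one(structure, ion)
    ion_atom = structure.atoms[ion_idx]
    ion_pos = ion_atom.position
    ligands: list[tuple[int, str, float]] = []
    for i in select(structure, Selection(element=ligand_element)):
        if i == ion_idx:
            continue
        a = structure.atoms[i]
        if not include_waters and a.resname.upper() in WATER_RESNAMES:
            continue
        d = float(np.linalg.norm(a.position - ion_pos))
        if d <= cutoff:
            ligands.append((i, a.label, d))
    ligands.sort(key=lambda t: t[2])
    return CoordinationShell(ion_idx, ion_atom.label, ligands, cutoff, ligand_element)


def valence_report(shell: CoordinationShell, params: BVPair) -> ValenceReport:
    """Per-ligand valences and the bond-valence sum for a coordination shell.

    Ligands beyond ``params.cutoff`` (when it is tighter than the shell's)
    are reported with zero valence and excluded from the total.
    """
    if len(shell) == 0:
        raise ValueError("empty coordination shell")
    if shell.ligand_element.upper() != params.ligand_element.upper():
        raise ValueError(
            f"shell ligand element {shell.ligand_element!r} does not match "
            f"parameters for {params.ligand_element!r}"
        )
    rows = [(label, d, pair_valence(d, params)) for _, label, d in shell.ligands]
    total = float(sum(v for *_, v in rows))
    return ValenceReport(rows, total, params)


def valence_from_distances(
    distances: "np.ndarray | list[float]", params: BVPair
) -> ValenceReport:
    """Valence report straight from a list of ion–ligand distances in Å.

    Convenience path for tabulated coordination geometry where no structure
    file exists; labels are positional.
    """
    rows = [
        (f"ligand{i + 1}", float(d), pair_valence(float(d), params))
        for i, d in enumerate(distances)
    ]
    total = float(sum(v for *_, v in rows))
    return ValenceReport(rows, total, params)


def calibrate_bv(
    pairs: list[tuple[float, float]],
    form: str = "power",
    cation: str = "K+",
    ligand_element: str = "O",
) -> tuple[BVPair, float]:
    """Least-squares bond-valence parameters from (distance Å, valence) pairs.

    The fit is linear in log space: for the power form,
    ln v = N·ln r0 − N·ln r; for the exponential form,
    ln v = R0/b − r/b. Returns the fitted :class:`BVPair` and the RMS
    log-residual of the fit.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 (distance, valence) pairs")
    r = np.asarray([p[0] for p in pairs], dtype=float)
    v = np.asarray([p[1] for p in pairs], dtype=float)
    if np.any(r <= 0):
        raise ValueError("distances must be positive")
    if np.any((v <= 0) | (v > 1)):
        raise ValueError("valences must lie in (0, 1]")
    if form == "power":
        x = np.log(r)
    elif form == "exponential":
        x = r
    else:
        raise ValueError(f"unknown bond-valence form {form!r}")
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate fit: distances are not distinct")
    slope, intercept = np.polyfit(x, np.log(v), 1)
    if slope >= 0:
        raise ValueError("degenerate fit: valence does not decrease with distance")
    if form == "power":
        n = -slope
        r0 = float(np.exp(intercept / n))
        params = BVPair(cation=cation, ligand_element=ligand_element,
                        form="power", r0=r0, exponent=float(n))
    else:
        b = -1.0 / slope
        r0 = float(intercept * b)
        params = BVPair(cation=cation, ligand_element=ligand_element,
                        form="exponential", r0=r0, exponent=float(b))
    resid = np.log(v) - (slope * x + intercept)
    rms = float(np.sqrt(np.mean(resid**2)))
    return params, rms


def trajectory_valence(
    trajectory: Trajectory,
    ion: Selection | str,
    params: BVPair,
    ligand_element: str = "O",
    cutoff: float = 4.0,
    frame_range: tuple[int, int] | None = None,
    include_waters: bool = False,
) -> TrajectoryValenceResult:
    """Frame-averaged bond valences around an ion.

    For every frame the coordination shell is rebuilt under the inclusion
    cutoff, so a ligand drifting outside the shell contributes zero valence
    in that frame. Per-ligand means and SEMs are taken over the analysed
    frames (``frame_range`` is a half-open [start, stop) window; default all
    frames); frames are treated as independent samples.
    """
    ion_idx = select_one(trajectory.topology, ion)
    start, stop = frame_range if frame_range is not None else (0, trajectory.frame_count)
    if not (0 <= start < stop <= trajectory.frame_count):
        raise ValueError(f"empty or out-of-range frame window [{start}, {stop})")
    n = stop - start

    candidates = [
        i
        for i in select(trajectory.topology, Selection(element=ligand_element))
        if i != ion_idx
        and (include_waters or trajectory.topology.atoms[i].resname.upper() not in WATER_RESNAMES)
    ]
    cand_labels = [trajectory.topology.atoms[i].label for i in candidates]

    frames = trajectory.frames[start:stop]
    ion_pos = frames[:, ion_idx, :]  # (n, 3)
    lig_pos = frames[:, candidates, :]  # (n, m, 3)
    dists = np.linalg.norm(lig_pos - ion_pos[:, None, :], axis=2)  # (n, m)

    inside = dists <= cutoff
    if params.form == "power":
        vals = (dists / params.r0) ** (-params.exponent)
    else:
        vals = np.exp((params.r0 - dists) / params.exponent)
    vals = np.where(inside & (dists <= params.cutoff), vals, 0.0)

    ever_inside = inside.any(axis=0)
    per_ligand: dict[str, tuple[float, float]] = {}
    for j, (label, keep) in enumerate(zip(cand_labels, ever_inside)):
        if not keep:
            continue
        col = vals[:, j]
        mean = float(col.mean())
        sem = float(col.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
        per_ligand[label] = (mean, sem)

    totals = vals.sum(axis=1)
    total_mean = float(totals.mean())
    total_sem = float(totals.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return TrajectoryValenceResult(per_ligand, total_mean, total_sem, n, params)
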