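"""Probe-excluded pairwise contact areas on ligand–receptor complexes.

Each atom is a van der Waals sphere expanded by a water-probe radius
(1.4 Å by default). For every ligand atom a deterministic spherical
Fibonacci lattice samples its expanded sphere; a sample point buried inside
one or more receptor expanded spheres is attributed to the receptor atom in
which it is most deeply buried. The attributed fraction of the ligand
sphere's area is the pairwise contact area: it is exactly zero whenever a
water molecule could be interposed between the two atoms, and it grows as
the pair packs more tightly. Per-residue aggregation over poses and ligands
(with the heme prosthetic group split into named subsites) yields the
interface fingerprint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "VDW_RADII",
    "DEFAULT_PROBE_RADIUS",
    "DEFAULT_N_POINTS",
    "AtomSphere",
    "SubsiteScheme",
    "default_heme_scheme",
    "ContactMap",
    "ContactProfile",
    "fibonacci_sphere",
    "load_complex",
    "assign_subsites",
    "contact_areas",
    "cap_contact_area",
    "aggregate_contacts",
    "export_contact_map",
]

#: Bondi-style van der Waals radii (Å). Iron is not in Bondi's table and is
#: given a common metallic value; elements outside the table fall back to
#: 1.70 Å with a warning.
VDW_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
    "ZN": 1.39,
    "FE": 2.00,
    "MG": 1.73,
    "NA": 2.27,
    "K": 2.75,
    "CA": 2.31,
}

DEFAULT_VDW_RADIUS = 1.70
DEFAULT_PROBE_RADIUS = 1.4
DEFAULT_N_POINTS = 960

LIGAND = "LIGAND"
RECEPTOR = "RECEPTOR"

_WATER_RESNAMES = {"HOH", "WAT", "DOD"}


@dataclass(frozen=True)
class AtomSphere:
    """One atom as a van der Waals sphere with residue/subsite bookkeeping.

    ``residue_key`` is ``(chain, residue name, residue number)`` for ordinary
    residues, or a plain subsite label string once a cofactor has been
    subdivided.
    """

    serial: int
    element: str
    name: str
    coords: tuple[float, float, float]
    vdw_radius: float
    owner: str
    residue_key: tuple[str, str, int] | str

    def __post_init__(self) -> None:
        if not (self.vdw_radius > 0):
            raise ValidationError(
                f"atom {self.serial}: vdw_radius must be positive, got {self.vdw_radius}"
            )
        if not all(math.isfinite(c) for c in self.coords):
            raise ValidationError(f"atom {self.serial}: non-finite coordinates")
        if self.owner not in (LIGAND, RECEPTOR):
            raise ValidationError(f"atom {self.serial}: unknown owner {self.owner!r}")

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.coords, dtype=float)

    def residue_label(self) -> str:
        if isinstance(self.residue_key, str):
            return self.residue_key
        chain, resname, resnum = self.residue_key
        return f"{resname}{resnum}" if not chain else f"{chain}:{resname}{resnum}"


def vdw_radius_for(element: str) -> float:
    key = element.strip().upper()
    if key in VDW_RADII:
        return VDW_RADII[key]
    warnings.warn(
        f"no van der Waals radius for element {element!r}; using "
        f"{DEFAULT_VDW_RADIUS} Å",
        stacklevel=2,
    )
    return DEFAULT_VDW_RADIUS


# ---------------------------------------------------------------------------
# PDB loading


def load_complex(
    path: str | Path,
    ligand_selector: str,
    keep_hydrogens: bool = False,
    keep_waters: bool = False,
) -> tuple[list[AtomSphere], list[AtomSphere]]:
    """Split a PDB complex into receptor and ligand sphere lists.

    ``ligand_selector`` matches either a residue name or a chain name. All
    other ATOM and HETATM records — including cofactors such as heme, zinc
    and pterins — belong to the receptor. Hydrogens (and, by default,
    waters) are dropped; only the first alternate location of each atom is
    kept. Radii come from the Bondi-style element table.
    """
    import gemmi

    try:
        structure = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    if len(structure) == 0:
        raise ParseError(f"{path}: no coordinate model found")

    selector = ligand_selector.strip()
    receptor: list[AtomSphere] = []
    ligand: list[AtomSphere] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            if not keep_waters and resname in _WATER_RESNAMES:
                continue
            is_ligand = resname == selector or chain.name.strip() == selector
            seen_names: set[str] = set()
            for atom in residue:
                if atom.name in seen_names:  # keep first altloc only
                    continue
                seen_names.add(atom.name)
                element = atom.element.name.upper()
                if not keep_hydrogens and element in ("H", "D"):
                    continue
                sphere = AtomSphere(
                    serial=int(atom.serial),
                    element=element,
                    name=atom.name,
                    coords=(atom.pos.x, atom.pos.y, atom.pos.z),
                    vdw_radius=vdw_radius_for(element),
                    owner=LIGAND if is_ligand else RECEPTOR,
                    residue_key=(chain.name.strip(), resname, residue.seqid.num),
                )
                (ligand if is_ligand else receptor).append(sphere)
    if not ligand:
        raise ValidationError(
            f"{path}: ligand selector {ligand_selector!r} matched no residue or chain"
        )
    return receptor, ligand


# ---------------------------------------------------------------------------
# subsite schemes


@dataclass
class SubsiteScheme:
    """Maps (residue name, atom name) pairs to named subsite labels."""

    mapping: dict[tuple[str, str], str]

    @property
    def residues(self) -> set[str]:
        return {resname for resname, _ in self.mapping}

    def label_for(self, resname: str, atom_name: str) -> str | None:
        return self.mapping.get((resname, atom_name))

    def to_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            [
                {"resname": resname, "atom_name": atom, "subsite": label}
                for (resname, atom), label in sorted(self.mapping.items())
            ]
        )
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "SubsiteScheme":
        # keep_default_na: "ND" and "NA" are legitimate atom names (heme
        # pyrrole nitrogens), not missing values
        frame = pd.read_csv(
            path, sep=None, engine="python", dtype=str, keep_default_na=False
        )
        missing = {"resname", "atom_name", "subsite"} - set(frame.columns)
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
        return cls(
            mapping={
                (str(r.resname).strip(), str(r.atom_name).strip()): str(r.subsite).strip()
                for r in frame.itertuples()
            }
        )


def default_heme_scheme() -> SubsiteScheme:
    """The heme (HEM, PDB v3 atom names) subsite partition.

    HFN: the iron and the four pyrrole nitrogens at the core. HCC: the sp2
    carbons of the porphyrin ring system, including methine bridges and the
    vinyl/methyl ring substituents. HCR: the sp3 propionate-chain carbons
    that carry the carboxylic groups. HCO: the carboxylate oxygens at the
    propionate ends.
    """
    groups = {
        "HFN": ["FE", "NA", "NB", "NC", "ND"],
        "HCC": [
            "C1A", "C2A", "C3A", "C4A",
            "C1B", "C2B", "C3B", "C4B",
            "C1C", "C2C", "C3C", "C4C",
            "C1D", "C2D", "C3D", "C4D",
            "CHA", "CHB", "CHC", "CHD",
            "CMA", "CMB", "CMC", "CMD",
            "CAB", "CBB", "CAC", "CBC",
        ],
        "HCR": ["CAA", "CBA", "CGA", "CAD", "CBD", "CGD"],
        "HCO": ["O1A", "O2A", "O1D", "O2D"],
    }
    return SubsiteScheme(
        mapping={
            ("HEM", atom): label for label, atoms in groups.items() for atom in atoms
        }
    )


def assign_subsites(
    receptor: Sequence[AtomSphere], scheme: SubsiteScheme
) -> list[AtomSphere]:
    """Relabel atoms of scheme-covered residues with their subsite label.

    Atoms of residues the scheme does not cover pass through unchanged. An
    atom of a covered residue whose name is missing from the scheme is an
    error (the partition must be exhaustive).
    """
    out: list[AtomSphere] = []
    unmapped: list[str] = []
    for atom in receptor:
        resname = (
            atom.residue_key[1] if isinstance(atom.residue_key, tuple) else None
        )
        if resname in scheme.residues:
            label = scheme.label_for(resname, atom.name)
            if label is None:
                unmapped.append(f"{resname}:{atom.name}")
                continue
            out.append(replace(atom, residue_key=label))
        else:
            out.append(atom)
    if unmapped:
        raise ValidationError(
            f"subsite scheme does not cover atom names: {sorted(set(unmapped))}"
        )
    return out


# ---------------------------------------------------------------------------
# contact areas


def fibonacci_sphere(n_points: int) -> np.ndarray:
    """Deterministic spherical Fibonacci lattice of unit vectors, shape (n, 3)."""
    if n_points < 1:
        raise ValidationError("n_points must be positive")
    k = np.arange(n_points, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n_points
    golden_angle = math.pi * (3.0 - math.sqrt(5.0))
    phi = k * golden_angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


@dataclass
class ContactMap:
    """Sparse pairwise contact areas for one posed ligand against a receptor.

    ``areas`` maps (ligand serial, receptor serial) to the contact area in
    Å²; pairs with zero area are absent.
    """

    areas: dict[tuple[int, int], float]
    ligand: list[AtomSphere]
    receptor: list[AtomSphere]
    probe_radius: float
    n_points: int

    def area_for_ligand_atom(self, serial: int) -> float:
        return sum(a for (i, _), a in self.areas.items() if i == serial)


def contact_areas(
    ligand: Sequence[AtomSphere],
    receptor: Sequence[AtomSphere],
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
) -> ContactMap:
    """Probe-excluded pairwise contact areas via Fibonacci-lattice sampling.

    For ligand atom *i* with expanded radius ``R_i = r_i + probe_radius``,
    ``n_points`` lattice points are placed on its expanded sphere. A point
    buried in at least one receptor expanded sphere is assigned to the
    receptor atom of deepest burial (ties to the lowest serial), and
    ``A(i, j)`` is the assigned point count times ``4·π·R_i²/n_points``.
    Whenever the expanded spheres of a pair are disjoint — i.e. a water
    probe fits between the atoms — the pair's area is exactly zero and the
    pair is absent from the map.
    """
    if probe_radius < 0:
        raise ValidationError(f"probe_radius must be >= 0, got {probe_radius}")
    if n_points < 100:
        raise ValidationError(f"n_points must be >= 100, got {n_points}")
    ligand = list(ligand)
    receptor = list(receptor)
    areas: dict[tuple[int, int], float] = {}
    if not ligand or not receptor:
        return ContactMap(
            areas=areas,
            ligand=ligand,
            receptor=receptor,
            probe_radius=probe_radius,
            n_points=n_points,
        )

    rec_centers = np.array([a.coords for a in receptor], dtype=float)
    rec_radii = np.array([a.vdw_radius for a in receptor], dtype=float) + probe_radius
    rec_serials = np.array([a.serial for a in receptor], dtype=int)
    # lowest-serial tie-break: order receptor columns by serial once
    order = np.argsort(rec_serials, kind="stable")
    rec_centers, rec_radii, rec_serials = (
        rec_centers[order],
        rec_radii[order],
        rec_serials[order],
    )

    unit = fibonacci_sphere(n_points)
    for lig_atom in ligand:
        c_i = lig_atom.xyz
        r_expanded = lig_atom.vdw_radius + probe_radius
        center_dist = np.linalg.norm(rec_centers - c_i, axis=1)
        if np.any(center_dist < 1e-9):
            j = rec_serials[int(np.argmin(center_dist))]
            raise ValidationError(
                f"ligand atom {lig_atom.serial} and receptor atom {j} have "
                "identical centers"
            )
        near = center_dist < r_expanded + rec_radii
        if not near.any():
            continue
        centers = rec_centers[near]
        radii = rec_radii[near]
        serials = rec_serials[near]

        points = c_i + r_expanded * unit  # (n, 3)
        # burial depth of each point in each near receptor sphere (negative inside)
        depth = np.linalg.norm(points[:, None, :] - centers[None, :, :], axis=2) - radii
        buried = depth < 0.0
        any_buried = buried.any(axis=1)
        if not any_buried.any():
            continue
        masked = np.where(buried, depth, np.inf)
        winner = np.argmin(masked[any_buried], axis=1)  # first min = lowest serial
        point_area = 4.0 * math.pi * r_expanded * r_expanded / n_points
        counts = np.bincount(winner, minlength=len(serials))
        for idx in np.nonzero(counts)[0]:
            areas[(lig_atom.serial, int(serials[idx]))] = float(
                counts[idx] * point_area
            )
    return ContactMap(
        areas=areas,
        ligand=ligand,
        receptor=receptor,
        probe_radius=probe_radius,
        n_points=n_points,
    )


def cap_contact_area(
    r_i: float, r_j: float, d: float, probe_radius: float = DEFAULT_PROBE_RADIUS
) -> float:
    """Closed-form contact area for one isolated atom pair.

    The area of the spherical cap of atom *i*'s expanded sphere (radius
    ``R_i = r_i + probe``) buried inside atom *j*'s expanded sphere:
    ``2·π·R_i·h`` with ``h = R_i − (d² + R_i² − R_j²)/(2d)``. Zero when the
    expanded spheres are disjoint (``d ≥ R_i + R_j``), the full sphere when
    *i* is engulfed by *j*.
    """
    if d <= 0:
        raise ValidationError(f"center distance must be positive, got {d}")
    R_i = r_i + probe_radius
    R_j = r_j + probe_radius
    if d >= R_i + R_j:
        return 0.0
    if d <= R_j - R_i:
        return 4.0 * math.pi * R_i * R_i  # engulfed
    if d <= R_i - R_j:
        return 0.0  # j inside i: no part of i's surface is inside j...
    h = R_i - (d * d + R_i * R_i - R_j * R_j) / (2.0 * d)
    h = min(max(h, 0.0), 2.0 * R_i)
    return 2.0 * math.pi * R_i * h


# ---------------------------------------------------------------------------
# aggregation


@dataclass
class ContactProfile:
    """Per-residue/subsite contact fingerprint aggregated over poses.

    ``mean_area`` is the pooled mean over the pose set of the per-pose summed
    area; ``frequency`` is the fraction of poses contacting the residue at
    all; ``cloud`` holds the contributing ligand-atom coordinates.
    """

    entries: pd.DataFrame  # index residue label; mean_area, frequency, n_poses
    clouds: dict[str, np.ndarray]
    receptor: list[AtomSphere]
    contacted_serials: set[int]
    n_poses: int


def aggregate_contacts(
    maps: Sequence[ContactMap], receptor: Sequence[AtomSphere]
) -> ContactProfile:
    """Aggregate per-pose contact maps into a per-residue fingerprint.

    All maps must have been computed against the same receptor (same serials
    and coordinates). Per pose and residue, pairwise areas are summed over
    the residue's atoms and all ligand atoms; the profile stores the mean
    over poses, the contact frequency, and the ligand-atom dot cloud.
    """
    maps = list(maps)
    receptor = list(receptor)
    if not maps:
        raise ValidationError("no contact maps to aggregate")
    ref = {(a.serial, a.coords) for a in receptor}
    for m in maps:
        if {(a.serial, a.coords) for a in m.receptor} != ref:
            raise ValidationError("contact maps computed against different receptors")

    label_of = {a.serial: a.residue_label() for a in receptor}
    per_pose: list[dict[str, float]] = []
    clouds: dict[str, list[np.ndarray]] = {}
    contacted: set[int] = set()
    for m in maps:
        lig_coords = {a.serial: a.xyz for a in m.ligand}
        pose_area: dict[str, float] = {}
        for (i, j), area in m.areas.items():
            label = label_of[j]
            pose_area[label] = pose_area.get(label, 0.0) + area
            contacted.add(j)
            clouds.setdefault(label, []).append(lig_coords[i])
        per_pose.append(pose_area)

    all_labels = sorted({lab for pose in per_pose for lab in pose})
    n_poses = len(maps)
    rows = []
    for label in all_labels:
        values = [pose.get(label, 0.0) for pose in per_pose]
        rows.append(
            {
                "residue": label,
                "mean_area": float(np.mean(values)),
                "frequency": float(np.mean([v > 0.0 for v in values])),
                "n_poses": n_poses,
            }
        )
    entries = pd.DataFrame(rows).set_index("residue") if rows else pd.DataFrame(
        columns=["mean_area", "frequency", "n_poses"]
    )
    return ContactProfile(
        entries=entries,
        clouds={
            label: np.unique(np.array(points, dtype=float), axis=0)
            for label, points in clouds.items()
        },
        receptor=receptor,
        contacted_serials=contacted,
        n_poses=n_poses,
    )


def export_contact_map(
    profile: ContactProfile, grid_spacing: float = 5.0
) -> tuple[pd.DataFrame, np.ndarray]:
    """Plot-ready fingerprint: residue centers recentred to the contact-set
    centroid, mean area (label size), frequency, and the ligand dot cloud.

    The origin convention recentres everything to the geometric center of
    the set of atoms involved in contacts (contacting receptor atoms plus the
    ligand cloud). Returns the table (with ``grid_spacing`` metadata column)
    and the recentred cloud as an (n, 3) array.
    """
    if profile.entries.empty:
        raise ValidationError("empty contact profile")
    cloud_points = (
        np.vstack(list(profile.clouds.values()))
        if profile.clouds
        else np.empty((0, 3))
    )
    contact_atoms = np.array(
        [a.xyz for a in profile.receptor if a.serial in profile.contacted_serials]
    )
    involved = np.vstack([contact_atoms, cloud_points])
    centroid = involved.mean(axis=0)

    rows = []
    for label, entry in profile.entries.iterrows():
        atoms = np.array(
            [a.xyz for a in profile.receptor if a.residue_label() == label]
        )
        center = atoms.mean(axis=0) - centroid
        rows.append(
            {
                "residue": label,
                "x": float(center[0]),
                "y": float(center[1]),
                "z": float(center[2]),
                "mean_area": float(entry["mean_area"]),
                "frequency": float(entry["frequency"]),
                "n_poses": int(entry["n_poses"]),
                "grid_spacing": grid_spacing,
            }
        )
    return pd.DataFrame(rows), cloud_points - centroid
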