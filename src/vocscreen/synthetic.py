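"""Synthetic inputs with known ground truth for every pipeline stage.

Three generators: planted docking-score panels whose TOP/MIDDLE/WORST truth
labels are known; toy ligand–receptor complexes built from isolated atom
pairs whose contact areas have a closed form; and chromatographic peak
tables that straddle the identification thresholds. All generators are pure
functions of their spec (same spec, byte-identical output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .contacts import VDW_RADII, cap_contact_area
from .errors import ValidationError
from .triage import Role

__all__ = [
    "ScorePanelSpec",
    "ToyComplexSpec",
    "gen_scores",
    "gen_toy_complex",
    "gen_peak_table",
]


@dataclass
class ScorePanelSpec:
    """Spec for a planted three-cluster docking-score panel.

    Candidates are drawn around the best positive-control mean (TOP-like),
    around the worst negative-control mean (WORST-like), or midway
    (MIDDLE-like), with Gaussian pose-level noise. Defaults emulate a panel
    with clearly separated controls: positive mean −9.0 kcal/mol, negative
    −4.0 kcal/mol, three scored poses per ligand.
    """

    n_top: int = 5
    n_middle: int = 10
    n_worst: int = 5
    control_means: dict[str, float] = field(
        default_factory=lambda: {
            "POSITIVE_CONTROL": -9.0,
            "NEGATIVE_CONTROL": -4.0,
        }
    )
    pose_sd: float = 0.25
    poses_per_ligand: int = 3
    seed: int = 0
    site_id: str = "SITE1"
    #: extra controls beyond the anchors, offset (kcal/mol) from each anchor
    #: mean; anchors stay at the spec'd means.
    control_offsets: tuple[float, ...] = (0.0, 0.4)

    def validate(self) -> None:
        if min(self.n_top, self.n_middle, self.n_worst) < 0:
            raise ValidationError("cluster counts must be >= 0")
        if not (self.pose_sd > 0):
            raise ValidationError("pose_sd must be > 0")
        if self.poses_per_ligand < 1:
            raise ValidationError("poses_per_ligand must be >= 1")
        pos = self.control_means.get("POSITIVE_CONTROL")
        neg = self.control_means.get("NEGATIVE_CONTROL")
        if pos is None or neg is None:
            raise ValidationError("control_means must name both control roles")
        if not pos < neg:
            raise ValidationError(
                f"positive control mean ({pos}) must be more negative than "
                f"negative control mean ({neg})"
            )


def gen_scores(spec: ScorePanelSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a planted score table plus its truth labels.

    Returns ``(scores, truth)``: a long-format table with columns
    ``ligand_id, site_id, role, pose_rank, score`` and a truth table with
    ``ligand_id, true_group``. Positive controls sit at the positive anchor
    mean and above (less negative) by ``control_offsets``; negative controls
    at the negative anchor mean and below. Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    pos_mean = spec.control_means["POSITIVE_CONTROL"]
    neg_mean = spec.control_means["NEGATIVE_CONTROL"]
    mid_mean = 0.5 * (pos_mean + neg_mean)

    ligands: list[tuple[str, Role, float, str]] = []  # id, role, mean, truth
    for k, offset in enumerate(spec.control_offsets, start=1):
        ligands.append((f"POS{k}", Role.POSITIVE_CONTROL, pos_mean + offset, ""))
    for k, offset in enumerate(spec.control_offsets, start=1):
        ligands.append((f"NEG{k}", Role.NEGATIVE_CONTROL, neg_mean - offset, ""))
    for k in range(1, spec.n_top + 1):
        ligands.append((f"TOP{k:02d}", Role.CANDIDATE, pos_mean, "TOP"))
    for k in range(1, spec.n_middle + 1):
        ligands.append((f"MID{k:02d}", Role.CANDIDATE, mid_mean, "MIDDLE"))
    for k in range(1, spec.n_worst + 1):
        ligands.append((f"WRS{k:02d}", Role.CANDIDATE, neg_mean, "WORST"))

    rows = []
    truth_rows = []
    for ligand_id, role, mean, truth in ligands:
        noise = rng.normal(0.0, spec.pose_sd, size=spec.poses_per_ligand)
        for rank, eps in enumerate(noise, start=1):
            rows.append(
                {
                    "ligand_id": ligand_id,
                    "site_id": spec.site_id,
                    "role": role.value,
                    "pose_rank": rank,
                    "score": mean + eps,
                }
            )
        if role is Role.CANDIDATE:
            truth_rows.append({"ligand_id": ligand_id, "true_group": truth})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


@dataclass
class ToyComplexSpec:
    """Spec for a toy complex of isolated ligand–receptor atom pairs.

    Each entry is ``(ligand radius Å, receptor radius Å, center distance Å)``.
    Pairs are laid out along x with enough spacing that no atom of one pair
    can touch any atom of another (≥ ``min_separation`` between cells), so
    each pair's contact area has the closed spherical-cap form. Radii are
    realized by the element with the nearest tabulated van der Waals radius;
    the analytic table reports the radius actually used.
    """

    pairs: list[tuple[float, float, float]]
    min_separation: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not self.pairs:
            raise ValidationError("need at least one pair")
        for k, (r_l, r_r, d) in enumerate(self.pairs):
            if not (r_l > 0 and r_r > 0):
                raise ValidationError(f"pair {k}: radii must be positive")
            if not (d > 0 and math.isfinite(d)):
                raise ValidationError(f"pair {k}: distance must be positive and finite")
        if self.min_separation < 20.0:
            raise ValidationError(
                "min_separation below 20 Å would let pairs interact"
            )


_HEAVY_ELEMENTS = {
    el: r for el, r in VDW_RADII.items() if el not in ("H",)
}


def _element_for_radius(radius: float) -> tuple[str, float]:
    element = min(
        sorted(_HEAVY_ELEMENTS), key=lambda el: (abs(_HEAVY_ELEMENTS[el] - radius), el)
    )
    return element, _HEAVY_ELEMENTS[element]


def gen_toy_complex(
    spec: ToyComplexSpec,
    path: str | Path | None = None,
    probe_radius: float = 1.4,
) -> tuple[str, pd.DataFrame]:
    """Emit a toy-complex PDB and its analytic contact-area table.

    Returns ``(pdb_text, analytic)`` and also writes the PDB if ``path`` is
    given. Ligand atoms form residue LIG on chain L; each receptor atom is
    its own residue (TOY 1..n) on chain R, so per-residue aggregation maps
    one-to-one onto pairs. ``analytic.expected_area`` is the closed-form
    spherical-cap area for the element radii actually used; it is exactly
    zero when the pair distance admits an interposed water probe
    (``d ≥ r_i + r_j + 2·probe``).
    """
    import gemmi

    spec.validate()
    spacing = max(d for _, _, d in spec.pairs) + spec.min_separation

    structure = gemmi.Structure()
    structure.name = "toy-contact-complex"
    model = gemmi.Model("1")
    chain_l = gemmi.Chain("L")
    chain_r = gemmi.Chain("R")
    lig_residue = gemmi.Residue()
    lig_residue.name = "LIG"
    lig_residue.seqid = gemmi.SeqId(1, " ")
    lig_residue.het_flag = "H"

    analytic_rows = []
    serial = 0
    for k, (r_l, r_r, d) in enumerate(spec.pairs):
        x0 = k * spacing
        el_l, used_l = _element_for_radius(r_l)
        el_r, used_r = _element_for_radius(r_r)

        serial += 1
        atom_l = gemmi.Atom()
        atom_l.name = f"L{k + 1}"
        atom_l.element = gemmi.Element(el_l.capitalize())
        atom_l.pos = gemmi.Position(x0, 0.0, 0.0)
        atom_l.serial = serial
        atom_l.occ = 1.0
        lig_residue.add_atom(atom_l)

        serial += 1
        rec_residue = gemmi.Residue()
        rec_residue.name = "TOY"
        rec_residue.seqid = gemmi.SeqId(k + 1, " ")
        rec_residue.het_flag = "H"
        atom_r = gemmi.Atom()
        atom_r.name = f"R{k + 1}"
        atom_r.element = gemmi.Element(el_r.capitalize())
        atom_r.pos = gemmi.Position(x0 + d, 0.0, 0.0)
        atom_r.serial = serial
        atom_r.occ = 1.0
        rec_residue.add_atom(atom_r)
        chain_r.add_residue(rec_residue)

        analytic_rows.append(
            {
                "pair": k,
                "ligand_atom": f"L{k + 1}",
                "receptor_atom": f"R{k + 1}",
                "receptor_residue": f"R:TOY{k + 1}",
                "ligand_element": el_l,
                "receptor_element": el_r,
                "requested_r_ligand": r_l,
                "requested_r_receptor": r_r,
                "r_ligand": used_l,
                "r_receptor": used_r,
                "distance": d,
                "expected_area": cap_contact_area(
                    used_l, used_r, d, probe_radius=probe_radius
                ),
            }
        )

    chain_l.add_residue(lig_residue)
    model.add_chain(chain_l)
    model.add_chain(chain_r)
    structure.add_model(model)
    structure.setup_entities()
    pdb_text = structure.make_pdb_string()
    if path is not None:
        Path(path).write_text(pdb_text, encoding="utf-8")
    return pdb_text, pd.DataFrame(analytic_rows)


def gen_peak_table(n: int, seed: int = 0) -> pd.DataFrame:
    """Peak table straddling the RSI > 600 and S/N > 50 thresholds.

    The first rows pin the boundary cases — exactly 600 or exactly 50 must
    fail the strict inequalities — and the remainder is uniform over
    RSI ∈ (0, 1200), S/N ∈ (0, 100). The ``passes`` column is the planted
    truth.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    boundary = [
        (600.0, 80.0),  # RSI exactly at threshold: fail
        (900.0, 50.0),  # S/N exactly at threshold: fail
        (601.0, 51.0),  # just above both: pass
        (599.0, 99.0),  # RSI just below: fail
    ]
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        if i < len(boundary):
            rsi, snr = boundary[i]
        else:
            rsi = float(rng.uniform(0.0, 1200.0))
            snr = float(rng.uniform(0.0, 100.0))
        rows.append(
            {
                "rt": round(1.0 + 0.25 * i, 3),
                "rsi": rsi,
                "snr": snr,
                "passes": bool(rsi > 600.0 and snr > 50.0),
            }
        )
    return pd.DataFrame(rows, columns=["rt", "rsi", "snr", "passes"])
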