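"""Molecular descriptors and descriptor–affinity correlograms.

Authoritative descriptor values (miLogP, TPSA, parachor, polarizability, ...)
are ingested from delimited text, mirroring the use of third-party property
calculators; a best-effort subset (molecular weight, N/O hydrogen-bond
counts, rotatable bonds, maximal interatomic length of a given conformer) is
computed directly with RDKit. Pearson correlations between descriptors and
per-site mean docking scores are assembled into a correlogram, either over
candidates plus controls or over candidates only.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .errors import ParseError, ValidationError

__all__ = [
    "KNOWN_DESCRIPTORS",
    "COUNT_DESCRIPTORS",
    "Variant",
    "DescriptorTable",
    "load_descriptors",
    "write_descriptors",
    "compute_basic_descriptors",
    "max_pairwise_distance",
    "Correlogram",
    "correlogram",
]

#: Descriptor columns the loader recognises (units in parentheses):
#: molar_volume (cm3/mol), polarizability (A^3), molar_refractivity
#: (cm3/mol), logP (unitless), parachor, tpsa (A^2), hba / hbd (counts),
#: max_length (A), rotatable_bonds (count), molecular_weight (g/mol).
KNOWN_DESCRIPTORS = (
    "molar_volume",
    "polarizability",
    "molar_refractivity",
    "logP",
    "parachor",
    "tpsa",
    "hba",
    "hbd",
    "max_length",
    "rotatable_bonds",
    "molecular_weight",
)

COUNT_DESCRIPTORS = ("hba", "hbd", "rotatable_bonds")

_MISSING_TOKENS = {"", "NA", "ND", "NAN", "N/A", "-"}


class Variant(str, enum.Enum):
    """Which ligands enter the correlation vectors."""

    WITH_CONTROLS = "WITH_CONTROLS"
    CANDIDATES_ONLY = "CANDIDATES_ONLY"


@dataclass
class DescriptorTable:
    """Named numeric descriptors per ligand.

    ``frame`` is indexed by ligand id; unknown columns are kept but listed in
    ``unknown_columns`` so downstream users can see what was not validated.
    """

    frame: pd.DataFrame
    unknown_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.frame.index.duplicated().any():
            dupes = self.frame.index[self.frame.index.duplicated()].tolist()
            raise ValidationError(f"duplicate ligand ids: {dupes}")
        for col in COUNT_DESCRIPTORS:
            if col in self.frame.columns:
                values = self.frame[col].dropna()
                if (values < 0).any():
                    raise ValidationError(f"{col}: negative count")
                if not np.allclose(values, np.round(values)):
                    raise ValidationError(f"{col}: non-integer count")
        for col in ("tpsa", "max_length"):
            if col in self.frame.columns and (self.frame[col].dropna() < 0).any():
                raise ValidationError(f"{col}: negative value")

    @property
    def ligands(self) -> list[str]:
        return [str(i) for i in self.frame.index]

    def merged_with(self, other: "DescriptorTable") -> "DescriptorTable":
        """Column-wise merge; ``other`` fills columns absent here."""
        frame = self.frame.combine_first(other.frame)
        unknown = sorted(set(self.unknown_columns) | set(other.unknown_columns))
        return DescriptorTable(frame=frame, unknown_columns=unknown)


def load_descriptors(path: str | Path) -> DescriptorTable:
    """Load a delimited descriptor table (one ligand per row).

    The first column (or a ``ligand_id`` column) is the ligand id; known
    descriptor names are validated, unknown columns are kept and flagged.
    Missing cells ("", "NA", "ND", "-") become NaN and are excluded pairwise
    downstream; any other non-numeric cell is a parse error naming the
    offending row and column.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    raw.columns = [c.strip() for c in raw.columns]
    id_col = "ligand_id" if "ligand_id" in raw.columns else raw.columns[0]
    raw[id_col] = raw[id_col].astype(str).str.strip()
    frame = raw.set_index(id_col)
    frame.index.name = "ligand_id"

    known_lower = {k.lower(): k for k in KNOWN_DESCRIPTORS}
    rename = {c: known_lower[c.lower()] for c in frame.columns if c.lower() in known_lower}
    frame = frame.rename(columns=rename)
    unknown = [c for c in frame.columns if c not in KNOWN_DESCRIPTORS]
    if unknown:
        warnings.warn(
            f"{path}: keeping unrecognised descriptor columns {unknown}",
            stacklevel=2,
        )

    def _to_number(cell: str, row: str, col: str) -> float:
        text = str(cell).strip()
        if text.upper() in _MISSING_TOKENS:
            return float("nan")
        try:
            return float(text.replace(",", ".") if text.count(",") == 1 and "." not in text else text)
        except ValueError as exc:
            raise ParseError(
                f"{path}: ligand {row!r}, column {col!r}: non-numeric value {cell!r}"
            ) from exc

    numeric = pd.DataFrame(
        {
            col: [
                _to_number(frame.at[idx, col], str(idx), col) for idx in frame.index
            ]
            for col in frame.columns
        },
        index=frame.index,
    )
    return DescriptorTable(frame=numeric, unknown_columns=unknown)


def write_descriptors(table: DescriptorTable, path: str | Path) -> None:
    """Serialize canonically (decimal point, empty cell for missing)."""
    table.frame.to_csv(path, index=True, na_rep="")


# ---------------------------------------------------------------------------
# computed descriptors


def max_pairwise_distance(coords: np.ndarray) -> float:
    """Maximum interatomic distance (A) of one conformer's coordinates."""
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or coords.shape[1] != 3:
        raise ValidationError(f"expected (n, 3) coordinates, got {coords.shape}")
    if len(coords) < 2:
        return 0.0
    return float(pdist(coords).max())


def compute_basic_descriptors(structures: Mapping[str, "object"]) -> DescriptorTable:
    """Compute the descriptors derivable from structure alone.

    ``structures`` maps ligand id to an RDKit ``Mol``. Computes molecular
    weight, hydrogen-bond acceptor/donor counts by the N/O convention
    (acceptors = N+O atoms, donors = NH+OH), rotatable bonds, and
    ``max_length`` as the maximum pairwise interatomic distance of the given
    conformer (no conformer search; the input geometry is taken as-is). A
    molecule without coordinates gets NaN max_length with a warning.
    """
    from rdkit.Chem import Descriptors, Lipinski

    rows = {}
    for ligand_id, mol in structures.items():
        if mol is None:
            raise ValidationError(f"{ligand_id}: no molecule")
        row = {
            "molecular_weight": float(Descriptors.MolWt(mol)),
            "hba": float(Lipinski.NOCount(mol)),
            "hbd": float(Lipinski.NHOHCount(mol)),
            "rotatable_bonds": float(Lipinski.NumRotatableBonds(mol)),
        }
        if mol.GetNumConformers() > 0:
            coords = mol.GetConformer().GetPositions()
            row["max_length"] = max_pairwise_distance(np.asarray(coords))
        else:
            warnings.warn(
                f"{ligand_id}: no conformer coordinates; max_length omitted",
                stacklevel=2,
            )
            row["max_length"] = float("nan")
        rows[str(ligand_id)] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "ligand_id"
    return DescriptorTable(frame=frame)


# ---------------------------------------------------------------------------
# correlogram


@dataclass
class Correlogram:
    """Pearson r (and two-sided p, and pair count n) per descriptor x site."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    variant: Variant

    def to_long(self) -> pd.DataFrame:
        rows = []
        for descriptor in self.r.index:
            for site in self.r.columns:
                rows.append(
                    {
                        "descriptor": descriptor,
                        "site": site,
                        "r": self.r.at[descriptor, site],
                        "p": self.p.at[descriptor, site],
                        "n": int(self.n.at[descriptor, site]),
                    }
                )
        return pd.DataFrame(rows)

    def with_bh_adjusted(self) -> pd.DataFrame:
        """Long format with a Benjamini–Hochberg adjusted q column.

        The raw correlogram carries unadjusted p-values; adjustment is
        opt-in.
        """
        from statsmodels.stats.multitest import multipletests

        long = self.to_long()
        mask = long["p"].notna()
        q = np.full(len(long), np.nan)
        if mask.any():
            q[mask.to_numpy()] = multipletests(long.loc[mask, "p"], method="fdr_bh")[1]
        long["q"] = q
        return long


def correlogram(
    descriptors: DescriptorTable,
    mean_scores: pd.DataFrame,
    variant: Variant = Variant.WITH_CONTROLS,
    control_ids: Iterable[str] = (),
    min_pairs: int = 3,
) -> Correlogram:
    """Pearson correlation of each descriptor against per-site mean scores.

    ``mean_scores`` is a ligand x site frame of mean docking scores (NaN
    where a ligand was not docked at a site). Pairs are pairwise-complete;
    cells with fewer than ``min_pairs`` pairs or zero variance in either
    vector are reported as undefined (NaN), never as 0. Negative r means the
    descriptor improves predicted affinity (scores are negative-better).
    """
    variant = Variant(variant)
    control_ids = {str(c) for c in control_ids}
    scores = mean_scores.copy()
    scores.index = scores.index.astype(str)
    if variant is Variant.CANDIDATES_ONLY:
        scores = scores.loc[[i for i in scores.index if i not in control_ids]]

    desc = descriptors.frame.copy()
    desc.index = desc.index.astype(str)
    common = [i for i in scores.index if i in desc.index]
    if not common:
        raise ValidationError("no ligands shared between descriptors and scores")
    scores = scores.loc[common]
    desc = desc.loc[common]

    r = pd.DataFrame(index=desc.columns, columns=scores.columns, dtype=float)
    p = pd.DataFrame(index=desc.columns, columns=scores.columns, dtype=float)
    n = pd.DataFrame(0, index=desc.columns, columns=scores.columns, dtype=int)
    for descriptor in desc.columns:
        x_all = desc[descriptor].astype(float)
        for site in scores.columns:
            y_all = scores[site].astype(float)
            mask = x_all.notna() & y_all.notna()
            n.at[descriptor, site] = int(mask.sum())
            if mask.sum() < min_pairs:
                continue
            x = x_all[mask].to_numpy()
            y = y_all[mask].to_numpy()
            if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
                continue  # zero variance: r undefined, left as NaN
            res = stats.pearsonr(x, y)
            r.at[descriptor, site] = float(res.statistic)
            p.at[descriptor, site] = float(res.pvalue)
    return Correlogram(r=r, p=p, n=n, variant=variant)
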