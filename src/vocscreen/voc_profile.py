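"""Volatile-compound profile handling.

Parses, filters and summarizes headspace GC-MS volatile profiles of seed
samples: per-compound percent abundances across sampled trees, chemical-class
tallies, per-sample abundance rankings, and the identification filter on raw
chromatographic peaks (spectral-library match quality RSI and peak
signal-to-noise).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "CHEM_CLASSES",
    "DEFAULT_RSI_MIN",
    "DEFAULT_SNR_MIN",
    "PeakRecord",
    "CompoundRecord",
    "VOCProfile",
    "filter_peaks",
    "read_peak_table",
    "parse_compound_table",
    "write_compound_table",
    "load_reference_profile",
    "summarize_sample",
    "class_counts",
    "presence_across_samples",
]

CHEM_CLASSES = ("MONOTERPENE", "SESQUITERPENE", "OTHER")

#: Identification filter defaults: spectral-library relative standard
#: intensity must exceed 600 and the peak signal-to-noise ratio (dB) must
#: exceed 50, both as strict inequalities.
DEFAULT_RSI_MIN = 600.0
DEFAULT_SNR_MIN = 50.0

#: Cell tokens that mean "not detected" in abundance columns.
MISSING_TOKENS = frozenset({"", "ND", "-", "N.D.", "n.d."})

_CLASS_ALIASES = {
    "MONOTERPENE": "MONOTERPENE",
    "MONOTERPENES": "MONOTERPENE",
    "SESQUITERPENE": "SESQUITERPENE",
    "SESQUITERPENES": "SESQUITERPENE",
    "OTHER": "OTHER",
    "OTHERS": "OTHER",
    "OTHER CLASSES": "OTHER",
}


@dataclass(frozen=True)
class PeakRecord:
    """One chromatographic peak: retention time (min), RSI, S/N (dB)."""

    retention_time: float
    rsi: float
    snr: float
    annotation: str = ""

    def __post_init__(self) -> None:
        for attr in ("retention_time", "rsi", "snr"):
            value = getattr(self, attr)
            try:
                value = float(value)
            except (TypeError, ValueError) as exc:
                raise ParseError(f"non-numeric {attr}: {value!r}") from exc
            object.__setattr__(self, attr, value)
        if not math.isfinite(self.snr):
            raise ValidationError(f"S/N must be finite, got {self.snr!r}")
        if not (self.rsi >= 0):
            raise ValidationError(f"RSI must be >= 0, got {self.rsi!r}")


@dataclass
class CompoundRecord:
    """One volatile compound with per-sample percent abundances.

    ``abundance`` maps sample id to percent in [0, 100]; a sample where the
    compound was not detected (ND) is simply absent from the map.
    """

    compound_id: int
    name: str
    cas: str
    formula: str
    chem_class: str
    abundance: dict[str, float] = field(default_factory=dict)

    def validate(self, samples: Iterable[str] | None = None) -> None:
        if self.chem_class not in CHEM_CLASSES:
            raise ValidationError(
                f"compound {self.compound_id} ({self.name}): unknown class "
                f"{self.chem_class!r}; expected one of {CHEM_CLASSES}"
            )
        if not self.abundance:
            raise ValidationError(
                f"compound {self.compound_id} ({self.name}): not detected in "
                "any sample"
            )
        for sample, value in self.abundance.items():
            if not (0.0 <= value <= 100.0):
                raise ValidationError(
                    f"compound {self.compound_id} ({self.name}), sample "
                    f"{sample}: abundance {value} outside [0, 100]"
                )
        if samples is not None:
            unknown = set(self.abundance) - set(samples)
            if unknown:
                raise ValidationError(
                    f"compound {self.compound_id} ({self.name}): abundances "
                    f"for unknown samples {sorted(unknown)}"
                )

    def presence(self) -> int:
        """Number of samples in which the compound was detected."""
        return len(self.abundance)

    def mean_abundance(self, samples: Iterable[str]) -> float:
        """Mean percent over *all* samples, counting ND as zero.

        This is the convention for molar-content aggregations; presence and
        ranking treat ND as missing instead.
        """
        sample_list = list(samples)
        return sum(self.abundance.get(s, 0.0) for s in sample_list) / len(sample_list)


@dataclass
class VOCProfile:
    """An ordered set of samples and the compounds detected across them."""

    samples: list[str]
    compounds: list[CompoundRecord]

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample ids")
        ids = [c.compound_id for c in self.compounds]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate compound ids")
        for compound in self.compounds:
            compound.validate(self.samples)

    def compound(self, key: int | str) -> CompoundRecord:
        """Look up a compound by id or (case-insensitive) name."""
        for c in self.compounds:
            if c.compound_id == key:
                return c
        if isinstance(key, str):
            for c in self.compounds:
                if c.name.casefold() == key.casefold():
                    return c
        raise KeyError(f"unknown compound {key!r}")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for c in self.compounds:
            row: dict[str, object] = {
                "compound_id": c.compound_id,
                "name": c.name,
                "cas": c.cas,
                "formula": c.formula,
                "class": c.chem_class,
            }
            for s in self.samples:
                row[s] = c.abundance.get(s, float("nan"))
            rows.append(row)
        return pd.DataFrame(rows)


def filter_peaks(
    peaks: Iterable[PeakRecord],
    rsi_min: float = DEFAULT_RSI_MIN,
    snr_min: float = DEFAULT_SNR_MIN,
) -> list[PeakRecord]:
    """Keep peaks with RSI strictly above ``rsi_min`` AND S/N strictly above
    ``snr_min``, preserving input order.

    Boundary peaks (RSI exactly 600 or S/N exactly 50 at the defaults) are
    rejected: the identification rule is a strict inequality.
    """
    rsi_min = float(rsi_min)
    snr_min = float(snr_min)
    if not (math.isfinite(rsi_min) and math.isfinite(snr_min)):
        raise ValidationError("rsi_min and snr_min must be finite")
    kept: list[PeakRecord] = []
    for i, peak in enumerate(peaks):
        try:
            rsi = float(peak.rsi)
            snr = float(peak.snr)
        except (TypeError, ValueError) as exc:
            raise ParseError(f"row {i}: non-numeric rsi/snr in {peak!r}") from exc
        if rsi > rsi_min and snr > snr_min:
            kept.append(peak)
    return kept


def read_peak_table(path: str | Path) -> list[PeakRecord]:
    """Read a delimited peak table with columns rt, rsi, snr [, annotation]."""
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    cols = {c.strip().lower(): c for c in df.columns}
    for required in ("rt", "rsi", "snr"):
        if required not in cols:
            raise ParseError(f"{path}: missing column {required!r}")
    peaks = []
    for i, row in df.iterrows():
        try:
            peaks.append(
                PeakRecord(
                    retention_time=float(row[cols["rt"]]),
                    rsi=float(row[cols["rsi"]]),
                    snr=float(row[cols["snr"]]),
                    annotation=str(row[cols["annotation"]]) if "annotation" in cols else "",
                )
            )
        except (ValueError, ParseError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return peaks


_DECIMAL_COMMA = re.compile(r"^\d+,\d+$")


def _parse_abundance(cell: str, where: str) -> float | None:
    text = cell.strip()
    if text in MISSING_TOKENS:
        return None
    if text.endswith("%"):
        text = text[:-1].strip()
    if _DECIMAL_COMMA.match(text):
        text = text.replace(",", ".")
    try:
        value = float(text)
    except ValueError as exc:
        raise ParseError(f"{where}: cannot parse abundance {cell!r}") from exc
    if not (0.0 <= value <= 100.0):
        raise ValidationError(f"{where}: abundance {value} outside [0, 100]")
    return value


def _normalize_class(label: str, where: str) -> str:
    key = label.strip().upper()
    if key not in _CLASS_ALIASES:
        raise ValidationError(f"{where}: unknown chemical class {label!r}")
    return _CLASS_ALIASES[key]


def parse_compound_table(path: str | Path) -> VOCProfile:
    """Parse a delimited compound-abundance table into a :class:`VOCProfile`.

    Expected header: ``compound_id,name,cas,formula,class,<sample>,...``.
    "ND", "-" and empty abundance cells are treated as not detected; a "%"
    suffix and a decimal comma are accepted. If the ``class`` column is
    absent, rows whose name cell is a bare class label (section headers such
    as "MONOTERPENES") switch the class of the rows that follow.
    """
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    lower = [c.lower() for c in df.columns]
    meta_names = ["compound_id", "name", "cas", "formula", "class"]
    has_class = "class" in lower
    required = [m for m in meta_names if m != "class" or has_class]
    for m in required:
        if m not in lower:
            raise ParseError(f"{path}: missing column {m!r}")
    meta_cols = {m: df.columns[lower.index(m)] for m in required}
    samples = [c for c in df.columns if c.lower() not in meta_names]
    if not samples:
        raise ParseError(f"{path}: no sample columns found")

    compounds: list[CompoundRecord] = []
    section_class: str | None = None
    for i, row in df.iterrows():
        where = f"{path}: row {i + 2}"  # 1-based, after header
        name = str(row[meta_cols["name"]]).strip()
        if not has_class:
            # Section-header dialect: a class label alone switches sections.
            if name.upper() in _CLASS_ALIASES and not any(
                str(row[s]).strip() for s in samples
            ):
                section_class = _CLASS_ALIASES[name.upper()]
                continue
            if section_class is None:
                raise ValidationError(f"{where}: no class column and no section header yet")
            chem_class = section_class
        else:
            chem_class = _normalize_class(str(row[meta_cols["class"]]), where)
        try:
            compound_id = int(str(row[meta_cols["compound_id"]]).strip())
        except ValueError as exc:
            raise ParseError(f"{where}: bad compound_id") from exc
        abundance: dict[str, float] = {}
        for s in samples:
            value = _parse_abundance(str(row[s]), f"{where}, sample {s}")
            if value is not None:
                abundance[s] = value
        compounds.append(
            CompoundRecord(
                compound_id=compound_id,
                name=name,
                cas=str(row[meta_cols["cas"]]).strip(),
                formula=str(row[meta_cols["formula"]]).strip(),
                chem_class=chem_class,
                abundance=abundance,
            )
        )
    profile = VOCProfile(samples=samples, compounds=compounds)
    profile.validate()
    return profile


def write_compound_table(profile: VOCProfile, path: str | Path) -> None:
    """Serialize in canonical form: decimal point, no "%", ND for missing."""
    df = profile.to_frame()
    for s in profile.samples:
        df[s] = df[s].map(lambda v: "ND" if pd.isna(v) else format(v, "g"))
    df.to_csv(path, index=False)


def load_reference_profile() -> VOCProfile:
    """Load the packaged seed-volatile abundance table (23 compounds, five
    sampled trees A.1–A.5)."""
    with resources.as_file(
        resources.files("vocscreen.data").joinpath("table1.csv")
    ) as fixture:
        return parse_compound_table(fixture)


def summarize_sample(
    profile: VOCProfile, sample_id: str
) -> list[tuple[CompoundRecord, float]]:
    """Compounds detected in one sample, ranked by descending abundance.

    Ties are broken by ascending compound id so rankings are deterministic.
    """
    if sample_id not in profile.samples:
        raise KeyError(f"unknown sample {sample_id!r}")
    present = [
        (c, c.abundance[sample_id]) for c in profile.compounds if sample_id in c.abundance
    ]
    present.sort(key=lambda pair: (-pair[1], pair[0].compound_id))
    return present


def class_counts(profile: VOCProfile) -> dict[str, int]:
    """Number of compounds per chemical class (all classes always present)."""
    counts = {label: 0 for label in CHEM_CLASSES}
    for c in profile.compounds:
        counts[c.chem_class] += 1
    return counts


def presence_across_samples(profile: VOCProfile, compound: int | str) -> int:
    """In how many samples was the compound detected?"""
    return profile.compound(compound).presence()
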