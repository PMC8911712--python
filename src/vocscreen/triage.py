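"""Control-anchored triage of docking scores.

Ligands are docked against one or more target sites (COX-1 active site, the
iNOS active site, the iNOS pterin-cofactor site); the first few poses per
ligand are scored in kcal/mol (more negative = stronger predicted binding).
This module averages pose scores, runs a one-way ANOVA with all-pairs Tukey
HSD over ligands (poses as replicates), builds a compact letter display
(CLD), and classifies each candidate as TOP / MIDDLE / WORST by whether it
shares a Tukey letter with the best positive control or the worst negative
control. Cross-site set algebra and per-group summary statistics round out
the triage.
"""

from __future__ import annotations

import enum
import itertools
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import DegenerateVarianceError, ParseError, ValidationError
from .voc_profile import CHEM_CLASSES, VOCProfile

__all__ = [
    "Role",
    "GROUP_LABELS",
    "ScoreSet",
    "TukeyGrouping",
    "TriageResult",
    "OverlapResult",
    "read_scores",
    "scoresets_from_frame",
    "average_pose_scores",
    "anova_tukey_cld",
    "classify_compounds",
    "triage_site",
    "cross_site_overlap",
    "summarize_groups",
    "abundance_coverage",
]

GROUP_LABELS = ("TOP", "MIDDLE", "WORST")

_LETTERS = "abcdefghijklmnopqrstuvwxyz"


class Role(str, enum.Enum):
    """Role of a ligand in the docking panel."""

    CANDIDATE = "CANDIDATE"
    POSITIVE_CONTROL = "POSITIVE_CONTROL"
    NEGATIVE_CONTROL = "NEGATIVE_CONTROL"

    @classmethod
    def parse(cls, text: str) -> "Role":
        key = str(text).strip().upper().replace("-", "_").replace(" ", "_")
        aliases = {
            "POSITIVE": cls.POSITIVE_CONTROL,
            "POS": cls.POSITIVE_CONTROL,
            "NEGATIVE": cls.NEGATIVE_CONTROL,
            "NEG": cls.NEGATIVE_CONTROL,
        }
        if key in cls.__members__:
            return cls[key]
        if key in aliases:
            return aliases[key]
        raise ValidationError(f"unknown role {text!r}")


@dataclass
class ScoreSet:
    """Pose-level affinity scores for one (ligand, site) pair."""

    ligand_id: str
    site_id: str
    role: Role
    pose_scores: list[float]

    def __post_init__(self) -> None:
        self.role = Role(self.role) if not isinstance(self.role, Role) else self.role
        self.pose_scores = [float(s) for s in self.pose_scores]
        if not self.pose_scores:
            raise ValidationError(
                f"{self.ligand_id}@{self.site_id}: empty pose score list"
            )
        if not all(math.isfinite(s) for s in self.pose_scores):
            raise ValidationError(
                f"{self.ligand_id}@{self.site_id}: non-finite pose score"
            )

    @property
    def mean(self) -> float:
        return float(np.mean(self.pose_scores))


@dataclass
class TukeyGrouping:
    """ANOVA + Tukey HSD result with a compact letter display.

    Two ligands whose letter sets are disjoint differ significantly at
    ``alpha``; sharing at least one letter means the pairwise Tukey test did
    not separate them.
    """

    means: dict[str, float]
    letters: dict[str, str]
    f_statistic: float
    p_value: float
    alpha: float
    pairwise: pd.DataFrame  # columns: ligand_1, ligand_2, mean_diff, p_adj, reject

    def share_letter(self, a: str, b: str) -> bool:
        return bool(set(self.letters[a]) & set(self.letters[b]))


@dataclass
class TriageResult:
    """TOP/MIDDLE/WORST label per candidate for one target site."""

    site_id: str
    labels: dict[str, str]
    anchor_top: tuple[str, float]  # (ligand, mean) of best positive control
    anchor_worst: tuple[str, float]  # (ligand, mean) of worst negative control
    grouping: TukeyGrouping | None = None

    def ligands(self, label: str) -> set[str]:
        return {lig for lig, lab in self.labels.items() if lab == label}


@dataclass
class OverlapResult:
    """Cross-site label tuples and per-label set intersections."""

    sites: list[str]
    per_ligand: dict[str, dict[str, str]]  # ligand -> site -> label
    label_sets: dict[str, dict[str, set[str]]]  # label -> site -> ligands
    intersections: dict[str, dict[tuple[str, ...], set[str]]]
    site_specific: dict[str, str]  # ligand -> its sole TOP site (WORST elsewhere)


# ---------------------------------------------------------------------------
# score I/O


_VINA_HEADER = re.compile(
    r"^#\s*ligand\s*=\s*(?P<ligand>\S+)\s+site\s*=\s*(?P<site>\S+)"
    r"(?:\s+role\s*=\s*(?P<role>\S+))?\s*$"
)
_VINA_MODE = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+")


def read_scores(path: str | Path, top_n: int | None = 3) -> list[ScoreSet]:
    """Read pose scores from delimited text or a concatenated Vina-log dialect.

    The tabular format has a header ``ligand_id,site_id,role,pose_rank,score``.
    The convenience dialect concatenates docking-log blocks, each introduced
    by a ``# ligand=<id> site=<id> role=<role>`` line followed by standard
    mode/affinity table rows; only the mode number and affinity are read.
    By default the first ``top_n`` poses per (ligand, site), in rank order,
    are kept.
    """
    text = Path(path).read_text(encoding="utf-8")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if first.lstrip().startswith("#"):
        frame = _parse_vina_blocks(text, str(path))
    else:
        frame = pd.read_csv(path, sep=None, engine="python")
        missing = {"ligand_id", "site_id", "role", "pose_rank", "score"} - set(
            frame.columns
        )
        if missing:
            raise ParseError(f"{path}: missing columns {sorted(missing)}")
    return scoresets_from_frame(frame, top_n=top_n)


def _parse_vina_blocks(text: str, where: str) -> pd.DataFrame:
    rows = []
    ligand = site = role = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        header = _VINA_HEADER.match(line)
        if header:
            ligand = header.group("ligand")
            site = header.group("site")
            role = header.group("role") or "CANDIDATE"
            continue
        mode = _VINA_MODE.match(line)
        if mode:
            if ligand is None:
                raise ParseError(
                    f"{where}: line {lineno}: pose row before any ligand header"
                )
            rows.append(
                {
                    "ligand_id": ligand,
                    "site_id": site,
                    "role": role,
                    "pose_rank": int(mode.group(1)),
                    "score": float(mode.group(2)),
                }
            )
    if not rows:
        raise ParseError(f"{where}: no pose rows found")
    return pd.DataFrame(rows)


def scoresets_from_frame(
    frame: pd.DataFrame, top_n: int | None = 3
) -> list[ScoreSet]:
    """Group a long-format score table into :class:`ScoreSet` objects."""
    sets: list[ScoreSet] = []
    for (ligand, site), sub in frame.groupby(["ligand_id", "site_id"], sort=False):
        sub = sub.sort_values("pose_rank")
        if top_n is not None:
            sub = sub.head(top_n)
        roles = {Role.parse(r) for r in sub["role"]}
        if len(roles) != 1:
            raise ValidationError(f"{ligand}@{site}: inconsistent roles {roles}")
        sets.append(
            ScoreSet(
                ligand_id=str(ligand),
                site_id=str(site),
                role=roles.pop(),
                pose_scores=list(sub["score"].astype(float)),
            )
        )
    return sets


def scores_to_frame(score_sets: Iterable[ScoreSet]) -> pd.DataFrame:
    rows = []
    for s in score_sets:
        for rank, score in enumerate(s.pose_scores, start=1):
            rows.append(
                {
                    "ligand_id": s.ligand_id,
                    "site_id": s.site_id,
                    "role": s.role.value,
                    "pose_rank": rank,
                    "score": score,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics


def average_pose_scores(scores: ScoreSet) -> float:
    """Arithmetic mean of the pose scores of one (ligand, site) pair."""
    return scores.mean


def _check_one_site(score_sets: Sequence[ScoreSet]) -> str:
    sites = {s.site_id for s in score_sets}
    if len(sites) != 1:
        raise ValidationError(f"expected scores for one site, got {sorted(sites)}")
    ids = [s.ligand_id for s in score_sets]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate ligand ids in score panel")
    return sites.pop()


def anova_tukey_cld(
    score_sets: Sequence[ScoreSet], alpha: float = 0.05
) -> TukeyGrouping:
    """One-way ANOVA over ligands (poses as replicates) plus all-pairs Tukey
    HSD, summarized as a compact letter display.

    Letters are assigned in order of ascending mean score (i.e. strongest
    predicted binders first, since lower is better) with the insert-and-absorb
    construction, so the display is deterministic.
    """
    score_sets = list(score_sets)
    if len(score_sets) < 2:
        raise ValidationError("need at least two ligands for ANOVA")
    if not (0.0 < alpha < 1.0):
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    _check_one_site(score_sets)
    for s in score_sets:
        if len(s.pose_scores) < 2:
            raise ValidationError(
                f"{s.ligand_id}: need >= 2 poses for within-ligand variance"
            )
    if all(np.var(s.pose_scores) == 0.0 for s in score_sets):
        raise DegenerateVarianceError(
            "all ligands have zero within-pose variance; Tukey HSD is "
            "undefined — jitter the scores or skip the test"
        )

    groups = [np.asarray(s.pose_scores, dtype=float) for s in score_sets]
    f_stat, p_value = stats.f_oneway(*groups)

    values = np.concatenate(groups)
    labels = np.concatenate(
        [[s.ligand_id] * len(s.pose_scores) for s in score_sets]
    )
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pair_frame = pd.DataFrame(
        tukey.summary().data[1:],
        columns=[str(c) for c in tukey.summary().data[0]],
    ).rename(
        columns={
            "group1": "ligand_1",
            "group2": "ligand_2",
            "meandiff": "mean_diff",
            "p-adj": "p_adj",
        }
    )[["ligand_1", "ligand_2", "mean_diff", "p_adj", "reject"]]
    pair_frame["reject"] = pair_frame["reject"].astype(bool)

    means = {s.ligand_id: s.mean for s in score_sets}
    significant = {
        frozenset((row.ligand_1, row.ligand_2))
        for row in pair_frame.itertuples()
        if row.reject
    }
    letters = _compact_letter_display(means, significant)
    return TukeyGrouping(
        means=means,
        letters=letters,
        f_statistic=float(f_stat),
        p_value=float(p_value),
        alpha=alpha,
        pairwise=pair_frame,
    )


def _compact_letter_display(
    means: Mapping[str, float], significant: set[frozenset]
) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Starts from one column holding every ligand; each significantly different
    pair splits every column containing both; columns that become subsets of
    another are absorbed. Letters are then assigned to columns sorted by the
    smallest member mean (ascending, ties by ligand id).
    """
    order = sorted(means, key=lambda lig: (means[lig], lig))
    columns: list[set[str]] = [set(order)]
    for pair in sorted(significant, key=lambda p: tuple(sorted(p))):
        a, b = sorted(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
            # absorb: drop any column contained in another
            columns = [
                c
                for i, c in enumerate(columns)
                if c
                and not any(
                    c < other or (c == other and i > j)
                    for j, other in enumerate(columns)
                    if j != i
                )
            ]
    rank = {lig: i for i, lig in enumerate(order)}
    columns.sort(key=lambda col: min(rank[lig] for lig in col))
    if len(columns) > len(_LETTERS):
        raise ValidationError("more than 26 letter groups; panel too fragmented")
    letters: dict[str, list[str]] = {lig: [] for lig in means}
    for letter, col in zip(_LETTERS, columns):
        for lig in col:
            letters[lig].append(letter)
    return {lig: "".join(sorted(ls)) for lig, ls in letters.items()}


# ---------------------------------------------------------------------------
# classification


def classify_compounds(
    grouping: TukeyGrouping, score_sets: Sequence[ScoreSet]
) -> TriageResult:
    """Label candidates TOP / MIDDLE / WORST against the control anchors.

    The anchors are the best (most negative mean) positive control and the
    worst (least negative mean) negative control. A candidate sharing a Tukey
    letter with the top anchor is TOP, with the worst anchor WORST, with
    neither MIDDLE; sharing with both resolves to the anchor with the smaller
    absolute mean difference (exact tie -> MIDDLE).
    """
    score_sets = list(score_sets)
    site = _check_one_site(score_sets)
    by_role: dict[Role, list[ScoreSet]] = {}
    for s in score_sets:
        by_role.setdefault(s.role, []).append(s)
    positives = by_role.get(Role.POSITIVE_CONTROL, [])
    negatives = by_role.get(Role.NEGATIVE_CONTROL, [])
    if not positives or not negatives:
        raise ValidationError(
            f"site {site}: need at least one positive and one negative control"
        )
    missing = [s.ligand_id for s in score_sets if s.ligand_id not in grouping.letters]
    if missing:
        raise ValidationError(
            f"site {site}: ligands missing from Tukey grouping: {missing} "
            "(controls and candidates must enter the ANOVA jointly)"
        )

    top_anchor = min(positives, key=lambda s: (s.mean, s.ligand_id))
    worst_anchor = max(negatives, key=lambda s: (s.mean, s.ligand_id))

    labels: dict[str, str] = {}
    for s in score_sets:
        if s.role is not Role.CANDIDATE:
            continue
        with_top = grouping.share_letter(s.ligand_id, top_anchor.ligand_id)
        with_worst = grouping.share_letter(s.ligand_id, worst_anchor.ligand_id)
        if with_top and with_worst:
            d_top = abs(s.mean - top_anchor.mean)
            d_worst = abs(s.mean - worst_anchor.mean)
            if d_top < d_worst:
                labels[s.ligand_id] = "TOP"
            elif d_worst < d_top:
                labels[s.ligand_id] = "WORST"
            else:
                labels[s.ligand_id] = "MIDDLE"
        elif with_top:
            labels[s.ligand_id] = "TOP"
        elif with_worst:
            labels[s.ligand_id] = "WORST"
        else:
            labels[s.ligand_id] = "MIDDLE"
    return TriageResult(
        site_id=site,
        labels=labels,
        anchor_top=(top_anchor.ligand_id, top_anchor.mean),
        anchor_worst=(worst_anchor.ligand_id, worst_anchor.mean),
        grouping=grouping,
    )


def triage_site(
    score_sets: Sequence[ScoreSet], alpha: float = 0.05
) -> TriageResult:
    """Convenience wrapper: ANOVA + Tukey CLD + anchor classification."""
    grouping = anova_tukey_cld(score_sets, alpha=alpha)
    return classify_compounds(grouping, score_sets)


def cross_site_overlap(results: Sequence[TriageResult]) -> OverlapResult:
    """Per-ligand label tuples across sites plus per-label set intersections.

    Also flags site-specific binders: ligands TOP at exactly one site and
    WORST at every other site.
    """
    results = list(results)
    if len(results) < 2:
        raise ValidationError("need results for at least two sites")
    sites = [r.site_id for r in results]
    if len(set(sites)) != len(sites):
        raise ValidationError(f"duplicate site ids: {sites}")
    universes = [set(r.labels) for r in results]
    if any(u != universes[0] for u in universes[1:]):
        details = {r.site_id: sorted(u) for r, u in zip(results, universes)}
        raise ValidationError(f"mismatched ligand universes across sites: {details}")

    per_ligand = {
        lig: {r.site_id: r.labels[lig] for r in results} for lig in universes[0]
    }
    label_sets = {
        label: {r.site_id: r.ligands(label) for r in results}
        for label in GROUP_LABELS
    }
    intersections: dict[str, dict[tuple[str, ...], set[str]]] = {}
    for label in GROUP_LABELS:
        intersections[label] = {}
        for k in range(2, len(sites) + 1):
            for combo in itertools.combinations(sites, k):
                common = set.intersection(*(label_sets[label][s] for s in combo))
                intersections[label][combo] = common
    site_specific = {}
    for lig, by_site in per_ligand.items():
        tops = [s for s, lab in by_site.items() if lab == "TOP"]
        worsts = [s for s, lab in by_site.items() if lab == "WORST"]
        if len(tops) == 1 and len(worsts) == len(sites) - 1:
            site_specific[lig] = tops[0]
    return OverlapResult(
        sites=sites,
        per_ligand=per_ligand,
        label_sets=label_sets,
        intersections=intersections,
        site_specific=site_specific,
    )


# ---------------------------------------------------------------------------
# group summaries


def _resolve_ligand(profile: VOCProfile, ligand_id: str):
    try:
        return profile.compound(int(ligand_id))
    except (ValueError, KeyError):
        pass
    try:
        return profile.compound(ligand_id)
    except KeyError:
        return None


def summarize_groups(
    results: TriageResult | Sequence[TriageResult],
    profile: VOCProfile,
    descriptors: "pd.DataFrame | None" = None,
    score_sets: Sequence[ScoreSet] | None = None,
) -> pd.DataFrame:
    """Per (site, group) statistics over the classified candidates.

    For each group: compound count, mean docking score, mean across-sample
    abundance (not-detected counted as zero), the mean of each descriptor
    column provided, and the chemical-class composition in percent (summing
    to 100 within each non-empty group). ``descriptors`` is indexed by ligand
    id (as used in the score tables).
    """
    if isinstance(results, TriageResult):
        results = [results]
    scores_by_key: dict[tuple[str, str], float] = {}
    if score_sets is not None:
        for s in score_sets:
            scores_by_key[(s.site_id, s.ligand_id)] = s.mean

    rows = []
    for result in results:
        unresolved = [
            lig for lig in result.labels if _resolve_ligand(profile, lig) is None
        ]
        if unresolved:
            raise ValidationError(
                f"site {result.site_id}: ligand ids not in profile: {sorted(unresolved)}"
            )
        for label in GROUP_LABELS:
            ligands = sorted(result.ligands(label))
            compounds = [_resolve_ligand(profile, lig) for lig in ligands]
            row: dict[str, object] = {
                "site_id": result.site_id,
                "group": label,
                "n_compounds": len(ligands),
                "ligands": ",".join(ligands),
            }
            if result.grouping is not None and ligands:
                row["mean_score"] = float(
                    np.mean([result.grouping.means[lig] for lig in ligands])
                )
            elif ligands and scores_by_key:
                row["mean_score"] = float(
                    np.mean([scores_by_key[(result.site_id, lig)] for lig in ligands])
                )
            else:
                row["mean_score"] = float("nan")
            row["mean_abundance"] = (
                float(np.mean([c.mean_abundance(profile.samples) for c in compounds]))
                if compounds
                else float("nan")
            )
            if descriptors is not None:
                for col in descriptors.columns:
                    present = [
                        lig for lig in ligands if lig in descriptors.index
                    ]
                    missing = set(ligands) - set(present)
                    if missing:
                        raise ValidationError(
                            f"site {result.site_id}: ligands missing from "
                            f"descriptor table: {sorted(missing)}"
                        )
                    row[f"mean_{col}"] = (
                        float(descriptors.loc[present, col].astype(float).mean())
                        if present
                        else float("nan")
                    )
            n = len(compounds)
            for chem_class in CHEM_CLASSES:
                k = sum(c.chem_class == chem_class for c in compounds)
                row[f"pct_{chem_class.lower()}"] = 100.0 * k / n if n else 0.0
            rows.append(row)
    return pd.DataFrame(rows)


def abundance_coverage(
    results: TriageResult | Sequence[TriageResult],
    profile: VOCProfile,
    groups: Sequence[str] = ("TOP", "MIDDLE"),
    across: str = "any",
) -> float | dict[str, float]:
    """Percent of total molar content carried by compounds in the given groups.

    Abundance is the across-sample mean with not-detected counted as zero.
    ``across="any"`` counts a compound once if it falls in ``groups`` at any
    site and returns a single percentage; ``across="per-site"`` returns one
    percentage per site. The aggregation is deliberately configurable — which
    rule underlies headline "percent of molar content able to bind" claims is
    a reporting choice, not a property of the data.
    """
    if isinstance(results, TriageResult):
        results = [results]
    bad = set(groups) - set(GROUP_LABELS)
    if bad:
        raise ValidationError(f"unknown group labels: {sorted(bad)}")
    total = sum(c.mean_abundance(profile.samples) for c in profile.compounds)

    def _pct(selected_ids: set[str]) -> float:
        mass = 0.0
        for lig in selected_ids:
            compound = _resolve_ligand(profile, lig)
            if compound is None:
                raise ValidationError(f"ligand id not in profile: {lig}")
            mass += compound.mean_abundance(profile.samples)
        return 100.0 * mass / total if total else 0.0

    if across == "any":
        selected: set[str] = set()
        for result in results:
            for label in groups:
                selected |= result.ligands(label)
        return _pct(selected)
    if across == "per-site":
        return {
            r.site_id: _pct(set().union(*(r.ligands(label) for label in groups)))
            for r in results
        }
    raise ValidationError(f"across must be 'any' or 'per-site', got {across!r}")
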