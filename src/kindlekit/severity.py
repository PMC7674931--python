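"""Seizure-severity (limbic index) scoring and group statistics.

The limbic index (LI) is the 0-8 ordinal seizure-severity scale of Racine as
modified by Pinel & Rovner, used to score kindled limbic seizures in rodents:

    0 immobility, 1 facial automatisms, 2 head myoclonus, 3 forelimb
    myoclonus, 4 rearing, 5 rearing and falling, 6 more than three fallings,
    7 wild running/jumping, 8 tonic-clonic seizure.

A scoring window (PRE / STIMULUS / POST around one electrical stimulus)
receives the *maximum* class realized by any behavior observed in it, which
is the standard kindling convention.  An animal is *fully kindled* once it
has shown at least two class-4 seizures or one class-5 (or worse) seizure
over the acquisition protocol.

Group comparisons are nonparametric: Mann-Whitney U between treatment
groups, and a Friedman test with Dunn's post-hoc across the repeated stimuli
of one cohort (severity scores are ordinal, so rank statistics throughout).
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "GROUPS",
    "PERIODS",
    "SeverityScale",
    "SeverityRecord",
    "classify_li",
    "is_fully_kindled",
    "compare_groups",
    "progression_test",
    "read_severity_csv",
    "write_severity_csv",
]

GROUPS = ("NoStim+Water", "Stim+Water", "NoStim+TMT", "Stim+TMT")
PERIODS = ("PRE", "STIMULUS", "POST")

#: Default mapping glossary code -> LI class.  Editable via YAML
#: (:meth:`SeverityScale.from_yaml`); descriptions follow the published scale.
_DEFAULT_SCALE: dict[int, tuple[str, tuple[str, ...]]] = {
    0: ("Immobility", ("IM",)),
    1: ("Facial automatism", ("EB", "MT")),
    2: ("Head myoclonia", ("MYO_h", "SH")),
    3: ("Forelimbs myoclonia", ("MYO_1",)),
    4: ("Rearing", ("REAR",)),
    5: ("Rearing and falling", ("FALL",)),
    6: ("More than three fallings", ("FALL_MULTIPLE",)),
    7: ("Running and/or jumping (wild running)", ("RU", "JP")),
    8: ("Tonic-clonic seizures", ("TC", "EXT")),
}

#: Number of FALL observations in one window that escalates class 5 to 6.
_FALL_ESCALATION_COUNT = 4


@dataclass(frozen=True)
class SeverityScale:
    """Ordered 0-8 severity scale with the glossary codes realizing each class."""

    entries: Mapping[int, tuple[str, tuple[str, ...]]] = field(
        default_factory=lambda: dict(_DEFAULT_SCALE)
    )

    def __post_init__(self) -> None:
        if sorted(self.entries) != list(range(9)):
            raise ValueError("severity scale must define exactly classes 0..8")
        for cls, (desc, codes) in self.entries.items():
            if not desc or not codes:
                raise ValueError(f"class {cls} needs a description and >=1 code")

    @property
    def code_to_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cls, (_, codes) in self.entries.items():
            for code in codes:
                out[code] = max(cls, out.get(code, 0))
        return out

    def description(self, li_class: int) -> str:
        return self.entries[li_class][0]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SeverityScale":
        """Load a scale from a YAML mapping ``class: {description, codes}``."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        entries = {
            int(k): (str(v["description"]), tuple(v["codes"])) for k, v in raw.items()
        }
        return cls(entries=entries)

    def to_yaml(self, path: str | Path) -> None:
        raw = {
            cls: {"description": desc, "codes": list(codes)}
            for cls, (desc, codes) in sorted(self.entries.items())
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(raw, fh, sort_keys=True)


@dataclass(frozen=True)
class SeverityRecord:
    """One LI score for one animal at one stimulus and period."""

    animal_id: str
    group: str
    stimulus_index: int
    period: str
    li_class: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if self.period not in PERIODS:
            raise ValueError(f"unknown period {self.period!r}; expected one of {PERIODS}")
        if not 1 <= self.stimulus_index <= 21:
            raise ValueError(f"stimulus_index {self.stimulus_index} outside 1..21")
        if not 0 <= self.li_class <= 8:
            raise ValueError(f"li_class {self.li_class} outside 0..8")


def classify_li(
    observed_codes: Iterable[str], scale: SeverityScale | None = None
) -> int:
    """Classify one observation window on the 0-8 limbic index.

    Returns the maximum class whose realizing behaviors intersect the
    observed codes.  ``observed_codes`` may carry repeats; four or more
    fallings in one window escalate class 5 (rearing and falling) to
    class 6 (more than three fallings).  An empty observation scores 0.

    Raises ``ValueError`` for a code absent from the scale's glossary.
    """
    scale = scale or SeverityScale()
    mapping = scale.code_to_class
    codes = list(observed_codes)
    best = 0
    for code in codes:
        if code not in mapping:
            raise ValueError(f"unknown behavior code {code!r}: not in the severity glossary")
        best = max(best, mapping[code])
    if best == 5 and codes.count("FALL") >= _FALL_ESCALATION_COUNT:
        best = 6
    return best


def is_fully_kindled(records: Sequence[SeverityRecord | int]) -> bool:
    """Whether one animal's protocol scores meet the fully-kindled criterion.

    True iff the animal showed at least two class-4 seizures or at least one
    seizure of class 5 or above across the supplied stimuli.  Accepts either
    :class:`SeverityRecord` objects or bare LI integers.  An empty record
    list warns and returns False.
    """
    if len(records) == 0:
        warnings.warn("no severity records supplied; animal treated as not kindled")
        return False
    scores = [r.li_class if isinstance(r, SeverityRecord) else int(r) for r in records]
    return scores.count(4) >= 2 or sum(s >= 5 for s in scores) >= 1


def compare_groups(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> dict[str, float]:
    """Two-sided Mann-Whitney U between two independent score samples.

    Returns the U statistic of the first sample (number of pairs where a
    beats b, ties counted 1/2) and the two-sided p-value.  Exact null
    distribution when both samples have n <= 8 and no ties; otherwise the
    normal approximation with mid-rank tie correction and no continuity
    correction (so exchangeable samples give p = 1).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty for a Mann-Whitney comparison")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    p = float(res.pvalue)
    if np.isnan(p):  # fully tied data: zero rank variance, no evidence
        p = 1.0
    return {"U": float(res.statistic), "p": min(p, 1.0)}


def _friedman_from_ranks(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square with mid-ranks and tie correction.

    Fully tied data (every animal constant across stimuli) is defined as
    statistic 0, p 1 rather than the indeterminate 0/0 of the textbook
    tie-corrected formula.
    """
    n, k = matrix.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    col_sums = ranks.sum(axis=0)
    uncorrected = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t)/(n k (k^2-1)) over tie groups per row
    tie_term = 0.0
    for row in matrix:
        _, counts = np.unique(row, return_counts=True)
        tie_term += float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_term / (n * k * (k**2 - 1))
    if correction <= 0:
        return 0.0, 1.0
    statistic = uncorrected / correction
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df=k - 1))
    return float(statistic), p


def progression_test(score_matrix: np.ndarray | pd.DataFrame) -> dict[str, object]:
    """Friedman test + Dunn's post-hoc over repeated stimuli of one cohort.

    ``score_matrix`` is animals x stimuli (complete; missing cells are an
    error, imputation is out of scope).  Returns the tie-corrected Friedman
    chi-square on within-animal ranks, its p-value, and a Dunn pairwise
    table (z statistic and Bonferroni-adjusted two-sided p for every
    stimulus pair).
    """
    if isinstance(score_matrix, pd.DataFrame):
        columns = list(score_matrix.columns)
        matrix = score_matrix.to_numpy(dtype=float)
    else:
        matrix = np.asarray(score_matrix, dtype=float)
        columns = list(range(1, matrix.shape[1] + 1)) if matrix.ndim == 2 else []
    if matrix.ndim != 2 or matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("score matrix must be 2-D with >=2 animals and >=2 stimuli")
    if not np.isfinite(matrix).all():
        raise ValueError("score matrix contains missing cells; complete data required")

    n, k = matrix.shape
    statistic, p = _friedman_from_ranks(matrix)

    ranks = np.apply_along_axis(stats.rankdata, 1, matrix)
    mean_ranks = ranks.mean(axis=0)
    se = np.sqrt(k * (k + 1) / (6.0 * n))
    n_pairs = k * (k - 1) // 2
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append(
                {
                    "stimulus_a": columns[i],
                    "stimulus_b": columns[j],
                    "z": float(z),
                    "p_adjusted": float(min(1.0, p_raw * n_pairs)),
                }
            )
    dunn = pd.DataFrame(rows)
    return {"statistic": statistic, "p": p, "dunn": dunn}


_SEVERITY_COLUMNS = ["animal_id", "group", "stimulus_index", "period", "li_class"]


def read_severity_csv(path: str | Path) -> list[SeverityRecord]:
    """Read severity records from a headered UTF-8 CSV."""
    frame = pd.read_csv(path, dtype={"animal_id": str})
    missing = [c for c in _SEVERITY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"severity CSV {path} lacks required columns: {missing}")
    return [
        SeverityRecord(
            animal_id=str(row.animal_id),
            group=str(row.group),
            stimulus_index=int(row.stimulus_index),
            period=str(row.period),
            li_class=int(row.li_class),
        )
        for row in frame.itertuples(index=False)
    ]


def write_severity_csv(records: Sequence[SeverityRecord], path: str | Path) -> None:
    frame = pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "group": r.group,
                "stimulus_index": r.stimulus_index,
                "period": r.period,
                "li_class": r.li_class,
            }
            for r in records
        ],
        columns=_SEVERITY_COLUMNS,
    )
    frame.to_csv(path, index=False)
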