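"""Likert questionnaire scoring into experience dimensions.

Dimension scores are arithmetic means of the items mapped to each
dimension; the bundled default map is a non-normative template (the real
instrument's item assignment is licensed separately — supply your own JSON
map for published work). The item scale is configurable; the default
anchors run 0 ("not at all") to 4 ("extremely").

Dimension comparison uses the paired Wilcoxon signed-rank test by default
(ordinal data), with a paired t-test as an option. All-zero differences are
a reported degenerate case, not an error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "CORE_DIMENSIONS",
    "SOCIAL_PRESENCE_DIMENSIONS",
    "DimensionMap",
    "default_dimension_map",
    "ComparisonResult",
    "score_dimensions",
    "compare_dimensions",
    "GEQError",
]

CORE_DIMENSIONS = (
    "competence",
    "sensory and imaginative immersion",
    "flow",
    "tension/annoyance",
    "challenge",
    "negative affect",
    "positive affect",
)
SOCIAL_PRESENCE_DIMENSIONS = (
    "psychological involvement - empathy",
    "psychological involvement - negative feelings",
    "behavioral involvement",
)


class GEQError(ValueError):
    pass


@dataclass(frozen=True)
class DimensionMap:
    """dimension name -> item ids; items may not overlap unless flagged."""

    dimensions: Mapping[str, tuple[str, ...]]
    scale_min: int = 0
    scale_max: int = 4
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.scale_min >= self.scale_max:
            raise GEQError("scale_min must be below scale_max")
        if not self.allow_overlap:
            seen: dict[str, str] = {}
            for dim, items in self.dimensions.items():
                for item in items:
                    if item in seen:
                        raise GEQError(f"item {item!r} mapped to both {seen[item]!r} and {dim!r}")
                    seen[item] = dim

    @property
    def items(self) -> set[str]:
        return {i for items in self.dimensions.values() for i in items}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "scale_min": self.scale_min,
                    "scale_max": self.scale_max,
                    "allow_overlap": self.allow_overlap,
                    "dimensions": {k: list(v) for k, v in self.dimensions.items()},
                },
                indent=2,
            )
            + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "DimensionMap":
        doc = json.loads(Path(path).read_text())
        return cls(
            dimensions={k: tuple(v) for k, v in doc["dimensions"].items()},
            scale_min=int(doc.get("scale_min", 0)),
            scale_max=int(doc.get("scale_max", 4)),
            allow_overlap=bool(doc.get("allow_overlap", False)),
        )


def default_dimension_map(items_per_dimension: int = 3) -> DimensionMap:
    """Template map: generic item ids, three items per dimension."""
    dims = {}
    for i, d in enumerate([*CORE_DIMENSIONS, *SOCIAL_PRESENCE_DIMENSIONS], start=1):
        dims[d] = tuple(f"item_{i:02d}_{j}" for j in range(1, items_per_dimension + 1))
    return DimensionMap(dims)


def score_dimensions(
    responses: pd.DataFrame,
    dim_map: DimensionMap,
) -> pd.DataFrame:
    """Mean item score per respondent per dimension.

    ``responses`` is long-format with columns respondent_id, item_id, score
    (and optionally modality). Missing items leave the dimension scored over
    the available items with ``<dimension>__incomplete`` set.
    """
    required = {"respondent_id", "item_id", "score"}
    if not required.issubset(responses.columns):
        raise GEQError(f"responses need columns {sorted(required)}")
    unknown = set(responses["item_id"]) - dim_map.items
    if unknown:
        raise GEQError(f"items not in dimension map: {sorted(unknown)}")
    bad = responses[
        (responses["score"] < dim_map.scale_min) | (responses["score"] > dim_map.scale_max)
    ]
    if not bad.empty:
        raise GEQError(
            f"scores outside [{dim_map.scale_min}, {dim_map.scale_max}] "
            f"for respondents {sorted(bad['respondent_id'].unique())}"
        )
    rows = []
    for rid, grp in responses.groupby("respondent_id", sort=True):
        scores = dict(zip(grp["item_id"], grp["score"]))
        row: dict = {"respondent_id": rid}
        if "modality" in responses.columns:
            row["modality"] = grp["modality"].iloc[0]
        for dim, items in dim_map.dimensions.items():
            avail = [scores[i] for i in items if i in scores]
            row[dim] = float(np.mean(avail)) if avail else np.nan
            row[f"{dim}__incomplete"] = len(avail) < len(items)
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ComparisonResult:
    dim_a: str
    dim_b: str
    test: str
    statistic: float
    pvalue: float
    n: int
    direction: str  # "a>b", "a<b", or "equal"
    degenerate: bool = False


def compare_dimensions(
    scores: pd.DataFrame,
    dim_a: str,
    dim_b: str,
    test: str = "wilcoxon",
) -> ComparisonResult:
    """Paired comparison of two dimension score columns."""
    for d in (dim_a, dim_b):
        if d not in scores.columns:
            raise GEQError(f"dimension {d!r} not in scores")
    a = scores[dim_a].to_numpy(dtype=float)
    b = scores[dim_b].to_numpy(dtype=float)
    mask = ~(np.isnan(a) | np.isnan(b))
    a, b = a[mask], b[mask]
    if len(a) < 2:
        raise GEQError("need at least 2 paired observations")
    diff = a - b
    direction = "a>b" if diff.mean() > 0 else ("a<b" if diff.mean() < 0 else "equal")
    if np.all(diff == 0):
        return ComparisonResult(dim_a, dim_b, test, 0.0, 1.0, len(a), "equal", degenerate=True)
    if test == "wilcoxon":
        res = stats.wilcoxon(a, b)
        return ComparisonResult(dim_a, dim_b, test, float(res.statistic), float(res.pvalue), len(a), direction)
    if test == "ttest":
        res = stats.ttest_rel(a, b)
        return ComparisonResult(dim_a, dim_b, test, float(res.statistic), float(res.pvalue), len(a), direction)
    raise GEQError(f"unknown test {test!r}")
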