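"""Design-matrix terms for the survey regression models.

A :class:`TermBlock` maps one survey variable to one or more design-matrix
columns.  Continuous variables map to a single column; categorical variables
map to a treatment-coded dummy block (reference level omitted) that is
included or excluded from candidate models as a unit, mirroring how whole
covariate blocks are reported in the results tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["TermBlock", "design_matrix", "default_blocks", "SURVEY_CATEGORICALS"]

#: Fixed level orderings (first level = reference) for the categorical
#: survey variables.
SURVEY_CATEGORICALS: dict[str, tuple[str, ...]] = {
    "gender": ("male", "female"),
    "language": ("english", "other"),
    "education": ("gcse", "alevel", "undergrad", "postgrad"),
    "time_outdoors": ("less", "same", "more"),
    "self_health": ("1", "2", "3", "4", "5"),
}


@dataclass(frozen=True)
class TermBlock:
    """One survey variable as a unit of model-subset inclusion."""

    name: str
    source: str
    kind: str = "continuous"  # or "categorical"
    levels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("continuous", "categorical"):
            raise ValueError(f"unknown term kind {self.kind!r}")
        if self.kind == "categorical" and len(self.levels) < 2:
            raise ValueError(f"categorical block {self.name!r} needs >= 2 levels")

    @property
    def columns(self) -> tuple[str, ...]:
        """Design-column names contributed by this block."""
        if self.kind == "continuous":
            return (self.source,)
        return tuple(f"{self.source}[{lvl}]" for lvl in self.levels[1:])

    def build(self, df: pd.DataFrame) -> pd.DataFrame:
        if self.kind == "continuous":
            return df[[self.source]].astype(float)
        col = df[self.source].astype(str)
        unknown = set(col.unique()) - set(self.levels)
        if unknown:
            raise ValueError(
                f"{self.source!r} contains levels {sorted(unknown)} outside "
                f"the declared set {self.levels}"
            )
        out = pd.DataFrame(index=df.index)
        for lvl in self.levels[1:]:
            out[f"{self.source}[{lvl}]"] = (col == lvl).astype(float)
        return out


def continuous(name: str, source: str | None = None) -> TermBlock:
    return TermBlock(name=name, source=source or name, kind="continuous")


def categorical(name: str, source: str | None = None, levels=None) -> TermBlock:
    src = source or name
    return TermBlock(
        name=name,
        source=src,
        kind="categorical",
        levels=tuple(levels) if levels else SURVEY_CATEGORICALS[src],
    )


def design_matrix(
    df: pd.DataFrame, blocks: tuple[TermBlock, ...], add_intercept: bool = True
) -> pd.DataFrame:
    """Assemble the design matrix for a set of term blocks."""
    parts = []
    if add_intercept:
        parts.append(pd.DataFrame({"Intercept": np.ones(len(df))}, index=df.index))
    for block in blocks:
        parts.append(block.build(df))
    if not parts:
        return pd.DataFrame(index=df.index)
    return pd.concat(parts, axis=1)


def default_blocks() -> dict[str, TermBlock]:
    """Term blocks for the standard survey schema, keyed by block name."""
    blocks = [
        continuous("age"),
        categorical("gender"),
        continuous("children"),
        categorical("language"),
        continuous("workdays"),
        continuous("income"),
        categorical("education"),
        categorical("time_outdoors"),
        # health outcomes usable as predictors of other outcomes
        continuous("exercise_days"),
        continuous("social_cohesion"),
        continuous("nature_relatedness"),
        categorical("self_health"),
        # the three nature doses
        continuous("frequency", source="freq_visits_per_week"),
        continuous("duration", source="duration_min_per_week"),
        continuous("intensity", source="vegetation_cover_pct"),
    ]
    return {b.name: b for b in blocks}
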