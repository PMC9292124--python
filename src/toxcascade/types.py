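"""Core domain types for the time-concordance pipeline.

The pipeline reasons about *time series* — one (compound, dose_level)
trajectory sampled at a handful of timepoints, each with treated and
matched vehicle-control replicates — and about *events*: directional
(up/down) changes of a gene, pathway, TF regulon activity or TF
expression within a time series.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TimeSeriesKey",
    "EventKey",
    "SampleSheet",
    "ExpressionData",
    "GeneSetCollection",
    "InteractionNetwork",
    "LEVELS",
    "DIRECTIONS",
]

LEVELS = ("gene", "pathway", "tf_activity", "tf_expression")
DIRECTIONS = ("up", "down")


class ValidationError(ValueError):
    """Raised when an input file or container violates a structural contract."""


class TimeSeriesKey(NamedTuple):
    """Identity of one time series: a compound-dose trajectory over all timepoints."""

    compound: str
    dose_level: str


class EventKey(NamedTuple):
    """Identity of a directional event."""

    entity: str
    level: str  # one of LEVELS
    direction: str  # "up" | "down"

    def label(self) -> str:
        return f"{self.entity}|{self.level}|{self.direction}"


SHEET_COLUMNS = ["sample_id", "compound", "dose_level", "time_h", "replicate", "is_control"]


@dataclasses.dataclass
class SampleSheet:
    """Sample annotations: compound, ordinal dose level, time in hours post
    first dose, replicate index and a vehicle-control flag.

    Dose levels are ordinal labels; the pipeline never compares doses
    numerically. Time is a non-negative real number of hours.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        missing = [c for c in SHEET_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df = df.copy()
        df["sample_id"] = df["sample_id"].astype(str)
        df["compound"] = df["compound"].astype(str)
        df["dose_level"] = df["dose_level"].astype(str)
        df["time_h"] = df["time_h"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        df["is_control"] = df["is_control"].astype(bool)
        if df["sample_id"].duplicated().any():
            dupes = sorted(df.loc[df["sample_id"].duplicated(), "sample_id"])
            raise ValidationError(f"duplicate sample_ids in sheet: {dupes}")
        if (df["time_h"] < 0).any():
            raise ValidationError("time_h must be non-negative")
        if (df["replicate"] < 1).any():
            raise ValidationError("replicate indices must be positive")
        # every treated (compound, time) needs a matched vehicle control
        treated = df.loc[~df["is_control"], ["compound", "time_h"]].drop_duplicates()
        ctrl = set(map(tuple, df.loc[df["is_control"], ["compound", "time_h"]].itertuples(index=False)))
        unmatched = [t for t in map(tuple, treated.itertuples(index=False)) if t not in ctrl]
        if unmatched:
            raise ValidationError(
                "treated conditions without a matched vehicle control at the same "
                f"compound and time: {sorted(unmatched)[:10]}"
            )
        object.__setattr__(self, "frame", df)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def series_keys(self, min_timepoints: int = 1) -> list[TimeSeriesKey]:
        """All (compound, dose_level) time series among non-control samples
        with at least ``min_timepoints`` measured timepoints."""
        tr = self.frame.loc[~self.frame["is_control"]]
        counts = tr.groupby(["compound", "dose_level"])["time_h"].nunique()
        return [TimeSeriesKey(*k) for k, n in counts.items() if n >= min_timepoints]


@dataclasses.dataclass
class ExpressionData:
    """A log2-scale gene x sample matrix plus its sample sheet."""

    matrix: pd.DataFrame  # genes x samples
    sheet: SampleSheet

    def __post_init__(self) -> None:
        m = self.matrix
        if m.index.duplicated().any():
            dupes = sorted(set(m.index[m.index.duplicated()]))
            raise ValidationError(f"duplicate gene symbols in matrix: {dupes[:10]}")
        sheet_ids = self.sheet.sample_ids
        absent = [s for s in sheet_ids if s not in m.columns]
        if absent:
            raise ValidationError(f"sheet references absent sample columns: {absent[:10]}")
        extra = [c for c in m.columns if c not in set(sheet_ids)]
        if extra:
            raise ValidationError(f"matrix columns missing from sheet: {extra[:10]}")
        if not np.isfinite(m.to_numpy(dtype=float)).all():
            raise ValidationError("expression matrix contains non-finite values")
        # canonical column order = sheet order
        object.__setattr__(self, "matrix", m.loc[:, sheet_ids].astype(float))

    @property
    def genes(self) -> list[str]:
        return list(self.matrix.index)

    def subset_compound(self, compound: str) -> "ExpressionData":
        """The per-compound sample universe (all doses, timepoints and vehicle
        controls of one treatment) used for activity scoring."""
        sub = self.sheet.frame.loc[self.sheet.frame["compound"] == compound]
        return ExpressionData(self.matrix.loc[:, list(sub["sample_id"])], SampleSheet(sub))


@dataclasses.dataclass
class GeneSetCollection:
    """Named gene sets (pathway maps or TF regulons).

    ``signs`` optionally carries a per-member mode of regulation for regulons
    (+1 activating / -1 repressing); repressing members are removed before
    scoring so that regulon score direction equals TF activity direction.
    ``confidence`` optionally grades each set (regulon confidence A-E).
    """

    sets: dict[str, frozenset[str]]
    kind: str = "pathway"  # "pathway" | "regulon"
    confidence: dict[str, str] = dataclasses.field(default_factory=dict)
    signs: dict[str, Mapping[str, int]] = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("pathway", "regulon"):
            raise ValidationError(f"unknown gene set kind: {self.kind!r}")
        self.sets = {name: frozenset(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def drop_negative_members(self) -> "GeneSetCollection":
        """Remove members with a negative mode of regulation (regulons only)."""
        if not self.signs:
            return self
        new_sets = {}
        for name, members in self.sets.items():
            sg = self.signs.get(name, {})
            new_sets[name] = frozenset(g for g in members if sg.get(g, 1) >= 0)
        return GeneSetCollection(new_sets, self.kind, dict(self.confidence), {})

    def filter_to_universe(
        self, universe: Iterable[str], min_size: int = 5
    ) -> tuple["GeneSetCollection", list[str]]:
        """Intersect each set with the expression universe and drop sets below
        ``min_size`` retained members. Returns (filtered collection, dropped names)."""
        uni = set(universe)
        kept: dict[str, frozenset[str]] = {}
        dropped: list[str] = []
        for name, members in self.sets.items():
            inter = frozenset(m for m in members if m in uni)
            if len(inter) >= min_size:
                kept[name] = inter
            else:
                dropped.append(name)
        conf = {k: v for k, v in self.confidence.items() if k in kept}
        signs = {k: v for k, v in self.signs.items() if k in kept}
        return GeneSetCollection(kept, self.kind, conf, signs), dropped

    def filter_confidence(self, allowed: Iterable[str] = ("A", "B", "C")) -> "GeneSetCollection":
        """Keep only sets whose confidence grade is in ``allowed`` (sets without
        a grade are kept)."""
        allowed = set(allowed)
        kept = {
            name: members
            for name, members in self.sets.items()
            if self.confidence.get(name) is None or self.confidence[name] in allowed
        }
        return GeneSetCollection(
            kept,
            self.kind,
            {k: v for k, v in self.confidence.items() if k in kept},
            {k: v for k, v in self.signs.items() if k in kept},
        )


EDGE_COLUMNS = ["source", "target", "sign", "kind", "confidence", "provenance"]
EDGE_KINDS = ("ppi", "tf_target")


@dataclasses.dataclass
class InteractionNetwork:
    """Signed, directed prior-knowledge interactions between entities."""

    edges: pd.DataFrame  # columns EDGE_COLUMNS, sign in {+1,-1}

    def __post_init__(self) -> None:
        df = self.edges.copy()
        for c in EDGE_COLUMNS:
            if c not in df.columns:
                df[c] = "" if c in ("confidence", "provenance") else np.nan
        df = df[EDGE_COLUMNS]
        df["sign"] = df["sign"].astype(int)
        if not df["sign"].isin([1, -1]).all():
            raise ValidationError("edge signs must be +1 or -1")
        bad = sorted(set(df["kind"]) - set(EDGE_KINDS))
        if bad:
            raise ValidationError(f"unknown interaction kinds: {bad}")
        object.__setattr__(self, "edges", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.edges)
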