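"""Data model and I/O for temporal-dominance-of-sensations (TDS) records.

A TDS experiment records, for each panelist, which attribute (taste or
mouthfeel) dominates at each second of tasting.  The natural compressed form
is a run-length encoding: an ordered list of (attribute, duration) spells.
This module provides the attribute scheme (attributes partitioned into
groups that share duration-model parameters), the per-panelist sequence
container, the panelist covariate table, and the duration table
``Y[i, j, c]`` (the c-th dominance duration of attribute j by panelist i)
with its count matrix ``C[i, j]``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TDSDataError",
    "ZeroVarianceError",
    "AttributeScheme",
    "TDSSequence",
    "CovariateTable",
    "DurationTable",
    "chocolate_scheme",
    "read_sequences",
    "write_sequences",
    "extract_durations",
    "preprocess_covariates",
]


class TDSDataError(ValueError):
    """Malformed TDS input (bad durations, unknown labels, time gaps...)."""


class ZeroVarianceError(TDSDataError):
    """A covariate column cannot be normalized (no variance among retained panelists)."""

    def __init__(self, column: str):
        self.column = column
        super().__init__(
            f"covariate column {column!r} has zero variance among retained "
            "panelists and cannot be scaled to unit standard deviation"
        )


# ---------------------------------------------------------------------------
# attribute scheme


@dataclass(frozen=True)
class AttributeScheme:
    """J attribute labels partitioned into G nonempty groups.

    Attributes in the same group share regression coefficients and shape
    parameters in the grouped duration models.  Group indices are 0-based
    internally and contiguous (0..G-1).

    Parameters
    ----------
    labels:
        Attribute names, in display order.
    group_of:
        For each attribute, the 0-based index of its group.
    group_names:
        Optional display names for the groups (e.g. roman numerals).
    """

    labels: tuple[str, ...]
    group_of: tuple[int, ...]
    group_names: tuple[str, ...] = ()

    def __post_init__(self):
        if len(self.labels) < 1:
            raise TDSDataError("attribute scheme needs at least one attribute")
        if len(set(self.labels)) != len(self.labels):
            raise TDSDataError("duplicate attribute labels")
        if len(self.group_of) != len(self.labels):
            raise TDSDataError("group_of must assign every attribute to a group")
        groups = sorted(set(self.group_of))
        n_groups = len(groups)
        if groups != list(range(n_groups)):
            raise TDSDataError("group indices must be contiguous starting at 0")
        names = self.group_names or tuple(str(g + 1) for g in range(n_groups))
        if len(names) != n_groups:
            raise TDSDataError("group_names length must equal the number of groups")
        object.__setattr__(self, "group_names", tuple(names))
        object.__setattr__(self, "_index", {lab: k for k, lab in enumerate(self.labels)})

    @property
    def n_attributes(self) -> int:
        return len(self.labels)

    @property
    def n_groups(self) -> int:
        return len(self.group_names)

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise TDSDataError(f"unknown attribute label {label!r}") from None

    def members(self, group: int) -> tuple[int, ...]:
        """Attribute indices belonging to ``group``."""
        return tuple(j for j, g in enumerate(self.group_of) if g == group)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "attribute": self.labels,
                "group": [self.group_names[g] for g in self.group_of],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "AttributeScheme":
        if not {"attribute", "group"} <= set(frame.columns):
            raise TDSDataError("attribute scheme needs columns 'attribute' and 'group'")
        labels = tuple(str(a) for a in frame["attribute"])
        raw_groups = [str(g) for g in frame["group"]]
        names: list[str] = []
        idx = []
        for g in raw_groups:
            if g not in names:
                names.append(g)
            idx.append(names.index(g))
        return cls(labels=labels, group_of=tuple(idx), group_names=tuple(names))

    @classmethod
    def from_csv(cls, path: str | Path) -> "AttributeScheme":
        return cls.from_frame(pd.read_csv(path, dtype=str))


def chocolate_scheme() -> AttributeScheme:
    """The nine milk-chocolate attributes in four groups.

    Groups: I bitterness (Cacao, Roast), II sweetness (Cocoa, Milk, Vanilla,
    Caramel), III mouthfeel (Nutty, Cohesiveness), IV Richness.
    """
    return AttributeScheme(
        labels=(
            "Cacao",
            "Roast",
            "Cocoa",
            "Milk",
            "Vanilla",
            "Caramel",
            "Nutty",
            "Cohesiveness",
            "Richness",
        ),
        group_of=(0, 0, 1, 1, 1, 1, 2, 2, 3),
        group_names=("I", "II", "III", "IV"),
    )


# ---------------------------------------------------------------------------
# sequences


def _merge_runs(pairs: Iterable[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    merged: list[list[int]] = []
    for attr, dur in pairs:
        if merged and merged[-1][0] == attr:
            merged[-1][1] += dur
        else:
            merged.append([attr, dur])
    return tuple((a, d) for a, d in merged)


@dataclass(frozen=True)
class TDSSequence:
    """One panelist's ordered dominance spells.

    ``runs`` is a tuple of (attribute_index, duration) pairs; durations are
    positive integer seconds and consecutive runs carry distinct attributes
    (re-selections of the same attribute are merged at construction).
    """

    panelist_id: str
    runs: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.runs:
            raise TDSDataError(f"panelist {self.panelist_id!r}: empty sequence")
        for attr, dur in self.runs:
            if not (isinstance(dur, (int, np.integer)) and dur >= 1):
                raise TDSDataError(
                    f"panelist {self.panelist_id!r}: duration {dur!r} is not a positive integer"
                )
            if not isinstance(attr, (int, np.integer)) or attr < 0:
                raise TDSDataError(
                    f"panelist {self.panelist_id!r}: bad attribute index {attr!r}"
                )
        for (a1, _), (a2, _) in itertools.pairwise(self.runs):
            if a1 == a2:
                raise TDSDataError(
                    f"panelist {self.panelist_id!r}: consecutive runs share an attribute; "
                    "merge before constructing"
                )

    @classmethod
    def from_runs(
        cls, panelist_id: str, pairs: Iterable[tuple[int, int]]
    ) -> "TDSSequence":
        """Build a sequence, merging consecutive runs of the same attribute."""
        return cls(panelist_id=str(panelist_id), runs=_merge_runs(pairs))

    @classmethod
    def from_states(cls, panelist_id: str, states: Sequence[int]) -> "TDSSequence":
        """Build from a per-second vector of attribute indices (1 s resolution)."""
        return cls.from_runs(panelist_id, ((int(s), 1) for s in states))

    @property
    def length(self) -> int:
        """Total duration in seconds."""
        return sum(d for _, d in self.runs)

    def states(self) -> np.ndarray:
        """Expand to the per-second attribute index vector (length ``self.length``)."""
        return np.repeat([a for a, _ in self.runs], [d for _, d in self.runs])

    def attribute_at(self, second: int) -> int:
        """Attribute dominant at 1-based ``second`` (inclusive run boundaries)."""
        if not 1 <= second <= self.length:
            raise TDSDataError(
                f"second {second} outside 1..{self.length} for panelist {self.panelist_id!r}"
            )
        t = 0
        for attr, dur in self.runs:
            t += dur
            if second <= t:
                return attr
        raise AssertionError("unreachable")


def _as_positive_int(value, *, what: str, row: int) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise TDSDataError(f"row {row}: {what} {value!r} is not an integer") from None
    if not np.isfinite(f) or f != int(f):
        raise TDSDataError(f"row {row}: {what} {value!r} is not an integer")
    iv = int(f)
    if iv < 1:
        raise TDSDataError(f"row {row}: {what} must be >= 1, got {iv}")
    return iv


def read_sequences(
    path: str | Path, scheme: AttributeScheme, format: str = "runs"
) -> list[TDSSequence]:
    """Read TDS sequences from CSV.

    ``format="runs"`` expects columns ``panelist,attribute,duration`` (one
    row per dominance spell).  ``format="long"`` expects
    ``panelist,time_sec,attribute`` with one row per second and times
    consecutive from 1 within each panelist.  In both formats consecutive
    identical attributes are merged into a single run, and panelists appear
    in the output in order of first appearance.

    Row numbers in error messages count the header as row 1.
    """
    frame = pd.read_csv(path, dtype=str)
    if format == "runs":
        required = {"panelist", "attribute", "duration"}
    elif format == "long":
        required = {"panelist", "time_sec", "attribute"}
    else:
        raise ValueError(f"format must be 'runs' or 'long', got {format!r}")
    if not required <= set(frame.columns):
        raise TDSDataError(f"missing columns: {sorted(required - set(frame.columns))}")

    per_panelist: dict[str, list[tuple[int, int]]] = {}
    if format == "runs":
        for pos, rec in enumerate(frame.itertuples(index=False)):
            row = pos + 2  # header is row 1
            attr = scheme.index_of(str(rec.attribute))
            dur = _as_positive_int(rec.duration, what="duration", row=row)
            per_panelist.setdefault(str(rec.panelist), []).append((attr, dur))
    else:
        last_time: dict[str, int] = {}
        for pos, rec in enumerate(frame.itertuples(index=False)):
            row = pos + 2
            pid = str(rec.panelist)
            t = _as_positive_int(rec.time_sec, what="time_sec", row=row)
            expected = last_time.get(pid, 0) + 1
            if t != expected:
                raise TDSDataError(
                    f"row {row}: panelist {pid!r} time_sec {t} breaks the "
                    f"consecutive 1,2,... sequence (expected {expected})"
                )
            last_time[pid] = t
            attr = scheme.index_of(str(rec.attribute))
            per_panelist.setdefault(pid, []).append((attr, 1))

    return [TDSSequence.from_runs(pid, pairs) for pid, pairs in per_panelist.items()]


def write_sequences(
    path: str | Path,
    sequences: Sequence[TDSSequence],
    scheme: AttributeScheme,
    format: str = "runs",
) -> None:
    """Write sequences to CSV in either dialect accepted by :func:`read_sequences`."""
    rows = []
    if format == "runs":
        for seq in sequences:
            for attr, dur in seq.runs:
                rows.append((seq.panelist_id, scheme.labels[attr], dur))
        pd.DataFrame(rows, columns=["panelist", "attribute", "duration"]).to_csv(
            path, index=False
        )
    elif format == "long":
        for seq in sequences:
            for t, attr in enumerate(seq.states(), start=1):
                rows.append((seq.panelist_id, t, scheme.labels[attr]))
        pd.DataFrame(rows, columns=["panelist", "time_sec", "attribute"]).to_csv(
            path, index=False
        )
    else:
        raise ValueError(f"format must be 'runs' or 'long', got {format!r}")


# ---------------------------------------------------------------------------
# duration table


@dataclass
class DurationTable:
    """All observed dominance durations Y[i, j, c] in long form.

    ``frame`` has one row per dominance spell with columns ``panelist``,
    ``attribute`` (label), ``attribute_index``, ``group`` (0-based),
    ``occurrence`` (1-based c, in temporal order within panelist/attribute)
    and ``duration`` (seconds).  ``C[i, j]``, the number of spells of
    attribute j by panelist i, is exposed through :meth:`counts`.
    """

    frame: pd.DataFrame
    panelists: tuple[str, ...]
    scheme: AttributeScheme

    @property
    def n_durations(self) -> int:
        return len(self.frame)

    def counts(self) -> pd.DataFrame:
        """Count matrix ``C`` as a panelist x attribute DataFrame of ints."""
        table = (
            self.frame.groupby(["panelist", "attribute"], sort=False)
            .size()
            .unstack(fill_value=0)
        )
        table = table.reindex(
            index=list(self.panelists), columns=list(self.scheme.labels), fill_value=0
        )
        return table.astype(int)

    def durations(self, panelist: str, attribute: str) -> np.ndarray:
        """Y[i, j, .] for one panelist/attribute, in temporal order."""
        mask = (self.frame["panelist"] == panelist) & (
            self.frame["attribute"] == attribute
        )
        return self.frame.loc[mask].sort_values("occurrence")["duration"].to_numpy()


def extract_durations(
    sequences: Sequence[TDSSequence], scheme: AttributeScheme
) -> DurationTable:
    """Tabulate every dominance spell of every panelist.

    Occurrences are numbered 1..C[i, j] in temporal order, so e.g. a
    panelist whose attribute-1 spells last 2, 3 and 3 seconds yields
    C = 3 and Y = (2, 3, 3) for that attribute.
    """
    if not sequences:
        raise TDSDataError("no sequences given")
    rows = []
    for seq in sequences:
        occ: dict[int, int] = {}
        for attr, dur in seq.runs:
            if attr >= scheme.n_attributes:
                raise TDSDataError(
                    f"panelist {seq.panelist_id!r}: attribute index {attr} outside scheme"
                )
            occ[attr] = occ.get(attr, 0) + 1
            rows.append(
                (
                    seq.panelist_id,
                    scheme.labels[attr],
                    attr,
                    scheme.group_of[attr],
                    occ[attr],
                    dur,
                )
            )
    frame = pd.DataFrame(
        rows,
        columns=[
            "panelist",
            "attribute",
            "attribute_index",
            "group",
            "occurrence",
            "duration",
        ],
    )
    return DurationTable(
        frame=frame,
        panelists=tuple(dict.fromkeys(s.panelist_id for s in sequences)),
        scheme=scheme,
    )


# ---------------------------------------------------------------------------
# covariates


@dataclass
class CovariateTable:
    """Per-panelist covariates; ``frame`` is indexed by panelist id, NaN = missing."""

    frame: pd.DataFrame
    normalized: bool = False
    binary_columns: tuple[str, ...] = field(default_factory=tuple)

    @property
    def variables(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    @property
    def panelists(self) -> tuple[str, ...]:
        return tuple(self.frame.index)

    def is_complete(self) -> bool:
        return not self.frame.isna().any().any()

    def row(self, panelist: str, variables: Sequence[str] | None = None) -> np.ndarray:
        sub = self.frame.loc[panelist]
        if variables is not None:
            sub = sub[list(variables)]
        return sub.to_numpy(dtype=float)

    def matrix(self, panelists: Sequence[str], variables: Sequence[str]) -> np.ndarray:
        return (
            self.frame.loc[list(panelists), list(variables)].to_numpy(dtype=float)
        )

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=True, index_label="panelist")

    @classmethod
    def from_csv(cls, path: str | Path) -> "CovariateTable":
        frame = pd.read_csv(path, index_col="panelist")
        frame.index = frame.index.astype(str)
        return cls(frame=frame.astype(float))


def _binary_columns(frame: pd.DataFrame) -> tuple[str, ...]:
    out = []
    for col in frame.columns:
        vals = set(frame[col].dropna().unique())
        if vals <= {0.0, 1.0}:
            out.append(col)
    return tuple(out)


def preprocess_covariates(
    table: CovariateTable,
    variables: Sequence[str] | None = None,
    normalize: bool = True,
    scale_binary: bool = True,
) -> tuple[CovariateTable, tuple[str, ...]]:
    """Drop panelists with missing values and z-score each column.

    Only the selected ``variables`` (default: all) are considered, both for
    the missingness screen and for normalization.  Scaling uses the sample
    standard deviation (n-1 denominator).  With ``scale_binary=False``,
    columns taking only values {0, 1} are passed through unchanged.

    Returns the processed table and the tuple of retained panelist ids.
    Raises :class:`ZeroVarianceError` if a column to be scaled is constant.
    """
    frame = table.frame
    if variables is not None:
        frame = frame[list(variables)]
    kept = frame.dropna(axis=0, how="any")
    if len(kept) < 2:
        raise TDSDataError(
            f"only {len(kept)} panelist(s) remain after omitting missing covariates; "
            "need at least 2"
        )
    kept = kept.astype(float)
    binary = _binary_columns(kept)
    if normalize:
        out = {}
        for col in kept.columns:
            if col in binary and not scale_binary:
                out[col] = kept[col]
                continue
            sd = kept[col].std(ddof=1)
            if sd == 0 or not np.isfinite(sd):
                raise ZeroVarianceError(col)
            out[col] = (kept[col] - kept[col].mean()) / sd
        kept = pd.DataFrame(out, index=kept.index)
    return (
        CovariateTable(frame=kept, normalized=normalize, binary_columns=binary),
        tuple(kept.index),
    )
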