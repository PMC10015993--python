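"""Readers and writers for simulation ensembles, ratings, and score tables.

Supported simulation dialects
-----------------------------
``vote_share_csv``
    Wide CSV, one row per simulation, one column per unit, cell = focal
    candidate's two-party vote share in [0, 1].  Shares are binarized with a
    strict ``share > win_rule`` rule (default 0.5): an exact 50/50 split is
    not a win.  A leading non-numeric or index-like column is ignored.
``binary_csv``
    Same layout with cells already 0/1.
``simmed_maps_json``
    JSON object with a ``"states"`` list of unit names and a ``"maps"`` list
    of per-simulation rows (the layout of FiveThirtyEight's simmed-maps
    file).  Each row may carry leading metadata entries; the last
    ``len(states)`` entries are taken as the per-state shares.

Ratings files are CSV with one row per participant: a ``participant`` id
column, optional metadata columns (``voted_for``, ``party_id``,
``believes_legitimate``), and one integer column in [0, 10] per rated unit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .possible_worlds import ElectoralMap, WorldEnsemble

__all__ = [
    "RatingsTable",
    "read_simulations",
    "read_ratings",
    "write_ratings",
    "write_table",
    "read_table",
    "METADATA_COLUMNS",
]

METADATA_COLUMNS = ("voted_for", "party_id", "believes_legitimate")
_VOTED_FOR_VOCAB = {"Biden", "Trump", "Other"}
_PARTY_VOCAB = {"Democrat", "Republican", "Independent", "Other"}


@dataclass
class RatingsTable:
    """Participant x unit causal ratings on the 0-10 agreement scale.

    ``ratings`` is indexed by participant id with one integer column per
    rated unit (no structural missingness: every participant rates every
    unit).  ``metadata`` is indexed identically and may carry ``voted_for``,
    ``party_id`` and ``believes_legitimate`` columns.
    """

    ratings: pd.DataFrame
    metadata: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.ratings.empty:
            raise ValueError("ratings table is empty")
        vals = self.ratings.to_numpy()
        bad = ~(
            np.isfinite(vals)
            & (vals == np.round(vals))
            & (vals >= 0)
            & (vals <= 10)
        )
        if bad.any():
            cells = [
                f"(participant={self.ratings.index[i]}, unit={self.ratings.columns[j]}, "
                f"value={vals[i, j]!r})"
                for i, j in zip(*np.nonzero(bad))
            ]
            raise ValueError(
                "ratings must be integers in [0, 10]; offending cells: "
                + "; ".join(cells[:20])
            )
        self.ratings = self.ratings.astype(int)
        if self.metadata is None:
            self.metadata = pd.DataFrame(index=self.ratings.index)
        if not self.metadata.index.equals(self.ratings.index):
            raise ValueError("metadata index must match ratings index")
        if "voted_for" in self.metadata:
            bad_v = set(self.metadata["voted_for"].dropna()) - _VOTED_FOR_VOCAB
            if bad_v:
                raise ValueError(f"unknown voted_for categories: {sorted(bad_v)}")
        if "party_id" in self.metadata:
            bad_p = set(self.metadata["party_id"].dropna()) - _PARTY_VOCAB
            if bad_p:
                raise ValueError(f"unknown party_id categories: {sorted(bad_p)}")

    @property
    def participants(self) -> pd.Index:
        return self.ratings.index

    @property
    def units(self) -> list[str]:
        return list(self.ratings.columns)

    @property
    def n_participants(self) -> int:
        return len(self.ratings)


# ---------------------------------------------------------------------------
# Simulations
# ---------------------------------------------------------------------------

def _sniff_dialect(path: Path) -> str:
    if path.suffix.lower() == ".json":
        return "simmed_maps_json"
    head = pd.read_csv(path, nrows=50)
    numeric = head.select_dtypes("number")
    if numeric.size and numeric.isin((0, 1)).all().all():
        return "binary_csv"
    return "vote_share_csv"


def _shares_frame(path: Path, dialect: str) -> pd.DataFrame:
    if dialect == "simmed_maps_json":
        with open(path) as fh:
            payload = json.load(fh)
        try:
            states = [str(s) for s in payload["states"]]
            maps = payload["maps"]
        except (TypeError, KeyError) as exc:
            raise ValueError(
                f"{path}: not a simmed-maps JSON (needs 'states' and 'maps')"
            ) from exc
        rows = []
        for i, row in enumerate(maps):
            if len(row) < len(states):
                raise ValueError(
                    f"{path}: simulation {i} has {len(row)} entries for "
                    f"{len(states)} states"
                )
            rows.append(row[-len(states):])
        return pd.DataFrame(rows, columns=states, dtype=float)

    frame = pd.read_csv(path)
    # drop a leading simulation-id / index-like column if present
    first = frame.columns[0]
    if first.lower() in ("sim", "simulation", "draw", "index", "") or (
        not pd.api.types.is_numeric_dtype(frame[first])
    ):
        frame = frame.drop(columns=[first])
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise ValueError(f"{path}: non-numeric outcome columns {non_numeric}")
    return frame.astype(float)


def read_simulations(
    path: str | Path,
    dialect: str | None = None,
    win_rule: float = 0.5,
    threshold: int | None = None,
    votes: dict[str, int] | None = None,
    emap: ElectoralMap | None = None,
) -> WorldEnsemble:
    """Read a forecast simulation file into a :class:`WorldEnsemble`.

    Vote shares are binarized with the strict rule ``share > win_rule``
    (a share of exactly ``win_rule`` is not a win).  The electoral map is
    taken from ``emap`` if given, else built from ``votes`` (unit -> electoral
    votes) with a majority threshold unless ``threshold`` overrides it.
    ``dialect`` is auto-detected from the extension and contents when omitted.
    Deterministic: the same file always yields the same ensemble.
    """
    path = Path(path)
    if dialect is None:
        dialect = _sniff_dialect(path)
    if dialect not in ("vote_share_csv", "binary_csv", "simmed_maps_json"):
        raise ValueError(f"unknown dialect {dialect!r}")

    shares = _shares_frame(path, dialect)
    if shares.isna().any().any():
        bad = shares.columns[shares.isna().any()].tolist()
        raise ValueError(
            f"{path}: missing outcome values (columns {bad}); every simulation "
            "must cover the same unit set"
        )
    vals = shares.to_numpy()
    if dialect == "binary_csv":
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{path}: binary_csv entries must be 0 or 1")
        outcomes = vals.astype(np.int8)
    else:
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: vote shares must lie in [0, 1]")
        outcomes = (vals > win_rule).astype(np.int8)

    units = list(shares.columns)
    if emap is None:
        if votes is None:
            raise ValueError("provide either emap or a votes mapping")
        missing = [u for u in units if u not in votes]
        if missing:
            raise ValueError(f"no electoral votes given for units {missing}")
        vote_list = [votes[u] for u in units]
        if threshold is None:
            emap = ElectoralMap.majority(units, vote_list)
        else:
            emap = ElectoralMap(tuple(units), tuple(vote_list), threshold)
    elif list(emap.units) != units:
        raise ValueError("file units do not match the supplied electoral map")
    return WorldEnsemble(emap, outcomes)


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def read_ratings(path: str | Path) -> RatingsTable:
    """Read a participant x unit ratings CSV; validates the 0-10 scale."""
    frame = pd.read_csv(path)
    if "participant" in frame.columns:
        frame = frame.set_index("participant")
    meta_cols = [c for c in METADATA_COLUMNS if c in frame.columns]
    metadata = frame[meta_cols].copy()
    if "believes_legitimate" in metadata:
        metadata["believes_legitimate"] = metadata["believes_legitimate"].astype(bool)
    ratings = frame.drop(columns=meta_cols)
    return RatingsTable(ratings=ratings, metadata=metadata)


def write_ratings(table: RatingsTable, path: str | Path) -> Path:
    """Write a ratings table (metadata columns first) as CSV."""
    path = Path(path)
    out = pd.concat([table.metadata, table.ratings], axis=1)
    out.index.name = "participant"
    out.to_csv(path)
    return path


# ---------------------------------------------------------------------------
# Score / result tables
# ---------------------------------------------------------------------------

def write_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a score or result table as CSV with a stable column order.

    NA cells are written as empty fields; the written file round-trips
    through :func:`read_table`.
    """
    if table.empty:
        raise ValueError("refusing to write an empty table")
    path = Path(path)
    table.to_csv(path, na_rep="")
    return path


def read_table(path: str | Path, index_col: str = "unit") -> pd.DataFrame:
    """Read a table written by :func:`write_table` (empty cells -> NaN)."""
    return pd.read_csv(path, index_col=index_col)
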