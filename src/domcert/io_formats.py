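"""Readers and writers for win/loss matrices, edge lists and result reports.

All on-disk formats are plain text: comma-separated UTF-8 with identifiers
treated as opaque strings, plus a JSON run summary. Zero-count dyads are a
meaningful state (never-interacting pairs) and are always stored explicitly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd

from .errors import (
    DuplicateIDError,
    ValidationError,
    IDMismatchError,
    MissingColumnError,
    NegativeCountError,
    NonIntegerCountError,
    NonSquareMatrixError,
    NonzeroDiagonalError,
    SelfInteractionError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .certainty import CertaintyReport
    from .ranking import RankOrderEnsemble, TierAssignment


@dataclass(frozen=True)
class WinLossMatrix:
    """Square count matrix of decided agonistic outcomes.

    ``counts[i, j]`` is the number of encounters individual ``ids[i]`` won
    against ``ids[j]``. The matrix is validated on construction: square,
    n >= 2, unique non-empty ids, nonnegative integer counts, zero diagonal.
    """

    ids: tuple[str, ...]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        object.__setattr__(self, "ids", ids)
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise NonSquareMatrixError(
                f"count matrix must be square, got shape {counts.shape}"
            )
        n = counts.shape[0]
        if len(ids) != n:
            raise IDMismatchError(
                f"{len(ids)} ids for a {n}x{n} matrix"
            )
        if n < 2:
            raise ValidationError("at least 2 individuals are required")
        if len(set(ids)) != n or any(i == "" for i in ids):
            raise DuplicateIDError("ids must be unique and non-empty")
        if not np.issubdtype(counts.dtype, np.integer):
            as_float = counts.astype(float)
            if not np.all(np.isfinite(as_float)) or np.any(as_float != np.round(as_float)):
                raise NonIntegerCountError("all counts must be integers")
            counts = as_float.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise NegativeCountError("counts must be nonnegative")
        if np.any(np.diagonal(counts) != 0):
            raise NonzeroDiagonalError("diagonal (self-interaction) must be zero")
        counts = counts.copy()
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, individual: str) -> int:
        try:
            return self.ids.index(individual)
        except ValueError:
            from .errors import UnknownIndividualError

            raise UnknownIndividualError(f"unknown individual {individual!r}") from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.ids), columns=list(self.ids))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WinLossMatrix):
            return NotImplemented
        return self.ids == other.ids and np.array_equal(self.counts, other.counts)


def read_winloss_csv(path: str | Path) -> WinLossMatrix:
    """Read a square win/loss CSV (first row and first column are ids).

    Row and column id orders must match exactly; cell (i, j) is the number
    of encounters row-individual i won against column-individual j.
    """
    df = pd.read_csv(path, header=0, index_col=0)
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    if len(row_ids) != len(col_ids):
        raise NonSquareMatrixError(
            f"body is {len(row_ids)} rows x {len(col_ids)} columns"
        )
    if row_ids != col_ids:
        raise IDMismatchError(
            f"row ids {row_ids} do not match column ids {col_ids}"
        )
    body = df.to_numpy()
    if not np.issubdtype(body.dtype, np.number):
        raise NonIntegerCountError("matrix body must be numeric")
    return WinLossMatrix(tuple(row_ids), body)


def read_edge_list(path: str | Path) -> WinLossMatrix:
    """Read a long-form edge list with columns winner, loser[, count].

    Duplicate (winner, loser) rows aggregate by summation; the id order of
    the resulting matrix is order of first appearance in the file.
    """
    df = pd.read_csv(path, header=0, dtype={"winner": str, "loser": str})
    for col in ("winner", "loser"):
        if col not in df.columns:
            raise MissingColumnError(f"edge list is missing required column {col!r}")
    if "count" in df.columns:
        counts = df["count"].to_numpy()
        if np.any(pd.isna(counts)) or np.any(counts != np.round(counts.astype(float))):
            raise NonIntegerCountError("edge-list counts must be integers")
        counts = counts.astype(np.int64)
        if np.any(counts < 0):
            raise NegativeCountError("edge-list counts must be nonnegative")
    else:
        counts = np.ones(len(df), dtype=np.int64)

    ids: list[str] = []
    index: dict[str, int] = {}
    for w, l in zip(df["winner"], df["loser"]):
        for who in (w, l):
            if who not in index:
                index[who] = len(ids)
                ids.append(who)
    n = len(ids)
    mat = np.zeros((n, n), dtype=np.int64)
    for w, l, c in zip(df["winner"], df["loser"], counts):
        if w == l:
            raise SelfInteractionError(f"row with winner == loser ({w!r})")
        mat[index[w], index[l]] += c
    return WinLossMatrix(tuple(ids), mat)


def write_winloss_csv(matrix: WinLossMatrix, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_frame().to_csv(path)
    return path


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(
    report: "CertaintyReport",
    order: "RankOrderEnsemble",
    out_dir: str | Path,
    tiers: "TierAssignment | None" = None,
) -> set[Path]:
    """Write dp.csv, dc_dyadic.csv, dc_individual.csv, tiers.csv, summary.json.

    dp.csv holds the dominance-probability matrix reordered by the best rank
    order (upper triangle = probability the row animal outranks the column
    animal). Content is deterministic for fixed inputs.
    """
    from .ranking import rank_tiers

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    best = order.best
    ids = list(best.order)
    if set(ids) != set(report.ids):
        raise IDMismatchError("report and rank order cover different individuals")
    if tiers is None:
        threshold = float(report.params.get("tier_threshold", 0.70))
        tiers = rank_tiers(report.dp, best, threshold=threshold)

    idx = [report.dp.index_of(i) for i in ids]
    written: set[Path] = set()

    dp_df = pd.DataFrame(
        report.dp.dp[np.ix_(idx, idx)], index=ids, columns=ids
    )
    p = out_dir / "dp.csv"
    dp_df.to_csv(p, float_format="%.10g")
    written.add(p)

    dc_df = pd.DataFrame(
        report.dyadic_dc[np.ix_(idx, idx)], index=ids, columns=ids
    )
    p = out_dir / "dc_dyadic.csv"
    dc_df.to_csv(p, float_format="%.10g")
    written.add(p)

    ind = {i: report.individual_dc[report.dp.index_of(i)] for i in ids}
    p = out_dir / "dc_individual.csv"
    pd.DataFrame({"id": ids, "dc": [ind[i] for i in ids]}).to_csv(
        p, index=False, float_format="%.10g"
    )
    written.add(p)

    p = out_dir / "tiers.csv"
    pd.DataFrame(
        {
            "id": ids,
            "rank_position": list(range(1, len(ids) + 1)),
            "tier": [tiers.tiers[i] for i in ids],
        }
    ).to_csv(p, index=False)
    written.add(p)

    summary = {
        "group_dc": float(report.group_dc),
        "transitivity": float(report.transitivity),
        "best_order": ids,
        "best_score": float(best.score),
        "method": order.method,
        "seed": order.seed,
        "restarts": order.restarts,
        "n_tiers": max(tiers.tiers.values()),
        "tier_threshold": float(tiers.threshold),
        "parameters": report.params,
    }
    if report.diagnostics is not None:
        summary["diagnostic_flag"] = report.diagnostics.get("flag")
    p = out_dir / "summary.json"
    p.write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=_json_default) + "\n"
    )
    written.add(p)
    return written
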