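"""Disease-microbe association networks: parsing, validation, indexing, I/O.

The central object is :class:`AssociationNetwork`, a labelled binary
adjacency matrix ``A`` of shape ``(nd, nm)`` where ``A[i, j] = 1`` records a
curated association between disease ``i`` and microbe ``j``. Edge lists are
read from two-column TSV files (disease, microbe), the format databases such
as HMDAD export; duplicate rows are collapsed, since a pair is either known
or not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, TYPE_CHECKING

import numpy as np
import pandas as pd

from .exceptions import EdgeListParseError

if TYPE_CHECKING:  # pragma: no cover
    from .projection import ScoreMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "AssociationNetwork",
    "EdgeRecord",
    "DedupReport",
    "read_edge_records",
    "build_network",
    "read_association_edgelist",
    "write_edgelist",
    "write_score_table",
    "read_score_table",
]


@dataclass(frozen=True)
class EdgeRecord:
    """One (disease, microbe) association row; labels are stripped of
    surrounding whitespace and must be non-empty."""

    disease: str
    microbe: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "disease", self.disease.strip())
        object.__setattr__(self, "microbe", self.microbe.strip())
        if not self.disease or not self.microbe:
            raise ValueError("disease and microbe labels must be non-empty")


@dataclass(frozen=True)
class DedupReport:
    """Bookkeeping from edge-list ingestion."""

    rows_read: int
    duplicates_removed: int
    nd: int
    nm: int
    n_associations: int


@dataclass(frozen=True)
class AssociationNetwork:
    """Labelled binary disease x microbe adjacency matrix.

    Parameters
    ----------
    diseases, microbes
        Unique entity labels; row/column order of ``A`` follows these lists.
    A
        ``(nd, nm)`` matrix with entries in {0, 1}.
    """

    diseases: tuple[str, ...]
    microbes: tuple[str, ...]
    A: np.ndarray

    def __post_init__(self) -> None:
        diseases = tuple(self.diseases)
        microbes = tuple(self.microbes)
        A = np.asarray(self.A)
        if A.ndim != 2:
            raise ValueError("A must be a 2-D matrix")
        if len(diseases) < 1 or len(microbes) < 1:
            raise ValueError("need at least one disease and one microbe")
        if A.shape != (len(diseases), len(microbes)):
            raise ValueError(
                f"A has shape {A.shape}, expected "
                f"({len(diseases)}, {len(microbes)}) from the label lists"
            )
        if len(set(diseases)) != len(diseases):
            raise ValueError("disease labels must be pairwise distinct")
        if len(set(microbes)) != len(microbes):
            raise ValueError("microbe labels must be pairwise distinct")
        if not np.isin(A, (0, 1)).all():
            raise ValueError("A must contain only 0/1 entries")
        A = A.astype(np.int8, copy=True)
        A.setflags(write=False)
        object.__setattr__(self, "diseases", diseases)
        object.__setattr__(self, "microbes", microbes)
        object.__setattr__(self, "A", A)

    # -- basic geometry -------------------------------------------------
    @property
    def nd(self) -> int:
        return len(self.diseases)

    @property
    def nm(self) -> int:
        return len(self.microbes)

    @property
    def n_associations(self) -> int:
        """Number of known (value 1) associations."""
        return int(self.A.sum())

    @property
    def disease_index(self) -> dict[str, int]:
        return {d: i for i, d in enumerate(self.diseases)}

    @property
    def microbe_index(self) -> dict[str, int]:
        return {m: j for j, m in enumerate(self.microbes)}

    def with_matrix(self, A: np.ndarray) -> "AssociationNetwork":
        """Same labels, different (validated) matrix."""
        return AssociationNetwork(self.diseases, self.microbes, A)

    def transposed(self) -> "AssociationNetwork":
        """Swap the roles of diseases and microbes."""
        return AssociationNetwork(self.microbes, self.diseases, self.A.T)

    def edges(self) -> list[EdgeRecord]:
        """All known associations, row-major order."""
        return [
            EdgeRecord(self.diseases[i], self.microbes[j])
            for i, j in np.argwhere(self.A == 1)
        ]


def read_edge_records(
    path: str | Path, header: bool = False
) -> list[EdgeRecord]:
    """Parse a two-column TSV edge list into records.

    Lines starting with ``#`` and blank lines are ignored; if *header* is
    true the first remaining line is skipped. A data row with fewer than two
    tab-separated columns raises :class:`EdgeListParseError` naming the line.
    """
    path = Path(path)
    records: list[EdgeRecord] = []
    skipped_header = not header
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if not skipped_header:
                skipped_header = True
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected >=2 tab-separated "
                    f"columns, got {len(cols)}"
                )
            try:
                records.append(EdgeRecord(cols[0], cols[1]))
            except ValueError as exc:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    if not records:
        raise EdgeListParseError(f"{path}: no association rows found")
    return records


def build_network(
    records: Iterable[EdgeRecord],
) -> tuple[AssociationNetwork, DedupReport]:
    """Deduplicate edge records and assemble the adjacency matrix.

    Entity order is first appearance in the record stream; this is
    deterministic and, because every downstream computation is equivariant
    under entity permutation, as good as any other fixed rule.
    """
    records = list(records)
    if not records:
        raise EdgeListParseError("no association records supplied")
    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    pairs: set[tuple[str, str]] = set()
    for rec in records:
        diseases.setdefault(rec.disease, len(diseases))
        microbes.setdefault(rec.microbe, len(microbes))
        pairs.add((rec.disease, rec.microbe))
    A = np.zeros((len(diseases), len(microbes)), dtype=np.int8)
    for d, m in pairs:
        A[diseases[d], microbes[m]] = 1
    net = AssociationNetwork(tuple(diseases), tuple(microbes), A)
    report = DedupReport(
        rows_read=len(records),
        duplicates_removed=len(records) - len(pairs),
        nd=net.nd,
        nm=net.nm,
        n_associations=len(pairs),
    )
    return net, report


def read_association_edgelist(
    path: str | Path, header: bool = False
) -> AssociationNetwork:
    """Read, deduplicate and index a TSV edge list into a network."""
    net, report = build_network(read_edge_records(path, header=header))
    logger.info(
        "read %s: %d rows, %d duplicates removed, %d diseases x %d microbes, "
        "%d associations",
        path,
        report.rows_read,
        report.duplicates_removed,
        report.nd,
        report.nm,
        report.n_associations,
    )
    return net


def write_edgelist(net: AssociationNetwork, path: str | Path) -> None:
    """Write the known associations back out as a two-column TSV."""
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# disease\tmicrobe\n")
        for rec in net.edges():
            fh.write(f"{rec.disease}\t{rec.microbe}\n")


def write_score_table(
    net: AssociationNetwork,
    scores: "ScoreMatrix",
    path: str | Path,
    include_known: bool = True,
    decimals: int = 6,
) -> None:
    """Write prediction scores as a long-format ranked TSV.

    Columns are ``disease, microbe, score, known``; rows are grouped by
    disease (network order) and sorted by descending score within each
    disease, ties broken by microbe label so output is fully deterministic.
    Pairs already known (``A = 1``) are flagged in the ``known`` column and
    can be dropped entirely with ``include_known=False`` when the table is
    meant as a novel-candidate ranking.
    """
    S = np.asarray(scores.S, dtype=float)
    if S.shape != net.A.shape:
        raise ValueError(
            f"score matrix shape {S.shape} does not match network "
            f"shape {net.A.shape}"
        )
    frames = []
    for i, disease in enumerate(net.diseases):
        df = pd.DataFrame(
            {
                "disease": disease,
                "microbe": net.microbes,
                "score": S[i],
                "known": net.A[i].astype(int),
            }
        )
        if not include_known:
            df = df[df["known"] == 0]
        df = df.sort_values(
            ["score", "microbe"], ascending=[False, True], kind="mergesort"
        )
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    table.to_csv(path, sep="\t", index=False, float_format=f"%.{decimals}f")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a score table written by :func:`write_score_table`."""
    return pd.read_csv(path, sep="\t")
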