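"""Domain types and delimited-text I/O for rearing-experiment data.

A rearing experiment exposes sections of dead wood of known host-tree
species in the field, isolates them, and counts the adult wood-boring
beetles that emerge from each section.  Each emergence event links one
host-tree species to one beetle species under one experimental treatment
(here: season x stratum, e.g. rain-canopy ``Rc``).  Aggregating the
counts per treatment yields a weighted bipartite interaction matrix,
the object every network statistic in this package consumes.

Conventions fixed across the package:

* rows are hosts, columns are beetles;
* labels are sorted lexicographically so outputs are byte-stable;
* matrices are trimmed (no all-zero row or column survives
  construction), which never changes the grand total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical treatment labels: Rain/Dry season x canopy/ground stratum
TREATMENTS = ("Rc", "Rg", "Dc", "Dg")

#: optional collection-interval labels (months of field exposure)
INTERVALS = ("2", "4", "6", "8")

RECORD_COLUMNS = ("treatment", "host", "beetle", "count")
TRAIT_COLUMNS = ("species", "role", "wood_density", "pdd", "bsi")


class ValidationError(ValueError):
    """Raised when input data violate a domain invariant."""


@dataclass(frozen=True)
class RearingRecord:
    """One (treatment, host, beetle) emergence tally.

    Repeated keys are legal; aggregation sums counts.
    """

    treatment: str
    host: str
    beetle: str
    count: int
    interval: str | None = None

    def __post_init__(self) -> None:
        for name in ("treatment", "host", "beetle"):
            value = getattr(self, name)
            if not isinstance(value, str) or not value:
                raise ValidationError(f"{name} must be a non-empty string, got {value!r}")
        if isinstance(self.count, float) and not float(self.count).is_integer():
            raise ValidationError(
                f"count must be an integer (emerged individuals), got {self.count!r}"
            )
        if int(self.count) < 0:
            raise ValidationError(f"count must be >= 0, got {self.count!r}")
        object.__setattr__(self, "count", int(self.count))
        if self.interval is not None and str(self.interval) not in INTERVALS:
            raise ValidationError(
                f"interval must be one of {INTERVALS} or None, got {self.interval!r}"
            )


class InteractionMatrix:
    """Weighted host x beetle count matrix with labels.

    Parameters
    ----------
    hosts, beetles
        Row and column labels.  Must be unique within each axis.
    counts
        Non-negative integer matrix ``a_ij`` of emergences of beetle
        ``j`` from host ``i``.
    trim
        Remove all-zero rows/columns (default).  Trimming never changes
        the grand total ``m``.
    """

    def __init__(
        self,
        hosts: Sequence[str],
        beetles: Sequence[str],
        counts: np.ndarray,
        *,
        trim: bool = True,
    ) -> None:
        hosts = list(hosts)
        beetles = list(beetles)
        A = np.asarray(counts)
        if A.shape != (len(hosts), len(beetles)):
            raise ValidationError(
                f"counts shape {A.shape} does not match labels "
                f"({len(hosts)} hosts x {len(beetles)} beetles)"
            )
        if len(set(hosts)) != len(hosts) or len(set(beetles)) != len(beetles):
            raise ValidationError("species labels must be unique within each axis")
        if np.issubdtype(A.dtype, np.floating):
            if not np.allclose(A, np.round(A)):
                raise ValidationError("interaction counts must be integers")
            A = np.round(A).astype(np.int64)
        A = A.astype(np.int64)
        if (A < 0).any():
            raise ValidationError("interaction counts must be non-negative")
        if trim:
            keep_r = A.sum(axis=1) > 0
            keep_c = A.sum(axis=0) > 0
            A = A[np.ix_(keep_r, keep_c)]
            hosts = [h for h, k in zip(hosts, keep_r) if k]
            beetles = [b for b, k in zip(beetles, keep_c) if k]
        self.hosts: list[str] = hosts
        self.beetles: list[str] = beetles
        self.A: np.ndarray = A

    # -- derived quantities -------------------------------------------------

    @property
    def m(self) -> int:
        """Grand total of interactions."""
        return int(self.A.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.A.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.A.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.A.shape

    @property
    def network_size(self) -> int:
        """Host-species count plus beetle-species count."""
        return len(self.hosts) + len(self.beetles)

    def links(self) -> set[tuple[str, str]]:
        """The set of realized (host, beetle) links (``a_ij > 0``)."""
        ii, jj = np.nonzero(self.A)
        return {(self.hosts[i], self.beetles[j]) for i, j in zip(ii, jj)}

    def species(self, level: str) -> list[str]:
        if level == "host":
            return list(self.hosts)
        if level == "beetle":
            return list(self.beetles)
        raise ValueError(f"level must be 'host' or 'beetle', got {level!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.A, index=self.hosts, columns=self.beetles)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractionMatrix):
            return NotImplemented
        return (
            self.hosts == other.hosts
            and self.beetles == other.beetles
            and np.array_equal(self.A, other.A)
        )

    def __repr__(self) -> str:
        return (
            f"InteractionMatrix({len(self.hosts)} hosts x "
            f"{len(self.beetles)} beetles, m={self.m})"
        )


@dataclass
class TreatmentNetworkSet:
    """The per-treatment interaction matrices of one experiment."""

    networks: dict[str, InteractionMatrix] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.networks)) != len(self.networks):
            raise ValidationError("treatment labels must be distinct")

    @property
    def treatments(self) -> list[str]:
        return list(self.networks)

    def network_size(self, treatment: str) -> int:
        return self.networks[treatment].network_size

    def __getitem__(self, treatment: str) -> InteractionMatrix:
        return self.networks[treatment]

    def __len__(self) -> int:
        return len(self.networks)

    def items(self):
        return self.networks.items()


class TraitTable:
    """Per-species traits: wood density and decomposition for hosts,
    body-size index for beetles.

    Wrapped DataFrame columns: ``species, role, wood_density, pdd, bsi``
    with NaN for role-inapplicable traits.
    """

    HOST_TRAITS = ("wood_density", "pdd")
    BEETLE_TRAITS = ("bsi",)

    def __init__(self, frame: pd.DataFrame) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"trait table missing columns: {missing}")
        frame = frame.loc[:, list(TRAIT_COLUMNS)].copy()
        if frame["species"].duplicated().any():
            dup = frame.loc[frame["species"].duplicated(), "species"].tolist()
            raise ValidationError(f"duplicate species in trait table: {dup}")
        bad_role = ~frame["role"].isin(["host", "beetle"])
        if bad_role.any():
            raise ValidationError(
                f"role must be 'host' or 'beetle': {frame.loc[bad_role, 'role'].tolist()}"
            )
        hosts = frame["role"] == "host"
        for col in self.BEETLE_TRAITS:
            if frame.loc[hosts, col].notna().any():
                raise ValidationError(f"host rows must not carry beetle trait {col!r}")
        for col in self.HOST_TRAITS:
            if frame.loc[~hosts, col].notna().any():
                raise ValidationError(f"beetle rows must not carry host trait {col!r}")
        numeric = frame[["wood_density", "pdd", "bsi"]].to_numpy(dtype=float)
        finite = numeric[~np.isnan(numeric)]
        if not np.all(np.isfinite(finite)):
            raise ValidationError("trait values must be finite")
        if (finite < 0).any():
            raise ValidationError("trait values must be >= 0")
        self.frame = frame.sort_values("species", kind="stable").reset_index(drop=True)

    def for_role(self, role: str) -> pd.DataFrame:
        sub = self.frame[self.frame["role"] == role].set_index("species")
        cols = self.HOST_TRAITS if role == "host" else self.BEETLE_TRAITS
        return sub[list(cols)]

    def __len__(self) -> int:
        return len(self.frame)


# ---------------------------------------------------------------------------
# construction


def build_matrix(
    records: Iterable[RearingRecord],
    *,
    by_interval: bool = False,
) -> InteractionMatrix | dict[str, InteractionMatrix]:
    """Aggregate records of a single treatment into a matrix.

    With ``by_interval=True``, returns one matrix per interval label
    instead of pooling across the four collection intervals.
    """
    records = list(records)
    if by_interval:
        groups: dict[str, list[RearingRecord]] = {}
        for rec in records:
            groups.setdefault(rec.interval or "pooled", []).append(rec)
        return {k: build_matrix(v) for k, v in sorted(groups.items())}
    hosts = sorted({r.host for r in records})
    beetles = sorted({r.beetle for r in records})
    h_idx = {h: i for i, h in enumerate(hosts)}
    b_idx = {b: j for j, b in enumerate(beetles)}
    A = np.zeros((len(hosts), len(beetles)), dtype=np.int64)
    for rec in records:
        A[h_idx[rec.host], b_idx[rec.beetle]] += rec.count
    return InteractionMatrix(hosts, beetles, A)


def build_networks(records: Iterable[RearingRecord]) -> TreatmentNetworkSet:
    """Aggregate rearing records into one trimmed matrix per treatment.

    Species observed in one treatment but not another are simply absent
    from the latter's matrix; cross-treatment alignment happens inside
    the beta-diversity operations only.
    """
    by_treatment: dict[str, list[RearingRecord]] = {}
    for rec in records:
        by_treatment.setdefault(rec.treatment, []).append(rec)
    if not by_treatment:
        raise ValidationError("no rearing records supplied")
    networks: dict[str, InteractionMatrix] = {}
    for treatment in sorted(by_treatment):
        mat = build_matrix(by_treatment[treatment])
        if mat.m == 0:
            raise ValidationError(
                f"treatment {treatment!r} has no emergences (all counts zero)"
            )
        networks[treatment] = mat
    return TreatmentNetworkSet(networks)


# ---------------------------------------------------------------------------
# I/O — long-format records, adjacency matrices, trait tables


def read_records(
    path: str | Path,
    *,
    sep: str = ",",
    columns: Mapping[str, str] | None = None,
) -> list[RearingRecord]:
    """Read long-format rearing records from delimited text.

    Expected header: ``treatment,host,beetle,count[,interval]``; the
    ``columns`` mapping renames non-standard headers (file -> standard).
    Unknown columns are ignored with a warning.
    """
    df = pd.read_csv(path, sep=sep, dtype=str)
    if columns:
        df = df.rename(columns=dict(columns))
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"records file {path} is missing mandatory columns {missing}; "
            f"expected header {RECORD_COLUMNS + ('interval',)}"
        )
    known = set(RECORD_COLUMNS) | {"interval"}
    extra = [c for c in df.columns if c not in known]
    if extra:
        logger.warning("ignoring unknown columns in %s: %s", path, extra)
    records = []
    for row in df.itertuples(index=False):
        interval = getattr(row, "interval", None)
        if interval is not None and (pd.isna(interval) or interval == ""):
            interval = None
        records.append(
            RearingRecord(
                treatment=row.treatment,
                host=row.host,
                beetle=row.beetle,
                count=int(row.count),
                interval=str(interval) if interval is not None else None,
            )
        )
    return records


def write_records(records: Iterable[RearingRecord], path: str | Path) -> None:
    rows = [
        {
            "treatment": r.treatment,
            "host": r.host,
            "beetle": r.beetle,
            "count": r.count,
            "interval": r.interval if r.interval is not None else "",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(RECORD_COLUMNS) + ["interval"]).to_csv(
        path, index=False
    )


def write_matrix(matrix: InteractionMatrix, path: str | Path) -> None:
    """Write an adjacency CSV: first column = host label, remaining
    columns = beetle labels, integer cells."""
    df = matrix.to_frame()
    df.index.name = "host"
    df.to_csv(path)


def read_matrix(path: str | Path) -> InteractionMatrix:
    df = pd.read_csv(path, index_col=0)
    return InteractionMatrix(
        [str(h) for h in df.index],
        [str(b) for b in df.columns],
        df.to_numpy(),
    )


def read_traits(path: str | Path, *, sep: str = ",") -> TraitTable:
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in TRAIT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(
            f"trait file {path} is missing columns {missing}; expected header "
            f"{TRAIT_COLUMNS}"
        )
    extra = [c for c in df.columns if c not in TRAIT_COLUMNS]
    if extra:
        logger.warning("ignoring unknown columns in %s: %s", path, extra)
    return TraitTable(df)


def write_traits(traits: TraitTable, path: str | Path) -> None:
    traits.frame.to_csv(path, index=False)
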