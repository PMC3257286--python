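"""Readers, writers and partitioning for descriptor/rate/affinity tables.

The on-disk dialect is a plain UTF-8 CSV with a header row whose first
column (``pdb``) holds the complex identifier.  Remaining columns are
numeric molecular descriptors, except for the response column
(``log10_kon``, ``log10_koff`` or ``dg_kcal_mol``) and the optional
membership flag columns ``has_kinetics`` / ``validated``.

Identifiers are case-folded to lower case on load: PDB codes are
case-insensitive and mixed-case duplicates would otherwise slip through
set arithmetic. Descriptor columns containing any non-finite cell are
dropped (with a warning) rather than imputed, so that feature selection
compares every column on an identical row set.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

RESPONSE_NAMES = ("log10_kon", "log10_koff")
AFFINITY_RESPONSE = "dg_kcal_mol"
FLAG_COLUMNS = ("has_kinetics", "validated")
ID_COLUMN = "pdb"


class TableIntegrityError(ValueError):
    """A table violates a structural invariant (duplicate ids, missing
    response column, empty table, broken partition)."""


def _casefold_ids(raw_ids: Iterable) -> list[str]:
    ids = [str(i).strip().casefold() for i in raw_ids]
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise TableIntegrityError(f"duplicate complex identifier {i!r}")
        seen.add(i)
    return ids


@dataclass
class DescriptorTable:
    """Rectangular complexes x descriptors matrix with named columns."""

    ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise TableIntegrityError("descriptor values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.ids) != n:
            raise TableIntegrityError(
                f"{len(self.ids)} ids for {n} rows of descriptors"
            )
        if len(self.descriptor_names) != p:
            raise TableIntegrityError(
                f"{len(self.descriptor_names)} names for {p} descriptor columns"
            )
        self.ids = _casefold_ids(self.ids)
        if not np.all(np.isfinite(self.values)):
            raise TableIntegrityError("non-finite descriptor cell after filtering")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise KeyError(f"descriptor column {name!r} not present") from None
        return self.values[:, j]

    def columns(self, names: Sequence[str]) -> np.ndarray:
        missing = [f for f in names if f not in self.descriptor_names]
        if missing:
            raise KeyError(f"descriptor columns missing: {missing}")
        idx = [self.descriptor_names.index(f) for f in names]
        return self.values[:, idx]


@dataclass
class RateTable:
    """Descriptors joined to a log10 rate-constant response.

    ``response`` is log10(k_on / M^-1 s^-1) or log10(k_off / s^-1)
    according to ``response_name``.
    """

    base: DescriptorTable
    response_name: str
    response: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response_name not in RESPONSE_NAMES:
            raise TableIntegrityError(
                f"response_name must be one of {RESPONSE_NAMES}, "
                f"got {self.response_name!r}"
            )
        self.response = np.asarray(self.response, dtype=float)
        if self.response.shape != (self.base.n,):
            raise TableIntegrityError("response length does not match row count")
        if not np.all(np.isfinite(self.response)):
            raise TableIntegrityError("non-finite response value")
        for key in FLAG_COLUMNS:
            flag = np.asarray(
                self.flags.get(key, np.ones(self.base.n, dtype=bool)), dtype=bool
            )
            if flag.shape != (self.base.n,):
                raise TableIntegrityError(f"flag {key!r} length mismatch")
            self.flags[key] = flag

    @property
    def ids(self) -> list[str]:
        return self.base.ids

    def subset(self, keep_ids: Iterable[str]) -> "RateTable":
        keep = {str(i).casefold() for i in keep_ids}
        mask = np.array([i in keep for i in self.base.ids], dtype=bool)
        return RateTable(
            base=DescriptorTable(
                ids=[i for i, m in zip(self.base.ids, mask) if m],
                descriptor_names=list(self.base.descriptor_names),
                values=self.base.values[mask],
            ),
            response_name=self.response_name,
            response=self.response[mask],
            flags={k: v[mask] for k, v in self.flags.items()},
        )


@dataclass
class AffinityTable:
    """Descriptors joined to experimental binding free energies.

    ``dg`` is in kcal/mol; negative values are favourable binding.
    """

    base: DescriptorTable
    dg: np.ndarray
    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.dg = np.asarray(self.dg, dtype=float)
        if self.dg.shape != (self.base.n,):
            raise TableIntegrityError("dg length does not match row count")
        if not np.all(np.isfinite(self.dg)):
            raise TableIntegrityError("non-finite dg value")
        for key in FLAG_COLUMNS:
            flag = np.asarray(
                self.flags.get(key, np.ones(self.base.n, dtype=bool)), dtype=bool
            )
            if flag.shape != (self.base.n,):
                raise TableIntegrityError(f"flag {key!r} length mismatch")
            self.flags[key] = flag

    @property
    def ids(self) -> list[str]:
        return self.base.ids

    def subset(self, keep_ids: Iterable[str]) -> "AffinityTable":
        keep = {str(i).casefold() for i in keep_ids}
        mask = np.array([i in keep for i in self.base.ids], dtype=bool)
        return AffinityTable(
            base=DescriptorTable(
                ids=[i for i, m in zip(self.base.ids, mask) if m],
                descriptor_names=list(self.base.descriptor_names),
                values=self.base.values[mask],
            ),
            dg=self.dg[mask],
            flags={k: v[mask] for k, v in self.flags.items()},
        )


@dataclass(frozen=True)
class PartitionScheme:
    """Disjoint train / selection / validation id sets."""

    name: str
    train_ids: frozenset[str]
    selection_ids: frozenset[str]
    validation_ids: frozenset[str]

    def __post_init__(self) -> None:
        pairs = [
            ("train", "selection", self.train_ids & self.selection_ids),
            ("train", "validation", self.train_ids & self.validation_ids),
            ("selection", "validation", self.selection_ids & self.validation_ids),
        ]
        for a, b, overlap in pairs:
            if overlap:
                raise TableIntegrityError(
                    f"scheme {self.name}: {a} and {b} sets overlap: "
                    f"{sorted(overlap)[:5]}"
                )


# ---------------------------------------------------------------------------
# CSV loading


def _load_frame(path, response_col: str):
    path = Path(path)
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if df.shape[0] == 0:
        raise TableIntegrityError(f"{path}: empty table")
    if df.shape[1] < 2:
        raise TableIntegrityError(f"{path}: no columns beyond the identifier")
    ids = _casefold_ids(df.iloc[:, 0])
    body = df.iloc[:, 1:].copy()
    if response_col not in body.columns:
        raise TableIntegrityError(f"{path}: missing response column {response_col!r}")
    body = body.apply(pd.to_numeric, errors="coerce")

    response = body.pop(response_col).to_numpy(dtype=float)
    ok = np.isfinite(response)
    if not ok.all():
        bad = [i for i, keep in zip(ids, ok) if not keep]
        logger.warning(
            "%s: rejecting %d rows with non-finite response: %s",
            path, len(bad), bad,
        )
        ids = [i for i, keep in zip(ids, ok) if keep]
        body = body.loc[ok]
        response = response[ok]
    if len(ids) == 0:
        raise TableIntegrityError(f"{path}: no rows with a finite response")

    flags: dict[str, np.ndarray] = {}
    for key in FLAG_COLUMNS:
        if key in body.columns:
            col = body.pop(key).to_numpy(dtype=float)
            flags[key] = np.nan_to_num(col, nan=0.0) != 0.0

    finite = np.isfinite(body.to_numpy(dtype=float)).all(axis=0)
    dropped = [c for c, keep in zip(body.columns, finite) if not keep]
    if dropped:
        logger.warning(
            "%s: dropping %d descriptor columns with non-finite cells: %s",
            path, len(dropped), dropped,
        )
        body = body.loc[:, finite]

    table = DescriptorTable(
        ids=ids,
        descriptor_names=[str(c) for c in body.columns],
        values=body.to_numpy(dtype=float),
    )
    return table, response, flags, dropped


def _apply_id_flags(flags, ids, has_kinetics, validated):
    if has_kinetics is not None:
        members = {str(i).casefold() for i in has_kinetics}
        flags["has_kinetics"] = np.array([i in members for i in ids])
    if validated is not None:
        members = {str(i).casefold() for i in validated}
        flags["validated"] = np.array([i in members for i in ids])
    return flags


def read_rate_table(
    path,
    response_name: str,
    has_kinetics: Iterable[str] | None = None,
    validated: Iterable[str] | None = None,
) -> RateTable:
    """Read a rate-constant CSV (descriptors + ``log10_kon``/``log10_koff``).

    Membership flags may come from ``has_kinetics``/``validated`` columns
    in the file or be supplied as explicit id lists (lists win).
    """
    if response_name not in RESPONSE_NAMES:
        raise TableIntegrityError(
            f"response_name must be one of {RESPONSE_NAMES}, got {response_name!r}"
        )
    base, response, flags, _ = _load_frame(path, response_name)
    flags = _apply_id_flags(flags, base.ids, has_kinetics, validated)
    return RateTable(base=base, response_name=response_name,
                     response=response, flags=flags)


def read_affinity_table(
    path,
    has_kinetics: Iterable[str] | None = None,
    validated: Iterable[str] | None = None,
) -> AffinityTable:
    """Read an affinity CSV (descriptors + ``dg_kcal_mol``)."""
    base, dg, flags, _ = _load_frame(path, AFFINITY_RESPONSE)
    flags = _apply_id_flags(flags, base.ids, has_kinetics, validated)
    return AffinityTable(base=base, dg=dg, flags=flags)


def _write_frame(path, base: DescriptorTable, response_col: str,
                 response: np.ndarray, flags: Mapping[str, np.ndarray]) -> None:
    df = pd.DataFrame(base.values, columns=base.descriptor_names)
    df.insert(0, ID_COLUMN, base.ids)
    df[response_col] = response
    for key, val in flags.items():
        df[key] = val.astype(int)
    # %.17g guarantees float64 round-trips exactly through the CSV
    df.to_csv(path, index=False, float_format="%.17g")


def write_rate_table(table: RateTable, path) -> None:
    _write_frame(path, table.base, table.response_name, table.response, table.flags)


def write_affinity_table(table: AffinityTable, path) -> None:
    _write_frame(path, table.base, AFFINITY_RESPONSE, table.dg, table.flags)


# ---------------------------------------------------------------------------
# Partition schemes


def make_scheme(
    all_ids: Iterable[str],
    has_kinetics: Iterable[str],
    validated: Iterable[str],
    scheme: int,
    exclude: Iterable[str] = (),
) -> PartitionScheme:
    """Build one of the four train/selection/validation partitions.

    With K = complexes having kinetic data and V = complexes with
    high-confidence (validated) affinities, inside the full benchmark A:

    ========  ===========  ==============  ==============
    scheme    train        selection       validation
    ========  ===========  ==============  ==============
    1         K ∩ V        V \\ K           A \\ V
    2         K ∩ V        A \\ V           V \\ K
    3         K            V \\ K           A \\ (V ∪ K)
    4         K            A \\ (V ∪ K)     V \\ K
    ========  ===========  ==============  ==============

    Schemes 1/2 train only on the high-confidence kinetic complexes;
    3/4 add the kinetic complexes outside the validated set.  Schemes
    2/4 reserve the high-quality affinities for final validation.
    """
    A = {str(i).casefold() for i in all_ids}
    K = {str(i).casefold() for i in has_kinetics}
    V = {str(i).casefold() for i in validated}
    drop = {str(i).casefold() for i in exclude}
    if not K <= A:
        raise TableIntegrityError(
            f"has_kinetics ids outside the benchmark: {sorted(K - A)[:5]}"
        )
    if not V <= A:
        raise TableIntegrityError(
            f"validated ids outside the benchmark: {sorted(V - A)[:5]}"
        )
    A, K, V = A - drop, K - drop, V - drop

    if scheme == 1:
        train, select, validate = K & V, V - K, A - V
    elif scheme == 2:
        train, select, validate = K & V, A - V, V - K
    elif scheme == 3:
        train, select, validate = K, V - K, A - (V | K)
    elif scheme == 4:
        train, select, validate = K, A - (V | K), V - K
    else:
        raise TableIntegrityError(f"scheme must be 1..4, got {scheme!r}")
    # training rows also in the selection set (schemes 2/3/4 place K or A\V
    # around it) must never leak: remove train from the other two sets
    select -= train
    validate -= train

    for label, ids in (("train", train), ("selection", select),
                       ("validation", validate)):
        if not ids:
            raise TableIntegrityError(f"scheme {scheme}: empty {label} set")
    return PartitionScheme(
        name=f"scheme-{scheme}",
        train_ids=frozenset(train),
        selection_ids=frozenset(select),
        validation_ids=frozenset(validate),
    )


def write_scheme(scheme: PartitionScheme, path) -> None:
    doc = {
        "name": scheme.name,
        "train_ids": sorted(scheme.train_ids),
        "selection_ids": sorted(scheme.selection_ids),
        "validation_ids": sorted(scheme.validation_ids),
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def read_scheme(path) -> PartitionScheme:
    doc = json.loads(Path(path).read_text())
    return PartitionScheme(
        name=doc["name"],
        train_ids=frozenset(doc["train_ids"]),
        selection_ids=frozenset(doc["selection_ids"]),
        validation_ids=frozenset(doc["validation_ids"]),
    )
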