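"""Programmatic access to a loaded database for building new tools.

A :class:`FrameworkSession` wraps a database file read-only (by default)
and yields variant rows whose genotype blobs are already unpacked, so a
downstream script can write::

    with open_session("study.db") as s:
        for row in s.variants():
            gt, gt_type, phased, depth = row.genotypes("NA12878")

Everything the command-line ``query`` tool can produce is reachable here
with identical values; the CLI is a thin shell over this interface.
"""

from __future__ import annotations

import sqlite3
from typing import Iterator, Optional

from .db import SCHEMA_VERSION, DatabaseHandle, open_handle
from .gtstore import unpack
from .query import GT_COLUMNS, QueryRequest, execute_query

__all__ = ["FrameworkSession", "VariantRow", "open_session", "SchemaVersionError"]


class SchemaVersionError(RuntimeError):
    """Database written by an incompatible schema version."""


class VariantRow:
    """One variants-table row with attribute access and unpacked genotypes."""

    __slots__ = ("_data", "_arrays", "_sample_index")

    def __init__(self, data: dict, sample_index: dict[str, int]):
        self._data = data
        self._sample_index = sample_index
        self._arrays: Optional[dict] = None

    def __getattr__(self, name: str):
        try:
            if name in GT_COLUMNS:
                return self._unpacked()[name]
            return self._data[name]
        except KeyError:
            raise AttributeError(name) from None

    def __getitem__(self, name: str):
        if name in GT_COLUMNS:
            return self._unpacked()[name]
        return self._data[name]

    def keys(self):
        return self._data.keys()

    def _unpacked(self) -> dict:
        if self._arrays is None:
            self._arrays = {c: unpack(self._data[c]) for c in GT_COLUMNS}
        return self._arrays

    def genotypes(self, sample_id: str) -> tuple:
        """(gt string, gt_type code, phased, depth) for one sample."""
        try:
            idx = self._sample_index[sample_id]
        except KeyError:
            known = ", ".join(sorted(self._sample_index))
            raise KeyError(
                f"unknown sample {sample_id!r}; known samples: {known}"
            ) from None
        arrays = self._unpacked()
        return (
            arrays["gts"][idx],
            arrays["gt_types"][idx],
            arrays["gt_phases"][idx],
            arrays["gt_depths"][idx],
        )


def row_genotypes(row: VariantRow, sample_id: str) -> tuple:
    """Functional spelling of :meth:`VariantRow.genotypes`."""
    return row.genotypes(sample_id)


class FrameworkSession:
    def __init__(self, handle: DatabaseHandle, writable: bool = False):
        if handle.schema_version != SCHEMA_VERSION:
            raise SchemaVersionError(
                f"database schema v{handle.schema_version}, "
                f"this build reads v{SCHEMA_VERSION}"
            )
        self.handle = handle
        self.samples: list[str] = list(handle.sample_order)
        self.sample_index: dict[str, int] = {s: i for i, s in enumerate(self.samples)}
        mode = "rw" if writable else "ro"
        self._conn = sqlite3.connect(f"file:{handle.path}?mode={mode}", uri=True)
        self._conn.row_factory = sqlite3.Row

    # -- context management -------------------------------------------------
    def __enter__(self) -> "FrameworkSession":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def close(self) -> None:
        self._conn.close()

    # -- queries ------------------------------------------------------------
    def run(self, sql: str, gt_filter: Optional[str] = None, **kwargs):
        """Execute SQL (+ optional genotype filter); yields result tuples."""
        return execute_query(
            self.handle, QueryRequest(sql=sql, gt_filter=gt_filter, **kwargs)
        )

    def scalar(self, sql: str):
        """First column of the first row (e.g. a COUNT)."""
        return self._conn.execute(sql).fetchone()[0]

    def variants(self, where: Optional[str] = None) -> Iterator[VariantRow]:
        """Iterate variants-table rows with lazily unpacked genotypes."""
        sql = "SELECT * FROM variants"
        if where:
            sql += f" WHERE {where}"
        sql += " ORDER BY variant_id"
        for raw in self._conn.execute(sql):
            yield VariantRow(dict(raw), self.sample_index)

    def sample_rows(self) -> list[sqlite3.Row]:
        return list(self._conn.execute("SELECT * FROM samples ORDER BY sample_idx"))


def open_session(db_path: str, writable: bool = False) -> FrameworkSession:
    """Open an existing database; never creates a file."""
    return FrameworkSession(open_handle(db_path), writable=writable)
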