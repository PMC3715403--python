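"""The single-file variant warehouse: schema creation and loading.

Everything lives in one SQLite file — the ``variants`` table (one row per
post-split variant, with derived statistics, annotation columns, and the
four packed genotype blobs), ``variant_impacts`` (one row per transcript
consequence), ``samples`` (VCF header order joined with the pedigree), and
``resources`` (provenance: path + checksum of every input file). The file
can be opened by stock SQLite tooling and shared as-is.

Loading streams the VCF once, assigns ``variant_id`` sequentially over the
post-split record stream *before* any parallelism, and hands fixed-size
record chunks (default 10,000) to workers that compute statistics, overlap
annotations and packed blobs. Because per-record processing is pure and
blob bytes are deterministic, the loaded database content is identical for
any worker count and any chunk size — batching and parallelism are purely
operational knobs.
"""

from __future__ import annotations

import hashlib
import multiprocessing
import os
import sqlite3
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

from . import gtstore
from .annotate import AnnotationTrack, read_track_config
from .io_formats import (
    PedigreeEntry,
    ValidationError,
    parse_impacts,
    pick_primary_impact,
    read_ped,
    read_vcf,
)
from .stats import site_stats

__all__ = [
    "SCHEMA_VERSION",
    "DatabaseHandle",
    "ResourceRecord",
    "create_schema",
    "load",
    "merge_chunks",
    "DatabaseExistsError",
    "ChunkOverlapError",
]

SCHEMA_VERSION = 1

DEFAULT_CHUNK_SIZE = 10_000
DEFAULT_BATCH_SIZE = 5_000

# (column name, SQL type) for the variants table, in insert order.
CORE_VARIANT_COLUMNS: tuple[tuple[str, str], ...] = (
    ("variant_id", "INTEGER PRIMARY KEY"),
    ("chrom", "TEXT"),
    ("start", "INTEGER"),
    ("end", "INTEGER"),
    ("ref", "TEXT"),
    ("alt", "TEXT"),
    ("qual", "REAL"),
    ("filter", "TEXT"),
    ("type", "TEXT"),
    ("sub_type", "TEXT"),
    ("gene", "TEXT"),
    ("transcript", "TEXT"),
    ("impact", "TEXT"),
    ("impact_severity", "TEXT"),
    ("is_lof", "INTEGER"),
    ("aa_change", "TEXT"),
    ("num_hom_ref", "INTEGER"),
    ("num_het", "INTEGER"),
    ("num_hom_alt", "INTEGER"),
    ("num_unknown", "INTEGER"),
    ("call_rate", "REAL"),
    ("aaf", "REAL"),
    ("hwe_chi2", "REAL"),
    ("hwe", "REAL"),
    ("inbreeding_coeff", "REAL"),
    ("pi", "REAL"),
    ("gts", "BLOB"),
    ("gt_types", "BLOB"),
    ("gt_phases", "BLOB"),
    ("gt_depths", "BLOB"),
)

_TRACK_SQL_TYPE = {
    "boolean": "INTEGER",
    "count": "INTEGER",
    "extract": "TEXT",
    "extract_numeric": "REAL",
}


class DatabaseExistsError(FileExistsError):
    """Target database exists and overwrite was not requested."""


class ChunkOverlapError(ValueError):
    """Partial stores do not cover disjoint contiguous variant ranges."""


@dataclass
class ResourceRecord:
    name: str
    source_path: str
    version_or_checksum: str


@dataclass
class DatabaseHandle:
    path: str
    schema_version: int
    sample_order: list[str]

    def connect(self) -> sqlite3.Connection:
        conn = sqlite3.connect(self.path)
        conn.row_factory = sqlite3.Row
        return conn


def open_handle(path: str) -> DatabaseHandle:
    """Attach to an existing database file and read its metadata."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    conn = sqlite3.connect(path)
    try:
        version = int(
            conn.execute(
                "SELECT value FROM meta WHERE key='schema_version'"
            ).fetchone()[0]
        )
        order = [
            r[0]
            for r in conn.execute("SELECT name FROM samples ORDER BY sample_idx")
        ]
    finally:
        conn.close()
    return DatabaseHandle(path=path, schema_version=version, sample_order=order)


def _file_checksum(path: str) -> str:
    digest = hashlib.md5()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            digest.update(block)
    return digest.hexdigest()


def create_schema(
    conn: sqlite3.Connection, track_columns: Sequence[tuple[str, str]] = ()
) -> None:
    """Create all tables and indexes; ``track_columns`` extends variants."""
    core_names = {name for name, _ in CORE_VARIANT_COLUMNS}
    for name, _ in track_columns:
        if name in core_names:
            raise ValidationError(
                f"track column {name!r} collides with a core schema column"
            )
    columns = list(CORE_VARIANT_COLUMNS) + list(track_columns)
    cols_sql = ", ".join(f'"{n}" {t}' for n, t in columns)
    conn.executescript(
        f"""
        CREATE TABLE variants ({cols_sql});
        CREATE TABLE variant_impacts (
            variant_id INTEGER,
            gene TEXT,
            transcript TEXT,
            consequence TEXT,
            impact_severity TEXT,
            is_lof INTEGER,
            aa_change TEXT,
            is_primary INTEGER
        );
        CREATE TABLE samples (
            sample_idx INTEGER PRIMARY KEY,
            name TEXT UNIQUE NOT NULL,
            family_id TEXT,
            paternal_id TEXT,
            maternal_id TEXT,
            sex TEXT,
            phenotype TEXT
        );
        CREATE TABLE resources (
            name TEXT,
            source_path TEXT,
            version_or_checksum TEXT
        );
        CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
        CREATE INDEX idx_variants_region ON variants (chrom, start, "end");
        CREATE INDEX idx_variants_gene ON variants (gene);
        CREATE INDEX idx_variants_is_lof ON variants (is_lof);
        CREATE INDEX idx_variants_aaf ON variants (aaf);
        CREATE INDEX idx_impacts_variant ON variant_impacts (variant_id);
        """
    )
    conn.execute(
        "INSERT INTO meta VALUES ('schema_version', ?)", (str(SCHEMA_VERSION),)
    )


# ---------------------------------------------------------------------------
# chunk processing (runs in workers when cores > 1)

_WORKER_TRACKS: list[AnnotationTrack] = []


def _track_specs(tracks: Sequence[AnnotationTrack]) -> list[tuple]:
    return [
        (t.name, t.path, t.format, t.mode, t.extract_column, t.require_allele_match)
        for t in tracks
    ]


def _tracks_from_specs(specs) -> list[AnnotationTrack]:
    return [
        AnnotationTrack(
            name=n,
            path=p,
            format=f,
            mode=m,
            extract_column=c,
            require_allele_match=am,
        ).load()
        for n, p, f, m, c, am in specs
    ]


def _init_worker(specs) -> None:
    global _WORKER_TRACKS
    _WORKER_TRACKS = _tracks_from_specs(specs)


class _SiteView:
    """Minimal picklable stand-in carrying what chunk processing needs."""

    __slots__ = ("chrom", "start", "end", "ref", "alt", "variant_id")

    def __init__(self, chrom, start, end, ref, alt, variant_id):
        self.chrom = chrom
        self.start = start
        self.end = end
        self.ref = ref
        self.alt = alt
        self.variant_id = variant_id


def _process_record(rec: dict, tracks: list[AnnotationTrack]) -> tuple:
    from .annotate import annotate_variant

    stats = site_stats(rec["gt_types"])
    site = _SiteView(
        rec["chrom"], rec["start"], rec["end"], rec["ref"], rec["alt"], rec["vid"]
    )
    ann_values = [annotate_variant(site, t) for t in tracks]
    blobs = gtstore.pack(
        gtstore.GenotypeRow(
            gts=rec["gts"],
            gt_types=rec["gt_types"],
            gt_phases=rec["gt_phases"],
            gt_depths=rec["gt_depths"],
        )
    )
    s = stats
    total = s.num_hom_ref + s.num_het + s.num_hom_alt + s.num_unknown
    return (
        (
            rec["vid"],
            rec["chrom"],
            rec["start"],
            rec["end"],
            rec["ref"],
            rec["alt"],
            rec["qual"],
            rec["filter"],
            rec["type"],
            rec["sub_type"],
            *rec["primary"],
            s.num_hom_ref if total else None,
            s.num_het if total else None,
            s.num_hom_alt if total else None,
            s.num_unknown if total else None,
            s.call_rate,
            s.aaf,
            s.hwe_chi2,
            s.hwe_p,
            s.inbreeding_F,
            s.pi,
            *(b.data for b in blobs),
            *ann_values,
        ),
        rec["impacts"],
    )


def _process_chunk(chunk: list[dict]) -> tuple[list[tuple], list[tuple]]:
    variant_rows, impact_rows = [], []
    for rec in chunk:
        vrow, impacts = _process_record(rec, _WORKER_TRACKS)
        variant_rows.append(vrow)
        impact_rows.extend(impacts)
    return variant_rows, impact_rows


# ---------------------------------------------------------------------------
# loading


def _samples_rows(
    vcf_samples: list[str], ped: Optional[list[PedigreeEntry]]
) -> list[tuple]:
    if ped is None:
        return [(i, s, None, None, None, None, None) for i, s in enumerate(vcf_samples)]
    by_id = {e.sample_id: e for e in ped}
    missing_from_vcf = [s for s in by_id if s not in set(vcf_samples)]
    if missing_from_vcf:
        raise ValidationError(
            "PED samples absent from VCF: " + ", ".join(sorted(missing_from_vcf))
        )
    rows = []
    for i, s in enumerate(vcf_samples):
        e = by_id.get(s)
        if e is None:
            warnings.warn(f"VCF sample {s!r} not in PED; pedigree fields left null")
            rows.append((i, s, None, None, None, None, None))
        else:
            rows.append(
                (i, s, e.family_id, e.paternal_id, e.maternal_id, e.sex, e.phenotype)
            )
    return rows


def _stream_records(reader, first_variant_id: int):
    offset = first_variant_id - 1
    for site, row in reader:
        impacts = parse_impacts(site, reader.csq_fields)
        vid = site.variant_id + offset
        if impacts:
            primary = pick_primary_impact(impacts)
            primary_cols = (
                primary.gene,
                primary.transcript,
                primary.consequence,
                primary.impact_severity,
                int(primary.is_lof),
                primary.amino_acid_change,
            )
        else:
            primary_cols = (None, None, None, None, None, None)
        impact_rows = [
            (
                vid,
                i.gene,
                i.transcript,
                i.consequence,
                i.impact_severity,
                int(i.is_lof),
                i.amino_acid_change,
                int(i.is_primary),
            )
            for i in impacts
        ]
        yield {
            "vid": vid,
            "chrom": site.chrom,
            "start": site.start,
            "end": site.end,
            "ref": site.ref,
            "alt": site.alt,
            "qual": site.quality,
            "filter": site.filter,
            "type": site.type,
            "sub_type": site.sub_type,
            "primary": primary_cols,
            "impacts": impact_rows,
            "gts": row.gts,
            "gt_types": row.gt_types,
            "gt_phases": row.gt_phases,
            "gt_depths": row.gt_depths,
        }


def _chunked(iterable, size: int):
    chunk = []
    for item in iterable:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def load(
    db_path: str,
    vcf_path: str,
    ped_path: Optional[str] = None,
    tracks: Optional[Sequence[AnnotationTrack] | str] = None,
    cores: int = 1,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    batch_size: int = DEFAULT_BATCH_SIZE,
    overwrite: bool = False,
    first_variant_id: int = 1,
) -> DatabaseHandle:
    """Load a VCF (+ optional PED and annotation tracks) into a new database.

    ``cores`` > 1 processes record chunks in worker processes; the result
    is byte-identical to a single-core load. ``tracks`` may be a list of
    AnnotationTrack or a path to a track config file. ``first_variant_id``
    offsets the id sequence so that slices of one VCF can be loaded into
    partial stores and combined with :func:`merge_chunks`.
    """
    if cores < 1:
        raise ValueError("cores must be >= 1")
    if os.path.exists(db_path):
        if not overwrite:
            raise DatabaseExistsError(
                f"{db_path} exists; pass overwrite=True to replace it"
            )
        os.remove(db_path)

    if isinstance(tracks, str):
        tracks = read_track_config(tracks)
    tracks = list(tracks or [])

    reader = read_vcf(vcf_path)
    ped = read_ped(ped_path) if ped_path else None
    sample_rows = _samples_rows(reader.samples, ped)

    track_cols = [(t.name, _TRACK_SQL_TYPE[t.mode]) for t in tracks]
    conn = sqlite3.connect(db_path)
    try:
        create_schema(conn, track_cols)
        conn.executemany(
            "INSERT INTO samples VALUES (?,?,?,?,?,?,?)", sample_rows
        )
        resources = [("vcf", vcf_path, _file_checksum(vcf_path))]
        if ped_path:
            resources.append(("ped", ped_path, _file_checksum(ped_path)))
        resources += [(t.name, t.path, _file_checksum(t.path)) for t in tracks]
        conn.executemany("INSERT INTO resources VALUES (?,?,?)", resources)

        n_cols = len(CORE_VARIANT_COLUMNS) + len(track_cols)
        insert_sql = "INSERT INTO variants VALUES (%s)" % ",".join(["?"] * n_cols)
        impact_sql = "INSERT INTO variant_impacts VALUES (?,?,?,?,?,?,?,?)"

        chunks = _chunked(_stream_records(reader, first_variant_id), chunk_size)
        specs = _track_specs(tracks)

        def write(results) -> None:
            pending_v, pending_i = [], []
            for variant_rows, impact_rows in results:
                pending_v.extend(variant_rows)
                pending_i.extend(impact_rows)
                while len(pending_v) >= batch_size:
                    conn.executemany(insert_sql, pending_v[:batch_size])
                    pending_v = pending_v[batch_size:]
            if pending_v:
                conn.executemany(insert_sql, pending_v)
            if pending_i:
                conn.executemany(impact_sql, pending_i)

        if cores == 1:
            _init_worker(specs)
            write(_process_chunk(c) for c in chunks)
        else:
            ctx = multiprocessing.get_context("fork")
            with ctx.Pool(cores, initializer=_init_worker, initargs=(specs,)) as pool:
                write(pool.imap(_process_chunk, chunks))
        conn.commit()
    finally:
        conn.close()
    return open_handle(db_path)


def merge_chunks(partial_paths: Sequence[str], out_path: str) -> DatabaseHandle:
    """Merge partial stores covering disjoint contiguous variant-id ranges.

    Partials are produced by loading slices of one VCF with
    ``first_variant_id`` offsets (see :func:`load_slice` in callers); the
    merged file is identical to a single-shot load of the whole VCF.
    """
    spans = []
    for p in partial_paths:
        conn = sqlite3.connect(p)
        lo, hi, n = conn.execute(
            "SELECT MIN(variant_id), MAX(variant_id), COUNT(*) FROM variants"
        ).fetchone()
        conn.close()
        if n == 0:
            continue
        if hi - lo + 1 != n:
            raise ChunkOverlapError(f"{p}: variant ids not contiguous")
        spans.append((lo, hi, p))
    spans.sort()
    for (lo1, hi1, p1), (lo2, hi2, p2) in zip(spans, spans[1:]):
        if lo2 <= hi1:
            raise ChunkOverlapError(f"{p1} and {p2} overlap in variant ids")
        if lo2 != hi1 + 1:
            raise ChunkOverlapError(f"gap between {p1} and {p2}")

    if os.path.exists(out_path):
        os.remove(out_path)
    if not spans:
        raise ValueError("nothing to merge")
    first = spans[0][2]
    conn = sqlite3.connect(out_path)
    try:
        # clone schema (including any track columns) from the first partial
        src = sqlite3.connect(first)
        for (sql,) in src.execute(
            "SELECT sql FROM sqlite_master WHERE sql IS NOT NULL"
        ):
            conn.execute(sql)
        src.close()
        conn.execute("DELETE FROM meta")
        for _, _, p in spans:
            conn.execute("ATTACH ? AS part", (p,))
            conn.execute(
                "INSERT INTO variants SELECT * FROM part.variants "
                "ORDER BY variant_id"
            )
            conn.execute(
                "INSERT INTO variant_impacts SELECT * FROM part.variant_impacts "
                "ORDER BY variant_id"
            )
            conn.commit()
            conn.execute("DETACH part")
        conn.execute("ATTACH ? AS part", (first,))
        conn.execute("INSERT INTO samples SELECT * FROM part.samples")
        conn.execute("INSERT INTO resources SELECT * FROM part.resources")
        conn.execute("INSERT INTO meta SELECT * FROM part.meta")
        conn.commit()
        conn.execute("DETACH part")
    finally:
        conn.close()
    return open_handle(out_path)
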