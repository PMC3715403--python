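"""Decorate variants with columns derived from user-supplied interval tracks.

A track is a BED, GFF/GTF, or sites-only VCF file indexed into per-chromosome
interval trees. Every source format is normalized to 0-based half-open
coordinates at index build time (BED already is; GFF and VCF are 1-based).
Chromosome naming is bridged in both directions: intervals are registered
under both the verbatim name and its "chr"-toggled spelling, so a
``chr1`` VCF matches a ``1`` track and vice versa. Strand is ignored —
variants are unstranded.

Three extraction modes mirror how such tracks are typically consumed:

* ``boolean`` — 1 if the variant overlaps any interval, else 0
  (the "is this position in dbSNP / a CpG island?" column);
* ``count``   — the number of overlapping intervals;
* ``extract`` — values pulled from a column (BED) or attribute key (GFF)
  of the overlapping intervals, deduplicated, sorted and comma-joined so
  the result is independent of file order. ``extract_numeric`` takes the
  maximum instead.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Optional

from intervaltree import IntervalTree

from .io_formats import VariantSite

__all__ = [
    "AnnotationTrack",
    "build_index",
    "annotate_variant",
    "annotate_all",
    "read_track_config",
    "TrackFormatError",
    "TrackConfigError",
]

_MODES = ("boolean", "count", "extract", "extract_numeric")
_FORMATS = ("bed", "gff", "vcf-sites")


class TrackFormatError(ValueError):
    """A track file line could not be parsed."""


class TrackConfigError(ValueError):
    """Invalid track configuration (bad mode, duplicate name...)."""


def _chrom_keys(chrom: str) -> tuple[str, ...]:
    if chrom.startswith("chr"):
        return (chrom, chrom[3:])
    return (chrom, "chr" + chrom)


@dataclass
class AnnotationTrack:
    name: str
    path: str
    format: str  # bed | gff | vcf-sites
    mode: str = "boolean"
    extract_column: Optional[str] = None  # BED column index or GFF attribute key
    require_allele_match: bool = False  # vcf-sites only: REF+ALT must match
    index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.format not in _FORMATS:
            raise TrackConfigError(f"unknown track format {self.format!r}")
        if self.mode not in _MODES:
            raise TrackConfigError(f"unknown track mode {self.mode!r}")
        if self.mode.startswith("extract") and self.extract_column is None:
            raise TrackConfigError(f"track {self.name!r}: extract mode needs a column")
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_]*", self.name):
            raise TrackConfigError(f"{self.name!r} is not a column-safe name")

    def load(self) -> "AnnotationTrack":
        self.index = build_index(self.path, self.format)
        return self

    def query(self, chrom: str, start: int, end: int) -> list:
        """All source intervals overlapping [start, end) on chrom."""
        tree = self.index.get(chrom)
        if tree is None:
            for key in _chrom_keys(chrom):
                tree = self.index.get(key)
                if tree is not None:
                    break
        if tree is None:
            return []
        return sorted(tree.overlap(start, end))


def _parse_gff_attributes(text: str) -> dict:
    """Handle both GFF3 (key=value;) and GTF (key "value";) attribute styles."""
    attrs = {}
    for chunk in text.strip().strip(";").split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "=" in chunk:
            key, _, value = chunk.partition("=")
        else:
            key, _, value = chunk.partition(" ")
        attrs[key.strip()] = value.strip().strip('"')
    return attrs


def build_index(path: str, format: str) -> dict:
    """Index a track file as {chrom: IntervalTree}; intervals stored 0-based
    half-open with the source record's payload as interval data.

    Input need not be sorted. Dual "chr"-spelling keys are registered.
    """
    trees: dict[str, IntervalTree] = {}

    def add(chrom: str, start: int, end: int, payload) -> None:
        if end <= start:  # zero-width insertions still annotate their point
            end = start + 1
        for key in set(_chrom_keys(chrom)):
            trees.setdefault(key, IntervalTree()).addi(start, end, payload)

    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            try:
                if format == "bed":
                    add(cols[0], int(cols[1]), int(cols[2]), cols)
                elif format == "gff":
                    # GFF/GTF: 1-based inclusive -> half-open
                    payload = dict(enumerate(cols))
                    payload["attrs"] = (
                        _parse_gff_attributes(cols[8]) if len(cols) > 8 else {}
                    )
                    add(cols[0], int(cols[3]) - 1, int(cols[4]), payload)
                elif format == "vcf-sites":
                    pos, ref = int(cols[1]), cols[3].upper()
                    alts = cols[4].upper().split(",") if len(cols) > 4 else []
                    add(cols[0], pos - 1, pos - 1 + len(ref), (ref, alts, cols))
                else:
                    raise TrackFormatError(f"unknown format {format!r}")
            except (IndexError, ValueError) as exc:
                raise TrackFormatError(f"{path}:{lineno}: {exc}") from exc
    return trees


def _extract_value(track: AnnotationTrack, interval) -> Optional[str]:
    data = interval.data
    key = track.extract_column
    if track.format == "bed":
        idx = int(key)
        return data[idx] if idx < len(data) else None
    if track.format == "gff":
        try:
            return data["attrs"].get(key) or data.get(int(key))
        except (TypeError, ValueError):
            return data["attrs"].get(key)
    # vcf-sites: allow INFO-free numeric column extraction by index
    cols = data[2]
    idx = int(key)
    return cols[idx] if idx < len(cols) else None


def annotate_variant(site: VariantSite, track: AnnotationTrack):
    """One annotation value for one variant; region is [start, end)."""
    hits = track.query(site.chrom, site.start, site.end)
    if track.format == "vcf-sites" and track.require_allele_match:
        hits = [
            h
            for h in hits
            if h.data[0] == site.ref and site.alt in h.data[1]
        ]
    if track.mode == "boolean":
        return 1 if hits else 0
    if track.mode == "count":
        return len(hits)
    values = []
    for h in hits:
        v = _extract_value(track, h)
        if v is None:
            warnings.warn(
                f"track {track.name}: overlapping record lacks "
                f"{track.extract_column!r}; skipped"
            )
            continue
        values.append(v)
    if track.mode == "extract_numeric":
        nums = [float(v) for v in values]
        return max(nums) if nums else None
    return ",".join(sorted(set(values))) if values else None


def annotate_all(
    variants: list[VariantSite], tracks: list[AnnotationTrack]
) -> dict[int, dict[str, object]]:
    """Per-variant column map {variant_id: {track_name: value}}."""
    names = [t.name for t in tracks]
    if len(set(names)) != len(names):
        raise TrackConfigError("duplicate track names")
    for t in tracks:
        if not t.index:
            t.load()
    return {
        site.variant_id: {t.name: annotate_variant(site, t) for t in tracks}
        for site in variants
    }


def read_track_config(path: str) -> list[AnnotationTrack]:
    """Read a whitespace-delimited track config.

    Columns: name  path  format  mode  [extract_column]
    Lines starting with '#' are comments.
    """
    tracks = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 4:
                raise TrackConfigError(
                    f"{path}:{lineno}: expected 'name path format mode [column]'"
                )
            tracks.append(
                AnnotationTrack(
                    name=cols[0],
                    path=cols[1],
                    format=cols[2],
                    mode=cols[3],
                    extract_column=cols[4] if len(cols) > 4 else None,
                )
            )
    if len({t.name for t in tracks}) != len(tracks):
        raise TrackConfigError(f"{path}: duplicate track names")
    return tracks
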