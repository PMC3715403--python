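"""Compressed per-variant genotype arrays.

Each variant row stores four parallel arrays — genotype strings, genotype
type codes, phase flags, and read depths — one element per sample, packed
into independent zlib-compressed blobs held in single database columns.
Rare variants make the type array nearly constant (almost everyone is
homozygous reference), which is exactly what a general-purpose lossless
compressor exploits; the row count of the database stays equal to the
number of variants no matter how many samples there are.

Blob layout (version 1)::

    byte 0        codec_tag (currently 1)
    byte 1        kind: b'S' strings / b'I' int32 / b'B' bool
    bytes 2-5     adler32 of the uncompressed payload (big-endian)
    bytes 6-      zlib-compressed payload

String payloads are a uint32 element count followed by the UTF-8 strings
joined on the unit separator ``\\x1f``; integer payloads are little-endian
int32; boolean payloads are one byte per flag. Identical input arrays
always produce byte-identical blobs (zlib at a fixed level), which the
parallel loader relies on for chunk-count-independent output.
"""

from __future__ import annotations

import struct
import zlib
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np

__all__ = [
    "HOM_REF",
    "HET",
    "UNKNOWN",
    "HOM_ALT",
    "GT_TYPE_NAMES",
    "GenotypeRow",
    "PackedBlob",
    "encode_gt_type",
    "pack_array",
    "pack",
    "unpack",
    "sample_value",
    "CodecVersionError",
    "BlobIntegrityError",
]

# Public genotype-type codes; the query DSL exposes these as keywords.
HOM_REF = 0
HET = 1
UNKNOWN = 2
HOM_ALT = 3

GT_TYPE_NAMES = {"HOM_REF": HOM_REF, "HET": HET, "UNKNOWN": UNKNOWN, "HOM_ALT": HOM_ALT}

_CODEC_TAG = 1
_ZLEVEL = 6
_SEP = "\x1f"


class CodecVersionError(ValueError):
    """Blob written by an unknown codec version."""


class BlobIntegrityError(ValueError):
    """Blob bytes fail checksum or structural validation."""


@dataclass(frozen=True)
class PackedBlob:
    """An opaque compressed array; ``data`` is self-describing."""

    data: bytes

    @property
    def codec_tag(self) -> int:
        return self.data[0]

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class GenotypeRow:
    """The four per-sample arrays for one variant."""

    gts: list[str]
    gt_types: list[int]
    gt_phases: list[bool]
    gt_depths: list[int]

    def __post_init__(self) -> None:
        n = len(self.gts)
        if not (len(self.gt_types) == len(self.gt_phases) == len(self.gt_depths) == n):
            raise ValueError("genotype arrays must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.gts)


def encode_gt_type(gt_field: str, n_alt: int = 1) -> int:
    """Map a raw VCF GT field (e.g. ``0/1``, ``1|1``, ``.``) to a type code.

    Any uncalled allele makes the genotype UNKNOWN; two distinct called
    alleles are HET. Allele indices above ``n_alt`` raise, since they
    cannot refer to an allele of the record.
    """
    field = gt_field.strip()
    if field in ("", "."):
        return UNKNOWN
    alleles = []
    for tok in field.replace("|", "/").split("/"):
        if tok == ".":
            alleles.append(-1)
            continue
        try:
            idx = int(tok)
        except ValueError as exc:
            raise ValueError(f"bad GT field {gt_field!r}") from exc
        if idx < 0 or idx > n_alt:
            raise ValueError(
                f"allele index {idx} out of range for {n_alt} ALT allele(s)"
            )
        alleles.append(idx)
    if not alleles or any(a == -1 for a in alleles):
        return UNKNOWN
    first = alleles[0]
    if any(a != first for a in alleles[1:]):
        return HET
    return HOM_REF if first == 0 else HOM_ALT


def _frame(kind: bytes, payload: bytes) -> PackedBlob:
    header = struct.pack(">BcI", _CODEC_TAG, kind, zlib.adler32(payload))
    return PackedBlob(header + zlib.compress(payload, _ZLEVEL))


def pack_array(values: Sequence) -> PackedBlob:
    """Pack one array (strings, ints, or bools) into a compressed blob."""
    values = list(values)
    if values and isinstance(values[0], str):
        body = _SEP.join(values).encode("utf-8")
        payload = struct.pack("<I", len(values)) + body
        return _frame(b"S", payload)
    if values and isinstance(values[0], (bool, np.bool_)):
        return _frame(b"B", np.asarray(values, dtype=np.uint8).tobytes())
    if not values:
        # empty cohort: default to the integer kind; all kinds round-trip
        return _frame(b"I", b"")
    return _frame(b"I", np.asarray(values, dtype="<i4").tobytes())


def pack(row: GenotypeRow) -> tuple[PackedBlob, PackedBlob, PackedBlob, PackedBlob]:
    """Pack a GenotypeRow into its four blobs (gts, types, phases, depths)."""
    return (
        pack_array(row.gts),
        pack_array(row.gt_types),
        _frame(b"B", np.asarray(row.gt_phases, dtype=np.uint8).tobytes()),
        pack_array(row.gt_depths),
    )


def unpack(blob: Union[PackedBlob, bytes]) -> list:
    """Recover the exact original array from a blob."""
    data = blob.data if isinstance(blob, PackedBlob) else bytes(blob)
    if len(data) < 6:
        raise BlobIntegrityError("blob too short")
    tag, kind, checksum = struct.unpack(">BcI", data[:6])
    if tag != _CODEC_TAG:
        raise CodecVersionError(f"unknown codec_tag {tag}")
    try:
        payload = zlib.decompress(data[6:])
    except zlib.error as exc:
        raise BlobIntegrityError(f"corrupted blob: {exc}") from exc
    if zlib.adler32(payload) != checksum:
        raise BlobIntegrityError("checksum mismatch")
    if kind == b"S":
        (count,) = struct.unpack("<I", payload[:4])
        if count == 0:
            return []
        return payload[4:].decode("utf-8").split(_SEP)
    if kind == b"B":
        return [bool(b) for b in payload]
    if kind == b"I":
        return [int(v) for v in np.frombuffer(payload, dtype="<i4")]
    raise BlobIntegrityError(f"unknown array kind {kind!r}")


def sample_value(blob: Union[PackedBlob, bytes], sample_index: int):
    """Value for one sample from a packed blob; bounds-checked."""
    values = unpack(blob)
    if not 0 <= sample_index < len(values):
        raise IndexError(
            f"sample index {sample_index} out of range for {len(values)} samples"
        )
    return values[sample_index]
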