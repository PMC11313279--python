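"""Minimal ABIF (.ab1) container reading and writing.

ABIF is the tagged binary container produced by Applied Biosystems DNA
analyzers: a 128-byte header whose single ``tdir`` entry points at a
directory of 28-byte entries, each naming a typed record (big-endian
throughout).  Only the records the genotyping pipeline consumes are exposed:

========  =============================================
``DATA``  9-12  analyzed trace, one channel per record
``FWO_``  1     channel order (maps DATA9-12 to bases)
``PBAS``  1/2   called bases (edited / basecaller)
``PLOC``  1/2   per-base peak locations (edited / basecaller)
``SMPL``  1     sample name
========  =============================================

Where both the user-editable (tag number 1) and basecaller-original (tag
number 2) versions of a record exist, the editable one is preferred.  All
indices are 0-based.  Raw traces, mobility data and quality values are out
of scope: peak locations index the *analyzed* traces, which is the signal
the genotyping model operates on.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .errors import IoError, MalformedDirectoryError, MissingRecordError, NotAbifError

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_MAGIC = b"ABIF"
_VERSION = 101
_DIR_ENTRY = struct.Struct(">4sihhiiii")
_HEADER_SIZE = 128

# ABIF element type codes -> struct format characters
_ELEMENT_FMT = {1: "B", 2: "s", 4: "h", 5: "i", 7: "f", 8: "d"}
_TYPE_BYTE, _TYPE_CHAR, _TYPE_SHORT, _TYPE_LONG = 1, 2, 4, 5
_TYPE_PSTRING, _TYPE_CSTRING = 18, 19


@dataclass
class AbifRecord:
    """One decoded directory record.

    ``payload`` is ``bytes`` for character-like types and a numpy array for
    numeric types; the decoded element count always equals the directory
    entry's element count.
    """

    tag_name: str
    tag_number: int
    element_type: int
    payload: bytes | np.ndarray


@dataclass
class ChromatogramRead:
    """One direction's parsed chromatogram.

    ``traces`` is keyed by nucleotide (A, C, G, T) after resolving the
    file's channel-order record, never by on-disk position.  ``direction``
    is assigned by the caller; nothing in an ABIF file states it.
    """

    sample_name: str
    direction: str
    called_bases: str
    peak_locations: np.ndarray
    traces: dict[str, np.ndarray]
    trace_length: int = field(default=0)

    def __post_init__(self):
        if self.direction not in ("forward", "reverse"):
            raise ValueError(f"direction must be forward/reverse, got {self.direction!r}")
        self.peak_locations = np.asarray(self.peak_locations, dtype=np.int64)
        self.traces = {b: np.asarray(t, dtype=np.int64) for b, t in self.traces.items()}
        if set(self.traces) != set(BASES):
            raise ValueError("traces must have exactly the four keys A, C, G, T")
        lengths = {len(t) for t in self.traces.values()}
        if len(lengths) != 1:
            raise ValueError("all four trace arrays must have identical length")
        self.trace_length = lengths.pop()
        if len(self.called_bases) != len(self.peak_locations):
            raise ValueError("called_bases and peak_locations must have equal length")
        if any(b not in "ACGTN" for b in self.called_bases):
            raise ValueError("called bases must be over {A,C,G,T,N}")
        if len(self.peak_locations) > 0:
            if np.any(np.diff(self.peak_locations) <= 0):
                raise ValueError("peak_locations must be strictly increasing")
            if self.peak_locations[0] < 0 or self.peak_locations[-1] >= self.trace_length:
                raise ValueError("peak locations must lie inside the trace arrays")
        if any(np.any(t < 0) for t in self.traces.values()):
            raise ValueError("analyzed traces must be non-negative")

    def __eq__(self, other):
        if not isinstance(other, ChromatogramRead):
            return NotImplemented
        return (
            self.sample_name == other.sample_name
            and self.direction == other.direction
            and self.called_bases == other.called_bases
            and np.array_equal(self.peak_locations, other.peak_locations)
            and all(np.array_equal(self.traces[b], other.traces[b]) for b in BASES)
        )


def _decode(entry_bytes: bytes, data: bytes) -> AbifRecord:
    name, number, etype, esize, nelem, dsize, _off, _handle = _DIR_ENTRY.unpack(entry_bytes)
    tag = name.decode("ascii", errors="replace")
    if etype in (_TYPE_CHAR, _TYPE_PSTRING, _TYPE_CSTRING):
        if etype == _TYPE_PSTRING:
            payload = data[1 : 1 + data[0]] if data else b""
        elif etype == _TYPE_CSTRING:
            payload = data.split(b"\x00", 1)[0]
        else:
            payload = data
    elif etype in _ELEMENT_FMT:
        fmt = ">" + str(nelem) + _ELEMENT_FMT[etype]
        try:
            payload = np.array(struct.unpack(fmt, data))
        except struct.error as exc:
            raise MalformedDirectoryError(f"record {tag}{number}: {exc}") from exc
    else:
        payload = data  # unknown type: keep raw bytes
    return AbifRecord(tag, number, etype, payload)


def _read_directory(blob: bytes) -> dict[tuple[str, int], AbifRecord]:
    if len(blob) < _HEADER_SIZE:
        raise MalformedDirectoryError("file shorter than the 128-byte ABIF header")
    tdir = _DIR_ENTRY.unpack(blob[6 : 6 + _DIR_ENTRY.size])
    _name, _num, _etype, esize, nelem, dsize, offset, _handle = tdir
    if esize != _DIR_ENTRY.size or nelem < 0 or offset < 0 or offset + nelem * esize > len(blob):
        raise MalformedDirectoryError("tdir entry offset/length out of bounds")
    records: dict[tuple[str, int], AbifRecord] = {}
    for i in range(nelem):
        entry = blob[offset + i * esize : offset + (i + 1) * esize]
        name, number, etype, el_size, el_num, data_size, data_off, _h = _DIR_ENTRY.unpack(entry)
        if data_size <= 4:
            data = entry[20:24][:data_size]  # small payloads live in the offset field
        else:
            if data_off < 0 or data_off + data_size > len(blob):
                raise MalformedDirectoryError(
                    f"record {name.decode(errors='replace')}{number}: data outside file"
                )
            data = blob[data_off : data_off + data_size]
        key = (name.decode("ascii", errors="replace"), number)
        if key in records:
            raise MalformedDirectoryError(f"duplicate directory entry {key}")
        records[key] = _decode(entry, data)
    return records


def _prefer(records, tag: str):
    """Editable (tag number 1) preferred over basecaller original (2)."""
    for number in (1, 2):
        if (tag, number) in records:
            return records[(tag, number)]
    raise MissingRecordError(tag)


def read_abif(path, direction: str = "forward") -> ChromatogramRead:
    """Parse an ABIF file into a :class:`ChromatogramRead`.

    ``direction`` is assigned by the caller — the ABIF container does not
    record which sequencing primer produced the read.
    """
    try:
        with open(path, "rb") as fh:
            blob = fh.read()
    except OSError as exc:
        raise IoError(str(exc)) from exc
    if blob[:4] != _MAGIC:
        raise NotAbifError(f"{path}: first four bytes are {blob[:4]!r}, not b'ABIF'")
    records = _read_directory(blob)

    fwo = records.get(("FWO_", 1))
    if fwo is None:
        raise MissingRecordError("FWO_", 1)
    order = bytes(fwo.payload).decode("ascii")
    if sorted(order) != sorted(BASES):
        raise MalformedDirectoryError(f"channel-order record is {order!r}, not a permutation of ACGT")

    traces = {}
    for i, base in enumerate(order):
        rec = records.get(("DATA", 9 + i))
        if rec is None:
            raise MissingRecordError("DATA", 9 + i)
        traces[base] = np.asarray(rec.payload, dtype=np.int64)

    pbas = _prefer(records, "PBAS")
    ploc = _prefer(records, "PLOC")
    sample = records.get(("SMPL", 1))
    name = bytes(sample.payload).decode("ascii", errors="replace") if sample else ""
    return ChromatogramRead(
        sample_name=name,
        direction=direction,
        called_bases=bytes(pbas.payload).decode("ascii"),
        peak_locations=np.asarray(ploc.payload, dtype=np.int64),
        traces=traces,
    )


def _encode(tag: str, number: int, etype: int, payload) -> tuple[bytes, bytes]:
    """Return (28-byte directory entry sans offset fields, data blob)."""
    if etype == _TYPE_CHAR:
        data = bytes(payload)
        nelem, esize = len(data), 1
    elif etype == _TYPE_PSTRING:
        raw = bytes(payload)
        if len(raw) > 255:
            raise IoError("pString payload longer than 255 bytes")
        data = bytes([len(raw)]) + raw
        nelem, esize = len(data), 1
    elif etype in _ELEMENT_FMT:
        arr = np.asarray(payload)
        esize = struct.calcsize(_ELEMENT_FMT[etype])
        lo, hi = (0, 255) if etype == _TYPE_BYTE else (-(2 ** (8 * esize - 1)), 2 ** (8 * esize - 1) - 1)
        if arr.size and (arr.min() < lo or arr.max() > hi):
            raise IoError(f"record {tag}{number}: values out of range for element type {etype}")
        data = struct.pack(">" + str(arr.size) + _ELEMENT_FMT[etype], *arr.tolist())
        nelem = arr.size
    else:
        raise IoError(f"unsupported element type {etype} for writing")
    return (tag.encode("ascii"), number, etype, esize, nelem, len(data)), data


def write_abif(read: ChromatogramRead, path, channel_order: str = "GATC"):
    """Serialize ``read`` as a minimal valid ABIF file.

    Traces are written in ``channel_order`` with a matching ``FWO_`` record,
    so a position-blind reader would mis-assign them — the round trip through
    :func:`read_abif` is exact regardless of the order chosen.  Called bases
    and peak locations are duplicated into tag numbers 1 and 2, mirroring
    analyzer output where the editable and original records start identical.
    """
    if sorted(channel_order) != sorted(BASES):
        raise IoError(f"channel_order {channel_order!r} is not a permutation of ACGT")
    specs = []
    for i, base in enumerate(channel_order):
        specs.append(("DATA", 9 + i, _TYPE_SHORT, read.traces[base]))
    specs.append(("FWO_", 1, _TYPE_CHAR, channel_order.encode("ascii")))
    basecalls = read.called_bases.encode("ascii")
    for number in (1, 2):
        specs.append(("PBAS", number, _TYPE_CHAR, basecalls))
        specs.append(("PLOC", number, _TYPE_SHORT, read.peak_locations))
    specs.append(("SMPL", 1, _TYPE_PSTRING, read.sample_name.encode("ascii")))

    blobs, entries = [], []
    offset = _HEADER_SIZE
    for tag, number, etype, payload in specs:
        (name, num, et, esize, nelem, dsize), data = _encode(tag, number, etype, payload)
        if dsize <= 4:
            data_off = int.from_bytes(data.ljust(4, b"\x00"), "big")
            stored = b""
        else:
            data_off = offset
            stored = data
            offset += dsize
        entries.append(_DIR_ENTRY.pack(name, num, et, esize, nelem, dsize, data_off, 0))
        blobs.append(stored)

    dir_offset = offset
    tdir = _DIR_ENTRY.pack(
        b"tdir", 1, 1023, _DIR_ENTRY.size, len(entries), len(entries) * _DIR_ENTRY.size, dir_offset, 0
    )
    header = _MAGIC + struct.pack(">h", _VERSION) + tdir
    header = header.ljust(_HEADER_SIZE, b"\x00")
    try:
        with open(path, "wb") as fh:
            fh.write(header)
            for blob in blobs:
                fh.write(blob)
            for entry in entries:
                fh.write(entry)
    except OSError as exc:
        raise IoError(str(exc)) from exc
    return path
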