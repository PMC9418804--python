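"""Map-reduce-style preprocessing of patient event records.

Records are hashed by person_id into a fixed number of partitions so that
all data of one patient lands in exactly one partition and each partition
fits in memory for per-partition group-and-sort.  Partitions are persisted
in a compact length-prefixed binary layout (optionally deflate-compressed)
with a plain-text JSON manifest; operations are pure per partition, so
callers may process partitions independently and in any order.
"""

from __future__ import annotations

import hashlib
import json
import struct
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

from .events import Event, PatientTimeline

FORMAT_VERSION = "claimseq-partition-1"
MANIFEST_NAME = "manifest.json"

__all__ = [
    "PartitionSpec",
    "stable_hash",
    "partition_records",
    "read_partition",
    "reduce_partition",
    "iter_timelines",
    "stream_minibatches",
]


def _fnv1a_64(data: bytes) -> int:
    h = 0xCBF29CE484222325
    for byte in data:
        h ^= byte
        h = (h * 0x100000001B3) & 0xFFFFFFFFFFFFFFFF
    return h


def stable_hash(person_id: str, hash_name: str = "md5") -> int:
    """Platform- and process-stable 64-bit hash of a person identifier.

    Python's built-in ``hash`` is salted per process and must never be used
    for partitioning; both offered hashes are published and deterministic.
    """
    data = person_id.encode("utf-8")
    if hash_name == "md5":
        return int.from_bytes(hashlib.md5(data).digest()[:8], "little")
    if hash_name == "fnv1a":
        return _fnv1a_64(data)
    raise ValueError(f"unknown hash_name {hash_name!r} (use 'md5' or 'fnv1a')")


@dataclass(frozen=True)
class PartitionSpec:
    n_partitions: int = 1000
    hash_name: str = "md5"
    compression: str = "none"  # or "deflate"

    def __post_init__(self) -> None:
        if self.n_partitions < 1:
            raise ValueError("n_partitions must be >= 1")
        if self.compression not in ("none", "deflate"):
            raise ValueError("compression must be 'none' or 'deflate'")
        stable_hash("probe", self.hash_name)  # validates hash_name

    def partition_of(self, person_id: str) -> int:
        return stable_hash(person_id, self.hash_name) % self.n_partitions


def _encode_record(person_id: str, concept_id: str, day: int) -> bytes:
    p = person_id.encode("utf-8")
    c = concept_id.encode("utf-8")
    return b"".join(
        [struct.pack("<I", len(p)), p, struct.pack("<i", day), struct.pack("<I", len(c)), c]
    )


def _partition_path(out_dir: Path, index: int, n: int) -> Path:
    width = max(5, len(str(n - 1)))
    return out_dir / f"part-{index:0{width}d}"


def partition_records(
    event_stream: Iterable[tuple[str, str, int]],
    spec: PartitionSpec,
    out_dir,
) -> dict:
    """Route (person_id, concept_id, day) records into hashed partition files.

    Every record of one patient goes to partition ``hash(person_id) mod N``;
    the record multiset is preserved exactly.  Returns the manifest (also
    written to ``out_dir/manifest.json``): partition count, hash name,
    compression, per-partition record counts and format version.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    buffers: list[bytearray] = [bytearray() for _ in range(spec.n_partitions)]
    counts = [0] * spec.n_partitions
    for i, rec in enumerate(event_stream):
        try:
            person_id, concept_id, day = rec
            payload = _encode_record(str(person_id), str(concept_id), int(day))
        except Exception as exc:  # noqa: BLE001 - re-raise with locator
            raise ValueError(f"malformed record at position {i}: {rec!r}") from exc
        part = spec.partition_of(str(person_id))
        buffers[part] += payload
        counts[part] += 1
    for idx, buf in enumerate(buffers):
        data = bytes(buf)
        if spec.compression == "deflate":
            data = zlib.compress(data, level=6)
        _partition_path(out, idx, spec.n_partitions).write_bytes(data)
    manifest = {
        "format_version": FORMAT_VERSION,
        "n_partitions": spec.n_partitions,
        "hash_name": spec.hash_name,
        "compression": spec.compression,
        "record_counts": counts,
        "total_records": sum(counts),
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1))
    return manifest


def read_manifest(part_dir) -> dict:
    path = Path(part_dir) / MANIFEST_NAME
    if not path.exists():
        raise FileNotFoundError(f"partition manifest not found: {path}")
    manifest = json.loads(path.read_text())
    if manifest.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported partition format {manifest.get('format_version')!r}"
        )
    return manifest


def read_partition(part_dir, index: int) -> list[tuple[str, str, int]]:
    """Decode one partition file back into its raw record list."""
    manifest = read_manifest(part_dir)
    path = _partition_path(Path(part_dir), index, manifest["n_partitions"])
    if not path.exists():
        raise FileNotFoundError(f"missing partition file: {path}")
    data = path.read_bytes()
    if manifest["compression"] == "deflate":
        data = zlib.decompress(data)
    records: list[tuple[str, str, int]] = []
    off = 0
    while off < len(data):
        (plen,) = struct.unpack_from("<I", data, off)
        off += 4
        person = data[off : off + plen].decode("utf-8")
        off += plen
        (day,) = struct.unpack_from("<i", data, off)
        off += 4
        (clen,) = struct.unpack_from("<I", data, off)
        off += 4
        concept = data[off : off + clen].decode("utf-8")
        off += clen
        records.append((person, concept, day))
    return records


def reduce_partition(
    records: Sequence[tuple[str, str, int]],
) -> list[PatientTimeline]:
    """Group one partition's records by patient and sort each by time.

    Duplicate records are retained as-is — repeated identical claims are
    legitimate.  Output is deterministic regardless of input order: patients
    come out sorted by person_id and events by (day, concept_id).
    """
    grouped: dict[str, list[tuple[int, str]]] = {}
    for person, concept, day in records:
        grouped.setdefault(person, []).append((day, concept))
    out = []
    for person in sorted(grouped):
        events = (Event(concept_id=c, day=d) for d, c in grouped[person])
        out.append(PatientTimeline.from_events(person, events))
    return out


def iter_timelines(part_dir) -> Iterator[PatientTimeline]:
    """Reduce every partition in manifest order and yield all timelines."""
    manifest = read_manifest(part_dir)
    for idx in range(manifest["n_partitions"]):
        if manifest["record_counts"][idx] == 0:
            continue
        yield from reduce_partition(read_partition(part_dir, idx))


def stream_minibatches(
    part_dir, batch_size: int, seed: int
) -> Iterator[list[PatientTimeline]]:
    """Yield every patient timeline exactly once, shuffled, in mini-batches.

    The shuffle is deterministic given ``seed``; the final batch may be
    short.  Partitions are materialized up front (they are sized to fit in
    memory by construction), so the shuffle is global rather than blockwise.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    timelines = list(iter_timelines(part_dir))
    order = np.random.default_rng(seed).permutation(len(timelines))
    for start in range(0, len(timelines), batch_size):
        yield [timelines[i] for i in order[start : start + batch_size]]
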