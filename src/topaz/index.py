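"""Protein database ingestion and suffix-array indexing.

The database is a set of proteins concatenated into one text ``T``, each
sequence followed by a single ``*`` delimiter (including the last).  The
delimiter is an ordinary alphabet symbol: it collates at whatever rank
the chosen ordering assigns it, so suffixes spanning a protein boundary
compare like any other suffix.  The suffix array is built over the
rank-encoded text with a prefix-doubling sort, giving exact collation
under arbitrary orderings without any alphabet-specific assumptions.
"""

from __future__ import annotations

import hashlib
import io
import json
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .alphabet import (
    DELIMITER,
    AlphabetOrdering,
    SubstitutionMatrix,
    normalize_sequence,
)

_MAGIC = b"TOPAZIDX"
_VERSION = 1


class FastaError(ValueError):
    """Malformed or empty FASTA input."""


class IndexError_(RuntimeError):
    """Corrupt, truncated or incompatible index file; rebuild the index."""


@dataclass(frozen=True)
class ProteinRecord:
    id: str
    description: str
    sequence: str


@dataclass(frozen=True)
class ProteinDatabase:
    records: list[ProteinRecord]

    @property
    def total_residues(self) -> int:
        return sum(len(r.sequence) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i: int) -> ProteinRecord:
        return self.records[i]


def database_from_sequences(pairs, descriptions=None) -> ProteinDatabase:
    """Build a database from ``(id, sequence)`` pairs, normalizing residues."""
    records = []
    seen = set()
    descriptions = descriptions or {}
    for ident, seq in pairs:
        if ident in seen:
            raise FastaError(f"duplicate sequence identifier {ident!r}")
        seen.add(ident)
        norm = normalize_sequence(seq)
        if not norm:
            raise FastaError(f"record {ident!r} has an empty sequence")
        records.append(ProteinRecord(ident, descriptions.get(ident, ""), norm))
    if not records:
        raise FastaError("no sequences found")
    return ProteinDatabase(records=records)


def read_fasta(path) -> ProteinDatabase:
    """Read a multi-record FASTA file into a normalized protein database."""
    pairs = []
    descriptions = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        pairs.append((rec.id, str(rec.seq)))
        descriptions[rec.id] = rec.description
    if not pairs:
        raise FastaError(f"no FASTA records in {path}")
    return database_from_sequences(pairs, descriptions)


@dataclass
class SuffixIndex:
    """Suffix array over the delimiter-joined, rank-encoded database text."""

    text: np.ndarray          # uint8 ranks, length = residues + #proteins
    sa: np.ndarray            # int64, permutation of 0..len(text)-1
    boundaries: np.ndarray    # int64 start offset of each protein in text
    ids: list[str]
    ordering: AlphabetOrdering
    matrix_name: str
    protein_of_pos: np.ndarray = field(default=None, repr=False)
    delim_dist: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.protein_of_pos is None:
            self.protein_of_pos = (
                np.searchsorted(self.boundaries, np.arange(len(self.text)), side="right")
                - 1
            ).astype(np.int32)
        if self.delim_dist is None:
            # scorable residues from each position up to the next delimiter
            n = len(self.text)
            delim_pos = np.nonzero(self.text == self.ordering.delimiter_rank)[0]
            nxt = delim_pos[np.searchsorted(delim_pos, np.arange(n), side="left")]
            self.delim_dist = (nxt - np.arange(n)).astype(np.int32)

    @property
    def n_proteins(self) -> int:
        return len(self.boundaries)

    def protein_at(self, text_pos: int) -> int:
        """Ordinal of the protein whose span (residues + its trailing
        delimiter) contains ``text_pos``."""
        if not 0 <= text_pos < len(self.text):
            raise IndexError_(f"text position {text_pos} out of range")
        return int(self.protein_of_pos[text_pos])

    def protein_sequence(self, ordinal: int) -> str:
        start = int(self.boundaries[ordinal])
        end = (
            int(self.boundaries[ordinal + 1]) - 1
            if ordinal + 1 < self.n_proteins
            else len(self.text) - 1
        )
        return self.ordering.decode(self.text[start:end])


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Prefix-doubling suffix array over an integer-coded text."""
    n = len(codes)
    rank = codes.astype(np.int64)
    k = 1
    order = np.argsort(rank, kind="stable")
    while True:
        key2 = np.full(n, -1, dtype=np.int64)
        if k < n:
            key2[: n - k] = rank[k:]
        order = np.lexsort((key2, rank))
        r1 = rank[order]
        r2 = key2[order]
        changed = np.empty(n, dtype=bool)
        changed[0] = True
        changed[1:] = (r1[1:] != r1[:-1]) | (r2[1:] != r2[:-1])
        new_rank = np.empty(n, dtype=np.int64)
        new_rank[order] = np.cumsum(changed) - 1
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order.astype(np.int64)
        k *= 2


def build_index(
    db: ProteinDatabase, ordering: AlphabetOrdering, matrix: SubstitutionMatrix
) -> SuffixIndex:
    """Concatenate, encode and suffix-sort a protein database."""
    if len(db) == 0:
        raise FastaError("cannot index an empty database")
    joined = DELIMITER.join(r.sequence for r in db.records) + DELIMITER
    text = ordering.encode(joined)
    boundaries = np.empty(len(db), dtype=np.int64)
    off = 0
    for i, rec in enumerate(db.records):
        boundaries[i] = off
        off += len(rec.sequence) + 1
    sa = _suffix_array(text)
    return SuffixIndex(
        text=text,
        sa=sa,
        boundaries=boundaries,
        ids=[r.id for r in db.records],
        ordering=ordering,
        matrix_name=matrix.name,
    )


def save_index(index: SuffixIndex, path) -> None:
    """Write a versioned, checksummed binary index file.

    Layout: magic, version, little-endian section lengths, JSON metadata
    (ordering, matrix name, protein ids, boundaries), uint8 text, int64
    suffix array, then a SHA-256 checksum over everything before it.
    """
    meta = json.dumps(
        {
            "ordering": index.ordering.order,
            "matrix_name": index.matrix_name,
            "ids": index.ids,
            "boundaries": index.boundaries.tolist(),
        }
    ).encode()
    buf = io.BytesIO()
    buf.write(_MAGIC)
    buf.write(struct.pack("<H", _VERSION))
    text_bytes = index.text.astype(np.uint8).tobytes()
    sa_bytes = index.sa.astype("<i8").tobytes()
    buf.write(struct.pack("<QQQ", len(meta), len(text_bytes), len(sa_bytes)))
    buf.write(meta)
    buf.write(text_bytes)
    buf.write(sa_bytes)
    payload = buf.getvalue()
    digest = hashlib.sha256(payload).digest()
    Path(path).write_bytes(payload + digest)


def load_index(path) -> SuffixIndex:
    """Load and verify an index written by :func:`save_index`."""
    raw = Path(path).read_bytes()
    if len(raw) < len(_MAGIC) + 2 + 24 + 32 or raw[: len(_MAGIC)] != _MAGIC:
        raise IndexError_(f"{path} is not an index file; rebuild the index")
    payload, digest = raw[:-32], raw[-32:]
    if hashlib.sha256(payload).digest() != digest:
        raise IndexError_(f"checksum mismatch in {path}; rebuild the index")
    off = len(_MAGIC)
    (version,) = struct.unpack_from("<H", payload, off)
    off += 2
    if version != _VERSION:
        raise IndexError_(
            f"index format version {version} != {_VERSION}; rebuild the index"
        )
    meta_len, text_len, sa_len = struct.unpack_from("<QQQ", payload, off)
    off += 24
    meta = json.loads(payload[off : off + meta_len])
    off += meta_len
    text = np.frombuffer(payload[off : off + text_len], dtype=np.uint8).copy()
    off += text_len
    sa = np.frombuffer(payload[off : off + sa_len], dtype="<i8").astype(np.int64)
    return SuffixIndex(
        text=text,
        sa=sa,
        boundaries=np.asarray(meta["boundaries"], dtype=np.int64),
        ids=list(meta["ids"]),
        ordering=AlphabetOrdering(order=meta["ordering"]),
        matrix_name=meta["matrix_name"],
    )
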