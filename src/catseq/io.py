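"""FASTA ingestion, profile sidecar persistence, and synthetic fixtures.

Profiles are persisted as JSON-lines "sidecar" files — one record per
sequence, schema version 1 — so a store is appendable and streamable.  A
round trip through the sidecar is lossless: floats are serialised with
Python's shortest round-tripping repr, and the reloaded profile compares
bit-equal to the in-memory one, which is what lets look-ups skip the heavy
profile computation entirely.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaFormatError, SchemaError
from .profiling import CatProfile, Provenance

SCHEMA_VERSION = 1

_VALID_SEQ = re.compile(r"^[ACGT]*$")


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence, uppercase and alphabet-validated."""

    id: str
    sequence: str


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Parse a FASTA file into validated records, in file order.

    Sequences are uppercased; line wrapping is ignored.  Raises
    :class:`FastaFormatError` for a missing ``>`` header (with line number),
    an empty sequence, a duplicate id, or a base outside {A, C, G, T}
    (naming the record and position).
    """
    path = Path(path)
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaFormatError(
                        f"{path}: line {lineno}: expected FASTA header "
                        f"starting with '>', got {line.strip()[:30]!r}"
                    )
                break
        else:
            return  # empty file -> empty stream

    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty id")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaFormatError(
                f"{path}: record {rec.id!r} has an empty sequence"
            )
        if not _VALID_SEQ.match(seq):
            pos = next(i for i, c in enumerate(seq) if c not in "ACGT")
            raise FastaFormatError(
                f"{path}: record {rec.id!r}: invalid base {seq[pos]!r} "
                f"at position {pos}"
            )
        yield SequenceRecord(rec.id, seq)


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as wrapped FASTA."""
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def generate_fixtures(
    n_sequences: int, length: int, seed: int
) -> list[SequenceRecord]:
    """Seeded synthetic sequences: uniform i.i.d. bases, ids ``synth_<k>``."""
    if n_sequences < 1 or length < 1:
        raise ValueError("n_sequences and length must be >= 1")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype=np.uint8)
    draws = rng.integers(0, 4, size=(n_sequences, length))
    return [
        SequenceRecord(f"synth_{k}", alphabet[draws[k]].tobytes().decode("ascii"))
        for k in range(n_sequences)
    ]


def _provenance_to_json(prov: Provenance) -> dict:
    return {
        "periods": dict(prov.periods),
        "baseDistance": list(prov.base_distance),
        "minPoint": prov.min_point,
        "pairing": prov.pairing,
    }


def _provenance_from_json(obj: dict) -> Provenance:
    try:
        return Provenance(
            periods=dict(obj["periods"]),
            base_distance=tuple(obj["baseDistance"]),
            min_point=obj["minPoint"],
            pairing=obj["pairing"],
        )
    except KeyError as exc:
        raise SchemaError(f"provenance record missing key {exc}") from exc


def profile_to_json(profile: CatProfile) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "sequence_id": profile.sequence_id,
        "length": profile.length,
        "profile": {
            key: {"D": profile.legs[key][0], "H": profile.legs[key][1]}
            for key in ("C", "A", "T")
        },
        "provenance": _provenance_to_json(profile.provenance),
    }


def profile_from_json(obj: dict) -> CatProfile:
    version = obj.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(
            f"unsupported profile schema version {version!r} "
            f"(expected {SCHEMA_VERSION})"
        )
    try:
        legs = {
            key: (obj["profile"][key]["D"], obj["profile"][key]["H"])
            for key in ("C", "A", "T")
        }
        return CatProfile(
            sequence_id=obj["sequence_id"],
            length=obj["length"],
            legs=legs,
            provenance=_provenance_from_json(obj["provenance"]),
        )
    except KeyError as exc:
        raise SchemaError(f"profile record missing key {exc}") from exc


def write_profiles(
    profiles: Iterable[CatProfile], path: str | Path
) -> None:
    """Write profiles as a JSON-lines sidecar.

    All profiles in one file must share provenance; a mixed write raises.
    """
    prov = None
    with Path(path).open("w") as fh:
        for p in profiles:
            if prov is None:
                prov = p.provenance
            elif p.provenance != prov:
                raise ValueError(
                    "cannot write profiles with mixed provenance to one file"
                )
            fh.write(json.dumps(profile_to_json(p)) + "\n")


def read_profiles(path: str | Path) -> Iterator[CatProfile]:
    """Stream profiles back from a JSON-lines sidecar."""
    with Path(path).open() as fh:
        for line in fh:
            if line.strip():
                yield profile_from_json(json.loads(line))
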