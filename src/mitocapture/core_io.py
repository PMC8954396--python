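"""Readers and writers for the plain-text formats every pipeline stage touches.

All genomic coordinates handled here are 0-based, half-open, on the
concatenated reference.  The canonical missing-data symbol is ``'?'``;
``'N'`` is accepted on FASTA input and normalized to ``'?'`` by the
consumers that build matrices (``read_fasta`` itself preserves it so the
round trip is faithful).
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import yaml

logger = logging.getLogger("mitocapture")

#: characters legal in any FASTA this pipeline reads
FASTA_ALPHABET = frozenset("ACGTN-?")

#: nucleotide/gap/missing byte codes used in all matrices
A, C, G, T = ord("A"), ord("C"), ord("G"), ord("T")
GAP = ord("-")
MISSING = ord("?")
BASES = np.array([A, C, G, T], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    """ASCII-encode a sequence string as a uint8 array, mapping N -> '?'."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8).copy()
    arr[arr == ord("N")] = MISSING
    return arr


def decode_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into an ordered list of ``(id, sequence)`` pairs.

    Sequences are uppercased; wrapping is collapsed.  Duplicate record ids
    and characters outside ``{A,C,G,T,N,-,?}`` are hard errors (the error
    message names the offending record and position).
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    name: str | None = None
    chunks: list[str] = []

    def _flush():
        if name is None:
            return
        seq = "".join(chunks).upper()
        for i, ch in enumerate(seq):
            if ch not in FASTA_ALPHABET:
                raise ValueError(
                    f"illegal character {ch!r} at position {i} of record {name!r}"
                )
        records.append((name, seq))

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise ValueError(f"empty FASTA header at line {lineno}")
                if name in seen:
                    raise ValueError(f"duplicate FASTA id {name!r}")
                seen.add(name)
                chunks = []
            else:
                if name is None:
                    raise ValueError("sequence data before first FASTA header")
                chunks.append(line)
    _flush()
    return records


def write_fasta(records: Iterable[tuple[str, str]], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)


def parse_newick(text: str, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    """Parse a single newick tree from a string; unbalanced input is a hard error."""
    if text.count("(") != text.count(")"):
        raise ValueError("unbalanced parentheses in newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            taxon_namespace=taxon_namespace,
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"malformed newick: {exc}") from exc
    return tree


def read_newick(path, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
    return parse_newick(Path(path).read_text(), taxon_namespace=taxon_namespace)


def tree_to_newick(tree: dendropy.Tree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True, unquoted_underscores=True).strip()


def write_newick(tree: dendropy.Tree, path) -> None:
    Path(path).write_text(tree_to_newick(tree) + "\n")


# ---------------------------------------------------------------------------
# Binary (0/1/?) indel matrix TSV

_STATE_TO_CHAR = {1: "1", 0: "0", -1: "?"}
_CHAR_TO_STATE = {"1": 1, "0": 0, "?": -1}


def write_binary_matrix(matrix, path) -> None:
    """Write an ``IndelMatrix`` as a TSV, one row per taxon.

    Column headers are ``contig:start-end:type`` (with the inserted
    sequence appended for insertions so the file is lossless).
    """
    with open(path, "w") as fh:
        headers = [ev.key() for ev in matrix.events]
        fh.write("\t".join(["taxon"] + headers) + "\n")
        for i, taxon in enumerate(matrix.taxa):
            row = [_STATE_TO_CHAR[int(s)] for s in matrix.states[i]]
            fh.write("\t".join([taxon] + row) + "\n")


def read_binary_matrix(path):
    """Inverse of :func:`write_binary_matrix`."""
    from .alignment import IndelEvent, IndelMatrix

    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        events = [IndelEvent.from_key(k) for k in header[1:] if k]
        taxa: list[str] = []
        rows: list[list[int]] = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            taxa.append(parts[0])
            rows.append([_CHAR_TO_STATE[c] for c in parts[1:] if c])
    states = np.array(rows, dtype=np.int8) if rows else np.zeros((0, len(events)), dtype=np.int8)
    return IndelMatrix(taxa=taxa, events=events, states=states.reshape(len(taxa), len(events)))


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class PipelineConfig:
    """Run-wide settings shared by the CLI subcommands."""

    coverage_threshold: int = 20
    missing_symbol: str = "?"
    group_assignments: dict[str, list[str]] = dataclasses.field(default_factory=dict)
    calibration_file: str | None = None
    rng_seed: int = 0

    def __post_init__(self):
        if self.coverage_threshold < 1:
            raise ValueError("coverage_threshold must be >= 1")
        for label, members in self.group_assignments.items():
            if len(members) != len(set(members)):
                raise ValueError(f"duplicate taxon id within group {label!r}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)


def load_groups(path) -> dict[str, list[str]]:
    """Read a YAML mapping of group label -> list of taxon ids."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError("groups file must be a mapping of label -> taxa")
    return {str(k): [str(t) for t in v] for k, v in data.items()}
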