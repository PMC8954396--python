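"""Build the cleaned reference-anchored alignment and the 0/1 indel matrix.

Inputs are per-sample reference-mapped consensus calls with per-position
read coverage.  The stages are: coverage masking, removal of short called
"islands" (the dominant artifact of capture dropout), column assembly
(all reference positions plus one column block per distinct observed
insertion), and simple indel coding — every distinct determinate gap run
or insertion is one binary presence/absence character.

Coordinates are 0-based half-open on the concatenated reference;
``IndelEvent`` records contig-local coordinates for display and I/O.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .core_io import A, C, G, T, BASES, GAP, MISSING, decode_seq, encode_seq


# ---------------------------------------------------------------------------
# Domain types


@dataclasses.dataclass
class ReferenceIndex:
    """Ordered contigs with a coordinate map into the concatenated reference."""

    contigs: list[tuple[str, int]]

    def __post_init__(self):
        if not self.contigs:
            raise ValueError("reference must contain at least one contig")
        offs = np.concatenate([[0], np.cumsum([l for _, l in self.contigs])])
        if any(l <= 0 for _, l in self.contigs):
            raise ValueError("contig lengths must be positive")
        self.offsets = offs[:-1].astype(np.int64)
        self.total_length = int(offs[-1])

    @classmethod
    def from_records(cls, records: Sequence[tuple[str, str]]) -> "ReferenceIndex":
        return cls([(name, len(seq)) for name, seq in records])

    def contig_of(self, pos: int) -> tuple[str, int]:
        """Return (contig id, contig-local position) for a concatenated position."""
        if not 0 <= pos < self.total_length:
            raise IndexError(f"position {pos} outside reference")
        i = int(np.searchsorted(self.offsets, pos, side="right")) - 1
        return self.contigs[i][0], pos - int(self.offsets[i])

    def contig_bounds(self) -> list[tuple[int, int]]:
        """Concatenated [start, end) of each contig."""
        return [
            (int(o), int(o) + l) for o, (_, l) in zip(self.offsets, self.contigs)
        ]


@dataclasses.dataclass
class SampleConsensus:
    """Per-position base call + read coverage for one sample.

    ``calls`` is a uint8 array over ``{A,C,G,T,-,?}`` of reference length;
    ``insertions`` holds ``(ref position, inserted sequence, coverage)``
    where the insertion sits between reference positions ``pos-1`` and
    ``pos``.
    """

    taxon: str
    calls: np.ndarray
    coverage: np.ndarray
    insertions: list[tuple[int, str, int]] = dataclasses.field(default_factory=list)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        self.coverage = np.asarray(self.coverage, dtype=np.int64)
        if self.calls.shape != self.coverage.shape:
            raise ValueError("calls and coverage must have equal length")
        self.calls[self.coverage == 0] = MISSING

    def copy(self) -> "SampleConsensus":
        return SampleConsensus(
            self.taxon, self.calls.copy(), self.coverage.copy(), list(self.insertions)
        )


@dataclasses.dataclass(frozen=True)
class IndelEvent:
    """One binary indel character: a deletion footprint or an insertion."""

    contig: str
    start: int  # contig-local, 0-based
    end: int  # half-open; for insertions end == start
    kind: str  # "del" | "ins"
    seq: str = ""  # inserted sequence, empty for deletions

    def key(self) -> str:
        base = f"{self.contig}:{self.start}-{self.end}:{self.kind}"
        return base + (f":{self.seq}" if self.kind == "ins" else "")

    @classmethod
    def from_key(cls, key: str) -> "IndelEvent":
        parts = key.split(":")
        contig, span, kind = parts[0], parts[1], parts[2]
        start, end = (int(x) for x in span.split("-"))
        seq = parts[3] if len(parts) > 3 else ""
        return cls(contig, start, end, kind, seq)


@dataclasses.dataclass
class IndelMatrix:
    """Taxa x indel-event binary matrix; states are {1, 0, -1='?'}."""

    taxa: list[str]
    events: list[IndelEvent]
    states: np.ndarray

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.taxa), len(self.events)):
            raise ValueError("states shape does not match taxa x events")
        if len(set(self.events)) != len(self.events):
            raise ValueError("duplicate indel events")

    def row(self, taxon: str) -> np.ndarray:
        return self.states[self.taxa.index(taxon)]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, IndelMatrix)
            and self.taxa == other.taxa
            and self.events == other.events
            and np.array_equal(self.states, other.states)
        )


@dataclasses.dataclass
class CaptureAlignment:
    """Reference-anchored taxa x columns nucleotide matrix.

    ``col_ref`` maps each column to its concatenated reference position,
    or -1 for insertion columns; ``col_insertion`` gives the index into
    ``insertion_keys`` for insertion columns (-1 otherwise).
    """

    taxa: list[str]
    matrix: np.ndarray
    ref: ReferenceIndex
    col_ref: np.ndarray
    col_insertion: np.ndarray
    insertion_keys: list[tuple[int, str]]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in alignment")
        if self.matrix.shape != (len(self.taxa), len(self.col_ref)):
            raise ValueError("matrix shape does not match taxa x columns")

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.matrix[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def sequence(self, taxon: str) -> str:
        return decode_seq(self.row(taxon))

    def subset_rows(self, taxa: Sequence[str]) -> np.ndarray:
        idx = [self.taxa.index(t) for t in taxa]
        return self.matrix[idx]

    @classmethod
    def from_records(
        cls, records: Sequence[tuple[str, str]], ref: ReferenceIndex | None = None
    ) -> "CaptureAlignment":
        """Wrap a plain FASTA alignment (no insertion bookkeeping)."""
        if not records:
            raise ValueError("empty alignment")
        n = len(records[0][1])
        if any(len(s) != n for _, s in records):
            raise ValueError("ragged alignment")
        if ref is None:
            ref = ReferenceIndex([("aln", n)])
        mat = np.stack([encode_seq(s) for _, s in records])
        return cls(
            taxa=[name for name, _ in records],
            matrix=mat,
            ref=ref,
            col_ref=np.arange(n, dtype=np.int64),
            col_insertion=np.full(n, -1, dtype=np.int64),
            insertion_keys=[],
        )


@dataclasses.dataclass
class CleaningConfig:
    coverage_threshold: int = 20
    min_island_len: int = 10
    ambiguous_indel_policy: str = "to-missing"

    def __post_init__(self):
        if self.coverage_threshold < 1 or self.min_island_len < 1:
            raise ValueError("thresholds must be positive")
        if self.ambiguous_indel_policy not in ("to-missing", "split-events"):
            raise ValueError("unknown ambiguous_indel_policy")


# ---------------------------------------------------------------------------
# Cleaning operations


def mask_low_coverage(s: SampleConsensus, cfg: CleaningConfig) -> SampleConsensus:
    """Set every call with coverage below the threshold to missing.

    Insertions whose supporting coverage is below the threshold are
    dropped.  Coverage itself is untouched.
    """
    out = s.copy()
    out.calls[out.coverage < cfg.coverage_threshold] = MISSING
    out.insertions = [
        (p, seq, cov) for (p, seq, cov) in out.insertions if cov >= cfg.coverage_threshold
    ]
    return out


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [start, end) runs of True in a boolean array."""
    if mask.size == 0:
        return []
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(diff == 1)[0] + 1)
    ends = list(np.nonzero(diff == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    return list(zip(starts, ends))


def clean_spurious_calls(
    s: SampleConsensus, cfg: CleaningConfig, ref: ReferenceIndex | None = None
) -> SampleConsensus:
    """Mask short called islands stranded inside missing regions.

    A contiguous run of non-missing calls shorter than ``min_island_len``
    that is flanked by '?' on both sides (or by a contig edge, when
    ``ref`` is given; otherwise by the sequence edge) is set to '?'.
    """
    out = s.copy()
    bounds = ref.contig_bounds() if ref is not None else [(0, out.calls.size)]
    for lo, hi in bounds:
        seg = out.calls[lo:hi]
        called = seg != MISSING
        for start, end in _runs(called):
            if end - start >= cfg.min_island_len:
                continue
            left_ok = start == 0 or seg[start - 1] == MISSING
            right_ok = end == seg.size or seg[end] == MISSING
            if left_ok and right_ok:
                seg[start:end] = MISSING
    return out


# ---------------------------------------------------------------------------
# Alignment construction


def _gap_runs_by_contig(
    calls: np.ndarray, bounds: list[tuple[int, int]]
) -> list[tuple[int, int, bool]]:
    """Maximal gap runs as (start, end, determinate) in concatenated coords.

    A run is *determinate* (its boundaries are trusted) iff each flank is
    a called base or a contig edge; a '?' flank makes the true extent of
    the gap unknowable.
    """
    out = []
    for lo, hi in bounds:
        seg = calls[lo:hi]
        for start, end in _runs(seg == GAP):
            left = start == 0 or seg[start - 1] != MISSING
            right = end == seg.size or seg[end] != MISSING
            out.append((lo + start, lo + end, left and right))
    return out


def _overlap_checker(runs: list[tuple[int, int, bool]]):
    """O(log n) query: does any gap run overlap [a, b)?"""
    starts = np.array(sorted(r[0] for r in runs), dtype=np.int64)
    ends_by_start = np.array([e for _, e in sorted((s, e) for s, e, _ in runs)], dtype=np.int64)
    prefix_max_end = np.maximum.accumulate(ends_by_start) if runs else np.array([], dtype=np.int64)

    def overlaps(a: int, b: int) -> bool:
        idx = int(np.searchsorted(starts, b, side="left"))
        return idx > 0 and int(prefix_max_end[idx - 1]) > a

    return overlaps


def build_alignment(
    samples: Sequence[SampleConsensus],
    ref: ReferenceIndex,
    cfg: CleaningConfig | None = None,
    reference_taxon: str | None = None,
) -> tuple[CaptureAlignment, IndelMatrix]:
    """Assemble the multi-taxon alignment and the 0/1 indel matrix.

    Columns are all reference positions plus one insertion column block
    per distinct observed ``(position, inserted sequence)``.  Deletion
    events are maximal determinate gap runs; identical-boundary runs
    across taxa form a single binary character.  Gap runs with untrusted
    boundaries ('?'-flanked), and runs overlapping an event with
    different boundaries, are handled by the ``to-missing`` policy: the
    conflicting taxon is '?' for every overlapped event and the gap
    characters of an untrusted run become '?' in the nucleotide matrix.
    """
    cfg = cfg or CleaningConfig()
    if cfg.ambiguous_indel_policy != "to-missing":
        raise NotImplementedError("only the 'to-missing' policy is implemented")
    R = ref.total_length
    for s in samples:
        if s.calls.size != R:
            raise ValueError(
                f"sample {s.taxon!r} has length {s.calls.size}, reference is {R}"
            )
    taxa = [s.taxon for s in samples]
    if len(set(taxa)) != len(taxa):
        raise ValueError("duplicate taxon ids")
    n = len(samples)
    bounds = ref.contig_bounds()

    # --- insertion column blocks, keyed and sorted by (position, sequence)
    ins_keys = sorted({(p, seq) for s in samples for (p, seq, _) in s.insertions})
    ins_lens = [len(seq) for _, seq in ins_keys]
    n_cols = R + sum(ins_lens)

    matrix = np.full((n, n_cols), MISSING, dtype=np.uint8)
    col_ref = np.full(n_cols, -1, dtype=np.int64)
    col_ins = np.full(n_cols, -1, dtype=np.int64)

    # column layout: insertion block (p, seq) sits immediately before ref column p
    col_map = np.empty(R, dtype=np.int64)  # ref position -> column index
    cursor = 0
    ins_col_start: list[int] = []
    ins_iter = 0
    for pos in range(R + 1):
        while ins_iter < len(ins_keys) and ins_keys[ins_iter][0] == pos:
            ins_col_start.append(cursor)
            L = ins_lens[ins_iter]
            col_ins[cursor : cursor + L] = ins_iter
            cursor += L
            ins_iter += 1
        if pos < R:
            col_map[pos] = cursor
            col_ref[cursor] = pos
            cursor += 1
    assert cursor == n_cols

    # --- fill reference-anchored columns
    for i, s in enumerate(samples):
        matrix[i, col_map] = s.calls

    # --- fill insertion blocks
    ins_key_index = {k: j for j, k in enumerate(ins_keys)}
    sample_ins: list[dict[int, set[str]]] = []
    for i, s in enumerate(samples):
        by_pos: dict[int, set[str]] = {}
        for (p, seq, _cov) in s.insertions:
            by_pos.setdefault(p, set()).add(seq)
        sample_ins.append(by_pos)
        for j, (p, seq) in enumerate(ins_keys):
            c0 = ins_col_start[j]
            L = ins_lens[j]
            if seq in by_pos.get(p, ()):
                matrix[i, c0 : c0 + L] = encode_seq(seq)
            else:
                # '-' if called at both flanking ref positions (contig edges count)
                left_called = p == 0 or s.calls[p - 1] != MISSING
                right_called = p >= R or s.calls[p] != MISSING
                if left_called and right_called:
                    matrix[i, c0 : c0 + L] = GAP
                # else stays '?'

    # --- gap runs and deletion events
    per_sample_runs: list[list[tuple[int, int, bool]]] = [
        _gap_runs_by_contig(s.calls, bounds) for s in samples
    ]
    det_runs = sorted(
        {(a, b) for runs in per_sample_runs for (a, b, det) in runs if det}
    )
    # untrusted runs: blank their gap characters in the nucleotide matrix
    for i, runs in enumerate(per_sample_runs):
        for a, b, det in runs:
            if not det:
                matrix[i, col_map[a:b]] = MISSING

    events: list[IndelEvent] = []
    ev_span: list[tuple[int, int]] = []  # concatenated coords for deletions
    for a, b in det_runs:
        contig, local = ref.contig_of(a)
        events.append(IndelEvent(contig, local, local + (b - a), "del"))
        ev_span.append((a, b))
    for (p, seq) in ins_keys:
        if p < R:
            contig, local = ref.contig_of(p)
        else:  # insertion after the last reference base
            contig, local = ref.contigs[-1][0], ref.contigs[-1][1]
        events.append(IndelEvent(contig, local, local, "ins", seq))

    n_del = len(det_runs)
    states = np.full((n, len(events)), -1, dtype=np.int8)

    for i, s in enumerate(samples):
        runs = per_sample_runs[i]
        own = {(a, b) for a, b, det in runs if det}
        overlaps = _overlap_checker(runs)
        # deletion events
        for j, (a, b) in enumerate(ev_span):
            if (a, b) in own:
                states[i, j] = 1
                continue
            # any gap run (trusted or not) overlapping with different boundaries?
            if overlaps(a, b):
                states[i, j] = -1  # to-missing policy
            else:
                footprint = s.calls[a:b]
                if np.all(np.isin(footprint, BASES)):
                    states[i, j] = 0
                else:
                    states[i, j] = -1
        # insertion events
        for k, (p, seq) in enumerate(ins_keys):
            j = n_del + k
            if seq in sample_ins[i].get(p, ()):
                states[i, j] = 1
            elif sample_ins[i].get(p):
                states[i, j] = -1  # carries a different insertion here: ambiguous
            else:
                left_called = p == 0 or s.calls[p - 1] != MISSING
                right_called = p >= R or s.calls[p] != MISSING
                states[i, j] = 0 if (left_called and right_called) else -1

    aln = CaptureAlignment(
        taxa=taxa,
        matrix=matrix,
        ref=ref,
        col_ref=col_ref,
        col_insertion=col_ins,
        insertion_keys=ins_keys,
    )
    if reference_taxon is not None:
        ref_row = aln.row(reference_taxon)
        anchored = col_ref >= 0
        if np.any(ref_row[anchored] == MISSING):
            raise ValueError("reference taxon carries missing data on anchored columns")
    return aln, IndelMatrix(taxa=taxa, events=events, states=states)


def indel_matrix_from_alignment(aln: CaptureAlignment) -> IndelMatrix:
    """Code the gap runs of an already-built (or imported) alignment as
    binary characters.

    Applies simple indel coding directly to the rows of ``aln``: every
    maximal determinate gap run (flanked by called bases or a contig
    edge) is one event; runs with a '?' flank are ambiguous and yield
    '?' states for every event they overlap.  Useful for alignments read
    from FASTA, where per-sample consensus objects are unavailable.
    """
    bounds = aln.ref.contig_bounds() if aln.matrix.shape[1] == aln.ref.total_length else [
        (0, aln.matrix.shape[1])
    ]
    n = len(aln.taxa)
    per_sample_runs = [_gap_runs_by_contig(aln.matrix[i], bounds) for i in range(n)]
    det_runs = sorted({(a, b) for runs in per_sample_runs for (a, b, det) in runs if det})
    events = []
    for a, b in det_runs:
        try:
            contig, local = aln.ref.contig_of(a)
        except IndexError:
            contig, local = "aln", a
        events.append(IndelEvent(contig, local, local + (b - a), "del"))
    states = np.full((n, len(events)), -1, dtype=np.int8)
    missing_any = np.zeros((n, aln.matrix.shape[1] + 1), dtype=np.int64)
    missing_any[:, 1:] = np.cumsum(aln.matrix == MISSING, axis=1)
    for i in range(n):
        runs = per_sample_runs[i]
        own = {(a, b) for a, b, det in runs if det}
        overlaps = _overlap_checker(runs)
        for j, (a, b) in enumerate(det_runs):
            if (a, b) in own:
                states[i, j] = 1
            elif overlaps(a, b):
                states[i, j] = -1
            else:
                has_missing = missing_any[i, b] - missing_any[i, a] > 0
                states[i, j] = -1 if has_missing else 0
    return IndelMatrix(taxa=list(aln.taxa), events=events, states=states)


def scored_fraction(aln: CaptureAlignment, taxon: str) -> float:
    """Fraction of alignment columns with a determinate state for ``taxon``."""
    row = aln.row(taxon)
    return float(np.count_nonzero(row != MISSING) / row.size)
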