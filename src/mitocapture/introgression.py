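"""Population consensus construction and ABBA-BABA counting.

Each population is collapsed to a plurality consensus (ties and
all-missing columns become '?'), then four consensuses — recipient (P1),
sister (P2), donor (P3), outgroup (P4) — are compared character by
character.  Nucleotide columns and binary indel characters are pooled.
A character is informative when all four consensus states are
determinate and exactly two states occur; the outgroup state defines the
ancestral state.  ABBA: P2 and P3 share the derived state; BABA: P1 and
P3 share it.  Under no gene flow the two pattern counts have equal
expectation, so their difference is assessed with an exact two-sided
binomial sign test (and optionally a block bootstrap over contiguous
columns).

Gap characters in nucleotide columns are treated as missing here: length
variation enters the test through the binary indel characters instead,
so each indel is counted exactly once.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats

from .alignment import CaptureAlignment, IndelMatrix
from .core_io import GAP, MISSING

# pooled character encoding: nucleotide columns keep their byte codes with
# gaps mapped to missing; indel characters are mapped to two private codes
_EV0, _EV1 = 1, 2
_POOL_MISSING = 0


@dataclasses.dataclass
class PopulationConsensus:
    """Plurality consensus of one population over pooled characters."""

    label: str
    states: np.ndarray  # pooled encoding, _POOL_MISSING where undetermined
    n_columns: int  # leading nucleotide columns; the rest are indel events


def _pool_rows(aln: CaptureAlignment, m: IndelMatrix, taxa: Sequence[str]) -> np.ndarray:
    nuc = aln.subset_rows(list(taxa)).copy()
    nuc[nuc == GAP] = MISSING
    nuc[nuc == MISSING] = _POOL_MISSING
    ev = m.states[[m.taxa.index(t) for t in taxa]]
    ev_pool = np.where(ev < 0, _POOL_MISSING, np.where(ev == 0, _EV0, _EV1)).astype(np.uint8)
    return np.concatenate([nuc.astype(np.uint8), ev_pool], axis=1)


def population_consensus(
    aln: CaptureAlignment, m: IndelMatrix, members: Sequence[str], label: str = ""
) -> PopulationConsensus:
    """Per-character plurality state among non-missing members; tie -> missing."""
    if not members:
        raise ValueError("population must have at least one member")
    rows = _pool_rows(aln, m, members)
    codes = np.array([c for c in np.unique(rows) if c != _POOL_MISSING], dtype=np.uint8)
    n_chars = rows.shape[1]
    if codes.size == 0:
        states = np.full(n_chars, _POOL_MISSING, dtype=np.uint8)
    else:
        counts = np.stack([(rows == c).sum(axis=0) for c in codes])
        best = counts.max(axis=0)
        ties = (counts == best).sum(axis=0) > 1
        states = codes[counts.argmax(axis=0)]
        states[(best == 0) | ties] = _POOL_MISSING
    return PopulationConsensus(label=label or "+".join(members), states=states, n_columns=aln.n_columns)


@dataclasses.dataclass
class AbbaBabaResult:
    n_abba: int
    n_baba: int
    n_informative: int
    d: float
    p_binomial: float
    d_undefined: bool
    patterns: np.ndarray | None = None  # per pooled character: 0 none, 1 ABBA, 2 BABA
    n_columns: int = 0  # nucleotide columns in the pooled vector


def abba_baba(
    p1: PopulationConsensus,
    p2: PopulationConsensus,
    p3: PopulationConsensus,
    p4: PopulationConsensus,
) -> AbbaBabaResult:
    """Count ABBA/BABA site patterns over four population consensuses.

    P4 (outgroup) defines the ancestral state.  ABBA: P1 ancestral, P2
    and P3 derived.  BABA: P2 ancestral, P1 and P3 derived.  Other
    biallelic patterns contribute to ``n_informative`` only.
    """
    mats = [p.states for p in (p1, p2, p3, p4)]
    if len({m.shape for m in mats}) != 1 or len({p.n_columns for p in (p1, p2, p3, p4)}) != 1:
        raise ValueError("population consensuses cover different character sets")
    s1, s2, s3, s4 = mats
    det = (s1 != _POOL_MISSING) & (s2 != _POOL_MISSING) & (s3 != _POOL_MISSING) & (s4 != _POOL_MISSING)
    # exactly two distinct states among the four
    stacked = np.stack(mats)
    n_distinct = np.zeros(s1.shape, dtype=np.int8)
    for c in np.unique(stacked):
        if c == _POOL_MISSING:
            continue
        n_distinct += (stacked == c).any(axis=0)
    informative = det & (n_distinct == 2)
    abba = informative & (s1 == s4) & (s2 == s3) & (s1 != s2)
    baba = informative & (s2 == s4) & (s1 == s3) & (s1 != s2)
    n_abba, n_baba = int(abba.sum()), int(baba.sum())
    total = n_abba + n_baba
    if total == 0:
        d, p, undef = 0.0, 1.0, True
    else:
        d = (n_abba - n_baba) / total
        p = float(stats.binomtest(n_abba, total, 0.5).pvalue)
        undef = False
    patterns = np.zeros(s1.shape, dtype=np.int8)
    patterns[abba] = 1
    patterns[baba] = 2
    return AbbaBabaResult(
        n_abba=n_abba,
        n_baba=n_baba,
        n_informative=int(informative.sum()),
        d=d,
        p_binomial=p,
        d_undefined=undef,
        patterns=patterns,
        n_columns=p1.n_columns,
    )


@dataclasses.dataclass
class SignificanceResult:
    p_sign_test: float
    p_block_bootstrap: float | None
    degenerate: bool


def dstat_significance(
    res: AbbaBabaResult,
    block_len: int = 1000,
    n_boot: int = 1000,
    seed: int = 0,
) -> SignificanceResult:
    """Exact binomial sign-test p plus a block-bootstrap p for D != 0.

    The bootstrap resamples contiguous blocks of pooled characters; the
    two-sided p is twice the smaller tail probability of the replicate D
    distribution around zero.  Degenerate cases (no informative ABBA/BABA
    characters, or a block length spanning the whole character set) are
    flagged and given p = 1 for the bootstrap.
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    if res.patterns is None:
        raise ValueError("result does not retain per-character patterns")
    n_chars = res.patterns.size
    if res.n_abba + res.n_baba == 0:
        return SignificanceResult(p_sign_test=1.0, p_block_bootstrap=1.0, degenerate=True)
    p_sign = float(stats.binomtest(res.n_abba, res.n_abba + res.n_baba, 0.5).pvalue)
    if block_len >= n_chars:
        return SignificanceResult(p_sign_test=p_sign, p_block_bootstrap=1.0, degenerate=True)
    rng = np.random.default_rng(seed)
    n_blocks = int(np.ceil(n_chars / block_len))
    block_id = np.arange(n_chars) // block_len
    abba_per_block = np.bincount(block_id, weights=res.patterns == 1, minlength=n_blocks)
    baba_per_block = np.bincount(block_id, weights=res.patterns == 2, minlength=n_blocks)
    ds = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        na, nb = abba_per_block[pick].sum(), baba_per_block[pick].sum()
        tot = na + nb
        ds[b] = (na - nb) / tot if tot else 0.0
    lo = float(np.mean(ds <= 0))
    hi = float(np.mean(ds >= 0))
    p_boot = min(1.0, 2.0 * min(lo, hi))
    return SignificanceResult(p_sign_test=p_sign, p_block_bootstrap=p_boot, degenerate=False)
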