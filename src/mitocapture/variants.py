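"""Variant counting and between-group distance tables.

Conventions: a SNP is a column with two or more distinct A/C/G/T states
among the taxa considered (multi-allelic columns count once; gaps and
missing data are ignored, so indel footprints never contribute to SNP
counts).  An indel character segregates when both presence and absence
are observed.  All pairwise quantities use pairwise deletion — only the
columns where both members of a pair are determinate are compared.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .alignment import CaptureAlignment, IndelMatrix
from .core_io import BASES, MISSING


def _subset_matrix(aln: CaptureAlignment, taxa: Sequence[str]) -> np.ndarray:
    if not taxa:
        raise ValueError("taxa subset must be nonempty")
    return aln.subset_rows(list(taxa))


def count_snps(aln: CaptureAlignment, taxa: Sequence[str] | None = None) -> int:
    """Number of columns with >= 2 distinct nucleotide states in the subset."""
    rows = _subset_matrix(aln, list(taxa) if taxa is not None else aln.taxa)
    present = np.zeros(rows.shape[1], dtype=np.int8)
    for b in BASES:
        present += (rows == b).any(axis=0)
    return int(np.count_nonzero(present >= 2))


def count_indel_events(m: IndelMatrix, taxa: Sequence[str] | None = None) -> int:
    """Number of indel characters with both 0 and 1 present in the subset."""
    taxa = list(taxa) if taxa is not None else m.taxa
    if not taxa:
        raise ValueError("taxa subset must be nonempty")
    rows = m.states[[m.taxa.index(t) for t in taxa]]
    if rows.shape[1] == 0:
        return 0
    has0 = (rows == 0).any(axis=0)
    has1 = (rows == 1).any(axis=0)
    return int(np.count_nonzero(has0 & has1))


def intraspecific_polymorphisms(
    aln: CaptureAlignment, m: IndelMatrix, taxa: Sequence[str]
) -> int:
    """Variable nucleotide columns plus variable indel characters within one species."""
    if len(taxa) < 2:
        raise ValueError("need at least two taxa")
    return count_snps(aln, taxa) + count_indel_events(m, taxa)


@dataclasses.dataclass
class VariantSummary:
    n_snp_sites: int
    n_indel_events: int
    scored_fraction: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"taxon": t, "scored_fraction": f} for t, f in self.scored_fraction.items()
        ]
        return pd.DataFrame(rows)


def summarize_variants(aln: CaptureAlignment, m: IndelMatrix) -> VariantSummary:
    from .alignment import scored_fraction

    return VariantSummary(
        n_snp_sites=count_snps(aln),
        n_indel_events=count_indel_events(m),
        scored_fraction={t: scored_fraction(aln, t) for t in aln.taxa},
    )


# ---------------------------------------------------------------------------
# Group distances


@dataclasses.dataclass
class GroupDistanceTable:
    groups: list[str]
    nuc: np.ndarray  # mean raw nucleotide differences
    indel: np.ndarray  # mean raw indel differences
    nuc_per_site: np.ndarray
    indel_per_event: np.ndarray

    def frame(self, which: str = "nuc") -> pd.DataFrame:
        mat = getattr(self, which)
        return pd.DataFrame(mat, index=self.groups, columns=self.groups)


def _pair_diffs(aln_rows: np.ndarray, ev_rows: np.ndarray, i: int, j: int):
    a, b = aln_rows[i], aln_rows[j]
    comp = (a != MISSING) & (b != MISSING)
    nuc = int(np.count_nonzero(comp & (a != b)))
    n_comp = int(np.count_nonzero(comp))
    if ev_rows.shape[1]:
        ea, eb = ev_rows[i], ev_rows[j]
        ecomp = (ea >= 0) & (eb >= 0)
        ind = int(np.count_nonzero(ecomp & (ea != eb)))
        e_comp = int(np.count_nonzero(ecomp))
    else:
        ind, e_comp = 0, 0
    return nuc, n_comp, ind, e_comp


def group_distances(
    aln: CaptureAlignment, m: IndelMatrix, groups: Mapping[str, Sequence[str]]
) -> GroupDistanceTable:
    """Mean pairwise nucleotide and indel differences between (and within) groups.

    Off-diagonal entries average over all cross pairs; the diagonal is the
    within-group mean over distinct pairs (0 for singletons).  Per-site
    versions divide each pair's difference count by that pair's comparable
    column/event count before averaging.
    """
    labels = list(groups)
    members = {g: list(groups[g]) for g in labels}
    seen: set[str] = set()
    for g in labels:
        if not members[g]:
            raise ValueError(f"group {g!r} is empty")
        dup = seen & set(members[g])
        if dup:
            raise ValueError(f"taxa {sorted(dup)} appear in multiple groups")
        seen |= set(members[g])

    order = [t for g in labels for t in members[g]]
    aln_rows = aln.subset_rows(order)
    ev_rows = m.states[[m.taxa.index(t) for t in order]]
    index = {t: i for i, t in enumerate(order)}

    n = len(labels)
    nuc = np.zeros((n, n))
    ind = np.zeros((n, n))
    nuc_ps = np.zeros((n, n))
    ind_pe = np.zeros((n, n))
    for gi in range(n):
        for gj in range(gi, n):
            pairs = []
            if gi == gj:
                ms = members[labels[gi]]
                pairs = [(ms[a], ms[b]) for a in range(len(ms)) for b in range(a + 1, len(ms))]
            else:
                pairs = [(x, y) for x in members[labels[gi]] for y in members[labels[gj]]]
            if not pairs:
                continue
            vals = np.zeros((len(pairs), 4))
            for k, (x, y) in enumerate(pairs):
                d_nuc, n_comp, d_ind, e_comp = _pair_diffs(aln_rows, ev_rows, index[x], index[y])
                vals[k] = (
                    d_nuc,
                    d_ind,
                    d_nuc / n_comp if n_comp else np.nan,
                    d_ind / e_comp if e_comp else np.nan,
                )
            nuc[gi, gj] = nuc[gj, gi] = vals[:, 0].mean()
            ind[gi, gj] = ind[gj, gi] = vals[:, 1].mean()
            for col, target in ((2, nuc_ps), (3, ind_pe)):
                finite = vals[np.isfinite(vals[:, col]), col]
                target[gi, gj] = target[gj, gi] = finite.mean() if finite.size else 0.0
    return GroupDistanceTable(labels, nuc, ind, nuc_ps, ind_pe)
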