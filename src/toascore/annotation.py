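"""Cross-tissue partitioning of chromatin-state segmentations and SNP lookup.

Per-tissue chromatin-state maps are each a genome segmentation (disjoint
intervals).  Across tissues the same state (say, strong enhancer) occupies
overlapping but non-identical intervals; this module decomposes each state's
intervals into maximal disjoint segments annotated with the exact set of
tissues carrying that state over the segment — tissue-specific segments,
segments shared by all tissues, and segments shared by a sub-combination.

A position can carry different states in different tissues (enhancer in
islet, transcribed in liver); partitioning is done independently per state
label, so a SNP may receive one hit per state label it touches.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .io import Variant


#: substrings of state labels treated as inactive when no explicit
#: included-state list is given; SNPs in these states route their PPA to
#: the unclassified score
DEFAULT_EXCLUDED_PATTERNS = ("quies", "repress", "low_signal")


def default_included_states(observed: Iterable[str]) -> frozenset[str]:
    """All observed labels minus quiescent/repressed/low-signal ones."""
    return frozenset(
        s
        for s in observed
        if not any(pat in s.lower() for pat in DEFAULT_EXCLUDED_PATTERNS)
    )


@dataclass(frozen=True)
class SnpAnnotationHit:
    """One (SNP, annotation) overlap with its tissue-membership set.

    ``annotation`` is a chromatin-state label or ``"CDS"``; CDS hits carry
    the overlapped gene id(s) and an empty tissue set (tissue relevance of
    coding SNPs comes from expression specificity, not chromatin).
    """

    snp_id: str
    annotation: str
    tissues_hit: frozenset[str]
    gene_ids: tuple[str, ...] = ()


def partition_states(state_maps: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Decompose per-tissue segmentations into cross-tissue disjoint segments.

    Parameters
    ----------
    state_maps
        tissue -> DataFrame with columns (chrom, start, end, state),
        0-based half-open, non-overlapping within each tissue.

    Returns
    -------
    DataFrame with columns (chrom, start, end, state, tissues) where
    ``tissues`` is a frozenset of tissue labels.  For a fixed state label
    the segments are pairwise disjoint, and restricting to segments whose
    set contains tissue *t* reproduces *t*'s input intervals base-for-base.
    """
    # group input intervals by (state, chrom)
    by_key: dict[tuple[str, str], dict[str, tuple[np.ndarray, np.ndarray]]] = {}
    for t, df in state_maps.items():
        for (state, chrom), grp in df.groupby(["state", "chrom"], sort=False):
            g = grp.sort_values("start")
            by_key.setdefault((state, chrom), {})[t] = (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
            )

    rows: list[tuple] = []
    for (state, chrom), per_tissue in sorted(by_key.items()):
        bounds = np.unique(
            np.concatenate([np.concatenate(v) for v in per_tissue.values()])
        )
        seg_start, seg_end = bounds[:-1], bounds[1:]
        t_order = sorted(per_tissue)
        # membership is constant on each atomic segment; test its left edge
        member = np.zeros((len(seg_start), len(t_order)), dtype=bool)
        for j, t in enumerate(t_order):
            starts, ends = per_tissue[t]
            idx = np.searchsorted(starts, seg_start, side="right") - 1
            ok = idx >= 0
            member[ok, j] = seg_start[ok] < ends[idx[ok]]
        # merge adjacent atomic segments with identical membership
        cur: list | None = None  # [start, end, member_key, tissue_set]
        for i in np.nonzero(member.any(axis=1))[0]:
            key = member[i].tobytes()
            if cur is not None and cur[1] == seg_start[i] and cur[2] == key:
                cur[1] = seg_end[i]
            else:
                if cur is not None:
                    rows.append((chrom, cur[0], cur[1], state, cur[3]))
                tset = frozenset(
                    t for j, t in enumerate(t_order) if member[i, j]
                )
                cur = [int(seg_start[i]), int(seg_end[i]), key, tset]
        if cur is not None:
            rows.append((chrom, cur[0], cur[1], state, cur[3]))
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "tissues"]
    )


class SnpAnnotator:
    """Resolves, for a SNP position, which annotations it hits in which tissues.

    Built once from a partitioned state table and (optionally) CDS records;
    lookups are O(log n) per (chrom, state) via sorted-array bisection, and
    CDS overlap (isoforms may overlap) goes through an interval tree.
    States outside ``included_states`` are dropped at build time, so SNPs in
    excluded states hit nothing and their PPA flows to the unclassified
    score.  When ``included_states`` is None, every observed label except
    quiescent/repressed/low-signal ones (see
    :data:`DEFAULT_EXCLUDED_PATTERNS`) is scored.
    """

    def __init__(
        self,
        partition: pd.DataFrame,
        cds: pd.DataFrame | None = None,
        included_states: Iterable[str] | None = None,
    ) -> None:
        if included_states is None and len(partition):
            included_states = default_included_states(partition["state"])
        self.included_states = (
            frozenset(included_states) if included_states is not None else None
        )
        self._index: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, list]] = {}
        for (chrom, state), grp in partition.groupby(
            ["chrom", "state"], sort=True
        ):
            if (
                self.included_states is not None
                and state not in self.included_states
            ):
                continue
            g = grp.sort_values("start")
            self._index[(chrom, state)] = (
                g["start"].to_numpy(np.int64),
                g["end"].to_numpy(np.int64),
                list(g["tissues"]),
            )
        self._states_by_chrom: dict[str, list[str]] = {}
        for chrom, state in self._index:
            self._states_by_chrom.setdefault(chrom, []).append(state)
        self._cds: dict[str, IntervalTree] = {}
        if cds is not None and len(cds):
            for chrom, grp in cds.groupby("chrom", sort=False):
                tree = IntervalTree()
                for s, e, g in zip(grp["start"], grp["end"], grp["gene_id"]):
                    tree.addi(int(s), int(e), str(g))
                self._cds[chrom] = tree

    def annotate(self, v: Variant) -> list[SnpAnnotationHit]:
        """All included-state and CDS hits for one variant (1-based pos)."""
        pos0 = v.pos - 1
        hits: list[SnpAnnotationHit] = []
        for state in self._states_by_chrom.get(v.chrom, ()):
            starts, ends, tsets = self._index[(v.chrom, state)]
            i = int(np.searchsorted(starts, pos0, side="right")) - 1
            if i >= 0 and pos0 < ends[i]:
                hits.append(
                    SnpAnnotationHit(
                        snp_id=v.snp_id,
                        annotation=state,
                        tissues_hit=tsets[i],
                    )
                )
        tree = self._cds.get(v.chrom)
        if tree is not None:
            genes = sorted({iv.data for iv in tree.at(pos0)})
            if genes:
                hits.append(
                    SnpAnnotationHit(
                        snp_id=v.snp_id,
                        annotation="CDS",
                        tissues_hit=frozenset(),
                        gene_ids=tuple(genes),
                    )
                )
        return hits


def annotate_snp(
    v: Variant,
    partition: pd.DataFrame,
    cds: pd.DataFrame | None = None,
    included_states: Iterable[str] | None = None,
) -> list[SnpAnnotationHit]:
    """One-shot convenience wrapper around :class:`SnpAnnotator`."""
    return SnpAnnotator(partition, cds, included_states).annotate(v)
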