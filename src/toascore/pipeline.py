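"""High-level wiring: from raw inputs to TOA profiles and assignments."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import SnpAnnotator, partition_states
from .classify import Assignment, classify_all
from .core import TOAProfile, WeightTable, score_credible_set
from .io import CredibleSet


def score_signals(
    credible_sets: Sequence[CredibleSet],
    state_maps: Mapping[str, pd.DataFrame],
    weights: WeightTable,
    ess: pd.DataFrame | None = None,
    cds: pd.DataFrame | None = None,
    included_states: Iterable[str] | None = None,
    tissues: Sequence[str] | None = None,
    **kw,
) -> list[TOAProfile]:
    """Partition states, annotate every credible SNP, and score each signal."""
    if tissues is None:
        tissues = list(state_maps)
    partition = partition_states(state_maps)
    annotator = SnpAnnotator(partition, cds=cds, included_states=included_states)
    return [
        score_credible_set(cs, annotator, weights, ess, tissues, **kw)
        for cs in credible_sets
    ]


def assign_signals(
    profiles: Sequence[TOAProfile],
    threshold: float = 0.2,
    allow_shared: bool = True,
) -> list[Assignment]:
    return classify_all(profiles, threshold=threshold, allow_shared=allow_shared)
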