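"""Rule-based assignment of signals to tissues from their TOA profiles.

A signal is assigned to the tissue with the maximum TOA score when that
score exceeds a stringency threshold (0.0, 0.2, 0.5 or 0.8 by convention).
When shared designation is enabled, a gap of at most 0.10 between the top
two tissue scores yields "shared" instead — the signature of a regulatory
element active in more than one tissue.  Shared signals are tiered by
fine-mapping resolution: (1) single-SNP credible set, (2) max PPA >= 0.50,
(3) max PPA < 0.50.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import TOAProfile

logger = logging.getLogger(__name__)

SHARED_GAP = 0.10
DEFAULT_THRESHOLDS = (0.0, 0.2, 0.5, 0.8)
DEFAULT_TISSUE_ORDER = ("islet", "adipose", "liver", "muscle")


@dataclass(frozen=True)
class Assignment:
    signal_id: str
    label: str  # a tissue label, "shared" or "unclassified"
    threshold: float
    top_score: float
    runner_up_gap: float


@dataclass(frozen=True)
class SharedTier:
    signal_id: str
    tier: int  # 1, 2 or 3


def classify(
    p: TOAProfile,
    threshold: float = 0.2,
    allow_shared: bool = True,
    tissue_order: Sequence[str] = DEFAULT_TISSUE_ORDER,
) -> Assignment:
    """Assign one signal to a tissue, "shared" or "unclassified".

    With ``allow_shared``, a top-two gap <= 0.10 (top still above threshold)
    is "shared"; otherwise the arg-max tissue wins if its score meets the
    threshold.  A top score of exactly 0 is always unclassified.  Exact
    arg-max ties with sharing disabled break by the configured tissue order,
    with a warning.
    """
    order = [t for t in tissue_order if t in p.tau] + [
        t for t in p.tau if t not in tissue_order
    ]
    scores = sorted(p.tau.items(), key=lambda kv: (-kv[1], order.index(kv[0])))
    top_tissue, top = scores[0]
    second = scores[1][1] if len(scores) > 1 else 0.0
    gap = top - second
    if top <= 0.0 or top < threshold:
        label = "unclassified"
    elif allow_shared and gap <= SHARED_GAP:
        label = "shared"
    else:
        if gap == 0.0 and len(scores) > 1:
            logger.warning(
                "signal %s: exact tie for top TOA score; assigning %s by "
                "tissue order", p.signal_id, top_tissue,
            )
        label = top_tissue
    return Assignment(
        signal_id=p.signal_id,
        label=label,
        threshold=threshold,
        top_score=float(top),
        runner_up_gap=float(gap),
    )


def tier_shared(p: TOAProfile, assignment: Assignment | None = None) -> SharedTier:
    """Tier a shared signal by fine-mapping resolution (rules tested 1->3).

    If the signal's :class:`Assignment` is supplied it must carry the
    "shared" label; tiering a tissue-assigned or unclassified signal is an
    error.
    """
    if assignment is not None and assignment.label != "shared":
        raise ValueError(
            f"signal {p.signal_id} is {assignment.label!r}, not 'shared'"
        )
    if p.n_snps == 1:
        tier = 1
    elif p.max_ppa >= 0.50:
        tier = 2
    else:
        tier = 3
    return SharedTier(signal_id=p.signal_id, tier=tier)


def classify_all(
    profiles: Sequence[TOAProfile],
    threshold: float = 0.2,
    allow_shared: bool = True,
    tissue_order: Sequence[str] = DEFAULT_TISSUE_ORDER,
) -> list[Assignment]:
    return [classify(p, threshold, allow_shared, tissue_order) for p in profiles]
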