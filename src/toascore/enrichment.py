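"""Permutation/resampling enrichment statistics for validating tissue assignments.

Three analyses share the same machinery: overlap of tissue-assigned signals
with tissue-specific eQTLs, with physiology-cluster memberships, and with
trait-associated SNP sets from a GWAS catalog.  Each compares an observed
overlap count against a null distribution of size-matched random sets and
reports a fold enrichment (observed over null mean) and the add-one
empirical p value

    p_emp = (n_{null >= obs} + 1) / (N + 1)

whose floor is 1/(N+1), never 0.  All sampling is seeded and without
replacement within a permutation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    query_label: str
    feature_label: str
    observed: float
    null_mean: float
    fold: float  # NaN when null_mean == 0 and observed > 0
    p_emp: float
    n_perm: int
    seed: int


def empirical_p(
    observed: float, null_draws: Sequence[float], tail: str = "ge"
) -> float:
    """Add-one empirical p value against a null sample.

    ``tail="ge"`` counts null draws >= observed (enrichment tests);
    ``tail="le"`` counts null draws <= observed (rank-sum similarity, where
    smaller statistics are more extreme).
    """
    null = np.asarray(null_draws, dtype=float)
    if null.size == 0:
        raise ValueError("null_draws must be non-empty")
    if tail == "ge":
        n_hit = int((null >= observed).sum())
    elif tail == "le":
        n_hit = int((null <= observed).sum())
    else:
        raise ValueError(f"tail must be 'ge' or 'le', got {tail!r}")
    return (n_hit + 1) / (null.size + 1)


def _fold(observed: float, null_mean: float) -> float:
    if null_mean > 0:
        return observed / null_mean
    return 0.0 if observed == 0 else float("nan")


# ---------------------------------------------------------------------------
# Null samplers
# ---------------------------------------------------------------------------


class UniformSampler:
    """Draw size-matched SNP sets uniformly from a universe, w/o replacement."""

    def __init__(self, universe: Iterable[str]) -> None:
        self.universe = np.array(sorted(set(map(str, universe))))
        if len(self.universe) == 0:
            raise ValueError("empty sampling universe")

    def __call__(self, rng: np.random.Generator, size: int) -> set[str]:
        if size > len(self.universe):
            raise ValueError("requested sample larger than universe")
        return set(rng.choice(self.universe, size=size, replace=False))


class StratifiedSampler:
    """Draw matched sets preserving a covariate-bin composition.

    ``strata`` maps each universe SNP to its bin (e.g. a MAF decile); a
    sampled set matches the query's per-bin counts.
    """

    def __init__(self, strata: Mapping[str, str]) -> None:
        self.strata = {str(k): str(v) for k, v in strata.items()}
        bins: dict[str, list[str]] = {}
        for snp, b in sorted(self.strata.items()):
            bins.setdefault(b, []).append(snp)
        self.bins = {b: np.array(v) for b, v in bins.items()}

    def matched(self, rng: np.random.Generator, query: Iterable[str]) -> set[str]:
        need: dict[str, int] = {}
        for s in query:
            b = self.strata.get(str(s))
            if b is None:
                raise ValueError(f"SNP {s} has no stratum")
            need[b] = need.get(b, 0) + 1
        out: set[str] = set()
        for b, n in sorted(need.items()):
            pool = self.bins[b]
            if n > len(pool):
                raise ValueError(f"stratum {b!r} smaller than query demand")
            out |= set(rng.choice(pool, size=n, replace=False))
        return out

    def __call__(self, rng: np.random.Generator, size: int) -> set[str]:
        raise TypeError(
            "StratifiedSampler needs the query set; use .matched(rng, query)"
        )


# ---------------------------------------------------------------------------
# Tissue-specific eQTLs
# ---------------------------------------------------------------------------


def tissue_specific_eqtls(
    significant: Mapping[str, set[str]]
) -> dict[str, set[str]]:
    """specific(t) = S_t minus the union of every other tissue's set.

    The resulting per-tissue sets are pairwise disjoint by construction.
    """
    out = {}
    for t, s_t in significant.items():
        others: set[str] = set()
        for u, s_u in significant.items():
            if u != t:
                others |= s_u
        out[t] = set(s_t) - others
    return out


def eqtl_enrichment(
    assigned_snps: Mapping[str, set[str]],
    specific_sets: Mapping[str, set[str]],
    sampler: Callable[[np.random.Generator, int], set[str]] | StratifiedSampler,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Observed vs permuted overlap on the (assigned tissue x eQTL tissue) grid.

    For every pair, the observed count of tissue-assigned index SNPs that
    are tissue-specific eQTLs is compared with ``n_perm`` size-matched SNP
    sets from the sampler.  Selective enrichment shows up on the diagonal.
    """
    results: list[EnrichmentResult] = []
    for qi, q_tissue in enumerate(sorted(assigned_snps)):
        query = set(map(str, assigned_snps[q_tissue]))
        rng = np.random.default_rng([seed, qi])
        null_sets = []
        for _ in range(n_perm):
            if isinstance(sampler, StratifiedSampler):
                null_sets.append(sampler.matched(rng, query))
            else:
                null_sets.append(sampler(rng, len(query)))
        for e_tissue in sorted(specific_sets):
            spec = specific_sets[e_tissue]
            obs = len(query & spec)
            nulls = np.array([len(ns & spec) for ns in null_sets], dtype=float)
            null_mean = float(nulls.mean())
            results.append(
                EnrichmentResult(
                    query_label=q_tissue,
                    feature_label=e_tissue,
                    observed=obs,
                    null_mean=null_mean,
                    fold=_fold(obs, null_mean),
                    p_emp=empirical_p(obs, nulls, "ge"),
                    n_perm=n_perm,
                    seed=seed,
                )
            )
    return results


# ---------------------------------------------------------------------------
# Physiology-cluster enrichment
# ---------------------------------------------------------------------------


def physiology_enrichment(
    query_signals: set[str],
    cluster_map: Mapping[str, set[str]],
    universe: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Overlap of tissue-assigned signals with physiology clusters.

    Null sets are drawn by sampling ``len(query_signals)`` signals without
    replacement from the full fine-mapped universe.
    """
    universe_arr = np.array(sorted(set(map(str, universe))))
    query = set(map(str, query_signals))
    if not query <= set(universe_arr):
        raise ValueError("query signals must be a subset of the universe")
    rng = np.random.default_rng([seed])
    n = len(query)
    null_sets = [
        set(rng.choice(universe_arr, size=n, replace=False))
        for _ in range(n_perm)
    ]
    results = []
    for cluster in sorted(cluster_map):
        members = set(map(str, cluster_map[cluster]))
        obs = len(query & members)
        nulls = np.array([len(ns & members) for ns in null_sets], dtype=float)
        null_mean = float(nulls.mean())
        results.append(
            EnrichmentResult(
                query_label="query",
                feature_label=cluster,
                observed=obs,
                null_mean=null_mean,
                fold=_fold(obs, null_mean),
                p_emp=empirical_p(obs, nulls, "ge"),
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


# ---------------------------------------------------------------------------
# GWAS-catalog enrichment with per-signal overlap collapsing
# ---------------------------------------------------------------------------


def _collapsed_overlap(
    signals: Iterable[str],
    signal_snps: Mapping[str, set[str]],
    trait_set: set[str],
) -> int:
    """Count signals whose index+proxy SNPs intersect a trait's SNP set.

    Multiple overlapping SNPs from one signal count once — this collapses
    local LD into a single per-signal overlap.
    """
    return sum(
        1 for s in signals if signal_snps.get(s, set()) & trait_set
    )


def gwascat_enrichment(
    query_signals: set[str],
    signal_snps: Mapping[str, set[str]],
    trait_snp_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> list[EnrichmentResult]:
    """Per-trait enrichment of tissue-assigned signals among catalog SNPs.

    ``signal_snps`` maps every universe signal to its index SNP plus LD
    proxies; null sets resample signals from the universe, each null signal
    bringing its own proxy expansion.
    """
    universe_arr = np.array(sorted(set(map(str, universe))))
    query = sorted(map(str, query_signals))
    rng = np.random.default_rng([seed])
    n = len(query)
    null_sets = [
        rng.choice(universe_arr, size=n, replace=False)
        for _ in range(n_perm)
    ]
    results = []
    for trait in sorted(trait_snp_sets):
        tset = set(map(str, trait_snp_sets[trait]))
        if not tset:
            logger.warning("trait %r has an empty SNP set; skipped", trait)
            continue
        obs = _collapsed_overlap(query, signal_snps, tset)
        nulls = np.array(
            [_collapsed_overlap(ns, signal_snps, tset) for ns in null_sets],
            dtype=float,
        )
        null_mean = float(nulls.mean())
        results.append(
            EnrichmentResult(
                query_label="query",
                feature_label=trait,
                observed=obs,
                null_mean=null_mean,
                fold=_fold(obs, null_mean),
                p_emp=empirical_p(obs, nulls, "ge"),
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def bh_qvalues(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p values.

    Utility for users holding only nominal eQTL p values; an approximation
    of a full q-value procedure for pre-filtering significant eQTLs at an
    FDR threshold.
    """
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]
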