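"""Nearest-gene expression similarity and co-expression tests.

Two validation analyses for tissue-assigned signals, both built on the
genes nearest to each signal's index SNP:

* **Expression similarity** — genes are ranked genome-wide by mean
  expression across all tissues (rank 1 = highest).  For a set of nearest
  genes, the within-tissue rank sum is compared against null gene sets
  sampled, per gene, from rank-matched neighbours (rank within +/-100 of
  the query gene, inside a +/-150-rank background pool).  A rank sum lower
  than the nulls means the set is unusually highly expressed in that
  tissue; the enrichment factor is null-mean over observed, and the
  empirical p uses the lower tail.

* **Co-expression (msr)** — the mean squared pairwise Spearman correlation
  of the gene set within a tissue, compared against random draws of
  equally many signal-proximal genes; upper-tail empirical p.

Signals whose credible sets carry a cumulative coding PPA >= 0.1 are
excluded (their tissue evidence comes from coding overlap, not regulation
of a nearby gene).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import CredibleSet, ValidationError

logger = logging.getLogger(__name__)

RANK_BACKGROUND_WINDOW = 150
RANK_NULL_WINDOW = 100
CODING_SCORE_CUTOFF = 0.1
MIN_TPM = 0.1


@dataclass
class GeneRanking:
    """Genome-wide expression ranking over the filtered gene universe.

    ``ranks`` maps gene -> rank, a permutation of 1..G with rank 1 the
    highest mean expression across all tissues.
    """

    ranks: pd.Series
    filtered_out: frozenset[str]

    @property
    def genes(self) -> list[str]:
        return list(self.ranks.index)


@dataclass(frozen=True)
class CoexprResult:
    tissue: str
    statistic: float  # observed rank sum, or observed msr
    null_mean: float
    enrichment_factor: float
    p_emp: float
    n_perm: int
    seed: int


def filter_and_rank(
    tpm: pd.DataFrame,
    sample_tissue: Mapping[str, str] | pd.Series,
    low_in_all: bool = True,
) -> GeneRanking:
    """Filter lowly expressed genes, then rank by mean expression.

    A gene is "low" in a tissue when its TPM is < 0.1 in more than 50% of
    that tissue's samples.  With ``low_in_all`` (default) a gene is removed
    only when low in every tissue, keeping tissue-specific genes; set it to
    False to remove genes low in any tissue (the stricter reading).
    Remaining genes are ranked by the mean of their per-tissue mean TPMs
    (rank 1 = highest), ties broken by gene id.
    """
    st = pd.Series(sample_tissue)
    tissues = sorted(st.unique())
    low = pd.DataFrame(index=tpm.index)
    per_tissue_mean = pd.DataFrame(index=tpm.index)
    for t in tissues:
        cols = tpm.columns.intersection(st.index[st == t])
        if len(cols) == 0:
            raise ValidationError(f"tissue {t!r} has no samples")
        sub = tpm[cols]
        low[t] = (sub < MIN_TPM).sum(axis=1) > 0.5 * len(cols)
        per_tissue_mean[t] = sub.mean(axis=1)
    drop = low.all(axis=1) if low_in_all else low.any(axis=1)
    kept = per_tissue_mean.loc[~drop]
    mean_expr = kept.mean(axis=1)
    order = sorted(kept.index, key=lambda g: (-mean_expr[g], g))
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order)
    return GeneRanking(ranks=ranks, filtered_out=frozenset(tpm.index[drop]))


def nearest_genes(
    signals: Sequence[CredibleSet],
    gene_positions: pd.DataFrame,
    k: int = 1,
    coding_scores: Mapping[str, float] | None = None,
    coding_cutoff: float = CODING_SCORE_CUTOFF,
) -> dict[str, str]:
    """k-th nearest gene (by TSS distance) to each signal's index SNP.

    ``gene_positions`` has columns (chrom, start, end, gene_id); the TSS
    anchor is ``start``.  Distance ties break by gene id.  Signals whose
    coding score reaches ``coding_cutoff`` are dropped, as are signals with
    fewer than k genes on their chromosome (with a warning).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    by_chrom = {
        chrom: grp.sort_values(["start", "gene_id"])
        for chrom, grp in gene_positions.groupby("chrom", sort=False)
    }
    out: dict[str, str] = {}
    for cs in signals:
        if coding_scores is not None:
            if coding_scores.get(cs.signal_id, 0.0) >= coding_cutoff:
                logger.info(
                    "signal %s excluded (coding score >= %g)",
                    cs.signal_id, coding_cutoff,
                )
                continue
        index_v = next(
            (v for v in cs.variants if v.snp_id == cs.index_snp),
            cs.variants[0],
        )
        genes = by_chrom.get(index_v.chrom)
        if genes is None or len(genes) < k:
            logger.warning(
                "signal %s: fewer than k=%d genes on %s; dropped",
                cs.signal_id, k, index_v.chrom,
            )
            continue
        dist = (genes["start"] - (index_v.pos - 1)).abs()
        ordered = sorted(
            zip(dist.to_numpy(), genes["gene_id"].to_numpy()),
            key=lambda dg: (dg[0], dg[1]),
        )
        out[cs.signal_id] = str(ordered[k - 1][1])
    return out


def _rank_matched_null(
    rng: np.random.Generator,
    query_ranks: np.ndarray,
    background: np.ndarray,
    background_ranks: np.ndarray,
) -> np.ndarray:
    """One null set: per query gene, a background gene within +/-100 ranks.

    Sampling is without replacement within the permutation; raises if any
    gene's eligible window is exhausted.
    """
    chosen: list[int] = []
    taken: set[int] = set()
    for r in query_ranks:
        eligible = np.nonzero(
            (np.abs(background_ranks - r) <= RANK_NULL_WINDOW)
        )[0]
        eligible = np.array([i for i in eligible if i not in taken])
        if eligible.size == 0:
            raise ValidationError(
                f"no eligible rank-matched null gene for rank {r}"
            )
        pick = int(rng.choice(eligible))
        taken.add(pick)
        chosen.append(pick)
    return background[chosen]


def expression_similarity_test(
    gene_set: Iterable[str],
    ranking: GeneRanking,
    tissue_expression: pd.DataFrame,
    n_perm: int = 1000,
    seed: int = 0,
) -> list[CoexprResult]:
    """Within-tissue rank-sum similarity of a gene set vs rank-matched nulls.

    ``tissue_expression`` is a gene x tissue table (e.g. median TPM per
    tissue) over at least the ranked gene universe.  For each tissue, genes
    are ranked within the tissue (1 = highest) and the set's rank sum is
    compared with ``n_perm`` null sets matched on global expression rank.
    """
    genes = sorted(set(map(str, gene_set)))
    missing = [g for g in genes if g not in ranking.ranks.index]
    if missing:
        raise ValidationError(f"genes not in ranking: {missing[:5]}")
    universe = ranking.ranks.index
    expr = tissue_expression.loc[universe]
    query_ranks = ranking.ranks.loc[genes].to_numpy()

    # background pool: all genes within +/-150 global ranks of any set gene
    glob = ranking.ranks.to_numpy()
    in_bg = np.zeros(len(universe), dtype=bool)
    for r in query_ranks:
        in_bg |= np.abs(glob - r) <= RANK_BACKGROUND_WINDOW
    background = universe.to_numpy()[in_bg]
    background_ranks = glob[in_bg]

    results: list[CoexprResult] = []
    for ti, tissue in enumerate(expr.columns):
        # within-tissue ranks over the full filtered universe, 1 = highest
        within = pd.Series(
            stats.rankdata(-expr[tissue].to_numpy(), method="average"),
            index=universe,
        )
        obs = float(within.loc[genes].sum())
        rng = np.random.default_rng([seed, ti])
        nulls = np.empty(n_perm)
        for i in range(n_perm):
            null_genes = _rank_matched_null(
                rng, query_ranks, background, background_ranks
            )
            nulls[i] = within.loc[null_genes].sum()
        null_mean = float(nulls.mean())
        from .enrichment import empirical_p

        results.append(
            CoexprResult(
                tissue=str(tissue),
                statistic=obs,
                null_mean=null_mean,
                enrichment_factor=null_mean / obs if obs > 0 else float("nan"),
                p_emp=empirical_p(obs, nulls, "le"),
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results


def mean_squared_rho(expr: pd.DataFrame, genes: Sequence[str]) -> float:
    """Mean over unordered gene pairs of squared Spearman correlation.

    ``expr`` is genes x samples for one tissue.  Zero-variance genes are
    dropped with a warning (their correlations are undefined); NaN when
    fewer than two genes remain.
    """
    keep = []
    for g in genes:
        x = expr.loc[g].to_numpy(float)
        if np.ptp(x) == 0:
            logger.warning("gene %s has zero variance; its pairs dropped", g)
        else:
            keep.append(g)
    if len(keep) < 2:
        return float("nan")
    mat = expr.loc[keep].to_numpy(float)
    rho = stats.spearmanr(mat, axis=1).statistic
    if np.isscalar(rho):
        rho = np.array([[1.0, rho], [rho, 1.0]])
    iu = np.triu_indices(len(keep), k=1)
    return float((np.asarray(rho)[iu] ** 2).mean())


def coexpression_msr_test(
    gene_set: Iterable[str],
    expression: pd.DataFrame,
    sample_tissue: Mapping[str, str] | pd.Series,
    proximal_universe: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
) -> list[CoexprResult]:
    """Per-tissue co-expression of a gene set vs random proximal-gene draws.

    ``expression`` is genes x samples; ``proximal_universe`` is the pool of
    nearest genes across all fine-mapped signals from which null sets are
    drawn (size-matched, without replacement).
    """
    genes = sorted(set(map(str, gene_set)))
    if len(genes) < 2:
        raise ValidationError("gene_set must contain at least 2 genes")
    universe = np.array(
        sorted(set(map(str, proximal_universe)) & set(expression.index))
    )
    if len(universe) < len(genes):
        raise ValidationError("proximal universe smaller than the gene set")
    st = pd.Series(sample_tissue)
    results: list[CoexprResult] = []
    from .enrichment import empirical_p

    for ti, tissue in enumerate(sorted(st.unique())):
        cols = expression.columns.intersection(st.index[st == tissue])
        sub = expression[cols]
        obs = mean_squared_rho(sub, genes)
        rng = np.random.default_rng([seed, ti])
        nulls = np.empty(n_perm)
        for i in range(n_perm):
            draw = rng.choice(universe, size=len(genes), replace=False)
            nulls[i] = mean_squared_rho(sub, list(draw))
        ok = ~np.isnan(nulls)
        null_mean = float(nulls[ok].mean()) if ok.any() else float("nan")
        results.append(
            CoexprResult(
                tissue=str(tissue),
                statistic=obs,
                null_mean=null_mean,
                enrichment_factor=(
                    obs / null_mean if null_mean and null_mean > 0 else float("nan")
                ),
                p_emp=empirical_p(obs, nulls[ok], "ge"),
                n_perm=n_perm,
                seed=seed,
            )
        )
    return results
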