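"""Tissue-of-action (TOA) scoring: the posterior-partitioning mathematics.

For a fine-mapped signal (99% credible set), each credible SNP *j* carries
a posterior probability of association P_j.  The SNP's annotation overlaps
across evaluated tissues define a per-tissue score vector

    s_{j,a,t} = w_{a,t} * 1(j,a,t) / sum_i 1(j,a,i)
    s_j       = sum_a s_{j,a}

where w_{a,t} is the enrichment-derived weight of annotation *a* in tissue
*t* and 1(j,a,t) is 1 for a chromatin-state overlap, the ESS value
eps_{g,t} for a coding-sequence overlap of gene *g*, and 0 otherwise.
The signal's TOA score per tissue and its unclassified residual are

    tau_c = sum_j P_j * s_j / sum_t s_{j,t}
    U_c   = sum_j P_j - sum_t tau_{c,t}

so the per-tissue scores plus U_c exactly partition the credible set's
cumulative PPA.  Because each SNP's vector is normalised by its own total,
the partition is invariant to rescaling all weights by a common factor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import SnpAnnotationHit
from .io import CredibleSet, ValidationError

logger = logging.getLogger(__name__)

CONSERVATION_TOL = 1e-9

CDS = "CDS"


class WeightTable:
    """Nonnegative annotation weights w_{a,t} = 2^(mean log2 fold enrichment).

    Chromatin-state weights are per (annotation, tissue); the coding-sequence
    weight is a single genome-wide value applied identically in every tissue
    (CDS is one annotation in the genome-wide enrichment model, not a
    tissue-level one).
    """

    def __init__(self, weights: Mapping[tuple[str, str], float],
                 cds_weight: float = 1.0) -> None:
        for (a, t), w in weights.items():
            if not w > 0:
                raise ValidationError(f"weight for ({a!r}, {t!r}) must be > 0")
        if not cds_weight > 0:
            raise ValidationError("CDS weight must be > 0")
        self._w = dict(weights)
        self.cds_weight = float(cds_weight)

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, t = key
        if a == CDS:
            return self.cds_weight
        try:
            return self._w[(a, t)]
        except KeyError:
            raise KeyError(f"no weight for annotation {a!r} in tissue {t!r}")

    def annotations(self) -> set[str]:
        return {a for a, _ in self._w}

    def scaled(self, k: float) -> "WeightTable":
        """A copy with every weight (including CDS) multiplied by k > 0."""
        return WeightTable(
            {key: w * k for key, w in self._w.items()}, self.cds_weight * k
        )

    @classmethod
    def from_log2fe(
        cls,
        table: Mapping[tuple[str, str], float] | pd.DataFrame,
        cds_log2fe: float | None = None,
        annotations: Iterable[str] | None = None,
        tissues: Iterable[str] | None = None,
    ) -> "WeightTable":
        """Exponentiate mean log2 fold enrichments: w = 2**log2FE.

        ``table`` is either a mapping (annotation, tissue) -> log2FE or a
        long DataFrame with columns (annotation, tissue, log2fe) in which a
        CDS row may use tissue ``"*"``.  Negative log2FE simply yields a
        weight in (0, 1).  If ``annotations``/``tissues`` are given, every
        pair must be covered.
        """
        if isinstance(table, pd.DataFrame):
            mapping: dict[tuple[str, str], float] = {}
            for _, r in table.iterrows():
                a, t, fe = str(r["annotation"]), str(r["tissue"]), float(r["log2fe"])
                if a == CDS:
                    if cds_log2fe is None:
                        cds_log2fe = fe
                    continue
                mapping[(a, t)] = fe
        else:
            mapping = {
                (a, t): float(fe)
                for (a, t), fe in table.items()
                if a != CDS
            }
            for (a, t), fe in table.items():
                if a == CDS and cds_log2fe is None:
                    cds_log2fe = float(fe)
        if annotations is not None and tissues is not None:
            missing = [
                (a, t)
                for a in annotations
                for t in tissues
                if a != CDS and (a, t) not in mapping
            ]
            if missing:
                raise ValidationError(
                    f"missing log2FE for pairs: {missing[:10]}"
                )
        weights = {key: float(2.0 ** fe) for key, fe in mapping.items()}
        cds_w = float(2.0 ** cds_log2fe) if cds_log2fe is not None else 1.0
        return cls(weights, cds_w)


def weights_from_log2fe(table, cds_log2fe=None, **kw) -> WeightTable:
    """Functional alias for :meth:`WeightTable.from_log2fe`."""
    return WeightTable.from_log2fe(table, cds_log2fe, **kw)


@dataclass
class SnpTissueVector:
    """The per-SNP tissue score vector s_j over an ordered tissue list."""

    snp_id: str
    tissues: tuple[str, ...]
    scores: np.ndarray  # aligned with tissues, all >= 0
    cds_total: float = 0.0  # the CDS annotation's share of sum(scores)

    @property
    def total(self) -> float:
        return float(self.scores.sum())


def snp_tissue_vector(
    hits: Sequence[SnpAnnotationHit],
    weights: WeightTable,
    ess: pd.DataFrame | None,
    tissues: Sequence[str],
) -> SnpTissueVector:
    """Combine a SNP's annotation hits into its tissue score vector s_j.

    Chromatin-state hit: w_{a,t} split evenly over the tissues carrying the
    state at that position (the formula's sum-of-indicators denominator).
    CDS hit: w_CDS distributed by the gene's ESS vector (mean across genes
    when isoforms of several genes overlap), normalised by its sum — the
    same denominator, with ESS playing the indicator role.  A CDS hit on a
    gene with no expression (or absent from the ESS matrix) contributes 0.
    """
    tissues = tuple(tissues)
    t_index = {t: i for i, t in enumerate(tissues)}
    scores = np.zeros(len(tissues))
    cds_total = 0.0
    snp_id = hits[0].snp_id if hits else ""
    for h in hits:
        if h.annotation == CDS:
            vecs = []
            for g in h.gene_ids:
                if ess is not None and g in ess.index:
                    vecs.append(ess.loc[g, list(tissues)].to_numpy(float))
                else:
                    logger.warning(
                        "gene %s absent from ESS matrix; coding SNP %s "
                        "contributes nothing via CDS", g, h.snp_id,
                    )
                    vecs.append(np.zeros(len(tissues)))
            vec = np.mean(vecs, axis=0)
            denom = vec.sum()
            if denom > 0:
                contrib = weights.cds_weight * vec / denom
                scores += contrib
                cds_total += float(contrib.sum())
        else:
            if not h.tissues_hit:
                raise ValidationError(
                    f"chromatin hit for {h.snp_id} has empty tissue set"
                )
            n = len(h.tissues_hit)
            for t in h.tissues_hit:
                if t in t_index:
                    scores[t_index[t]] += weights[h.annotation, t] / n
    return SnpTissueVector(
        snp_id=snp_id, tissues=tissues, scores=scores, cds_total=cds_total
    )


@dataclass
class TOAProfile:
    """Per-signal tissue-of-action scores and the unclassified residual."""

    signal_id: str
    tau: dict[str, float]
    unclassified: float
    cumulative_ppa: float
    max_ppa: float
    n_snps: int
    coding_score: float = 0.0

    def __post_init__(self) -> None:
        if any(v < -CONSERVATION_TOL for v in self.tau.values()):
            raise ValidationError(f"{self.signal_id}: negative tau")
        if self.unclassified < -CONSERVATION_TOL:
            raise ValidationError(f"{self.signal_id}: negative unclassified")

    @property
    def tissues(self) -> list[str]:
        return list(self.tau)

    def as_array(self) -> np.ndarray:
        return np.array(list(self.tau.values()))


def compute_toa(
    cs: CredibleSet,
    vectors: Mapping[str, SnpTissueVector],
    tissues: Sequence[str],
    simple_coding_score: bool = False,
) -> TOAProfile:
    """Partition a credible set's PPA into per-tissue TOA scores plus U.

    Each SNP with a nonzero score vector contributes P_j * s_j / sum_t s_{j,t};
    SNPs hitting no included annotation contribute their whole P_j to the
    unclassified score.  ``coding_score`` is the cumulative PPA attributable
    to coding overlap — by default share-weighted (P_j times the CDS share
    of s_j); with ``simple_coding_score`` it is the plain sum of P_j over
    SNPs with any CDS contribution.
    """
    tissues = tuple(tissues)
    tau = np.zeros(len(tissues))
    coding = 0.0
    total_ppa = 0.0
    for v in cs.variants:
        total_ppa += v.ppa
        vec = vectors[v.snp_id]
        if tuple(vec.tissues) != tissues:
            raise ValidationError("tissue order mismatch between vectors")
        tot = vec.total
        if tot > 0:
            tau += v.ppa * vec.scores / tot
            if vec.cds_total > 0:
                coding += (
                    v.ppa if simple_coding_score
                    else v.ppa * vec.cds_total / tot
                )
    unclassified = total_ppa - tau.sum()
    return TOAProfile(
        signal_id=cs.signal_id,
        tau={t: float(x) for t, x in zip(tissues, tau)},
        unclassified=float(max(unclassified, 0.0)),
        cumulative_ppa=float(total_ppa),
        max_ppa=cs.max_ppa,
        n_snps=cs.n_snps,
        coding_score=float(coding),
    )


def score_credible_set(
    cs: CredibleSet,
    annotator,
    weights: WeightTable,
    ess: pd.DataFrame | None,
    tissues: Sequence[str],
    **kw,
) -> TOAProfile:
    """Annotate every credible SNP and compute the signal's TOA profile."""
    vectors = {
        v.snp_id: snp_tissue_vector(annotator.annotate(v), weights, ess, tissues)
        for v in cs.variants
    }
    return compute_toa(cs, vectors, tissues, **kw)


@dataclass
class WeightedTOAProfile:
    """TOA scores scaled by the index SNP's |beta|/SE (association strength)."""

    signal_id: str
    omega: dict[str, float]


def weighted_toa(p: TOAProfile, beta: float | None, se: float | None) -> WeightedTOAProfile:
    """omega_c = tau_c * |beta| / SE, elementwise."""
    if beta is None or se is None:
        raise ValidationError(f"{p.signal_id}: beta/SE required for weighted scores")
    if se <= 0:
        raise ValidationError(f"{p.signal_id}: SE must be > 0")
    k = abs(beta) / se
    return WeightedTOAProfile(
        signal_id=p.signal_id, omega={t: v * k for t, v in p.tau.items()}
    )


def ssd(p: TOAProfile) -> float:
    """Sum of squared pairwise differences between tissue scores.

    Computed over the tissue scores only (unclassified excluded), summing
    (tau_i - tau_j)^2 over unordered tissue pairs; 0 means perfectly even
    scores, larger means more tissue-specific.
    """
    x = p.as_array()
    n = len(x)
    # sum over unordered pairs = n*sum(x^2) - (sum x)^2, halved twice over
    return float(n * (x ** 2).sum() - x.sum() ** 2)


def build_credible_set_99(
    snps: Sequence[tuple[str, float]], target: float = 0.99
) -> list[tuple[str, float]]:
    """Minimal descending-PPA prefix whose cumulative PPA reaches ``target``.

    Ties in PPA break by SNP id (lexicographic) for determinism.  If the
    total PPA never reaches the target all SNPs are retained and a warning
    is logged.
    """
    for s, p in snps:
        if not 0.0 <= p <= 1.0:
            raise ValidationError(f"PPA out of [0,1] for {s}")
    total = sum(p for _, p in snps)
    if total > 1.0 + 1e-6:
        raise ValidationError(f"PPA sum {total:.6g} exceeds 1")
    ordered = sorted(snps, key=lambda sp: (-sp[1], sp[0]))
    if total < target:
        logger.warning(
            "cumulative PPA %.4g < %.2f; retaining all %d SNPs",
            total, target, len(ordered),
        )
        return ordered
    out, cum = [], 0.0
    for s, p in ordered:
        out.append((s, p))
        cum += p
        if cum >= target:
            break
    return out


def max_ppa_differential(
    scheme_ppa: Mapping[str, float], null_ppa: Mapping[str, float]
) -> dict[str, float]:
    """Per-signal (scheme - null) difference of maximum credible-set PPA.

    Measures how much a functional fine-mapping scheme sharpens resolution
    over an annotation-free baseline.
    """
    if set(scheme_ppa) != set(null_ppa):
        only_s = set(scheme_ppa) - set(null_ppa)
        only_n = set(null_ppa) - set(scheme_ppa)
        raise ValidationError(
            f"signal keys differ (scheme-only {sorted(only_s)[:5]}, "
            f"null-only {sorted(only_n)[:5]})"
        )
    return {k: scheme_ppa[k] - null_ppa[k] for k in scheme_ppa}
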