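"""TPM normalisation and expression specificity scores (ESS).

The ESS of gene *g* in tissue *t* is its median TPM in *t* divided by the
sum of its median TPMs over all evaluated tissues:

    eps_{g,t} = med(TPM_{g,t}) / sum_x med(TPM_{g,x})

Rows of the resulting gene x tissue matrix therefore sum to 1 for every
gene expressed in at least one tissue; genes with all-zero medians get an
all-zero row and are flagged.  ESS vectors weight coding credible-set SNPs
by the relative expression of the overlapped gene across tissues.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, ValidationError

logger = logging.getLogger(__name__)


def tpm_normalize(expr: ExpressionMatrix) -> pd.DataFrame:
    """Transcripts-per-million normalisation of a gene x sample count matrix.

    Per sample: rate_g = count_g / length_kb_g, TPM_g = 1e6 * rate_g / sum(rate).
    Corrects for gene length and library depth; each column sums to 1e6.
    """
    lengths_kb = expr.gene_length.loc[expr.counts.index].to_numpy(float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValidationError("gene lengths must be positive")
    rate = expr.counts.to_numpy(float) / lengths_kb[:, None]
    colsum = rate.sum(axis=0)
    zero = np.nonzero(colsum == 0)[0]
    if len(zero):
        raise ValidationError(
            f"sample(s) with all-zero counts: {list(expr.counts.columns[zero])}"
        )
    tpm = 1e6 * rate / colsum
    return pd.DataFrame(tpm, index=expr.counts.index, columns=expr.counts.columns)


def tissue_medians(
    tpm: pd.DataFrame,
    sample_tissue: Mapping[str, str] | pd.Series,
    tissues: Sequence[str],
) -> pd.DataFrame:
    """Median TPM of every gene within each tissue's samples (midpoint median)."""
    st = pd.Series(sample_tissue)
    med = {}
    for t in tissues:
        samples = st.index[st == t]
        samples = tpm.columns.intersection(samples)
        if len(samples) == 0:
            raise ValidationError(f"tissue {t!r} has no samples")
        med[t] = tpm[samples].median(axis=1)
    return pd.DataFrame(med, index=tpm.index)[list(tissues)]


def compute_ess(
    tpm: pd.DataFrame,
    sample_tissue: Mapping[str, str] | pd.Series,
    tissues: Sequence[str],
) -> pd.DataFrame:
    """Gene x tissue ESS matrix; rows sum to 1 for expressed genes.

    Genes whose median TPM is zero in every evaluated tissue yield all-zero
    rows (their coding SNPs contribute nothing through the CDS annotation).
    """
    med = tissue_medians(tpm, sample_tissue, tissues)
    denom = med.sum(axis=1)
    silent = denom == 0
    if silent.any():
        logger.warning(
            "%d gene(s) have zero median expression in all evaluated tissues",
            int(silent.sum()),
        )
    ess = med.div(denom.where(~silent, 1.0), axis=0)
    ess[silent] = 0.0
    return ess


def ess_from_counts(
    expr: ExpressionMatrix,
    tissues: Sequence[str] | None = None,
    pre_normalized: bool = False,
) -> pd.DataFrame:
    """Convenience: counts (or an already TPM-normalised matrix) -> ESS."""
    tissues = list(tissues) if tissues is not None else expr.tissues
    tpm = expr.counts.astype(float) if pre_normalized else tpm_normalize(expr)
    return compute_ess(tpm, expr.sample_tissue, tissues)
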