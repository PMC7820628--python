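"""Readers and writers for the tabular and interval formats the pipeline touches.

Coordinate conventions
----------------------
* Credible-set SNP positions are 1-based (the convention of GWAS summary
  files and dbSNP).
* Chromatin-state and coding-sequence intervals are 0-based half-open
  (BED convention).
* The SNP-in-interval test used downstream is ``start <= pos - 1 < end``.

Chromosome names are normalised to a single style (``"chr"`` prefixed or
plain) via the ``chrom_style`` argument; mixing styles across inputs is an
error rather than a silent non-overlap.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PPA_SUM_TOL = 1e-6


class FormatError(ValueError):
    """A file does not have the expected columns/shape."""


class ValidationError(ValueError):
    """A file parsed, but violates a domain invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Variant:
    """One credible-set SNP with its posterior probability of association."""

    snp_id: str
    chrom: str
    pos: int  # 1-based
    ppa: float

    def __post_init__(self) -> None:
        if not self.snp_id:
            raise ValidationError("snp_id must be non-empty")
        if self.pos < 1:
            raise ValidationError(f"pos must be >= 1, got {self.pos}")
        if not 0.0 <= self.ppa <= 1.0:
            raise ValidationError(f"ppa must be in [0,1], got {self.ppa}")


@dataclass
class CredibleSet:
    """One conditionally independent GWAS signal: its SNPs and PPAs.

    Variants are stored sorted by descending PPA.  ``beta``/``se`` are the
    index-SNP effect size and standard error, used only for effect-weighted
    scores.
    """

    signal_id: str
    variants: list[Variant]
    locus_name: str = ""
    index_snp: str | None = None
    beta: float | None = None
    se: float | None = None

    def __post_init__(self) -> None:
        self.variants = sorted(
            self.variants, key=lambda v: (-v.ppa, v.snp_id)
        )
        total = sum(v.ppa for v in self.variants)
        if not 0.0 < total <= 1.0 + PPA_SUM_TOL:
            raise ValidationError(
                f"signal {self.signal_id}: PPA sum {total:.6g} outside (0, 1]"
            )
        if self.se is not None and self.se <= 0:
            raise ValidationError(f"signal {self.signal_id}: se must be > 0")
        if self.index_snp is not None:
            if self.index_snp not in {v.snp_id for v in self.variants}:
                logger.warning(
                    "signal %s: index SNP %s not among credible variants",
                    self.signal_id,
                    self.index_snp,
                )

    @property
    def cumulative_ppa(self) -> float:
        return float(sum(v.ppa for v in self.variants))

    @property
    def max_ppa(self) -> float:
        return max(v.ppa for v in self.variants)

    @property
    def n_snps(self) -> int:
        return len(self.variants)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample read counts plus gene lengths and sample->tissue labels."""

    counts: pd.DataFrame  # genes x samples
    gene_length: pd.Series  # gene -> bp
    sample_tissue: pd.Series  # sample -> tissue label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValidationError("expression counts must be nonnegative")
        missing = self.counts.columns.difference(self.sample_tissue.index)
        if len(missing):
            raise ValidationError(
                f"samples without a tissue label: {list(missing)[:5]}"
            )
        missing_len = self.counts.index.difference(self.gene_length.index)
        if len(missing_len):
            raise ValidationError(
                f"genes without a length: {list(missing_len)[:5]}"
            )
        if (self.gene_length.loc[self.counts.index] <= 0).any():
            raise ValidationError("gene lengths must be positive")

    @property
    def tissues(self) -> list[str]:
        return sorted(self.sample_tissue.unique())


# ---------------------------------------------------------------------------
# Dialects and chromosome-name normalisation
# ---------------------------------------------------------------------------

#: logical name -> default header for credible-set tables
CREDIBLE_SET_DIALECT = {
    "signal_id": "signal_id",
    "locus": "locus",
    "snp_id": "snp_id",
    "chrom": "chrom",
    "pos": "pos",
    "ppa": "ppa",
    "beta": "beta",
    "se": "se",
    "is_index": "is_index",
}

_OPTIONAL_CS_COLS = {"locus", "beta", "se", "is_index"}


def normalize_chrom(values: pd.Series, style: str | None) -> pd.Series:
    """Coerce chromosome names to one style: ``"chr"``, ``"plain"`` or None."""
    s = values.astype(str)
    if style is None:
        has_prefix = s.str.startswith("chr")
        if has_prefix.any() and not has_prefix.all():
            raise ValidationError(
                "mixed chromosome-name styles ('chr1' and '1'); "
                "pass chrom_style to normalise"
            )
        return s
    if style == "chr":
        return s.where(s.str.startswith("chr"), "chr" + s)
    if style == "plain":
        return s.str.removeprefix("chr")
    raise ValueError(f"unknown chrom_style {style!r}")


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    return pd.read_csv(path, sep="\t", **kw)


def _resolve(df: pd.DataFrame, dialect: Mapping[str, str], logical: str,
             required: bool, path) -> str | None:
    col = dialect.get(logical, logical)
    if col in df.columns:
        return col
    if required:
        raise FormatError(
            f"{path}: missing required column {col!r} (for {logical!r})"
        )
    return None


# ---------------------------------------------------------------------------
# Credible sets
# ---------------------------------------------------------------------------


def read_credible_sets(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    chrom_style: str | None = None,
) -> list[CredibleSet]:
    """Read a credible-set TSV into one :class:`CredibleSet` per signal.

    Required columns (through the dialect mapping): signal_id, snp_id,
    chrom, pos, ppa.  Optional: locus, beta, se, is_index.
    """
    dialect = {**CREDIBLE_SET_DIALECT, **(dialect or {})}
    df = _read_tsv(path)
    cols = {
        k: _resolve(df, dialect, k, k not in _OPTIONAL_CS_COLS, path)
        for k in CREDIBLE_SET_DIALECT
    }
    if len(df) == 0:
        return []
    ppa = pd.to_numeric(df[cols["ppa"]], errors="coerce")
    bad = df.index[(ppa.isna()) | (ppa < 0) | (ppa > 1)]
    if len(bad):
        raise ValidationError(
            f"{path}: PPA outside [0,1] at data row(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    dup = df.duplicated(subset=[cols["signal_id"], cols["snp_id"]])
    if dup.any():
        raise ValidationError(
            f"{path}: duplicated (signal_id, snp_id) at data row(s) "
            f"{[int(i) + 2 for i in df.index[dup][:5]]}"
        )
    chrom = normalize_chrom(df[cols["chrom"]], chrom_style)
    out: list[CredibleSet] = []
    for sid, grp in df.groupby(cols["signal_id"], sort=True):
        variants = [
            Variant(
                snp_id=str(r[cols["snp_id"]]),
                chrom=str(chrom.loc[i]),
                pos=int(r[cols["pos"]]),
                ppa=float(r[cols["ppa"]]),
            )
            for i, r in grp.iterrows()
        ]
        index_snp = None
        if cols["is_index"] is not None:
            flagged = grp[grp[cols["is_index"]].astype(bool)]
            if len(flagged):
                index_snp = str(flagged.iloc[0][cols["snp_id"]])
        if index_snp is None:
            index_snp = max(variants, key=lambda v: (v.ppa, v.snp_id)).snp_id
        kw = {}
        for opt, key in (("beta", "beta"), ("se", "se")):
            if cols[key] is not None:
                val = grp.iloc[0][cols[key]]
                if pd.notna(val):
                    kw[opt] = float(val)
        locus = ""
        if cols["locus"] is not None:
            locus = str(grp.iloc[0][cols["locus"]])
        out.append(
            CredibleSet(
                signal_id=str(sid),
                variants=variants,
                locus_name=locus,
                index_snp=index_snp,
                **kw,
            )
        )
    return out


def write_credible_sets(sets: Sequence[CredibleSet], path: str | Path) -> None:
    rows = []
    for cs in sets:
        for v in cs.variants:
            rows.append(
                {
                    "signal_id": cs.signal_id,
                    "locus": cs.locus_name,
                    "snp_id": v.snp_id,
                    "chrom": v.chrom,
                    "pos": v.pos,
                    "ppa": v.ppa,
                    "beta": cs.beta if cs.beta is not None else "",
                    "se": cs.se if cs.se is not None else "",
                    "is_index": int(v.snp_id == cs.index_snp),
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Chromatin states / CDS / gene positions
# ---------------------------------------------------------------------------


def _validate_segmentation(df: pd.DataFrame, tissue: str, path) -> None:
    """Within one tissue, intervals on a chromosome must not overlap."""
    for chrom, grp in df.groupby("chrom", sort=False):
        g = grp.sort_values(["start", "end"])
        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        bad = np.nonzero(starts[1:] < ends[:-1])[0]
        if len(bad):
            i = bad[0]
            raise ValidationError(
                f"{path}: tissue {tissue!r} chrom {chrom}: overlapping "
                f"intervals [{starts[i]},{ends[i]}) and "
                f"[{starts[i + 1]},{ends[i + 1]})"
            )


def read_state_map(
    path: str | Path, tissue: str, chrom_style: str | None = None
) -> pd.DataFrame:
    """Read one tissue's BED4 chromatin-state segmentation."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "state"],
        dtype={0: str, 1: np.int64, 2: np.int64, 3: str},
    )
    if (df["start"] >= df["end"]).any():
        row = df.index[df["start"] >= df["end"]][0]
        raise ValidationError(f"{path}: start >= end at row {row + 1}")
    df["chrom"] = normalize_chrom(df["chrom"], chrom_style)
    df["tissue"] = tissue
    _validate_segmentation(df, tissue, path)
    return df


def read_state_maps(
    paths: Mapping[str, str | Path], chrom_style: str | None = None
) -> dict[str, pd.DataFrame]:
    """Read per-tissue segmentations; keys are tissue labels."""
    return {t: read_state_map(p, t, chrom_style) for t, p in paths.items()}


def read_bed4(
    path: str | Path, value_name: str, chrom_style: str | None = None
) -> pd.DataFrame:
    """BED4 reader for CDS (value=gene_id) or gene-position files."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", value_name],
        dtype={0: str, 1: np.int64, 2: np.int64, 3: str},
    )
    if (df["start"] >= df["end"]).any():
        row = int(df.index[df["start"] >= df["end"]][0])
        raise ValidationError(f"{path}: start >= end at row {row + 1}")
    if (df[value_name].astype(str) == "").any():
        raise ValidationError(f"{path}: empty {value_name}")
    df["chrom"] = normalize_chrom(df["chrom"], chrom_style)
    return df


def read_cds(path: str | Path, chrom_style: str | None = None) -> pd.DataFrame:
    """Coding-sequence intervals; overlap between records is allowed (isoforms)."""
    return read_bed4(path, "gene_id", chrom_style)


def read_gene_positions(
    path: str | Path, chrom_style: str | None = None
) -> pd.DataFrame:
    """Gene spans used for nearest-gene lookup; the TSS anchor is ``start``."""
    return read_bed4(path, "gene_id", chrom_style)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------


def read_expression(
    matrix_path: str | Path,
    sample_tissue_path: str | Path,
    gene_length_path: str | Path,
) -> ExpressionMatrix:
    """Assemble an :class:`ExpressionMatrix` from three TSVs.

    * ``matrix_path``: genes x samples, first column is the gene ID.
    * ``sample_tissue_path``: two columns (sample, tissue).
    * ``gene_length_path``: two columns (gene, length_bp).
    """
    counts = _read_tsv(matrix_path, index_col=0)
    st = _read_tsv(sample_tissue_path)
    if st.shape[1] < 2:
        raise FormatError(f"{sample_tissue_path}: need (sample, tissue) columns")
    sample_tissue = pd.Series(
        st.iloc[:, 1].astype(str).values, index=st.iloc[:, 0].astype(str)
    )
    gl = _read_tsv(gene_length_path)
    gene_length = pd.Series(
        gl.iloc[:, 1].astype(np.int64).values, index=gl.iloc[:, 0].astype(str)
    )
    return ExpressionMatrix(counts=counts, gene_length=gene_length,
                            sample_tissue=sample_tissue)


# ---------------------------------------------------------------------------
# Enrichment / weight tables and the small set-valued tables
# ---------------------------------------------------------------------------


def read_log2fe(path: str | Path) -> pd.DataFrame:
    """Annotation x tissue log2 fold-enrichment table.

    Long format with columns (annotation, tissue, log2fe); the coding-sequence
    row uses tissue ``"*"`` (a single genome-wide annotation).
    """
    df = _read_tsv(path)
    for c in ("annotation", "tissue", "log2fe"):
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    return df


def write_log2fe(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_snp_sets(path: str | Path, key_col: str, value_col: str) -> dict[str, set[str]]:
    """Generic two-column grouping reader (eQTL lists, trait catalogs, clusters)."""
    df = _read_tsv(df_path := path)
    for c in (key_col, value_col):
        if c not in df.columns:
            raise FormatError(f"{df_path}: missing column {c!r}")
    return {
        str(k): set(map(str, grp[value_col]))
        for k, grp in df.groupby(key_col, sort=True)
    }


def read_eqtl_sets(paths: Mapping[str, str | Path]) -> dict[str, set[str]]:
    """Per-tissue significant-eQTL SNP lists (one SNP id per line, no header)."""
    out = {}
    for tissue, p in paths.items():
        s = pd.read_csv(p, sep="\t", header=None).iloc[:, 0]
        out[tissue] = set(map(str, s))
    return out


def read_proxy_table(path: str | Path) -> dict[str, set[str]]:
    """snp_id -> set of LD proxies (columns snp_id, proxy_id)."""
    return read_snp_sets(path, "snp_id", "proxy_id")


# ---------------------------------------------------------------------------
# TOA score table
# ---------------------------------------------------------------------------


def write_toa_table(profiles: Sequence, path: str | Path,
                    tissues: Sequence[str] | None = None) -> None:
    """Write per-signal TOA profiles as a TSV.

    Columns: signal_id, one per tissue, unclassified, cumulative_ppa,
    max_ppa, n_snps, coding_score, ssd.
    """
    if len(profiles) == 0:
        raise ValidationError("no profiles to write")
    ids = [p.signal_id for p in profiles]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate signal_id among profiles")
    if tissues is None:
        tissues = list(profiles[0].tau.keys())
    from .core import ssd  # local import to avoid a cycle

    rows = []
    for p in profiles:
        row = {"signal_id": p.signal_id}
        for t in tissues:
            row[t] = p.tau[t]
        row["unclassified"] = p.unclassified
        row["cumulative_ppa"] = p.cumulative_ppa
        row["max_ppa"] = p.max_ppa
        row["n_snps"] = p.n_snps
        row["coding_score"] = p.coding_score
        row["ssd"] = ssd(p)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_toa_table(path: str | Path, tissues: Sequence[str]) -> list:
    """Round-trip reader for :func:`write_toa_table` output."""
    from .core import TOAProfile

    df = _read_tsv(path)
    need = ["signal_id", *tissues, "unclassified"]
    for c in need:
        if c not in df.columns:
            raise FormatError(f"{path}: missing column {c!r}")
    if df["signal_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate signal_id")
    out = []
    for _, r in df.iterrows():
        out.append(
            TOAProfile(
                signal_id=str(r["signal_id"]),
                tau={t: float(r[t]) for t in tissues},
                unclassified=float(r["unclassified"]),
                cumulative_ppa=float(r.get("cumulative_ppa", np.nan)),
                max_ppa=float(r.get("max_ppa", np.nan)),
                n_snps=int(r.get("n_snps", 0)),
                coding_score=float(r.get("coding_score", 0.0)),
            )
        )
    return out
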