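"""Deterministic synthetic fixtures: toy genomes with planted tissues of action.

The generator emulates the structure of the real inputs — per-tissue
chromatin-state segmentations of a genome, 99% credible sets with PPAs,
a tissue-skewed expression count matrix, an annotation enrichment table,
and the small set-valued tables used by the permutation analyses — on a
single toy chromosome, with a planted tissue of action per signal recorded
in a ground-truth table so recovery can be measured.

Construction, in outline:

* Regulatory elements are laid along the chromosome with exponential gaps;
  each carries one functional chromatin state and a tissue-membership set
  (a single tissue, or a random combination with probability
  ``fraction_shared_elements``).  Per-tissue segmentations place the
  element states over a quiescent background, so each tissue's map is a
  valid genome segmentation.
* Each signal draws a credible-set size (geometric) and a descending PPA
  vector (sorted Dirichlet).  SNPs are placed, in PPA order, inside
  elements active in the planted tissue until a target share of the PPA is
  "planted"; remaining SNPs fall uniformly on the chromosome.
* Genes get evenly spaced coding intervals, tissue-skewed Poisson counts,
  and random lengths; eQTL, physiology-cluster, proxy and trait-catalog
  tables are derived from the planted assignments plus decoys.

Identical seeds give byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as tio
from .io import CredibleSet, ExpressionMatrix, Variant

DEFAULT_TISSUES = ("islet", "adipose", "liver", "muscle")
FUNCTIONAL_STATES = (
    "Active_TSS",
    "Strong_enhancer",
    "Weak_enhancer",
    "Weak_transcription",
)
BACKGROUND_STATE = "Quiescent_low"

#: default genome-wide log2 fold enrichments per functional state
DEFAULT_LOG2FE = {
    "Active_TSS": 2.6,
    "Strong_enhancer": 2.8,
    "Weak_enhancer": 1.5,
    "Weak_transcription": 0.8,
}
CDS_LOG2FE = 2.59


@dataclass
class FixtureConfig:
    """Knobs of the synthetic study; defaults are the standard conditions."""

    seed: int
    n_tissues: int = 4
    n_signals: int = 60
    genome_length: int = 1_000_000
    state_labels: tuple[str, ...] = FUNCTIONAL_STATES
    fraction_shared_elements: float = 0.3
    cs_size_mean: float = 10.0
    max_cs_size: int = 100
    single_snp_only: bool = False
    ppa_in_planted: float = 0.8  # PPA share forced into planted-tissue elements
    mean_element_length: int = 600
    mean_gap_length: int = 1500
    n_genes: int = 80
    samples_per_tissue: int = 8
    fraction_specific_genes: float = 0.5
    expression_skew: float = 6.0
    enrichment_profile: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG2FE)
    )
    planted_tissues: tuple[str, ...] | None = None  # default: cycle

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction_shared_elements <= 1.0:
            raise ValueError("fraction_shared_elements must be in [0,1]")
        if not 0.0 <= self.ppa_in_planted <= 1.0:
            raise ValueError("ppa_in_planted must be in [0,1]")
        if (
            self.fraction_shared_elements >= 1.0
            and self.n_tissues > 1
            and self.n_signals > 0
        ):
            raise ValueError(
                "infeasible config: with every element shared no tissue-"
                "specific signal can be planted"
            )

    @property
    def tissues(self) -> tuple[str, ...]:
        base = list(DEFAULT_TISSUES)
        while len(base) < self.n_tissues:
            base.append(f"tissue{len(base) + 1}")
        return tuple(base[: self.n_tissues])


@dataclass
class Fixture:
    """The generated bundle: every pipeline input plus the ground truth."""

    config: FixtureConfig
    tissues: tuple[str, ...]
    elements: pd.DataFrame  # chrom,start,end,state,tissues (frozenset)
    state_maps: dict[str, pd.DataFrame]
    credible_sets: list[CredibleSet]
    expression: ExpressionMatrix
    cds: pd.DataFrame
    gene_positions: pd.DataFrame
    log2fe: pd.DataFrame
    truth: pd.DataFrame  # signal_id, planted_tissue
    eqtl_significant: dict[str, set[str]]
    cluster_map: dict[str, set[str]]
    proxy_table: dict[str, set[str]]
    trait_snp_sets: dict[str, set[str]]
    snp_universe: list[str]

    @property
    def included_states(self) -> tuple[str, ...]:
        return tuple(self.config.state_labels)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the bundle in the pipeline's external formats; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}

        p = outdir / "credible_sets.tsv"
        tio.write_credible_sets(self.credible_sets, p)
        paths["credible_sets"] = p

        for t in self.tissues:
            p = outdir / f"states_{t}.bed"
            self.state_maps[t][["chrom", "start", "end", "state"]].to_csv(
                p, sep="\t", header=False, index=False
            )
            paths[f"states_{t}"] = p

        p = outdir / "cds.bed"
        self.cds.to_csv(p, sep="\t", header=False, index=False)
        paths["cds"] = p
        p = outdir / "genes.bed"
        self.gene_positions.to_csv(p, sep="\t", header=False, index=False)
        paths["genes"] = p

        p = outdir / "expression_counts.tsv"
        self.expression.counts.to_csv(p, sep="\t", index_label="gene_id")
        paths["expression_counts"] = p
        p = outdir / "sample_tissue.tsv"
        self.expression.sample_tissue.rename("tissue").to_frame().to_csv(
            p, sep="\t", index_label="sample"
        )
        paths["sample_tissue"] = p
        p = outdir / "gene_lengths.tsv"
        self.expression.gene_length.rename("length_bp").to_frame().to_csv(
            p, sep="\t", index_label="gene_id"
        )
        paths["gene_lengths"] = p

        p = outdir / "log2fe.tsv"
        tio.write_log2fe(self.log2fe, p)
        paths["log2fe"] = p

        p = outdir / "truth.tsv"
        self.truth.to_csv(p, sep="\t", index=False)
        paths["truth"] = p

        for t, snps in self.eqtl_significant.items():
            p = outdir / f"eqtl_{t}.txt"
            pd.Series(sorted(snps)).to_csv(p, sep="\t", header=False, index=False)
            paths[f"eqtl_{t}"] = p

        p = outdir / "clusters.tsv"
        pd.DataFrame(
            [
                {"cluster": c, "signal_id": s}
                for c in sorted(self.cluster_map)
                for s in sorted(self.cluster_map[c])
            ]
        ).to_csv(p, sep="\t", index=False)
        paths["clusters"] = p

        p = outdir / "proxies.tsv"
        pd.DataFrame(
            [
                {"snp_id": k, "proxy_id": v}
                for k in sorted(self.proxy_table)
                for v in sorted(self.proxy_table[k])
            ]
        ).to_csv(p, sep="\t", index=False)
        paths["proxies"] = p

        p = outdir / "trait_catalog.tsv"
        pd.DataFrame(
            [
                {"trait": tr, "snp_id": s}
                for tr in sorted(self.trait_snp_sets)
                for s in sorted(self.trait_snp_sets[tr])
            ]
        ).to_csv(p, sep="\t", index=False)
        paths["trait_catalog"] = p
        return paths


def _place_elements(cfg: FixtureConfig, rng: np.random.Generator) -> pd.DataFrame:
    tissues = cfg.tissues
    rows = []
    pos = int(rng.exponential(cfg.mean_gap_length)) + 1
    while True:
        length = max(60, int(rng.exponential(cfg.mean_element_length)))
        if pos + length >= cfg.genome_length:
            break
        state = cfg.state_labels[rng.integers(len(cfg.state_labels))]
        if len(tissues) > 1 and rng.random() < cfg.fraction_shared_elements:
            size = int(rng.integers(2, len(tissues) + 1))
            members = frozenset(
                rng.choice(tissues, size=size, replace=False)
            )
        else:
            members = frozenset([tissues[rng.integers(len(tissues))]])
        rows.append(("chr1", pos, pos + length, state, members))
        pos += length + int(rng.exponential(cfg.mean_gap_length)) + 1
    return pd.DataFrame(
        rows, columns=["chrom", "start", "end", "state", "tissues"]
    )


def _state_maps_from_elements(
    cfg: FixtureConfig, elements: pd.DataFrame
) -> dict[str, pd.DataFrame]:
    maps = {}
    for t in cfg.tissues:
        rows = []
        cursor = 0
        for _, el in elements.iterrows():
            if t not in el["tissues"]:
                continue
            if el["start"] > cursor:
                rows.append(("chr1", cursor, el["start"], BACKGROUND_STATE))
            rows.append(("chr1", el["start"], el["end"], el["state"]))
            cursor = el["end"]
        if cursor < cfg.genome_length:
            rows.append(("chr1", cursor, cfg.genome_length, BACKGROUND_STATE))
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "state"])
        df["tissue"] = t
        maps[t] = df
    return maps


def _credible_sets(
    cfg: FixtureConfig,
    elements: pd.DataFrame,
    cds: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[list[CredibleSet], pd.DataFrame]:
    tissues = cfg.tissues
    by_tissue: dict[str, pd.DataFrame] = {
        t: elements[[t in s for s in elements["tissues"]]].reset_index(drop=True)
        for t in tissues
    }
    for t, sub in by_tissue.items():
        if len(sub) == 0:
            raise ValueError(f"no elements active in tissue {t!r}; enlarge genome")
    planted_cycle = cfg.planted_tissues or tissues
    cds_starts = cds["start"].to_numpy(np.int64)
    cds_ends = cds["end"].to_numpy(np.int64)

    def in_cds(pos0: int) -> bool:
        return bool(((cds_starts <= pos0) & (pos0 < cds_ends)).any())

    sets: list[CredibleSet] = []
    truth_rows = []
    for i in range(cfg.n_signals):
        planted = planted_cycle[i % len(planted_cycle)]
        if cfg.single_snp_only or cfg.cs_size_mean <= 1:
            size = 1
        else:
            size = min(int(rng.geometric(1.0 / cfg.cs_size_mean)), cfg.max_cs_size)
        if size == 1:
            ppas = np.array([1.0])
        else:
            ppas = np.sort(rng.dirichlet(np.full(size, 0.5)))[::-1]
        pool = by_tissue[planted]
        variants = []
        cum = 0.0
        for j, ppa in enumerate(ppas):
            if cum < cfg.ppa_in_planted:
                # planted placement: inside an element active in the planted
                # tissue, avoiding coding overlap so the chromatin signal is
                # unconfounded (coding SNPs carry expression evidence instead)
                for _ in range(50):
                    el = pool.iloc[int(rng.integers(len(pool)))]
                    pos0 = int(rng.integers(el["start"], el["end"]))
                    if not in_cds(pos0):
                        break
            else:
                pos0 = int(rng.integers(0, cfg.genome_length))
            cum += ppa
            variants.append(
                Variant(
                    snp_id=f"rs{i:04d}_{j:03d}",
                    chrom="chr1",
                    pos=pos0 + 1,
                    ppa=float(ppa),
                )
            )
        beta = float(rng.normal(0.0, 0.08))
        se = float(rng.uniform(0.01, 0.04))
        sets.append(
            CredibleSet(
                signal_id=f"signal_{i:04d}",
                variants=variants,
                locus_name=f"locus_{i:04d}",
                index_snp=variants[0].snp_id,
                beta=beta,
                se=se,
            )
        )
        truth_rows.append(
            {"signal_id": f"signal_{i:04d}", "planted_tissue": planted}
        )
    return sets, pd.DataFrame(truth_rows)


def _expression(
    cfg: FixtureConfig, rng: np.random.Generator
) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame]:
    tissues = cfg.tissues
    genes = [f"gene_{g:04d}" for g in range(cfg.n_genes)]
    samples, sample_tissue = [], {}
    for t in tissues:
        for k in range(cfg.samples_per_tissue):
            s = f"{t}_s{k}"
            samples.append(s)
            sample_tissue[s] = t
    base = rng.lognormal(mean=3.0, sigma=1.0, size=cfg.n_genes)
    primary = [tissues[g % len(tissues)] for g in range(cfg.n_genes)]
    specific = rng.random(cfg.n_genes) < cfg.fraction_specific_genes
    mean = np.empty((cfg.n_genes, len(samples)))
    for j, s in enumerate(samples):
        t = sample_tissue[s]
        skew = np.where(
            specific & (np.array(primary) == t), cfg.expression_skew, 1.0
        )
        mean[:, j] = base * skew
    counts = rng.poisson(mean).astype(np.int64)
    lengths = pd.Series(
        rng.integers(500, 5001, size=cfg.n_genes), index=genes, name="length_bp"
    )
    expr = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_length=lengths,
        sample_tissue=pd.Series(sample_tissue),
    )
    spacing = cfg.genome_length // (cfg.n_genes + 1)
    cds_rows, gene_rows = [], []
    for g, gene in enumerate(genes):
        tss = (g + 1) * spacing
        cds_rows.append(("chr1", tss, tss + 300, gene))
        gene_rows.append(("chr1", tss, tss + 2000, gene))
    cds = pd.DataFrame(cds_rows, columns=["chrom", "start", "end", "gene_id"])
    gene_pos = pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "gene_id"]
    )
    return expr, cds, gene_pos


def _log2fe_table(cfg: FixtureConfig) -> pd.DataFrame:
    rows = []
    for state in cfg.state_labels:
        fe = cfg.enrichment_profile.get(state, 1.0)
        for t in cfg.tissues:
            key = f"{state}|{t}"
            fe_t = cfg.enrichment_profile.get(key, fe)
            rows.append({"annotation": state, "tissue": t, "log2fe": fe_t})
    rows.append({"annotation": "CDS", "tissue": "*", "log2fe": CDS_LOG2FE})
    return pd.DataFrame(rows)


def _validation_tables(
    cfg: FixtureConfig,
    sets: list[CredibleSet],
    truth: pd.DataFrame,
    rng: np.random.Generator,
) -> tuple[dict, dict, dict, dict, list[str]]:
    planted = dict(zip(truth["signal_id"], truth["planted_tissue"]))
    index_of = {cs.signal_id: cs.index_snp for cs in sets}
    eqtl: dict[str, set[str]] = {t: set() for t in cfg.tissues}
    for cs in sets:
        t = planted[cs.signal_id]
        if rng.random() < 0.8:
            eqtl[t].add(index_of[cs.signal_id])
            if rng.random() < 0.1:  # a little cross-tissue contamination
                other = cfg.tissues[int(rng.integers(len(cfg.tissues)))]
                eqtl[other].add(index_of[cs.signal_id])
    for t in cfg.tissues:
        eqtl[t] |= {f"decoy_{t}_{k}" for k in range(30)}
    cluster_map = {
        f"cluster_{t}": {
            s for s, pt in planted.items() if pt == t
        }
        for t in cfg.tissues
    }
    proxy_table = {}
    for cs in sets:
        snp = index_of[cs.signal_id]
        k = int(rng.integers(0, 4))
        proxy_table[snp] = {snp} | {f"{snp}_p{i}" for i in range(k)}
    trait_sets = {}
    for t in cfg.tissues:
        members = sorted(s for s, pt in planted.items() if pt == t)
        chosen = {index_of[s] for s in members if rng.random() < 0.7}
        chosen |= {f"catalog_decoy_{t}_{k}" for k in range(10)}
        trait_sets[f"trait_{t}"] = chosen
    snp_universe = sorted(index_of.values())
    return eqtl, cluster_map, proxy_table, trait_sets, snp_universe


def generate_fixture(cfg: FixtureConfig) -> Fixture:
    """Generate the full bundle deterministically from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    elements = _place_elements(cfg, rng)
    state_maps = _state_maps_from_elements(cfg, elements)
    expr, cds, gene_pos = _expression(cfg, rng)
    sets, truth = _credible_sets(cfg, elements, cds, rng)
    log2fe = _log2fe_table(cfg)
    eqtl, clusters, proxies, traits, universe = _validation_tables(
        cfg, sets, truth, rng
    )
    return Fixture(
        config=cfg,
        tissues=cfg.tissues,
        elements=elements,
        state_maps=state_maps,
        credible_sets=sets,
        expression=expr,
        cds=cds,
        gene_positions=gene_pos,
        log2fe=log2fe,
        truth=truth,
        eqtl_significant=eqtl,
        cluster_map=clusters,
        proxy_table=proxies,
        trait_snp_sets=traits,
        snp_universe=universe,
    )
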