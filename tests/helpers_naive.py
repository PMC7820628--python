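"""Independent brute-force oracles, kept free of the package's fast paths.

These re-derive per-SNP tissue vectors and TOA profiles by linear scans
over the *raw* per-tissue interval tables (no partitioning, no bisection),
evaluating the scoring formulas SNP by SNP and annotation by annotation.
"""

from __future__ import annotations

import numpy as np


def naive_hits_per_base(state_maps, chrom, start, end, state):
    """Per-base tissue labelling over [start, end) for one state label."""
    labels = []
    for pos in range(start, end):
        tset = set()
        for t, df in state_maps.items():
            sub = df[(df["state"] == state) & (df["chrom"] == chrom)]
            for s, e in zip(sub["start"], sub["end"]):
                if s <= pos < e:
                    tset.add(t)
        labels.append(frozenset(tset))
    return labels


def naive_snp_vector(v, state_maps, cds, ess, weights, cds_weight,
                     tissues, included_states):
    """Evaluate s_j by scanning every raw interval for every annotation."""
    pos0 = v.pos - 1
    s = np.zeros(len(tissues))
    all_states = set()
    for df in state_maps.values():
        all_states |= set(df["state"])
    for a in sorted(all_states):
        if a not in included_states:
            continue
        ind = np.zeros(len(tissues))
        for i, t in enumerate(tissues):
            df = state_maps[t]
            for chrom, st, en, state in zip(
                df["chrom"], df["start"], df["end"], df["state"]
            ):
                if state == a and chrom == v.chrom and st <= pos0 < en:
                    ind[i] = 1.0
                    break
        denom = ind.sum()
        if denom > 0:
            for i, t in enumerate(tissues):
                s[i] += weights[(a, t)] * ind[i] / denom
    genes = sorted(
        {
            g
            for chrom, st, en, g in zip(
                cds["chrom"], cds["start"], cds["end"], cds["gene_id"]
            )
            if chrom == v.chrom and st <= pos0 < en
        }
    )
    cds_part = np.zeros(len(tissues))
    if genes:
        vecs = []
        for g in genes:
            if g in ess.index:
                vecs.append(ess.loc[g, list(tissues)].to_numpy(float))
            else:
                vecs.append(np.zeros(len(tissues)))
        vec = np.mean(vecs, axis=0)
        if vec.sum() > 0:
            cds_part = cds_weight * vec / vec.sum()
    return s + cds_part, float(cds_part.sum())


def naive_profile(cs, state_maps, cds, ess, weights, cds_weight,
                  tissues, included_states):
    """TOA profile by direct per-SNP enumeration of the partition formula."""
    tau = np.zeros(len(tissues))
    total = 0.0
    coding = 0.0
    for v in cs.variants:
        vec, cds_total = naive_snp_vector(
            v, state_maps, cds, ess, weights, cds_weight, tissues,
            included_states,
        )
        total += v.ppa
        if vec.sum() > 0:
            tau += v.ppa * vec / vec.sum()
            coding += v.ppa * cds_total / vec.sum()
    return tau, total - tau.sum(), coding
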