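import numpy as np
import pandas as pd
import pytest

import toascore as ts
from toascore.expression import compute_ess, tpm_normalize

SMALL = dict(
    n_signals=3,
    genome_length=60_000,
    n_genes=10,
    samples_per_tissue=4,
    cs_size_mean=8.0,
    max_cs_size=25,
)


def small_config(seed: int, **overrides) -> ts.FixtureConfig:
    """A fast fixture configuration for property sweeps."""
    kw = {**SMALL, **overrides}
    return ts.FixtureConfig(seed=seed, **kw)


def score_fixture(fx: ts.Fixture):
    """Run the full scoring pipeline on a fixture bundle."""
    tpm = tpm_normalize(fx.expression)
    ess = compute_ess(tpm, fx.expression.sample_tissue, list(fx.tissues))
    weights = ts.WeightTable.from_log2fe(fx.log2fe)
    profiles = ts.score_signals(
        fx.credible_sets,
        fx.state_maps,
        weights,
        ess=ess,
        cds=fx.cds,
        included_states=fx.included_states,
        tissues=list(fx.tissues),
    )
    return profiles, ess, weights


@pytest.fixture(scope="session")
def standard_fixture() -> ts.Fixture:
    """The standard study conditions: 60 signals, 30% shared elements,
    geometric credible-set sizes of mean 20."""
    return ts.generate_fixture(
        ts.FixtureConfig(seed=11, n_signals=60, cs_size_mean=20.0)
    )


@pytest.fixture(scope="session")
def standard_scored(standard_fixture):
    return score_fixture(standard_fixture)


@pytest.fixture(scope="session")
def specific_fixture() -> ts.Fixture:
    """Fully tissue-specific elements, single-SNP credible sets."""
    return ts.generate_fixture(
        ts.FixtureConfig(
            seed=11,
            n_signals=40,
            fraction_shared_elements=0.0,
            single_snp_only=True,
            ppa_in_planted=1.0,
        )
    )


def make_profile(tau: dict[str, float], n_snps: int = 1,
                 max_ppa: float | None = None, signal_id: str = "sig",
                 unclassified: float | None = None) -> ts.TOAProfile:
    total = sum(tau.values())
    if unclassified is None:
        unclassified = max(0.0, 1.0 - total)
    return ts.TOAProfile(
        signal_id=signal_id,
        tau=dict(tau),
        unclassified=unclassified,
        cumulative_ppa=total + unclassified,
        max_ppa=max_ppa if max_ppa is not None else 1.0,
        n_snps=n_snps,
    )
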