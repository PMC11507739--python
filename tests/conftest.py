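import numpy as np
import pandas as pd
import pytest

from eqtlkit import simgen


@pytest.fixture(scope="session")
def small_pop():
    return simgen.PopulationModel(
        n_variants=60, block_size=20, region_span=120_000, ld_decay=5e-5
    )


@pytest.fixture(scope="session")
def panel300(small_pop):
    """300-sample genotype panel shared across tests (read-only)."""
    return simgen.simulate_genotypes(small_pop, 300, seed=42)


@pytest.fixture(scope="session")
def one_gene():
    return pd.DataFrame(
        [
            {
                "gene_id": "g0",
                "chrom": "1",
                "start": 60_000,
                "end": 80_000,
                "strand": "+",
            }
        ]
    )


def make_track(beta, se, start_pos=1, chrom="1", trait_id="t", n=1000,
               trait_type="quantitative", ref=None, alt=None):
    """Build a SummaryStatTrack from effect vectors, for coloc unit tests."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    m = beta.size
    ref = ref if ref is not None else ["A"] * m
    alt = alt if alt is not None else ["C"] * m
    pos = np.arange(start_pos, start_pos + m)
    table = pd.DataFrame(
        {
            "variant_id": [f"{chrom}_{p}" for p in pos],
            "chrom": chrom,
            "pos": pos,
            "ref": ref,
            "alt": alt,
            "beta": beta,
            "se": se,
            "z": beta / se,
            "p": 1.0,
            "maf": 0.3,
        }
    )
    return simgen.SummaryStatTrack(
        trait_id=trait_id, trait_type=trait_type, table=table, n=n
    )
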