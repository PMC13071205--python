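import numpy as np
import pandas as pd
import pytest

from spectragwas import simulate as sim


@pytest.fixture(scope="session")
def small_founders():
    return sim.simulate_founders(n_founders=26, n_snps=400, n_chrom=3, seed=11)


@pytest.fixture(scope="session")
def small_genotypes(small_founders):
    return sim.simulate_rils(small_founders, n_rils=150, seed=12)


@pytest.fixture(scope="session")
def small_dataset(small_genotypes):
    """Genotypes plus structured spectra with one planted causal SNP and
    known environmental terms."""
    effects = sim.EffectSpec(
        causal_snps=[sim.CausalSNP(snp_index=50, band_lo=1400, band_hi=1500,
                                   effect=0.01)],
        structure_sd=0.008,
        water_sd=0.008,
    )
    env = sim.EnvironmentalDesign(rep_sd=0.01, patch_sd=0.006, dt_ct_sd=0.004)
    spectra, meta, truth = sim.simulate_spectra(
        small_genotypes, effects, env, noise_sd=0.003,
        phytometer_fraction=0.25, seed=13,
    )
    return {
        "genotypes": small_genotypes,
        "spectra": spectra,
        "metadata": meta,
        "truth": truth,
    }


def make_block_factors(n_samples, block_sizes, snr=10.0, seed=0,
                       band_start=0):
    """Samples x bands matrix: one latent factor per disjoint band block,
    unit noise, factor amplitude sqrt(snr).

    Returns (X, block_band_ids) with integer band ids starting at
    ``band_start``.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    cols = []
    start = band_start
    for size in block_sizes:
        f = rng.normal(size=n_samples)
        loading = rng.uniform(0.8, 1.2, size=size)
        cols.append(np.outer(f, loading) * np.sqrt(snr)
                    + rng.normal(size=(n_samples, size)))
        blocks.append(np.arange(start, start + size))
        start += size
    X = np.hstack(cols)
    bands = np.concatenate(blocks)
    return pd.DataFrame(X, columns=bands), [set(b.tolist()) for b in blocks]
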