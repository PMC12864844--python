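import numpy as np
import pytest

import glorimap as gm


@pytest.fixture(scope="session")
def small_params() -> gm.SimParams:
    return gm.SimParams(
        n_genes=40,
        length_range=(600, 1500),
        depth_mean=250,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_params):
    """One simulated experiment shared by read-level tests: transcripts,
    truth sites, treated reads, pileups, backgrounds, calls, site table."""
    transcripts = gm.simulate_transcriptome(small_params)
    sites = gm.plant_m6a_sites(transcripts, small_params)
    treated, untreated = gm.simulate_glori_reads(transcripts, sites, small_params)
    counts = gm.pileup_counts(treated, transcripts)
    backgrounds = {
        s: gm.estimate_background(pg, transcripts) for s, pg in counts.items()
    }
    calls = gm.call_sites(counts, transcripts, backgrounds)
    condition_map = {s: s.rsplit("_rep", 1)[0] for s in counts}
    site_df = gm.aggregate_conditions(calls, condition_map)
    return {
        "params": small_params,
        "transcripts": transcripts,
        "true_sites": sites,
        "treated": treated,
        "untreated": untreated,
        "counts": counts,
        "backgrounds": backgrounds,
        "calls": calls,
        "site_df": site_df,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
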