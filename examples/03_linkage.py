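"""Single-molecule co-methylation linkage between adjacent sites.

Simulates 300 genes each carrying two intermediate-stoichiometry sites
20 nt apart. With independent methylation the per-pair chi-square
p-values are uniform (~5% below 0.05); with molecule-coupled methylation
essentially every pair is detected.
"""

import numpy as np

import glorimap as gm
from glorimap import linkage
from glorimap.calibration import _transcripts_with_sites

rng = np.random.default_rng(3)
transcripts, sites = _transcripts_with_sites(
    rng, 300, 60, site_positions=[20, 40], stoichiometries=[0.5, 0.5], prefix="g"
)
params = gm.SimParams(
    n_genes=300, length_range=(60, 60), read_length=60, depth_mean=200,
    conversion_efficiency=1.0, n_replicates=1, seed=3,
)

for coupled in (False, True):
    treated, _ = gm.simulate_glori_reads(
        transcripts, sites, params, coupling=coupled, with_untreated=False
    )
    pairs = [(t.gene_id, 20, 40) for t in transcripts]
    survey = linkage.linkage_survey(pairs, treated)
    label = "coupled" if coupled else "independent"
    print(f"{label:12s} fraction p<0.05: {survey.attrs['frac_p_lt_05']:.3f} "
          f"(KS vs uniform: {survey.attrs['ks_stat']:.3f}, "
          f"n={survey.attrs['n_tested']})")
# Independent methylation: ~0.05 and a small KS statistic. Coupled
# methylation (shared latent state per molecule): near-complete rejection.
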