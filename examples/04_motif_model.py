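"""Sequence determinants of methylation stoichiometry.

Builds contexts whose score is a pure function of the +1/+4 bases
(+1 C high, +1 U with +4 U moderate, otherwise background), then shows
(i) the +1 composition by score band, (ii) the information-content logo
matrix, and (iii) a gradient-boosted regression that recovers the rule
and concentrates feature importance at +1.
"""

import numpy as np
import pandas as pd

from glorimap import motif
from glorimap.calibration import _rule_contexts

rng = np.random.default_rng(11)
contexts, scores = _rule_contexts(rng, 1200)
sites = pd.DataFrame(
    {
        "gene_id": [f"g{i}" for i in range(1200)],
        "position": 100,
        "context13": contexts,
        "median_control": scores,
        "coverage_control": 100.0,
    }
)

comp = motif.plus1_composition(sites)
print("+1 base frequency by score band:")
print(comp.round(3).to_string(index=False))

logo = motif.logo_matrix([c for c, s in zip(contexts, scores) if s > 0.8])
print("\ninformation content (bits) at offsets -1..+4 for high-score sites:")
print(logo[(logo.offset >= -1) & (logo.offset <= 4)][["offset", "ic"]]
      .round(3).to_string(index=False))

cm = motif.ContextMatrix(
    contexts=contexts,
    X=np.stack([motif.one_hot(c) for c in contexts]),
    y=np.asarray(scores),
    coverage=np.full(1200, 100.0),
    eij_dist=np.full(1200, np.nan),
    index=sites[["gene_id", "position"]],
)
report = motif.fit_score_model(cm, seed=1)
top = int(np.argmax(report.importance_by_position())) - motif.FLANK
print(f"\nmodel: held-out R^2 = {report.r2_test:.3f}, "
      f"largest positional importance at offset {top:+d}")
# R^2 near 1 and importance at +1: the model recovers the planted rule.
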