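"""Published summary statistics bundled as reference inputs.

The zebra element is the promoter-proximal cis-regulatory element of the
Drosophila pair-rule gene *fushi tarazu* (*ftz*).  Deleting it from the
endogenous locus (the *ftzΔZ* allele) reduces *ftz* stripe 4 to roughly a
quarter of wild-type levels while leaving the other six stripes marginally
affected.  The published experiment reports, per stripe and genotype, the
mean and standard deviation of the per-embryo fluorescent integrations
(HCR signal, area under the central-band 1D profile) for n=6 wild-type
(*w1118*) and n=5 mutant embryos.

These summaries are the canonical worked example for the statistics layer
and the parameter source for cohort simulation.
"""

from __future__ import annotations

import pandas as pd

WILDTYPE = "w1118"
MUTANT = "ftzDZ"

#: per-stripe (mean, sd) of integration, arbitrary units x %EL
_WT_INTEGRATIONS = [
    (63.9, 23.6),
    (69.1, 24.2),
    (56.9, 21.6),
    (58.6, 20.6),
    (68.9, 26.5),
    (90.3, 35.7),
    (157.0, 55.5),
]
_MUT_INTEGRATIONS = [
    (47.4, 19.6),
    (60.9, 21.1),
    (34.6, 8.37),
    (16.1, 9.22),
    (34.1, 13.4),
    (63.2, 29.8),
    (63.9, 62.3),
]

WT_N = 6
MUT_N = 5


def zebra_deletion_summaries() -> pd.DataFrame:
    """Per-stripe group summaries of the zebra-element deletion experiment.

    Returns a tidy frame with columns ``stripe`` (1..7, anterior to
    posterior), ``genotype``, ``n``, ``mean``, ``sd``.  Integration units
    are arbitrary fluorescence units times percent egg length.
    """
    rows = []
    for stripe, (m, s) in enumerate(_WT_INTEGRATIONS, start=1):
        rows.append((stripe, WILDTYPE, WT_N, m, s))
    for stripe, (m, s) in enumerate(_MUT_INTEGRATIONS, start=1):
        rows.append((stripe, MUTANT, MUT_N, m, s))
    return pd.DataFrame(rows, columns=["stripe", "genotype", "n", "mean", "sd"])
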