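"""Bundled published summary data.

A rat liver mutagenesis study comparing duplex error-corrected sequencing
against the transgenic-rodent (gpt) reporter assay on the same animals:
three corn-oil controls and three diethylnitrosamine (DEN)-treated F344
gpt delta rats.  The table holds, per sample, the sequenced read count,
the duplex-analysed base count (the frequency denominator), the accepted
mutation count, and the gpt assay mutant frequency (x 1e-5) reported for
the same livers.  These published totals let the whole frequency/CV/test
arithmetic be reproduced without any sequencing data (counts mode).
"""

from __future__ import annotations

import pandas as pd

_ROWS = [
    # sample, group, reads, analyzed_bases, mutations, gpt MF (x 1e-5)
    ("Control 3", "control", 987_423_042, 38_838_583, 20, 0.70),
    ("Control 8", "control", 1_077_081_792, 37_591_524, 35, 0.52),
    ("Control 9", "control", 1_065_771_452, 38_233_853, 60, 0.16),
    ("DEN P11", "treated", 923_538_038, 64_822_157, 476, 88.89),
    ("DEN P13", "treated", 886_468_356, 60_749_075, 373, 32.24),
    ("DEN P15", "treated", 812_319_594, 56_400_757, 350, 76.19),
]

#: Published group-average A:T>T:A (T>A class) mutation frequencies per
#: analysed base, used for the class fold-change worked example.
AT_TA_CLASS_FREQUENCY = {"control": 4.36e-8, "treated": 1.87e-6}


def rat_liver_den_study() -> pd.DataFrame:
    """Per-sample summary table of the DEN rat liver comparison study."""
    return pd.DataFrame(
        _ROWS,
        columns=["sample", "group", "reads", "analyzed_bases", "mutations", "external_mf"],
    )
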