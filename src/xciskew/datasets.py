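"""Published clinical validation-cohort results bundled as worked-example
inputs.

Eleven female patients were scored both by the clinical AR methylation
assay (XCI ratios from the androgen-receptor CAG-repeat test) and by the
NGS outlier method (percentage of heterozygous X sites with significantly
biased allelic expression). These printed per-sample values let the
classification and concordance stages be exercised without any sequence
data.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["clinical_validation_cohort"]

_ROWS = [
    # sample, assay call, % significantly skewed sites (NGS)
    ("Sample_1", "highly skewed", 73.04),
    ("Sample_2", "highly skewed", 22.43),
    ("Sample_3", "highly skewed", 46.32),
    ("Sample_5", "moderately skewed", 40.85),
    ("Sample_6", "moderately skewed", 25.93),
    ("Sample_7", "random", 2.35),
    ("Sample_8", "random", 8.24),
    ("Sample_9", "random", 2.94),
    ("Sample_11", "random", 2.63),
    ("Sample_10", "random", 18.37),
    ("Sample_14", "uninformative", 25.84),
]


def clinical_validation_cohort() -> pd.DataFrame:
    """The 11-sample clinical validation cohort (assay call + NGS pct)."""
    return pd.DataFrame(_ROWS, columns=["sample_id", "assay_call", "pct_skewed"])
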