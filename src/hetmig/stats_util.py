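"""Small shared statistical helpers."""
from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
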