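"""Shared test utilities."""

import numpy as np

from lhsched.constraints import ConstraintEvaluation


def make_evaluation(n, affected=(), soft=(), hard=(), extent=None):
    """Constraint evaluation with explicitly chosen boolean vectors."""
    hard_v = np.zeros(n, dtype=bool)
    soft_v = np.zeros(n, dtype=bool)
    aff_v = np.zeros(n, dtype=bool)
    hard_v[list(hard)] = True
    soft_v[list(soft)] = True
    aff_v[list(affected)] = True
    aff_v &= ~hard_v
    ext = np.zeros(n) if extent is None else np.asarray(extent, dtype=float)
    return ConstraintEvaluation(hard_v, soft_v, aff_v, ext)
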