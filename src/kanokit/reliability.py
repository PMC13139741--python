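"""Scale reliability (Cronbach's alpha) and coder agreement (Cohen's kappa).

Both statistics belong to the instrument-development stage of a survey:
alpha measures the internal consistency of a multi-item Likert scale,
kappa the chance-corrected agreement of two coders assigning categorical
labels.  The conventional benchmark applied here treats kappa >= 0.80 as
substantial agreement.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .core import UndefinedReliabilityError, ValidationError

#: Agreement at or above this kappa is reported as substantial.
SUBSTANTIAL_AGREEMENT = 0.80


def cronbach_alpha(matrix) -> float:
    """Cronbach's alpha of a respondents x items score matrix.

    alpha = k/(k-1) * (1 - sum of item variances / variance of row totals)

    with sample variances (denominator n-1).  Requires at least 2 items,
    2 respondents and no missing cells; raises
    :class:`UndefinedReliabilityError` when the row totals have zero
    variance (alpha's denominator vanishes).
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise ValidationError("score matrix must be 2-dimensional")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError(
            f"need >=2 respondents and >=2 items, got {n} x {k}"
        )
    if np.isnan(m).any():
        raise ValidationError("score matrix has missing cells; filter first")
    item_var = m.var(axis=0, ddof=1).sum()
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0.0:
        raise UndefinedReliabilityError("row totals have zero variance")
    return k / (k - 1) * (1.0 - item_var / total_var)


def cohens_kappa(labels_a: Sequence, labels_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two equally long label sequences.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the product of the two coders' marginal
    label distributions.  Undefined (raises) when both coders assign a
    single identical label throughout, since then p_e = 1.
    """
    a = list(labels_a)
    b = list(labels_b)
    if len(a) != len(b):
        raise ValidationError(
            f"label sequences differ in length: {len(a)} vs {len(b)}"
        )
    if not a:
        raise ValidationError("label sequences are empty")
    n = len(a)
    labels = sorted(set(a) | set(b), key=repr)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    table /= n
    p_o = np.trace(table)
    p_e = float(table.sum(axis=1) @ table.sum(axis=0))
    if p_e >= 1.0 - 1e-15:
        raise UndefinedReliabilityError(
            "kappa undefined: both coders constant and identical (p_e = 1)"
        )
    return float((p_o - p_e) / (1.0 - p_e))


def is_substantial_agreement(kappa: float) -> bool:
    """Apply the kappa >= 0.80 benchmark for substantial agreement."""
    return kappa >= SUBSTANTIAL_AGREEMENT
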