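"""AUC significance machinery: Hanley-McNeil SE, FDR, activation index.

A classifier's ROC AUC is tested against the chance level 0.5 with the
Hanley & McNeil (1982) closed-form standard error,

    SE(A) = sqrt[ (A(1-A) + (n+ - 1)(Q1 - A^2) + (n- - 1)(Q2 - A^2))
                  / (n+ n-) ],
    Q1 = A / (2 - A),      Q2 = 2 A^2 / (1 + A),

via a one-sided normal test (the analyses only ever interpret above-chance
discrimination).  P-values are pooled per analysis family and corrected with
Benjamini-Hochberg FDR; the corrected p maps to an activation index

    AI(p) = -ln(p)  if p < 0.01,   else 0,

so AI > 0 marks a significant electrode (or time bin) and its magnitude
grows with the strength of the discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.metrics import roc_auc_score

__all__ = [
    "AUCStat",
    "roc_auc",
    "hanley_mcneil_se",
    "auc_pvalue",
    "fdr_adjust",
    "activation_index",
    "auc_stat",
    "AI_ALPHA",
]

#: Significance threshold of the activation index (applied to FDR-adjusted p).
AI_ALPHA = 0.01

# Smallest representable p before the -log transform; keeps the activation
# index finite when the normal tail underflows to exactly 0.
_P_FLOOR = np.finfo(float).tiny


@dataclass
class AUCStat:
    auc: float
    n_pos: int
    n_neg: int
    se: float
    p: float
    p_adj: float | None = None
    ai: float | None = None


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC AUC with True ("+") as the positive class.

    Equals the Mann-Whitney statistic: the fraction of (positive, negative)
    pairs ranked correctly, counting ties as 1/2.
    """
    labels = np.asarray(labels, dtype=bool).ravel()
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float).ravel()))


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of an AUC given the class sizes."""
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be at least 1")
    a = float(auc)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a) + (n_pos - 1) * (q1 - a * a) + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auc_pvalue(auc: float, se: float, two_sided: bool = False) -> float:
    """Normal-approximation p-value of AUC vs the chance level 0.5.

    One-sided (above chance) by default.  ``se = 0`` is legal only for the
    degenerate perfect/null cases.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0.0:
        if auc == 0.5:
            return 0.5 if not two_sided else 1.0
        p = 0.0 if auc > 0.5 else 1.0
        return p if not two_sided else (0.0 if auc != 0.5 else 1.0)
    z = (auc - 0.5) / se
    p = float(norm.sf(z))
    if two_sided:
        p = float(min(1.0, 2.0 * norm.sf(abs(z))))
    return p


def fdr_adjust(pvals: np.ndarray, m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``m`` is the multiplicity family size; it may exceed ``len(pvals)``
    when the family includes tests not passed in (equivalent to padding
    with p = 1).  Adjusted values are monotone and clipped at 1.
    """
    p = np.asarray(pvals, dtype=float).ravel()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    n = len(p)
    if m is None:
        m = n
    if m < n:
        raise ValueError("family size m cannot be smaller than len(pvals)")
    if n == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, n + 1)
    # step-up: running minimum from the largest rank down
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def activation_index(p_adj, alpha: float = AI_ALPHA):
    """AI(p) = -ln p when p < alpha (strict), else 0.  Vectorized."""
    p = np.asarray(p_adj, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    ai = np.where(p < alpha, -np.log(np.maximum(p, _P_FLOOR)), 0.0)
    if np.ndim(p_adj) == 0:
        return float(ai)
    return ai


def auc_stat(auc: float, n_pos: int, n_neg: int,
             two_sided: bool = False) -> AUCStat:
    """Bundle an AUC with its Hanley-McNeil SE and raw p-value.

    FDR adjustment and the activation index are filled in later, once the
    full multiplicity family for the analysis is known.
    """
    se = hanley_mcneil_se(auc, n_pos, n_neg)
    return AUCStat(auc=float(auc), n_pos=n_pos, n_neg=n_neg, se=se,
                   p=auc_pvalue(auc, se, two_sided=two_sided))
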