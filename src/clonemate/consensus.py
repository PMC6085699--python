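"""Cross-method aggregation: Cohen's kappa agreement and consensus tallies.

Each clonality method produces a clonal/independent/not_evaluable call per
patient. This module measures chance-corrected agreement between pairs of
methods (unweighted Cohen's kappa on the two informative categories,
dropping not_evaluable rows pairwise) and tallies, per patient, how many
evaluable methods voted clonal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import CallLabel, PairTestResult

__all__ = [
    "cohens_kappa",
    "agreement_matrix",
    "consensus_tally",
    "build_call_matrix",
]

_MISSING = {CallLabel.NOT_EVALUABLE.value, None, np.nan}


def _clean(calls) -> list:
    out = []
    for c in calls:
        if isinstance(c, CallLabel):
            c = c.value
        out.append(c)
    return out


def cohens_kappa(calls_a, calls_b) -> float:
    """Unweighted Cohen's kappa between two binary call vectors.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and
    chance agreement p_e from the marginal call frequencies.
    ``not_evaluable`` entries are dropped pairwise. Returns NaN when fewer
    than two jointly evaluable rows remain or when p_e = 1 (both raters
    constant), where chance correction is undefined.
    """
    a, b = _clean(calls_a), _clean(calls_b)
    if len(a) != len(b):
        raise ValueError("call vectors must have equal length")
    pairs = [
        (x, y) for x, y in zip(a, b)
        if x not in _MISSING and y not in _MISSING
        and isinstance(x, str) and isinstance(y, str)
    ]
    if len(pairs) < 2:
        return float("nan")
    n = len(pairs)
    cats = sorted({x for x, _ in pairs} | {y for _, y in pairs})
    p_o = sum(1 for x, y in pairs if x == y) / n
    p_e = sum(
        (sum(1 for x, _ in pairs if x == c) / n)
        * (sum(1 for _, y in pairs if y == c) / n)
        for c in cats
    )
    if p_e == 1.0:
        return float("nan")
    return (p_o - p_e) / (1.0 - p_e)


def build_call_matrix(
    results_by_method: dict[str, list[PairTestResult]]
) -> pd.DataFrame:
    """Assemble per-method result lists into a patients x methods matrix."""
    frames = {}
    for method, results in results_by_method.items():
        frames[method] = pd.Series(
            {
                r.pair.patient_id: (
                    r.call.value if isinstance(r.call, CallLabel) else r.call
                )
                for r in results
            }
        )
    matrix = pd.DataFrame(frames)
    return matrix.fillna(CallLabel.NOT_EVALUABLE.value)


def agreement_matrix(call_matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Pairwise kappa table and per-method mean kappa (excluding self).

    The method with the highest mean kappa agrees best with the others.
    """
    methods = list(call_matrix.columns)
    if len(methods) < 2:
        raise ValueError("agreement needs at least 2 methods")
    kk = pd.DataFrame(np.eye(len(methods)), index=methods, columns=methods)
    for i, m1 in enumerate(methods):
        for m2 in methods[i + 1:]:
            k = cohens_kappa(call_matrix[m1], call_matrix[m2])
            kk.loc[m1, m2] = kk.loc[m2, m1] = k
    mean_k = pd.Series(
        {
            m: np.nanmean([kk.loc[m, o] for o in methods if o != m])
            for m in methods
        },
        name="mean_kappa",
    ).sort_values(ascending=False)
    return kk, mean_k


def consensus_tally(call_matrix: pd.DataFrame) -> pd.DataFrame:
    """Per patient: methods calling clonal over methods evaluable."""
    n_clonal = (call_matrix == CallLabel.CLONAL.value).sum(axis=1)
    n_eval = call_matrix.isin(
        [CallLabel.CLONAL.value, CallLabel.INDEPENDENT.value]
    ).sum(axis=1)
    return pd.DataFrame(
        {"n_clonal": n_clonal, "n_evaluable": n_eval},
        index=call_matrix.index,
    )
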