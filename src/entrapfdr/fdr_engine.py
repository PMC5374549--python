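"""Target-decoy FDR, q-values, and the entrapment false match rate (FMR).

Two standard FDR estimators are provided.  For a separate target/decoy
search::

    FDR = N_decoy / N_target

and for a concatenated search::

    FDR = 2 * N_decoy / (N_target + N_decoy)

The false match rate uses entrapment-labeled hits among accepted targets::

    FMR = N_trap / N_target

Entrapment-labeled records count as targets in FDR estimation (they are
target-database hits by construction); FMR measures how many of those
accepted targets are observable false positives.  q-values are the usual
monotonized running FDR down the score ranking; score ties are always
admitted or rejected together, so a threshold is a property of the score
value, not of an arbitrary ordering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .psm_model import LABEL_DECOY, LABEL_ENTRAPMENT

FORMULA_SEPARATE = "separate"
FORMULA_CONCATENATED = "concatenated"


def fdr_separate(n_target: int, n_decoy: int) -> float:
    """N_decoy / N_target; 0 for the empty set, +inf if targets vanish first."""
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be non-negative")
    if n_target == 0:
        return 0.0 if n_decoy == 0 else math.inf
    return n_decoy / n_target

def fdr_concatenated(n_target: int, n_decoy: int) -> float:
    """2*N_decoy / (N_target + N_decoy); 0 when the denominator is 0."""
    if n_target < 0 or n_decoy < 0:
        raise ValueError("counts must be non-negative")
    denom = n_target + n_decoy
    if denom == 0:
        return 0.0
    return 2.0 * n_decoy / denom

def fmr(n_trap: int, n_target: int) -> float:
    """N_trap / N_target; 0 when no targets are accepted."""
    if n_trap < 0 or n_target < 0:
        raise ValueError("counts must be non-negative")
    if n_trap > n_target:
        raise ValueError("n_trap cannot exceed n_target")
    if n_target == 0:
        return 0.0
    return n_trap / n_target


_FORMULAS = {FORMULA_SEPARATE: fdr_separate, FORMULA_CONCATENATED: fdr_concatenated}


def _fdr_fn(formula: str):
    try:
        return _FORMULAS[formula]
    except KeyError:
        raise ValueError(
            f"unknown FDR formula {formula!r}; use 'separate' or 'concatenated'"
        ) from None


@dataclass(slots=True)
class ThresholdResult:
    """The accepted target set at a score threshold, with its error estimates.

    ``accepted`` holds the target-labeled entities at or above the
    threshold; ``accepted_decoys`` holds the decoy entities above the same
    threshold (useful for pooling engines while keeping sub-FDRs
    estimable).  ``n_trap`` counts entrapment-labeled members of the
    accepted target set.
    """

    threshold: float
    n_target: int
    n_decoy: int
    n_trap: int
    fdr: float
    fmr: float
    accepted: list = field(default_factory=list)
    accepted_decoys: list = field(default_factory=list)


def compute_qvalues(records: Sequence, formula: str = FORMULA_CONCATENATED) -> list[float]:
    """Assign a q-value to every record; returns them in input order.

    Records are ranked by descending (higher-is-better) score; at each
    distinct score the running FDR is computed from cumulative target and
    decoy counts, and the q-value is the minimum running FDR at or below
    that rank.  Tied scores share one q-value.  Records must carry
    ``score`` and ``label`` attributes; ``q_value`` is set in place.
    """
    fdr_fn = _fdr_fn(formula)
    n = len(records)
    if n == 0:
        return []
    scores = np.empty(n)
    is_decoy = np.empty(n, dtype=bool)
    for i, rec in enumerate(records):
        if rec.label is None:
            raise ValueError(f"record {i} has no label; run labeling first")
        scores[i] = rec.score
        is_decoy[i] = rec.label == LABEL_DECOY

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    cum_decoy = np.cumsum(is_decoy[order])
    cum_target = np.arange(1, n + 1) - cum_decoy

    # ties share the counts at the end of their block
    block_end = np.empty(n, dtype=np.intp)
    i = n - 1
    while i >= 0:
        j = i
        while j > 0 and sorted_scores[j - 1] == sorted_scores[i]:
            j -= 1
        block_end[j : i + 1] = i
        i = j - 1
    running = np.array(
        [fdr_fn(int(cum_target[e]), int(cum_decoy[e])) for e in block_end]
    )
    qvals_sorted = np.minimum.accumulate(running[::-1])[::-1]

    qvals = np.empty(n)
    qvals[order] = qvals_sorted
    for rec, q in zip(records, qvals):
        rec.q_value = float(min(q, 1.0)) if math.isfinite(q) else 1.0
    return [rec.q_value for rec in records]


def filter_at_fdr(
    records: Sequence, alpha: float, formula: str = FORMULA_CONCATENATED
) -> ThresholdResult:
    """Largest score-thresholded target set with estimated FDR <= alpha.

    q-values are (re)computed, targets with q <= alpha are accepted, and
    the decoy count is taken above the same score threshold.  The reported
    ``fdr`` applies the chosen formula to the accepted counts and ``fmr``
    is the entrapment fraction of accepted targets.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    fdr_fn = _fdr_fn(formula)
    records = list(records)
    compute_qvalues(records, formula=formula)

    accepted = [
        r for r in records if r.label != LABEL_DECOY and r.q_value is not None and r.q_value <= alpha
    ]
    if not accepted:
        return ThresholdResult(
            threshold=math.inf, n_target=0, n_decoy=0, n_trap=0, fdr=0.0, fmr=0.0
        )
    threshold = min(r.score for r in accepted)
    accepted_decoys = [r for r in records if r.label == LABEL_DECOY and r.score >= threshold]
    n_target = len(accepted)
    n_decoy = len(accepted_decoys)
    n_trap = sum(1 for r in accepted if r.label == LABEL_ENTRAPMENT)
    return ThresholdResult(
        threshold=threshold,
        n_target=n_target,
        n_decoy=n_decoy,
        n_trap=n_trap,
        fdr=fdr_fn(n_target, n_decoy),
        fmr=fmr(n_trap, n_target),
        accepted=accepted,
        accepted_decoys=accepted_decoys,
    )
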