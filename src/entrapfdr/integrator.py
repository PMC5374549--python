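"""Multi-engine integration under subgroup sub-FDR control.

Naively pooling the 1%-FDR outputs of several search engines inflates the
error rate: the engines agree on correct matches but each contributes its
own random ones, so the union's false fraction exceeds any single list's.
The subgroup-agreement framework partitions the pooled (spectrum, peptide)
pairs by the number of engines k that identified them, then filters each
subgroup so that its own decoy-estimated sub-FDR stays below the
pre-defined threshold.  High-k subgroups are nearly error-free and pass
intact; the error concentrates in k = 1, which is trimmed, so the union
keeps more identifications than any single engine at a lower realized
error.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .fdr_engine import (
    FORMULA_CONCATENATED,
    ThresholdResult,
    _fdr_fn,
    filter_at_fdr,
    fmr as _fmr,
)
from .psm_model import LABEL_DECOY, LABEL_ENTRAPMENT, PSMRecord

CONSENSUS_MIN_Q = "min_q"
CONSENSUS_MEAN_RANK = "mean_rank"


class IntegrationError(ValueError):
    """Inconsistent per-engine inputs (label conflicts, too few engines)."""


@dataclass(slots=True)
class ConsensusPSM:
    """One pooled (spectrum, peptide) pair with per-engine evidence."""

    spectrum_id: str
    peptide: str
    engines: tuple[str, ...]
    per_engine_score: dict[str, float]
    per_engine_q: dict[str, float | None]
    accessions: tuple[str, ...]
    label: str
    score: float = math.nan  # consensus, higher is better
    q_value: float | None = None
    truth: bool | None = None

    @property
    def k(self) -> int:
        return len(self.engines)


@dataclass(slots=True)
class AgreementGroup:
    """All pooled pairs identified by exactly k engines, with sub-FDR/FMR."""

    k: int
    members: list[ConsensusPSM]
    n_target: int
    n_decoy: int
    n_trap: int
    sub_fdr: float
    sub_fmr: float


def _consensus_scores(
    merged: dict, per_engine_rank: dict, method: str
) -> None:
    for cons in merged.values():
        if method == CONSENSUS_MIN_Q:
            qs = [q for q in cons.per_engine_q.values() if q is not None]
            if not qs:
                raise IntegrationError(
                    f"no q-values for ({cons.spectrum_id}, {cons.peptide}); "
                    "min_q consensus requires q-values from every engine"
                )
            cons.score = -min(qs)
        elif method == CONSENSUS_MEAN_RANK:
            ranks = [per_engine_rank[(e, cons.spectrum_id, cons.peptide)] for e in cons.engines]
            cons.score = -sum(ranks) / len(ranks)
        else:
            raise IntegrationError(f"unknown consensus method {method!r}")


def pool_engines(
    per_engine: Sequence[tuple[str, Sequence[PSMRecord]]],
    formula: str = FORMULA_CONCATENATED,
    consensus: str = CONSENSUS_MIN_Q,
) -> list[AgreementGroup]:
    """Merge per-engine accepted PSM lists into agreement groups.

    Input lists are each engine's FDR-filtered output — targets plus the
    decoys above the same threshold, as produced by
    :func:`entrapfdr.fdr_engine.filter_at_fdr` (``accepted`` +
    ``accepted_decoys``) — each internally deduplicated per spectrum.
    Records merge on exact (spectrum_id, peptide) equality; k is the
    number of engines carrying the pair.  Labels must agree across
    engines, since labeling depends only on the accessions.  The consensus
    score is minus the best per-engine q-value by default (``min_q``), or
    minus the mean within-engine rank (``mean_rank``).
    """
    if len(per_engine) < 2:
        raise IntegrationError("pooling requires at least 2 engines")
    seen_engines = [e for e, _ in per_engine]
    if len(set(seen_engines)) != len(seen_engines):
        raise IntegrationError("duplicate engine ids in pool input")

    merged: dict[tuple[str, str], ConsensusPSM] = {}
    per_engine_rank: dict[tuple[str, str, str], int] = {}
    for engine_id, records in per_engine:
        ranked = sorted(records, key=lambda r: -r.score)
        for rank, rec in enumerate(ranked, start=1):
            if rec.label is None:
                raise IntegrationError(f"unlabeled record from engine {engine_id!r}")
            key = (rec.spectrum_id, rec.peptide)
            per_engine_rank[(engine_id, rec.spectrum_id, rec.peptide)] = rank
            cons = merged.get(key)
            if cons is None:
                merged[key] = ConsensusPSM(
                    spectrum_id=rec.spectrum_id,
                    peptide=rec.peptide,
                    engines=(engine_id,),
                    per_engine_score={engine_id: rec.score},
                    per_engine_q={engine_id: rec.q_value},
                    accessions=rec.accessions,
                    label=rec.label,
                    truth=rec.truth,
                )
                continue
            if cons.label != rec.label:
                raise IntegrationError(
                    f"label conflict for ({rec.spectrum_id}, {rec.peptide}): "
                    f"{cons.label} vs {rec.label}; per-engine database indices disagree"
                )
            cons.engines = cons.engines + (engine_id,)
            cons.per_engine_score[engine_id] = rec.score
            cons.per_engine_q[engine_id] = rec.q_value
    _consensus_scores(merged, per_engine_rank, consensus)

    fdr_fn = _fdr_fn(formula)
    by_k: dict[int, list[ConsensusPSM]] = defaultdict(list)
    for cons in merged.values():
        by_k[cons.k].append(cons)
    groups = []
    for k in sorted(by_k):
        members = by_k[k]
        n_decoy = sum(1 for m in members if m.label == LABEL_DECOY)
        n_target = len(members) - n_decoy
        n_trap = sum(1 for m in members if m.label == LABEL_ENTRAPMENT)
        groups.append(
            AgreementGroup(
                k=k,
                members=members,
                n_target=n_target,
                n_decoy=n_decoy,
                n_trap=n_trap,
                sub_fdr=fdr_fn(n_target, n_decoy),
                sub_fmr=_fmr(n_trap, n_target),
            )
        )
    return groups


def filter_subgroups(
    groups: Sequence[AgreementGroup],
    alpha: float,
    formula: str = FORMULA_CONCATENATED,
) -> ThresholdResult:
    """Filter each agreement group to sub-FDR <= alpha and pool the survivors.

    Within each group the standard q-value filter runs on the consensus
    score; the integrated result is the union of the per-group accepted
    sets, with overall counts, FDR, and FMR recomputed on that union.  The
    reported threshold is NaN because each group has its own.
    """
    fdr_fn = _fdr_fn(formula)
    accepted: list[ConsensusPSM] = []
    accepted_decoys: list[ConsensusPSM] = []
    for group in groups:
        res = filter_at_fdr(group.members, alpha, formula=formula)
        accepted.extend(res.accepted)
        accepted_decoys.extend(res.accepted_decoys)
    n_target = len(accepted)
    n_decoy = len(accepted_decoys)
    n_trap = sum(1 for m in accepted if m.label == LABEL_ENTRAPMENT)
    return ThresholdResult(
        threshold=math.nan,
        n_target=n_target,
        n_decoy=n_decoy,
        n_trap=n_trap,
        fdr=fdr_fn(n_target, n_decoy),
        fmr=_fmr(n_trap, n_target),
        accepted=accepted,
        accepted_decoys=accepted_decoys,
    )


def pool_union(
    per_engine: Sequence[tuple[str, Sequence[PSMRecord]]],
    formula: str = FORMULA_CONCATENATED,
    consensus: str = CONSENSUS_MIN_Q,
) -> ThresholdResult:
    """Naive union of the per-engine accepted sets, without sub-FDR control.

    Every pooled pair is kept; the decoy-estimated FDR of this union is
    typically well above each engine's filtering threshold.
    """
    fdr_fn = _fdr_fn(formula)
    groups = pool_engines(per_engine, formula=formula, consensus=consensus)
    members = [m for g in groups for m in g.members]
    targets = [m for m in members if m.label != LABEL_DECOY]
    decoys = [m for m in members if m.label == LABEL_DECOY]
    n_trap = sum(1 for m in targets if m.label == LABEL_ENTRAPMENT)
    return ThresholdResult(
        threshold=math.nan,
        n_target=len(targets),
        n_decoy=len(decoys),
        n_trap=n_trap,
        fdr=fdr_fn(len(targets), len(decoys)),
        fmr=_fmr(n_trap, len(targets)),
        accepted=targets,
        accepted_decoys=decoys,
    )
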