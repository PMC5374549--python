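"""Peptide- and protein-level aggregation with the same FDR/FMR filtering.

PSMs are collapsed to distinct peptide sequences (best score, short
peptides dropped), and peptides are assembled into protein groups by
greedy parsimony.  Each level is then filtered exactly like PSMs: rank by
score, compute q-values from target/decoy counts, accept at the chosen
FDR, and report the entrapment FMR of the accepted set.  Protein-level
FDR here is plain target-decoy counting on groups — deliberately simpler
than hypergeometric corrections used by dedicated protein-FDR tools.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Sequence

from .fdr_engine import FORMULA_CONCATENATED, ThresholdResult, filter_at_fdr
from .psm_model import LABEL_DECOY, LABEL_ENTRAPMENT, LABEL_SAMPLE, PSMRecord

_LABEL_RANK = {LABEL_SAMPLE: 0, LABEL_ENTRAPMENT: 1, LABEL_DECOY: 2}


def _combine_labels(labels) -> str:
    """Sample beats entrapment beats decoy, mirroring accession-set labeling."""
    return min(labels, key=_LABEL_RANK.__getitem__)


@dataclass
class PeptideIdent:
    """One distinct peptide with its best supporting evidence."""

    peptide: str
    best_score: float
    n_spectra: int
    accessions: frozenset[str]
    label: str
    q_value: float | None = None

    @property
    def score(self) -> float:
        return self.best_score


@dataclass
class ProteinGroup:
    """Accessions sharing one evidence set, led by the greedy-cover winner."""

    lead_accession: str
    member_accessions: tuple[str, ...]
    peptides: list[PeptideIdent]
    group_score: float
    label: str
    q_value: float | None = None

    @property
    def score(self) -> float:
        return self.group_score


def rollup_peptides(psms: Sequence[PSMRecord], min_length: int = 7) -> list[PeptideIdent]:
    """Collapse labeled PSMs to distinct peptides.

    Peptides shorter than ``min_length`` (default 7 residues) are not taken
    into account.  The peptide label is recomputed from the union of
    supporting accessions, with sample precedence, and the best score wins.
    """
    by_pep: dict[str, list[PSMRecord]] = defaultdict(list)
    for psm in psms:
        if psm.label is None:
            raise ValueError(f"unlabeled PSM for spectrum {psm.spectrum_id!r}")
        if len(psm.peptide) < min_length:
            continue
        by_pep[psm.peptide].append(psm)
    out = []
    for pep, group in by_pep.items():
        out.append(
            PeptideIdent(
                peptide=pep,
                best_score=max(p.score for p in group),
                n_spectra=len(group),
                accessions=frozenset(a for p in group for a in p.accessions),
                label=_combine_labels(p.label for p in group),
            )
        )
    return out


def infer_proteins(peptides: Sequence[PeptideIdent]) -> list[ProteinGroup]:
    """Greedy parsimony assembly of peptides into protein groups.

    Repeatedly pick the accession covering the most unexplained peptides
    (ties broken by accession order), assign those peptides to it, and
    merge accessions whose full peptide evidence is identical into one
    group.  Every peptide ends up in exactly one group.
    """
    pep_sets: dict[str, set[int]] = defaultdict(set)
    for i, pep in enumerate(peptides):
        for acc in pep.accessions:
            pep_sets[acc].add(i)
    full_sets = {acc: frozenset(s) for acc, s in pep_sets.items()}

    unexplained = set(range(len(peptides)))
    groups: list[ProteinGroup] = []
    claimed: set[str] = set()
    while unexplained:
        lead = min(
            pep_sets,
            key=lambda acc: (-len(pep_sets[acc] & unexplained), acc),
        )
        assigned = sorted(pep_sets[lead] & unexplained)
        if not assigned:
            break
        unexplained -= set(assigned)
        members = tuple(
            sorted(
                acc
                for acc, s in full_sets.items()
                if s == full_sets[lead] and acc not in claimed
            )
        )
        claimed.update(members)
        group_peps = [peptides[i] for i in assigned]
        groups.append(
            ProteinGroup(
                lead_accession=lead,
                member_accessions=members,
                peptides=group_peps,
                group_score=max(p.best_score for p in group_peps),
                label=_combine_labels(p.label for p in group_peps),
            )
        )
    return groups


def level_filter(
    level_records: Sequence, alpha: float, formula: str = FORMULA_CONCATENATED
) -> ThresholdResult:
    """FDR-filter peptide or protein entities exactly like PSMs.

    Entities must carry ``score`` and ``label``; FMR is the entrapment
    fraction of the accepted targets at this level.
    """
    return filter_at_fdr(level_records, alpha, formula=formula)
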