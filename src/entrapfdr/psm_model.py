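"""Peptide-spectrum-match records, table parsing, and origin labeling.

Search engines emit heterogeneous result tables; this module normalizes
them into :class:`PSMRecord` objects carrying a bare peptide string, a
higher-is-better score, and a label derived from the mapped accessions.
The labeling rule resolves shared matches in favor of the sample side: a
spectrum matching both sample and entrapment sequences counts as a sample
identification, and any target accession beats a decoy-only mapping.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import pandas as pd

from .db_builder import ORIGIN_ENTRAPMENT, ORIGIN_SAMPLE, SearchDatabase

logger = logging.getLogger(__name__)

LABEL_SAMPLE = "sample"
LABEL_ENTRAPMENT = "entrapment"
LABEL_DECOY = "decoy"

HIGHER_BETTER = "higher_better"
LOWER_BETTER = "lower_better"


class PSMError(ValueError):
    """Malformed PSM input (missing column, bad score, empty accessions)."""


@dataclass(slots=True)
class PSMRecord:
    """One peptide-spectrum match.

    ``peptide`` is the bare sequence with modification annotations stripped
    so that identity is comparable across engines.  ``label`` is derived
    from ``accessions`` via :func:`label_psm`.  ``truth`` is only populated
    by the synthetic-data generator.
    """

    spectrum_id: str
    engine_id: str
    peptide: str
    accessions: tuple[str, ...]
    score: float
    score_direction: str = HIGHER_BETTER
    q_value: float | None = None
    label: str | None = None
    truth: bool | None = None

    def __post_init__(self) -> None:
        self.accessions = tuple(self.accessions)
        if not self.accessions:
            raise PSMError(
                f"PSM {self.spectrum_id!r}/{self.peptide!r} has no mapped accessions"
            )
        if self.q_value is not None and not 0.0 <= self.q_value <= 1.0:
            raise PSMError(f"q_value {self.q_value} outside [0, 1]")


@dataclass(frozen=True)
class ColumnMap:
    """Where to find the mandatory PSM fields in a delimited table.

    Each field is a column name (header row required) or a 0-based integer
    position.  ``accession_delim`` splits multi-protein cells.
    """

    spectrum: str | int = "spectrum"
    peptide: str | int = "peptide"
    accessions: str | int = "proteins"
    score: str | int = "score"
    qvalue: str | int | None = None
    accession_delim: str = ";"
    score_direction: str = HIGHER_BETTER


_MOD_BRACKETS = re.compile(r"\([^)]*\)|\[[^\]]*\]|\{[^}]*\}")
_NON_LETTER = re.compile(r"[^A-Za-z]")


def strip_modifications(peptide: str) -> str:
    """Bare uppercase sequence: bracketed annotations and non-letters removed.

    ``"PEPT[+79.97]IDEK"`` and ``"PEPTIDEK"`` become the same string, which
    is what cross-engine peptide identity requires.
    """
    bare = _MOD_BRACKETS.sub("", peptide)
    bare = _NON_LETTER.sub("", bare)
    return bare.upper()


def _resolve(df: pd.DataFrame, selector: str | int, role: str) -> pd.Series:
    if isinstance(selector, int):
        if selector >= df.shape[1]:
            raise PSMError(f"column position {selector} for {role} out of range")
        return df.iloc[:, selector]
    if selector not in df.columns:
        raise PSMError(f"missing mandatory column {selector!r} ({role})")
    return df[selector]


def read_psm_table(
    source,
    colmap: ColumnMap | None = None,
    engine_id: str = "engine",
    sep: str = "\t",
) -> list[PSMRecord]:
    """Parse a delimited PSM table into records.

    One best-scoring row is kept per spectrum (the dropped duplicates are
    logged); peptide strings are stripped of modification annotations; the
    accession cell is split on ``colmap.accession_delim``.
    """
    colmap = colmap or ColumnMap()
    header = None if any(
        isinstance(s, int)
        for s in (colmap.spectrum, colmap.peptide, colmap.accessions, colmap.score)
    ) else 0
    df = pd.read_csv(source, sep=sep, header=header, dtype=str)
    if df.empty:
        return []

    spectra = _resolve(df, colmap.spectrum, "spectrum id")
    peptides = _resolve(df, colmap.peptide, "peptide")
    prots = _resolve(df, colmap.accessions, "protein accessions")
    scores_raw = _resolve(df, colmap.score, "score")
    qvals = _resolve(df, colmap.qvalue, "q-value") if colmap.qvalue is not None else None

    records: list[PSMRecord] = []
    for i in range(len(df)):
        try:
            score = float(scores_raw.iloc[i])
        except (TypeError, ValueError):
            raise PSMError(f"unparsable score {scores_raw.iloc[i]!r} at data row {i}") from None
        acc_cell = prots.iloc[i]
        accessions = tuple(
            a.strip() for a in str(acc_cell).split(colmap.accession_delim) if a.strip()
        ) if not pd.isna(acc_cell) else ()
        if not accessions:
            raise PSMError(f"empty accession field at data row {i}")
        qv = None
        if qvals is not None and not pd.isna(qvals.iloc[i]):
            qv = float(qvals.iloc[i])
        records.append(
            PSMRecord(
                spectrum_id=str(spectra.iloc[i]),
                engine_id=engine_id,
                peptide=strip_modifications(str(peptides.iloc[i])),
                accessions=accessions,
                score=score,
                score_direction=colmap.score_direction,
                q_value=qv,
            )
        )
    return dedupe_by_spectrum(records)


def dedupe_by_spectrum(records: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Keep the best-scoring record per spectrum within one engine's list."""
    best: dict[tuple[str, str], PSMRecord] = {}
    dropped = 0
    for rec in records:
        key = (rec.engine_id, rec.spectrum_id)
        cur = best.get(key)
        if cur is None:
            best[key] = rec
            continue
        dropped += 1
        if rec.score_direction == LOWER_BETTER:
            if rec.score < cur.score:
                best[key] = rec
        elif rec.score > cur.score:
            best[key] = rec
    if dropped:
        logger.info("dropped %d duplicate spectrum rows (kept best score)", dropped)
    return list(best.values())


def label_psm(record: PSMRecord, index: SearchDatabase | dict) -> str:
    """Assign sample/entrapment/decoy from the mapped accessions.

    Precedence: any non-decoy sample accession -> sample; else any
    non-decoy entrapment accession -> entrapment; else all-decoy -> decoy.
    A record mapping to both target and decoy entries therefore counts as a
    target.  The result depends only on the accession *set*, never its
    order.
    """
    lookup = index.index if isinstance(index, SearchDatabase) else index
    missing = [a for a in record.accessions if a not in lookup]
    if missing:
        raise PSMError(f"unresolvable accessions: {missing}")
    label = LABEL_DECOY
    for acc in record.accessions:
        origin, is_decoy = lookup[acc]
        if is_decoy:
            continue
        if origin == ORIGIN_SAMPLE:
            return LABEL_SAMPLE
        if origin == ORIGIN_ENTRAPMENT:
            label = LABEL_ENTRAPMENT
    return label


def label_psms(records: Iterable[PSMRecord], index: SearchDatabase | dict) -> list[PSMRecord]:
    """Label every record in place; returns the same list for chaining."""
    records = list(records)
    for rec in records:
        rec.label = label_psm(rec, index)
    return records


def normalize_scores(records: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Return records with scores oriented so that higher is better.

    Lower-is-better scores (e-values, q-values used as scores) are negated,
    a monotone map that exactly inverts the ranking.  All records in one
    batch must share a direction.
    """
    records = list(records)
    if not records:
        return []
    directions = {rec.score_direction for rec in records}
    if len(directions) > 1:
        raise PSMError(f"mixed score directions in one batch: {sorted(directions)}")
    direction = directions.pop()
    if direction == HIGHER_BETTER:
        return records
    if direction != LOWER_BETTER:
        raise PSMError(f"unknown score direction {direction!r}")
    out = []
    for rec in records:
        out.append(replace_score(rec, -rec.score))
    return out


def replace_score(rec: PSMRecord, score: float) -> PSMRecord:
    """Copy of a record with a new higher-is-better score."""
    if math.isnan(score):
        raise PSMError(f"NaN score for spectrum {rec.spectrum_id!r}")
    return replace(rec, score=score, score_direction=HIGHER_BETTER)
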