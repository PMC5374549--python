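"""Construction of labeled sample/entrapment/decoy protein databases.

An entrapment benchmark database concatenates the *sample* proteome (the
organism actually measured) with a much larger set of *entrapment* proteins
known to be absent from the sample.  Target hits that map to entrapment
sequences are directly observable false positives, which makes the false
match rate (FMR) measurable alongside the decoy-estimated FDR.  This module
assembles such databases: it expands an entrapment set by per-sequence
residue shuffling, reverses every target sequence into a decoy, audits the
tryptic-peptide overlap between the sample and entrapment sides, and reads
and writes plain FASTA.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import parser as _pyt_parser

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

ORIGIN_SAMPLE = "sample"
ORIGIN_ENTRAPMENT = "entrapment"

DEFAULT_DECOY_PREFIX = "rev_"
DEFAULT_TRAP_PREFIX = "trap_"


class DatabaseError(ValueError):
    """Invalid database content (empty sequence, duplicate accession, ...)."""


@dataclass(slots=True)
class SequenceEntry:
    """One protein record with its benchmark role.

    Parameters
    ----------
    accession : str
        Identifier, unique within a database after prefixing.
    residues : str
        Uppercase amino-acid string.  Non-standard letters (B, J, O, U, X,
        Z) are tolerated and kept verbatim but trigger a warning; they are
        never treated as cleavage sites.
    origin : str
        ``"sample"`` or ``"entrapment"``.
    is_decoy : bool
        True for reversed decoy entries.
    """

    accession: str
    residues: str
    origin: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise DatabaseError(f"empty sequence for accession {self.accession!r}")
        if self.origin not in (ORIGIN_SAMPLE, ORIGIN_ENTRAPMENT):
            raise DatabaseError(f"unknown origin {self.origin!r}")
        self.residues = self.residues.upper()
        odd = set(self.residues) - STANDARD_RESIDUES
        if odd:
            logger.warning(
                "accession %s contains non-standard residues %s; kept verbatim",
                self.accession,
                "".join(sorted(odd)),
            )


@dataclass(frozen=True)
class DigestConfig:
    """In-silico digestion parameters.

    Defaults follow common shotgun practice: tryptic cleavage after Lys or
    Arg, at most one missed cleavage, peptides of at least 7 residues.  The
    classical proline suppression (no cleavage before P) is off by default
    and available via ``proline_rule``.
    """

    cleavage_residues: frozenset[str] = frozenset({"K", "R"})
    max_missed: int = 1
    min_length: int = 7
    proline_rule: bool = False

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.max_missed < 0:
            raise ValueError("max_missed must be >= 0")
        if not self.cleavage_residues:
            raise ValueError("cleavage_residues must be non-empty")
        object.__setattr__(self, "cleavage_residues", frozenset(self.cleavage_residues))

    @property
    def rule(self) -> str:
        """Regular expression locating the residue after which cleavage occurs."""
        cls = "[" + "".join(sorted(self.cleavage_residues)) + "]"
        return cls + "(?=[^P])" if self.proline_rule else cls


@dataclass(frozen=True)
class OverlapReport:
    """Tryptic-peptide bookkeeping between sample and entrapment databases.

    ``shared_pct`` is asymmetric by design: the denominator is the sample
    side, because the quantity of interest is how much of the sample's
    searchable peptide space the entrapment sequences shadow.
    """

    n_sample_peptides: int
    n_trap_peptides: int
    n_shared: int

    def __post_init__(self) -> None:
        if self.n_shared > min(self.n_sample_peptides, self.n_trap_peptides):
            raise ValueError("n_shared exceeds one of the per-side peptide counts")

    @property
    def shared_ratio(self) -> float:
        """Raw fraction n_shared / n_sample_peptides."""
        if self.n_sample_peptides == 0:
            return 0.0
        return self.n_shared / self.n_sample_peptides

    @property
    def shared_pct(self) -> float:
        """Shared/sample percentage, rounded to 3 decimals for reporting."""
        return round(100.0 * self.shared_ratio, 3)


def digest(residues: str, config: DigestConfig | None = None) -> set[str]:
    """Return all distinct peptides from an in-silico enzymatic digest.

    Cleavage occurs after every residue in ``config.cleavage_residues``
    (suppressed before proline when ``proline_rule`` is set), with up to
    ``config.max_missed`` retained internal sites; peptides shorter than
    ``config.min_length`` are dropped.
    """
    if not residues:
        raise DatabaseError("cannot digest an empty sequence")
    config = config or DigestConfig()
    return _pyt_parser.cleave(
        residues.upper(),
        config.rule,
        missed_cleavages=config.max_missed,
        min_length=config.min_length,
    )


def digest_database(entries: Iterable[SequenceEntry], config: DigestConfig | None = None) -> set[str]:
    """Union of digest peptides over a list of entries."""
    config = config or DigestConfig()
    peptides: set[str] = set()
    for entry in entries:
        peptides |= digest(entry.residues, config)
    return peptides


def build_entrapment_db(
    entries: Sequence[SequenceEntry],
    n_copies: int,
    seed: int,
    suffix_template: str = "{accession}_shuf{copy}",
) -> list[SequenceEntry]:
    """Expand an entrapment set to ``n_copies`` times its size.

    Copy 1 is the original entries unchanged.  Each further copy shuffles
    the residues of every sequence independently (length and residue
    multiset preserved) and suffixes the accession with the copy index, so
    an input of 20,825 sequences with ``n_copies=10`` yields 208,250
    distinct entries.  Deterministic for a fixed seed.
    """
    if n_copies < 1:
        raise ValueError("n_copies must be >= 1")
    for entry in entries:
        if entry.origin != ORIGIN_ENTRAPMENT:
            raise DatabaseError(
                f"entry {entry.accession!r} has origin {entry.origin!r}; "
                "entrapment expansion applies to entrapment entries only"
            )
    rng = np.random.default_rng(seed)
    out: list[SequenceEntry] = list(entries)
    for copy_idx in range(2, n_copies + 1):
        for entry in entries:
            arr = np.frombuffer(entry.residues.encode("ascii"), dtype=np.uint8)
            shuffled = rng.permutation(arr).tobytes().decode("ascii")
            out.append(
                SequenceEntry(
                    accession=suffix_template.format(accession=entry.accession, copy=copy_idx),
                    residues=shuffled,
                    origin=ORIGIN_ENTRAPMENT,
                )
            )
    return out


def reverse_decoys(
    entries: Iterable[SequenceEntry], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[SequenceEntry]:
    """One reversed decoy per target entry; origin preserved, prefix added."""
    decoys = []
    for entry in entries:
        if entry.is_decoy:
            raise DatabaseError(f"entry {entry.accession!r} is already a decoy")
        decoys.append(
            SequenceEntry(
                accession=decoy_prefix + entry.accession,
                residues=entry.residues[::-1],
                origin=entry.origin,
                is_decoy=True,
            )
        )
    return decoys


@dataclass(slots=True)
class SearchDatabase:
    """A concatenated search database plus its accession index.

    ``index`` maps every accession to ``(origin, is_decoy)`` so that PSM
    labeling is a pure lookup.
    """

    entries: list[SequenceEntry]
    index: dict[str, tuple[str, bool]] = field(default_factory=dict)

    def lookup(self, accession: str) -> tuple[str, bool]:
        try:
            return self.index[accession]
        except KeyError:
            raise KeyError(f"accession {accession!r} not in database index") from None


def build_search_db(
    sample: Sequence[SequenceEntry],
    entrapment: Sequence[SequenceEntry],
    with_decoys: bool = True,
    trap_prefix: str = DEFAULT_TRAP_PREFIX,
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
) -> SearchDatabase:
    """Concatenate sample + entrapment targets and optionally their decoys.

    Entrapment accessions receive ``trap_prefix`` so that origin is
    recoverable from the accession alone; decoys receive ``decoy_prefix``.
    Raises on duplicate accessions after prefixing.
    """
    for entry in sample:
        if entry.origin != ORIGIN_SAMPLE or entry.is_decoy:
            raise DatabaseError(f"sample-side entry {entry.accession!r} is not a plain sample target")
    for entry in entrapment:
        if entry.origin != ORIGIN_ENTRAPMENT or entry.is_decoy:
            raise DatabaseError(
                f"entrapment-side entry {entry.accession!r} is not a plain entrapment target"
            )

    targets = list(sample) + [
        SequenceEntry(
            accession=trap_prefix + entry.accession,
            residues=entry.residues,
            origin=ORIGIN_ENTRAPMENT,
        )
        for entry in entrapment
    ]
    entries = list(targets)
    if with_decoys:
        entries += reverse_decoys(targets, decoy_prefix=decoy_prefix)

    index: dict[str, tuple[str, bool]] = {}
    for entry in entries:
        if entry.accession in index:
            raise DatabaseError(f"duplicate accession after prefixing: {entry.accession!r}")
        index[entry.accession] = (entry.origin, entry.is_decoy)
    return SearchDatabase(entries=entries, index=index)


def overlap_report(
    sample: Sequence[SequenceEntry],
    entrapment: Sequence[SequenceEntry],
    config: DigestConfig | None = None,
) -> OverlapReport:
    """Digest both sides and report distinct-peptide counts and overlap."""
    if not sample or not entrapment:
        raise DatabaseError("overlap_report requires non-empty databases on both sides")
    for entry in list(sample) + list(entrapment):
        if entry.is_decoy:
            raise DatabaseError("overlap_report operates on target entries only")
    config = config or DigestConfig()
    sample_peps = digest_database(sample, config)
    trap_peps = digest_database(entrapment, config)
    return OverlapReport(
        n_sample_peptides=len(sample_peps),
        n_trap_peptides=len(trap_peps),
        n_shared=len(sample_peps & trap_peps),
    )


_ACCESSION_RE = re.compile(r"^\S+")


def read_fasta(path, origin: str) -> list[SequenceEntry]:
    """Read a FASTA file into entries carrying the given origin label.

    The accession is the first whitespace-delimited token of the header;
    the rest of the description is ignored.
    """
    entries = []
    for record in SeqIO.parse(str(path), "fasta"):
        entries.append(SequenceEntry(accession=record.id, residues=str(record.seq), origin=origin))
    if not entries:
        raise DatabaseError(f"no FASTA records found in {path}")
    return entries


def write_fasta(entries: Iterable[SequenceEntry], path) -> None:
    """Write entries as FASTA, sequence lines wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(entry.residues), id=entry.accession, description="")
        for entry in entries
    ]
    SeqIO.write(records, str(path), "fasta")
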