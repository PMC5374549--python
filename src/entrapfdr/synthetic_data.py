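"""Synthetic databases and multi-engine PSM lists with known ground truth.

The generator emulates the structure a concatenated target-decoy search
with entrapment sequences assumes, so that the FDR and FMR estimators can
be validated against a realized truth:

* random protein sequences over the 20-letter alphabet form the sample
  and the (roughly ten times larger) entrapment database; decoys are their
  reversals, so target and decoy search spaces are the same size;
* each spectrum either has a correct match available (probability
  ``pi_correct``) or only random matches; correct matches score from a
  high bell curve and map to a sample protein, random matches score from a
  low one and hit the decoy half of the space with probability 1/2,
  otherwise sample vs. entrapment in proportion to their tryptic-peptide
  content — the regime in which decoy counts estimate false target
  matches and the entrapment fraction of false matches approaches the
  entrapment peptide share;
* several engines observe the same spectra: a correct match is detected
  independently per engine with ``p_detect_correct`` and shares a
  per-spectrum latent score shift, so engine agreement is informative;
  random matches are drawn independently per engine and therefore almost
  never agree.

Scores are bell curves by construction and make no claim of resembling
any real engine's score; what matters for validation is the two-component
mixture and the proportional allocation of random matches.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .db_builder import (
    DigestConfig,
    ORIGIN_ENTRAPMENT,
    ORIGIN_SAMPLE,
    SearchDatabase,
    SequenceEntry,
    build_search_db,
    digest,
)
from .fdr_engine import FORMULA_SEPARATE, ThresholdResult, filter_at_fdr
from .psm_model import (
    LABEL_DECOY,
    LABEL_ENTRAPMENT,
    LABEL_SAMPLE,
    PSMRecord,
    label_psms,
)

ALPHABET = np.frombuffer(b"ACDEFGHIKLMNPQRSTVWY", dtype=np.uint8)

CLASS_CORRECT = "correct-sample"
CLASS_RANDOM_SAMPLE = "random-sample"
CLASS_RANDOM_TRAP = "random-entrapment"
CLASS_RANDOM_DECOY = "random-decoy"

_CLASS_TO_LABEL = {
    CLASS_CORRECT: LABEL_SAMPLE,
    CLASS_RANDOM_SAMPLE: LABEL_SAMPLE,
    CLASS_RANDOM_TRAP: LABEL_ENTRAPMENT,
    CLASS_RANDOM_DECOY: LABEL_DECOY,
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulator.

    The sample:entrapment protein ratio defaults to 1:10, mirroring the
    benchmark-database construction this package targets.  Score
    distributions are unit-variance bell curves three location units
    apart; ``latent_sd`` controls how strongly engines agree on correct
    matches.
    """

    n_sample_proteins: int = 200
    n_trap_proteins: int = 2000
    protein_length_mean: float = 300.0
    protein_length_sd: float = 80.0
    protein_length_min: int = 50
    n_spectra: int = 20_000
    pi_correct: float = 0.5
    mu_correct: float = 3.0
    sigma_correct: float = 1.0
    mu_incorrect: float = 0.0
    sigma_incorrect: float = 1.0
    latent_sd: float = 1.0
    engine_count: int = 5
    p_detect_correct: float = 0.9
    p_detect_incorrect: float = 0.8
    seed: int = 0
    digest_config: DigestConfig = field(default_factory=DigestConfig)

    def __post_init__(self) -> None:
        for name in ("pi_correct", "p_detect_correct", "p_detect_incorrect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mu_correct <= self.mu_incorrect:
            raise ValueError("mu_correct must exceed mu_incorrect (separability)")
        if min(self.n_sample_proteins, self.n_trap_proteins, self.n_spectra) < 1:
            raise ValueError("counts must be >= 1")
        if self.engine_count < 1:
            raise ValueError("engine_count must be >= 1")


@dataclass
class SimTruth:
    """Ground truth for one simulated run.

    ``correct`` is keyed by (spectrum_id, peptide) — correctness of a pair
    is engine-independent; ``sim_class`` is keyed by (engine_id,
    spectrum_id), at most one record per engine per spectrum.
    """

    correct: dict[tuple[str, str], bool]
    sim_class: dict[tuple[str, str], str]


@dataclass
class RealizedMetrics:
    """Realized error of an accepted set against simulation truth."""

    n_accepted: int
    fdp: float
    trap_fraction: float
    est_fdr: float
    est_fmr: float


@dataclass
class SimResult:
    """Everything one simulated experiment produced."""

    records: list[PSMRecord]
    truth: SimTruth
    search_db: SearchDatabase
    trap_peptide_share: float
    engine_ids: tuple[str, ...]

    def by_engine(self) -> list[tuple[str, list[PSMRecord]]]:
        out = {e: [] for e in self.engine_ids}
        for rec in self.records:
            out[rec.engine_id].append(rec)
        return list(out.items())


def _random_proteins(
    rng: np.random.Generator, n: int, config: SimConfig, prefix: str, origin: str
) -> list[SequenceEntry]:
    lengths = np.maximum(
        rng.normal(config.protein_length_mean, config.protein_length_sd, n).astype(int),
        config.protein_length_min,
    )
    entries = []
    for i, length in enumerate(lengths):
        seq = ALPHABET[rng.integers(0, len(ALPHABET), int(length))].tobytes().decode("ascii")
        entries.append(SequenceEntry(accession=f"{prefix}{i:05d}", residues=seq, origin=origin))
    return entries


def simulate_database(
    config: SimConfig, seed: int | None = None
) -> tuple[list[SequenceEntry], list[SequenceEntry]]:
    """Random sample and entrapment protein sets; deterministic per seed."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sample = _random_proteins(rng, config.n_sample_proteins, config, "SP", ORIGIN_SAMPLE)
    trap = _random_proteins(rng, config.n_trap_proteins, config, "EP", ORIGIN_ENTRAPMENT)
    return sample, trap


def _peptide_pool(
    entries: Sequence[SequenceEntry], config: DigestConfig
) -> tuple[list[str], list[str]]:
    """Parallel (peptide, accession) lists over all entries' digests."""
    peps: list[str] = []
    accs: list[str] = []
    for entry in entries:
        for pep in digest(entry.residues, config):
            peps.append(pep)
            accs.append(entry.accession)
    return peps, accs


def simulate_psms(
    config: SimConfig,
    db: tuple[list[SequenceEntry], list[SequenceEntry]],
    seed: int | None = None,
) -> SimResult:
    """Simulate multi-engine PSM lists against a (sample, entrapment) database.

    Per spectrum and engine at most one record is emitted.  Correct
    matches carry the spectrum's fixed true sample peptide; incorrect ones
    draw a random peptide from the decoy pool with probability 1/2, else
    from the pooled target peptides (sample and entrapment in proportion
    to their content).  Scores are ``mu + latent + noise`` for correct and
    ``mu + noise`` for incorrect matches, already higher-is-better.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sample, trap = db
    search_db = build_search_db(sample, trap, with_decoys=True)

    targets = [e for e in search_db.entries if not e.is_decoy]
    decoys = [e for e in search_db.entries if e.is_decoy]
    sample_targets = [e for e in targets if e.origin == ORIGIN_SAMPLE]
    target_peps, target_accs = _peptide_pool(targets, config.digest_config)
    decoy_peps, decoy_accs = _peptide_pool(decoys, config.digest_config)
    sample_peps, sample_accs = _peptide_pool(sample_targets, config.digest_config)
    target_origin = np.array(
        [search_db.index[acc][0] == ORIGIN_ENTRAPMENT for acc in target_accs], dtype=bool
    )
    trap_share = float(target_origin.mean())

    n, E = config.n_spectra, config.engine_count
    correct_class = rng.random(n) < config.pi_correct
    latent = rng.normal(0.0, config.latent_sd, n)
    true_idx = rng.integers(0, len(sample_peps), n)

    detect_c = rng.random((E, n)) < config.p_detect_correct
    emit_correct = detect_c & correct_class[None, :]
    detect_i = rng.random((E, n)) < config.p_detect_incorrect
    emit_incorrect = ~emit_correct & detect_i
    to_decoy = rng.random((E, n)) < 0.5
    rand_t_idx = rng.integers(0, len(target_peps), (E, n))
    rand_d_idx = rng.integers(0, len(decoy_peps), (E, n))
    score_c = config.mu_correct + latent[None, :] + rng.normal(0.0, config.sigma_correct, (E, n))
    score_i = config.mu_incorrect + rng.normal(0.0, config.sigma_incorrect, (E, n))

    spectrum_ids = [f"sp{i:06d}" for i in range(n)]
    engine_ids = tuple(f"engine{e + 1}" for e in range(E))
    records: list[PSMRecord] = []
    correct_map: dict[tuple[str, str], bool] = {}
    class_map: dict[tuple[str, str], str] = {}

    for e in range(E):
        eng = engine_ids[e]
        for i in np.nonzero(emit_correct[e])[0]:
            pep, acc = sample_peps[true_idx[i]], sample_accs[true_idx[i]]
            records.append(
                PSMRecord(
                    spectrum_id=spectrum_ids[i],
                    engine_id=eng,
                    peptide=pep,
                    accessions=(acc,),
                    score=float(score_c[e, i]),
                    label=LABEL_SAMPLE,
                    truth=True,
                )
            )
            correct_map[(spectrum_ids[i], pep)] = True
            class_map[(eng, spectrum_ids[i])] = CLASS_CORRECT
        for i in np.nonzero(emit_incorrect[e])[0]:
            if to_decoy[e, i]:
                pep, acc = decoy_peps[rand_d_idx[e, i]], decoy_accs[rand_d_idx[e, i]]
                cls = CLASS_RANDOM_DECOY
            else:
                j = rand_t_idx[e, i]
                pep, acc = target_peps[j], target_accs[j]
                cls = CLASS_RANDOM_TRAP if target_origin[j] else CLASS_RANDOM_SAMPLE
            records.append(
                PSMRecord(
                    spectrum_id=spectrum_ids[i],
                    engine_id=eng,
                    peptide=pep,
                    accessions=(acc,),
                    score=float(score_i[e, i]),
                    label=_CLASS_TO_LABEL[cls],
                    truth=False,
                )
            )
            correct_map.setdefault((spectrum_ids[i], pep), False)
            class_map[(eng, spectrum_ids[i])] = cls

    return SimResult(
        records=records,
        truth=SimTruth(correct=correct_map, sim_class=class_map),
        search_db=search_db,
        trap_peptide_share=trap_share,
        engine_ids=engine_ids,
    )


def per_engine_results(
    sim: SimResult, alpha: float, formula: str = FORMULA_SEPARATE
) -> list[tuple[str, ThresholdResult]]:
    """Run the standard q-value filter independently on each engine's list."""
    return [
        (engine_id, filter_at_fdr(records, alpha, formula=formula))
        for engine_id, records in sim.by_engine()
    ]


def evaluate_truth(result: ThresholdResult, truth: SimTruth) -> RealizedMetrics:
    """Realized false-discovery proportion and entrapment fraction.

    Every accepted record must have a truth entry; the realized FDP is the
    fraction of accepted targets whose (spectrum, peptide) pair is not a
    correct match.
    """
    n = len(result.accepted)
    if n == 0:
        return RealizedMetrics(0, 0.0, 0.0, result.fdr, result.fmr)
    n_false = 0
    n_trap = 0
    for rec in result.accepted:
        key = (rec.spectrum_id, rec.peptide)
        if key not in truth.correct:
            raise KeyError(f"no ground truth for accepted record {key}")
        if not truth.correct[key]:
            n_false += 1
        if rec.label == LABEL_ENTRAPMENT:
            n_trap += 1
    return RealizedMetrics(
        n_accepted=n,
        fdp=n_false / n,
        trap_fraction=n_trap / n,
        est_fdr=result.fdr,
        est_fmr=result.fmr,
    )
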