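"""Stepwise lncRNA identification.

Candidate long non-coding RNAs are what survives an ordered cascade of
filters: a minimum transcript length (> 200 nt), a maximum length of the
longest open reading frame (<= 300 nt, start codon through stop codon),
a series of pluggable external-evidence predicates (protein homology,
Pfam motifs, coding-potential scores, known ncRNA families — supplied as
id blacklists, since the underlying tools run outside this package), and
finally an expression-noise filter that removes transcripts with FPKM
below a cutoff in all but at most one sample.

Each stage emits a :class:`FilterReport` so survivor counts can be audited;
counts are conserved across the cascade by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .core_io import ExpressionMatrix, FilterConfig, revcomp

logger = logging.getLogger("hypolnc")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class TranscriptRecord:
    """One assembled transcript with sequence-derived features."""

    id: str
    sequence: str
    label: str = "unassigned"  # unassigned | mRNA | lncRNA | removed
    removal_stage: str | None = None
    _orf: tuple[int, int, int, str] | None = field(default=None, repr=False)

    @property
    def length_nt(self) -> int:
        return len(self.sequence)

    @property
    def gc_content(self) -> float:
        from .seq_features import gc_content

        return gc_content(self.sequence)

    @property
    def longest_orf_nt(self) -> int:
        return self.orf()[0]

    def orf(self) -> tuple[int, int, int, str]:
        if self._orf is None:
            self._orf = longest_orf(self.sequence)
        return self._orf


@dataclass
class FilterReport:
    stage_name: str
    n_in: int
    n_out: int
    removed_ids: list[str]

    def __post_init__(self) -> None:
        assert self.n_out == self.n_in - len(self.removed_ids)


def longest_orf(sequence: str, strands: str = "both") -> tuple[int, int, int, str]:
    """Longest open reading frame in a nucleotide sequence.

    An ORF is ATG ... {TAA, TAG, TGA} in a single frame with no internal
    stop; the reported length counts both the start and the stop codon.
    Codons containing N never act as start or stop. Returns
    ``(orf_length_nt, start, frame, strand)`` with ``start`` 0-based on the
    reported strand (``+`` forward, ``-`` reverse complement); all zeros
    with ``strand='+'`` if no ORF exists. Ties break toward the smaller
    start, then the forward strand, then the lower frame.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"unknown strands option {strands!r}")
    candidates: list[tuple[int, int, int, int, str]] = []  # (-len, start, srank, frame, strand)
    variants = [("+", sequence)]
    if strands == "both":
        variants.append(("-", revcomp(sequence)))
    for srank, (strand, seq) in enumerate(variants):
        n = len(seq)
        for frame in range(3):
            open_start = -1  # earliest unclosed ATG in this frame
            for i in range(frame, n - 2, 3):
                codon = seq[i:i + 3]
                if codon == "ATG" and open_start < 0:
                    open_start = i
                elif codon in STOP_CODONS and open_start >= 0:
                    candidates.append(
                        (-(i + 3 - open_start), open_start, srank, frame, strand))
                    open_start = -1
    if not candidates:
        return (0, 0, 0, "+")
    neg_len, start, _, frame, strand = min(candidates)
    return (-neg_len, start, frame, strand)


def make_blacklist_predicate(name: str, id_blacklist: set[str] | Sequence[str]) -> Callable:
    """Adapter turning an external tool's hit list into a pipeline stage.

    The returned predicate keeps a transcript (returns True) unless its id
    is blacklisted — i.e. unless the external tool flagged it as having
    protein homology, a Pfam motif, coding potential, or a known ncRNA
    family, depending on the stage.
    """
    blacklist = frozenset(id_blacklist)

    def predicate(record: TranscriptRecord) -> bool:
        return record.id not in blacklist

    predicate.__name__ = name
    return predicate


def _expression_keep(record_id: str, fpkm: ExpressionMatrix,
                     config: FilterConfig) -> bool:
    if record_id not in fpkm.values.index:
        return False
    row = fpkm.values.loc[record_id]
    return int((row >= config.fpkm_min).sum()) >= config.min_expressed_samples


def run_identification(
    transcripts: Sequence[TranscriptRecord],
    fpkm: ExpressionMatrix | None,
    config: FilterConfig | None = None,
    predicates: Sequence[Callable] | None = None,
    mrna_ids: Sequence[str] | None = None,
) -> tuple[list[TranscriptRecord], list[TranscriptRecord], list[FilterReport]]:
    """Run the full identification cascade.

    Stage order: length, orf, each named predicate in the given order,
    then the expression-noise filter (skipped if ``fpkm`` is None).
    ``mrna_ids`` is the externally supplied list of transcripts with
    protein homology plus functional annotation; those become the mRNA
    set regardless of the lncRNA cascade. Returns
    ``(lncRNA records, mRNA records, reports)``.
    """
    config = config or FilterConfig()
    predicates = list(predicates or [])
    mrna_idset = set(mrna_ids or [])

    survivors = list(transcripts)
    reports: list[FilterReport] = []

    def apply_stage(stage_name: str, keep: Callable[[TranscriptRecord], bool]) -> None:
        nonlocal survivors
        kept, removed = [], []
        for rec in survivors:
            try:
                ok = keep(rec)
            except Exception as exc:  # a failing predicate aborts with its stage
                raise RuntimeError(f"predicate failed at stage {stage_name!r}: {exc}") from exc
            if ok:
                kept.append(rec)
            else:
                rec.label = "removed"
                rec.removal_stage = stage_name
                removed.append(rec.id)
        reports.append(FilterReport(stage_name, len(survivors), len(kept), removed))
        logger.info("stage %-12s in=%d out=%d removed=%d",
                    stage_name, len(survivors), len(kept), len(removed))
        survivors = kept

    apply_stage("length", lambda r: r.length_nt > config.min_len_nt)
    apply_stage("orf", lambda r: r.longest_orf_nt <= config.max_orf_nt)
    for pred in predicates:
        apply_stage(getattr(pred, "__name__", "predicate"), pred)
    if fpkm is not None:
        apply_stage("expression", lambda r: _expression_keep(r.id, fpkm, config))

    for rec in survivors:
        rec.label = "lncRNA"
    mrnas = []
    for rec in transcripts:
        if rec.id in mrna_idset and rec.label != "lncRNA":
            rec.label = "mRNA"
            mrnas.append(rec)
    return survivors, mrnas, reports
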