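"""miRNA target and target-mimic prediction on transcripts.

A miRNA can bind a transcript in two mechanistically different ways:

* **target** — near-perfect pairing across the central region (miRNA
  positions 9-12 from the 5' end) permits cleavage. Rule: at most one
  mismatch or indel in positions 9-12, at most 4 nt of mismatches or
  bulges elsewhere, and no two consecutive mismatches anywhere.
* **target mimic** (sponge / decoy) — the duplex bulges in the central
  region so the miRNA is sequestered without cleavage. Rule: 2-5 nt of
  mismatches or indels in positions 9-12, perfect pairing in the seed
  (positions 2-8), and at most 4 nt of mismatches and indels elsewhere.

G-U wobble pairs count as pairing, never as mismatches. Sites are found
by windowed global alignment of the reverse complement of the miRNA
against the transcript (unit cost per mismatch or bulged base; window
length within +-4 of the miRNA length), then classified per alignment.

Only miRNAs conserved across species (identical mature sequence in at
least two species) enter prediction, mirroring the usual confidence
filter applied to miRBase collections.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import revcomp

logger = logging.getLogger("hypolnc")

WC = "WC"
GU = "GU"
MISMATCH = "MISMATCH"
MIRNA_BULGE = "MIRNA_BULGE"
TARGET_BULGE = "TARGET_BULGE"

TARGET, MIMIC, NONE = "TARGET", "MIMIC", "NONE"

CENTRAL = (9, 12)   # closed interval of miRNA positions, 1-based from 5' end
SEED = (2, 8)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: cap on co-optimal tracebacks enumerated per alignment window; duplexes
#: near the rule boundaries have few co-optimal paths, so the cap only
#: truncates enumeration for high-cost junk alignments
MAX_COOPTIMAL = 24

WINDOW_SLOP = 4  # window length may deviate from the miRNA length by this


@dataclass
class MiRNARecord:
    """One mature miRNA; ``species`` is the set of species carrying it."""

    id: str
    sequence: str  # internal DNA alphabet
    species: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"miRNA {self.id!r} has empty sequence")
        self.sequence = self.sequence.upper().replace("U", "T")
        self.species = frozenset(self.species)
        if not 18 <= len(self.sequence) <= 26:
            warnings.warn(
                f"miRNA {self.id!r} length {len(self.sequence)} outside 18-26 nt")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DuplexAlignment:
    """One aligned miRNA:transcript site.

    ``columns`` is ordered by miRNA position ascending (5' to 3'); each
    column is ``(mirna_pos, status)`` with ``mirna_pos`` None for a bulged
    transcript base (TARGET_BULGE). ``bases`` carries the aligned
    (mirna_char, transcript_char) pairs ('-' on the gapped side) for
    rendering. ``site_start``/``site_end`` are 0-based half-open on the
    transcript.
    """

    mirna_id: str
    transcript_id: str
    site_start: int
    site_end: int
    columns: tuple
    bases: tuple = ()
    mfe_kcal: float | None = None

    @property
    def n_edits(self) -> int:
        return sum(1 for _, status in self.columns
                   if status in (MISMATCH, MIRNA_BULGE, TARGET_BULGE))

    def alignment_string(self) -> str:
        """Three-row text: miRNA 5'->3', pairing row, transcript 3'->5'."""
        top, mid, bot = [], [], []
        for (pos, status), (mb, tb) in zip(self.columns, self.bases):
            top.append(mb)
            bot.append(tb)
            mid.append({WC: "|", GU: "o"}.get(status, " "))
        return (f"miRNA      5' {''.join(top)} 3'\n"
                f"              {''.join(mid)}\n"
                f"transcript 3' {''.join(bot)} 5'")


@dataclass(frozen=True)
class Diagnostics:
    central_edits: int
    seed_perfect: bool
    other_edits: int
    has_adjacent_mismatches: bool


@dataclass(frozen=True)
class InteractionCall:
    duplex: DuplexAlignment
    role: str
    diagnostics: Diagnostics


def conserved_mirnas(records: Iterable[MiRNARecord]) -> list[MiRNARecord]:
    """Collapse records by sequence; keep sequences seen in >= 2 species.

    Species sets of identical sequences are merged; the kept id is the
    lexicographically smallest contributing id.
    """
    by_seq: dict[str, list[MiRNARecord]] = {}
    for rec in records:
        by_seq.setdefault(rec.sequence, []).append(rec)
    out = []
    for seq, recs in by_seq.items():
        species = frozenset().union(*(r.species for r in recs))
        if len(species) >= 2:
            out.append(MiRNARecord(min(r.id for r in recs), seq, species))
    out.sort(key=lambda r: r.id)
    return out


def _pair_status(mirna_base: str, transcript_base: str) -> str:
    if transcript_base == _COMP[mirna_base] and mirna_base != "N":
        return WC
    if (mirna_base == "G" and transcript_base == "T") or (
            mirna_base == "T" and transcript_base == "G"):
        return GU
    return MISMATCH


def _match_matrix(query: str, target_codes: np.ndarray) -> np.ndarray:
    """match[k, j]: does query char k (revcomp-miRNA space) pair with
    transcript base j (WC or GU wobble)?"""
    # query char c pairs target t iff t == c (WC) or (c=='C', t=='T') or
    # (c=='A', t=='G'); never for N
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    allowed = {
        "A": (0, 2),  # miRNA U : transcript A (WC) or G (wobble)
        "C": (1, 3),  # miRNA G : transcript C (WC) or U (wobble)
        "G": (2,),
        "T": (3,),
        "N": (),
    }
    out = np.zeros((len(query), len(target_codes)), dtype=bool)
    for k, ch in enumerate(query):
        for a in allowed[ch]:
            out[k] |= target_codes == a
    return out


def _candidate_ends(match: np.ndarray, max_edits: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized semi-global DP (free transcript flanks) returning all
    transcript end positions whose best full-query alignment costs
    <= max_edits, with those best costs. A superset of the
    window-constrained hits."""
    q, L = match.shape
    idx = np.arange(L + 1)
    prev = np.zeros(L + 1)
    for i in range(1, q + 1):
        sub = np.where(match[i - 1], 0.0, 1.0)
        vert = np.minimum(prev[:-1] + sub, prev[1:] + 1)
        full = np.concatenate(([float(i)], vert))
        prev = np.minimum.accumulate(full - idx) + idx
    hits = np.nonzero(prev <= max_edits)[0]
    return hits, prev[hits]


def _enumerate_paths(G: list, match_fn, w: int, q: int,
                     cap: int = MAX_COOPTIMAL) -> list[list[str]]:
    """Enumerate co-optimal global alignment paths from G[q][w] back to
    G[0][0], depth-first in a fixed move order (diagonal, query gap,
    target gap). Each path is a list of moves ('D','U','L') read forward."""
    paths: list[list[str]] = []
    stack: list[tuple[int, int, list]] = [(q, w, [])]
    while stack and len(paths) < cap:
        i, j, acc = stack.pop()
        if i == 0 and j == 0:
            paths.append(acc[::-1])
            continue
        here = G[i][j]
        # pushed in reverse so exploration order is D, U, L
        if j > 0 and G[i][j - 1] + 1 == here:
            stack.append((i, j - 1, acc + ["L"]))
        if i > 0 and G[i - 1][j] + 1 == here:
            stack.append((i - 1, j, acc + ["U"]))
        if i > 0 and j > 0 and G[i - 1][j - 1] + (0 if match_fn(i - 1, j - 1) else 1) == here:
            stack.append((i - 1, j - 1, acc + ["D"]))
    return paths


#: an alignment with more than this many edits cannot satisfy the target
#: rule (1 central + 4 other); with an imperfect seed it cannot satisfy
#: the mimic rule either, so such alignments are hopeless junk
TARGET_MAX_TOTAL = 5


def _seed_block_possible(match: np.ndarray, q: int) -> np.ndarray:
    """seed_ok[t]: can miRNA positions 8..2 pair contiguously (WC/GU,
    ungapped) with transcript bases t..t+6?"""
    L = match.shape[1]
    if q < 9 or L < 7:
        return np.ones(max(L - 6, 0), dtype=bool)  # too short to prune on
    ok = match[q - 8, : L - 6].copy()
    for off, p in enumerate(range(7, 1, -1), start=1):
        ok &= match[q - p, off: L - 6 + off]
    return ok


def scan_duplexes(mirna: MiRNARecord, transcript_id: str, sequence: str,
                  max_edits: int = 9, exhaustive: bool = False) -> list[DuplexAlignment]:
    """Find duplex sites of one miRNA on one transcript.

    For every transcript window of length len(miRNA) +- 4, the reverse
    complement of the miRNA is globally aligned to the window (unit cost
    per mismatch and per bulged base; Watson-Crick and G-U columns cost
    0). Windows whose optimal cost is <= ``max_edits`` emit their
    co-optimal alignments; flanking bulged transcript bases are trimmed
    and alignments with identical trimmed column sets are deduplicated.

    By default, alignments that provably cannot bear a target or mimic
    role are suppressed: any alignment with more than ``TARGET_MAX_TOTAL``
    edits fails the target rule outright, and fails the mimic rule too
    unless its seed (miRNA positions 2-8) is perfectly paired — so
    high-cost windows are only examined where an ungapped seed block
    pairs, and their alignments kept only if they classify as mimics.
    ``exhaustive=True`` disables the pruning and emits every co-optimal
    alignment of every qualifying window.
    """
    m = mirna.sequence
    q = len(m)
    L = len(sequence)
    if L < q - WINDOW_SLOP:
        return []
    r = revcomp(m)
    code = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
    tcodes = np.fromiter((code[c] for c in sequence), dtype=np.int8, count=L)
    match = _match_matrix(r, tcodes)
    ends, end_costs = _candidate_ends(match, max_edits)
    if not exhaustive:
        seed_ok = _seed_block_possible(match, q)
        seed_cum = np.concatenate(([0], np.cumsum(seed_ok)))

        def seed_possible(end: int) -> bool:
            # the whole seed block must lie inside the window span
            lo = max(end - (q + WINDOW_SLOP), 0)
            hi = max(end - 7, lo)
            return seed_cum[min(hi + 1, len(seed_cum) - 1)] > seed_cum[lo]

    results: dict[tuple, DuplexAlignment] = {}
    seen_cores: set = set()
    for e, end_cost in zip(ends, end_costs):
        e = int(e)
        if e == 0:
            continue
        if not exhaustive and end_cost > TARGET_MAX_TOTAL and not seed_possible(e):
            continue
        w_max = min(q + WINDOW_SLOP, e)
        # mrev[i][j]: does miRNA position i+1 pair with transcript base
        # e-1-j (WC or wobble)?
        mrev = match[::-1, e - w_max:e][:, ::-1].tolist()

        def mfn(i: int, j: int) -> bool:
            return mrev[i][j]

        G = [[0] * (w_max + 1) for _ in range(q + 1)]
        for j in range(w_max + 1):
            G[0][j] = j
        for i in range(1, q + 1):
            Gi, Gp, mi = G[i], G[i - 1], mrev[i - 1]
            Gi[0] = i
            for j in range(1, w_max + 1):
                best = Gp[j - 1] + (0 if mi[j - 1] else 1)
                up = Gp[j] + 1
                if up < best:
                    best = up
                left = Gi[j - 1] + 1
                if left < best:
                    best = left
                Gi[j] = best
        for w in range(max(1, q - WINDOW_SLOP), w_max + 1):
            cost = G[q][w]
            if cost > max_edits:
                continue
            prune_window = not exhaustive and cost > TARGET_MAX_TOTAL
            if prune_window and not seed_possible(e):
                continue
            for path in _enumerate_paths(G, mfn, w, q):
                # strip flanking bulged transcript bases on the move string
                lead = 0
                while lead < len(path) and path[lead] == "L":
                    lead += 1
                trail = 0
                while trail < len(path) - lead and path[-1 - trail] == "L":
                    trail += 1
                core = path[lead:len(path) - trail] if (lead or trail) else path
                if not core:
                    continue
                seen_key = (e - lead, tuple(core))
                if seen_key in seen_cores:
                    continue
                seen_cores.add(seen_key)
                trimmed_cost = cost - lead - trail
                if trimmed_cost > max_edits:
                    continue
                if prune_window and trimmed_cost > TARGET_MAX_TOTAL and \
                        not _quick_mimic_check(core, mrev, lead):
                    continue
                dup = _path_to_duplex(core, mirna, transcript_id, sequence,
                                      e - lead, w - lead - trail, max_edits)
                if dup is None:
                    continue
                key = (dup.site_start, dup.columns)
                results.setdefault(key, dup)
    return sorted(results.values(), key=lambda d: (d.site_start, d.site_end))


def _quick_mimic_check(core, mrev, lead) -> bool:
    """Decide from the move string alone whether an alignment with more
    than TARGET_MAX_TOTAL edits can classify as a mimic (perfect seed,
    2-5 central edits, <= 4 elsewhere), without building the duplex."""
    i = 0  # miRNA positions consumed
    j = lead  # offset into the reversed window
    central = other = 0
    seed_ok = True
    for move in core:
        if move == "D":
            if not mrev[i][j]:
                pos = i + 1
                if 9 <= pos <= 12:
                    central += 1
                else:
                    other += 1
                if 2 <= pos <= 8:
                    seed_ok = False
            i += 1
            j += 1
        elif move == "U":
            pos = i + 1
            if 9 <= pos <= 12:
                central += 1
            else:
                other += 1
            if 2 <= pos <= 8:
                seed_ok = False
            i += 1
        else:  # bulged transcript base between miRNA positions i and i+1
            if 9 <= i <= 11:
                central += 1
            else:
                other += 1
            if 2 <= i <= 7:
                seed_ok = False
            j += 1
        if not seed_ok or other > 4 or central > 5:
            return False
    return 2 <= central <= 5


def _path_to_duplex(path, mirna: MiRNARecord, transcript_id: str,
                    sequence: str, e: int, w: int,
                    max_edits: int) -> DuplexAlignment | None:
    """Convert a traceback path (ascending miRNA position) into a trimmed
    DuplexAlignment, or None if trimming empties it."""
    m = mirna.sequence
    cols: list[tuple] = []
    bases: list[tuple] = []
    i = 0  # miRNA positions consumed
    j = 0  # transcript bases consumed (descending from e-1)
    for move in path:
        if move == "D":
            mb, tb = m[i], sequence[e - 1 - j]
            cols.append((i + 1, _pair_status(mb, tb)))
            bases.append((mb, tb))
            i += 1
            j += 1
        elif move == "U":
            cols.append((i + 1, MIRNA_BULGE))
            bases.append((m[i], "-"))
            i += 1
        else:  # "L": bulged transcript base
            cols.append((None, TARGET_BULGE))
            bases.append(("-", sequence[e - 1 - j]))
            j += 1
    # trim terminal bulged transcript bases: they are flanking sequence,
    # not part of the duplex
    lead = 0
    while lead < len(cols) and cols[lead][1] == TARGET_BULGE:
        lead += 1
    trail = 0
    while trail < len(cols) - lead and cols[-1 - trail][1] == TARGET_BULGE:
        trail += 1
    if lead or trail:
        cols = cols[lead:len(cols) - trail]
        bases = bases[lead:len(bases) - trail]
    if not cols:
        return None
    n_edits = sum(1 for _, s in cols if s in (MISMATCH, MIRNA_BULGE, TARGET_BULGE))
    if n_edits > max_edits:
        return None
    # leading columns (ascending miRNA order) consume the highest transcript
    # positions; trailing the lowest
    site_end = e - lead
    site_start = e - w + trail
    return DuplexAlignment(mirna.id, transcript_id, site_start, site_end,
                           tuple(cols), tuple(bases))


def classify_duplex(duplex: DuplexAlignment) -> InteractionCall:
    """Apply the target / target-mimic rules to one duplex alignment.

    Central region: miRNA positions 9-12; seed: 2-8; an edit is 1 nt per
    mismatch column or bulged base. A bulged transcript base between
    miRNA positions i and i+1 counts as central iff 9 <= i <= 11 (the
    8|9 boundary bulge is non-central). Seed perfection requires WC or
    G-U pairing at positions 2-8 with no bulges interleaved. The
    no-consecutive-mismatches condition applies to target classification
    only and to MISMATCH columns only.
    """
    central_edits = 0
    other_edits = 0
    seed_perfect = True
    prev_mismatch = False
    has_adjacent = False
    last_real = 0
    c_lo, c_hi = CENTRAL
    s_lo, s_hi = SEED
    for pos, status in duplex.columns:
        if status in (WC, GU):
            last_real = pos
            prev_mismatch = False
            continue
        if status == MISMATCH:
            if c_lo <= pos <= c_hi:
                central_edits += 1
            else:
                other_edits += 1
            if s_lo <= pos <= s_hi:
                seed_perfect = False
            if prev_mismatch:
                has_adjacent = True
            prev_mismatch = True
            last_real = pos
        elif status == MIRNA_BULGE:
            if c_lo <= pos <= c_hi:
                central_edits += 1
            else:
                other_edits += 1
            if s_lo <= pos <= s_hi:
                seed_perfect = False
            prev_mismatch = False
            last_real = pos
        elif status == TARGET_BULGE:
            # between miRNA positions last_real and last_real + 1
            if c_lo <= last_real <= c_hi - 1:
                central_edits += 1
            else:
                other_edits += 1
            if s_lo <= last_real <= s_hi - 1:
                seed_perfect = False
            prev_mismatch = False
        else:
            raise ValueError(f"unknown column status {status!r}")

    diag = Diagnostics(central_edits, seed_perfect, other_edits, has_adjacent)
    if central_edits <= 1 and other_edits <= 4 and not has_adjacent:
        role = TARGET
    elif 2 <= central_edits <= 5 and seed_perfect and other_edits <= 4:
        role = MIMIC
    else:
        role = NONE
    return InteractionCall(duplex, role, diag)


_ROLE_RANK = {TARGET: 0, MIMIC: 1, NONE: 2}


def predict_interactions(
    mirnas: Sequence[MiRNARecord],
    transcripts: Sequence[tuple[str, str]],
    classes: dict[str, str] | None = None,
    max_edits: int = 9,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Scan every miRNA against every transcript and classify all sites.

    ``transcripts`` is (id, sequence) pairs; ``classes`` maps transcript
    id to 'lncRNA'/'mRNA' for the summary. Returns (site table,
    pair table, summary). The pair-level role is TARGET if any site is a
    target, else MIMIC if any site is a mimic; pairs whose sites are all
    NONE are reported with role NONE.
    """
    classes = classes or {}
    site_rows = []
    pair_best: dict[tuple[str, str], str] = {}
    for mir in mirnas:
        for tid, seq in transcripts:
            calls = [classify_duplex(d) for d in scan_duplexes(mir, tid, seq, max_edits)]
            if not calls:
                continue
            for call in calls:
                d = call.duplex
                site_rows.append({
                    "mirna_id": mir.id,
                    "transcript_id": tid,
                    "transcript_class": classes.get(tid, "unknown"),
                    "site_start": d.site_start,
                    "site_end": d.site_end,
                    "role": call.role,
                    "n_edits": d.n_edits,
                    "central_edits": call.diagnostics.central_edits,
                    "seed_perfect": call.diagnostics.seed_perfect,
                    "other_edits": call.diagnostics.other_edits,
                    "alignment_string": d.alignment_string(),
                })
            best = min((c.role for c in calls), key=_ROLE_RANK.get)
            key = (mir.id, tid)
            if key not in pair_best or _ROLE_RANK[best] < _ROLE_RANK[pair_best[key]]:
                pair_best[key] = best
    sites = pd.DataFrame(site_rows, columns=[
        "mirna_id", "transcript_id", "transcript_class", "site_start",
        "site_end", "role", "n_edits", "central_edits", "seed_perfect",
        "other_edits", "alignment_string"])
    pairs = pd.DataFrame(
        [{"mirna_id": mi, "transcript_id": ti,
          "transcript_class": classes.get(ti, "unknown"), "role": role}
         for (mi, ti), role in sorted(pair_best.items())],
        columns=["mirna_id", "transcript_id", "transcript_class", "role"])
    if len(pairs):
        summary = (pairs[pairs["role"] != NONE]
                   .groupby(["role", "transcript_class"]).size()
                   .rename("n_pairs").reset_index())
    else:
        summary = pd.DataFrame(columns=["role", "transcript_class", "n_pairs"])
    return sites, pairs, summary
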