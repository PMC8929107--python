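"""Synthetic transcriptomes with planted ground truth.

Every input the pipeline needs can be generated here: mRNA-like
transcripts (long embedded ORFs, higher GC), lncRNA-like transcripts
(no substantial ORF, lower GC), mature miRNAs shared across species,
duplex sites planted to satisfy or violate the target / target-mimic
rules, negative-binomial count matrices with planted fold changes, and
block-correlated expression profiles. The planted truth is returned as
a :class:`TruthTable` so every downstream stage can be scored.

Class-level defaults emulate the contrasts reported for real rodent
transcriptomes: lncRNAs shorter (median ~700 nt) and GC-poorer (~0.43)
than mRNAs (median ~2100 nt, GC ~0.50). All randomness flows from a
single integer seed through one :class:`numpy.random.Generator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import ExpressionMatrix, SampleMeta, revcomp
from .lncrna_id import TranscriptRecord, longest_orf
from .mirna_interactions import MIMIC, NONE, TARGET, MiRNARecord

_BASES = np.array(list("ACGT"))
_STOPS = {"TAA", "TAG", "TGA"}
_GU_PARTNER = {"G": "T", "T": "G"}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class TruthTable:
    """Planted ground truth of one simulation."""

    planted_interactions: list = field(default_factory=list)  # (mirna_id, transcript_id, role, site_start)
    planted_de: dict = field(default_factory=dict)  # transcript -> {contrast: log2fc}
    planted_coexpr_blocks: list = field(default_factory=list)  # list[set[str]]
    class_labels: dict = field(default_factory=dict)  # transcript -> mRNA|lncRNA

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for mid, tid, role, start in self.planted_interactions:
            rows.append(("interaction", mid, tid, role, start))
        for tid, contrasts in self.planted_de.items():
            for key, lfc in contrasts.items():
                rows.append(("de", tid, key, lfc, ""))
        for b, members in enumerate(self.planted_coexpr_blocks):
            for tid in sorted(members):
                rows.append(("block", str(b), tid, "", ""))
        for tid, label in self.class_labels.items():
            rows.append(("class", tid, label, "", ""))
        pd.DataFrame(rows, columns=["kind", "a", "b", "c", "d"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        truth = cls()
        blocks: dict[str, set] = {}
        for _, row in df.iterrows():
            if row["kind"] == "interaction":
                truth.planted_interactions.append(
                    (row["a"], row["b"], row["c"], int(row["d"])))
            elif row["kind"] == "de":
                truth.planted_de.setdefault(row["a"], {})[row["b"]] = float(row["c"])
            elif row["kind"] == "block":
                blocks.setdefault(row["a"], set()).add(row["b"])
            elif row["kind"] == "class":
                truth.class_labels[row["a"]] = row["b"]
        truth.planted_coexpr_blocks = [blocks[k] for k in sorted(blocks)]
        return truth


#: default length distributions (lognormal) per transcript class
DEFAULT_LEN_DIST = {
    "lncrna_meanlog": 6.55,   # median ~700 nt
    "lncrna_sdlog": 0.5,
    "lncrna_range": (201, 8000),
    "mrna_meanlog": 7.65,     # median ~2100 nt
    "mrna_sdlog": 0.5,
    "mrna_range": (450, 12000),
}


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _random_orf(rng: np.random.Generator, orf_nt: int, gc: float) -> str:
    """ATG + (orf_nt/3 - 2) non-stop codons + stop codon."""
    assert orf_nt % 3 == 0 and orf_nt >= 9
    n_codons = orf_nt // 3 - 2
    codons = []
    while len(codons) < n_codons:
        c = _random_seq(rng, 3, gc)
        if c not in _STOPS and c != "ATG":  # internal ATG fine, but keep ORF start unambiguous at 5' end
            codons.append(c)
    stop = ["TAA", "TAG", "TGA"][rng.integers(3)]
    return "ATG" + "".join(codons) + stop


def gen_transcriptome(
    n_mrna: int,
    n_lncrna: int,
    seed: int | None = None,
    gc_mrna: float = 0.50,
    gc_lncrna: float = 0.43,
    len_dist: dict | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[list[TranscriptRecord], TruthTable]:
    """Generate mRNA-like and lncRNA-like transcripts.

    mRNA-like records embed an in-frame ORF of at least 400 nt; lncRNA
    records are rejection-sampled until their longest ORF is under 300 nt
    and their length exceeds 200 nt. GC content per class targets the
    given fractions.
    """
    if n_mrna < 0 or n_lncrna < 0:
        raise ValueError("transcript counts must be non-negative")
    rng = rng if rng is not None else np.random.default_rng(seed)
    dist = dict(DEFAULT_LEN_DIST, **(len_dist or {}))
    lo, hi = dist["lncrna_range"]
    if hi <= 200:
        raise ValueError("lncRNA length range must allow lengths > 200 nt")
    truth = TruthTable()
    records: list[TranscriptRecord] = []

    for k in range(n_mrna):
        length = int(np.clip(rng.lognormal(dist["mrna_meanlog"], dist["mrna_sdlog"]),
                             *dist["mrna_range"]))
        orf_nt = max(402, int(0.45 * length) // 3 * 3)
        orf_nt = min(orf_nt, (length - 20) // 3 * 3)
        if orf_nt < 402:
            length = orf_nt = 402
            length += 40
        utr_total = length - orf_nt
        utr5 = int(rng.integers(0, utr_total + 1))
        seq = (_random_seq(rng, utr5, gc_mrna) + _random_orf(rng, orf_nt, gc_mrna)
               + _random_seq(rng, utr_total - utr5, gc_mrna))
        tid = f"MRNA_{k + 1:05d}"
        records.append(TranscriptRecord(tid, seq, label="mRNA"))
        truth.class_labels[tid] = "mRNA"

    for k in range(n_lncrna):
        for _ in range(1000):
            length = int(np.clip(rng.lognormal(dist["lncrna_meanlog"], dist["lncrna_sdlog"]),
                                 max(lo, 201), hi))
            seq = _random_seq(rng, length, gc_lncrna)
            if longest_orf(seq)[0] < 300:
                break
        else:
            raise RuntimeError("could not sample an lncRNA satisfying the ORF constraint")
        tid = f"LNC_{k + 1:05d}"
        records.append(TranscriptRecord(tid, seq, label="lncRNA"))
        truth.class_labels[tid] = "lncRNA"

    return records, truth


def gen_mirnas(
    n: int,
    species: list[str],
    conserved_fraction: float,
    length: int = 22,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> list[MiRNARecord]:
    """Generate ``n`` distinct mature miRNA sequences across species.

    Exactly ``round(n * conserved_fraction)`` sequences are emitted
    identically under two species (one record per species, as in a
    per-species miRBase dump); the rest belong to a single species.
    """
    n_cons = round(n * conserved_fraction)
    if n_cons > 0 and len(species) < 2:
        raise ValueError("conserved miRNAs require at least two species")
    rng = rng if rng is not None else np.random.default_rng(seed)
    seqs: set[str] = set()
    while len(seqs) < n:
        seqs.add(_random_seq(rng, length, 0.5))
    ordered = sorted(seqs)
    rng.shuffle(ordered)
    records: list[MiRNARecord] = []
    for k, seq in enumerate(ordered):
        if k < n_cons:
            sp_idx = rng.choice(len(species), size=2, replace=False)
            for si in sorted(sp_idx):
                sp = species[si]
                records.append(MiRNARecord(f"{sp}-mir-{k + 1}", seq, {sp}))
        else:
            sp = species[int(rng.integers(len(species)))]
            records.append(MiRNARecord(f"{sp}-mir-{k + 1}", seq, {sp}))
    return records


def _pair_partners(mirna_base: str) -> set[str]:
    partners = {_COMP[mirna_base]}
    if mirna_base in _GU_PARTNER:
        partners.add(_GU_PARTNER[mirna_base])
    return partners


def _mismatch_base(rng: np.random.Generator, mirna_base: str,
                   neighbor_bases: str = "") -> str:
    """A transcript base that neither Watson-Crick- nor wobble-pairs the
    given miRNA base — preferring bases that also fail to pair the
    neighboring miRNA positions, so a planted mismatch cannot be rescued
    by shifting the register by one."""
    forbidden = _pair_partners(mirna_base)
    strict_choices = [b for b in "ACGT"
                      if b not in forbidden
                      and all(b not in _pair_partners(nb) for nb in neighbor_bases)]
    choices = strict_choices or [b for b in "ACGT" if b not in forbidden]
    return choices[int(rng.integers(len(choices)))]


def _pick_spaced(rng: np.random.Generator, pool: list[int], k: int,
                 taken: list[int]) -> list[int]:
    """Pick k positions from pool keeping pairwise distance >= 2 (also to
    positions already taken)."""
    chosen: list[int] = []
    avail = list(pool)
    rng.shuffle(avail)
    for p in avail:
        if len(chosen) == k:
            break
        if all(abs(p - t) >= 2 for t in chosen + taken):
            chosen.append(p)
    if len(chosen) < k:
        raise ValueError("cannot place the requested number of spaced edits")
    return chosen


def _site_edits(rng: np.random.Generator, q: int, role: str,
                strict: bool) -> tuple[set, set, dict]:
    """Choose edit positions for a planted site.

    Returns (mismatch positions, miRNA-bulge positions, target-bulge
    counts keyed by the miRNA position they follow)."""
    mm: set[int] = set()
    dels: set[int] = set()
    tb: dict[int, int] = {}
    central = [9, 10, 11, 12]
    other = [1] + list(range(13, q + 1)) + list(range(2, 9))
    if role == TARGET:
        n_c = int(rng.integers(0, 2))
        n_o = int(rng.integers(0, 3)) if strict else int(rng.integers(0, 5))
        c_pos = _pick_spaced(rng, central, n_c, [])
        o_pos = _pick_spaced(rng, other, n_o, c_pos)
        mm.update(c_pos + o_pos)
    elif role == MIMIC:
        if strict:
            # the classic sponge pattern: a central bulge of 2-3 inserted
            # transcript bases between positions 10 and 11. Any alignment
            # of the locus must bulge the insert (central edits >= 2), so
            # no register of this site can read as a cleavable target
            n_c = int(rng.integers(2, 4))
            tb[10] = n_c
            n_o = int(rng.integers(0, 2))
            o_pool = [1] + list(range(14, q + 1))
            mm.update(_pick_spaced(rng, o_pool, n_o, []))
        else:
            n_c = int(rng.integers(2, 6))
            if n_c == 2:
                mm.update([(9, 11), (9, 12), (10, 12)][int(rng.integers(3))])
            elif n_c == 3:
                mm.update([9, 12])
                dels.add(int(rng.integers(10, 12)))
            elif n_c == 4:
                mm.update([9, 11])
                dels.update([10, 12])
            else:
                mm.update([9, 11])
                dels.update([10, 12])
                tb[10] = 1
            # other-region edits must spare the seed (positions 2-8)
            n_o = int(rng.integers(0, 5))
            o_pool = [1] + list(range(14, q + 1))
            mm.update(_pick_spaced(rng, o_pool, n_o, sorted(mm)))
    elif role == NONE:
        # violates both rule sets while staying the best-pairing structure
        # of its locus: a central 2-nt bulge (kills the target rule in
        # every register, since the insert must be bulged) plus a seed
        # mismatch (kills the mimic rule); only 3 edits, so no
        # alternative register aligns better
        tb[10] = 2
        mm.add(5)
    else:
        raise ValueError(f"unknown role {role!r}")
    return mm, dels, tb


def _bulge_base(rng: np.random.Generator, mirna_seq: str, boundary: int) -> str:
    """A base for an inserted (bulged) transcript base between miRNA
    positions ``boundary`` and ``boundary + 1``, preferring bases that
    pair none of the surrounding miRNA positions so the bulge cannot
    float into a neighboring region or be absorbed by re-registration."""
    q = len(mirna_seq)
    context = mirna_seq[max(boundary - 2, 0):min(boundary + 2, q)]
    scored = []
    for b in "ACGT":
        conflicts = sum(b in _pair_partners(mb) for mb in context)
        scored.append((conflicts, b))
    best = min(c for c, _ in scored)
    choices = [b for c, b in scored if c == best]
    return choices[int(rng.integers(len(choices)))]


def build_site(mirna: MiRNARecord, role: str, rng: np.random.Generator,
               strict: bool = True) -> str:
    """Construct the transcript-strand sequence of a planted duplex site
    (5'->3' on the transcript; miRNA position q pairs the first base)."""
    m = mirna.sequence
    q = len(m)
    mm, dels, tb = _site_edits(rng, q, role, strict)
    out: list[str] = []
    for p in range(q, 0, -1):  # transcript order pairs miRNA 3'->5'
        if p not in dels:
            if p in mm:
                neighbors = m[max(p - 2, 0):p + 1].replace(m[p - 1], "", 1)
                out.append(_mismatch_base(rng, m[p - 1], neighbors))
            else:
                out.append(_COMP[m[p - 1]])
        for _ in range(tb.get(p - 1, 0)):
            out.append(_bulge_base(rng, m, p - 1))
    return "".join(out)


def plant_site(
    transcript: TranscriptRecord,
    mirna: MiRNARecord,
    role: str,
    offset: int,
    rng: np.random.Generator,
    strict: bool = True,
) -> tuple[TranscriptRecord, tuple]:
    """Write a duplex site of the requested role into a transcript.

    The site replaces an equally long stretch starting at ``offset``
    (0-based); transcript length is unchanged. Returns the modified
    record and the truth row ``(mirna_id, transcript_id, role, offset)``.
    """
    site = build_site(mirna, role, rng, strict=strict)
    if offset < 0 or offset + len(site) > transcript.length_nt:
        raise ValueError(
            f"site [{offset}, {offset + len(site)}) outside transcript "
            f"{transcript.id!r} of length {transcript.length_nt}")
    seq = transcript.sequence
    new_seq = seq[:offset] + site + seq[offset + len(site):]
    rec = TranscriptRecord(transcript.id, new_seq, label=transcript.label)
    return rec, (mirna.id, transcript.id, role, offset)


def design_samples(tissues=("heart", "liver"), oxygens=(6.5, 10.5, 21.0),
                   replicates: int = 3) -> list[SampleMeta]:
    """Full-factorial tissue x oxygen design with replicates."""
    design = []
    for tissue in tissues:
        for ox in oxygens:
            for rep in range(1, replicates + 1):
                sid = f"{tissue[:2]}_{ox:g}_{rep}"
                design.append(SampleMeta(sid, tissue, float(ox), rep))
    return design


def contrast_key(tissue: str, ox_a: float, ox_b: float) -> str:
    return f"{tissue}:{ox_a:g}_vs_{ox_b:g}"


def parse_contrast_key(key: str) -> tuple[str, float, float]:
    tissue, _, rest = key.partition(":")
    a, _, b = rest.partition("_vs_")
    return tissue, float(a), float(b)


def gen_counts(
    design: list[SampleMeta],
    transcripts: int | dict[str, int],
    de_spec: dict[str, tuple[float, float]] | None = None,
    nb_dispersion: float = 0.1,
    base_mean_dist: tuple[float, float] = (3.5, 1.2),
    coexpr_blocks: list[tuple[int, float, float]] | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    truth: TruthTable | None = None,
) -> tuple[ExpressionMatrix, ExpressionMatrix, TruthTable]:
    """Negative-binomial counts with planted fold changes and co-expression
    blocks, plus the matching FPKM matrix.

    ``transcripts`` is either a gene count (lengths default to 1 kb) or a
    mapping transcript id -> length in nt. ``de_spec`` maps a contrast key
    (see :func:`contrast_key`) to ``(fraction_de, log2fc)``; affected genes
    get the fold change applied to the first group of the contrast, with
    random sign. ``coexpr_blocks`` lists ``(n_members, amplitude_log2,
    gene_noise_sd)`` blocks whose members share a latent per-sample
    profile. Block members and DE genes are disjoint so the truth is
    unambiguous. FPKM = counts / (length_kb * library_size_millions).
    """
    if not design:
        raise ValueError("empty sample design")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if isinstance(transcripts, int):
        ids = [f"T{k + 1:05d}" for k in range(transcripts)]
        lengths = np.full(transcripts, 1000.0)
    else:
        ids = list(transcripts)
        lengths = np.array([float(transcripts[t]) for t in ids])
    G, S = len(ids), len(design)
    truth = truth if truth is not None else TruthTable()

    base = rng.lognormal(base_mean_dist[0], base_mean_dist[1], size=G)
    effects = np.zeros((G, S))

    pool = list(range(G))
    rng.shuffle(pool)

    for n_members, amplitude, gene_noise in (coexpr_blocks or []):
        members = [pool.pop() for _ in range(n_members)]
        profile = rng.normal(0.0, 1.0, size=S)
        effects[members] += amplitude * profile[None, :]
        effects[members] += rng.normal(0.0, gene_noise, size=(len(members), S))
        truth.planted_coexpr_blocks.append({ids[g] for g in members})

    cols_by_group: dict[tuple[str, float], list[int]] = {}
    for j, s in enumerate(design):
        cols_by_group.setdefault(s.group, []).append(j)

    for key, (fraction, log2fc) in (de_spec or {}).items():
        tissue, ox_a, _ = parse_contrast_key(key)
        cols_a = cols_by_group.get((tissue, ox_a))
        if cols_a is None:
            raise ValueError(f"contrast {key!r} references a group absent from the design")
        n_de = round(fraction * G)
        if n_de > len(pool):
            raise ValueError("not enough unassigned genes for the requested DE fraction")
        genes = [pool.pop() for _ in range(n_de)]
        signs = rng.choice([-1.0, 1.0], size=n_de)
        for g, sgn in zip(genes, signs):
            effects[g, cols_a] += sgn * log2fc
            truth.planted_de.setdefault(ids[g], {})[key] = float(sgn * log2fc)

    mu = base[:, None] * np.exp2(effects)
    if nb_dispersion > 1e-12:
        counts = rng.negative_binomial(1.0 / nb_dispersion,
                                       1.0 / (1.0 + nb_dispersion * mu))
    else:
        counts = rng.poisson(mu)
    counts = counts.astype(float)

    meta = pd.DataFrame(
        [{"sample_id": s.sample_id, "tissue": s.tissue,
          "oxygen_pct": s.oxygen_pct, "replicate": s.replicate}
         for s in design]).set_index("sample_id", drop=False)
    counts_df = pd.DataFrame(counts, index=ids,
                             columns=[s.sample_id for s in design])
    lib = counts_df.sum(axis=0).to_numpy()
    lib = np.where(lib > 0, lib, 1.0)
    fpkm = counts / (lengths[:, None] / 1e3 * lib[None, :] / 1e6)
    fpkm_df = pd.DataFrame(fpkm, index=ids, columns=counts_df.columns)
    return (ExpressionMatrix(counts_df, meta),
            ExpressionMatrix(fpkm_df, meta), truth)


_ROLE_RANK = {TARGET: 0, MIMIC: 1, NONE: 2}


def score_site_recovery(truth: TruthTable, sites: pd.DataFrame,
                        mirna_length: int = 22) -> dict:
    """Score rule-classifier role recovery at the planted sites.

    For each planted (miRNA, transcript, role, offset), the predicted role
    is taken from the best-pairing alignments of that pair overlapping the
    planted site: among overlapping calls, those with the fewest edits are
    the predicted duplex structures, and the most favorable of their roles
    wins (NONE if there are no calls). Precision and recall are
    micro-averaged over the TARGET and MIMIC classes; planted NONE sites
    predicted as TARGET/MIMIC count against precision.
    """
    if len(sites):
        grouped = {k: g for k, g in sites.groupby(["mirna_id", "transcript_id"])}
    else:
        grouped = {}
    tp = fp = fn = 0
    n_scored = 0
    for mid, tid, role, offset in truth.planted_interactions:
        span = (offset, offset + mirna_length + WINDOW_SLOP_GUESS)
        predicted = NONE
        g = grouped.get((mid, tid))
        if g is not None:
            overlapping = g[(g["site_start"] < span[1]) & (g["site_end"] > span[0])]
            if len(overlapping):
                best_cost = overlapping["n_edits"].min()
                co_optimal = overlapping[overlapping["n_edits"] == best_cost]
                predicted = min(co_optimal["role"], key=_ROLE_RANK.get)
        n_scored += 1
        if role in (TARGET, MIMIC):
            if predicted == role:
                tp += 1
            else:
                fn += 1
                if predicted in (TARGET, MIMIC):
                    fp += 1
        elif predicted in (TARGET, MIMIC):
            fp += 1
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return {"precision": precision, "recall": recall, "tp": tp, "fp": fp,
            "fn": fn, "n_planted": n_scored}


WINDOW_SLOP_GUESS = 6  # planted sites are at most this much longer than the miRNA


@dataclass
class SimConfig:
    """End-to-end simulation parameters (the study conditions)."""

    n_mrna: int = 120
    n_lncrna: int = 120
    n_mirna: int = 40
    species: tuple = ("rat", "mouse", "hamster", "squirrel")
    conserved_fraction: float = 0.6
    mirna_length: int = 22
    n_target_sites: int = 60
    n_mimic_sites: int = 40
    n_none_sites: int = 20
    strict_sites: bool = True
    tissues: tuple = ("heart", "liver")
    oxygens: tuple = (6.5, 10.5, 21.0)
    replicates: int = 3
    nb_dispersion: float = 0.1
    de_fraction: float = 0.05
    de_log2fc: float = 2.0
    coexpr_blocks: tuple = ((20, 2.0, 0.15), (20, 2.0, 0.15))
    len_dist: dict | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        return cfg


def _best_role_at(mirna: MiRNARecord, sequence: str, offset: int,
                  site_len: int) -> str:
    """Most favorable role among the best-pairing alignments overlapping
    [offset, offset + site_len) — the site-level read-out of the rule
    classifier."""
    from .mirna_interactions import classify_duplex, scan_duplexes

    lo = max(0, offset - 30)
    hi = min(len(sequence), offset + site_len + 30)
    local_off = offset - lo
    overlapping = [
        d for d in scan_duplexes(mirna, "_local", sequence[lo:hi])
        if d.site_start < local_off + site_len and d.site_end > local_off
    ]
    if not overlapping:
        return NONE
    best = min(d.n_edits for d in overlapping)
    roles = [classify_duplex(d).role for d in overlapping if d.n_edits == best]
    return min(roles, key=_ROLE_RANK.get)


@dataclass
class SimulatedData:
    transcripts: list
    mirnas: list
    counts: ExpressionMatrix
    fpkm: ExpressionMatrix
    truth: TruthTable


def simulate_all(config: SimConfig) -> SimulatedData:
    """Generate a complete synthetic study: transcripts, miRNAs, planted
    duplex sites, counts and FPKM, with one truth table."""
    rng = np.random.default_rng(config.seed)
    records, truth = gen_transcriptome(
        config.n_mrna, config.n_lncrna, rng=rng, len_dist=config.len_dist)
    mirnas = gen_mirnas(config.n_mirna, list(config.species),
                        config.conserved_fraction, config.mirna_length, rng=rng)
    from .mirna_interactions import conserved_mirnas

    cons = conserved_mirnas(mirnas)
    by_id = {r.id: i for i, r in enumerate(records)}
    used: dict[str, list[tuple[int, int]]] = {}

    def plant_many(role: str, n_sites: int) -> None:
        planted = 0
        attempts = 0
        planted_pairs = {(m, t) for m, t, _, _ in truth.planted_interactions}
        while planted < n_sites and attempts < n_sites * 200:
            attempts += 1
            mir = cons[int(rng.integers(len(cons)))]
            rec = records[int(rng.integers(len(records)))]
            if (mir.id, rec.id) in planted_pairs:
                continue
            span = mir.length + 6
            if rec.length_nt < span + 10:
                continue
            offset = int(rng.integers(0, rec.length_nt - span))
            if any(offset < e and offset + span > s for s, e in used.get(rec.id, [])):
                continue
            if rec.label == "mRNA":
                # keep mRNA sites in the UTRs, as miRNA sites mostly are —
                # and so planting never disrupts the embedded ORF
                orf_len, orf_start, _, strand = rec.orf()
                if strand == "+" and offset < orf_start + orf_len and \
                        offset + span > orf_start:
                    continue
            new_rec, row = plant_site(rec, mir, role, offset, rng,
                                      strict=config.strict_sites)
            if config.strict_sites and _best_role_at(
                    mir, new_rec.sequence, offset, mir.length + 6) != role:
                continue  # ambiguous locus (e.g. repeat context); re-draw
            records[by_id[rec.id]] = new_rec
            used.setdefault(rec.id, []).append((offset, offset + span))
            truth.planted_interactions.append(row)
            planted_pairs.add((mir.id, rec.id))
            planted += 1
        if planted < n_sites:
            raise RuntimeError(f"could not plant {n_sites} {role} sites")

    plant_many(TARGET, config.n_target_sites)
    plant_many(MIMIC, config.n_mimic_sites)
    plant_many(NONE, config.n_none_sites)

    design = design_samples(config.tissues, config.oxygens, config.replicates)
    de_spec = {}
    for tissue in config.tissues:
        o = sorted(config.oxygens)
        for ox_a, ox_b in [(o[0], o[2]), (o[1], o[2]), (o[0], o[1])]:
            de_spec[contrast_key(tissue, ox_a, ox_b)] = (
                config.de_fraction, config.de_log2fc)
    lengths = {r.id: r.length_nt for r in records}
    counts, fpkm, truth = gen_counts(
        design, lengths, de_spec=de_spec, nb_dispersion=config.nb_dispersion,
        coexpr_blocks=list(config.coexpr_blocks), rng=rng, truth=truth)
    return SimulatedData(records, mirnas, counts, fpkm, truth)
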