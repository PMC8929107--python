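"""Conservation filter, duplex scanning and the target/mimic rule
classifier, checked against an independent brute-force recount."""

import numpy as np
import pytest

from hypolnc.core_io import revcomp
from hypolnc.mirna_interactions import (GU, MIMIC, MIRNA_BULGE, MISMATCH,
                                        NONE, TARGET, TARGET_BULGE, WC,
                                        DuplexAlignment, MiRNARecord,
                                        classify_duplex, conserved_mirnas,
                                        predict_interactions, scan_duplexes)

MIR = "ACGTACGGTACGATCGATCGAT"  # 22 nt


def make_duplex(columns):
    return DuplexAlignment("m", "t", 0, sum(1 for _, s in columns
                                            if s != MIRNA_BULGE), tuple(columns))


def brute_force_classify(columns):
    """Independent recount of the rules straight from the column list.

    Walks the columns explicitly, assigning every edited nt to the
    central region (positions 9-12) or elsewhere, tracking seed pairing
    (2-8) and consecutive mismatches, then applies the two rule sets.
    """
    central = 0
    other = 0
    seed_broken = False
    adjacent = False
    previous_was_mismatch = False
    last_position = 0
    for pos, status in columns:
        if status in (WC, GU):
            previous_was_mismatch = False
            last_position = pos
            continue
        if status == TARGET_BULGE:
            i = last_position
            if i in (9, 10, 11):
                central += 1
            else:
                other += 1
            if i in (2, 3, 4, 5, 6, 7):
                seed_broken = True
            previous_was_mismatch = False
            continue
        # MISMATCH or MIRNA_BULGE: an edit at a real miRNA position
        if 9 <= pos <= 12:
            central += 1
        else:
            other += 1
        if 2 <= pos <= 8:
            seed_broken = True
        if status == MISMATCH:
            if previous_was_mismatch:
                adjacent = True
            previous_was_mismatch = True
        else:
            previous_was_mismatch = False
        last_position = pos
    if central <= 1 and other <= 4 and not adjacent:
        return TARGET
    if 2 <= central <= 5 and not seed_broken and other <= 4:
        return MIMIC
    return NONE


def random_columns(rng, q=22):
    """A random plausible duplex column list over miRNA positions 1..q."""
    cols = []
    for pos in range(1, q + 1):
        status = rng.choice(
            [WC, GU, MISMATCH, MIRNA_BULGE],
            p=[0.55, 0.15, 0.2, 0.1])
        cols.append((int(pos), str(status)))
        if rng.random() < 0.08:
            cols.append((None, TARGET_BULGE))
    return cols


class TestConservedMirnas:
    def test_shared_sequence_kept_and_merged(self):
        recs = [MiRNARecord("b-mir-1", "A" * 22, {"b"}),
                MiRNARecord("a-mir-9", "A" * 22, {"a"})]
        out = conserved_mirnas(recs)
        assert len(out) == 1
        assert out[0].id == "a-mir-9"  # lexicographically smallest id
        assert out[0].species == {"a", "b"}

    def test_single_species_dropped(self):
        assert conserved_mirnas([MiRNARecord("a-mir-1", "C" * 22, {"a"})]) == []

    def test_counts_match_generated_fraction(self, rng):
        from hypolnc.synthetic import gen_mirnas
        recs = gen_mirnas(100, ["A", "B", "C", "D"], 0.3, seed=9)
        kept = conserved_mirnas(recs)
        assert len(kept) == 30
        # independent cross-check: count sequences appearing under >= 2 species
        seen = {}
        for r in recs:
            seen.setdefault(r.sequence, set()).update(r.species)
        assert sum(1 for sp in seen.values() if len(sp) >= 2) == 30


class TestClassifyDuplex:
    def test_all_wc_is_target(self):
        call = classify_duplex(make_duplex([(p, WC) for p in range(1, 23)]))
        assert call.role == TARGET
        d = call.diagnostics
        assert (d.central_edits, d.other_edits) == (0, 0)
        assert d.seed_perfect and not d.has_adjacent_mismatches

    def test_two_scattered_other_mismatches_still_target(self):
        cols = [(p, MISMATCH if p in (3, 15) else WC) for p in range(1, 23)]
        assert classify_duplex(make_duplex(cols)).role == TARGET

    def test_central_bulges_with_perfect_seed_is_mimic(self):
        cols = []
        for p in range(1, 23):
            cols.append((p, WC))
            if p == 10:
                cols.extend([(None, TARGET_BULGE)] * 3)
        call = classify_duplex(make_duplex(cols))
        assert call.role == MIMIC
        assert call.diagnostics.central_edits == 3
        assert call.diagnostics.seed_perfect

    def test_three_central_mismatches_perfect_seed_is_mimic(self):
        cols = [(p, MISMATCH if p in (9, 11, 12) else WC) for p in range(1, 23)]
        cols[14] = (15, MISMATCH)
        cols[17] = (18, MISMATCH)
        call = classify_duplex(make_duplex(cols))
        assert call.role == MIMIC
        assert call.diagnostics.other_edits == 2

    def test_adjacent_mismatches_and_empty_center_is_none(self):
        cols = [(p, MISMATCH if p in (15, 16) else WC) for p in range(1, 23)]
        call = classify_duplex(make_duplex(cols))
        assert call.role == NONE
        assert call.diagnostics.has_adjacent_mismatches

    def test_boundary_bulge_between_8_and_9_is_other_region(self):
        cols = []
        for p in range(1, 23):
            cols.append((p, WC))
            if p == 8:
                cols.append((None, TARGET_BULGE))
        d = classify_duplex(make_duplex(cols)).diagnostics
        assert d.central_edits == 0 and d.other_edits == 1

    def test_six_central_edits_is_none(self):
        cols = []
        for p in range(1, 23):
            cols.append((p, MISMATCH if p in (9, 10, 11, 12) else WC))
            if p in (9, 11):
                cols.append((None, TARGET_BULGE))
        assert classify_duplex(make_duplex(cols)).role == NONE

    def test_gu_columns_never_count_as_edits(self, rng):
        # metamorphic: converting any WC column to GU leaves diagnostics
        for _ in range(200):
            cols = random_columns(rng)
            base = classify_duplex(make_duplex(cols))
            wc_idx = [i for i, (_, s) in enumerate(cols) if s == WC]
            if not wc_idx:
                continue
            flip = list(cols)
            i = int(rng.choice(wc_idx))
            flip[i] = (flip[i][0], GU)
            assert classify_duplex(make_duplex(flip)).diagnostics == base.diagnostics

    def test_agrees_with_brute_force_recount(self, rng):
        for _ in range(3000):
            cols = random_columns(rng)
            assert classify_duplex(make_duplex(cols)).role == brute_force_classify(cols)

    def test_target_and_mimic_mutually_exclusive(self, rng):
        # central edits cannot be both <= 1 and >= 2
        for _ in range(500):
            d = classify_duplex(make_duplex(random_columns(rng))).diagnostics
            target_ok = d.central_edits <= 1 and d.other_edits <= 4 and not d.has_adjacent_mismatches
            mimic_ok = 2 <= d.central_edits <= 5 and d.seed_perfect and d.other_edits <= 4
            assert not (target_ok and mimic_ok)


class TestScanDuplexes:
    def test_exact_reverse_complement_found_all_wc(self, rng):
        m = MiRNARecord("m", MIR)
        t = "GG" + revcomp(MIR) + "AACC"
        dups = scan_duplexes(m, "t", t)
        perfect = [d for d in dups if all(s == WC for _, s in d.columns)]
        assert len(perfect) == 1
        assert (perfect[0].site_start, perfect[0].site_end) == (2, 24)

    def test_columns_cover_positions_ascending(self):
        m = MiRNARecord("m", MIR)
        dups = scan_duplexes(m, "t", "GG" + revcomp(MIR) + "AACC")
        for d in dups:
            pos = [p for p, _ in d.columns if p is not None]
            assert pos == sorted(pos)
            assert set(pos) == set(range(1, 23))

    def test_random_sequence_max_edits_2_empty(self, rng):
        m = MiRNARecord("m", MIR)
        hits = 0
        for _ in range(100):
            t = "".join(rng.choice(list("ACGT"), size=1000))
            hits += len(scan_duplexes(m, "t", t, max_edits=2))
        assert hits == 0

    def test_short_transcript_empty(self):
        assert scan_duplexes(MiRNARecord("m", MIR), "t", "ACGT") == []

    def test_site_coordinates_reverse_complement_convention(self):
        # scanning the reverse complement of the transcript finds the same
        # site at mirrored coordinates
        m = MiRNARecord("m", MIR)
        t = "GGCC" + revcomp(MIR) + "TTTTAA"
        fwd = scan_duplexes(m, "t", t)
        # the site written as revcomp(miRNA) on the + strand does not
        # exist on the - strand, where it reads as the miRNA itself
        assert any(all(s == WC for _, s in d.columns) for d in fwd)
        rc_hits = scan_duplexes(m, "t", revcomp(t))
        perfect_rc = [d for d in rc_hits if all(s == WC for _, s in d.columns)]
        assert perfect_rc == []

    def test_exhaustive_superset_of_pruned(self, rng):
        m = MiRNARecord("m", MIR)
        t = "".join(rng.choice(list("ACGT"), size=300))
        t = t[:100] + revcomp(MIR) + t[122:]
        pruned_dups = scan_duplexes(m, "t", t)
        full_dups = scan_duplexes(m, "t", t, exhaustive=True)
        pruned = {(d.site_start, d.columns) for d in pruned_dups}
        full = {(d.site_start, d.columns) for d in full_dups}
        assert pruned <= full

        def site_role(dups, lo, hi):
            at = [d for d in dups if d.site_start < hi and d.site_end > lo]
            best = min(d.n_edits for d in at)
            ranks = {TARGET: 0, MIMIC: 1, NONE: 2}
            return min((classify_duplex(d).role for d in at
                        if d.n_edits == best), key=ranks.get)

        # the best-pairing role at the planted locus is identical in both
        # modes
        assert site_role(pruned_dups, 100, 122) == site_role(full_dups, 100, 122) == TARGET


class TestPlantedSites:
    def test_planted_target_recovered_with_pattern(self, rng):
        from hypolnc.lncrna_id import TranscriptRecord
        from hypolnc.synthetic import plant_site
        m = MiRNARecord("m", MIR)
        base = TranscriptRecord("t", "".join(rng.choice(list("ACGT"), size=400)))
        rec, row = plant_site(base, m, TARGET, 150, rng)
        dups = scan_duplexes(m, "t", rec.sequence)
        at_site = [d for d in dups if d.site_start < 180 and d.site_end > 150]
        assert at_site
        best = min(d.n_edits for d in at_site)
        roles = {classify_duplex(d).role for d in at_site if d.n_edits == best}
        assert TARGET in roles

    def test_pair_with_target_and_mimic_sites(self, rng):
        from hypolnc.lncrna_id import TranscriptRecord
        from hypolnc.synthetic import plant_site
        m = MiRNARecord("m", MIR)
        base = TranscriptRecord("t", "".join(rng.choice(list("ACGT"), size=500)))
        rec, _ = plant_site(base, m, TARGET, 50, rng)
        rec, _ = plant_site(rec, m, MIMIC, 300, rng)
        sites, pairs, _ = predict_interactions([m], [("t", rec.sequence)],
                                               {"t": "lncRNA"})
        assert pairs.loc[0, "role"] == TARGET  # pair level: target wins
        target_rows = sites[(sites["role"] == TARGET) & (sites["site_start"] < 80)]
        mimic_rows = sites[(sites["role"] == MIMIC) & (sites["site_start"] > 280)]
        assert len(target_rows) and len(mimic_rows)

    def test_empty_mirna_set(self):
        sites, pairs, summary = predict_interactions([], [("t", "ACGT" * 100)])
        assert len(sites) == 0 and len(pairs) == 0 and len(summary) == 0


def test_length_warning_outside_18_26():
    with pytest.warns(UserWarning):
        MiRNARecord("m", "ACGT")
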