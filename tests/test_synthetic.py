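"""The synthetic-data generators and their planted ground truth."""

import numpy as np
import pytest

from hypolnc.core_io import revcomp
from hypolnc.lncrna_id import TranscriptRecord, longest_orf
from hypolnc.mirna_interactions import MIMIC, NONE, TARGET, MiRNARecord
from hypolnc.seq_features import gc_content
from hypolnc.synthetic import (SimConfig, TruthTable, build_site,
                               design_samples, gen_counts, gen_mirnas,
                               gen_transcriptome, plant_site, simulate_all)


class TestGenTranscriptome:
    def test_empty(self):
        records, truth = gen_transcriptome(0, 0, seed=1)
        assert records == [] and truth.class_labels == {}

    def test_deterministic_under_seed(self):
        r1, _ = gen_transcriptome(10, 10, seed=1)
        r2, _ = gen_transcriptome(10, 10, seed=1)
        assert [(r.id, r.sequence) for r in r1] == [(r.id, r.sequence) for r in r2]

    def test_class_constraints(self):
        records, truth = gen_transcriptome(30, 30, seed=2)
        for r in records:
            if truth.class_labels[r.id] == "mRNA":
                assert r.longest_orf_nt >= 400
            else:
                assert r.longest_orf_nt < 300
                assert r.length_nt > 200

    def test_gc_contrast(self):
        records, truth = gen_transcriptome(200, 200, seed=7)
        gc = {"mRNA": [], "lncRNA": []}
        for r in records:
            gc[truth.class_labels[r.id]].append(gc_content(r.sequence))
        assert np.mean(gc["lncRNA"]) < np.mean(gc["mRNA"])
        assert abs(np.mean(gc["lncRNA"]) - 0.43) < 0.03
        assert abs(np.mean(gc["mRNA"]) - 0.50) < 0.03

    def test_unattainable_lncrna_length_raises(self):
        with pytest.raises(ValueError):
            gen_transcriptome(0, 5, seed=1, len_dist={"lncrna_range": (50, 200)})


class TestGenMirnas:
    def test_conserved_fraction_arithmetic(self):
        recs = gen_mirnas(10, ["A", "B"], 0.5, seed=3)
        by_seq = {}
        for r in recs:
            by_seq.setdefault(r.sequence, set()).update(r.species)
        conserved = [s for s, sp in by_seq.items() if len(sp) >= 2]
        assert len(conserved) == 5
        assert len(by_seq) == 10

    def test_zero_fraction(self):
        recs = gen_mirnas(10, ["A", "B"], 0.0, seed=3)
        by_seq = {}
        for r in recs:
            by_seq.setdefault(r.sequence, set()).update(r.species)
        assert all(len(sp) == 1 for sp in by_seq.values())

    def test_single_species_with_conservation_raises(self):
        with pytest.raises(ValueError):
            gen_mirnas(10, ["A"], 0.5, seed=1)

    def test_lengths(self):
        assert all(len(r.sequence) == 22 for r in gen_mirnas(5, ["A", "B"], 0.4, seed=1))


class _ZeroRng:
    """Degenerate rng making every random edit count zero."""

    def integers(self, *a, **k):
        return 0

    def random(self):
        return 0.0

    def shuffle(self, x):
        pass


class TestPlantSite:
    def test_target_with_zero_edits_is_exact_revcomp(self):
        m = MiRNARecord("m", "ACGTACGGTACGATCGATCGAT")
        site = build_site(m, TARGET, _ZeroRng())
        assert site == revcomp(m.sequence)

    def test_site_replaces_stretch_preserving_length(self, rng):
        m = MiRNARecord("m", "ACGTACGGTACGATCGATCGAT")
        base = TranscriptRecord("t", "".join(rng.choice(list("ACGT"), 300)))
        rec, row = plant_site(base, m, TARGET, 100, rng)
        assert rec.length_nt == base.length_nt
        assert row == ("m", "t", TARGET, 100)
        assert rec.sequence[:100] == base.sequence[:100]

    def test_out_of_bounds_offset_raises(self, rng):
        m = MiRNARecord("m", "ACGTACGGTACGATCGATCGAT")
        base = TranscriptRecord("t", "ACGT" * 10)
        with pytest.raises(ValueError):
            plant_site(base, m, TARGET, 30, rng)

    @pytest.mark.parametrize("role", [TARGET, MIMIC, NONE])
    def test_strict_sites_classified_as_intended(self, role, rng):
        # central region (positions 9-12) of this miRNA pairs only A/G
        # bases, so an adversarial central insert cannot float
        from hypolnc.synthetic import _best_role_at
        m = MiRNARecord("m", "ATCTCCGAACCAATGGATCGAT")
        hits = 0
        for k in range(10):
            base = TranscriptRecord("t", "".join(rng.choice(list("ACGT"), 200)))
            rec, _ = plant_site(base, m, role, 80, rng)
            if _best_role_at(m, rec.sequence, 80, m.length + 6) == role:
                hits += 1
        assert hits >= 7  # ambiguous loci are re-drawn by the corpus generator


class TestGenCounts:
    DESIGN = design_samples()

    def test_deterministic(self):
        c1, f1, _ = gen_counts(self.DESIGN, 50, None, 0.1, seed=4)
        c2, f2, _ = gen_counts(self.DESIGN, 50, None, 0.1, seed=4)
        assert (c1.values.values == c2.values.values).all()
        assert np.allclose(f1.values.values, f2.values.values)

    def test_empty_design_raises(self):
        with pytest.raises(ValueError):
            gen_counts([], 10)

    def test_poisson_limit_group_means_equal(self):
        counts, _, _ = gen_counts(self.DESIGN, 400, None, nb_dispersion=0.0,
                                  base_mean_dist=(np.log(200), 0.0), seed=8)
        groups = counts.groups()
        means = np.array([counts.values[cols].values.mean()
                          for cols in groups.values()])
        assert means.std() / means.mean() < 0.05

    def test_planted_log2fc_shifts_group_mean(self):
        key = "heart:6.5_vs_21"
        counts, _, truth = gen_counts(self.DESIGN, 300, {key: (0.1, 2.0)}, 0.05,
                                      (np.log(200), 0.0), seed=9)
        groups = counts.groups()
        up = [t for t, d in truth.planted_de.items() if d[key] > 0]
        a = counts.values.loc[up, groups[("heart", 6.5)]].values.mean()
        b = counts.values.loc[up, groups[("heart", 21.0)]].values.mean()
        assert a / b == pytest.approx(4.0, rel=0.25)

    def test_fpkm_invariant_under_count_duplication(self):
        counts, fpkm, _ = gen_counts(self.DESIGN, 40, None, 0.1, seed=10)
        lengths = np.full(40, 1000.0)
        lib = counts.values.sum(axis=0).to_numpy()
        recompute = counts.values.values / (lengths[:, None] / 1e3 * lib[None, :] / 1e6)
        doubled = 2 * counts.values.values
        lib2 = doubled.sum(axis=0)
        recompute2 = doubled / (lengths[:, None] / 1e3 * lib2[None, :] / 1e6)
        assert np.allclose(recompute, fpkm.values.values)
        assert np.allclose(recompute2, recompute)

    def test_block_members_share_profile(self):
        counts, fpkm, truth = gen_counts(self.DESIGN, 200, None, 0.1,
                                         (np.log(300), 0.5),
                                         coexpr_blocks=[(15, 2.0, 0.1)], seed=11)
        block = sorted(truth.planted_coexpr_blocks[0])
        data = np.log2(fpkm.values.loc[block].values + 1)
        r = np.corrcoef(data)
        off_diag = r[np.triu_indices(len(block), 1)]
        assert np.median(off_diag) > 0.8


class TestTruthTableIO:
    def test_round_trip(self, tmp_path, small_sim):
        path = tmp_path / "truth.tsv"
        small_sim.truth.to_tsv(path)
        back = TruthTable.from_tsv(path)
        assert back.planted_interactions == small_sim.truth.planted_interactions
        assert back.planted_de == small_sim.truth.planted_de
        assert back.class_labels == small_sim.truth.class_labels
        assert back.planted_coexpr_blocks == small_sim.truth.planted_coexpr_blocks


def test_simulate_all_is_deterministic_and_consistent(small_sim):
    cfg = SimConfig(
        n_mrna=25, n_lncrna=25, n_mirna=12, conserved_fraction=0.5,
        n_target_sites=10, n_mimic_sites=6, n_none_sites=4,
        coexpr_blocks=((8, 2.0, 0.15),), de_fraction=0.05, seed=42,
        len_dist={"mrna_meanlog": 6.6, "lncrna_meanlog": 6.2},
    )
    again = simulate_all(cfg)
    assert [(r.id, r.sequence) for r in again.transcripts] == \
        [(r.id, r.sequence) for r in small_sim.transcripts]
    assert (again.counts.values.values == small_sim.counts.values.values).all()
    # planted sites lie inside their transcripts
    lengths = {r.id: r.length_nt for r in again.transcripts}
    for mid, tid, role, off in again.truth.planted_interactions:
        assert 0 <= off < lengths[tid]
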