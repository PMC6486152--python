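"""PWM scanning, exact threshold calibration and the candidate funnel."""
import itertools

import numpy as np
import pandas as pd
import pytest

import blastoquant as bq
from blastoquant.regulatory import (
    SCORE_SCALE,
    MotifHit,
    read_bed,
    write_bed,
    write_pwm,
)

UNIFORM = (0.25, 0.25, 0.25, 0.25)


def random_pwm(width, seed, background=UNIFORM):
    rng = np.random.default_rng(seed)
    m = rng.dirichlet(np.full(4, 0.8), size=width)
    return bq.MotifModel(matrix=m, background=background)


def naive_scan(seq, model, thr_int):
    """Pure-python per-window rescoring oracle (both strands)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    ints = model.int_scores()
    w = model.width
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    hits = []
    for i in range(len(seq) - w + 1):
        win = seq[i:i + w]
        if "N" in win:
            continue
        s_fwd = sum(ints[j, idx[b]] for j, b in enumerate(win))
        if s_fwd >= thr_int:
            hits.append((i, i + w, "+", int(s_fwd)))
        rc = "".join(comp[b] for b in reversed(win))
        s_rev = sum(ints[j, idx[b]] for j, b in enumerate(rc))
        if s_rev >= thr_int:
            hits.append((i, i + w, "-", int(s_rev)))
    return sorted(hits)


class TestLoadPwm:
    def test_width_one_certain_base(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("Pos\tA\tC\tG\tT\n1\t1\t0\t0\t0\n")
        m = bq.load_pwm(p, pseudocount=0.0)
        assert m.consensus == "A"
        lo = m.log_odds()
        assert lo[0, 0] == pytest.approx(np.log2(1 / 0.25))
        assert np.isneginf(lo[0, 1:]).all()

    def test_count_matrix_normalization_identity(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text("Pos\tA\tC\tG\tT\n1\t6\t2\t1\t1\n2\t0\t10\t0\t0\n")
        pc = 0.5
        m = bq.load_pwm(p, pseudocount=pc)
        np.testing.assert_allclose(
            m.matrix[0], (np.array([6, 2, 1, 1]) + pc) / (10 + 4 * pc)
        )
        np.testing.assert_allclose(m.matrix.sum(axis=1), 1.0)

    def test_jaspar_block_dialect(self, tmp_path):
        p = tmp_path / "m.jaspar"
        p.write_text(
            ">MA0001.1 test\nA [ 3 0 ]\nC [ 1 0 ]\nG [ 0 4 ]\nT [ 0 0 ]\n"
        )
        m = bq.load_pwm(p, pseudocount=0.0)
        assert m.consensus == "AG"
        assert m.name == "MA0001.1"

    def test_round_trip(self, tmp_path):
        m = random_pwm(7, seed=0)
        p = tmp_path / "m.txt"
        write_pwm(m, p)
        m2 = bq.load_pwm(p, pseudocount=0.0)
        np.testing.assert_allclose(m.matrix, m2.matrix, atol=1e-9)


class TestCalibrateThreshold:
    @pytest.mark.parametrize("width", [1, 2, 4, 6])
    def test_tail_equals_exhaustive_enumeration(self, width):
        model = random_pwm(width, seed=width)
        cal = bq.calibrate_threshold(model, alpha=1e-3)
        ints = model.int_scores()
        scores = np.zeros(1, dtype=np.int64)
        for j in range(width):
            scores = (scores[:, None] + ints[j][None, :]).ravel()
        # uniform background: every word has probability 4^-width
        for s in np.unique(scores):
            tail = (scores >= s).sum() / 4**width
            assert cal.tail_prob(int(s)) == pytest.approx(tail, abs=1e-12)

    def test_alpha_one_accepts_everything(self):
        model = random_pwm(3, seed=1)
        cal = bq.calibrate_threshold(model, alpha=1.0)
        assert cal.threshold_int == int(cal.scores[0])

    def test_certain_consensus_tail_is_background_product(self):
        m = np.zeros((2, 4))
        m[0, 0] = 1.0  # A
        m[1, 2] = 1.0  # G
        bg = (0.4, 0.1, 0.3, 0.2)
        model = bq.MotifModel(matrix=m, background=bg)
        cal = bq.calibrate_threshold(model, alpha=0.4 * 0.3)
        assert cal.tail_prob(cal.threshold_int) == pytest.approx(0.4 * 0.3)

    def test_unattainable_alpha_warns_and_blocks_all(self):
        model = random_pwm(2, seed=2)
        with pytest.warns(UserWarning, match="alpha"):
            cal = bq.calibrate_threshold(model, alpha=1e-12)
        assert cal.threshold_int > int(cal.scores[-1])


class TestScanSequence:
    def test_printed_binding_site_and_its_mutation(self):
        pwm = bq.rbpj_consensus_pwm()
        thr = bq.calibrate_threshold(pwm, alpha=1e-4)
        seq = "A" * 30 + "TGTGGGAAA" + "C" * 30
        hits = bq.scan_sequence(seq, pwm, thr)
        assert any(h.start == 30 and h.end == 39 for h in hits)
        mutant = "A" * 30 + "TGTCCGAAA" + "C" * 30
        assert bq.scan_sequence(mutant, pwm, thr) == []

    def test_strand_symmetry_under_reverse_complement(self):
        model = random_pwm(5, seed=3)
        cal = bq.calibrate_threshold(model, alpha=0.01)
        rng = np.random.default_rng(4)
        seq = "".join(rng.choice(list("ACGT"), 300))
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        rc = "".join(comp[b] for b in reversed(seq))
        fwd = bq.scan_sequence(seq, model, cal)
        rev = bq.scan_sequence(rc, model, cal)
        L = len(seq)
        mirrored = sorted(
            (L - h.end, L - h.start, {"+": "-", "-": "+"}[h.strand],
             h.score_int)
            for h in rev
        )
        ours = sorted((h.start, h.end, h.strand, h.score_int) for h in fwd)
        assert ours == mirrored

    def test_equals_pure_python_oracle(self):
        model = random_pwm(6, seed=5)
        cal = bq.calibrate_threshold(model, alpha=0.02)
        rng = np.random.default_rng(6)
        seq = "".join(rng.choice(list("ACGT"), 2000))
        ours = sorted(
            (h.start, h.end, h.strand, h.score_int)
            for h in bq.scan_sequence(seq, model, cal)
        )
        assert ours == naive_scan(seq, model, cal.threshold_int)

    def test_windows_with_n_are_skipped(self):
        pwm = bq.rbpj_consensus_pwm()
        thr = bq.calibrate_threshold(pwm, alpha=1e-4)
        seq = "TGTGGNAAA" + "TGTGGGAAA"
        hits = bq.scan_sequence(seq, pwm, thr)
        assert [(h.start, h.end) for h in hits] == [(9, 18)]

    def test_short_sequence_empty(self):
        pwm = bq.rbpj_consensus_pwm()
        thr = bq.calibrate_threshold(pwm, alpha=1e-4)
        assert bq.scan_sequence("TGT", pwm, thr) == []


class TestTssWindows:
    def test_plus_strand_left_clip(self):
        g = bq.GenomicInterval("chr1", 5000, 8000, "+", "g")
        w = bq.window_around_tss([g], half_width=10_000)[0]
        assert (w.start, w.end) == (0, 15_000)

    def test_minus_strand_tss_at_end(self):
        g = bq.GenomicInterval("chr1", 5000, 8000, "-", "g")
        w = bq.window_around_tss([g], half_width=10_000)[0]
        assert (w.start, w.end) == (0, 18_000)

    def test_right_clip_needs_chrom_sizes(self):
        g = bq.GenomicInterval("chr1", 5000, 8000, "+", "g")
        w = bq.window_around_tss([g], 10_000, chrom_sizes={"chr1": 12_000})[0]
        assert w.end == 12_000
        with pytest.raises(KeyError, match="chr9"):
            bq.window_around_tss(
                [bq.GenomicInterval("chr9", 0, 10, "+", "g")],
                10_000, chrom_sizes={"chr1": 12_000},
            )

    def test_degenerate_half_width_rejected(self):
        g = bq.GenomicInterval("chr1", 5000, 8000, "+", "g")
        with pytest.raises(ValueError, match="half_width"):
            bq.window_around_tss([g], half_width=0)


class TestContainment:
    def test_containment_vs_overlap(self):
        peak = bq.GenomicInterval("chr1", 0, 100, ".", "p")
        inside = MotifHit("chr1", 10, 19, "+", 0, 0.0)
        straddle = MotifHit("chr1", 95, 104, "+", 0, 0.0)
        kept = bq.intersect_contained([inside, straddle], [peak])
        assert kept == [inside]

    def test_equals_quadratic_oracle(self):
        rng = np.random.default_rng(7)
        hits = [
            MotifHit("chr1", int(s), int(s) + 9, "+", 0, 0.0)
            for s in rng.integers(0, 10_000, 400)
        ]
        peaks = [
            bq.GenomicInterval("chr1", int(s), int(s) + int(w), ".", f"p{i}")
            for i, (s, w) in enumerate(
                zip(rng.integers(0, 10_000, 80), rng.integers(5, 400, 80))
            )
        ]
        kept = set(bq.intersect_contained(hits, peaks))
        oracle = {
            h for h in hits
            if any(p.start <= h.start and h.end <= p.end for p in peaks)
        }
        assert kept == oracle


class TestFilterReport:
    def test_empty_deg_table(self):
        deg = pd.DataFrame(columns=["gene_id", "logFC", "adj_p"])
        rep = bq.candidate_filter_report(
            deg, [], {"chr1": "A" * 100}, bq.rbpj_consensus_pwm(), []
        )
        assert rep.funnel == (0, 0, 0)

    def test_removing_peaks_zeroes_final_stage(self):
        fx = bq.simulate_genome_fixture(
            bq.GenomeFixtureParams(seed=1, genome_length=100_000, n_genes=3)
        )
        genes = [
            bq.GenomicInterval(r.chrom, r.start, r.end, r.strand, r.name)
            for r in fx.genes.itertuples()
        ]
        rep = bq.candidate_filter_report(
            fx.deg, genes, {fx.chrom: fx.sequence},
            bq.rbpj_consensus_pwm(), [],
            half_width=fx.half_width, alpha=fx.alpha,
        )
        assert rep.funnel == (3, 3, 0)

    def test_missing_gene_coordinates_counted_no_motif(self):
        deg = pd.DataFrame(
            {"gene_id": ["ghost"], "logFC": [2.0], "adj_p": [1e-5]}
        )
        rep = bq.candidate_filter_report(
            deg, [], {"chr1": "A" * 100}, bq.rbpj_consensus_pwm(), []
        )
        assert rep.funnel == (1, 0, 0)
        assert any("ghost" in w for w in rep.warnings)

    def test_significance_filter_applied_to_input(self):
        deg = pd.DataFrame(
            {
                "gene_id": ["a", "b", "c"],
                "logFC": [2.0, 0.5, -3.0],
                "adj_p": [1e-4, 1e-4, 0.2],
            }
        )
        rep = bq.candidate_filter_report(
            deg, [], {"chr1": "A" * 100}, bq.rbpj_consensus_pwm(), []
        )
        assert rep.n_deg == 1  # only |logFC|>1 and adj_p<0.05 survives

    def test_funnel_monotone_on_fuzzed_fixtures(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 5))
            planted = [
                (i, int(rng.integers(-8000, 8000)), "+",
                 bool(rng.random() < 0.5))
                for i in range(n) if rng.random() < 0.7
            ]
            fx = bq.simulate_genome_fixture(
                bq.GenomeFixtureParams(
                    seed=seed + 100, genome_length=160_000, n_genes=n,
                    planted_motifs=planted,
                )
            )
            genes = [
                bq.GenomicInterval(r.chrom, r.start, r.end, r.strand, r.name)
                for r in fx.genes.itertuples()
            ]
            peaks = [
                bq.GenomicInterval(r.chrom, r.start, r.end, ".", r.name)
                for r in fx.peaks.itertuples()
            ]
            rep = bq.candidate_filter_report(
                fx.deg, genes, {fx.chrom: fx.sequence},
                bq.rbpj_consensus_pwm(), peaks,
                half_width=fx.half_width, alpha=fx.alpha,
            )
            assert rep.n_deg >= rep.n_with_motif >= rep.n_in_open_chromatin
            assert rep.funnel == fx.expected_funnel


def test_bed_round_trip_preserves_half_open_coordinates(tmp_path):
    hits = [
        MotifHit("chr1", 10, 19, "+", 1234, 1.234),
        MotifHit("chr2", 0, 9, "-", 555, 0.555),
    ]
    p = tmp_path / "hits.bed"
    write_bed(hits, p)
    back = read_bed(p)
    assert [(b.chrom, b.start, b.end, b.strand) for b in back] == [
        ("chr1", 10, 19, "+"), ("chr2", 0, 9, "-")
    ]
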