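"""PWM scanning, exact p-values, category enrichment, TF-segregation PCA."""

import numpy as np
import pandas as pd
import pytest

from _oracles import enum_kmer_scores

from peakfactor.io_formats import GenomicInterval, MotifModel
from peakfactor.intervals import PeakSet
from peakfactor.motifs import (
    MotifHit,
    ScoreDistribution,
    logodds_score,
    motif_category_enrichment,
    scan,
    score_pvalue,
    tf_segregation_pca,
)

HAND_MOTIF = MotifModel.from_rows(
    "hand", [[0.8, 0.1, 0.05, 0.05], [0.1, 0.1, 0.6, 0.2]], pseudocount=0.0)


def strong_motif(width=12, p=0.97, motif_id="strong"):
    rows = []
    for i in range(width):
        row = [(1 - p) / 3] * 4
        row["ACGT".index("ACGT"[i % 4])] = p
        rows.append(row)
    return MotifModel.from_rows(motif_id, rows, pseudocount=0.01)


class TestLogOdds:
    def test_hand_computed_score(self):
        assert logodds_score(HAND_MOTIF, "AG") == pytest.approx(
            np.log2(3.2) + np.log2(2.4), abs=1e-9)

    def test_background_motif_scores_zero(self):
        flat = MotifModel.from_rows("flat", [[0.25] * 4] * 3, pseudocount=0.0)
        for kmer in ("AAA", "ACG", "TTT"):
            assert logodds_score(flat, kmer) == pytest.approx(0.0, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="width"):
            logodds_score(HAND_MOTIF, "AGG")

    def test_reverse_complement_symmetry(self, rng):
        """Scanning the reverse complement sequence with the reverse
        complement matrix reproduces forward scores."""
        m = MotifModel.from_rows("m", rng.dirichlet(np.ones(4), size=5))
        rc_rows = m.probs[::-1, ::-1]
        m_rc = MotifModel(motif_id="rc", probs=rc_rows, background=m.background,
                          pseudocount=m.pseudocount)
        comp = str.maketrans("ACGT", "TGCA")
        for kmer in ("ACGTA", "GGGTT", "TATAT"):
            rc_kmer = kmer.translate(comp)[::-1]
            assert logodds_score(m, kmer) == pytest.approx(
                logodds_score(m_rc, rc_kmer), abs=1e-9)


class TestScorePvalue:
    def test_max_score_uniform_background_width2(self):
        best = logodds_score(HAND_MOTIF, "AG")
        assert score_pvalue(HAND_MOTIF, best) == pytest.approx(1 / 16)

    def test_minus_infinity_gives_one(self):
        assert score_pvalue(HAND_MOTIF, -np.inf) == 1.0

    @pytest.mark.parametrize("width", [2, 3, 4, 5])
    def test_dp_matches_enumeration(self, width):
        """DP p-values bracket exhaustive enumeration within the
        discretisation tolerance (one lattice unit per position plus
        the final rounding)."""
        rng = np.random.default_rng(width)
        m = MotifModel.from_rows(f"w{width}", rng.dirichlet(np.ones(4), size=width))
        dist = ScoreDistribution(m, resolution=1e-3)
        scores, probs = enum_kmer_scores(m)
        tol = (2 * width + 1) * 1e-3
        for s in scores:
            p_dp = dist.pvalue(s)
            lo = probs[scores >= s + tol].sum()
            hi = probs[scores >= s - tol].sum()
            assert lo - 1e-12 <= p_dp <= hi + 1e-12

    def test_monotone_non_increasing_in_score(self):
        dist = ScoreDistribution(HAND_MOTIF)
        grid = np.linspace(-6, 4, 101)
        ps = [dist.pvalue(s) for s in grid]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))

    def test_finer_resolution_converges_to_enumeration(self):
        rng = np.random.default_rng(9)
        m = MotifModel.from_rows("c", rng.dirichlet(np.ones(4), size=3))
        scores, probs = enum_kmer_scores(m)
        target = scores[5]
        exact = probs[scores >= target - 1e-9].sum()
        for res, tol in [(1e-2, 0.1), (1e-3, 0.02), (1e-4, 0.002)]:
            approx = ScoreDistribution(m, resolution=res).pvalue(target)
            assert abs(approx - exact) <= tol + 1e-12


class TestScan:
    def _genome_with_site(self, site, at, length=500):
        rng = np.random.default_rng(0)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
        return {"chr1": seq[:at] + site + seq[at + len(site):]}

    def test_planted_consensus_found_at_offset(self):
        m = strong_motif()
        genome = self._genome_with_site(m.consensus(), 200)
        peaks = PeakSet([GenomicInterval("chr1", 100, 400, name="pk")])
        hits = scan(peaks, genome, [m], p_threshold=1e-4)
        assert any(h.start == 200 and h.strand == "+" for h in hits)

    def test_all_n_sequence_yields_no_hits(self):
        genome = {"chr1": "N" * 300}
        peaks = PeakSet([GenomicInterval("chr1", 0, 300)])
        assert scan(peaks, genome, [strong_motif()], p_threshold=1.0) == []

    def test_threshold_one_counts_all_windows(self):
        m = strong_motif(width=4)
        genome = {"chr1": "ACGTACGTACGTACGTACGT"}  # length 20
        peaks = PeakSet([GenomicInterval("chr1", 0, 20)])
        hits = scan(peaks, genome, [m], p_threshold=1.0)
        assert len(hits) == 2 * (20 - 4 + 1)

    def test_peak_beyond_contig_end_is_error(self):
        genome = {"chr1": "ACGT" * 10}
        peaks = PeakSet([GenomicInterval("chr1", 0, 100, name="bad")])
        with pytest.raises(ValueError, match="bad"):
            scan(peaks, genome, [strong_motif(width=4)])

    def test_reverse_strand_site_recovered(self):
        m = strong_motif()
        comp = str.maketrans("ACGT", "TGCA")
        rc_site = m.consensus().translate(comp)[::-1]
        genome = self._genome_with_site(rc_site, 150)
        peaks = PeakSet([GenomicInterval("chr1", 50, 350)])
        hits = scan(peaks, genome, [m], p_threshold=1e-4)
        assert any(h.start == 150 and h.strand == "-" for h in hits)

    def test_hits_invariant_under_peak_order_and_batching(self):
        m = strong_motif(width=6)
        rng = np.random.default_rng(4)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        genome = {"chr1": seq}
        peaks = [GenomicInterval("chr1", i * 400, i * 400 + 300) for i in range(5)]
        full = scan(PeakSet(peaks), genome, [m], p_threshold=0.01)
        reordered = scan(PeakSet(peaks[::-1]), genome, [m], p_threshold=0.01)
        assert full == reordered
        batched = []
        for p in peaks:
            batched.extend(scan(PeakSet([p]), genome, [m], p_threshold=0.01))
        assert sorted(batched, key=lambda h: (h.motif_id, h.chrom, h.start, h.strand)) == full


def _mock_hits(categories, background, rates, rng, motif_id="m"):
    """Synthesise presence/absence hits at the given per-category rates."""
    hits = []
    for name, ps in {**categories, "background": background}.items():
        rate = rates[name]
        for iv in ps:
            if rng.random() < rate:
                hits.append(MotifHit(motif_id, iv.chrom, iv.start,
                                     min(iv.start + 8, iv.end), "+", 10.0, 1e-5))
    return hits


def _peakset(label, n, offset):
    return PeakSet([GenomicInterval("chr1", offset + i * 1000, offset + i * 1000 + 200,
                                    name=f"{label}{i}") for i in range(n)], label)


class TestCategoryEnrichment:
    def test_planted_enrichment_detected(self):
        rng = np.random.default_rng(1)
        categories = {"SYN": _peakset("s", 200, 0), "TCR": _peakset("t", 200, 10**6)}
        background = _peakset("b", 200, 2 * 10**6)
        hits = _mock_hits(categories, background,
                          {"SYN": 0.8, "TCR": 0.05, "background": 0.05}, rng)
        matrix = motif_category_enrichment(hits, categories, background)
        assert matrix.q.loc["m", "SYN"] < 0.05
        assert matrix.log2_fold.loc["m", "SYN"] > 1
        assert matrix.q.loc["m", "TCR"] > 0.05

    def test_zero_peak_category_is_nan_flagged(self):
        rng = np.random.default_rng(2)
        categories = {"SYN": _peakset("s", 50, 0), "EMPTY": PeakSet(label="EMPTY")}
        background = _peakset("b", 50, 10**6)
        hits = _mock_hits({"SYN": categories["SYN"]}, background,
                          {"SYN": 0.5, "background": 0.5}, rng)
        with pytest.warns(UserWarning, match="zero peaks"):
            matrix = motif_category_enrichment(hits, categories, background)
        assert np.isnan(matrix.log2_fold.loc["m", "EMPTY"])
        assert np.isfinite(matrix.log2_fold.loc["m", "SYN"])

    def test_empty_background_is_error(self):
        with pytest.raises(ValueError, match="background"):
            motif_category_enrichment([], {"SYN": _peakset("s", 5, 0)},
                                      PeakSet(label="bg"))

    def test_invariant_to_background_order(self):
        rng = np.random.default_rng(3)
        categories = {"A": _peakset("a", 40, 0), "B": _peakset("b", 40, 10**6)}
        background = _peakset("g", 60, 2 * 10**6)
        hits = _mock_hits(categories, background,
                          {"A": 0.6, "B": 0.2, "background": 0.3}, rng)
        m1 = motif_category_enrichment(hits, categories, background)
        reversed_bg = PeakSet(list(background)[::-1], label="bg")
        m2 = motif_category_enrichment(hits, categories, reversed_bg)
        pd.testing.assert_frame_equal(m1.p, m2.p)


class TestTfSegregationPca:
    def _block_matrix(self):
        rows = {}
        for b, cat in enumerate(["TCR", "IL2", "SYN"]):
            for i in range(4):
                row = [0.2, 0.2, 0.2]
                row[b] = 3.0
                rows[f"tf_{cat}_{i}"] = row
        return pd.DataFrame(rows, index=["TCR", "IL2", "SYN"]).T

    def test_block_diagonal_assignment(self):
        table = self._block_matrix()
        result = tf_segregation_pca(table)
        for tf, cat in result.assignment.items():
            assert tf.split("_")[1] == cat
        assert result.category_counts.tolist() == [4, 4, 4]

    def test_duplicating_a_row_preserves_assignments(self):
        """Adding a duplicate TF row must not move any TF between
        categories (centring is per motif, across categories)."""
        table = self._block_matrix()
        r1 = tf_segregation_pca(table)
        dup = pd.concat([table, table.iloc[[0]].rename(index={table.index[0]: "dup"})])
        r2 = tf_segregation_pca(dup)
        for tf in table.index:
            assert r2.assignment[tf] == r1.assignment[tf]
        assert r2.assignment["dup"] == r1.assignment[table.index[0]]

    def test_two_by_two_matches_closed_form_eigenvector(self):
        table = pd.DataFrame([[2.0, 0.0], [0.0, 1.0]],
                             index=["tf1", "tf2"], columns=["c1", "c2"])
        result = tf_segregation_pca(table, n_components=1)
        # centred matrix rows are (+/-1, -/+0.5); PC1 direction (2,-1)/sqrt(5)
        load = result.loadings["PC1"].to_numpy()
        expected = np.array([2.0, -1.0]) / np.sqrt(5)
        assert np.allclose(np.abs(load), np.abs(expected), atol=1e-9)

    def test_constant_matrix_is_error(self):
        table = pd.DataFrame(np.ones((3, 3)),
                             index=list("abc"), columns=list("xyz"))
        with pytest.raises(ValueError, match="variance"):
            tf_segregation_pca(table)
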