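"""Mapping contract, RPKM arithmetic, expressed filter and modality QC."""
import numpy as np
import pandas as pd
import pytest

from alomypipe import quant
from alomypipe.quant import (
    BulkMapper,
    ExpressionMatrix,
    MappingParams,
    count_and_rpkm,
    expressed_filter,
    map_read,
    modality_qc,
    rpkm_for_coverage,
)
from conftest import mutate, random_seq


def oracle_map(read, contigs, params):
    """Plain-python exhaustive enumeration of every ungapped placement."""
    import math

    L = len(read)
    min_ov = math.ceil(params.min_aligned_frac * L)
    placements = []
    for cid, seq in contigs.items():
        n = len(seq)
        for off in range(-(L - min_ov), n - min_ov + 1):
            sa, ea = max(0, off), min(n, off + L)
            ov = ea - sa
            if ov < min_ov:
                continue
            mm = sum(
                1 for i in range(sa, ea) if seq[i] != read[i - off]
            )
            score = ov - mm
            if mm <= params.max_mismatches and score >= params.min_score:
                placements.append((cid, off, mm, score))
    if not placements:
        return []
    best = max(p[3] for p in placements)
    return sorted(p for p in placements if p[3] == best)


class TestMapRead:
    def test_exact_substring_single_placement(self, rng):
        contig = random_seq(rng, 300)
        read = contig[57:157]
        out = map_read(read, {"c": contig})
        assert out == [("c", 57, 0, 100, "+")]

    def test_six_mismatches_unmapped(self, rng):
        contig = random_seq(rng, 300)
        read = mutate(rng, contig[50:150], 6)
        assert map_read(read, {"c": contig}) == []

    def test_equal_score_on_redundant_contigs_returns_both(self, rng):
        contig = random_seq(rng, 300)
        read = contig[100:200]
        out = map_read(read, {"c1": contig, "c2": contig})
        assert {p.contig_id for p in out} == {"c1", "c2"}
        assert all(p.score == 100 for p in out)

    def test_matches_brute_force_oracle_on_random_instances(self, rng):
        params = MappingParams()
        for trial in range(100):
            contigs = {
                f"c{j}": random_seq(rng, int(rng.integers(60, 160)))
                for j in range(int(rng.integers(1, 4)))
            }
            for _ in range(10):
                kind = rng.random()
                if kind < 0.4:  # planted (possibly mutated) substring
                    seq = contigs[
                        str(rng.choice(list(contigs)))
                    ]
                    L = int(rng.integers(30, min(61, len(seq))))
                    a = int(rng.integers(0, len(seq) - L + 1))
                    read = seq[a : a + L]
                    if rng.random() < 0.5:
                        read = mutate(rng, read, int(rng.integers(1, 5)))
                else:  # random read
                    read = random_seq(rng, int(rng.integers(30, 61)))
                got = [
                    (p.contig_id, p.position, p.mismatches, p.score)
                    for p in map_read(read, contigs, params)
                ]
                assert got == oracle_map(read, contigs, params)

    def test_min_score_binds_for_short_reads(self, rng):
        contig = random_seq(rng, 100)
        read = contig[10:40]  # 30 nt exact
        strict = MappingParams(min_score=35)
        assert map_read(read, {"c": contig}, strict) == []
        assert map_read(read, {"c": contig}) != []


class TestBulkMapper:
    def test_agrees_with_map_read_on_embedded_reads(self, rng):
        contigs = {f"c{j}": random_seq(rng, 400) for j in range(5)}
        # redundant copy to exercise multi-mapping
        contigs["c_dup"] = contigs["c0"]
        reads = []
        for _ in range(300):
            seq = contigs[str(rng.choice(list(contigs)))]
            a = int(rng.integers(0, len(seq) - 100 + 1))
            read = seq[a : a + 100]
            if rng.random() < 0.6:
                read = mutate(rng, read, int(rng.integers(1, 6)))
            reads.append(read)
        mapper = BulkMapper(contigs, 100)
        ri, ci, sc = mapper.best_placements(reads)
        got = {}
        for r, c, s in zip(ri, ci, sc):
            got.setdefault(int(r), set()).add((mapper.names[c], int(s)))
        for i, read in enumerate(reads):
            expect = {
                (p.contig_id, p.score) for p in map_read(read, contigs)
            }
            assert got.get(i, set()) == expect

    def test_unmappable_reads_absent(self, rng):
        contigs = {"c": random_seq(rng, 300)}
        mapper = BulkMapper(contigs, 100)
        ri, ci, sc = mapper.best_placements([random_seq(rng, 100)])
        assert len(ri) == 0


class TestRpkm:
    def test_direct_formula(self):
        m = ExpressionMatrix(
            counts=pd.DataFrame({"mod": [10, 0]}, index=["a", "b"]),
            lengths=pd.Series({"a": 1000, "b": 500}),
            library_sizes=pd.Series({"mod": 1_000_000}),
        )
        assert m.rpkm.at["a", "mod"] == pytest.approx(10.0)
        assert m.rpkm.at["b", "mod"] == 0.0

    def test_zero_length_contig_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(
                counts=pd.DataFrame({"mod": [1]}, index=["a"]),
                lengths=pd.Series({"a": 0}),
                library_sizes=pd.Series({"mod": 100}),
            )

    def test_rpkm_linearity(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, size=(5, 3)), index=list("abcde"), columns=list("xyz")
        )
        lengths = pd.Series(rng.integers(200, 900, 5), index=list("abcde"))
        sizes = pd.Series([1000, 2000, 1500], index=list("xyz"))
        m1 = ExpressionMatrix(counts, lengths, sizes)
        m2 = ExpressionMatrix(counts * 2, lengths, sizes)
        assert np.allclose(m2.rpkm, m1.rpkm * 2)

    def test_simulated_modality_rpkm_tracks_truth(self, rng):
        """Per-transcript counts from a simulated library, quantified against
        the true transcript sequences, stay within 3 Poisson SD of truth."""
        from alomypipe import simdata

        cfg = simdata.SimConfig(
            n_transcripts=12,
            length_range=(400, 700),
            library_size=20_000,
            seed=31,
            error_rate=0.002,
            het_rate=0.0,
            effect_classes=(),
        )
        trs = simdata.generate_transcripts(cfg)
        mod = cfg.design()[0]
        rs = simdata.simulate_library(trs, mod, cfg)
        contigs = {t.id: t.hapA_seq for t in trs}
        matrix = count_and_rpkm({mod.name: rs.seqs}, contigs)
        expect = simdata.expected_read_counts(trs, mod, cfg)
        for t, mu in zip(trs, expect):
            got = matrix.counts.at[t.id, mod.name]
            assert abs(got - mu) < 3 * np.sqrt(max(mu, 1.0)) + 1


class TestRpkmForCoverage:
    def test_study_depth_reproduces_published_threshold(self):
        # 2x coverage of 100-base reads at the per-library depth of the study
        val = rpkm_for_coverage(2, 100, 159_089_080 / 14)
        assert val == pytest.approx(1.76, abs=0.005)
        assert round(val, 1) == 1.8

    def test_cancellation(self):
        assert rpkm_for_coverage(2, 100, 2e7) == pytest.approx(1.0)

    def test_length_independence(self, rng):
        # a contig with exactly c-fold coverage has RPKM independent of length
        c, rl, N = 3.0, 100, 5e6
        for L in (300, 1000, 4135):
            reads = c * L / rl
            rpkm = reads * 1e9 / (N * L)
            assert rpkm == pytest.approx(rpkm_for_coverage(c, rl, N))


class TestExpressedFilter:
    @pytest.mark.parametrize(
        "max_rpkm,kept", [(1.8, True), (1.79, False), (0.0, False), (200.0, True)]
    )
    def test_threshold_boundary(self, max_rpkm, kept):
        counts = pd.DataFrame({"m1": [1], "m2": [0]}, index=["c"])
        lengths = pd.Series({"c": 1000})
        # library size chosen so that RPKM(m1) == max_rpkm
        n = 1e9 / (1000 * max_rpkm) if max_rpkm else 1e6
        m = ExpressionMatrix(counts, lengths, pd.Series({"m1": n, "m2": n}))
        assert (("c" in expressed_filter(m)) == kept) or max_rpkm == 0.0
        if max_rpkm == 0.0:
            counts0 = pd.DataFrame({"m1": [0]}, index=["c"])
            m0 = ExpressionMatrix(counts0, lengths, pd.Series({"m1": 1e6}))
            assert "c" not in expressed_filter(m0)


class TestModalityQC:
    def make_matrix(self, fractions, n_contigs=200):
        rng = np.random.default_rng(5)
        cols = {}
        for j, f in enumerate(fractions):
            col = np.zeros(n_contigs, dtype=int)
            k = int(round(f * n_contigs))
            col[rng.choice(n_contigs, k, replace=False)] = 5
            cols[f"m{j}"] = col
        counts = pd.DataFrame(cols, index=[f"c{i}" for i in range(n_contigs)])
        lengths = pd.Series(500, index=counts.index)
        sizes = pd.Series(10_000, index=counts.columns)
        return ExpressionMatrix(counts, lengths, sizes)

    def test_equal_fractions_unflagged(self):
        qc = modality_qc(self.make_matrix([0.9] * 6))
        assert qc.flagged == ()

    def test_half_coverage_modality_flagged(self):
        qc = modality_qc(self.make_matrix([0.9, 0.9, 0.9, 0.9, 0.9, 0.5]))
        assert qc.flagged == ("m5",)

    def test_high_outlier_not_flagged_as_low(self):
        qc = modality_qc(self.make_matrix([0.5, 0.5, 0.5, 0.5, 0.5, 0.95]))
        assert qc.flagged == ()

    def test_too_few_modalities_skipped(self):
        with pytest.warns(UserWarning):
            qc = modality_qc(self.make_matrix([0.9, 0.5]))
        assert qc.skipped and qc.flagged == ()
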