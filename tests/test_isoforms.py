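"""Gene assignment, quantification, major-isoform matching and dynamics."""

import numpy as np
import pandas as pd
import pytest

from rcatseq.annotation import GeneModel
from rcatseq.isoforms import (
    Novelty,
    assign_peaks,
    call_major_isoforms,
    classify_novelty,
    compare_isoform_expression,
    detect_switches,
    quantify,
    stage_ratios,
)
from rcatseq.peaks import TagCluster
from rcatseq.read_ends import EndType


def make_peak(pid, pos, strand="+", chrom="c", end_type=EndType.TSS_5p, width=1):
    return TagCluster(pid, chrom, strand, pos, pos + width, pos, 1.0, 1.0, 1, end_type)


GENE = GeneModel("gA", "c", "+", tss_sites=(10000,), tes_sites=(14000,))


class TestAssignPeaks:
    def test_peak_1500bp_upstream_is_assigned(self):
        (a,) = assign_peaks([make_peak("p", 10000 - 1500)], [GENE])
        assert a.gene_id == "gA"

    def test_peak_2001bp_upstream_is_unassigned(self):
        (a,) = assign_peaks([make_peak("p", 10000 - 2001)], [GENE])
        assert a.gene_id is None

    def test_boundary_2000bp_is_assigned(self):
        (a,) = assign_peaks([make_peak("p", 10000 - 2000)], [GENE])
        assert a.gene_id == "gA"

    def test_strand_must_match(self):
        (a,) = assign_peaks([make_peak("p", 12000, strand="-")], [GENE])
        assert a.gene_id is None

    def test_overlap_tie_broken_by_nearest_end(self):
        g1 = GeneModel("g1", "c", "+", (10000,), (12000,))
        g2 = GeneModel("g2", "c", "+", (13000,), (15000,))
        # peak between the genes, inside both 2 kb windows, nearer g2's TSS
        (a,) = assign_peaks([make_peak("p", 12800)], [g1, g2])
        assert a.gene_id == "g2"

    def test_matches_interval_containment_oracle(self, rng):
        genes = []
        for i in range(25):
            s = int(rng.integers(0, 200000))
            genes.append(
                GeneModel(
                    f"g{i}", "c", str(rng.choice(["+", "-"])),
                    (s,), (s + int(rng.integers(1000, 4000)),),
                )
            )
        peaks = [
            make_peak(f"p{i}", int(rng.integers(0, 210000)), str(rng.choice(["+", "-"])))
            for i in range(300)
        ]
        got = {a.peak_id: a.gene_id for a in assign_peaks(peaks, genes)}
        for p in peaks:
            candidates = []
            for g in genes:
                s, e = g.span
                if g.strand == p.strand and s - 2000 <= p.dominant_pos < e + 2000:
                    d = min(abs(p.dominant_pos - x) for x in g.tss_sites)
                    candidates.append((d, g.gene_id))
            expected = min(candidates)[1] if candidates else None
            assert got[p.peak_id] == expected


class TestNovelty:
    def test_three_bp_from_annotated_tss_is_known(self):
        peaks = [make_peak("p", 10003)]
        a = assign_peaks(peaks, [GENE])
        assert classify_novelty(a, peaks, [GENE])["p"] is Novelty.known_end

    def test_distant_assigned_peak_is_novel_end(self):
        peaks = [make_peak("p", 10500)]
        a = assign_peaks(peaks, [GENE])
        assert classify_novelty(a, peaks, [GENE])["p"] is Novelty.novel_end_known_gene

    def test_unassigned_peak_is_novel_gene(self):
        peaks = [make_peak("p", 50000)]
        a = assign_peaks(peaks, [GENE])
        assert classify_novelty(a, peaks, [GENE])["p"] is Novelty.novel_gene

    def test_matches_nearest_end_oracle(self, rng):
        genes = [
            GeneModel(f"g{i}", "c", "+", (int(s),), (int(s) + 3000,))
            for i, s in enumerate(rng.integers(0, 100000, size=10))
        ]
        peaks = [make_peak(f"p{i}", int(rng.integers(0, 110000))) for i in range(200)]
        a = assign_peaks(peaks, genes)
        got = classify_novelty(a, peaks, genes, tolerance=50)
        gene_of = {x.peak_id: x.gene_id for x in a}
        for p in peaks:
            gid = gene_of[p.peak_id]
            if gid is None:
                expected = Novelty.novel_gene
            else:
                g = next(x for x in genes if x.gene_id == gid)
                d = min(abs(p.dominant_pos - x) for x in g.tss_sites)
                expected = Novelty.known_end if d <= 50 else Novelty.novel_end_known_gene
            assert got[p.peak_id] is expected


def ends_frame(rows):
    """rows: (pos, sample, barcode, umi) on chr c, + strand, TSS reads."""
    return pd.DataFrame(
        {
            "read_id": [f"r{i}" for i in range(len(rows))],
            "chrom": "c",
            "pos": [r[0] for r in rows],
            "strand": "+",
            "end_type": EndType.TSS_5p.value,
            "sample_id": [r[1] for r in rows],
            "cell_barcode": [r[2] for r in rows],
            "umi": [r[3] for r in rows],
        }
    )


class TestQuantify:
    def test_umi_mode_collapses_duplicates(self):
        peaks = [make_peak("p", 100, width=10)]
        ends = ends_frame(
            [(102, "s", "BC1", "U1"), (103, "s", "BC1", "U1"), (104, "s", "BC1", "U2")]
        )
        reads, _ = quantify(peaks, ends, mode="reads")
        umis, _ = quantify(peaks, ends, mode="umi")
        assert reads["count"].iloc[0] == 3
        assert umis["count"].iloc[0] == 2

    def test_rpm_sums_to_one_million_per_population(self, rng):
        peaks = [make_peak(f"p{i}", 100 * i, width=10) for i in range(1, 8)]
        rows = [
            (int(rng.integers(100, 800)), f"s{rng.integers(0, 2)}", "BC", f"U{i}")
            for i in range(500)
        ]
        expr, _ = quantify(peaks, ends_frame(rows))
        sums = expr.groupby("population")["rpm"].sum()
        for v in sums:
            assert v == pytest.approx(1e6)

    def test_conservation_of_end_counts(self, rng):
        peaks = [make_peak("p1", 100, width=10), make_peak("p2", 300, width=10)]
        rows = [(int(rng.integers(0, 500)), "s", "BC", f"U{i}") for i in range(300)]
        expr, unassigned = quantify(peaks, ends_frame(rows))
        assert expr["count"].sum() + unassigned.sum() == 300

    def test_reads_equal_umis_without_pcr_duplication(self):
        from dataclasses import replace

        from rcatseq.peaks import EndCountTrack, call_peaks
        from rcatseq.simulate import (
            SimulationConfig,
            simulate_end_reads,
            simulate_genome_and_genes,
        )

        config = SimulationConfig(
            seed=9, n_genes=10, genome_length=50000, cells_per_population=20,
            reads_per_cell=50, pcr_duplication_rate=0.0,
        )
        _, genes, truth = simulate_genome_and_genes(config)
        ends, truth = simulate_end_reads(config, genes, truth)
        sub = ends[ends["end_type"] == EndType.TSS_5p.value]
        peaks = call_peaks(EndCountTrack.from_ends(sub), end_type=EndType.TSS_5p)
        reads, _ = quantify(peaks, sub, mode="reads")
        umis, _ = quantify(peaks, sub, mode="umi")
        r = np.corrcoef(reads["count"], umis["count"])[0, 1]
        assert r == pytest.approx(1.0)


def expr_table(rows):
    """rows: (peak_id, population, count)."""
    df = pd.DataFrame(rows, columns=["peak_id", "population", "count"])
    totals = df.groupby("population")["count"].transform("sum")
    df["rpm"] = df["count"] * 1e6 / totals
    return df


class TestMajorIsoforms:
    def _setup(self):
        peaks = [
            make_peak("t1", 1000, end_type=EndType.TSS_5p),
            make_peak("t2", 1500, end_type=EndType.TSS_5p),
            make_peak("e1", 5000, end_type=EndType.TES_3p),
        ]
        genes = [GeneModel("g", "c", "+", (1000, 1500), (5000,))]
        assignments = assign_peaks(peaks, genes)
        return peaks, genes, assignments

    def test_single_pair_gene(self):
        peaks, _, assignments = self._setup()
        expr = expr_table([("t1", "A", 10), ("e1", "A", 10)])
        (call,) = call_major_isoforms(expr, assignments, peaks, "A")
        assert (call.major_tss, call.major_tes) == (1000, 5000)

    def test_higher_rpm_wins(self):
        peaks, _, assignments = self._setup()
        expr = expr_table([("t1", "A", 10), ("t2", "A", 30), ("e1", "A", 20)])
        (call,) = call_major_isoforms(expr, assignments, peaks, "A")
        assert call.major_tss == 1500
        assert call.tss_peak_id == "t2"

    def test_tie_breaks_to_5prime(self):
        peaks, _, assignments = self._setup()
        expr = expr_table([("t1", "A", 10), ("t2", "A", 10), ("e1", "A", 5)])
        (call,) = call_major_isoforms(expr, assignments, peaks, "A")
        assert call.major_tss == 1000

    def test_matches_argmax_oracle(self, rng):
        peaks, _, assignments = self._setup()
        for _ in range(30):
            c1, c2, c3 = (int(x) for x in rng.integers(1, 100, size=3))
            expr = expr_table([("t1", "A", c1), ("t2", "A", c2), ("e1", "A", c3)])
            (call,) = call_major_isoforms(expr, assignments, peaks, "A")
            expected = 1000 if c1 >= c2 else 1500
            assert call.major_tss == expected


def iso_call(gene, pop, tss, tes):
    from rcatseq.isoforms import IsoformCall

    return IsoformCall(gene, pop, tss, tes, "tp", "ep", 10.0, 10.0)


class TestSwitches:
    def test_identical_majors_is_none(self):
        t = detect_switches([iso_call("g", "A", 100, 5000)], [iso_call("g", "B", 100, 5000)])
        assert list(t["category"]) == ["none"]

    def test_tss_switch_with_common_tes(self):
        t = detect_switches(
            [iso_call("g", "A", 1000, 5000)], [iso_call("g", "B", 6000, 5030)]
        )
        assert list(t["category"]) == ["TSS_switch"]

    def test_direction_relative_to_gene_center(self):
        genes = [GeneModel("g", "c", "+", (0, 2000), (10000,))]  # center ~5000
        t = detect_switches(
            [iso_call("g", "A", 0, 10000)], [iso_call("g", "B", 2000, 10000)], genes
        )
        assert t["tss_direction"].iloc[0] == "proximal"
        t2 = detect_switches(
            [iso_call("g", "A", 2000, 10000)], [iso_call("g", "B", 0, 10000)], genes
        )
        assert t2["tss_direction"].iloc[0] == "distal"

    def test_matches_rule_oracle_on_random_calls(self, rng):
        tol = 100
        for _ in range(100):
            tss_a, tes_a = int(rng.integers(0, 3000)), int(rng.integers(5000, 8000))
            tss_b, tes_b = int(rng.integers(0, 3000)), int(rng.integers(5000, 8000))
            t = detect_switches(
                [iso_call("g", "A", tss_a, tes_a)],
                [iso_call("g", "B", tss_b, tes_b)],
                same_end_tolerance=tol,
            )
            tss_m, tes_m = abs(tss_a - tss_b) > tol, abs(tes_a - tes_b) > tol
            expected = (
                "both" if tss_m and tes_m
                else "TSS_switch" if tss_m
                else "TES_switch" if tes_m
                else "none"
            )
            assert t["category"].iloc[0] == expected


class TestStageRatios:
    def _ends(self, rows):
        """rows: (pos, barcode)."""
        return pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(len(rows))],
                "chrom": "c",
                "pos": [r[0] for r in rows],
                "strand": "+",
                "end_type": EndType.TSS_5p.value,
                "sample_id": "s",
                "cell_barcode": [r[1] for r in rows],
                "umi": "U",
            }
        )

    def test_equal_counts_give_zero_ratio(self):
        rows = [(100, "BC1")] * 5 + [(900, "BC1")] * 5
        s = stage_ratios(self._ends(rows), {"BC1": 1}, "c", "+", EndType.TSS_5p, 100, 900)
        assert s.ratios[0] == 0.0

    def test_eight_vs_two_with_unit_pseudocount(self):
        rows = [(100, "BC1")] * 8 + [(900, "BC1")] * 2
        s = stage_ratios(self._ends(rows), {"BC1": 1}, "c", "+", EndType.TSS_5p, 100, 900)
        assert s.ratios[0] == pytest.approx(np.log2(3))

    def test_default_series_has_six_stages(self):
        s = stage_ratios(self._ends([]), {}, "c", "+", EndType.TSS_5p, 100, 900)
        assert len(s.ratios) == 6


class TestDifferentialExpression:
    def test_identical_groups_give_zero_fold_change(self):
        a = pd.DataFrame([[5.0, 5.0, 5.0]], index=["iso1"])
        out = compare_isoform_expression(a, a.copy())
        assert out.loc["iso1", "log2_fc"] == 0.0
        assert out.loc["iso1", "pvalue"] == 1.0

    def test_bh_stepup_worked_example(self, monkeypatch):
        # p = (.01,.02,.03,.04), m=4 -> all q = .04 by the step-up procedure
        from statsmodels.stats.multitest import multipletests

        q = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_q_monotone_in_p_and_detects_shift(self, rng):
        n_iso, n_cells = 15, 12
        a = pd.DataFrame(rng.random((n_iso, n_cells)), index=[f"i{k}" for k in range(n_iso)])
        b = a + 0.0
        b.iloc[0] = a.iloc[0] + 5.0  # one clearly shifted isoform
        out = compare_isoform_expression(a, b)
        srt = out.sort_values("pvalue")
        assert srt["qvalue"].is_monotonic_increasing
        assert out["pvalue"].idxmin() == "i0"
        assert out.loc["i0", "log2_fc"] < 0
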