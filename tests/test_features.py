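"""IUPAC motif scanning, feature groups, and normalization."""

import numpy as np
import pandas as pd
import pytest

from _oracles import encode_batch, hamming_matches, hamming_mismatch_batch
from rcatseq.features import (
    DEFAULT_MOTIFS,
    Normalizer,
    artifact_features,
    assemble_features,
    distribution_features,
    scan_motif,
    tes_motif_features,
    tss_motif_features,
)
from rcatseq.io import GenomeSource, revcomp
from rcatseq.peaks import TagCluster
from rcatseq.read_ends import EndType


def peak(pos, strand="+", end_type=EndType.TSS_5p, chrom="c", width=1,
         dominant=10.0, total=10.0, n_positions=1, peak_id="p0"):
    return TagCluster(
        peak_id=peak_id, chrom=chrom, strand=strand, start=pos,
        end=pos + width, dominant_pos=pos, dominant_signal=dominant,
        total_signal=total, n_positions=n_positions, end_type=EndType(end_type),
    )


class TestScanMotif:
    def test_exact_tata_match(self):
        hits = scan_motif("TATAAAAG", "TATAWAWR", 0)
        assert list(hits) == [1]

    def test_no_pas_in_c_run(self):
        assert scan_motif("CCCCCCCC", "AATAAA", 0).sum() == 0

    def test_short_sequence_gives_empty_vector(self):
        assert scan_motif("ACG", "AATAAA", 0).size == 0

    def test_invalid_pattern_character_raises(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGT", "AXGT", 0)

    def test_invalid_sequence_character_raises(self):
        with pytest.raises(ValueError):
            scan_motif("ACZT", "AATAAA", 0)

    def test_n_in_sequence_never_matches(self):
        assert scan_motif("NNNNNN", "NNNNNN", 0).sum() == 0

    def test_saturation_at_pattern_length_mismatches(self):
        hits = scan_motif("CCCCCCCCCC", "TATAWAWR", 8)
        assert hits.sum() == hits.size == 3

    def test_matches_hamming_oracle_on_random_sequences(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=60)) for _ in range(300)]
        mat = encode_batch(seqs)
        patterns = [p for _, p in DEFAULT_MOTIFS.tss_motifs] + list(
            DEFAULT_MOTIFS.tes_motifs
        )
        for pat in patterns:
            mism = hamming_mismatch_batch(mat, pat)
            for mm in (0, 1, 2):
                expected = (mism <= mm).astype(np.int8)
                got = np.vstack([scan_motif(s, pat, mm) for s in seqs])
                np.testing.assert_array_equal(got, expected)

    def test_slow_and_batch_oracles_agree(self, rng):
        seqs = ["".join(rng.choice(list("ACGT"), size=30)) for _ in range(20)]
        mism = hamming_mismatch_batch(encode_batch(seqs), "TATAWAWR")
        for i, s in enumerate(seqs):
            assert list((mism[i] <= 1).astype(int)) == hamming_matches(s, "TATAWAWR", 1)


def _plant(background, offset_upstream, motif, pos, strand, length=400):
    """Genome with ``motif`` starting ``offset_upstream`` nt upstream of
    ``pos`` in transcript orientation."""
    seq = list(background * (length // len(background) + 1))[:length]
    if strand == "+":
        start = pos - offset_upstream
        seq[start : start + len(motif)] = motif
    else:
        start = pos + offset_upstream - len(motif) + 1
        seq[start : start + len(motif)] = revcomp(motif)
    return GenomeSource({"c": "".join(seq)})


class TestMotifFeatures:
    def test_planted_tata_at_offset_30(self):
        from rcatseq.features import MotifSet

        genome = _plant("CG", 30, "TATATATA", pos=200, strand="+")
        # exact matching isolates the planted occurrence (mismatch tolerance
        # legitimately lights up shifted offsets overlapping the plant)
        vec = tss_motif_features(genome, peak(200), MotifSet(max_mismatch=0))
        tata = vec[[f"TATA_up{k:02d}" for k in range(1, 51)]]
        assert tata["TATA_up30"] == 1
        assert tata.sum() == 1
        assert len(vec) == 150

    def test_minus_strand_uses_reverse_complement_window(self):
        genome = _plant("CG", 30, "TATATATA", pos=200, strand="-")
        vec = tss_motif_features(genome, peak(200, strand="-"))
        assert vec["TATA_up30"] == 1

    def test_planted_pas_at_offset_20(self):
        for strand in "+-":
            genome = _plant("CG", 20, "AATAAA", pos=200, strand=strand)
            vec = tes_motif_features(genome, peak(200, strand, EndType.TES_3p))
            assert vec["AATAAA_up20"] == 1
            assert len(vec) == 650

    def test_all_c_window_is_all_zero(self):
        genome = GenomeSource({"c": "C" * 400})
        vec = tes_motif_features(genome, peak(200, "+", EndType.TES_3p))
        assert vec.sum() == 0

    def test_contig_edge_padding_keeps_length(self):
        genome = GenomeSource({"c": "ACGT" * 100})
        vec = tss_motif_features(genome, peak(5))  # window extends past the edge
        assert len(vec) == 150
        assert not vec.isna().any()

    def test_centered_tes_window_mode(self):
        genome = GenomeSource({"c": "C" * 175 + "AATAAA" + "C" * 219})
        # motif downstream of the cleavage site: only the centered window sees it
        up = tes_motif_features(genome, peak(170, "+", EndType.TES_3p), window_mode="upstream")
        cen = tes_motif_features(genome, peak(170, "+", EndType.TES_3p), window_mode="centered")
        assert up.sum() == 0
        assert cen.sum() == 1


class TestDistributionFeatures:
    def test_single_position_peak(self):
        f = distribution_features(peak(100))
        assert f["width"] == 1
        assert f["dominant_fraction"] == 1.0
        assert f["gene_rel_pos"] == 0.5  # unassigned

    def test_dominant_fraction_half(self):
        p = peak(100, width=5, dominant=30.0, total=60.0, n_positions=3)
        assert distribution_features(p)["dominant_fraction"] == 0.5

    def test_gene_relative_position_is_strand_aware(self):
        p_plus = peak(150)
        p_minus = peak(150, strand="-")
        span = (100, 201)
        assert distribution_features(p_plus, span)["gene_rel_pos"] == 0.5
        assert distribution_features(peak(100), span)["gene_rel_pos"] == 0.0
        assert distribution_features(peak(100, strand="-"), span)["gene_rel_pos"] == 1.0
        assert distribution_features(p_minus, span)["gene_rel_pos"] == 0.5


class TestArtifactFeatures:
    def test_full_a_window_downstream_of_tes(self):
        genome = GenomeSource({"c": "C" * 201 + "A" * 20 + "C" * 179})
        f = artifact_features(genome, peak(200, "+", EndType.TES_3p))
        assert f["downstream_a_fraction"] == 1.0
        assert f["downstream_a_run"] == 1.0
        assert f["internal_priming_flag"] == 1.0

    def test_twelve_of_twenty_a_hits_flag_threshold(self):
        down = "A" * 12 + "C" * 8
        genome = GenomeSource({"c": "C" * 201 + down + "C" * 179})
        f = artifact_features(genome, peak(200, "+", EndType.TES_3p))
        assert f["downstream_a_fraction"] == pytest.approx(0.6)
        assert f["internal_priming_flag"] == 1.0  # >= is inclusive

    def test_minus_strand_reads_transcript_orientation(self):
        # genomic T-run left of the site is an A-run downstream on -
        genome = GenomeSource({"c": "C" * 180 + "T" * 20 + "C" * 200})
        f = artifact_features(genome, peak(200, "-", EndType.TES_3p))
        assert f["downstream_a_fraction"] == 1.0

    def test_tss_ggg_flag(self):
        genome = GenomeSource({"c": "C" * 200 + "GGG" + "C" * 197})
        f = artifact_features(genome, peak(200, "+", EndType.TSS_5p))
        assert f["site_ggg_flag"] == 1.0
        assert f["site_g_fraction"] == 1.0
        assert f["upstream_c_fraction"] == 1.0


class TestNormalizationAndAssembly:
    def _random_peaks(self, rng, n, end_type):
        prefix = "t"
        out = []
        for i in range(n):
            pos = int(rng.integers(100, 1900))
            total = float(rng.uniform(1, 1000))
            dom = float(rng.uniform(0.1, 1.0)) * total
            w = int(rng.integers(1, 15))
            out.append(
                TagCluster(
                    peak_id=f"{prefix}{i}", chrom="c", strand=str(rng.choice(["+", "-"])),
                    start=pos, end=pos + w, dominant_pos=pos, dominant_signal=dom,
                    total_signal=total, n_positions=int(rng.integers(1, w + 1)),
                    end_type=end_type,
                )
            )
        return out

    def test_values_in_unit_interval_and_dimensions(self, rng):
        genome = GenomeSource({"c": "".join(rng.choice(list("ACGT"), size=2000))})
        for end_type, width in ((EndType.TSS_5p, 150), (EndType.TES_3p, 650)):
            fm = assemble_features(self._random_peaks(rng, 25, end_type), genome, end_type)
            assert fm.motif_block_width == width
            assert ((fm.X >= 0) & (fm.X <= 1)).all().all()
            assert not fm.X.isna().any().any()

    def test_stored_normalization_reproduces_training_matrix(self, rng):
        genome = GenomeSource({"c": "".join(rng.choice(list("ACGT"), size=2000))})
        pks = self._random_peaks(rng, 20, EndType.TES_3p)
        fm = assemble_features(pks, genome, EndType.TES_3p)
        fm2 = assemble_features(pks, genome, EndType.TES_3p, normalizer=fm.normalizer)
        pd.testing.assert_frame_equal(fm.X, fm2.X)

    def test_constant_minmax_column_maps_to_zero(self):
        df = pd.DataFrame({"width": [3.0, 3.0, 3.0], "flag": [0.0, 1.0, 0.0]})
        norm = Normalizer().fit(df)
        out = norm.transform(df)
        assert (out["width"] == 0.0).all()
        assert list(out["flag"]) == [0.0, 1.0, 0.0]

    def test_duplicate_peak_ids_rejected(self, rng):
        genome = GenomeSource({"c": "ACGT" * 500})
        p1 = peak(200, peak_id="dup")
        p2 = peak(300, peak_id="dup")
        with pytest.raises(ValueError, match="duplicate"):
            assemble_features([p1, p2], genome, EndType.TSS_5p)

    def test_missing_contig_is_hard_error(self):
        genome = GenomeSource({"other": "ACGT" * 200})
        with pytest.raises(KeyError):
            assemble_features([peak(200)], genome, EndType.TSS_5p)

    def test_strand_antisymmetry(self, rng):
        L = 2000
        seq = "".join(rng.choice(list("ACGT"), size=L))
        genome = GenomeSource({"c": seq})
        mirror = GenomeSource({"c": revcomp(seq)})
        for end_type in (EndType.TSS_5p, EndType.TES_3p):
            p_fwd = TagCluster("p", "c", "+", 800, 805, 802, 5.0, 9.0, 3, end_type)
            p_rev = TagCluster(
                "p", "c", "-", L - 805, L - 800, L - 1 - 802, 5.0, 9.0, 3, end_type
            )
            fm_fwd = assemble_features([p_fwd], genome, end_type)
            fm_rev = assemble_features([p_rev], mirror, end_type)
            pd.testing.assert_frame_equal(fm_fwd.X, fm_rev.X)

    def test_save_load_roundtrip(self, rng, tmp_path):
        genome = GenomeSource({"c": "".join(rng.choice(list("ACGT"), size=2000))})
        fm = assemble_features(self._random_peaks(rng, 10, EndType.TSS_5p), genome, EndType.TSS_5p)
        path = tmp_path / "X.tsv"
        fm.save(path)
        from rcatseq.features import FeatureMatrix

        fm2 = FeatureMatrix.load(path)
        pd.testing.assert_frame_equal(fm.X, fm2.X)
        assert fm2.groups == fm.groups
        out = fm2.normalizer.transform(fm.normalizer.transform(fm.X) * 0 + fm.X)
        assert out.shape == fm.X.shape
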