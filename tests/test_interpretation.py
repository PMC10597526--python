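"""Importance tracks, masking, metagenes, motif windows and perturbations."""

import numpy as np
import pytest

from rnacoding.attribution import MutationEffectMatrix
from rnacoding.interpretation import (
    ImportanceTrack,
    binned_metagene,
    build_control_set,
    codon_shuffle,
    dinucleotide_shuffle,
    extract_motif_windows,
    importance_track,
    mask_canonical,
    metagene,
    nonsense_bin_means,
    partition_regions,
    perturb_and_score,
    write_windows_fasta,
)
from rnacoding.model import ModelConfig, init_params
from rnacoding.sequences import STOP_CODONS, Transcript, translate

CFG = ModelConfig(window_length=6, hidden_dim=8, n_heads=2,
                  n_encoder_layers=1, n_decoder_layers=1)


def _mem(values, seq):
    return MutationEffectMatrix(np.asarray(values, dtype=float), seq, method="ism")


class TestImportanceTrack:
    def test_zero_matrix(self):
        t = importance_track(_mem(np.zeros((4, 3)), "ACGU"), "up_PC")
        assert np.allclose(t.values, 0)

    def test_hand_row(self):
        vals = np.zeros((1, 3))
        vals[0] = [-2.0, -1.0, 3.0]
        up_pc = importance_track(_mem(vals, "A"), "up_PC")
        up_nc = importance_track(_mem(vals, "A"), "up_NC")
        assert up_pc.values[0] == pytest.approx(2.0)
        assert up_nc.values[0] == pytest.approx(3.0)

    def test_negation_swaps_directions(self):
        vals = np.random.RandomState(0).randn(6, 3)
        seq = "ACGUAC"
        a = importance_track(_mem(vals, seq), "up_PC").values
        b = importance_track(_mem(-vals, seq), "up_NC").values
        assert np.allclose(a, b)

    def test_bad_direction(self):
        with pytest.raises(ValueError):
            importance_track(_mem(np.zeros((1, 3)), "A"), "sideways")


class TestMaskCanonical:
    def test_start_stop_and_nonsense_masked(self):
        # AUG AAA AAA UAA: position 3 (A, codon AAA) mutated to U creates UAA
        seq = "AUGAAAAAAUAA"
        t = Transcript("t", seq, "PC", cds=(0, 12), protein="MKK")
        vals = np.zeros((12, 3))
        # at position 3 the strongest up_NC mutation is U (alt order C,G,U for ref A)
        vals[3] = [0.0, 0.0, 5.0]
        # at position 4 (middle of codon): no substitution can create a stop
        vals[4] = [4.0, 0.0, 0.0]
        m = _mem(vals, seq)
        track = mask_canonical(importance_track(m, "up_NC"), t, m)
        assert track.mask[:3].all()      # start codon
        assert track.mask[9:].all()      # stop codon
        assert track.mask[3]             # nonsense-creating argmax
        assert not track.mask[4]         # missense argmax left unmasked

    def test_masked_maximum_moves(self):
        seq = "AUGAAAAAAUAA"
        t = Transcript("t", seq, "PC", cds=(0, 12), protein="MKK")
        vals = np.zeros((12, 3))
        vals[0] = [9.0, 9.0, 9.0]   # maximum on the start codon
        vals[5] = [1.0, 0.0, 0.0]
        m = _mem(vals, seq)
        track = mask_canonical(importance_track(m, "up_NC"), t, m)
        assert track.masked_argmax() == 5

    def test_no_orf_no_mask(self):
        t = Transcript("t", "CCCCCCCCC", "NC")
        m = _mem(np.ones((9, 3)), t.sequence)
        track = mask_canonical(importance_track(m, "up_NC"), t, m)
        assert not track.mask.any()

    def test_masked_argmax_never_masked(self):
        rng = np.random.RandomState(0)
        seq = "GGAUGAAACCCGGGUAAGG"
        t = Transcript("t", seq, "PC", cds=(2, 17), protein="MKPG")
        for _ in range(10):
            m = _mem(rng.randn(len(seq), 3), seq)
            track = mask_canonical(importance_track(m, "up_PC"), t, m)
            peak = track.masked_argmax()
            if peak is not None:
                assert not track.mask[peak]


class TestRegions:
    def test_mrna_partition(self):
        t = Transcript("t", "GGAUGAAAUAACC", "PC", cds=(2, 11), protein="MK")
        p = partition_regions(t)
        assert p.intervals == [("utr5", 0, 2), ("cds", 2, 11), ("utr3", 11, 13)]

    def test_lncrna_uses_longest_orf(self):
        seq = "CCAUGAAAUAGCC"
        t = Transcript("t", seq, "NC")
        p = partition_regions(t)
        assert p.get("orf") == (2, 11)
        assert p.anchored_on == "longest_orf"


class TestMetagene:
    def test_single_series_identity(self):
        s = np.arange(5.0)
        prof = metagene([s], [2], coverage_threshold=0.5)
        assert np.allclose(prof.mean, s)
        assert list(prof.positions) == [-2, -1, 0, 1, 2]

    def test_two_series_mean(self):
        a, b = np.ones(4), np.full(4, 3.0)
        prof = metagene([a, b], [0, 0], coverage_threshold=1.0)
        assert np.allclose(prof.mean, 2.0)

    def test_coverage_threshold_counting(self):
        # ten series; a relative position present in 6 of 10 is dropped, 7 kept
        series = [np.ones(7)] * 7 + [np.ones(6)] * 3
        prof = metagene(series, [0] * 10, coverage_threshold=0.7)
        assert 6 in prof.positions      # present in 7 series -> kept
        assert 5 in prof.positions
        series = [np.ones(7)] * 6 + [np.ones(6)] * 4
        prof = metagene(series, [0] * 10, coverage_threshold=0.7)
        assert 6 not in prof.positions  # present in only 6 series -> dropped


class TestBinnedMetagene:
    def test_constant_values(self):
        m = _mem(np.full((50, 3), 2.5), "A" * 50)
        prof = binned_metagene([m], n_bins=25)
        assert np.allclose(prof.mean, 2.5)

    def test_bin_index_arithmetic(self):
        # length 50, 25 bins: positions 0-1 in bin 0, 2-3 in bin 1, ...
        vals = np.repeat(np.arange(50.0)[:, None], 3, axis=1)
        prof = binned_metagene([_mem(vals, "A" * 50)], n_bins=25)
        expected = [(2 * b + 2 * b + 1) / 2 for b in range(25)]
        assert np.allclose(prof.mean, expected)

    def test_bins_equal_length_width_one(self):
        vals = np.repeat(np.arange(10.0)[:, None], 3, axis=1)
        prof = binned_metagene([_mem(vals, "A" * 10)], n_bins=10)
        assert np.allclose(prof.mean, np.arange(10.0))


def _tracked_transcript(idx=0, peak=30):
    rng = np.random.RandomState(idx)
    n_cod = 20
    seq = "GC" * 12 + "AUG" + "".join(rng.choice(["AAA", "GGA", "CCA"]) for _ in range(n_cod)) + "UAA" + "AU" * 12
    cds = (24, 24 + 3 * (n_cod + 2))
    t = Transcript(f"t{idx}", seq, "PC", cds=cds, protein=translate(seq[cds[0] : cds[1] - 3]))
    values = rng.rand(len(seq))
    values[peak] = 10.0
    track = ImportanceTrack(values=values, direction="up_PC",
                            mask=np.zeros(len(seq), dtype=bool), sequence=seq)
    return t, track


class TestMotifWindows:
    def test_windows_are_21nt_and_centered(self):
        t, track = _tracked_transcript(0, peak=40)
        windows = extract_motif_windows({t.id: track}, [t], window_flank=10)
        assert windows
        for w in windows:
            assert w.end - w.start == 21
            assert len(w.sequence) == 21
            assert w.sequence == t.sequence[w.start : w.end]

    def test_tie_breaks_five_prime(self):
        t, track = _tracked_transcript(1, peak=40)
        track.values[:] = 1.0  # all tied: argmax must be the 5'-most in each region
        windows = extract_motif_windows({t.id: track}, [t], window_flank=10)
        part = partition_regions(t)
        for w in windows:
            s, e = part.get(w.region)
            assert w.start == s

    def test_short_region_skipped(self):
        t = Transcript("t", "GGAUGAAACCCAAAUAACC", "PC", cds=(2, 17), protein="MKPK")
        track = ImportanceTrack(np.ones(len(t)), "up_PC", np.zeros(len(t), dtype=bool), t.sequence)
        windows = extract_motif_windows({t.id: track}, [t], window_flank=10)
        assert windows == []  # every region is shorter than 21 nt

    def test_strategy1_controls_never_overlap(self):
        items = [_tracked_transcript(i, peak=40 + i) for i in range(6)]
        transcripts = [t for t, _ in items]
        tracks = {t.id: tr for t, tr in items}
        primaries = extract_motif_windows(tracks, transcripts, window_flank=10)
        controls = build_control_set(1, primaries, transcripts, seed=0)
        by_key = {(w.transcript_id, w.region): w for w in primaries}
        for c in controls:
            p = by_key[(c.transcript_id, c.region)]
            assert c.end <= p.start or c.start >= p.end  # exhaustive interval check
            assert c.end - c.start == 21

    def test_strategy2_requires_opposite(self):
        with pytest.raises(ValueError):
            build_control_set(2, [], [])

    def test_fasta_output(self, tmp_path):
        t, track = _tracked_transcript(2, peak=40)
        windows = extract_motif_windows({t.id: track}, [t], window_flank=10)
        path = tmp_path / "w.fa"
        write_windows_fasta(windows, path)
        lines = path.read_text().strip().splitlines()
        assert len(lines) == 2 * len(windows)
        assert all(len(lines[i + 1]) == 21 for i in range(0, len(lines), 2))


def _dinuc_counts(seq):
    out = {}
    for a, b in zip(seq, seq[1:]):
        out[a + b] = out.get(a + b, 0) + 1
    return out


class TestShuffles:
    @pytest.mark.parametrize("seed", range(5))
    def test_dinucleotide_counts_preserved(self, seed):
        rng = np.random.RandomState(seed)
        seq = "".join(rng.choice(list("ACGU"), size=80))
        shuffled = dinucleotide_shuffle(seq, rng)
        assert len(shuffled) == len(seq)
        assert _dinuc_counts(shuffled) == _dinuc_counts(seq)
        assert shuffled[0] == seq[0] and shuffled[-1] == seq[-1]

    def test_homopolymer_fixed_point(self):
        rng = np.random.RandomState(0)
        assert dinucleotide_shuffle("AAAAAA", rng) == "AAAAAA"

    def test_codon_shuffle_degenerate(self):
        # one internal codon: shuffle must return the identical CDS
        t = Transcript("t", "AUGAAAUAA", "PC", cds=(0, 9), protein="MK")
        rng = np.random.RandomState(0)
        assert codon_shuffle(t, rng) == t.sequence

    def test_codon_shuffle_preserves_structure(self):
        seq = "GGAUGAAACCCGGGUUCUAACC"
        t = Transcript("t", seq, "PC", cds=(2, 20), protein="MKPGF")
        rng = np.random.RandomState(1)
        out = codon_shuffle(t, rng)
        assert len(out) == len(seq)
        assert out[2:5] == "AUG" and out[17:20] == "UAA"
        orig = sorted(seq[i : i + 3] for i in range(5, 17, 3))
        new = sorted(out[i : i + 3] for i in range(5, 17, 3))
        assert orig == new


@pytest.fixture(scope="module")
def model():
    return init_params(CFG, seed=4), CFG


class TestPerturbations:
    def test_nonsense_scan_matches_brute_force(self, model):
        params, cfg = model
        seq = "GGGAUGAAAAAACACUGGUAACCC"
        t = Transcript("t", seq, "PC", cds=(3, 21), protein=translate(seq[3:18]))
        res = perturb_and_score(params, cfg, t, "nonsense_scan")
        got = {(m["position"], m["alt"]) for m in res.meta}
        # brute force: every variant whose CDS translation terminates early
        expected = set()
        s, e = t.cds
        wt_len = len(translate(seq[s : e - 3]))
        for i in range(s + 3, e - 3):
            for b in "ACGU":
                if b == seq[i]:
                    continue
                var = seq[:i] + b + seq[i + 1 :]
                if len(translate(var[s : e - 3])) < wt_len:
                    expected.add((i, b))
        assert got == expected
        # delta-S values equal direct rescoring
        from rnacoding.attribution import make_score_fn
        from rnacoding.model import one_hot

        fn = make_score_fn(params, cfg)
        s_wt = float(fn(one_hot(seq)[None])[0])
        for (i, b), ds in zip([(m["position"], m["alt"]) for m in res.meta], res.delta_s):
            var = seq[:i] + b + seq[i + 1 :]
            assert ds == pytest.approx(float(fn(one_hot(var)[None])[0]) - s_wt, abs=1e-9)

    def test_start_knockout_nine_variants(self, model):
        params, cfg = model
        seq = "GGGAUGAAAAAACACUGGUAACCC"
        t = Transcript("t", seq, "PC", cds=(3, 21), protein=translate(seq[3:18]))
        res = perturb_and_score(params, cfg, t, "start_knockout")
        assert len(res.delta_s) == 9

    def test_utr_shuffle_requires_long_utr(self, model):
        params, cfg = model
        seq = "GGGAUGAAAAAACACUGGUAACCC"
        t = Transcript("t", seq, "PC", cds=(3, 21), protein=translate(seq[3:18]))
        res = perturb_and_score(params, cfg, t, "utr5_dinuc_shuffle")
        assert res.empty and "25" in res.reason

    def test_utr_shuffle_scores_one_variant(self, model):
        params, cfg = model
        rng = np.random.RandomState(0)
        utr5 = "".join(rng.choice(list("ACGU"), size=40))
        seq = utr5 + "AUGAAACACUAA" + "CC"
        t = Transcript("t", seq, "PC", cds=(40, 52), protein="MKH")
        res = perturb_and_score(params, cfg, t, "utr5_dinuc_shuffle", seed=1)
        assert len(res.delta_s) == 1

    def test_no_orf_empty_with_reason(self, model):
        params, cfg = model
        t = Transcript("t", "C" * 30, "NC")
        res = perturb_and_score(params, cfg, t, "codon_shuffle")
        assert res.empty and res.reason

    def test_nonsense_bin_means(self, model):
        params, cfg = model
        seq = "GGGAUGAAAAAACACUGGUAACCC"
        t = Transcript("t", seq, "PC", cds=(3, 21), protein=translate(seq[3:18]))
        res = perturb_and_score(params, cfg, t, "nonsense_scan", nonsense_bin_codons=2)
        means = nonsense_bin_means(res)
        assert means
        for b, v in means.items():
            sel = [float(d) for d, m in zip(res.delta_s, res.meta) if m["bin"] == b]
            assert v == pytest.approx(np.mean(sel))


class TestAttentionSummary:
    def test_single_transcript_profile(self, model):
        from rnacoding.interpretation import attention_summary

        params, cfg = model
        seq = "GGGAUGAAAAAACACUGGUAACCC"
        t = Transcript("t", seq, "PC", cds=(3, 21), protein=translate(seq[3:18]))
        prof = attention_summary(params, cfg, [t], head=0, layer=0, coverage_threshold=0.5)
        assert prof.mean.sum() == pytest.approx(1.0, abs=1e-6)  # one softmax row
        assert len(prof.mean) == len(seq)
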