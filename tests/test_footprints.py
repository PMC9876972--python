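"""PWM scanning, bias model, mixture FLR, curation and differential metrics."""

import numpy as np
import pandas as pd
import pytest

from synchrodiff.core import GenomicInterval, IntervalSet
from synchrodiff.footprints import (
    PWM,
    CurationConfig,
    bagfoot_metrics,
    bh_adjust,
    build_bias_model,
    curate_footprints,
    fit_footprint_mixture,
    flat_bias_model,
    footprint_flr,
    footprint_overrepresentation,
    genome_kmer_frequencies,
    protection_score,
    scan_pwm,
    window_counts,
)
from synchrodiff.sequtils import revcomp
from synchrodiff.simulate import SimulationConfig, consensus_pwm, simulate_atac, simulate_genome


def hard_pwm(consensus: str, name="HARD") -> PWM:
    m = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        m[i, "ACGT".index(b)] = 1.0
    return PWM(name, m)


class TestScanPwm:
    def test_planted_consensus_found_exactly(self):
        rng = np.random.default_rng(0)
        seq = list(rng.choice(list("ACGT"), 5000))
        cons = "ACGTTTGCAACG"
        seq[1000:1012] = list(cons)
        genome = {"chr1": "".join(seq)}
        hits = scan_pwm(genome, hard_pwm(cons), p_threshold=1e-4)
        fwd = hits[hits.strand == "+"]
        assert 1000 in set(fwd.start)
        # the planted exact match is the top-scoring hit; any other hit is a
        # near-neighbour within the p<1e-4 mass (<= 2 mismatches for a 12-mer)
        top = fwd.sort_values("score", ascending=False).iloc[0]
        assert top.start == 1000
        for _, h in fwd.iterrows():
            word = genome["chr1"][h.start : h.end]
            mismatches = sum(a != b for a, b in zip(word, cons))
            assert mismatches <= 2

    def test_zero_threshold_empty(self):
        genome = {"chr1": "ACGT" * 100}
        assert scan_pwm(genome, hard_pwm("ACGTAC"), p_threshold=0).empty

    def test_palindrome_reported_on_both_strands(self):
        cons = "ACGCGT"  # reverse complement of itself
        assert revcomp(cons) == cons
        genome = {"chr1": "T" * 50 + cons + "T" * 50}
        hits = scan_pwm(genome, hard_pwm(cons), p_threshold=1e-3)
        at_site = hits[hits.start == 50]
        assert set(at_site.strand) == {"+", "-"}

    def test_match_rate_on_iid_background(self):
        """Match count on i.i.d. sequence agrees with the exact tail mass of
        the score distribution (binomial closed form for a two-level PWM)."""
        from scipy.stats import binom

        rng = np.random.default_rng(1)
        L = 200_000
        genome = {"chr1": "".join(rng.choice(list("ACGT"), L))}
        # soft consensus PWM: per column the score takes 2 values, so the
        # null score is a Binomial(12, 1/4) count of consensus bases
        pwm = PWM("soft", consensus_pwm("ACGTACGTAGCT", soft=0.7)["matrix"])
        p = 1e-3
        hits = scan_pwm(genome, pwm, p_threshold=p)
        # exact threshold: smallest k with P(X >= k) < p for X~Bin(12, 1/4)
        k_thr = next(k for k in range(13) if binom.sf(k - 1, 12, 0.25) < p)
        tail = binom.sf(k_thr - 1, 12, 0.25)
        assert tail < p  # the scan is conservative, never anti-conservative
        n_windows = 2 * (L - 12 + 1)
        expected = n_windows * tail
        sd = np.sqrt(n_windows * tail)
        assert abs(len(hits) - expected) < 4 * sd


@pytest.fixture(scope="module")
def biased_sim():
    cfg = SimulationConfig(
        seed=21, chrom_lengths={"chr1": 120_000}, n_open_regions=10,
        n_genes=30, n_motif_sites=20, bias={"ACGTAC": 2.0},
    )
    seqs, regions, sites, genes, pwm = simulate_genome(cfg)
    _, control = simulate_atac(cfg, seqs, regions, sites)
    return seqs, control


class TestBiasModel:

    def test_flat_input_weights_near_one(self):
        cfg = SimulationConfig(
            seed=22, chrom_lengths={"chr1": 120_000}, n_open_regions=10,
            n_genes=30, n_motif_sites=20, bias={},
        )
        seqs, regions, sites, genes, pwm = simulate_genome(cfg)
        _, control = simulate_atac(cfg, seqs, regions, sites)
        model = build_bias_model(control, seqs)
        # sampling bound from the control depth: each 6-mer sees roughly
        # n_control/4096 insertions, so weight SD ~ sqrt(1/E[count])
        mean_count = len(control) / 4096
        sd = np.sqrt(1.0 / mean_count)
        w = model.weight_array
        assert np.median(w) == pytest.approx(1.0, abs=0.1)
        assert np.mean(w) == pytest.approx(1.0, abs=0.1)
        assert (np.abs(w - 1.0) < 5 * sd).mean() > 0.995

    def test_hot_kmer_weight_recovered(self, biased_sim):
        seqs, control = biased_sim
        model = build_bias_model(control, seqs)
        assert 1.7 < model.weight("ACGTAC") < 2.3

    def test_absent_kmer_finite_pseudocount_weight(self):
        genome = {"chr1": "ACGT" * 3000}
        ins = pd.DataFrame({"chrom": ["chr1"] * 20, "pos": np.arange(20) * 4 + 10, "strand": "+"})
        with pytest.warns(UserWarning):
            model = build_bias_model(ins, genome)
        w = model.weight("TTTTTT")  # never occurs in control or genome
        assert np.isfinite(w) and w > 0

    def test_chromosome_mismatch_rejected(self):
        ins = pd.DataFrame({"chrom": ["chrX"], "pos": [10], "strand": ["+"]})
        with pytest.raises(KeyError):
            build_bias_model(ins, {"chr1": "ACGT" * 100}, min_insertions=0)

    def test_background_is_genome_kmer_distribution(self):
        genome = {"chr1": "ACGTACGTAA" * 50}
        freq = genome_kmer_frequencies(genome, k=2, pseudocount=0.0)
        assert freq.sum() == pytest.approx(1.0)
        # both-strand counting makes the distribution reverse-complement symmetric
        from synchrodiff.sequtils import kmer_to_id
        assert freq[kmer_to_id("AC")] == pytest.approx(freq[kmer_to_id("GT")])


def _toy_windows(rng, n, W, motif, depth, n_ins=50):
    """Draw multinomial windows with optional central depletion."""
    p = np.ones(W)
    p[motif] *= 1 - depth
    p /= p.sum()
    return rng.multinomial(n_ins, p, size=n).astype(float)


class TestMixture:
    def test_null_windows_rarely_reach_threshold(self):
        rng = np.random.default_rng(30)
        W, L = 62, 12
        motif = slice(25, 25 + L)
        counts = _toy_windows(rng, 400, W, motif, depth=0.0)
        fit = fit_footprint_mixture(counts, np.ones_like(counts), motif, min_matches=10)
        assert (fit.flr >= 10).mean() < 0.01

    def test_zero_count_window_flr_zero(self):
        rng = np.random.default_rng(31)
        W, L = 62, 12
        motif = slice(25, 37)
        counts = _toy_windows(rng, 50, W, motif, depth=0.8)
        counts[0] = 0.0
        fit = fit_footprint_mixture(counts, np.ones_like(counts), motif, min_matches=10)
        assert fit.flr[0] == 0.0

    def test_planted_depletion_separates_bound_from_unbound(self):
        rng = np.random.default_rng(32)
        W, L = 62, 12
        motif = slice(25, 37)
        bound = _toy_windows(rng, 150, W, motif, depth=0.8, n_ins=120)
        unbound = _toy_windows(rng, 150, W, motif, depth=0.0, n_ins=120)
        counts = np.vstack([bound, unbound])
        fit = fit_footprint_mixture(counts, np.ones_like(counts), motif, min_matches=10)
        labels = np.array([True] * 150 + [False] * 150)
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(labels, fit.flr) > 0.95
        assert fit.protection.mean() < 0.5  # learned shape shows depletion

    def test_flr_antisymmetric_under_component_swap(self):
        """Swapping which component is 'bound' negates the likelihood ratio."""
        rng = np.random.default_rng(33)
        W = 40
        motif = slice(15, 25)
        counts = _toy_windows(rng, 80, W, motif, depth=0.6, n_ins=60)
        bias = np.ones_like(counts)
        fit = fit_footprint_mixture(counts, bias, motif, min_matches=10)
        q0 = bias / bias.sum(axis=1, keepdims=True)
        pi_full = np.ones(W)
        pi_full[motif] = fit.protection
        q1 = bias * pi_full
        q1 /= q1.sum(axis=1, keepdims=True)
        ll1 = np.einsum("ij,ij->i", counts, np.log(q1))
        ll0 = np.einsum("ij,ij->i", counts, np.log(q0))
        swapped = ll0 - ll1
        assert np.allclose(fit.flr, -swapped, atol=1e-9)

    def test_bias_correction_reduces_false_positives_at_hotspot(self):
        """A hot unprotected 6-mer at the motif edge mimics a footprint;
        correcting with the fitted weights must lower the FLR>=10 rate
        relative to forcing all weights to 1 (same seed, paired)."""
        kmer = "GGGCCC"
        cfg = SimulationConfig(
            seed=34, chrom_lengths={"chr1": 150_000}, n_open_regions=25,
            n_genes=30, n_motif_sites=40, bias={kmer: 12.0},
            protection_depth=0.0, occupancy=0.0, region_rate=3.0,
        )
        seqs, regions, sites, genes, pwm_d = simulate_genome(cfg)
        # plant the hot 6-mer twice in each flank of every candidate site so
        # biased insertions pile up outside the motif, faking central depletion
        seq = list(seqs["chr1"])
        for _, s in sites.iterrows():
            seq[s.start - 12 : s.start - 6] = list(kmer)
            seq[s.start - 18 : s.start - 12] = list(kmer)
            seq[s.end + 6 : s.end + 12] = list(kmer)
            seq[s.end + 12 : s.end + 18] = list(kmer)
        seqs = {"chr1": "".join(seq)}
        atac, control = simulate_atac(cfg, seqs, regions, sites)
        ins = atac[0][0]
        matches = sites[["chrom", "start", "end", "strand"]].copy()
        bias = build_bias_model(control, seqs)
        corrected = footprint_flr(matches, ins, seqs, bias, min_matches=10)
        uncorrected = footprint_flr(matches, ins, seqs, flat_bias_model(), min_matches=10)
        fp_corr = (corrected.flr >= 10).mean()
        fp_raw = (uncorrected.flr >= 10).mean()
        assert fp_corr < fp_raw


class TestProtectionScore:
    def _matches(self):
        return pd.DataFrame(
            {"chrom": ["chr1"], "start": [100], "end": [112], "strand": ["+"]}
        )

    def test_sign_and_magnitude(self):
        # flank rate 2/bp, motif rate 1/bp (library scaling cancels in sign;
        # magnitude checked against the defined formula)
        ins = []
        for p in range(75, 100):
            ins += [p, p]
        for p in range(100, 112):
            ins += [p]
        for p in range(112, 137):
            ins += [p, p]
        df = pd.DataFrame({"chrom": "chr1", "pos": ins, "strand": "+"})
        ps = protection_score(self._matches(), df)
        scale = 1e6 / len(df)
        assert ps[0] == pytest.approx((2 - 1) * scale, rel=1e-9)

    def test_flat_profile_zero(self):
        ins = pd.DataFrame({"chrom": "chr1", "pos": list(range(75, 137)), "strand": "+"})
        ps = protection_score(self._matches(), ins)
        assert ps[0] == pytest.approx(0.0, abs=1e-12)

    def test_enriched_motif_negative(self):
        ins = pd.DataFrame({"chrom": "chr1", "pos": list(range(100, 112)) * 3, "strand": "+"})
        assert protection_score(self._matches(), ins)[0] < 0

    def test_occupied_sites_mostly_positive(self, small_study):
        sites = small_study.truth.motif_sites
        occupied = sites[sites.bound_0].reset_index(drop=True)
        pooled = pd.concat(small_study.atac[0], ignore_index=True)
        ps = protection_score(occupied[["chrom", "start", "end", "strand"]], pooled)
        assert (ps > 0).mean() >= 0.95


def _candidate(chrom, start, flr1, flr2, ps, pwm, tf_expr_key):
    return {
        "chrom": chrom, "start": start, "end": start + 10, "strand": "+",
        "pwm": pwm, "flr1": flr1, "flr2": flr2, "ps": ps,
    }


class TestCuration:
    """Eight scripted candidates against exhaustive application of the six
    printed filters."""

    @pytest.fixture()
    def fixture_calls(self):
        rows = [
            # passes everything
            _candidate("chr1", 100, 12.0, 15.0, 0.5, "PWM_A", None),
            # fails: FLR < 10 in replicate 2
            _candidate("chr1", 300, 12.0, 9.0, 0.5, "PWM_A", None),
            # fails: negative protection score
            _candidate("chr1", 500, 11.0, 11.0, -0.2, "PWM_A", None),
            # overlapping pair, same TF: keep the higher mean FLR (15 > 12)
            _candidate("chr1", 700, 12.0, 12.0, 0.5, "PWM_A", None),
            _candidate("chr1", 705, 15.0, 15.0, 0.5, "PWM_A", None),
            # fails: multi-TF PWM
            _candidate("chr1", 900, 20.0, 20.0, 0.5, "PWM_MULTI", None),
            # fails: TF below 1.0 FPKM
            _candidate("chr1", 1100, 20.0, 20.0, 0.5, "PWM_SILENT", None),
            # fails: outside the external evidence set
            _candidate("chr1", 2000, 20.0, 20.0, 0.5, "PWM_A", None),
        ]
        df = pd.DataFrame(rows)
        rep1 = df.drop(columns=["flr1", "flr2"]).assign(flr=df.flr1)
        rep2 = df.drop(columns=["flr1", "flr2", "ps"]).assign(flr=df.flr2)
        pwm_tfs = {"PWM_A": ("TFA",), "PWM_MULTI": ("TFB", "TFC"), "PWM_SILENT": ("TFD",)}
        expression = {"TFA": 5.0, "TFB": 5.0, "TFC": 5.0, "TFD": 0.2}
        external = IntervalSet([GenomicInterval("chr1", 0, 1500)])
        return [rep1, rep2], pwm_tfs, expression, external

    def test_survivors_match_exhaustive_filtering(self, fixture_calls):
        reps, pwm_tfs, expression, external = fixture_calls
        cfg = CurationConfig(min_footprints_per_pwm=1)
        out = curate_footprints(reps, pwm_tfs, expression, external, cfg)
        assert sorted(out.start) == [100, 705]
        assert (out.tf == "TFA").all()
        assert out.loc[out.start == 705, "flr_mean"].iloc[0] == 15.0

    def test_per_pwm_floor_drops_sparse_pwm(self, fixture_calls):
        reps, pwm_tfs, expression, external = fixture_calls
        # PWM_A has exactly 5 candidates surviving the FLR filter, so a floor
        # of 6 removes the whole PWM
        cfg = CurationConfig(min_footprints_per_pwm=6)
        out = curate_footprints(reps, pwm_tfs, expression, external, cfg)
        assert out[out.pwm == "PWM_A"].empty

    def test_all_below_flr_threshold_empty(self, fixture_calls):
        reps, pwm_tfs, expression, external = fixture_calls
        low = [df.assign(flr=df.flr * 0.1) for df in reps]
        out = curate_footprints(low, pwm_tfs, expression, external,
                                CurationConfig(min_footprints_per_pwm=1))
        assert out.empty

    def test_pure_filter_idempotent(self, fixture_calls):
        reps, pwm_tfs, expression, external = fixture_calls
        cfg = CurationConfig(min_footprints_per_pwm=1)
        once = curate_footprints(reps, pwm_tfs, expression, external, cfg)
        again_reps = [once.drop(columns=["flr_mean", "tf", "curated"]).assign(flr=once.flr_mean)
                      for _ in reps]
        twice = curate_footprints(again_reps, pwm_tfs, expression, external, cfg)
        assert list(twice.start) == list(once.start)

    def test_missing_expression_drops_tf_with_warning(self, fixture_calls):
        reps, pwm_tfs, expression, external = fixture_calls
        expression = {k: v for k, v in expression.items() if k != "TFA"}
        with pytest.warns(UserWarning, match="TFA"):
            out = curate_footprints(reps, pwm_tfs, expression, external,
                                    CurationConfig(min_footprints_per_pwm=1))
        assert out.empty


class TestOverrepresentation:
    def test_identical_proportions_not_significant(self):
        diff = {"A": 10, "B": 90}
        bg = {"A": 100, "B": 900}
        out = footprint_overrepresentation(diff, bg)
        assert (out.p > 0.9).all()

    def test_hand_computed_chi_squared(self):
        diff = {"A": 10, "rest": 90}
        bg = {"A": 10, "rest": 990}
        out = footprint_overrepresentation(diff, bg)
        # textbook 2x2 chi-squared without continuity correction
        table = np.array([[10, 90], [10, 990]])
        n = table.sum()
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / n
        chi2 = ((table - expected) ** 2 / expected).sum()
        assert out.loc[out.tf == "A", "chi2"].iloc[0] == pytest.approx(chi2, rel=1e-9)

    def test_bh_identity_for_single_test(self):
        assert bh_adjust(np.array([0.037]))[0] == pytest.approx(0.037)

    def test_absent_tf_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="absent"):
            out = footprint_overrepresentation({"A": 5, "Z": 3}, {"A": 50, "B": 50})
        assert "Z" not in set(out.tf)


class TestBagfoot:
    def _matches(self):
        return pd.DataFrame({"chrom": ["chr1"], "start": [500], "end": [512], "strand": ["+"]})

    def _insertions(self, flank_per_bp, motif_per_bp):
        pos = []
        for p in range(400, 500):
            pos += [p] * flank_per_bp
        for p in range(500, 512):
            pos += [p] * motif_per_bp
        for p in range(512, 612):
            pos += [p] * flank_per_bp
        return pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+"})

    def test_identical_conditions_zero_deltas(self):
        ins = self._insertions(4, 1)
        out = bagfoot_metrics(self._matches(), ins, ins)
        assert out["delta_fa"] == pytest.approx(0.0, abs=1e-12)
        assert out["delta_fpd"] == pytest.approx(0.0, abs=1e-12)

    def test_doubled_flank_rate_gives_delta_fa_one(self):
        # equal library sizes so depth normalisation cancels: pad condition 1
        # with insertions far from the motif
        c1 = self._insertions(2, 1)
        c2 = self._insertions(4, 2)
        pad = pd.DataFrame({
            "chrom": "chr1",
            "pos": np.arange(5000, 5000 + len(c2) - len(c1)),
            "strand": "+",
        })
        c1 = pd.concat([c1, pad], ignore_index=True)
        out = bagfoot_metrics(self._matches(), c1, c2)
        assert out["delta_fa"] == pytest.approx(1.0, abs=1e-9)
        assert out["delta_fpd"] == pytest.approx(0.0, abs=1e-9)

    def test_deeper_depletion_positive_delta_fpd(self):
        c1 = self._insertions(4, 2)
        c2 = self._insertions(4, 1)
        out = bagfoot_metrics(self._matches(), c1, c2)
        assert out["delta_fpd"] > 0
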