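import math

import numpy as np
import pytest

from rose.errors import ParameterError
from rose.io_formats import GenomeSequence, revcomp
from rose.motif_discovery import (
    MotifModel,
    PromoterSequence,
    ScoreCutoff,
    _score_window,
    discover_motif,
    dual_motif_report,
    extract_promoters,
    filter_by_score,
    logo_counts,
    null_score_cutoff,
    score_sequence,
    shuffle_window,
)
from rose.tss_detection import ConsensusTSS


def tss(pos, strand="+"):
    return ConsensusTSS("c", pos, strand, 4, {"r": 10})


def prom(window, plus1="A"):
    return PromoterSequence(tss(1), window, plus1, window[-1])


def point_mass_model(consensus, hit=0.97, sd=1e7, mean=0.0):
    """Near-deterministic PWM with an effectively uniform positional prior."""
    probs = np.full((len(consensus), 4), (1 - hit) / 3)
    for j, b in enumerate(consensus):
        probs[j, "ACGT".index(b)] = hit
    return MotifModel(len(consensus), probs, np.full(4, 0.25), mean, sd)


def plant_windows(n, length, motif, offset, mutation, rng):
    windows = []
    for _ in range(n):
        w = list(rng.choice(list("ACGT"), size=length))
        for j, b in enumerate(motif):
            w[offset + j] = (
                rng.choice([x for x in "ACGT" if x != b])
                if rng.random() < mutation
                else b
            )
        windows.append("".join(w))
    return windows


class TestExtractPromoters:
    def test_plus_strand_direct_slice(self):
        g = GenomeSequence("c", "AAAATTTG")
        (p,) = extract_promoters(g, [tss(8)], window=4)
        assert (p.window, p.plus1, p.minus1, p.truncated) == ("ATTT", "G", "T", False)

    def test_minus_strand_reverse_complement(self):
        g = GenomeSequence("c", "AAAATTTG")
        (p,) = extract_promoters(g, [tss(1, "-")], window=4)
        assert p.window == revcomp(g.sequence[1:5])
        assert p.plus1 == "T"  # complement of genome base A at position 1

    def test_minus1_equals_last_window_base(self):
        g = GenomeSequence("c", "ACGTACGTACGT")
        for t in [tss(8), tss(5, "-")]:
            (p,) = extract_promoters(g, [t], window=4)
            assert p.minus1 == p.window[-1]

    def test_truncation_flag_near_edge(self):
        g = GenomeSequence("c", "ACGTACGT")
        (p,) = extract_promoters(g, [tss(3)], window=5)
        assert p.truncated
        assert p.window == "AC"

    def test_circular_genome_wraps_instead_of_truncating(self):
        g = GenomeSequence("c", "ACGTACGT", circular=True)
        (p,) = extract_promoters(g, [tss(3)], window=5)
        assert not p.truncated
        assert p.window == "CGTAC"  # positions 6,7,8,1,2 wrapped around the origin

    def test_full_length_windows_away_from_edges(self, small_fixture):
        genome, truth = small_fixture["genome"], small_fixture["truth"]
        proms = extract_promoters(genome, [tss(r.tss_position, r.strand) for r in truth], 50)
        assert all(len(p.window) == 50 and not p.truncated for p in proms)


class TestScoring:
    def test_closed_form_score_of_exact_consensus(self):
        model = point_mass_model("TATAAT")
        window = "G" * 20 + "TATAAT" + "G" * 20
        hit = score_sequence(model, prom(window))
        assert hit.offset == 20
        assert hit.score == pytest.approx(6 * math.log2(0.97 / 0.25), abs=1e-3)

    def test_uniform_model_scores_only_prior_term(self):
        model = MotifModel(4, np.full((4, 4), 0.25), np.full(4, 0.25), 0.0, 1e7)
        hit = score_sequence(model, prom("ACGTACGTACGT"))
        assert hit.score == pytest.approx(0.0, abs=1e-3)

    def test_deterministic_on_repeated_calls(self):
        model = point_mass_model("TATAAT")
        p = prom("G" * 20 + "TATAAT" + "G" * 20)
        assert score_sequence(model, p) == score_sequence(model, p)

    def test_n_window_excluded(self):
        model = point_mass_model("TATAAT")
        assert score_sequence(model, prom("NNNNNNNNNN")) is None

    def test_matches_independent_offset_enumeration(self):
        rng = np.random.default_rng(4)
        model = discover_motif(
            [prom("".join(rng.choice(list("ACGT"), 30))) for _ in range(15)],
            width=5, prior_mean=10, prior_sd=5, n_seeds=1, seed=0,
        )
        window = "".join(rng.choice(list("ACGT"), 30))
        K = 30 - 5 + 1
        prior = model.offset_prior(K)
        expected = []
        for o in range(K):
            s = math.log2(prior[o] * K)
            for j in range(5):
                b = "ACGT".index(window[o + j])
                s += math.log2(model.column_probs[j, b] / model.background[b])
            expected.append(s)
        o_got, s_got = _score_window(model, window)
        assert s_got == pytest.approx(max(expected))
        assert o_got == int(np.argmax(expected))


class TestDiscoverMotif:
    def test_planted_motif_recovery(self):
        rng = np.random.default_rng(42)
        proms = [prom(w) for w in plant_windows(200, 50, "TATAAT", 38, 0.10, rng)]
        model = discover_motif(proms, width=6, prior_mean=38, prior_sd=4,
                               n_seeds=3, seed=0)
        assert model.consensus == "TATAAT"
        assert (model.information_content() > 1.0).all()
        assert 34 <= model.position_prior_mean <= 42

    def test_same_seed_identical_model(self):
        rng = np.random.default_rng(5)
        proms = [prom(w) for w in plant_windows(40, 50, "TTGACA", 10, 0.2, rng)]
        m1 = discover_motif(proms, n_seeds=2, seed=9, prior_mean=10)
        m2 = discover_motif(proms, n_seeds=2, seed=9, prior_mean=10)
        assert np.array_equal(m1.column_probs, m2.column_probs)
        assert m1.log_likelihood == m2.log_likelihood

    def test_too_few_sequences_is_error(self):
        with pytest.raises(ParameterError, match=">= 10"):
            discover_motif([prom("ACGTACGTAC")] * 5, width=4, prior_mean=2)

    def test_degenerate_prior_is_error(self):
        proms = [prom("ACGTACGTACGTACGT")] * 12
        with pytest.raises(ParameterError):
            discover_motif(proms, width=4, prior_mean=5, prior_sd=0)

    def test_null_column_information_low_on_random_sequences(self):
        # average column IC over 20 seeded runs on uniform-random windows
        # stays below 0.3 bits; a weak spurious motif is expected, so the
        # per-run ceiling is loose
        ics = []
        for s in range(20):
            rng = np.random.default_rng(1000 + s)
            proms = [prom("".join(rng.choice(list("ACGT"), 50))) for _ in range(200)]
            m = discover_motif(proms, width=6, prior_mean=38, prior_sd=4,
                               n_seeds=2, seed=s)
            ics.append(float(m.information_content().mean()))
        assert np.mean(ics) <= 0.3
        assert max(ics) < 0.6


class TestNullCutoff:
    def _random_promoters(self, n, seed=0):
        rng = np.random.default_rng(seed)
        return [prom("".join(rng.choice(list("ACGT"), 50))) for _ in range(n)]

    def test_nearest_rank_against_sort_oracle(self):
        model = point_mass_model("TATAAT")
        proms = self._random_promoters(200, 1)
        cut = null_score_cutoff(model, proms, quantile=0.9, seed=3)
        k = math.ceil(0.1 * 200)
        assert cut.cutoff == sorted(cut.null_scores)[200 - k]

    def test_exact_upper_tail_count(self):
        # a continuous random PWM avoids tied scores, so the count is exact
        rng = np.random.default_rng(17)
        probs = rng.dirichlet(np.ones(4), size=6)
        model = MotifModel(6, probs, np.full(4, 0.25), 20.0, 8.0)
        proms = self._random_promoters(1000, 2)
        cut = null_score_cutoff(model, proms, quantile=0.95, seed=5)
        assert cut.null_size == 1000
        assert int((cut.null_scores >= cut.cutoff).sum()) == 50

    def test_same_seed_same_cutoff(self):
        model = point_mass_model("TATAAT")
        proms = self._random_promoters(50, 3)
        a = null_score_cutoff(model, proms, seed=11)
        b = null_score_cutoff(model, proms, seed=11)
        assert a.cutoff == b.cutoff

    def test_bad_quantile_is_error(self):
        model = point_mass_model("TATAAT")
        with pytest.raises(ParameterError):
            null_score_cutoff(model, self._random_promoters(10), quantile=1.0)

    def test_shuffle_preserves_composition(self):
        rng = np.random.default_rng(0)
        w = "AACCGGTTACGT"
        s = shuffle_window(w, rng)
        assert sorted(s) == sorted(w)

    def test_dinucleotide_shuffle_preserves_dinucleotide_counts(self):
        from collections import Counter

        from rose.motif_discovery import dinucleotide_shuffle

        rng = np.random.default_rng(1)
        w = "".join(rng.choice(list("ACGT"), 50))
        for _ in range(10):
            s = dinucleotide_shuffle(w, rng)
            assert len(s) == len(w)
            assert s[0] == w[0] and s[-1] == w[-1]
            assert Counter(zip(s, s[1:])) == Counter(zip(w, w[1:]))

    def test_dinucleotide_null_option(self):
        rng = np.random.default_rng(2)
        probs = rng.dirichlet(np.ones(4), size=6)
        model = MotifModel(6, probs, np.full(4, 0.25), 20.0, 8.0)
        proms = self._random_promoters(100, 4)
        cut = null_score_cutoff(model, proms, seed=0, shuffle="dinucleotide")
        assert cut.null_size == 100
        with pytest.raises(ParameterError):
            null_score_cutoff(model, proms, shuffle="bogus")


class TestFilterAndReport:
    def test_exact_consensus_windows_all_pass(self):
        model = point_mass_model("TATAAT")
        cut = ScoreCutoff(0.95, 5.0, 100, 0)
        proms = [prom("G" * 20 + "TATAAT" + "G" * 20)] * 5
        passing, failing = filter_by_score(proms, model, cut)
        assert len(passing) == 5 and not failing

    def test_planted_fraction_passes_well_above_null_rate(self):
        rng = np.random.default_rng(6)
        planted = [prom(w) for w in plant_windows(180, 50, "TATAAT", 38, 0.10, rng)]
        noise = [prom("".join(rng.choice(list("ACGT"), 50))) for _ in range(20)]
        proms = planted + noise
        model = discover_motif(proms, width=6, prior_mean=38, prior_sd=4,
                               n_seeds=3, seed=1)
        cut = null_score_cutoff(model, proms, seed=1)
        passing, _ = filter_by_score(proms, model, cut)
        assert len(passing) / len(proms) >= 0.5

    def test_dual_motif_spacer(self):
        # -35 then 17 nt spacer then -10, the canonical sigma-70 layout
        window = ("G" * 5 + "TTGACA" + "C" * 17 + "TATAAT" + "G" * 16)
        assert len(window) == 50
        m10, m35 = point_mass_model("TATAAT"), point_mass_model("TTGACA")
        low = ScoreCutoff(0.95, 5.0, 100, 0)
        rows, spacers = dual_motif_report([prom(window)], m10, m35, low, low)
        assert rows[0]["both"]
        assert spacers == {17: 1}

    def test_shuffled_window_usually_neither(self):
        rng = np.random.default_rng(8)
        m10, m35 = point_mass_model("TATAAT"), point_mass_model("TTGACA")
        high = ScoreCutoff(0.95, 8.0, 100, 0)
        rows, _ = dual_motif_report(
            [prom("".join(rng.choice(list("ACGT"), 50))) for _ in range(40)],
            m10, m35, high, high)
        assert sum(r["neither"] for r in rows) >= 30


class TestLogoCounts:
    def test_identical_windows_give_point_columns(self):
        model = point_mass_model("TATAAT")
        proms = [prom("G" * 10 + "TATAAT" + "G" * 10)] * 10
        counts = logo_counts(proms, model)
        assert counts.shape == (6, 4)
        assert (counts.sum(axis=1) == 10).all()
        consensus = "".join("ACGT"[i] for i in counts.argmax(axis=1))
        assert consensus == "TATAAT"
        assert counts.max(axis=1).tolist() == [10] * 6

    def test_information_peaks_at_planted_columns(self):
        rng = np.random.default_rng(9)
        proms = [prom(w) for w in plant_windows(100, 50, "TATAAT", 38, 0.10, rng)]
        model = discover_motif(proms, width=6, prior_mean=38, prior_sd=4,
                               n_seeds=2, seed=0)
        counts = logo_counts(proms, model, flank=2)
        assert (counts.sum(axis=1) == counts.sum(axis=1)[0]).all()
        freqs = counts / counts.sum(axis=1, keepdims=True)
        ic = (freqs * np.log2(np.maximum(freqs, 1e-12) / 0.25)).sum(axis=1)
        assert ic[2:8].mean() > 1.0  # motif columns
        assert ic[[0, 1, 8, 9]].mean() < 0.3  # flanking background columns
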