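"""EM motif discovery: background fitting, EM properties, E-values, masking."""

import math

import numpy as np
import pytest

import phenossu as ph
from phenossu.motifs import (
    Background,
    best_width_fit,
    compute_evalue,
    discover_motifs,
    em_fit,
    fit_background,
    seed_pwm,
    split_on_O,
)

UNIFORM = Background(np.full(9, 1 / 9))


class TestBackground:
    def test_hand_computed_pseudocounts(self):
        bg = fit_background(["AAAA"])
        a_idx = ph.ALPHABET.index("A")
        assert bg.freqs[a_idx] == pytest.approx((4 + 0.1) / (4 + 0.9))
        others = np.delete(bg.freqs, a_idx)
        assert others == pytest.approx(0.1 / 4.9)

    def test_two_letter_symmetry(self):
        bg = fit_background(["AP" * 50])
        a, p = ph.ALPHABET.index("A"), ph.ALPHABET.index("P")
        assert bg.freqs[a] == pytest.approx(bg.freqs[p])
        assert bg.freqs[a] == pytest.approx(0.5, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_background([])
        with pytest.raises(ValueError):
            fit_background(["", ""])


class TestEMFit:
    def test_planted_word_recovered(self):
        seqs, sites = ph.generate_planted_sequences(
            UNIFORM, "AAP", copies=20, n_seqs=10, seq_len=50, noise_rate=0.0, seed=5
        )
        motif = em_fit(seqs, 3, "AAP", fit_background(seqs))
        assert motif.consensus == "AAP"
        found = {(s, o) for s, o, _ in motif.sites}
        assert len(found & set(sites)) >= 18

    def test_degenerate_single_letter(self):
        # against a uniform background the repeated letter is all signal
        motif = em_fit(["PPPPPPPP"], 2, "PP", UNIFORM)
        assert motif.consensus == "PP"
        assert motif.lam > 0.5
        p_idx = ph.ALPHABET.index("P")
        assert motif.pwm[:, p_idx].min() > 0.8

    def test_tol_inf_returns_seed_pwm(self):
        seqs = ["APAPAP", "PPAA"]
        motif = em_fit(seqs, 2, "AP", fit_background(seqs), tol=math.inf)
        np.testing.assert_allclose(motif.pwm, seed_pwm("AP"))

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            em_fit(["AAPP"], 1, "A", UNIFORM)
        with pytest.raises(ValueError):
            em_fit(["AP"], 3, "APP", UNIFORM)

    def test_no_windows(self):
        with pytest.raises(ValueError, match="no window"):
            em_fit(["AP"], 4, "APAP", UNIFORM)

    def test_loglik_monotone_on_random_instances(self):
        """EM log-likelihood is non-decreasing on every random instance."""
        rng = np.random.default_rng(42)
        letters = np.array(list(ph.ALPHABET))
        for rep in range(100):
            n_seq = int(rng.integers(1, 4))
            seqs = [
                "".join(rng.choice(letters, size=rng.integers(5, 25)))
                for _ in range(n_seq)
            ]
            w = int(rng.integers(2, 5))
            if not any(len(s) >= w for s in seqs):
                continue
            pool = [s[i : i + w] for s in seqs for i in range(len(s) - w + 1)]
            seed_word = pool[int(rng.integers(len(pool)))]
            motif = em_fit(seqs, w, seed_word, fit_background(seqs), max_iter=50)
            diffs = np.diff(motif.trace)
            assert (diffs >= -1e-8).all(), f"rep {rep}: decreasing log-likelihood"

    def test_small_instance_global_optimality(self):
        """Converged EM beats a coarse grid of smoothed point-mass PWMs on
        the penalized objective it maximizes."""
        corpora = [["APAPAPAP"], ["AAPP", "APAP"], ["PAPPA", "APP", "AA"]]
        pc = 0.1
        for seqs in corpora:
            bg = fit_background(seqs)
            # exhaustive seeding: converge EM from every distinct 2-mer and
            # keep the best converged fit
            words = sorted({s[i : i + 2] for s in seqs for i in range(len(s) - 1)})
            motif = max(
                (em_fit(seqs, 2, word, bg, pseudocount=pc) for word in words),
                key=lambda m: m.trace[-1],
            )
            X = np.array(
                [
                    [ph.ALPHABET.index(c) for c in s[i : i + 2]]
                    for s in seqs
                    for i in range(len(s) - 1)
                ]
            )
            log_pb = np.log(bg.freqs)[X].sum(axis=1)

            def penalized(pwm, lam):
                lp = np.log(pwm)[np.arange(2)[None, :], X].sum(axis=1)
                ll = np.logaddexp(np.log(lam) + lp, np.log1p(-lam) + log_pb).sum()
                return ll + pc * np.log(pwm).sum()

            em_obj = penalized(motif.pwm, motif.lam)
            rows = []
            for a in range(9):
                for g in np.arange(0.0, 1.0, 0.1):
                    row = np.full(9, (1 - g) / 9)
                    row[a] += g
                    rows.append(row)
            best_grid = max(
                penalized(np.array([r1, r2]), motif.lam)
                for r1 in rows
                for r2 in rows
            )
            assert em_obj >= best_grid - 1e-6


class TestDiscovery:
    def test_planted_words_both_recovered(self):
        seqs1, sites1 = ph.generate_planted_sequences(
            UNIFORM, "AAP", copies=25, n_seqs=8, seq_len=60, seed=1
        )
        seqs2, sites2 = ph.generate_planted_sequences(
            UNIFORM, "LNU", copies=25, n_seqs=8, seq_len=60, seed=2
        )
        motifs = discover_motifs(
            seqs1 + seqs2, min_w=2, max_w=4, n_motifs=4, seed=0, n_shuffles=99
        )
        planted = {
            "AAP": set(sites1),
            "LNU": {(sid + len(seqs1), off) for sid, off in sites2},
        }
        for word, truth in planted.items():
            # width selection may extend the word by a background column, so
            # match by containment and site overlap
            owners = [m for m in motifs if word in m.consensus]
            assert owners, f"{word} not among {[m.consensus for m in motifs]}"
            m = owners[0]
            shift = m.consensus.index(word)
            found = {(sid, off + shift) for sid, off, _ in m.sites}
            assert len(found & truth) >= 0.9 * len(truth)

    def test_sorted_by_evalue(self):
        seqs, _ = ph.generate_planted_sequences(
            UNIFORM, "APC", copies=20, n_seqs=6, seq_len=50, seed=3
        )
        motifs = discover_motifs(seqs, min_w=2, max_w=3, n_motifs=3, seed=0, n_shuffles=99)
        evalues = [m.evalue for m in motifs]
        assert evalues == sorted(evalues)

    def test_too_short_sequences(self):
        assert discover_motifs(["A"], min_w=2, max_w=4, n_motifs=2, seed=0) == []

    def test_sequence_order_invariance(self):
        seqs, _ = ph.generate_planted_sequences(
            UNIFORM, "AAP", copies=16, n_seqs=6, seq_len=40, seed=7
        )
        a = discover_motifs(seqs, min_w=2, max_w=3, n_motifs=2, seed=5, n_shuffles=79)
        b = discover_motifs(seqs[::-1], min_w=2, max_w=3, n_motifs=2, seed=5, n_shuffles=79)
        assert [m.consensus for m in a] == [m.consensus for m in b]
        assert [m.evalue for m in a] == [m.evalue for m in b]


class TestEvalue:
    def test_minimum_attainable(self):
        """A strongly planted motif beats every shuffle: E = widths/(n+1)."""
        seqs, _ = ph.generate_planted_sequences(
            UNIFORM, "AAPP", copies=20, n_seqs=6, seq_len=50, seed=9
        )
        bg = fit_background(seqs)
        motif = best_width_fit(seqs, 4, bg)
        e = compute_evalue(motif, seqs, bg, n_shuffles=99, seed=0, widths_scanned=3)
        assert e == pytest.approx(3 / 100)

    def test_null_not_significant(self):
        """Refitting on shuffled data yields unremarkable E-values."""
        rng = np.random.default_rng(11)
        letters = np.array(list(ph.ALPHABET))
        small = 0
        for rep in range(10):
            seqs = ["".join(rng.choice(letters, size=50)) for _ in range(4)]
            bg = fit_background(seqs)
            motif = best_width_fit(seqs, 3, bg)
            e = compute_evalue(
                motif, seqs, bg, n_shuffles=39, seed=rep, widths_scanned=1
            )
            small += e < 0.05
        assert small <= 1

    def test_zero_shuffles_rejected(self, library):
        seqs = ["APAP"]
        bg = fit_background(seqs)
        motif = best_width_fit(seqs, 2, bg)
        with pytest.raises(ValueError):
            compute_evalue(motif, seqs, bg, n_shuffles=0, seed=0)


class TestSplitOnO:
    @pytest.mark.parametrize(
        "consensus,segments",
        [
            ("OAPO", ["AP"]),
            ("AAP", ["AAP"]),
            ("OOO", []),
            ("APOLNU", ["AP", "LNU"]),
            ("AOP", []),  # both fragments shorter than 2
        ],
    )
    def test_examples(self, consensus, segments):
        assert split_on_O(consensus) == segments


class TestMinerEstimator:
    def test_fit_and_params(self):
        seqs, _ = ph.generate_planted_sequences(
            UNIFORM, "AAP", copies=20, n_seqs=8, seq_len=40, seed=4
        )
        miner = ph.MotifMiner(min_w=2, max_w=3, n_motifs=2, n_shuffles=99, random_state=0)
        assert miner.get_params()["min_w"] == 2
        miner.set_params(n_motifs=1)
        miner.fit(seqs)
        assert len(miner.motifs_) <= 1
        assert all(len(seg) >= 2 and "O" not in seg for seg in miner.segments_)
        for m in miner.motifs_:
            np.testing.assert_allclose(m.pwm.sum(axis=1), 1.0, atol=1e-9)
            assert (m.pwm > 0).all()
            assert 0 < m.lam < 1
            assert m.evalue >= 0
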