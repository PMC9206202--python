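"""Motif discovery on single-letter sequences by expectation-maximization.

The site model is the two-component mixture (TCM) form of the
"any number of repetitions" distribution: every length-w window of every
sequence is independently either a motif site (probability ``lambda``,
letters drawn from a position weight matrix) or background (order-0 letter
frequencies).  Discovery is sequential: per round, every width in
``[min_w, max_w]`` is fitted from the best warm start (each distinct w-mer
in the data seeds one EM iteration), the winning motif per width is scored
by a Monte-Carlo E-value (composition-preserving letter shuffles of the
corpus), the best width is reported and its sites are erased with a
reserved mask letter before the next round.

The objective maximized by EM is the window likelihood

    LL = sum_i log( lambda * P(x_i | PWM) + (1 - lambda) * P(x_i | bg) )

plus the Dirichlet smoothing term ``pseudocount * sum(log PWM)`` (PWM rows
carry a pseudocount per cell).  That penalized objective is non-decreasing
over iterations, and the returned trace makes this assertable.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .alphabet import ALPHABET, LETTER_INDEX, MASK_LETTER

_K = len(ALPHABET)


@dataclass
class Background:
    """Order-0 letter frequencies over the alphabet."""

    freqs: np.ndarray  # shape (len(ALPHABET),), sums to 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (_K,) or (self.freqs < 0).any():
            raise ValueError("background must be a non-negative vector over the alphabet")
        if not math.isclose(self.freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("background frequencies must sum to 1")


@dataclass
class Motif:
    """A fitted motif: PWM, mixing weight, selected sites and significance."""

    width: int
    pwm: np.ndarray  # (width, |alphabet|), rows sum to 1, all entries > 0
    lam: float
    sites: list[tuple[int, int, float]]  # (sequence id, offset, posterior)
    llr: float  # summed log-odds of the selected sites
    consensus: str
    evalue: float = math.nan
    trace: list[float] = field(default_factory=list)  # per-iteration penalized log-likelihood

    @property
    def nsites(self) -> int:
        return len(self.sites)


def fit_background(sequences: list[str], pseudocount: float = 0.1) -> Background:
    """Empirical letter frequencies with a pseudocount per letter."""
    counts = np.full(_K, pseudocount, dtype=float)
    total = 0
    for s in sequences:
        for ch in s:
            idx = LETTER_INDEX.get(ch)
            if idx is not None:  # mask letters do not count
                counts[idx] += 1
                total += 1
    if total == 0:
        raise ValueError("cannot fit a background on empty sequences")
    return Background(counts / counts.sum())


def _index_sequences(sequences: list[str]) -> list[np.ndarray]:
    """Letters to alphabet indices; anything else (mask) becomes -1."""
    return [
        np.fromiter((LETTER_INDEX.get(c, -1) for c in s), dtype=np.int64, count=len(s))
        for s in sequences
    ]


def _windows(seq_idx: list[np.ndarray], w: int):
    """All mask-free length-w windows: (X, seq_ids, offsets)."""
    mats, ids, offs = [], [], []
    for sid, arr in enumerate(seq_idx):
        if len(arr) < w:
            continue
        win = np.lib.stride_tricks.sliding_window_view(arr, w)
        ok = (win >= 0).all(axis=1)
        if ok.any():
            mats.append(win[ok])
            ids.append(np.full(int(ok.sum()), sid, dtype=np.int64))
            offs.append(np.nonzero(ok)[0])
    if not mats:
        return np.empty((0, w), dtype=np.int64), np.empty(0, np.int64), np.empty(0, np.int64)
    return np.concatenate(mats), np.concatenate(ids), np.concatenate(offs)


def seed_pwm(word: str, pseudocount: float = 0.1) -> np.ndarray:
    """Pseudocounted point-mass PWM for a seed word (one count on each seed letter)."""
    pwm = np.full((len(word), _K), pseudocount, dtype=float)
    for k, ch in enumerate(word):
        pwm[k, LETTER_INDEX[ch]] += 1.0
    return pwm / pwm.sum(axis=1, keepdims=True)


def _log_pm(pwm_log: np.ndarray, X: np.ndarray) -> np.ndarray:
    return pwm_log[np.arange(X.shape[1])[None, :], X].sum(axis=1)


def _e_step(pwm: np.ndarray, lam: float, X: np.ndarray, log_pb: np.ndarray,
            pseudocount: float = 0.0):
    logp = np.log(pwm)
    lp = _log_pm(logp, X)
    a = math.log(lam) + lp
    b = math.log1p(-lam) + log_pb
    # objective ascended by pseudocounted EM: window log-likelihood plus the
    # Dirichlet smoothing term (guaranteed non-decreasing over iterations)
    ll = float(np.logaddexp(a, b).sum()) + pseudocount * float(logp.sum())
    z = 1.0 / (1.0 + np.exp(b - a))
    return ll, z, lp


def _m_step(z: np.ndarray, X: np.ndarray, pseudocount: float):
    w = X.shape[1]
    counts = np.full((w, _K), pseudocount, dtype=float)
    for k in range(w):
        counts[k] += np.bincount(X[:, k], weights=z, minlength=_K)
    pwm = counts / counts.sum(axis=1, keepdims=True)
    lam = float(np.clip(z.sum() / len(z), 1e-8, 1.0 - 1e-8))
    return pwm, lam


def _select_sites(z, lp, log_pb, seq_ids, offsets, w, threshold=0.5):
    """Greedy by descending posterior, no overlaps within a sequence."""
    order = np.lexsort((offsets, seq_ids, -z))
    occupied: dict[int, list[tuple[int, int]]] = {}
    sites, llr = [], 0.0
    for i in order:
        if z[i] <= threshold:
            break
        sid, off = int(seq_ids[i]), int(offsets[i])
        spans = occupied.setdefault(sid, [])
        if any(off < e and s < off + w for s, e in spans):
            continue
        spans.append((off, off + w))
        sites.append((sid, off, float(z[i])))
        llr += float(lp[i] - log_pb[i])
    sites.sort()
    return sites, llr


def _init_lambda(n_windows: int) -> float:
    return min(0.1, math.sqrt(n_windows) / n_windows) if n_windows else 0.1


def em_fit(
    sequences: list[str],
    w: int,
    seed_word: str,
    background: Background,
    max_iter: int = 200,
    tol: float = 1e-6,
    pseudocount: float = 0.1,
) -> Motif:
    """Fit one motif of width ``w`` from a seed word by TCM expectation-maximization.

    With ``tol=inf`` no M-step is taken and the returned PWM is exactly the
    pseudocounted seed PWM.
    """
    if not 2 <= w <= 30:
        raise ValueError(f"width {w} outside [2, 30]")
    if len(seed_word) != w:
        raise ValueError("seed word length must equal the motif width")
    X, seq_ids, offsets = _windows(_index_sequences(sequences), w)
    if len(X) == 0:
        raise ValueError(f"no window of length {w} in the input sequences")
    log_bg = np.log(background.freqs)
    log_pb = log_bg[X].sum(axis=1)
    pwm = seed_pwm(seed_word, pseudocount)
    lam = _init_lambda(len(X))
    trace: list[float] = []
    for _ in range(max_iter):
        ll, z, lp = _e_step(pwm, lam, X, log_pb, pseudocount)
        trace.append(ll)
        if math.isinf(tol) or (len(trace) > 1 and trace[-1] - trace[-2] < tol):
            break
        pwm, lam = _m_step(z, X, pseudocount)
    else:
        ll, z, lp = _e_step(pwm, lam, X, log_pb, pseudocount)
        trace.append(ll)
    sites, llr = _select_sites(z, lp, log_pb, seq_ids, offsets, w)
    consensus = "".join(ALPHABET[i] for i in pwm.argmax(axis=1))
    return Motif(width=w, pwm=pwm, lam=lam, sites=sites, llr=llr, consensus=consensus,
                 trace=trace)


def _warm_start_word(
    X: np.ndarray,
    log_pb: np.ndarray,
    words: list[str],
    pseudocount: float,
    chunk: int = 64,
) -> str:
    """Best seed among ``words``: one EM iteration each, ranked by likelihood."""
    w = X.shape[1]
    n = len(X)
    lam = _init_lambda(n)
    hi = (1.0 + pseudocount) / (1.0 + _K * pseudocount)
    lo = pseudocount / (1.0 + _K * pseudocount)
    log_hi, log_lo = math.log(hi), math.log(lo)
    best_word, best_ll = None, -math.inf
    word_arr = np.array([[LETTER_INDEX[c] for c in word] for word in words], dtype=np.int64)
    for start in range(0, len(words), chunk):
        idx = word_arr[start : start + chunk]  # (m, w)
        m = len(idx)
        # matches[i, s] = #positions where window i equals seed s
        matches = np.zeros((n, m), dtype=np.float64)
        for k in range(w):
            matches += X[:, k : k + 1] == idx[:, k][None, :]
        lp0 = matches * (log_hi - log_lo) + w * log_lo  # (n, m)
        a = math.log(lam) + lp0
        b = (math.log1p(-lam) + log_pb)[:, None]
        z = 1.0 / (1.0 + np.exp(b - a))  # (n, m)
        # M-step for all seeds in the chunk
        counts = np.full((m, w, _K), pseudocount)
        for k in range(w):
            onehot = np.equal(X[:, k][:, None], np.arange(_K)[None, :]).astype(float)
            counts[:, k, :] += z.T @ onehot
        pwm1 = counts / counts.sum(axis=2, keepdims=True)
        lam1 = np.clip(z.sum(axis=0) / n, 1e-8, 1 - 1e-8)  # (m,)
        logp1 = np.log(pwm1)
        lp1 = np.zeros((m, n))
        for k in range(w):
            lp1 += logp1[:, k, X[:, k]]
        ll1 = np.logaddexp(
            np.log(lam1)[:, None] + lp1, np.log1p(-lam1)[:, None] + log_pb[None, :]
        ).sum(axis=1) + pseudocount * logp1.sum(axis=(1, 2))
        j = int(np.argmax(ll1))
        # deterministic tie-break: larger likelihood, then lexicographic word
        if ll1[j] > best_ll + 1e-12 or (
            abs(ll1[j] - best_ll) <= 1e-12
            and best_word is not None
            and words[start + j] < best_word
        ):
            best_ll, best_word = float(ll1[j]), words[start + j]
    return best_word


def _distinct_words(sequences: list[str], w: int, max_starts: int | None) -> list[str]:
    counter: Counter[str] = Counter()
    for s in sequences:
        for i in range(len(s) - w + 1):
            word = s[i : i + w]
            if MASK_LETTER not in word:
                counter[word] += 1
    words = sorted(counter, key=lambda x: (-counter[x], x))
    if max_starts is not None:
        words = words[:max_starts]
    return words


def best_width_fit(
    sequences: list[str],
    w: int,
    background: Background,
    max_starts: int | None = None,
    pseudocount: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> Motif | None:
    """Warm-start over distinct w-mers, then run the best start to convergence."""
    words = _distinct_words(sequences, w, max_starts)
    if not words:
        return None
    X, _, _ = _windows(_index_sequences(sequences), w)
    log_pb = np.log(background.freqs)[X].sum(axis=1)
    best = _warm_start_word(X, log_pb, words, pseudocount)
    return em_fit(sequences, w, best, background, max_iter=max_iter, tol=tol,
                  pseudocount=pseudocount)


def _canonical_shuffle(sequences: list[str], rng: np.random.Generator) -> list[str]:
    """Composition-preserving shuffle, invariant to the input sequence order.

    Mask letters stay in place; the remaining letters are pooled, sorted and
    dealt back by a seeded permutation into the sequences taken in canonical
    (sorted) order.
    """
    ordered = sorted(sequences)
    letters = sorted(c for s in ordered for c in s if c != MASK_LETTER)
    perm = rng.permutation(len(letters))
    shuffled = [letters[i] for i in perm]
    out, pos = [], 0
    for s in ordered:
        chars = []
        for c in s:
            if c == MASK_LETTER:
                chars.append(c)
            else:
                chars.append(shuffled[pos])
                pos += 1
        out.append("".join(chars))
    return out


def compute_evalue(
    motif: Motif,
    sequences: list[str],
    background: Background,
    n_shuffles: int,
    seed: int,
    widths_scanned: int = 1,
    max_null_starts: int | None = 100,
    pseudocount: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> float:
    """Monte-Carlo E-value of a fitted motif under a letter-shuffle null.

    For each shuffle the width-w discovery (best warm start, EM to
    convergence) is rerun and its site LLR recorded;
    ``p = (1 + #{null LLR >= observed LLR}) / (n_shuffles + 1)`` and the
    E-value is ``p * widths_scanned``.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_shuffles):
        null_seqs = _canonical_shuffle(sequences, rng)
        null = best_width_fit(
            null_seqs, motif.width, background, max_starts=max_null_starts,
            pseudocount=pseudocount, tol=tol, max_iter=max_iter,
        )
        null_llr = null.llr if null is not None else 0.0
        if null_llr >= motif.llr:
            exceed += 1
    p = (1 + exceed) / (n_shuffles + 1)
    return p * widths_scanned


def _mask_sites(sequences: list[str], motif: Motif) -> list[str]:
    out = [list(s) for s in sequences]
    for sid, off, _ in motif.sites:
        for k in range(off, off + motif.width):
            out[sid][k] = MASK_LETTER
    return ["".join(s) for s in out]


def discover_motifs(
    sequences: list[str],
    min_w: int = 2,
    max_w: int = 30,
    n_motifs: int = 10,
    seed: int = 0,
    n_shuffles: int = 99,
    evalue_threshold: float = 0.05,
    pseudocount: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 200,
    max_starts: int | None = None,
    max_null_starts: int | None = 100,
) -> list[Motif]:
    """Sequential motif discovery with per-round E-value width selection.

    Returns motifs sorted by ascending E-value; discovery stops after
    ``n_motifs`` rounds or when no width reaches the significance threshold.
    """
    if not sequences:
        raise ValueError("no input sequences")
    work = list(sequences)
    try:
        background = fit_background(work)
    except ValueError:
        return []
    found: list[Motif] = []
    widths = [w for w in range(min_w, max_w + 1)]
    for round_no in range(n_motifs):
        best: Motif | None = None
        for w in widths:
            cand = best_width_fit(
                work, w, background, max_starts=max_starts,
                pseudocount=pseudocount, tol=tol, max_iter=max_iter,
            )
            if cand is None or cand.nsites == 0:
                continue
            cand.evalue = compute_evalue(
                cand, work, background, n_shuffles=n_shuffles,
                seed=int(np.random.SeedSequence([seed, round_no, w]).generate_state(1)[0] % (2**31)),
                widths_scanned=len(widths), max_null_starts=max_null_starts,
                pseudocount=pseudocount, tol=tol, max_iter=max_iter,
            )
            if (
                best is None
                or cand.evalue < best.evalue - 1e-12
                or (abs(cand.evalue - best.evalue) <= 1e-12 and cand.llr > best.llr)
            ):
                best = cand
        if best is None or not best.evalue < evalue_threshold:
            break
        found.append(best)
        work = _mask_sites(work, best)
    found.sort(key=lambda m: (m.evalue, -m.llr))
    return found


def split_on_O(consensus: str) -> list[str]:
    """Maximal O-free substrings of a consensus, dropping segments shorter than 2."""
    return [seg for seg in consensus.split("O") if len(seg) >= 2]


class MotifMiner(BaseEstimator):
    """Sequence-motif discovery estimator (scikit-learn style).

    Parameters mirror :func:`discover_motifs`.  After :meth:`fit`, the
    discovered motifs are in ``motifs_`` (ascending E-value), the fitted
    background in ``background_`` and the O-free consensus segments in
    ``segments_``.
    """

    def __init__(
        self,
        min_w: int = 2,
        max_w: int = 30,
        n_motifs: int = 10,
        n_shuffles: int = 99,
        evalue_threshold: float = 0.05,
        pseudocount: float = 0.1,
        tol: float = 1e-6,
        max_iter: int = 200,
        max_starts: int | None = None,
        max_null_starts: int | None = 100,
        random_state: int = 0,
    ):
        self.min_w = min_w
        self.max_w = max_w
        self.n_motifs = n_motifs
        self.n_shuffles = n_shuffles
        self.evalue_threshold = evalue_threshold
        self.pseudocount = pseudocount
        self.tol = tol
        self.max_iter = max_iter
        self.max_starts = max_starts
        self.max_null_starts = max_null_starts
        self.random_state = random_state

    def fit(self, X: list[str], y=None) -> "MotifMiner":
        """Discover motifs in a corpus of single-letter sequences."""
        self.background_ = fit_background(X, self.pseudocount)
        self.motifs_ = discover_motifs(
            X,
            min_w=self.min_w,
            max_w=self.max_w,
            n_motifs=self.n_motifs,
            seed=self.random_state,
            n_shuffles=self.n_shuffles,
            evalue_threshold=self.evalue_threshold,
            pseudocount=self.pseudocount,
            tol=self.tol,
            max_iter=self.max_iter,
            max_starts=self.max_starts,
            max_null_starts=self.max_null_starts,
        )
        self.segments_ = [seg for m in self.motifs_ for seg in split_on_O(m.consensus)]
        return self
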