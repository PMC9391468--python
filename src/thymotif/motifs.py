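"""De novo motif discovery in active-region sequences.

Over-represented 6–30 bp motifs are found with a seeded expectation–
maximization finder under the ZOOPS model (zero or one motif occurrence
per sequence), scored against a first-order Markov background so that
mono- and dinucleotide biases (e.g. CG content) do not masquerade as
motifs. Discovery significance is an empirical E-value: the final ZOOPS
objective is recomputed on dinucleotide-preserving shuffles of the
sequence set, and the resulting empirical p-value is multiplied by the
number of motif widths examined. Discovered motifs can be compared to a
known-motif library by best-aligned Pearson correlation with
column-permutation p-values and Benjamini–Hochberg q-values.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.optimize import minimize_scalar
from scipy.stats import false_discovery_control

from .sequences import ALPHABET, N_CODE, decode, dinucleotide_shuffle, encode

logger = logging.getLogger(__name__)

_COMP = np.array([3, 2, 1, 0, 4])


# ---------------------------------------------------------------------------
# background model


@dataclass
class BackgroundModel:
    """Order-0 or order-1 Markov model of nucleotide composition.

    ``freq0`` is the marginal base distribution; for order 1, ``cond[a, b]``
    is P(next = b | current = a). Fitted with pseudocount 1 per cell and
    both strands pooled, so the model is reverse-complement symmetric.
    """

    order: int
    freq0: np.ndarray
    cond: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.order not in (0, 1):
            raise ValueError("background order must be 0 or 1")
        if not math.isclose(float(self.freq0.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("marginal frequencies must sum to 1")
        if self.order == 1:
            if self.cond is None:
                raise ValueError("order-1 model needs conditional frequencies")
            if not np.allclose(self.cond.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError("conditional rows must sum to 1")

    @property
    def log0(self) -> np.ndarray:
        """log freq0 padded with a zero entry for N."""
        out = np.zeros(5)
        out[:4] = np.log(self.freq0)
        return out

    @property
    def logcond(self) -> np.ndarray:
        """(5, 5) log conditional matrix; N rows/columns are 0."""
        out = np.zeros((5, 5))
        if self.order == 1:
            out[:4, :4] = np.log(self.cond)
        else:
            out[:4, :4] = np.log(self.freq0)[None, :]
        return out

    def word_logprobs(self, width: int) -> np.ndarray:
        """Log-probability of every ``4**width`` word.

        Word codes put position 0 in the lowest two bits (little-endian
        base-4), matching the seed enumeration in discovery.
        """
        lp = np.log(self.freq0).copy()
        trans = self.logcond[:4, :4]
        last = np.arange(4)  # last base of each current word code
        for _ in range(1, width):
            m = len(lp)
            # new code = old code + d * 4^(k-1): old varies fastest
            lp = (lp[:, None] + trans[last, :]).ravel(order="F")
            last = np.repeat(np.arange(4), m)
        return lp

    def sample(self, length: int, rng: np.random.Generator) -> np.ndarray:
        """Draw an encoded sequence of ``length`` bases from the model."""
        out = np.empty(length, dtype=np.int8)
        out[0] = rng.choice(4, p=self.freq0)
        if self.order == 0:
            out[1:] = rng.choice(4, size=length - 1, p=self.freq0)
        else:
            cum = np.cumsum(self.cond, axis=1)
            u = rng.random(length - 1)
            for t in range(1, length):
                out[t] = np.searchsorted(cum[out[t - 1]], u[t - 1])
        return out


def fit_background(seqs: Sequence[str], order: int = 1) -> BackgroundModel:
    """Maximum-likelihood background from sequences, both strands pooled.

    Pseudocount 1 per count cell. Requires ≥ 100 total bases.
    """
    if not seqs:
        raise ValueError("cannot fit a background model from no sequences")
    total = sum(len(s) for s in seqs)
    if total < 100:
        raise ValueError(f"need ≥ 100 bases to fit a background, got {total}")
    base_counts = np.ones(4)
    pair_counts = np.ones((4, 4))
    for s in seqs:
        codes = encode(s)
        ok = codes != N_CODE
        vals, cnts = np.unique(codes[ok], return_counts=True)
        base_counts[vals] += cnts
        base_counts[_COMP[vals]] += cnts  # opposite strand
        if order == 1 and len(codes) > 1:
            a, b = codes[:-1], codes[1:]
            keep = (a != N_CODE) & (b != N_CODE)
            np.add.at(pair_counts, (a[keep], b[keep]), 1)
            np.add.at(pair_counts, (_COMP[b[keep]], _COMP[a[keep]]), 1)
    freq0 = base_counts / base_counts.sum()
    if order == 0:
        return BackgroundModel(0, freq0)
    cond = pair_counts / pair_counts.sum(axis=1, keepdims=True)
    return BackgroundModel(1, freq0, cond)


# ---------------------------------------------------------------------------
# PWM container


@dataclass
class Pwm:
    """Position probability matrix of a DNA motif.

    ``probs`` is 4×width (rows A, C, G, T); every column sums to 1 and all
    entries are positive after the export pseudocount.
    """

    probs: np.ndarray
    name: str = "motif"
    nsites: int = 0
    evalue: float | None = None
    source_dataset: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM must have 4 rows (A, C, G, T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError(f"PWM columns must sum to 1 ({self.name})")
        if np.any(self.probs <= 0):
            raise ValueError(f"PWM entries must be positive ({self.name})")

    @property
    def width(self) -> int:
        return self.probs.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in np.argmax(self.probs, axis=0))

    def reverse_complement(self) -> "Pwm":
        return Pwm(
            self.probs[::-1, ::-1].copy(),
            name=f"{self.name}_rc",
            nsites=self.nsites,
            evalue=self.evalue,
            source_dataset=self.source_dataset,
            meta=dict(self.meta),
        )

    def information_content(self, bg: np.ndarray | None = None) -> np.ndarray:
        """Per-column information content in bits relative to ``bg``."""
        q = np.full(4, 0.25) if bg is None else np.asarray(bg)
        return np.sum(self.probs * np.log2(self.probs / q[:, None]), axis=0)


# ---------------------------------------------------------------------------
# encoded-set helpers


def _pad_encode(seqs: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """Encode sequences into a padded (n, Lmax) matrix; N=4 pads the tail."""
    n = len(seqs)
    lmax = max(len(s) for s in seqs)
    X = np.full((n, lmax), N_CODE, dtype=np.int8)
    lengths = np.empty(n, dtype=np.int64)
    for i, s in enumerate(seqs):
        codes = encode(s)
        X[i, : len(codes)] = codes
        lengths[i] = len(codes)
    return X, lengths


def _bg_window_logprob(X: np.ndarray, bg: BackgroundModel, width: int) -> np.ndarray:
    """Order-aware background log-prob of each window start (n, L-w+1)."""
    log0 = bg.log0
    logcond = bg.logcond
    t0 = log0[X]  # marginal at window start
    c = np.zeros_like(t0)
    c[:, 1:] = logcond[X[:, :-1], X[:, 1:]]
    C = np.cumsum(c, axis=1)
    nwin = X.shape[1] - width + 1
    # window [j, j+w): t0[:, j] + C[:, j+w-1] - C[:, j]
    return t0[:, :nwin] + C[:, width - 1 :] - C[:, :nwin]


def _pwm_window_scores(Xw: np.ndarray, logprobs: np.ndarray) -> np.ndarray:
    """Sum log-prob of each window under a (5, w) per-position table."""
    w = Xw.shape[-1]
    return logprobs[Xw, np.arange(w)].sum(axis=-1)


class _ZoopsScan:
    """Precomputed window views and validity masks for one width."""

    def __init__(self, X: np.ndarray, bg: BackgroundModel, width: int):
        self.X = X
        self.width = width
        self.Xw = sliding_window_view(X, width, axis=1)  # (n, nwin, w)
        self.valid = ~np.any(self.Xw == N_CODE, axis=-1)
        self.m = self.valid.sum(axis=1)  # valid windows per strand
        self.lp_bg = _bg_window_logprob(X, bg, width)

    def llr(self, probs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Forward and reverse-strand log likelihood ratios per window."""
        lp = np.zeros((5, self.width))
        lp[:4] = np.log(probs)
        lp_rc = np.zeros((5, self.width))
        lp_rc[:4] = np.log(probs[::-1, ::-1])
        f = _pwm_window_scores(self.Xw, lp) - self.lp_bg
        r = _pwm_window_scores(self.Xw, lp_rc) - self.lp_bg
        ninf = -np.inf
        f = np.where(self.valid, f, ninf)
        r = np.where(self.valid, r, ninf)
        return f, r


def _zoops_loglik(gamma: float, ratio_sum: np.ndarray) -> float:
    """Relative ZOOPS log-likelihood given per-sequence mean LLR-exp sums."""
    return float(np.sum(np.log((1.0 - gamma) + gamma * ratio_sum)))


def _em_zoops(
    scan: _ZoopsScan,
    probs: np.ndarray,
    gamma: float = 0.3,
    max_iter: int = 200,
    tol: float = 1e-4,
    em_pseudocount: float = 0.01,
) -> tuple[np.ndarray, float, float, np.ndarray, np.ndarray]:
    """Run ZOOPS EM from ``probs``; returns refined PWM, gamma, final
    log-likelihood and the final responsibilities (fwd, rev).

    The EM objective — the ZOOPS log likelihood plus the Dirichlet
    smoothing term of the M-step — never decreases; a drop beyond
    round-off raises, guarding the M-step implementation.
    """
    n, nwin = scan.valid.shape
    w = scan.width
    denom = np.where(scan.m > 0, 2.0 * scan.m, 1.0)
    prev_obj = -np.inf
    ll = -np.inf
    zf = zr = None
    for _ in range(max_iter):
        f, r = scan.llr(probs)
        with np.errstate(over="ignore"):
            ef = np.where(scan.valid, np.exp(f), 0.0)
            er = np.where(scan.valid, np.exp(r), 0.0)
        ratio_sum = (ef.sum(axis=1) + er.sum(axis=1)) / denom
        ll = _zoops_loglik(gamma, ratio_sum)
        obj = ll + em_pseudocount * float(np.sum(np.log(probs)))
        if obj < prev_obj - 1e-8 * max(1.0, abs(prev_obj)):
            raise AssertionError(
                f"ZOOPS EM objective decreased: {prev_obj} -> {obj}"
            )
        seq_denom = (1.0 - gamma) + gamma * ratio_sum
        zf = (gamma / denom)[:, None] * ef / seq_denom[:, None]
        zr = (gamma / denom)[:, None] * er / seq_denom[:, None]
        if obj - prev_obj < tol and prev_obj > -np.inf:
            break
        prev_obj = obj
        # M-step
        gamma = float(np.clip((zf.sum() + zr.sum()) / n, 1e-6, 0.999))
        counts = np.full((4, w), em_pseudocount)
        flat_f = zf.ravel()
        flat_r = zr.ravel()
        base_f = scan.Xw.reshape(-1, w)
        for i in range(w):
            col = base_f[:, i]
            ok = col != N_CODE
            np.add.at(counts[:, i], col[ok], flat_f[ok])
            # reverse strand: motif column i aligns to window pos w-1-i, complemented
            col_r = base_f[:, w - 1 - i]
            ok_r = col_r != N_CODE
            np.add.at(counts[:, i], _COMP[col_r[ok_r]], flat_r[ok_r])
        probs = counts / counts.sum(axis=0, keepdims=True)
    return probs, gamma, ll, zf, zr


def _zoops_objective(pwm_probs: np.ndarray, scan: _ZoopsScan) -> float:
    """ZOOPS objective of a fixed PWM with the site rate profiled out."""
    f, r = scan.llr(pwm_probs)
    with np.errstate(over="ignore"):
        ef = np.where(scan.valid, np.exp(f), 0.0)
        er = np.where(scan.valid, np.exp(r), 0.0)
    denom = np.where(scan.m > 0, 2.0 * scan.m, 1.0)
    ratio_sum = (ef.sum(axis=1) + er.sum(axis=1)) / denom
    res = minimize_scalar(
        lambda g: -_zoops_loglik(g, ratio_sum),
        bounds=(1e-6, 0.999),
        method="bounded",
    )
    return float(-res.fun)


# ---------------------------------------------------------------------------
# public operations


def subsample_sequences(
    seqs: Sequence[str], n: int = 600, seed: int | np.random.Generator = 0
) -> list[str]:
    """Uniform sample of ``n`` sequences without replacement.

    Identity when the input has at most ``n`` sequences; reproducible for
    a fixed seed. Mirrors the default initial-discovery subsampling of
    600 sequences.
    """
    if n < 1:
        raise ValueError("subsample size must be ≥ 1")
    if len(seqs) <= n:
        return list(seqs)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(seqs), size=n, replace=False)
    return [seqs[i] for i in sorted(idx)]


def significance_threshold(alpha: float = 0.01, counts: Sequence[int] = ()) -> float:
    """Bonferroni bound: ``alpha`` divided by the product of test counts.

    E.g. 0.01 over 17 datasets × 20 motifs → 2.94e-5.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    out = float(alpha)
    for c in counts:
        if c < 1:
            raise ValueError(f"test count must be ≥ 1, got {c}")
        out /= c
    return out


def _seed_words(
    scan: _ZoopsScan, bg: BackgroundModel, width: int, n_seeds: int
) -> list[int]:
    """Top seed words by background-corrected enrichment, rc-deduplicated."""
    pows = 4 ** np.arange(width)
    Xw = scan.Xw
    ok = scan.valid
    codes = (Xw[ok].astype(np.int64) * pows).sum(axis=-1)
    obs = np.bincount(codes, minlength=4**width).astype(float)
    # add opposite-strand occurrences
    idx = np.arange(4**width)
    digits = (idx[:, None] >> (2 * np.arange(width))) & 3
    rc_digits = 3 - digits[:, ::-1]
    rc_map = (rc_digits * pows).sum(axis=1)
    obs_both = obs + obs[rc_map]
    expected = 2.0 * ok.sum() * np.exp(bg.word_logprobs(width))
    enrich = (obs_both + 1.0) / (expected + 1.0)
    order = np.argsort(-enrich)
    seeds: list[int] = []
    seen: set[int] = set()
    for code in order:
        canon = min(int(code), int(rc_map[code]))
        if canon in seen:
            continue
        seen.add(canon)
        seeds.append(int(code))
        if len(seeds) >= n_seeds:
            break
    return seeds


def _seed_probs(code: int, width: int, match: float = 0.55) -> np.ndarray:
    probs = np.full((4, width), (1.0 - match) / 3.0)
    for i in range(width):
        probs[(code >> (2 * i)) & 3, i] = match
    return probs


def _seed_flank_init(
    scan: _ZoopsScan, code: int, flank_init: int = 3
) -> tuple[np.ndarray, float]:
    """Initial PWM from the exact occurrences of a seed word, extended by
    ``flank_init`` columns of their observed flanking bases.

    Exact matches of an enriched word are dominated by true sites, so
    their flanks carry the motif's outer columns from the start — this
    is what lets EM escape the width bottleneck on long sequences.
    Returns the initial probability matrix and its summed column
    information content (used to pre-rank candidates cheaply).
    """
    w = scan.width
    pows = 4 ** np.arange(w)
    codes = (scan.Xw.astype(np.int64) * pows).sum(axis=-1)
    codes[~scan.valid] = -1
    digits = [(code >> (2 * i)) & 3 for i in range(w)]
    rc_code = sum((3 - d) * 4 ** (w - 1 - i) for i, d in enumerate(digits))
    w0 = w + 2 * flank_init
    counts = np.zeros((4, w0))
    Xp = np.pad(scan.X, ((0, 0), (flank_init, flank_init)), constant_values=N_CODE)
    for s, j in zip(*np.nonzero(codes == code)):
        win = Xp[s, j : j + w0]
        for i, b in enumerate(win):
            if b != N_CODE:
                counts[b, i] += 1.0
    for s, j in zip(*np.nonzero(codes == rc_code)):
        win = Xp[s, j : j + w0]
        for i, b in enumerate(win[::-1]):
            if b != N_CODE:
                counts[_COMP[b], i] += 1.0
    probs = (counts + 0.5) / (counts + 0.5).sum(axis=0, keepdims=True)
    ic = float(np.sum(probs * np.log2(probs / 0.25)))
    return probs, ic


def _site_counts_extended(
    X: np.ndarray, zf: np.ndarray, zr: np.ndarray, width: int
) -> np.ndarray:
    """Responsibility-weighted base counts over sites extended by 1 bp
    on each side (motif coordinates; reverse-strand sites contribute
    reverse-complemented)."""
    wext = width + 2
    counts = np.zeros((4, wext))
    Xp = np.pad(X, ((0, 0), (1, 1)), constant_values=N_CODE)
    # window j of Xe spans original positions j-1 .. j+width
    Xe = sliding_window_view(Xp, wext, axis=1).reshape(-1, wext)
    flat_f, flat_r = zf.ravel(), zr.ravel()
    for i in range(wext):
        col = Xe[:, i]
        ok = col != N_CODE
        np.add.at(counts[:, i], col[ok], flat_f[ok])
        col_r = Xe[:, wext - 1 - i]
        ok_r = col_r != N_CODE
        np.add.at(counts[:, i], _COMP[col_r[ok_r]], flat_r[ok_r])
    return counts


def discover_motifs(
    seqs: Sequence[str],
    bg: BackgroundModel,
    wmin: int = 6,
    wmax: int = 30,
    nmotifs: int = 20,
    seed: int | np.random.Generator = 0,
    n_seed_candidates: int = 8,
    n_null: int = 50,
    min_extend_ic: float = 0.25,
    export_pseudocount: float = 0.1,
) -> list[Pwm]:
    """Discover up to ``nmotifs`` motifs of width ``wmin``–``wmax``.

    For each motif: candidate seed words of width ``wmin`` are ranked by
    background-corrected enrichment on both strands; the best candidates
    are refined by ZOOPS EM; the winning motif is greedily extended one
    column at a time while the flanking column's information content
    stays above ``min_extend_ic`` bits (width selection within
    [wmin, wmax]); its sites are masked and the search repeats.

    E-values are computed on a held-out half of the sequences that EM
    never sees: the fixed PWM's ZOOPS objective there is compared with
    the same objective on a shared set of dinucleotide-shuffled nulls
    (:func:`score_evalue`), so the E-value is free of the selection bias
    of evaluating a fitted motif on its own training data. Motifs are
    returned sorted by E-value.
    """
    if len(seqs) < 10:
        raise ValueError("motif discovery needs at least 10 sequences")
    if min(len(s) for s in seqs) < wmin:
        raise ValueError(f"all sequences must be at least {wmin} bases long")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seqs))
    train_idx = np.sort(perm[: max(5, len(seqs) // 2)])
    eval_idx = np.sort(perm[max(5, len(seqs) // 2) :])
    if len(eval_idx) < 5:  # too few sequences to split; evaluate in-sample
        eval_idx = train_idx
    train_seqs = [seqs[i] for i in train_idx]
    eval_seqs = [seqs[i] for i in eval_idx]
    X, _ = _pad_encode(train_seqs)
    eval_X, _ = _pad_encode(eval_seqs)

    # shared held-out null sequence sets for E-value scoring
    null_X = [
        _pad_encode(
            [decode(dinucleotide_shuffle(encode(s), rng)) for s in eval_seqs]
        )[0]
        for _ in range(n_null)
    ]

    motifs: list[Pwm] = []
    low_complexity_seen = False
    for imotif in range(nmotifs):
        scans: dict[int, _ZoopsScan] = {}
        scan0 = _ZoopsScan(X, bg, wmin)
        if scan0.m.sum() == 0:
            break
        seeds = _seed_words(scan0, bg, wmin, n_seed_candidates)
        if not seeds:
            break
        # initialize each candidate from its exact-occurrence flanks and
        # pre-rank by initial information content; EM only the best few
        inits = [_seed_flank_init(scan0, code) for code in seeds]
        order = np.argsort([-ic for _, ic in inits])
        best = None
        for k in order[:3]:
            probs0 = inits[k][0]
            if probs0.shape[1] > wmax:
                cut = (probs0.shape[1] - wmax) // 2
                probs0 = probs0[:, cut : cut + wmax]
                probs0 = probs0 / probs0.sum(axis=0, keepdims=True)
            w0 = probs0.shape[1]
            if w0 not in scans:
                scans[w0] = _ZoopsScan(X, bg, w0)
            probs, gamma, ll, zf, zr = _em_zoops(scans[w0], probs0, max_iter=30)
            if best is None or ll > best[2]:
                best = (probs, gamma, ll, zf, zr, w0)
        width = best[5]
        probs, gamma, ll, zf, zr = _em_zoops(
            scans[width], best[0], gamma=best[1], max_iter=120
        )
        widths_examined = 1
        scan = scans[width]
        uni = np.full(4, 0.25)
        # trim uninformative edge columns (downward width selection)
        while width > wmin:
            col_ic = np.sum(probs * np.log2(probs / uni[:, None]), axis=0)
            if col_ic[0] < min_extend_ic and col_ic[0] <= col_ic[-1]:
                probs = probs[:, 1:]
            elif col_ic[-1] < min_extend_ic:
                probs = probs[:, :-1]
            else:
                break
            probs = probs / probs.sum(axis=0, keepdims=True)
            width -= 1
            widths_examined += 1
            if width not in scans:
                scans[width] = _ZoopsScan(X, bg, width)
            scan = scans[width]
            probs, gamma, ll, zf, zr = _em_zoops(scan, probs, gamma=gamma, max_iter=30)
        # greedy width growth
        while width < wmax:
            ext = _site_counts_extended(X, zf, zr, width)
            tot = ext.sum(axis=0)
            if tot[0] <= 0 and tot[-1] <= 0:
                break
            with np.errstate(divide="ignore", invalid="ignore"):
                probs_ext = (ext + 0.25) / (ext + 0.25).sum(axis=0, keepdims=True)
            uni = np.full(4, 0.25)
            ic = np.sum(
                probs_ext * np.log2(probs_ext / uni[:, None]), axis=0
            )
            side = 0 if ic[0] >= ic[-1] else -1
            widths_examined += 1
            if ic[side] < min_extend_ic:
                break
            if side == 0:
                cand = np.concatenate([probs_ext[:, :1], probs], axis=1)
            else:
                cand = np.concatenate([probs, probs_ext[:, -1:]], axis=1)
            scan_w = _ZoopsScan(X, bg, width + 1)
            probs_w, gamma_w, ll_w, zf_w, zr_w = _em_zoops(
                scan_w, cand, gamma=gamma, max_iter=50
            )
            probs, gamma, ll, zf, zr = probs_w, gamma_w, ll_w, zf_w, zr_w
            width += 1
            scan = scan_w
        # export with pseudocount
        exp_sites = float(zf.sum() + zr.sum())
        counts = probs * max(exp_sites, 1.0)
        final = (counts + export_pseudocount) / (
            counts + export_pseudocount
        ).sum(axis=0, keepdims=True)
        consensus_bases = set(np.argmax(final, axis=0).tolist())
        low_complexity = len(consensus_bases) <= 1
        if low_complexity and low_complexity_seen:
            _mask_sites(X, zf, zr, width)
            continue
        pwm = Pwm(
            final,
            name=f"motif_{imotif + 1}",
            nsites=max(1, round(exp_sites)),
            meta={
                "widths_examined": widths_examined,
                "gamma": gamma,
                "objective": ll,
                "low_complexity": low_complexity,
            },
        )
        # width selection used only the training half, so the held-out
        # empirical p needs no width correction (multiplier 1)
        stats = _evalue_stats(pwm.probs, pwm.width, eval_X, null_X[:n_null], bg)
        pwm.evalue = stats["p_emp"]
        pwm.meta.update(stats)
        motifs.append(pwm)
        if low_complexity:
            low_complexity_seen = True
        _mask_sites(X, zf, zr, width)
    motifs.sort(key=lambda m: (m.evalue, -m.meta.get("null_z", 0.0), m.name))
    for i, m in enumerate(motifs, 1):
        m.name = f"motif_{i}"
    return motifs


def _mask_sites(
    X: np.ndarray, zf: np.ndarray, zr: np.ndarray, width: int, min_z: float = 0.5
) -> None:
    """Mask (set to N) the best site per sequence where the total site
    responsibility exceeds ``min_z``."""
    z = zf + zr
    tot = z.sum(axis=1)
    for s in np.flatnonzero(tot > min_z):
        j = int(np.argmax(z[s]))
        X[s, j : j + width] = N_CODE


def _evalue_stats(
    probs: np.ndarray,
    width: int,
    obs_X: np.ndarray,
    null_X: Sequence[np.ndarray],
    bg: BackgroundModel,
) -> dict:
    obs = _zoops_objective(probs, _ZoopsScan(obs_X, bg, width))
    null_objs = np.array(
        [_zoops_objective(probs, _ZoopsScan(Xn, bg, width)) for Xn in null_X]
    )
    exceed = int(np.sum(null_objs >= obs))
    sd = float(null_objs.std(ddof=1)) if len(null_objs) > 1 else 0.0
    z = (obs - float(null_objs.mean())) / sd if sd > 0 else 0.0
    return {
        "p_emp": (1 + exceed) / (len(null_objs) + 1),
        "eval_objective": obs,
        "null_z": float(z),
    }


def score_evalue(
    pwm: Pwm,
    seqs: Sequence[str],
    bg: BackgroundModel,
    n_null: int = 50,
    seed: int | np.random.Generator = 0,
    widths_examined: int | None = None,
    _null_X: list[np.ndarray] | None = None,
    _obs_X: np.ndarray | None = None,
) -> float:
    """Empirical discovery E-value of a motif on a sequence set.

    The ZOOPS objective of the fixed PWM (site rate profiled out) is
    compared against the same objective on ``n_null`` dinucleotide-
    preserving shuffles of the sequences; the empirical p-value
    ``(1 + #{null ≥ observed}) / (n_null + 1)`` is multiplied by the
    number of widths examined (relevant for in-sample evaluation;
    :func:`discover_motifs` evaluates on held-out sequences where width
    selection played no part and uses multiplier 1).
    """
    if n_null < 1:
        raise ValueError("n_null must be ≥ 1")
    if n_null < 10:
        warnings.warn("n_null < 10 gives a very coarse E-value", stacklevel=2)
    if widths_examined is None:
        widths_examined = int(pwm.meta.get("widths_examined", 1))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if _obs_X is None:
        _obs_X, _ = _pad_encode(seqs)
    if _null_X is None:
        _null_X = []
        for _ in range(n_null):
            codes = [dinucleotide_shuffle(encode(s), rng) for s in seqs]
            _null_X.append(_pad_encode([decode(c) for c in codes])[0])
    stats = _evalue_stats(pwm.probs, pwm.width, _obs_X, _null_X[:n_null], bg)
    return stats["p_emp"] * max(1, widths_examined)


# ---------------------------------------------------------------------------
# motif comparison (tomtom role, simplified)


@dataclass
class MotifMatch:
    query: Pwm
    target: Pwm
    offset: int
    orientation: str  # "+" or "-"
    similarity: float
    p_value: float
    q_value: float = float("nan")


def _best_alignment(qp: np.ndarray, tp: np.ndarray, min_overlap: int):
    """Best Pearson correlation of aligned probability columns."""
    wq, wt = qp.shape[1], tp.shape[1]
    best = (-2.0, 0)
    for off in range(-(wq - min_overlap), wt - min_overlap + 1):
        qlo, qhi = max(0, -off), min(wq, wt - off)
        if qhi - qlo < min_overlap:
            continue
        a = qp[:, qlo:qhi].ravel()
        b = tp[:, qlo + off : qhi + off].ravel()
        sa, sb = a.std(), b.std()
        if sa == 0 or sb == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        if r > best[0]:
            best = (r, off)
    return best


def compare_motifs(
    query: Pwm,
    library: Sequence[Pwm],
    n_perm: int = 1000,
    seed: int | np.random.Generator = 0,
) -> list[MotifMatch]:
    """Compare a motif to a library by best-aligned column correlation.

    Similarity is the maximum Pearson correlation of overlapping
    probability columns over all offsets and both orientations, with
    minimum overlap ``max(4, min(widths) // 2)``. P-values come from
    column-order permutations of the query; q-values are Benjamini–
    Hochberg over the library.
    """
    if not library:
        raise ValueError("motif library is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = [rng.permutation(query.width) for _ in range(n_perm)]
    matches = []
    for target in library:
        min_overlap = max(4, min(query.width, target.width) // 2)
        cand = []
        for orient, tp in (("+", target.probs), ("-", target.probs[::-1, ::-1])):
            r, off = _best_alignment(query.probs, tp, min_overlap)
            cand.append((r, orient, off))
        sim, orient, off = max(cand)
        exceed = 0
        for perm in perms:
            qp = query.probs[:, perm]
            r_p = max(
                _best_alignment(qp, target.probs, min_overlap)[0],
                _best_alignment(qp, target.probs[::-1, ::-1], min_overlap)[0],
            )
            if r_p >= sim:
                exceed += 1
        p = (1 + exceed) / (n_perm + 1)
        matches.append(MotifMatch(query, target, off, orient, sim, p))
    qvals = false_discovery_control([m.p_value for m in matches], method="bh")
    for m, q in zip(matches, qvals):
        m.q_value = float(q)
    return matches


# ---------------------------------------------------------------------------
# MEME minimal format I/O


def write_meme(
    path: str | Path, motifs: Sequence[Pwm], bg: BackgroundModel | None = None
) -> None:
    """Write motifs in MEME minimal text format (version 4)."""
    freqs = bg.freq0 if bg is not None else np.full(4, 0.25)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            " ".join(f"{b} {f:.5f}" for b, f in zip(ALPHABET, freqs)) + "\n\n"
        )
        for m in motifs:
            fh.write(f"MOTIF {m.name}\n")
            ev = m.evalue if m.evalue is not None else 0
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {max(1, m.nsites)} E= {ev:.3g}\n"
            )
            for col in m.probs.T:
                fh.write(" " + " ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[Pwm]:
    """Read motifs from MEME minimal text format.

    Parsed directly: Bio.motifs' minimal parser quantizes letter
    probabilities to nsites-scaled integer counts, which destroys the
    small probabilities that log-odds scanning depends on.
    """
    out = []
    with open(path) as fh:
        lines = iter(fh)
        name = None
        for line in lines:
            line = line.strip()
            if line.startswith("MOTIF"):
                name = line.split()[1]
            elif line.startswith("letter-probability matrix") and name is not None:
                attrs = dict(
                    zip(*(iter(line.split(":", 1)[1].replace("=", " ").split()),) * 2)
                )
                width = int(attrs["w"])
                cols = []
                for _ in range(width):
                    cols.append([float(x) for x in next(lines).split()])
                probs = np.asarray(cols, dtype=float).T
                probs = np.clip(probs, 1e-7, None)
                probs /= probs.sum(axis=0, keepdims=True)
                out.append(
                    Pwm(
                        probs,
                        name=name,
                        nsites=int(float(attrs.get("nsites", 0))),
                        evalue=float(attrs["E"]) if "E" in attrs else None,
                    )
                )
                name = None
    return out


def read_jaspar_pfm(path: str | Path) -> list[Pwm]:
    """Read motifs from JASPAR PFM text; counts are normalized to
    probabilities with pseudocount 1 per cell."""
    from Bio import motifs as bio_motifs

    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        counts = np.array([m.counts[b] for b in ALPHABET], dtype=float)
        counts += 1.0
        out.append(Pwm(counts / counts.sum(axis=0, keepdims=True), name=m.name))
    return out
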