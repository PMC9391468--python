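"""Shared fixtures: planted-motif sequence sets and a tiny genome."""

from __future__ import annotations

import numpy as np
import pytest

from thymotif.motifs import Pwm, discover_motifs, fit_background

PLANT = "TGACGTCATTGG"


def planted_pwm_probs(consensus: str = PLANT, match: float = 0.925) -> np.ndarray:
    """The matrix a 1.5-bit/column planted motif corresponds to."""
    probs = np.full((4, len(consensus)), (1 - match) / 3)
    for i, b in enumerate(consensus):
        probs["ACGT".index(b), i] = match
    return probs


def make_planted_set(
    seed: int = 1,
    n: int = 200,
    length: int = 100,
    rate: float = 0.7,
    consensus: str = PLANT,
) -> list[str]:
    rng = np.random.default_rng(seed)
    seqs = []
    for _ in range(n):
        s = "".join(rng.choice(list("ACGT"), length))
        if rng.random() < rate:
            j = int(rng.integers(0, length - len(consensus)))
            s = s[:j] + consensus + s[j + len(consensus) :]
        seqs.append(s)
    return seqs


@pytest.fixture(scope="session")
def planted_seqs() -> list[str]:
    return make_planted_set()


@pytest.fixture(scope="session")
def planted_motifs(planted_seqs):
    """Discovery output on the default planted fixture (shared: ~3 s)."""
    bg = fit_background(planted_seqs, order=1)
    return discover_motifs(planted_seqs, bg, nmotifs=3, seed=5)


def best_orientation_corr(pwm: Pwm, truth: np.ndarray) -> float:
    """Mean per-column Pearson correlation, best over both orientations."""
    best = -1.0
    for cand in (pwm.probs, pwm.probs[::-1, ::-1]):
        if cand.shape[1] != truth.shape[1]:
            continue
        cors = [
            np.corrcoef(cand[:, i], truth[:, i])[0, 1]
            for i in range(truth.shape[1])
        ]
        best = max(best, float(np.mean(cors)))
    return best


@pytest.fixture()
def tiny_genome() -> dict[str, str]:
    rng = np.random.default_rng(42)
    return {
        "chr1": "".join(rng.choice(list("ACGT"), 500)),
        "chr2": "".join(rng.choice(list("ACGT"), 300)),
    }
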