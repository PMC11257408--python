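"""Dinucleotide motif density profiles and edit-context matrices.

The central quantity is the UC dinucleotide density along a transcript:
occurrences are counted in consecutive non-overlapping windows (default
100 nt) and compared with the analytic random expectation. For
independent equiprobable bases the expected count per 100-nt window is
100 x (1/4)^2 = 6.25, under the window-length convention (L x p rather
than (L - |motif| + 1) x p); this convention reproduces the published
baseline exactly and is applied consistently.

Edit-sequence contexts (default +/-10 nt around the edited C) are
aggregated into a position-frequency matrix suitable for any logo
renderer, and the preceding-base composition is tested for enrichment
with an exact two-sided binomial test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

PFM_ALPHABET = ("A", "C", "G", "U", "-")


@dataclass(frozen=True)
class WindowMotifProfile:
    window_start: int
    window_length: int
    observed: int
    expected: float

    @property
    def enrichment(self) -> float:
        return self.observed / self.expected if self.expected > 0 else float("nan")


def count_motif(seq: str, motif: str) -> int:
    """Number of (possibly overlapping) occurrences of ``motif``."""
    if len(motif) < 1:
        raise ValueError("motif must be non-empty")
    return sum(1 for i in range(len(seq) - len(motif) + 1)
               if seq[i:i + len(motif)] == motif)


def expected_motif_count(window_length: int, base_probs, motif: str) -> float:
    """Analytic expected occurrences per window of a random sequence.

    Window-length convention: L x prod(P(base)) over the motif's bases.
    """
    p = np.asarray(base_probs, dtype=float)
    if p.shape != (4,) or np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("base_probs must be a non-negative 4-vector summing to 1")
    lookup = dict(zip("ACGU", p))
    prob = 1.0
    for base in motif:
        prob *= lookup[base]
    return window_length * prob


def windowed_motif_profile(seq: str, motif: str = "UC", window: int = 100,
                           base_probs=(0.25, 0.25, 0.25, 0.25),
                           ) -> list[WindowMotifProfile]:
    """Motif counts over consecutive non-overlapping windows.

    An occurrence belongs to the window containing its start index, so
    window counts always sum to the full-sequence count. The final
    partial window is reported with its true length and a pro-rated
    expectation.
    """
    if not seq:
        raise ValueError("empty sequence")
    profiles = []
    full_expected = expected_motif_count(window, base_probs, motif)
    for start in range(0, len(seq), window):
        length = min(window, len(seq) - start)
        # count by start index within [start, start+length)
        observed = sum(
            1 for i in range(start, min(start + length, len(seq) - len(motif) + 1))
            if seq[i:i + len(motif)] == motif
        )
        expected = full_expected * length / window
        profiles.append(WindowMotifProfile(start, length, observed, expected))
    return profiles


def profile_to_frame(profiles: list[WindowMotifProfile]) -> pd.DataFrame:
    return pd.DataFrame([{
        "window_start": p.window_start, "window_len": p.window_length,
        "observed": p.observed, "expected": p.expected,
        "enrichment": p.enrichment,
    } for p in profiles])


@dataclass
class PositionFrequencyMatrix:
    """Per-position base counts over aligned edit contexts."""

    counts: pd.DataFrame      # index: positions -flank..+flank; columns: A C G U -
    n_sequences: int

    @property
    def flank(self) -> int:
        return (len(self.counts) - 1) // 2


def build_pfm(contexts: list[str], gap: str = "-") -> PositionFrequencyMatrix:
    """Aggregate equal-length, C-centred context windows into a PFM."""
    if not contexts:
        raise ValueError("no context windows supplied")
    length = len(contexts[0])
    if length % 2 != 1:
        raise ValueError("context windows must have odd length (centred on the C)")
    flank = length // 2
    for ctx in contexts:
        if len(ctx) != length:
            raise ValueError("context windows must all have the same length")
        if ctx[flank] != "C":
            raise ValueError(f"window {ctx!r} is not centred on a C")
    positions = np.arange(-flank, flank + 1)
    counts = pd.DataFrame(0, index=positions, columns=list(PFM_ALPHABET))
    for ctx in contexts:
        for pos, ch in zip(positions, ctx):
            col = ch if ch in PFM_ALPHABET[:4] else gap
            counts.loc[pos, col] += 1
    return PositionFrequencyMatrix(counts, len(contexts))


def preceding_base_enrichment(contexts: list[str], base: str = "U",
                              p0: float = 0.25) -> dict:
    """Exact two-sided test of the base immediately upstream of the C.

    Compares the observed count of ``base`` at position -1 against the
    random expectation ``p0 * n`` with a binomial test, doubling the
    smaller exact tail (capped at 1).
    """
    if not contexts:
        raise ValueError("no contexts to test")
    pfm = build_pfm(contexts)
    n = pfm.n_sequences
    k = int(pfm.counts.loc[-1, base])
    lower = float(stats.binom.cdf(k, n, p0))
    upper = float(stats.binom.sf(k - 1, n, p0))
    p = min(1.0, 2.0 * min(lower, upper))
    return {
        "count": k, "n": n, "expected": p0 * n, "p_value": p,
        "enriched": k > p0 * n and p < 0.05,
    }
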