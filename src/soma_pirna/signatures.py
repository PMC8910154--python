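"""Biogenesis-signature statistics for annotated piRNA reads.

Germline piRNA amplification (the ping-pong cycle) leaves three footprints in
sequencing data: a uridine bias at read position 1 (primary piRNAs), an
adenine bias at position 10 (secondary piRNAs), and an excess of
opposite-strand read pairs whose 5' ends overlap by exactly 10 nt. This
module computes all three per sample, plus the length x first-base histogram,
and condenses the overlap spectrum into a Z-score against the 19 non-10
overlaps as empirical null — the local-background idea behind pingpongpro.
Somatic samples are expected to show none of these signals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .align_annotate import AnnotatedRead, CATEGORY_PIRNA

MAX_OVERLAP = 20
PINGPONG_Z_THRESHOLD = 1.645  # one-sided 5%


@dataclass
class SignatureProfile:
    """Per-sample signature bundle."""

    length_hist: pd.DataFrame  # index: length, columns: first base, fractions
    u1_fraction: float
    a10_fraction: float
    n_reads: int
    overlap_spectrum: np.ndarray | None = None  # index 0 -> overlap k=1
    pingpong_z: float | None = None

    @property
    def has_pingpong_signal(self) -> bool:
        return self.pingpong_z is not None and self.pingpong_z >= PINGPONG_Z_THRESHOLD


def length_base_profile(
    annotated: Iterable[AnnotatedRead],
    min_len: int = 20,
    max_len: int = 32,
) -> SignatureProfile:
    """Length x first-base histogram and 1U/10A fractions of piRNA reads.

    Each read counts once regardless of its placement count (its x placements
    each carry 1/x weight, summing to 1), so cells are plain read fractions.
    """
    bases = ["A", "C", "G", "T", "N"]
    hist = pd.DataFrame(0.0, index=range(min_len, max_len + 1), columns=bases)
    n = u1 = a10 = 0
    for ann in annotated:
        if ann.category != CATEGORY_PIRNA:
            continue
        seq = ann.read.seq
        n += 1
        first = seq[0] if seq[0] in bases else "N"
        length = min(max(len(seq), min_len), max_len)
        hist.loc[length, first] += 1.0
        u1 += seq[0] == "T"
        a10 += len(seq) >= 10 and seq[9] == "A"
    if n == 0:
        raise ValueError("no annotated piRNA reads")
    return SignatureProfile(hist / n, u1 / n, a10 / n, n)


def pingpong_statistic(
    annotated: Iterable[AnnotatedRead],
    max_overlap: int = MAX_OVERLAP,
) -> tuple[np.ndarray, float | None]:
    """5'-overlap spectrum of opposite-strand read pairs and its Z-score.

    For every pair of placements (p on +, m on -) on one chromosome the
    overlap is k = 5'(m) - 5'(p) + 1 in plus coordinates; pairs with
    1 <= k <= max_overlap contribute weight 1/(x_p * x_m). The Z-score
    contrasts the k=10 count with the mean and sd (ddof=1) of the other
    overlaps; it is None ("no signal") when reads lie on one strand only or
    the null spectrum is degenerate.

    The spectrum is accumulated per 5'-position via weighted position maps,
    which is exactly equivalent to all-pairs enumeration.
    """
    plus: dict[str, dict[int, float]] = {}
    minus: dict[str, dict[int, float]] = {}
    for ann in annotated:
        if ann.category != CATEGORY_PIRNA:
            continue
        w = 1.0 / ann.read.x
        for pl in ann.read.placements:
            side = plus if pl.strand == "+" else minus
            pos = ann.read.five_prime(pl)
            chrom_map = side.setdefault(pl.chrom, {})
            chrom_map[pos] = chrom_map.get(pos, 0.0) + w

    spectrum = np.zeros(max_overlap)
    for chrom, pmap in plus.items():
        mmap = minus.get(chrom)
        if not mmap:
            continue
        for pos, wp in pmap.items():
            for k in range(1, max_overlap + 1):
                wm = mmap.get(pos + k - 1)
                if wm:
                    spectrum[k - 1] += wp * wm

    if spectrum.sum() == 0:
        return spectrum, None
    null = np.delete(spectrum, 9)
    sd = null.std(ddof=1)
    if sd == 0:
        return spectrum, None
    return spectrum, float((spectrum[9] - null.mean()) / sd)


def bias_test(profile: SignatureProfile) -> pd.DataFrame:
    """One-sided binomial tests of 1U and 10A enrichment over a uniform null.

    Under a uniform base composition each bias fraction is 0.25; the test is
    P(X >= k) with X ~ Binomial(n, 0.25) on unweighted read counts.
    """
    if profile.n_reads == 0:
        raise ValueError("empty profile")
    rows = []
    for name, frac in [("u1", profile.u1_fraction), ("a10", profile.a10_fraction)]:
        k = int(round(frac * profile.n_reads))
        res = stats.binomtest(k, profile.n_reads, 0.25, alternative="greater")
        rows.append({"bias": name, "fraction": frac, "n": profile.n_reads,
                     "p_value": res.pvalue, "significant": res.pvalue < 0.05})
    return pd.DataFrame(rows)


def signature_report(
    annotated: Iterable[AnnotatedRead],
    z_threshold: float = PINGPONG_Z_THRESHOLD,
) -> SignatureProfile:
    """Full signature profile for one sample (histogram, biases, ping-pong)."""
    anns = list(annotated)
    profile = length_base_profile(anns)
    spectrum, z = pingpong_statistic(anns)
    profile.overlap_spectrum = spectrum
    profile.pingpong_z = z
    return profile


def verdict(profile: SignatureProfile, z_threshold: float = PINGPONG_Z_THRESHOLD) -> str:
    """Machine-readable ping-pong call for one sample."""
    if profile.pingpong_z is None:
        return "no_signal"
    return "signal" if profile.pingpong_z >= z_threshold else "no_signal"
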