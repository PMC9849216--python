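"""Fragment 5'-end motif analysis.

The k-mer (default 4-mer) of reference sequence at a fragment's 5' end
reflects the cutting preference of the nuclease that produced it.  In
paired-end data both ends are 5' ends: the U end contributes the k
bases starting at ``start`` on the forward strand, the D end the
reverse complement of the k bases ending at ``end - 1``.  Single-end
mode counts only U ends.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping

import numpy as np
from scipy import stats

from .core import FragmentSet, revcomp

__all__ = [
    "MotifSpectrum",
    "end_motif_spectrum",
    "motif_usage",
    "paired_usage_comparison",
]

_VALID = frozenset("ACGT")


@dataclasses.dataclass
class MotifSpectrum:
    """End-motif counts over the 4^k possible k-mers."""

    k: int
    counts: dict[str, int]
    total_ends: int
    skipped_ends: int = 0

    def frequencies(self) -> dict[str, float]:
        if self.total_ends == 0:
            return {m: 0.0 for m in self.counts}
        return {m: c / self.total_ends for m, c in self.counts.items()}

    def merge(self, other: "MotifSpectrum") -> "MotifSpectrum":
        """Count-weighted combination of two spectra."""
        if self.k != other.k:
            raise ValueError("cannot merge spectra of different k")
        counts = dict(self.counts)
        for m, c in other.counts.items():
            counts[m] = counts.get(m, 0) + c
        return MotifSpectrum(
            self.k,
            counts,
            self.total_ends + other.total_ends,
            self.skipped_ends + other.skipped_ends,
        )


def _fetch(reference, chrom: str, start: int, end: int) -> str | None:
    """Slice a reference that is either a plain mapping of strings or a
    pyfaidx.Fasta; returns None when out of bounds."""
    seq = reference[chrom]
    if start < 0:
        return None
    piece = str(seq[start:end]).upper()
    if len(piece) != end - start:
        return None
    return piece


def end_motif_spectrum(
    fs: FragmentSet,
    reference: Mapping[str, str],
    k: int = 4,
    mode: str = "both",
) -> MotifSpectrum:
    """Frequency spectrum of fragment 5'-end k-mers.

    ``mode`` is ``"both"`` (U and D ends; paired-end convention) or
    ``"single-end"`` (U ends only, for data where only the sequenced
    read's own 5' end is known).  Ends at contig edges or containing
    non-ACGT bases are skipped and counted.
    """
    if mode not in ("both", "single-end"):
        raise ValueError("mode must be 'both' or 'single-end'")
    if len(fs) == 0:
        raise ValueError("empty fragment set has no motif spectrum")
    counts = {"".join(m): 0 for m in itertools.product("ACGT", repeat=k)}
    total = 0
    skipped = 0
    for i in range(len(fs)):
        chrom = str(fs.chroms[i])
        start = int(fs.starts[i])
        end = int(fs.ends[i])
        u_mer = _fetch(reference, chrom, start, start + k)
        candidates = [u_mer]
        if mode == "both":
            d_piece = _fetch(reference, chrom, end - k, end)
            candidates.append(None if d_piece is None else revcomp(d_piece))
        for mer in candidates:
            if mer is None or not set(mer) <= _VALID:
                skipped += 1
                continue
            counts[mer] += 1
            total += 1
    return MotifSpectrum(k=k, counts=counts, total_ends=total, skipped_ends=skipped)


def motif_usage(spectrum: MotifSpectrum, motif: str) -> float:
    """Frequency of one motif in the spectrum (0 when absent)."""
    return spectrum.frequencies().get(motif.upper(), 0.0)


def paired_usage_comparison(
    pairs: list[tuple[float, float]]
) -> tuple[float, float]:
    """Mean (captured - shotgun) usage difference and two-tailed paired t P.

    Each pair is (usage in whole-genome shotgun data, usage in the
    matched methylation-capture library).  Identical pairs report a
    mean difference of 0 and P = 1; fewer than two pairs give P = NaN.
    """
    arr = np.asarray(pairs, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (wgs, medip) tuples")
    diffs = arr[:, 1] - arr[:, 0]
    mean_diff = float(diffs.mean())
    if len(diffs) < 2:
        return mean_diff, float("nan")
    if np.allclose(diffs.std(ddof=1), 0.0):
        return mean_diff, 1.0 if mean_diff == 0 else 0.0
    t = stats.ttest_rel(arr[:, 1], arr[:, 0])
    return mean_diff, float(t.pvalue)
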