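"""Core containers for fragment-level cfDNA data.

A cfDNA molecule is represented as a genomic interval in 0-based
half-open coordinates.  The two ends of a fragment are labelled by
genome coordinate order: the upstream (U) end is ``start`` and the
downstream (D) end is ``end - 1`` (the last covered base), so the
inclusive fragment size is ``D - U + 1 == end - start``.  Strand plays
no role in U/D assignment.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterator, Sequence

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe, case preserving)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass(frozen=True)
class FragmentRecord:
    """One cfDNA molecule.

    ``methylation`` is an optional tuple of ``(cpg_position, state)``
    pairs with state in {0, 1}; CpG positions must lie inside the
    fragment interval.
    """

    chrom: str
    start: int
    end: int
    sample_id: str = ""
    frag_id: str | None = None
    methylation: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"fragment must have start < end, got [{self.start}, {self.end})"
            )
        if self.methylation is not None:
            for pos, state in self.methylation:
                if not (self.start <= pos < self.end):
                    raise ValueError(
                        f"CpG position {pos} outside fragment "
                        f"[{self.start}, {self.end})"
                    )
                if state not in (0, 1):
                    raise ValueError(f"methylation state must be 0/1, got {state}")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def u_end(self) -> int:
        return self.start

    @property
    def d_end(self) -> int:
        return self.end - 1


@dataclasses.dataclass
class MethCalls:
    """Per-fragment CpG methylation calls in compressed sparse row form.

    ``indptr`` has length ``n_fragments + 1``; fragment ``i`` owns
    ``positions[indptr[i]:indptr[i+1]]`` / ``states[...]``.
    """

    indptr: np.ndarray
    positions: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.indptr = np.asarray(self.indptr, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.indptr[0] != 0 or self.indptr[-1] != len(self.positions):
            raise ValueError("inconsistent CSR indptr")
        if len(self.positions) != len(self.states):
            raise ValueError("positions/states length mismatch")

    def __len__(self) -> int:
        return len(self.indptr) - 1

    def counts(self) -> np.ndarray:
        """CpG count per fragment."""
        return np.diff(self.indptr)

    def methylated_counts(self) -> np.ndarray:
        """Number of methylated CpGs per fragment."""
        csum = np.concatenate([[0], np.cumsum(self.states, dtype=np.int64)])
        return csum[self.indptr[1:]] - csum[self.indptr[:-1]]

    def fragment_means(self) -> np.ndarray:
        """Mean methylation per fragment; NaN where a fragment has no CpGs."""
        counts = self.counts()
        with np.errstate(invalid="ignore", divide="ignore"):
            means = self.methylated_counts() / counts
        means[counts == 0] = np.nan
        return means

    def fragment(self, i: int) -> tuple[tuple[int, int], ...]:
        lo, hi = self.indptr[i], self.indptr[i + 1]
        return tuple(
            (int(p), int(s))
            for p, s in zip(self.positions[lo:hi], self.states[lo:hi])
        )

    def subset(self, index: np.ndarray) -> "MethCalls":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        counts = self.counts()[index]
        new_indptr = np.concatenate([[0], np.cumsum(counts)])
        take = np.concatenate(
            [np.arange(self.indptr[i], self.indptr[i + 1]) for i in index]
        ).astype(np.int64) if len(index) else np.empty(0, dtype=np.int64)
        return MethCalls(new_indptr, self.positions[take], self.states[take])

    @staticmethod
    def from_lists(per_fragment: Sequence[Sequence[tuple[int, int]]]) -> "MethCalls":
        counts = np.array([len(x) for x in per_fragment], dtype=np.int64)
        indptr = np.concatenate([[0], np.cumsum(counts)])
        if counts.sum():
            positions = np.array(
                [p for frag in per_fragment for p, _ in frag], dtype=np.int64
            )
            states = np.array(
                [s for frag in per_fragment for _, s in frag], dtype=np.int8
            )
        else:
            positions = np.empty(0, dtype=np.int64)
            states = np.empty(0, dtype=np.int8)
        return MethCalls(indptr, positions, states)


class FragmentSet:
    """An ordered collection of fragments from one sample.

    Internally columnar (NumPy arrays) for speed; :meth:`records` and
    iteration materialise :class:`FragmentRecord` views.
    """

    def __init__(
        self,
        sample_id: str,
        chroms: str | np.ndarray | Sequence[str],
        starts: np.ndarray | Sequence[int],
        ends: np.ndarray | Sequence[int],
        label: str = "control",
        meth: MethCalls | None = None,
        origins: np.ndarray | None = None,
        frag_ids: Sequence[str] | None = None,
        tumor_fraction: float | None = None,
    ) -> None:
        self.sample_id = sample_id
        self.label = label
        self.starts = np.asarray(starts, dtype=np.int64)
        self.ends = np.asarray(ends, dtype=np.int64)
        n = len(self.starts)
        if isinstance(chroms, str):
            self.chroms = np.full(n, chroms, dtype=object)
        else:
            self.chroms = np.asarray(chroms, dtype=object)
        if not (len(self.chroms) == len(self.starts) == len(self.ends)):
            raise ValueError("chroms/starts/ends length mismatch")
        if np.any(self.starts >= self.ends):
            bad = int(np.flatnonzero(self.starts >= self.ends)[0])
            raise ValueError(
                f"fragment {bad} has start >= end "
                f"({self.starts[bad]} >= {self.ends[bad]})"
            )
        if meth is not None and len(meth) != n:
            raise ValueError("methylation calls do not match fragment count")
        self.meth = meth
        self.origins = None if origins is None else np.asarray(origins, dtype=object)
        self._frag_ids = list(frag_ids) if frag_ids is not None else None
        self.tumor_fraction = tumor_fraction

    # -- basic protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.starts)

    @property
    def sizes(self) -> np.ndarray:
        return self.ends - self.starts

    @property
    def u_ends(self) -> np.ndarray:
        return self.starts

    @property
    def d_ends(self) -> np.ndarray:
        return self.ends - 1

    @property
    def frag_ids(self) -> list[str]:
        if self._frag_ids is None:
            self._frag_ids = [f"{self.sample_id}.{i}" for i in range(len(self))]
        return self._frag_ids

    def record(self, i: int) -> FragmentRecord:
        return FragmentRecord(
            chrom=str(self.chroms[i]),
            start=int(self.starts[i]),
            end=int(self.ends[i]),
            sample_id=self.sample_id,
            frag_id=self.frag_ids[i],
            methylation=None if self.meth is None else self.meth.fragment(i),
        )

    def __iter__(self) -> Iterator[FragmentRecord]:
        for i in range(len(self)):
            yield self.record(i)

    @property
    def records(self) -> list[FragmentRecord]:
        return list(self)

    def subset(self, index: np.ndarray, sample_id: str | None = None) -> "FragmentSet":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return FragmentSet(
            sample_id=sample_id or self.sample_id,
            chroms=self.chroms[index],
            starts=self.starts[index],
            ends=self.ends[index],
            label=self.label,
            meth=None if self.meth is None else self.meth.subset(index),
            origins=None if self.origins is None else self.origins[index],
            frag_ids=None if self._frag_ids is None
            else [self._frag_ids[i] for i in index],
            tumor_fraction=self.tumor_fraction,
        )

    @staticmethod
    def from_records(
        records: Sequence[FragmentRecord],
        sample_id: str | None = None,
        label: str = "control",
    ) -> "FragmentSet":
        if sample_id is None:
            sample_id = records[0].sample_id if records else ""
        have_meth = any(r.methylation is not None for r in records)
        return FragmentSet(
            sample_id=sample_id,
            chroms=np.array([r.chrom for r in records], dtype=object),
            starts=np.array([r.start for r in records], dtype=np.int64),
            ends=np.array([r.end for r in records], dtype=np.int64),
            label=label,
            meth=MethCalls.from_lists([r.methylation or () for r in records])
            if have_meth
            else None,
            frag_ids=[r.frag_id or f"{sample_id}.{i}" for i, r in enumerate(records)],
        )

    @staticmethod
    def concat(sets: Sequence["FragmentSet"], sample_id: str = "pooled") -> "FragmentSet":
        """Pool several samples into one set (order preserved)."""
        if not sets:
            raise ValueError("nothing to pool")
        meth = None
        if all(s.meth is not None for s in sets):
            meth = MethCalls(
                np.concatenate([[0]] + [s.meth.indptr[1:] + o for s, o in zip(
                    sets, np.cumsum([0] + [s.meth.indptr[-1] for s in sets])[:-1])]),
                np.concatenate([s.meth.positions for s in sets]),
                np.concatenate([s.meth.states for s in sets]),
            )
        origins = np.concatenate(
            [s.origins if s.origins is not None
             else np.full(len(s), s.sample_id, dtype=object) for s in sets]
        )
        return FragmentSet(
            sample_id=sample_id,
            chroms=np.concatenate([s.chroms for s in sets]),
            starts=np.concatenate([s.starts for s in sets]),
            ends=np.concatenate([s.ends for s in sets]),
            label=sets[0].label,
            meth=meth,
            origins=origins,
        )


@dataclasses.dataclass
class NucleosomeTrack:
    """Ordered nucleosome-center coordinates per chromosome.

    The core spans ``center ± core_halfwidth`` (147 bp of wrapped DNA
    for the default 73) and adjacent nucleosomes are nominally
    ``center ± spacing_halfwidth`` apart at the midpoint of the linker.
    """

    centers: dict[str, np.ndarray]
    core_halfwidth: int = 73
    spacing_halfwidth: int = 90

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, c in self.centers.items():
            c = np.asarray(c, dtype=np.int64)
            if len(c) == 0:
                raise ValueError(f"empty center list for {chrom}")
            gaps = np.diff(c)
            if np.any(gaps <= 0):
                raise ValueError(f"centers on {chrom} not strictly increasing")
            if np.any(gaps < 2 * self.core_halfwidth):
                warnings.warn(
                    f"nucleosome centers on {chrom} closer than "
                    f"{2 * self.core_halfwidth} bp: cores overlap",
                    stacklevel=2,
                )
            clean[chrom] = c
        self.centers = clean

    @property
    def n_nucleosomes(self) -> int:
        return sum(len(c) for c in self.centers.values())

    def single_chrom(self) -> tuple[str, np.ndarray]:
        """Return (chrom, centers) for a single-chromosome track."""
        if len(self.centers) != 1:
            raise ValueError("operation requires a single-chromosome track")
        return next(iter(self.centers.items()))

    def span(self, chrom: str) -> tuple[int, int]:
        c = self.centers[chrom]
        return (
            int(c[0] - self.spacing_halfwidth),
            int(c[-1] + self.spacing_halfwidth),
        )
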