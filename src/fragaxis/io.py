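"""Reading and writing fragment-level data.

Formats
-------
* Fragments: BED3+3 (chrom, start, end, sample_id, size, strand="."),
  0-based half-open; gzip transparent on both read and write.
* Nucleosome centers: BED3 of 1-bp intervals (center == start).
* Per-read methylation calls: TSV (fragment_id, cpg_position, state).
* Paired-end alignments: SAM/BAM via pysam, reduced to one fragment
  per properly paired template.
"""

from __future__ import annotations

import gzip
import logging
import os
from typing import IO, Mapping, Sequence

import numpy as np

from .core import FragmentSet, MethCalls, NucleosomeTrack

logger = logging.getLogger(__name__)

__all__ = [
    "read_fragments_bed",
    "write_fragments_bed",
    "fragments_from_paired_alignments",
    "dedup_fragments",
    "read_nucleosome_track",
    "write_nucleosome_track",
    "read_methylation_calls",
    "write_methylation_calls",
    "attach_methylation_calls",
    "write_fasta",
]


def _open(path: str | os.PathLike, mode: str = "rt") -> IO:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# fragments


def read_fragments_bed(
    path: str | os.PathLike, sample_id: str | None = None, label: str = "control"
) -> FragmentSet:
    """Load fragments from BED3+.

    Column 4, when present, is the sample id (the file must be
    single-sample).  Records with start >= end are rejected with a
    warning; lines that do not parse raise with their line number.
    Fragment ids are assigned as ``<sample_id>.<row>`` in file order so
    that companion methylation-call TSVs written by this package join
    deterministically.
    """
    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    seen_sample = sample_id
    n_rejected = 0
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >= 3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                logger.warning("%s:%d: start >= end, record rejected", path, lineno)
                n_rejected += 1
                continue
            if len(fields) >= 4 and seen_sample is None:
                seen_sample = fields[3]
            chroms.append(fields[0])
            starts.append(start)
            ends.append(end)
    sid = seen_sample if seen_sample is not None else os.path.basename(
        os.fspath(path)
    ).split(".")[0]
    fs = FragmentSet(
        sample_id=sid,
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
        label=label,
    )
    if n_rejected:
        logger.warning("%s: rejected %d malformed intervals", path, n_rejected)
    return fs


def write_fragments_bed(fs: FragmentSet, path: str | os.PathLike) -> None:
    sizes = fs.sizes
    with _open(path, "wt") as fh:
        for i in range(len(fs)):
            fh.write(
                f"{fs.chroms[i]}\t{fs.starts[i]}\t{fs.ends[i]}"
                f"\t{fs.sample_id}\t{sizes[i]}\t.\n"
            )


def fragments_from_paired_alignments(
    path: str | os.PathLike, sample_id: str | None = None
) -> FragmentSet:
    """Reduce coordinate-sorted paired-end alignments to fragments.

    One fragment per proper pair, spanning the leftmost start to the
    rightmost end of the template; secondary, supplementary, unmapped
    and improperly paired reads are skipped (and counted in the log).
    """
    import pysam

    chroms: list[str] = []
    starts: list[int] = []
    ends: list[int] = []
    n_skipped = 0
    with pysam.AlignmentFile(os.fspath(path), check_sq=False) as bam:
        if sample_id is None:
            sample_id = os.path.basename(os.fspath(path)).split(".")[0]
        for read in bam:
            if (
                read.is_secondary
                or read.is_supplementary
                or read.is_unmapped
                or read.mate_is_unmapped
                or not read.is_proper_pair
            ):
                n_skipped += 1
                continue
            # emit once per template, from its leftmost read
            if read.template_length <= 0:
                continue
            chroms.append(read.reference_name)
            starts.append(read.reference_start)
            ends.append(read.reference_start + read.template_length)
    if n_skipped:
        logger.warning("%s: skipped %d non-proper alignments", path, n_skipped)
    return FragmentSet(
        sample_id=sample_id,
        chroms=np.array(chroms, dtype=object),
        starts=np.array(starts, dtype=np.int64),
        ends=np.array(ends, dtype=np.int64),
    )


def dedup_fragments(fs: FragmentSet) -> FragmentSet:
    """Drop PCR duplicates: fragments with identical ending positions.

    At most one record per (chrom, start, end); the first occurrence is
    kept and input order is preserved.  Idempotent.
    """
    seen: set[tuple[str, int, int]] = set()
    keep = np.zeros(len(fs), dtype=bool)
    for i in range(len(fs)):
        key = (fs.chroms[i], int(fs.starts[i]), int(fs.ends[i]))
        if key not in seen:
            seen.add(key)
            keep[i] = True
    if keep.all():
        return fs
    return fs.subset(keep)


# ---------------------------------------------------------------------------
# nucleosome tracks


def read_nucleosome_track(
    path: str | os.PathLike, core_halfwidth: int = 73, spacing_halfwidth: int = 90
) -> NucleosomeTrack:
    """Load nucleosome centers from a BED3 of 1-bp intervals.

    Unsorted input is sorted with a warning; duplicate centers are
    collapsed.
    """
    by_chrom: dict[str, list[int]] = {}
    with _open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected BED3")
            by_chrom.setdefault(fields[0], []).append(int(fields[1]))
    centers: dict[str, np.ndarray] = {}
    for chrom, vals in by_chrom.items():
        arr = np.array(vals, dtype=np.int64)
        if np.any(np.diff(arr) <= 0):
            logger.warning("%s: centers on %s unsorted; sorting", path, chrom)
            arr = np.unique(arr)
        centers[chrom] = arr
    return NucleosomeTrack(
        centers=centers,
        core_halfwidth=core_halfwidth,
        spacing_halfwidth=spacing_halfwidth,
    )


def write_nucleosome_track(track: NucleosomeTrack, path: str | os.PathLike) -> None:
    with _open(path, "wt") as fh:
        for chrom in sorted(track.centers):
            for c in track.centers[chrom]:
                fh.write(f"{chrom}\t{c}\t{c + 1}\n")


# ---------------------------------------------------------------------------
# methylation calls


def write_methylation_calls(fs: FragmentSet, path: str | os.PathLike) -> None:
    if fs.meth is None:
        raise ValueError("fragment set carries no methylation calls")
    ids = fs.frag_ids
    with _open(path, "wt") as fh:
        fh.write("fragment_id\tcpg_position\tstate\n")
        for i in range(len(fs)):
            lo, hi = fs.meth.indptr[i], fs.meth.indptr[i + 1]
            for pos, state in zip(fs.meth.positions[lo:hi], fs.meth.states[lo:hi]):
                fh.write(f"{ids[i]}\t{pos}\t{state}\n")


def read_methylation_calls(
    path: str | os.PathLike,
) -> dict[str, list[tuple[int, int]]]:
    """TSV (fragment_id, cpg_position, state) grouped by fragment id."""
    calls: dict[str, list[tuple[int, int]]] = {}
    with _open(path) as fh:
        header = fh.readline()
        if header and not header.startswith("fragment_id"):
            fh.seek(0)
        for lineno, line in enumerate(fh, 2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected 3 TSV columns")
            calls.setdefault(fields[0], []).append((int(fields[1]), int(fields[2])))
    return calls


def attach_methylation_calls(
    fs: FragmentSet, calls: Mapping[str, Sequence[tuple[int, int]]]
) -> FragmentSet:
    """Join a calls mapping onto a fragment set by fragment id.

    Fragments without calls get empty CpG lists; call ids that match
    no fragment are skipped and counted in the log.
    """
    ids = fs.frag_ids
    known = set(ids)
    n_orphan = sum(1 for k in calls if k not in known)
    if n_orphan:
        logger.warning("%d call groups matched no fragment; skipped", n_orphan)
    per_fragment = [tuple(calls.get(fid, ())) for fid in ids]
    fs.meth = MethCalls.from_lists(per_fragment)
    return fs


# ---------------------------------------------------------------------------
# reference sequence


def write_fasta(
    reference: Mapping[str, str], path: str | os.PathLike, width: int = 60
) -> None:
    with _open(path, "wt") as fh:
        for chrom in sorted(reference):
            fh.write(f">{chrom}\n")
            seq = reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
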