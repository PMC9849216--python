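"""Synthetic cfDNA fragment generator.

Emulates the generative structure that nucleosome-relative cfDNA end
analyses assume: a phased nucleosome array (modelled on the well
positioned chr12p11.1-like arrays), preferred nuclease cut sites on a
10-bp lattice inside the nucleosome core plus a dominant cut site in
each flanking linker, and methylation-dependent accessibility of the
core.  The linker cut pair sits at (-83, +82) relative to the center so
the canonical linker-to-linker fragment has the hallmark inclusive
length 82 - (-83) + 1 = 166 bp; intra-core cuts on the 10-bp lattice
anchored at -68 (U) and +63/+74 (D) produce the sub-147 bp fragment
population with 10-bp size periodicity.

Local CpG methylation protects the core: the intra-core cut weight
interpolates between an unmethylated and a methylated weight as local
methylation rises, so hypomethylated regions yield shorter,
core-internal fragments.  Tumor-derived fragments are drawn from a
globally hypomethylated methylation profile, giving mixtures the
shifted-short, hypomethylated tumor component seen in plasma.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from typing import Mapping

import numpy as np

from .core import FragmentSet, MethCalls, NucleosomeTrack, revcomp

__all__ = [
    "CutModel",
    "MethylationLandscape",
    "SampleSpec",
    "make_nucleosome_array",
    "make_methylation_landscape",
    "synthesize_reference",
    "sample_fragments",
    "mix_samples",
    "simulate_medip_capture",
    "write_fixture_bundle",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclasses.dataclass
class CutModel:
    """Preferred nuclease cut sites and their weights.

    Offsets are in bp relative to a nucleosome center; U offsets are
    where upstream (lower-coordinate) fragment ends fall, D offsets
    where downstream ends fall.  ``core_weight`` maps a local
    methylation level m in [0, 1] to the per-site intra-core cut
    weight; the linker weight is methylation independent (the
    accessibility mechanism acts on the wrapped core, not the linker).
    """

    u_core_offsets: tuple[int, ...] = (-68, -58, -48, -38, -28, -18, -8)
    d_core_offsets: tuple[int, ...] = (63, 74)
    u_linker_offset: int = -83
    d_linker_offset: int = 82
    peak_sd: float = 1.5
    w_core_unmethylated: float = 1.0
    w_core_methylated: float = 0.25
    w_linker: float = 3.0
    methylation_exponent: float = 1.0
    dinucleosome_fraction: float = 0.15

    def __post_init__(self) -> None:
        for w in (self.w_core_unmethylated, self.w_core_methylated, self.w_linker):
            if w < 0:
                raise ValueError("cut weights must be non-negative")
        for off in (
            *self.u_core_offsets,
            *self.d_core_offsets,
            self.u_linker_offset,
            self.d_linker_offset,
        ):
            if not -90 <= off <= 90:
                raise ValueError(f"cut offset {off} outside [-90, 90]")
        if self.u_linker_offset >= self.d_linker_offset:
            raise ValueError("U linker offset must be left of D linker offset")
        if not 0.0 <= self.dinucleosome_fraction < 1.0:
            raise ValueError("dinucleosome_fraction must be in [0, 1)")

    def core_weight(self, m: np.ndarray | float) -> np.ndarray | float:
        """Intra-core cut weight at local methylation level ``m``."""
        m = np.clip(m, 0.0, 1.0)
        frac = m ** self.methylation_exponent
        return self.w_core_unmethylated + (
            self.w_core_methylated - self.w_core_unmethylated
        ) * frac


@dataclasses.dataclass
class MethylationLandscape:
    """CpG sites with per-tissue methylation probabilities (one chromosome)."""

    chrom: str
    positions: np.ndarray
    profiles: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if len(self.positions) and np.any(np.diff(self.positions) <= 0):
            raise ValueError("CpG positions must be strictly increasing")
        for name, p in self.profiles.items():
            p = np.asarray(p, dtype=np.float64)
            if p.shape != self.positions.shape:
                raise ValueError(f"profile {name!r} does not match CpG sites")
            if np.any((p < 0) | (p > 1)):
                raise ValueError(f"profile {name!r} has probabilities outside [0, 1]")
            self.profiles[name] = p

    def local_levels(
        self, centers: np.ndarray, profile: str, halfwidth: int = 73
    ) -> np.ndarray:
        """Mean site methylation probability within ±halfwidth of each center.

        Centers with no CpG in range fall back to the profile mean.
        """
        p = self.profiles[profile]
        lo = np.searchsorted(self.positions, centers - halfwidth)
        hi = np.searchsorted(self.positions, centers + halfwidth + 1)
        csum = np.concatenate([[0.0], np.cumsum(p)])
        counts = hi - lo
        with np.errstate(invalid="ignore"):
            means = (csum[hi] - csum[lo]) / counts
        means[counts == 0] = p.mean() if len(p) else 0.5
        return means


@dataclasses.dataclass
class SampleSpec:
    """What to simulate for one plasma sample."""

    sample_id: str = "sample"
    label: str = "control"
    n_fragments: int = 200_000
    tumor_fraction: float = 0.0
    seed: int = 0
    background_profile: str = "blood"
    tumor_profile: str = "tumor"
    emit_methylation: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.tumor_fraction <= 1.0:
            raise ValueError("tumor fraction must be in [0, 1]")
        if self.label == "control" and self.tumor_fraction != 0.0:
            raise ValueError("control samples must have tumor fraction 0")
        if self.n_fragments < 0:
            raise ValueError("n_fragments must be >= 0")


# ---------------------------------------------------------------------------
# generators


def make_nucleosome_array(
    n_nucleosomes: int,
    spacing: int = 185,
    chrom_name: str = "chrS",
    origin: int = 1000,
    jitter_sd: float = 0.0,
    seed: int = 0,
) -> NucleosomeTrack:
    """A phased array of well-positioned nucleosomes.

    Centers sit at ``origin + k * spacing`` with optional Gaussian
    positional jitter, re-sorted after jittering.
    """
    if n_nucleosomes < 1:
        raise ValueError("need at least one nucleosome")
    if spacing < 147:
        raise ValueError("spacing below 147 bp would overlap nucleosome cores")
    centers = origin + spacing * np.arange(n_nucleosomes, dtype=np.int64)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        centers = centers + np.rint(rng.normal(0.0, jitter_sd, n_nucleosomes)).astype(
            np.int64
        )
        centers.sort()
        if n_nucleosomes > 1 and np.min(np.diff(centers)) < 147:
            raise ValueError(
                "jitter produced overlapping nucleosome cores; reduce jitter_sd"
            )
    return NucleosomeTrack(centers={chrom_name: centers})


def _beta_around(
    rng: np.random.Generator, mean: np.ndarray, concentration: float
) -> np.ndarray:
    """Beta draws with the given per-element mean; 0/1 means are degenerate."""
    mean = np.array(mean, dtype=np.float64, copy=True)
    out = np.empty_like(mean)
    interior = (mean > 0.0) & (mean < 1.0)
    if interior.any():
        a = mean[interior] * concentration
        b = (1.0 - mean[interior]) * concentration
        out[interior] = rng.beta(a, b)
    out[~interior] = mean[~interior]
    return out


def make_methylation_landscape(
    track: NucleosomeTrack,
    cpg_step: int = 10,
    profiles: Mapping[str, float] | None = None,
    hypo_domain_fraction: float = 0.15,
    seed: int = 0,
    domain_length: int = 1000,
    hypo_level: float = 0.05,
    site_concentration: float = 30.0,
    domain_concentration: float = 12.0,
) -> MethylationLandscape:
    """Place CpG sites across the track span and draw per-tissue levels.

    Methylation is spatially correlated: the span is tiled with
    contiguous domains (``domain_length`` bp); each domain draws a
    regional mean around the tissue mean, and per-site probabilities
    are drawn around the regional mean.  A ``hypo_domain_fraction`` of
    domains per profile is forced to ``hypo_level``, emulating
    unmethylated islands (and, for a hypomethylated tumor profile, the
    broader hypomethylated blocks of tumor genomes).  Domains are drawn
    independently per profile, so tissue pairs carry differential
    sites.
    """
    if profiles is None:
        profiles = {"blood": 0.8, "tumor": 0.4}
    for name, mean in profiles.items():
        if not 0.0 <= mean <= 1.0:
            raise ValueError(f"profile mean for {name!r} outside [0, 1]")
    if not track.centers:
        raise ValueError("empty nucleosome track")
    chrom, _ = track.single_chrom()
    lo, hi = track.span(chrom)
    lo = max(lo, 0)
    positions = np.arange(lo, hi, cpg_step, dtype=np.int64)
    if len(positions) == 0:
        raise ValueError("track span too small for any CpG site")
    rng = np.random.default_rng(seed)
    n_domains = int(np.ceil((hi - lo) / domain_length))
    domain_of_site = ((positions - lo) // domain_length).astype(np.int64)
    out: dict[str, np.ndarray] = {}
    for name in sorted(profiles):
        mean = float(profiles[name])
        dom_mean = _beta_around(
            rng, np.full(n_domains, mean), domain_concentration
        )
        hypo = rng.random(n_domains) < hypo_domain_fraction
        dom_mean[hypo] = hypo_level
        site_p = _beta_around(rng, dom_mean[domain_of_site], site_concentration)
        out[name] = site_p
    return MethylationLandscape(chrom=chrom, positions=positions, profiles=out)


def synthesize_reference(
    track: NucleosomeTrack,
    landscape: MethylationLandscape | None = None,
    cut_model: CutModel | None = None,
    seed: int = 0,
    motif: str = "CCCA",
    motif_enrichment: float = 0.5,
    pad: int = 200,
) -> dict[str, str]:
    """Random reference sequence with motif-seeded linker cut sites.

    Bases are uniform A/C/G/T, with ``CG`` written at every landscape
    CpG site.  At a ``motif_enrichment`` fraction of nucleosomes the
    linker cut sites are seeded so that a fragment cut exactly there
    carries ``motif`` at its 5' end: ``motif`` itself at the U linker
    site, and its reverse complement ending at the D linker site.
    Linker cuts dominate in methylated DNA, so methylated fragments are
    the motif-enriched component — the association that MeDIP-style
    capture experiments read out.
    """
    cut_model = cut_model or CutModel()
    chrom, centers = track.single_chrom()
    length = int(centers[-1] + track.spacing_halfwidth + pad)
    rng = np.random.default_rng(seed)
    seq = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length)
    if landscape is not None:
        sites = landscape.positions
        sites = sites[sites < length - 1]
        seq[sites] = b"C"
        seq[sites + 1] = b"G"
    k = len(motif)
    motif_arr = np.frombuffer(motif.encode(), dtype="S1")
    rc_arr = np.frombuffer(revcomp(motif).encode(), dtype="S1")
    seeded = rng.random(len(centers)) < motif_enrichment
    for c in centers[seeded]:
        u_site = int(c + cut_model.u_linker_offset)
        d_site = int(c + cut_model.d_linker_offset)
        if 0 <= u_site and u_site + k <= length:
            seq[u_site : u_site + k] = motif_arr
        if 0 <= d_site - k + 1 and d_site + 1 <= length:
            seq[d_site - k + 1 : d_site + 1] = rc_arr
    return {chrom: seq.tobytes().decode()}


# ---------------------------------------------------------------------------
# fragment sampling


def _draw_cut_positions(
    rng: np.random.Generator,
    centers: np.ndarray,
    local_m: np.ndarray,
    cm: CutModel,
    n: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised draw of (start, end) pairs for ``n`` fragments."""
    n_nuc = len(centers)
    nuc = rng.integers(0, n_nuc, n)

    u_core = np.asarray(cm.u_core_offsets, dtype=np.int64)
    d_core = np.asarray(cm.d_core_offsets, dtype=np.int64)

    w_core_u = np.asarray(cm.core_weight(local_m[nuc]), dtype=np.float64)
    p_u_linker = cm.w_linker / (cm.w_linker + len(u_core) * w_core_u)
    u_is_linker = rng.random(n) < p_u_linker
    u_off = np.where(
        u_is_linker,
        cm.u_linker_offset,
        u_core[rng.integers(0, len(u_core), n)],
    )

    # the downstream cut may fall on the next nucleosome (di-nucleosomal
    # fragments populate the long, >=170 bp class)
    d_nuc = nuc.copy()
    advance = (rng.random(n) < cm.dinucleosome_fraction) & (nuc < n_nuc - 1)
    d_nuc[advance] += 1
    w_core_d = np.asarray(cm.core_weight(local_m[d_nuc]), dtype=np.float64)
    p_d_linker = cm.w_linker / (cm.w_linker + len(d_core) * w_core_d)
    d_is_linker = rng.random(n) < p_d_linker
    d_off = np.where(
        d_is_linker,
        cm.d_linker_offset,
        d_core[rng.integers(0, len(d_core), n)],
    )

    u = centers[nuc] + u_off + np.rint(rng.normal(0.0, cm.peak_sd, n)).astype(np.int64)
    d = centers[d_nuc] + d_off + np.rint(rng.normal(0.0, cm.peak_sd, n)).astype(np.int64)
    d = np.maximum(d, u + 1)  # U strictly left of D
    return u, d + 1  # start, end (half-open)


def sample_fragments(
    track: NucleosomeTrack,
    landscape: MethylationLandscape,
    cut_model: CutModel | None = None,
    spec: SampleSpec | None = None,
) -> FragmentSet:
    """Draw one sample's fragments from the cut-site model.

    Each fragment picks a nucleosome, then samples its U and D cut
    among the preferred sites; intra-core weights shrink with local
    methylation of the relevant profile, linker weights do not.
    Per-CpG binary methylation states are Bernoulli draws from the
    per-site probabilities of the profile the fragment derives from.
    """
    cut_model = cut_model or CutModel()
    spec = spec or SampleSpec()
    chrom, centers = track.single_chrom()
    if chrom != landscape.chrom:
        raise ValueError("track and landscape are on different chromosomes")
    n = spec.n_fragments
    if n == 0:
        return FragmentSet(
            spec.sample_id, chrom, np.empty(0, np.int64), np.empty(0, np.int64),
            label=spec.label, tumor_fraction=spec.tumor_fraction,
        )
    if spec.tumor_fraction > 0 and spec.tumor_profile not in landscape.profiles:
        raise ValueError(
            f"tumor fraction > 0 but no {spec.tumor_profile!r} profile in landscape"
        )
    rng = np.random.default_rng(spec.seed)
    is_tumor = rng.random(n) < spec.tumor_fraction

    starts = np.empty(n, dtype=np.int64)
    ends = np.empty(n, dtype=np.int64)
    prof_idx = np.zeros(n, dtype=np.int64)  # 0 = background, 1 = tumor
    components = [(~is_tumor, spec.background_profile, 0)]
    if is_tumor.any():
        components.append((is_tumor, spec.tumor_profile, 1))
    for mask, profile, idx in components:
        m = int(mask.sum())
        if m == 0:
            continue
        local_m = landscape.local_levels(centers, profile, track.core_halfwidth)
        s, e = _draw_cut_positions(rng, centers, local_m, cut_model, m)
        starts[mask] = s
        ends[mask] = e
        prof_idx[mask] = idx

    meth = None
    if spec.emit_methylation and len(landscape.positions):
        pos = landscape.positions
        lo = np.searchsorted(pos, starts)
        hi = np.searchsorted(pos, ends)
        counts = hi - lo
        indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
        total = int(indptr[-1])
        flat = (
            np.repeat(lo, counts)
            + np.arange(total)
            - np.repeat(indptr[:-1], counts)
        )
        prof_names = [spec.background_profile, spec.tumor_profile]
        prof_mat = np.stack(
            [
                landscape.profiles[prof_names[0]],
                landscape.profiles.get(prof_names[1], landscape.profiles[prof_names[0]]),
            ]
        )
        probs = prof_mat[np.repeat(prof_idx, counts), flat]
        states = (rng.random(total) < probs).astype(np.int8)
        meth = MethCalls(indptr, pos[flat], states)

    origins = np.where(is_tumor, "tumor", "background").astype(object)
    return FragmentSet(
        sample_id=spec.sample_id,
        chroms=chrom,
        starts=starts,
        ends=ends,
        label=spec.label,
        meth=meth,
        origins=origins,
        tumor_fraction=spec.tumor_fraction,
    )


def mix_samples(
    control: FragmentSet,
    tumor: FragmentSet,
    tumor_fraction: float,
    n: int,
    seed: int = 0,
    sample_id: str = "mixture",
) -> FragmentSet:
    """Emulate plasma at a given tumor DNA load by pool mixing.

    Each of the ``n`` output fragments is drawn (with replacement) from
    the tumor pool with probability ``tumor_fraction``, else from the
    control pool; per-fragment provenance is kept in ``origins``.
    """
    if not 0.0 <= tumor_fraction <= 1.0:
        raise ValueError("tumor fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    from_tumor = rng.random(n) < tumor_fraction
    n_t = int(from_tumor.sum())
    if n_t > 0 and len(tumor) == 0:
        raise ValueError("tumor pool is empty but tumor draws were requested")
    if n_t < n and len(control) == 0:
        raise ValueError("control pool is empty but control draws were requested")
    parts = []
    if n - n_t:
        idx = rng.integers(0, len(control), n - n_t)
        parts.append((control.subset(idx), "control"))
    if n_t:
        idx = rng.integers(0, len(tumor), n_t)
        parts.append((tumor.subset(idx), "tumor"))
    pooled = FragmentSet.concat([p for p, _ in parts], sample_id=sample_id)
    pooled.origins = np.concatenate(
        [np.full(len(p), tag, dtype=object) for p, tag in parts]
    )
    pooled.label = "cancer" if tumor_fraction > 0 else "control"
    pooled.tumor_fraction = tumor_fraction
    return pooled


def simulate_medip_capture(
    fragments: FragmentSet,
    capture_weight_per_methylated_cpg: float = 0.05,
    seed: int = 0,
) -> FragmentSet:
    """Methylation-proportional capture (cfMeDIP-style enrichment).

    A fragment carrying ``m`` methylated CpGs is retained with
    probability ``min(1, w * m)``; unmethylated fragments are lost.
    """
    w = capture_weight_per_methylated_cpg
    if w < 0:
        raise ValueError("capture weight must be non-negative")
    if fragments.meth is None:
        raise ValueError("fragments carry no methylation states")
    meth_count = fragments.meth.methylated_counts()
    p = np.minimum(1.0, w * meth_count)
    rng = np.random.default_rng(seed)
    keep = rng.random(len(fragments)) < p
    return fragments.subset(keep, sample_id=f"{fragments.sample_id}.medip")


# ---------------------------------------------------------------------------
# fixture bundle


def write_fixture_bundle(
    outdir: str | os.PathLike,
    seed: int = 1,
    n_nucleosomes: int = 400,
    spacing: int = 185,
    n_fragments: int = 20_000,
    n_controls: int = 6,
    n_cancers: int = 2,
    tumor_fraction: float = 0.3,
) -> dict:
    """Emit a complete on-disk test dataset and its manifest.

    Writes the nucleosome track (BED), synthetic reference (FASTA),
    per-sample fragment BEDs with companion methylation-call TSVs, and
    a JSON manifest of all parameters and file names.  Byte-identical
    across runs at a fixed seed.
    """
    from . import io as fio  # deferred: io imports core only

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    track = make_nucleosome_array(n_nucleosomes, spacing, seed=seed)
    landscape = make_methylation_landscape(track, seed=seed + 1)
    cut_model = CutModel()
    reference = synthesize_reference(track, landscape, cut_model, seed=seed + 2)

    files: dict[str, str] = {}
    fio.write_nucleosome_track(track, os.path.join(outdir, "nucleosomes.bed"))
    files["nucleosome_track"] = "nucleosomes.bed"
    fio.write_fasta(reference, os.path.join(outdir, "reference.fa"))
    files["reference"] = "reference.fa"

    samples = []
    for i in range(n_controls):
        spec = SampleSpec(
            sample_id=f"control_{i:02d}", label="control",
            n_fragments=n_fragments, seed=seed * 1000 + i,
        )
        samples.append(spec)
    for i in range(n_cancers):
        spec = SampleSpec(
            sample_id=f"cancer_{i:02d}", label="cancer",
            n_fragments=n_fragments, tumor_fraction=tumor_fraction,
            seed=seed * 1000 + 500 + i,
        )
        samples.append(spec)

    sample_entries = []
    for spec in samples:
        fs = sample_fragments(track, landscape, cut_model, spec)
        bed = f"{spec.sample_id}.bed"
        tsv = f"{spec.sample_id}.meth.tsv"
        fio.write_fragments_bed(fs, os.path.join(outdir, bed))
        fio.write_methylation_calls(fs, os.path.join(outdir, tsv))
        files[f"fragments:{spec.sample_id}"] = bed
        files[f"methylation:{spec.sample_id}"] = tsv
        sample_entries.append(
            {
                "sample_id": spec.sample_id,
                "label": spec.label,
                "n_fragments": len(fs),
                "tumor_fraction": spec.tumor_fraction,
                "seed": spec.seed,
                "fragments": bed,
                "methylation": tsv,
                "fraction_with_cpg": float(np.mean(fs.meth.counts() > 0)),
            }
        )

    manifest = {
        "seed": seed,
        "parameters": {
            "n_nucleosomes": n_nucleosomes,
            "spacing": spacing,
            "n_fragments": n_fragments,
            "n_controls": n_controls,
            "n_cancers": n_cancers,
            "tumor_fraction": tumor_fraction,
            "cut_model": dataclasses.asdict(cut_model),
        },
        "files": files,
        "samples": sample_entries,
    }
    text = json.dumps(manifest, indent=2, sort_keys=True)
    manifest["checksum"] = hashlib.sha256(text.encode()).hexdigest()
    with open(os.path.join(outdir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
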