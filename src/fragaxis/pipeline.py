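"""End-to-end orchestration: simulate -> profile -> periodicity ->
methylation -> motifs -> E-index, driven by one config and one seed.

Every stage is a pure function of (inputs, parameters, seed), so a
repeated run with the same config reproduces the summary byte for
byte.  Stage outputs land as TSV/JSON files under ``outdir``, together
with an effective-config snapshot.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os

import numpy as np
import yaml

from . import io as fio
from .core import FragmentSet
from .eindex import build_end_model, e_index, evaluate_scores
from .methylation import (
    MethylationClassRule,
    sample_methylation_density,
    size_by_methylation_class,
    size_methylation_curve,
)
from .motifs import end_motif_spectrum, motif_usage
from .periodicity import detrend, dominant_period, periodogram
from .profiling import (
    call_end_peaks,
    partition_by_size,
    pseudo_fragment_sizes,
    relative_end_profile,
    size_distribution,
    within_core_fraction,
)
from .simulate import (
    CutModel,
    SampleSpec,
    make_methylation_landscape,
    make_nucleosome_array,
    sample_fragments,
    simulate_medip_capture,
    synthesize_reference,
)

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "simulate",
    "profile",
    "periodicity",
    "peaks",
    "methylation",
    "motifs",
    "eindex",
)


@dataclasses.dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus the global seed."""

    outdir: str = "fragaxis_out"
    seed: int = 1
    stages: tuple[str, ...] = ALL_STAGES
    # simulation scale
    n_nucleosomes: int = 400
    spacing: int = 185
    n_fragments: int = 50_000
    n_controls: int = 12
    n_cancers: int = 6
    tumor_fraction: float = 0.3
    # analysis parameters
    short_max: int = 147
    long_min: int = 170
    window: int = 93
    core_halfwidth: int = 73
    detrend_span: float = 0.3
    period_band: tuple[float, float] = (5.0, 20.0)
    min_cpgs: int = 2
    hyper_threshold: float = 0.8
    hypo_threshold: float = 0.2
    motif: str = "CCCA"
    medip_weight: float = 0.05

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        d["period_band"] = list(self.period_band)
        return d

    @staticmethod
    def from_dict(d: dict) -> "PipelineConfig":
        d = dict(d)
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        if "period_band" in d:
            d["period_band"] = tuple(d["period_band"])
        return PipelineConfig(**d)

    @staticmethod
    def from_yaml(path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            return PipelineConfig.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def _child_seed(seed: int, *tags: int) -> int:
    """Stable derived seed below 2**31."""
    ss = np.random.SeedSequence([seed, *tags])
    return int(ss.generate_state(1)[0] % (2**31))


def _write_profile_tsv(path, profile) -> None:
    with open(path, "w") as fh:
        fh.write("position\tcount_u\tcount_d\tfreq_u\tfreq_d\n")
        fu = profile.frequencies("U")
        fd = profile.frequencies("D")
        for p, cu, cd, u, d in zip(
            profile.positions, profile.u_counts, profile.d_counts, fu, fd
        ):
            fh.write(f"{p}\t{cu}\t{cd}\t{u:.8g}\t{d:.8g}\n")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the requested stages in dependency order.

    Returns (and writes as ``summary.json``) the per-stage headline
    numbers: within-core fractions, dominant periods, called peak sets
    and pseudo-fragment sizes, methylation class short-fractions and
    the size–methylation slope, end-motif usages, and the E-index
    score table with its ROC evaluation.
    """
    os.makedirs(config.outdir, exist_ok=True)
    config.to_yaml(os.path.join(config.outdir, "effective_config.yaml"))
    summary: dict = {"seed": config.seed, "stages": list(config.stages)}
    cm = CutModel()

    # -- simulate -------------------------------------------------------
    track = make_nucleosome_array(
        config.n_nucleosomes, config.spacing, seed=_child_seed(config.seed, 0)
    )
    landscape = make_methylation_landscape(track, seed=_child_seed(config.seed, 1))
    reference = synthesize_reference(
        track, landscape, cm, seed=_child_seed(config.seed, 2)
    )
    controls: list[FragmentSet] = []
    for i in range(config.n_controls):
        controls.append(
            sample_fragments(
                track,
                landscape,
                cm,
                SampleSpec(
                    sample_id=f"control_{i:02d}",
                    n_fragments=config.n_fragments,
                    seed=_child_seed(config.seed, 10, i),
                ),
            )
        )
    cancers: list[FragmentSet] = []
    for i in range(config.n_cancers):
        cancers.append(
            sample_fragments(
                track,
                landscape,
                cm,
                SampleSpec(
                    sample_id=f"cancer_{i:02d}",
                    label="cancer",
                    n_fragments=config.n_fragments,
                    tumor_fraction=config.tumor_fraction,
                    seed=_child_seed(config.seed, 20, i),
                ),
            )
        )
    if "simulate" in config.stages:
        fio.write_nucleosome_track(
            track, os.path.join(config.outdir, "nucleosomes.bed")
        )
        fio.write_fasta(reference, os.path.join(config.outdir, "reference.fa"))
        for fs in controls + cancers:
            fio.write_fragments_bed(
                fs, os.path.join(config.outdir, f"{fs.sample_id}.bed.gz")
            )
        summary["simulate"] = {
            "n_controls": len(controls),
            "n_cancers": len(cancers),
            "n_fragments_per_sample": config.n_fragments,
        }

    pooled = FragmentSet.concat(controls, sample_id="pooled_controls")
    partition = partition_by_size(pooled, config.short_max, config.long_min)
    short_profile = relative_end_profile(partition.short, track, config.window)
    long_profile = relative_end_profile(partition.long, track, config.window)

    # -- profile --------------------------------------------------------
    if "profile" in config.stages:
        _write_profile_tsv(
            os.path.join(config.outdir, "profile_short.tsv"), short_profile
        )
        _write_profile_tsv(
            os.path.join(config.outdir, "profile_long.tsv"), long_profile
        )
        _, counts, mode = size_distribution(pooled)
        summary["profile"] = {
            "modal_size": mode,
            "within_core_short": within_core_fraction(
                short_profile, config.core_halfwidth
            ),
            "within_core_long": within_core_fraction(
                long_profile, config.core_halfwidth
            ),
            "n_short": len(partition.short),
            "n_long": len(partition.long),
        }

    # -- periodicity ----------------------------------------------------
    if "periodicity" in config.stages:
        periods = {}
        for orientation in ("U", "D"):
            resid = detrend(
                short_profile.frequencies(orientation), config.detrend_span
            )
            periods[orientation] = dominant_period(
                periodogram(resid), config.period_band
            )
        summary["periodicity"] = {"dominant_period_short": periods}

    # -- peaks ----------------------------------------------------------
    if "peaks" in config.stages:
        u_peaks = call_end_peaks(short_profile, "U")
        d_peaks = call_end_peaks(short_profile, "D")
        pseudo = pseudo_fragment_sizes(u_peaks, d_peaks)
        summary["peaks"] = {
            "u_positions": u_peaks.positions.tolist(),
            "d_positions": d_peaks.positions.tolist(),
            "pseudo_fragment_sizes": sorted({s for _, _, s in pseudo}),
        }

    # -- methylation ----------------------------------------------------
    if "methylation" in config.stages:
        rule = MethylationClassRule(
            config.min_cpgs, config.hyper_threshold, config.hypo_threshold
        )
        cmp_result = size_by_methylation_class(pooled, rule=rule)
        curve = size_methylation_curve(pooled)
        summary["methylation"] = {
            "short_fraction": cmp_result.short_fraction,
            "class_p": cmp_result.p_value,
            "slope_per_bp": curve.slope,
            "slope_p": curve.p_value,
            "density_control": sample_methylation_density(pooled),
            "density_cancer": sample_methylation_density(
                FragmentSet.concat(cancers, sample_id="pooled_cancers")
            )
            if cancers
            else None,
        }

    # -- motifs ---------------------------------------------------------
    if "motifs" in config.stages:
        whole = end_motif_spectrum(controls[0], reference)
        captured = simulate_medip_capture(
            controls[0], config.medip_weight, seed=_child_seed(config.seed, 30)
        )
        medip = end_motif_spectrum(captured, reference)
        summary["motifs"] = {
            "motif": config.motif,
            "usage_wgs": motif_usage(whole, config.motif),
            "usage_medip": motif_usage(medip, config.motif),
        }

    # -- eindex ---------------------------------------------------------
    if "eindex" in config.stages:
        model = build_end_model(controls)
        model.to_tsv(os.path.join(config.outdir, "end_model.tsv.gz"))
        eval_controls = [
            sample_fragments(
                track,
                landscape,
                cm,
                SampleSpec(
                    sample_id=f"eval_control_{i:02d}",
                    n_fragments=config.n_fragments,
                    seed=_child_seed(config.seed, 40, i),
                ),
            )
            for i in range(max(config.n_cancers, 2))
        ]
        rows = []
        scores, labels = [], []
        for fs in eval_controls + cancers:
            res = e_index(fs, model)
            rows.append(res)
            scores.append(res.e_index)
            labels.append(fs.label)
        with open(os.path.join(config.outdir, "e_index.tsv"), "w") as fh:
            fh.write("sample\tlabel\tn\te_index\n")
            for res, lab in zip(rows, labels):
                fh.write(f"{res.sample_id}\t{lab}\t{res.n_fragments}\t{res.e_index:.6g}\n")
        entry: dict = {
            "scores": {r.sample_id: r.e_index for r in rows},
        }
        if cancers:
            entry["evaluation"] = evaluate_scores(scores, labels)
        summary["eindex"] = entry

    with open(os.path.join(config.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
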