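import numpy as np
import pytest

import fragaxis as fx


@pytest.fixture(scope="session")
def track():
    """The phased 400-nucleosome model array (185 bp repeat)."""
    return fx.make_nucleosome_array(400, 185, seed=1)


@pytest.fixture(scope="session")
def landscape(track):
    return fx.make_methylation_landscape(track, seed=2)


@pytest.fixture(scope="session")
def cut_model():
    return fx.CutModel()


@pytest.fixture(scope="session")
def reference(track, landscape, cut_model):
    return fx.synthesize_reference(track, landscape, cut_model, seed=3)


@pytest.fixture(scope="session")
def control_samples(track, landscape):
    """Three moderate control samples with methylation states."""
    return [
        fx.sample_fragments(
            track,
            landscape,
            spec=fx.SampleSpec(
                sample_id=f"ctrl_{i}", n_fragments=30_000, seed=100 + i
            ),
        )
        for i in range(3)
    ]


@pytest.fixture(scope="session")
def control_pool(control_samples):
    return fx.FragmentSet.concat(control_samples, sample_id="pooled")


@pytest.fixture(scope="session")
def tumor_pure(track, landscape):
    """A pure tumor-derived fragment pool."""
    return fx.sample_fragments(
        track,
        landscape,
        spec=fx.SampleSpec(
            sample_id="tumor_pool",
            label="cancer",
            n_fragments=60_000,
            tumor_fraction=1.0,
            seed=777,
        ),
    )


@pytest.fixture(scope="session")
def flat_landscape(track):
    """Methylation constant everywhere: no methylation-size coupling."""
    chrom, _ = track.single_chrom()
    lo, hi = track.span(chrom)
    positions = np.arange(max(lo, 0), hi, 10, dtype=np.int64)
    return fx.MethylationLandscape(
        chrom=chrom,
        positions=positions,
        profiles={"blood": np.full(len(positions), 0.7)},
    )


@pytest.fixture(scope="session")
def bundle_dir(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("bundle")
    manifest = fx.write_fixture_bundle(
        outdir, seed=5, n_fragments=2_000, n_controls=2, n_cancers=1
    )
    return outdir, manifest
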