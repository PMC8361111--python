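import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from hypothesis import strategies as st

from flavoscreen import (
    ScreenConfig,
    Spectrum,
    SyntheticSpec,
    default_blocks,
    generate_contaminants,
    generate_decoys,
    generate_library_spectra,
    load_library,
)
from flavoscreen.spectra_io import FragmentPeak

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def blocks():
    return default_blocks()


@pytest.fixture(scope="session")
def library():
    return load_library()


@pytest.fixture(scope="session")
def synthetic_cohort(library):
    """Seeded cohort: 18 embedded library spectra + 50 decoys + 20 contaminants."""
    spec = SyntheticSpec(seed=42, n_decoys=50, contaminant_fraction=0.2)
    cfg = ScreenConfig()
    rng = np.random.default_rng(spec.seed)
    lib_spectra = generate_library_spectra(library, spec, rng)
    decoys = generate_decoys(spec, cfg=cfg, library=library, rng=rng)
    contaminants = generate_contaminants(spec, 20, cfg=cfg, rng=rng)
    return {
        "spec": spec,
        "cfg": cfg,
        "library_spectra": lib_spectra,
        "decoys": decoys,
        "contaminants": contaminants,
        "all": lib_spectra + decoys + contaminants,
    }


# ---- hypothesis strategies shared across test modules ----

mz_values = st.integers(min_value=50_000, max_value=2_000_000).map(lambda n: n / 1000.0)
intensities = st.integers(min_value=0, max_value=10_000_000).map(lambda n: n / 10.0)


@st.composite
def spectra(draw, min_fragments=0, max_fragments=8):
    mzs = draw(
        st.lists(
            mz_values, min_size=min_fragments, max_size=max_fragments, unique=True
        )
    )
    frags = tuple(FragmentPeak(mz, draw(intensities)) for mz in sorted(mzs))
    return Spectrum(
        id=draw(st.uuids().map(str)),
        precursor_mz=draw(mz_values),
        charge=draw(st.integers(min_value=1, max_value=3)),
        rt=draw(st.integers(min_value=0, max_value=6000)) / 600.0,
        fragments=frags,
        sample=draw(st.sampled_from(["", "KB", "PP", "AP"])),
    )
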