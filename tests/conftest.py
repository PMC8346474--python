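import numpy as np
import pytest

from organoidquant.synthetic import (
    NMJFixtureSpec,
    SphereFixtureSpec,
    VideoFixtureSpec,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def sphere_spec(n=9, sox2=0.6, tbxt=0.3, unstained=0.1, seed=1, **kw):
    """Small sphere-field spec with uniform per-sphere fractions."""
    kw.setdefault("field_shape", (384, 384))
    return SphereFixtureSpec(
        n_spheres=n,
        sox2_fraction=(sox2,),
        tbxt_fraction=(tbxt,),
        unstained_fraction=(unstained,),
        seed=seed,
        **kw,
    )


def video_spec(event_times=(20, 50, 80), extent=0.3, amplitude=50.0, seed=0, **kw):
    kw.setdefault("n_frames", 120)
    kw.setdefault("field_shape", (64, 64))
    return VideoFixtureSpec(
        event_times=tuple(event_times),
        event_extent=extent,
        event_amplitude=amplitude,
        seed=seed,
        **kw,
    )


def nmj_spec(n=12, innervated_frac=0.5, diameters=None, seed=3, **kw):
    """NMJ field spec with deterministic innervation pattern."""
    inn = tuple(i < round(innervated_frac * n) for i in range(n))
    if diameters is None:
        diameters = tuple(np.linspace(15, 45, n))
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("field_shape", (384, 384))
    return NMJFixtureSpec(
        n_clusters=n,
        diameter_um=tuple(diameters),
        btx_intensity=(8000.0,),
        egfp_intensity=tuple(12000.0 if b else 500.0 for b in inn),
        innervated_truth=inn,
        seed=seed,
        **kw,
    )
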