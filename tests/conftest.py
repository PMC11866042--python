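import pytest

from hecif.phantom import (
    FibrosisField,
    Misalignment,
    PhantomSpec,
    generate_phantom,
)


@pytest.fixture(scope="session")
def smooth_phantom():
    """A mid-size phantom with a spatially varying field, misalignment,
    bone loss and both compartments populated; shared across tests."""
    spec = PhantomSpec(
        width_px=768,
        height_px=768,
        fibrosis_field=FibrosisField("smooth", mean=0.5, amplitude=0.35, correlation_length_px=80),
        n_bone_blobs=3,
        fat_fraction=0.08,
        misalignment=Misalignment(rotation_deg=3.0, translation_px=(12, -7), scale=1.0),
        bone_loss_fraction=0.3,
        seed=7,
    )
    return generate_phantom(spec)


@pytest.fixture()
def make_constant_phantom():
    def _make(severity: float, seed: int = 11, size: int = 512, **kw):
        spec = PhantomSpec(
            width_px=size,
            height_px=size,
            fibrosis_field=FibrosisField("constant", value=severity),
            n_bone_blobs=kw.pop("n_bone_blobs", 2),
            fat_fraction=kw.pop("fat_fraction", 0.05),
            seed=seed,
            **kw,
        )
        return generate_phantom(spec)

    return _make
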