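import pytest

from farmarker import FamilySpec, build_profile, generate_family


@pytest.fixture(scope="session")
def default_family():
    """One default-condition family (20 target + 20 background, rate 0.05)."""
    return generate_family(FamilySpec(seed=0))


@pytest.fixture(scope="session")
def default_profiles(default_family):
    fam = default_family
    return (
        build_profile(fam.class_alignment("target")),
        build_profile(fam.class_alignment("background")),
        build_profile(list(fam.alignment)),
    )
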