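import pytest

from isinv.simgen import CanonicalElementSpec, SimConfig, build_canonical_element


@pytest.fixture(scope="session")
def spec():
    return CanonicalElementSpec()


@pytest.fixture(scope="session")
def element(spec):
    """One canonical element realised under a fixed seed."""
    return build_canonical_element(spec, 1)


@pytest.fixture()
def small_config():
    """10 strains, explicit clades sized like the worked phylogeny:
    5-leaf monophyletic insertion clade with a nested 2-leaf inversion."""
    newick = ("((((((s01:0.1,s02:0.1):0.2,s03:0.3):0.2,(s04:0.2,s05:0.2):0.3)"
              ":0.2,(s06:0.3,s07:0.3):0.4):0.2,(s08:0.4,s09:0.4):0.5):0.1,"
              "s10:1.0);")
    return SimConfig(
        n_strains=10,
        tree=newick,
        insertion_clade=["s01", "s02", "s03", "s04", "s05"],
        inversion_clade=["s01", "s02"],
        scenario="conversion_left_d",
        mutation_rate=0.0,
        seed=7,
    )
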