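import numpy as np
import pytest

from cdkp.library import Guide, GuideLibrary, build_reference
from cdkp.simulate import synthetic_library


@pytest.fixture(scope="session")
def tiny_library() -> GuideLibrary:
    """Four genes x two guides plus one NTC and one AAVS1 control."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))

    def spacer():
        return "".join(rng.choice(bases, 20))

    guides = []
    for gi in range(4):
        gene = f"GENE{gi + 1:02d}"
        for k in range(2):
            guides.append(Guide(f"{gene}_g{k + 1}", gene, spacer()))
    guides.append(Guide("NTC_g1", "NTC", spacer()))
    guides.append(Guide("AAVS1_g1", "AAVS1", spacer()))
    return GuideLibrary(guides, n_guides_per_gene=2)


@pytest.fixture(scope="session")
def tiny_reference(tiny_library):
    return build_reference(tiny_library)


@pytest.fixture(scope="session")
def screen_library() -> GuideLibrary:
    """A mid-sized screen design: 8 genes x 4 guides + 4 NTC + 4 AAVS1."""
    return synthetic_library(n_genes=8, guides_per_gene=4, seed=7)
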