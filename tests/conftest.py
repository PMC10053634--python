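import numpy as np
import pytest

from gaatract import AmpliconDesign, random_design


@pytest.fixture(scope="session")
def design() -> AmpliconDesign:
    """Standard synthetic design: 800 bp flanks (flank_total_bp = 1600)."""
    return random_design()


@pytest.fixture(scope="session")
def tiny_design() -> AmpliconDesign:
    """Minimal design with 10 bp flanks (too short for default anchors)."""
    return AmpliconDesign("ACGTACGTAC", "TGCATGCATG")


def make_flanks(length: int, seed: int) -> tuple[str, str]:
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    return (
        "".join(rng.choice(bases, size=length)),
        "".join(rng.choice(bases, size=length)),
    )
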