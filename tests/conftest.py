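"""Shared fixtures: synthetic sequences and titration ground truth.

``CLAMP_LIKE_FRAGMENT`` is a synthetic stand-in for the CLAMP
N-terminal zinc-finger region (residues 127-153): it is NOT the real
CLAMP sequence, but it places the experimentally characterised
residues (H138, L139, L141, L142, N143, A144, K146, R147, H149, T150)
at their published coordinates around a canonical C2H2 scaffold, so
the annotation and numbering machinery can be exercised against the
published helix-relative labels.
"""

import pytest

from fingermap import annotate_c2h2, default_titration_spec, simulate_titration

# synthetic; residues 127..153
CLAMP_LIKE_FRAGMENT = "FVCQVCNKGFSHLQLLNAHKRSHTGEE"
CLAMP_LIKE_START = 127

# two canonical C2H2 fingers joined by a TGEKP linker (synthetic)
TANDEM_FINGERS = "YKCPECGKSFSQSSNLQKHQRTH" + "TGEKP" + "YECDHCGKAFRQSSHLQRHIRTH"


@pytest.fixture
def clamp_like_annotation():
    anns = annotate_c2h2(CLAMP_LIKE_FRAGMENT, start=CLAMP_LIKE_START)
    assert len(anns) == 1
    return anns[0]


@pytest.fixture
def noiseless_series():
    spec = default_titration_spec(noise_sd_h=0.0, noise_sd_n=0.0, seed=11)
    return spec, simulate_titration(spec)


@pytest.fixture
def noisy_series():
    spec = default_titration_spec(seed=42)
    return spec, simulate_titration(spec)
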