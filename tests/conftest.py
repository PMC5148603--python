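import numpy as np
import pytest

from hdxpulse.isotopes import IsotopeEnvelope, centroid_mass
from hdxpulse.simulate import reference_envelopes


@pytest.fixture(scope="session")
def state_envelopes():
    """Noiseless folded and unfolded envelopes of the diagnostic peptide."""
    return reference_envelopes()


@pytest.fixture(scope="session")
def reference_init(state_envelopes):
    folded, unfolded = state_envelopes
    return (centroid_mass(folded), centroid_mass(unfolded))


def gaussian_stick_envelope(mu, sigma, amplitude=1.0, spacing=0.25, half_width=6.0):
    """Stick envelope sampled from one Gaussian profile."""
    x = np.arange(mu - half_width * sigma, mu + half_width * sigma + spacing, spacing)
    y = amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)
    return IsotopeEnvelope(x, y, normalized=False)


def two_gaussian_stick_envelope(mu1, s1, a1, mu2, s2, a2, spacing=0.25):
    lo = min(mu1 - 6 * s1, mu2 - 6 * s2)
    hi = max(mu1 + 6 * s1, mu2 + 6 * s2)
    x = np.arange(lo, hi + spacing, spacing)
    y = a1 * np.exp(-0.5 * ((x - mu1) / s1) ** 2) + a2 * np.exp(-0.5 * ((x - mu2) / s2) ** 2)
    return IsotopeEnvelope(x, y, normalized=False)
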