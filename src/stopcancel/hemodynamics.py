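"""Shared optical and haemodynamic constants.

Both the forward simulator (synthgen) and the analysis inverse (fnirs) use
the extinction-coefficient table and canonical haemodynamic response
function defined here, so concentration round-trips are exact by
construction.

Extinction coefficients are for oxy- and deoxy-haemoglobin at the two
instrument wavelengths, expressed per micromolar per centimetre with the
natural-log optical-density convention (values follow the compiled
Gratzer/Cope whole-blood spectra commonly shipped with continuous-wave
NIRS software).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

__all__ = [
    "WAVELENGTHS_NM",
    "EXTINCTION_PER_UM_CM",
    "DPF_DEFAULT",
    "FNIRS_FS_HZ",
    "extinction_matrix",
    "canonical_hrf",
    "hrf_kernel",
]

WAVELENGTHS_NM = (760, 850)

#: {wavelength_nm: (epsilon_HbO2, epsilon_HbR)} in (uM * cm)^-1, ln convention
EXTINCTION_PER_UM_CM: Mapping[int, tuple[float, float]] = {
    760: (1.4866e-3, 3.8437e-3),
    850: (2.5264e-3, 1.7986e-3),
}

#: differential pathlength factors (dimensionless), adult forehead defaults
DPF_DEFAULT: Mapping[int, float] = {760: 6.0, 850: 5.2}

FNIRS_FS_HZ = 7.8125

#: double-gamma HRF shape parameters: response gamma (shape, scale s),
#: undershoot gamma (shape, scale s), undershoot ratio.  The response
#: component peaks ~5 s after the event, inside the 4-7 s analysis window.
HRF_RESPONSE_SHAPE = 6.0
HRF_RESPONSE_SCALE_S = 0.9
HRF_UNDERSHOOT_SHAPE = 16.0
HRF_UNDERSHOOT_SCALE_S = 0.9
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_DURATION_S = 30.0


def extinction_matrix(wavelengths=WAVELENGTHS_NM) -> np.ndarray:
    """2x2 matrix E with E[i] = (eps_HbO2, eps_HbR) at wavelength i."""
    return np.array([EXTINCTION_PER_UM_CM[int(w)] for w in wavelengths], dtype=float)


def canonical_hrf(
    t_s: np.ndarray,
    response_shape: float = HRF_RESPONSE_SHAPE,
    response_scale_s: float = HRF_RESPONSE_SCALE_S,
    undershoot_shape: float = HRF_UNDERSHOOT_SHAPE,
    undershoot_scale_s: float = HRF_UNDERSHOOT_SCALE_S,
    undershoot_ratio: float = HRF_UNDERSHOOT_RATIO,
) -> np.ndarray:
    """Double-gamma haemodynamic response evaluated at ``t_s`` (seconds).

    Normalised so the positive peak equals 1; zero for t < 0 and beyond
    ``HRF_DURATION_S`` (truncated support keeps well-separated events
    exactly non-overlapping).
    """
    from scipy.stats import gamma

    t = np.asarray(t_s, dtype=float)
    h = gamma.pdf(t, response_shape, scale=response_scale_s) - undershoot_ratio * gamma.pdf(
        t, undershoot_shape, scale=undershoot_scale_s
    )
    h = np.where((t >= 0) & (t <= HRF_DURATION_S), h, 0.0)
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def hrf_kernel(fs: float, **hrf_kwargs) -> np.ndarray:
    """The canonical HRF sampled at ``fs`` over its truncated support."""
    n = int(round(HRF_DURATION_S * fs)) + 1
    return canonical_hrf(np.arange(n) / fs, **hrf_kwargs)
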