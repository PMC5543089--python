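"""Canonical double-gamma hemodynamic response function."""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps

__all__ = ["HrfParams", "double_gamma"]


@dataclass(frozen=True)
class HrfParams:
    """Double-gamma parameters: 6 s peak, 16 s undershoot, 1/6 ratio."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    ratio: float = 1.0 / 6.0

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay,
               self.peak_dispersion, self.undershoot_dispersion) <= 0:
            raise ValueError("HRF delays and dispersions must be positive")


def double_gamma(
    t: np.ndarray,
    params: HrfParams = HrfParams(),
    normalize: bool = True,
) -> np.ndarray:
    """Evaluate the response at times ``t`` seconds after event onset.

    Zero for t < 0; with ``normalize`` the peak value is scaled to 1 so that
    amplitude parameters are in signal units.
    """
    t = np.asarray(t, dtype=float)
    p = params
    h = sps.gamma.pdf(t, a=p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    h = h - p.ratio * sps.gamma.pdf(
        t, a=p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = np.where(t < 0, 0.0, h)
    if normalize:
        h = h / _peak_value(p)
    return h


@lru_cache(maxsize=32)
def _peak_value(p: HrfParams) -> float:
    fine = np.arange(0.0, 32.0, 0.01)
    return float(
        np.max(
            sps.gamma.pdf(fine, a=p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
            - p.ratio
            * sps.gamma.pdf(
                fine, a=p.undershoot_delay / p.undershoot_dispersion,
                scale=p.undershoot_dispersion,
            )
        )
    )
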