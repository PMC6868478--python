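"""Analysis frequency bands.

Spectral features are averaged over the traditional EEG bands plus a
high-frequency band ("HF", 70-100 Hz) that lies above the range of typical
scalp EEG and serves as a proxy for scalp-muscle EMG. Frequencies below
5 Hz are excluded throughout because they are dominated by gross-movement
artifacts in an interactive (standing, reaching) task.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band, inclusive on both edges.

    Parameters
    ----------
    name : str
        Band label, e.g. ``"theta"``.
    lo, hi : float
        Band edges in Hz. Bins with ``lo <= f <= hi`` belong to the band.
    """

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo <= self.hi):
            raise ValueError(
                f"band {self.name!r}: edges must satisfy 0 <= lo <= hi, "
                f"got lo={self.lo}, hi={self.hi}"
            )

    def contains(self, f) -> "object":
        """Boolean mask of frequencies inside the band (inclusive edges)."""
        return (f >= self.lo) & (f <= self.hi)


THETA = BandDefinition("theta", 5.0, 7.0)
ALPHA = BandDefinition("alpha", 8.0, 14.0)
BETA = BandDefinition("beta", 15.0, 30.0)
GAMMA = BandDefinition("gamma", 31.0, 55.0)
HF = BandDefinition("HF", 70.0, 100.0)

#: The five analysis bands, in canonical order.
DEFAULT_BANDS = (THETA, ALPHA, BETA, GAMMA, HF)

#: Names of the low-frequency (EEG) bands that undergo HF suppression.
LOW_BAND_NAMES = ("theta", "alpha", "beta", "gamma")

#: Name of the EMG-proxy band; never itself suppressed.
HF_NAME = "HF"
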