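"""Epoch grid: the fixed 10-s sampling lattice all traces live on.

Velocity traces are anchored to Zeitgeber time (ZT): ZT0 is lights-on and
ZT12 lights-off under the standard 12:12 light:dark cycle.  A day is 8640
epochs of 10 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

SECONDS_PER_DAY = 86_400


@dataclass(frozen=True)
class EpochGrid:
    """Uniform epoch lattice anchored to Zeitgeber time.

    Parameters
    ----------
    epoch_length_s:
        Epoch duration in seconds (10 s for Ethoscope velocity data).
    epochs_per_day:
        Number of epochs per 24-h day; must satisfy
        ``epochs_per_day * epoch_length_s == 86400``.
    t0:
        ZT (hours) of the first epoch of a trace.
    lights_on, lights_off:
        ZT hours of the light transitions (0 and 12 for 12:12 LD).
    """

    epoch_length_s: int = 10
    epochs_per_day: int = 8640
    t0: float = 0.0
    lights_on: float = 0.0
    lights_off: float = 12.0

    def __post_init__(self) -> None:
        if self.epoch_length_s <= 0 or self.epochs_per_day <= 0:
            raise ConfigurationError("epoch_length_s and epochs_per_day must be positive")
        if self.epoch_length_s * self.epochs_per_day != SECONDS_PER_DAY:
            raise ConfigurationError(
                f"epochs_per_day ({self.epochs_per_day}) x epoch_length_s "
                f"({self.epoch_length_s}) must equal {SECONDS_PER_DAY}"
            )

    def zt_hours(self, n_epochs: int) -> np.ndarray:
        """ZT (hours, mod 24) of the start of each of ``n_epochs`` epochs."""
        t = self.t0 + np.arange(n_epochs) * (self.epoch_length_s / 3600.0)
        return np.mod(t, 24.0)

    def zt_seconds(self, n_epochs: int) -> np.ndarray:
        """Seconds since ZT0 of day 0 for each epoch start."""
        return self.t0 * 3600.0 + np.arange(n_epochs) * float(self.epoch_length_s)

    def is_night(self, zt: np.ndarray) -> np.ndarray:
        """Boolean mask of epochs falling in the dark phase."""
        zt = np.asarray(zt)
        return (zt >= self.lights_off) | (zt < self.lights_on)

    def epochs_for_hours(self, hours: float) -> int:
        seconds = hours * 3600.0
        n = seconds / self.epoch_length_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(f"{hours} h is not a whole number of epochs")
        return int(round(n))


DEFAULT_GRID = EpochGrid()
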