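"""Event trains: ordered (time, amplitude) impulses with optional outputs.

The input to every model in this package is a train of graded impulses
x(t) = sum_i A_i * delta(t - t_i): stimulation pulses (amplitude in uA) or
upstream population-spike amplitudes (mV).  When the train was recorded
together with a response, each impulse also carries one contemporaneous
output amplitude (e.g. the fEPSP amplitude evoked by that impulse, in mV).
"""

from __future__ import annotations

import numpy as np

from .errors import DataError

__all__ = ["EventTrain"]


class EventTrain:
    """An ordered train of amplitude-graded impulse events.

    Parameters
    ----------
    times : array-like
        Event times in seconds, strictly increasing.
    amplitudes : array-like
        Non-negative input amplitude of each impulse (uA for stimulation
        trains, mV for upstream response amplitudes used as input).
    outputs : array-like, optional
        Contemporaneous response amplitude per event (mV).  Either absent
        or the same length as ``times``.
    train_id : str
        Label used in CSV files and error messages.
    """

    __slots__ = ("times", "amplitudes", "outputs", "train_id",
                 "amplitude_unit", "output_unit")

    def __init__(self, times, amplitudes, outputs=None, train_id="train",
                 amplitude_unit="uA", output_unit="mV"):
        self.times = np.asarray(times, dtype=float)
        self.amplitudes = np.asarray(amplitudes, dtype=float)
        self.outputs = None if outputs is None else np.asarray(outputs, dtype=float)
        self.train_id = str(train_id)
        self.amplitude_unit = amplitude_unit
        self.output_unit = output_unit
        self._validate()

    def _validate(self):
        tid = self.train_id
        if self.times.ndim != 1 or self.amplitudes.ndim != 1:
            raise DataError(f"train {tid!r}: times and amplitudes must be 1-D")
        if len(self.times) != len(self.amplitudes):
            raise DataError(f"train {tid!r}: times and amplitudes differ in length")
        if not np.all(np.isfinite(self.times)):
            raise DataError(f"train {tid!r}: non-finite event times")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise DataError(
                f"train {tid!r}: event times must be strictly increasing "
                "(unsorted or duplicate times)")
        if not np.all(np.isfinite(self.amplitudes)):
            raise DataError(f"train {tid!r}: non-finite amplitudes")
        if np.any(self.amplitudes < 0):
            raise DataError(f"train {tid!r}: amplitudes must be non-negative")
        if self.outputs is not None:
            if len(self.outputs) != len(self.times):
                raise DataError(
                    f"train {tid!r}: outputs length {len(self.outputs)} does not "
                    f"match event count {len(self.times)}")
            if not np.all(np.isfinite(self.outputs)):
                raise DataError(f"train {tid!r}: non-finite outputs")

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def has_outputs(self) -> bool:
        return self.outputs is not None

    def with_outputs(self, outputs) -> "EventTrain":
        """Return a copy of this train carrying the given output amplitudes."""
        return EventTrain(self.times, self.amplitudes, outputs,
                          train_id=self.train_id,
                          amplitude_unit=self.amplitude_unit,
                          output_unit=self.output_unit)

    def __len__(self) -> int:
        return self.n_events

    def __repr__(self) -> str:  # pragma: no cover - convenience
        out = "with outputs" if self.has_outputs else "no outputs"
        return (f"EventTrain(id={self.train_id!r}, n={self.n_events}, {out}, "
                f"amplitude_unit={self.amplitude_unit!r})")
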