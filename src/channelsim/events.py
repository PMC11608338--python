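"""Alternating open/closed dwell sequences (the idealization's output)."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["EventList"]


@dataclass
class EventList:
    """Train of consecutive dwell times in either the open or closed class.

    ``classes`` holds ``"C"``/``"O"`` labels, strictly alternating;
    ``durations_samples`` the matching dwell lengths as positive integer
    sample counts at ``sampling_frequency``. The first and last dwells of a
    finite recording are censored (the channel entered/left them outside the
    observation window); they are kept but flagged so that downstream pairing
    can exclude them.
    """

    classes: np.ndarray
    durations_samples: np.ndarray
    sampling_frequency: float
    first_truncated: bool = True
    last_truncated: bool = True

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes, dtype="<U1")
        self.durations_samples = np.asarray(self.durations_samples, dtype=np.int64)
        if self.classes.shape != self.durations_samples.shape:
            raise ValueError("classes and durations must have equal length")
        if self.classes.size:
            if not set(np.unique(self.classes)) <= {"C", "O"}:
                raise ValueError("classes must be 'C' or 'O'")
            if np.any(self.durations_samples <= 0):
                raise ValueError("all dwell durations must be positive")
            if np.any(self.classes[1:] == self.classes[:-1]):
                raise ValueError("classes must strictly alternate")
        if self.sampling_frequency <= 0:
            raise ValueError("sampling_frequency must be positive")

    def __len__(self) -> int:
        return self.classes.size

    @property
    def durations_s(self) -> np.ndarray:
        """Dwell durations in seconds."""
        return self.durations_samples / self.sampling_frequency

    @property
    def total_samples(self) -> int:
        return int(self.durations_samples.sum())

    def retained(self) -> "EventList":
        """Drop censored boundary dwells; the result is flagged untruncated."""
        lo = 1 if (self.first_truncated and len(self) > 0) else 0
        hi = len(self) - 1 if (self.last_truncated and len(self) > lo) else len(self)
        return EventList(
            self.classes[lo:hi],
            self.durations_samples[lo:hi],
            self.sampling_frequency,
            first_truncated=False,
            last_truncated=False,
        )

    @classmethod
    def from_class_samples(
        cls, class_per_sample: np.ndarray, sampling_frequency: float
    ) -> "EventList":
        """Run-length encode a per-sample C/O sequence (0/1 or 'C'/'O')."""
        arr = np.asarray(class_per_sample)
        if arr.dtype.kind in "ui" or arr.dtype == bool:
            sym = np.where(arr.astype(bool), "O", "C")
        else:
            sym = arr.astype("<U1")
        if sym.size == 0:
            return cls(sym, np.empty(0, dtype=np.int64), sampling_frequency)
        change = np.flatnonzero(sym[1:] != sym[:-1]) + 1
        starts = np.concatenate([[0], change])
        ends = np.concatenate([change, [sym.size]])
        return cls(sym[starts], ends - starts, sampling_frequency)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# sampling_frequency_hz={self.sampling_frequency}\n")
            fh.write(f"# first_truncated={self.first_truncated}\n")
            fh.write(f"# last_truncated={self.last_truncated}\n")
            fh.write("class,duration_s\n")
            for c, d in zip(self.classes, self.durations_s):
                fh.write(f"{c},{d:.10g}\n")

    @classmethod
    def from_csv(cls, path) -> "EventList":
        meta = {}
        classes, durs = [], []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("#"):
                    k, _, v = line.lstrip("# ").partition("=")
                    meta[k] = v
                elif line and not line.startswith("class"):
                    c, _, d = line.partition(",")
                    classes.append(c)
                    durs.append(float(d))
        fs = float(meta.get("sampling_frequency_hz", 1.0))
        samples = np.rint(np.asarray(durs) * fs).astype(np.int64)
        return cls(
            np.asarray(classes),
            samples,
            fs,
            first_truncated=meta.get("first_truncated", "True") == "True",
            last_truncated=meta.get("last_truncated", "True") == "True",
        )
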