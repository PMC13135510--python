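"""Recording container and plain-text serialization.

A :class:`Recording` holds a channels x samples matrix with its sampling
rate, channel labels/roles, a per-sample bad mask and subject/condition
labels.  Serialization uses one delimited-text matrix per recording plus a
JSON sidecar so that datasets stay text-only and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

VALID_ROLES = ("cortical", "lfp")


@dataclass
class Recording:
    """Multichannel time series with metadata.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal matrix in arbitrary units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per row of ``data``.
    channel_roles : list of str
        Per-channel role, each one of ``{"cortical", "lfp"}``.
    bad_mask : ndarray of bool, shape (n_samples,)
        True marks samples excluded from estimation.
    subject : str
    condition : str
        Typically ``"off"`` or ``"on"``.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    channel_roles: list[str]
    bad_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    subject: str = "s0"
    condition: str = "off"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains non-finite values")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length must match data rows")
        if len(self.channel_roles) != self.data.shape[0]:
            raise ValueError("channel_roles length must match data rows")
        for role in self.channel_roles:
            if role not in VALID_ROLES:
                raise ValueError(f"invalid channel role {role!r}")
        if self.bad_mask is None:
            self.bad_mask = np.zeros(self.data.shape[1], dtype=bool)
        self.bad_mask = np.asarray(self.bad_mask, dtype=bool)
        if self.bad_mask.shape != (self.data.shape[1],):
            raise ValueError("bad_mask length must equal number of samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_index(label)]

    def channels_with_role(self, role: str) -> list[str]:
        return [
            lab
            for lab, r in zip(self.channel_labels, self.channel_roles)
            if r == role
        ]

    def good_mask(self) -> np.ndarray:
        return ~self.bad_mask

    def copy_with(self, **kwargs) -> "Recording":
        return replace(self, **kwargs)

    # ---------------------------------------------------------------- I/O

    def save(self, basepath: str | Path) -> None:
        """Write ``<basepath>.tsv`` (samples x channels) and ``<basepath>.json``."""
        basepath = Path(basepath)
        basepath.parent.mkdir(parents=True, exist_ok=True)
        np.savetxt(
            basepath.with_suffix(".tsv"),
            self.data.T,
            delimiter="\t",
            header="\t".join(self.channel_labels),
            comments="",
        )
        meta = {
            "fs": self.fs,
            "channel_labels": self.channel_labels,
            "channel_roles": self.channel_roles,
            "subject": self.subject,
            "condition": self.condition,
            "bad_mask": np.flatnonzero(self.bad_mask).tolist(),
            "n_samples": int(self.n_samples),
        }
        basepath.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, basepath: str | Path) -> "Recording":
        basepath = Path(basepath)
        meta = json.loads(basepath.with_suffix(".json").read_text())
        data = np.loadtxt(
            basepath.with_suffix(".tsv"), delimiter="\t", skiprows=1
        ).T
        if data.ndim == 1:
            data = data[None, :]
        bad = np.zeros(meta["n_samples"], dtype=bool)
        bad[np.asarray(meta["bad_mask"], dtype=int)] = True
        return cls(
            data=data,
            fs=meta["fs"],
            channel_labels=meta["channel_labels"],
            channel_roles=meta["channel_roles"],
            bad_mask=bad,
            subject=meta["subject"],
            condition=meta["condition"],
        )
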