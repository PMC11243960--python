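"""In-memory containers for the three kinds of input data.

These are deliberately thin wrappers around numpy arrays / pandas objects:
a fast-fluorescence transient, a PAM rapid-light-curve dataset, and an
omics feature-by-sample table with its group design.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: minimum number of samples a usable OJIP record must contain
MIN_TRANSIENT_SAMPLES = 50
#: cardinal times (s) that must lie inside the record: K at 300 µs, I at 30 ms
T_K, T_J, T_I = 3e-4, 2e-3, 3e-2


@dataclass
class FluorescenceTransient:
    """A fast chlorophyll-fluorescence induction record (OJIP transient).

    Parameters
    ----------
    time
        Sample times in seconds, strictly increasing and positive.
    fluorescence
        Fluorescence in instrument units, same length as ``time``.
    label
        Treatment-group identifier (e.g. ``"A"`` control, ``"B"`` UV-B).
    """

    time: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.time.shape != self.fluorescence.shape or self.time.ndim != 1:
            raise ValidationError("time and fluorescence must be equal-length 1-D arrays")
        if self.time.size < MIN_TRANSIENT_SAMPLES:
            raise ValidationError(
                f"transient has {self.time.size} samples; "
                f"at least {MIN_TRANSIENT_SAMPLES} are required"
            )
        if self.time[0] <= 0 or np.any(np.diff(self.time) <= 0):
            raise ValidationError("time must be positive and strictly increasing")
        if np.any(~np.isfinite(self.fluorescence)) or np.any(self.fluorescence < 0):
            raise ValidationError("fluorescence must be finite and non-negative")
        if self.time[0] > T_K or self.time[-1] < T_I:
            raise ValidationError(
                "record does not cover the cardinal points: need the K point "
                f"(300 µs) through the I point (30 ms); got "
                f"[{self.time[0]:g}, {self.time[-1]:g}] s"
            )

    def __len__(self) -> int:
        return self.time.size


@dataclass
class LightCurveDataset:
    """Saturation-pulse records over a sequence of actinic light (PAR) steps.

    ``f0``/``fm`` are the dark-adapted minimum and maximum fluorescence;
    per step we store PAR (µmol photons m⁻² s⁻¹), the steady-state
    fluorescence F and the pulse maximum Fm′.
    """

    f0: float
    fm: float
    par: np.ndarray
    f: np.ndarray
    fm_prime: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.par = np.asarray(self.par, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        self.fm_prime = np.asarray(self.fm_prime, dtype=float)
        if not (self.fm > self.f0 > 0):
            raise ValidationError("dark reference must satisfy Fm > F0 > 0")
        if not (self.par.shape == self.f.shape == self.fm_prime.shape):
            raise ValidationError("par, f and fm_prime must have equal length")
        if np.any(np.diff(self.par) <= 0) or self.par[0] < 0:
            raise ValidationError("PAR steps must be non-negative and strictly increasing")
        if np.any(self.f <= 0) or np.any(self.fm_prime < self.f):
            raise ValidationError("each step must satisfy Fm' >= F > 0")

    @property
    def n_steps(self) -> int:
        return self.par.size

    @property
    def fv_fm(self) -> float:
        return (self.fm - self.f0) / self.fm


@dataclass
class OmicsFeatureTable:
    """A positive feature × sample abundance matrix with its group design.

    ``layer`` is one of ``transcript`` (FPKM), ``protein`` or ``metabolite``.
    ``design`` maps sample id -> group label (index = sample).  Optional
    ``annotations`` may carry e.g. an EC number or TF family per feature.
    """

    layer: str
    values: pd.DataFrame
    design: pd.Series
    annotations: pd.DataFrame | None = field(default=None)

    LAYERS = ("transcript", "protein", "metabolite")

    def __post_init__(self) -> None:
        if self.layer not in self.LAYERS:
            raise ValidationError(f"layer must be one of {self.LAYERS}, got {self.layer!r}")
        self.design = pd.Series(self.design)
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples without a group assignment: {missing}")
        if (self.values.values < 0).any():
            raise ValidationError("abundances must be non-negative")

    def groups(self) -> list[str]:
        return sorted(self.design.loc[list(self.values.columns)].unique())

    def samples_in(self, group: str) -> list[str]:
        sel = self.design.loc[list(self.values.columns)]
        return list(sel.index[sel == group])
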