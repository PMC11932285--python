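"""Shared domain containers for the urinary NMR metabolomics pipeline.

These classes are deliberately thin: a metabolite resonance, a processed
1D spectrum, and a subjects-by-metabolites concentration table expressed
in µmol/mmol creatinine. Heavier behaviour (simulation, quantification,
modelling) lives in the stage modules.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Class labels used throughout; +1 codes Exposed, -1 codes CTRL.
GROUP_CONTROL = "CTRL"
GROUP_EXPOSED = "Exposed"


@dataclass(frozen=True)
class MetaboliteSignal:
    """One quantifiable resonance: name, integration window, proton count.

    ``window_ppm`` is a half-open interval [lo, hi) on the chemical-shift
    axis. ``n_protons`` is the number of equivalent protons generating the
    signal; ``multiplicity`` the number of lines (binomial intensity
    pattern, 1 = singlet).
    """

    name: str
    window_ppm: tuple[float, float]
    n_protons: int
    multiplicity: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.window_ppm
        if not lo < hi:
            raise ValueError(f"{self.name}: window [{lo}, {hi}) is empty")
        if self.n_protons < 1:
            raise ValueError(f"{self.name}: n_protons must be >= 1")
        if self.multiplicity < 1:
            raise ValueError(f"{self.name}: multiplicity must be >= 1")

    @property
    def center_ppm(self) -> float:
        lo, hi = self.window_ppm
        return 0.5 * (lo + hi)

    def overlaps(self, other: "MetaboliteSignal") -> bool:
        a_lo, a_hi = self.window_ppm
        b_lo, b_hi = other.window_ppm
        return a_lo < b_hi and b_lo < a_hi


@dataclass
class Spectrum:
    """A processed 1D 1H spectrum: ppm axis plus intensity vector.

    The ppm axis must be strictly monotone; it is normalised to increasing
    order on construction so downstream integration can assume it.
    """

    ppm: np.ndarray
    intensity: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ValueError("ppm and intensity must be 1-D vectors of equal length")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # stored high-to-low, flip to increasing
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValueError("ppm axis must be strictly monotone")

    def to_text(self, path: str | Path, sep: str = "\t") -> None:
        """Write as two-column delimited text (ppm, intensity)."""
        np.savetxt(path, np.column_stack([self.ppm, self.intensity]),
                   delimiter=sep, header="ppm\tintensity", comments="")

    @classmethod
    def from_text(cls, path: str | Path, subject_id: str = "") -> "Spectrum":
        arr = np.loadtxt(path, skiprows=1)
        return cls(ppm=arr[:, 0], intensity=arr[:, 1],
                   subject_id=subject_id or Path(path).stem)


@dataclass
class ConcentrationMatrix:
    """Subjects x metabolites table in µmol/mmol creatinine, with labels."""

    values: pd.DataFrame            # index = subject ids, columns = metabolites
    groups: pd.Series               # index-aligned group labels

    def __post_init__(self) -> None:
        if not self.values.columns.is_unique:
            raise ValueError("metabolite column names must be unique")
        if self.values.isna().any().any():
            raise ValueError("concentration matrix contains missing entries")
        self.groups = pd.Series(self.groups, index=self.values.index)
        bad = set(self.groups.unique()) - {GROUP_CONTROL, GROUP_EXPOSED}
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def metabolites(self) -> list[str]:
        return list(self.values.columns)

    def class_codes(self) -> np.ndarray:
        """±1 coding: +1 = Exposed, -1 = CTRL."""
        return np.where(self.groups.to_numpy() == GROUP_EXPOSED, 1.0, -1.0)

    def to_csv(self, path: str | Path | io.TextIOBase) -> None:
        out = self.values.copy()
        out.insert(0, "group", self.groups)
        out.index.name = "subject"
        out.to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path | io.TextIOBase) -> "ConcentrationMatrix":
        df = pd.read_csv(path, index_col=0)
        groups = df.pop("group")
        return cls(values=df, groups=groups)

    def subset(self, rows: Sequence[int]) -> "ConcentrationMatrix":
        return ConcentrationMatrix(values=self.values.iloc[list(rows)],
                                   groups=self.groups.iloc[list(rows)])
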