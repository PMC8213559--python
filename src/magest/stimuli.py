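"""Stimulus specifications for the luminance and red-saturation experiments.

Two fixed stimulus sets are shipped with the package: nine achromatic
luminances (CIE xyY, 1.0-100.0 cd/m^2, reference 10 cd/m^2) and nine red
chromatic stimuli differing only in saturation (CIE LCh-derived saturation S,
reference at nominal 50%).  In both sets four test stimuli lie below and four
above the reference, and the reference stimulus carries the modulus rating 10.

For model fitting and simulation, physical intensities are normalised to a
0-1 scale: luminance as Y/100 (fraction of the maximum luminance, so the
reference maps to 0.1) and red saturation as the nominal fraction
(0.15 ... 0.85, reference 0.50).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSet",
    "ColorimetricRecord",
    "luminance_stimulus_table",
    "red_stimulus_table",
    "saturation_from_chroma",
]

#: Modulus — the rating arbitrarily assigned to the reference stimulus.
REFERENCE_RATING = 10.0

_LUMINANCE_HEADER = ["stimulus", "x_chrom", "y_chrom", "Y", "is_reference"]
_RED_HEADER = [
    "stimulus",
    "nominal_pct",
    "X",
    "Y",
    "Z",
    "L_star",
    "h_star",
    "S",
    "is_reference",
]


def saturation_from_chroma(c_star: float, l_star: float) -> float:
    """CIE LCh saturation S = C* / sqrt(C*^2 + L*^2) * 100 (percent).

    Monotone increasing in chroma at fixed lightness, scale-invariant
    (f(cC*, cL*) = f(C*, L*)), and bounded in [0, 100].

    Raises
    ------
    ValueError
        If either argument is negative, or both are zero (undefined).
    """
    if c_star < 0 or l_star < 0:
        raise ValueError("chroma and lightness must be non-negative")
    if c_star == 0 and l_star == 0:
        raise ValueError("saturation undefined for zero chroma and zero lightness")
    return float(c_star / math.hypot(c_star, l_star) * 100.0)


def _chroma_from_saturation(s_pct: float, l_star: float) -> float:
    # inverse of saturation_from_chroma at fixed L*
    s = s_pct / 100.0
    return float(l_star * s / math.sqrt(1.0 - s * s))


@dataclass(frozen=True)
class ColorimetricRecord:
    """One row of the red-stimulus colorimetry table.

    CIE XYZ tristimulus values (Y in cd/m^2), xy chromaticities, and the
    LCh-1976 quantities L* (lightness), C* (chroma), h* (hue angle, degrees)
    and S (saturation percent).  The shipped table prints L*, h* and S only;
    C* is back-computed from S and L* via C* = L* s / sqrt(1 - s^2), s = S/100.
    """

    name: str
    X: float
    Y: float
    Z: float
    L_star: float
    h_star: float
    S: float
    C_star: float = field(default=float("nan"))
    x_chrom: float = field(default=float("nan"))
    y_chrom: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not (0.0 <= self.S <= 100.0):
            raise ValueError("S must lie in [0, 100]")
        if self.Y <= 0:
            raise ValueError("Y must be positive")
        if math.isnan(self.C_star):
            object.__setattr__(self, "C_star", _chroma_from_saturation(self.S, self.L_star))
        total = self.X + self.Y + self.Z
        if math.isnan(self.x_chrom) and total > 0:
            object.__setattr__(self, "x_chrom", self.X / total)
            object.__setattr__(self, "y_chrom", self.Y / total)


@dataclass(frozen=True)
class StimulusSet:
    """An ordered set of test stimuli plus one reference stimulus.

    ``stimuli`` maps integer stimulus ids (1-based, increasing with physical
    intensity) to physical magnitudes: cd/m^2 for luminance, saturation
    fraction (nominal) for red.  ``reference_rating`` is the modulus (10).
    """

    dimension_label: str
    stimuli: tuple[tuple[int, float], ...]
    reference_id: int
    reference_rating: float = REFERENCE_RATING
    #: optional per-stimulus colorimetry (red set only), keyed by stimulus id
    colorimetry: tuple[ColorimetricRecord, ...] = ()

    def __post_init__(self) -> None:
        ids = [sid for sid, _ in self.stimuli]
        vals = [v for _, v in self.stimuli]
        if self.reference_id not in ids:
            raise ValueError("reference_id not among stimuli")
        if any(v <= 0 for v in vals):
            raise ValueError("intensities must be strictly positive")
        if ids != sorted(ids) or any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("intensities must be strictly increasing by stimulus_id")
        ref = dict(self.stimuli)[self.reference_id]
        others = [v for sid, v in self.stimuli if sid != self.reference_id]
        if not (min(others) < ref < max(others)):
            raise ValueError("reference intensity must lie strictly inside the test range")

    # -- basic queries -----------------------------------------------------
    @property
    def reference_intensity(self) -> float:
        return dict(self.stimuli)[self.reference_id]

    @property
    def test_ids(self) -> tuple[int, ...]:
        return tuple(sid for sid, _ in self.stimuli if sid != self.reference_id)

    @property
    def n_above(self) -> int:
        ref = self.reference_intensity
        return sum(1 for sid, v in self.stimuli if sid != self.reference_id and v > ref)

    @property
    def n_below(self) -> int:
        ref = self.reference_intensity
        return sum(1 for sid, v in self.stimuli if sid != self.reference_id and v < ref)

    def intensity(self, stimulus_id: int) -> float:
        return dict(self.stimuli)[stimulus_id]

    # -- normalisation for modelling --------------------------------------
    def normalized(self) -> dict[int, float]:
        """Physical intensities mapped to the 0-1 modelling scale.

        Luminance divides by 100 cd/m^2 (the maximum); red nominal fractions
        are already on 0-1.
        """
        if self.dimension_label == "luminance":
            return {sid: v / 100.0 for sid, v in self.stimuli}
        return {sid: v for sid, v in self.stimuli}

    def normalized_intensity(self, stimulus_id: int) -> float:
        return self.normalized()[stimulus_id]

    # -- round-trippable CSV form ------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "dimension_label": self.dimension_label,
                "stimulus_id": [sid for sid, _ in self.stimuli],
                "intensity": [repr(v) for _, v in self.stimuli],
                "is_reference": [int(sid == self.reference_id) for sid, _ in self.stimuli],
            }
        )
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "StimulusSet":
        df = pd.read_csv(path)
        expected = ["dimension_label", "stimulus_id", "intensity", "is_reference"]
        if list(df.columns) != expected:
            raise ValueError(f"unexpected columns {list(df.columns)!r}, want {expected!r}")
        ref = int(df.loc[df["is_reference"] == 1, "stimulus_id"].item())
        return cls(
            dimension_label=str(df["dimension_label"].iloc[0]),
            stimuli=tuple(
                (int(r.stimulus_id), float(r.intensity)) for r in df.itertuples()
            ),
            reference_id=ref,
        )


def _read_packaged(name: str, header: list[str]) -> pd.DataFrame:
    with resources.files("magest.data").joinpath(name).open("r") as fh:
        df = pd.read_csv(fh)
    if list(df.columns) != header:
        raise ValueError(f"fixture {name}: columns {list(df.columns)!r} != {header!r}")
    return df


def luminance_stimulus_table() -> StimulusSet:
    """The nine achromatic luminances (Studies of brightness perception).

    Stimulus 5 (10.0 cd/m^2) is the reference; four test stimuli are darker
    and four brighter.
    """
    df = _read_packaged("luminance_stimuli.csv", _LUMINANCE_HEADER)
    ref = int(df.loc[df["is_reference"] == 1, "stimulus"].item())
    return StimulusSet(
        dimension_label="luminance",
        stimuli=tuple((int(r.stimulus), float(r.Y)) for r in df.itertuples()),
        reference_id=ref,
    )


def red_stimulus_table() -> StimulusSet:
    """The nine red stimuli differing only in saturation.

    Keyed by nominal saturation fraction (0.15 ... 0.85); "Red 50%" is the
    reference.  Measured colorimetry (XYZ, L*, h*, S and back-computed C*)
    rides along in ``colorimetry``.
    """
    df = _read_packaged("red_stimuli.csv", _RED_HEADER)
    records = tuple(
        ColorimetricRecord(
            name=str(r.stimulus),
            X=float(r.X),
            Y=float(r.Y),
            Z=float(r.Z),
            L_star=float(r.L_star),
            h_star=float(r.h_star),
            S=float(r.S),
        )
        for r in df.itertuples()
    )
    ref_row = df.loc[df["is_reference"] == 1].index[0]
    return StimulusSet(
        dimension_label="red_saturation",
        stimuli=tuple(
            (i + 1, float(r.nominal_pct) / 100.0) for i, r in enumerate(df.itertuples())
        ),
        reference_id=int(ref_row) + 1,
        colorimetry=records,
    )
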