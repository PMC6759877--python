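"""Perceptual and motor spaces: typed points and distance functions.

The motor space is the set of articulatory configurations — 20-dimensional
descriptions of the instantaneous physical state of the vocal tract.  The
perceptual space is the set of instantaneous sounds — 12-dimensional acoustic
descriptions.  Both are abstract, normalized spaces: the model's claims depend
on the topology induced by the distances below, not on psychoacoustic
calibration, so no unit conversion (Bark, phon) is performed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SOUND_FIELDS",
    "ARTIC_FIELDS",
    "SoundPoint",
    "ArticConfig",
    "make_sound_point",
    "make_artic_config",
    "apply_sound_zeroing",
    "validate_artic",
    "d_artic",
    "d_sounds",
    "sound_difference_vector",
]

#: Coordinate order of an instantaneous sound.  dLoud is the time derivative
#: of loudness; per is the binary periodicity flag; Z1..Z3 are the
#: Bark-transformed formants; cog/width describe the aperiodic spectrum; the
#: d* fields are time derivatives of the five spectral coordinates.
SOUND_FIELDS = (
    "dLoud", "per", "Z1", "Z2", "Z3", "cog", "width",
    "dZ1", "dZ2", "dZ3", "dCog", "dWidth",
)

#: Coordinate order of an articulatory configuration: glottal width, eight
#: normalized cross-sectional areas, velum height, their time derivatives,
#: and the signed jaw-cycle coordinate (opening > 0, closing < 0).
ARTIC_FIELDS = (
    "g", "c1", "c2", "c3", "c4", "c5", "c6", "c7", "c8", "v",
    "dc1", "dc2", "dc3", "dc4", "dc5", "dc6", "dc7", "dc8", "dv", "jdir",
)

N_SOUND = len(SOUND_FIELDS)
N_ARTIC = len(ARTIC_FIELDS)

# index groups used by the zeroing rules and by d_sounds
_I = {name: i for i, name in enumerate(SOUND_FIELDS)}
_FORMANT_IDX = np.array([_I["Z1"], _I["Z2"], _I["Z3"], _I["dZ1"], _I["dZ2"], _I["dZ3"]])
_APERIODIC_IDX = np.array([_I["cog"], _I["width"], _I["dCog"], _I["dWidth"]])
#: the nine non-formant coordinates entering the perceptual distance directly
_NONFORMANT_IDX = np.array(
    [_I[n] for n in ("dLoud", "per", "cog", "width", "dZ1", "dZ2", "dZ3", "dCog", "dWidth")]
)

_AI = {name: i for i, name in enumerate(ARTIC_FIELDS)}
#: range-bounded articulatory coordinates (g, c1..c8, v in [0,1])
UNIT_BOX_IDX = np.arange(0, 10)
JDIR_IDX = _AI["jdir"]


class ValidationError(ValueError):
    """A candidate point violates a space invariant."""


def apply_sound_zeroing(values: np.ndarray) -> np.ndarray:
    """Apply the periodicity zeroing rules to candidate sound coordinates.

    Aperiodic sounds (per = 0) carry no formant structure, so the formants and
    their derivatives are zeroed; periodic sounds (per = 1) carry no dominant
    noise spectrum, so center-of-gravity and peak-width fields are zeroed.
    Works on a single row or an (n, 12) array; returns a new array.
    """
    arr = np.array(values, dtype=float, copy=True)
    one_d = arr.ndim == 1
    rows = arr[None, :] if one_d else arr
    if rows.shape[-1] != N_SOUND:
        raise ValidationError(f"expected {N_SOUND} sound coordinates, got {rows.shape[-1]}")
    per = rows[:, _I["per"]]
    if not np.all((per == 0.0) | (per == 1.0)):
        raise ValidationError("per flag must be 0 or 1")
    aper = per == 0.0
    rows[np.ix_(aper, _FORMANT_IDX)] = 0.0
    rows[np.ix_(~aper, _APERIODIC_IDX)] = 0.0
    return rows[0] if one_d else rows


def validate_artic(values: np.ndarray) -> np.ndarray:
    """Validate candidate articulatory coordinates, returning a float copy.

    g, c1..c8 and v must lie in [0, 1]; jdir in [-1, 1].  The derivative
    coordinates are unbounded (no physical bound is imposed on articulator
    velocities).
    """
    arr = np.array(values, dtype=float, copy=True)
    rows = arr[None, :] if arr.ndim == 1 else arr
    if rows.shape[-1] != N_ARTIC:
        raise ValidationError(f"expected {N_ARTIC} articulatory coordinates, got {rows.shape[-1]}")
    box = rows[:, UNIT_BOX_IDX]
    if np.any(box < -1e-12) or np.any(box > 1 + 1e-12):
        raise ValidationError("g, c1..c8, v must lie in [0, 1]")
    j = rows[:, JDIR_IDX]
    if np.any(np.abs(j) > 1 + 1e-12):
        raise ValidationError("jdir must lie in [-1, 1]")
    return arr


@dataclass(frozen=True)
class SoundPoint:
    """An instantaneous sound: a validated 12-coordinate perceptual point."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", apply_sound_zeroing(self.values))

    def __getattr__(self, name):
        if name in _I:
            return float(self.values[_I[name]])
        raise AttributeError(name)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype)


@dataclass(frozen=True)
class ArticConfig:
    """An articulatory configuration: a validated 20-coordinate motor point."""

    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", validate_artic(self.values))

    def __getattr__(self, name):
        if name in _AI:
            return float(self.values[_AI[name]])
        raise AttributeError(name)

    def __array__(self, dtype=None, copy=None):
        return np.array(self.values, dtype=dtype)


def make_sound_point(**fields) -> SoundPoint:
    """Build a SoundPoint from named coordinates; zeroing rules are applied.

    ``per`` must be supplied as 0 or 1.  Unnamed coordinates default to 0.
    """
    vals = np.zeros(N_SOUND)
    for name, v in fields.items():
        if name not in _I:
            raise ValidationError(f"unknown sound coordinate {name!r}")
        vals[_I[name]] = v
    return SoundPoint(vals)


def make_artic_config(**fields) -> ArticConfig:
    vals = np.zeros(N_ARTIC)
    for name, v in fields.items():
        if name not in _AI:
            raise ValidationError(f"unknown articulatory coordinate {name!r}")
        vals[_AI[name]] = v
    return ArticConfig(vals)


def _as_rows(x, n) -> np.ndarray:
    arr = np.asarray(getattr(x, "values", x), dtype=float)
    if arr.shape[-1] != n:
        raise ValidationError(f"dimension mismatch: expected {n}, got {arr.shape[-1]}")
    return arr


def d_artic(a, a2) -> np.ndarray | float:
    """Euclidean articulatory distance over all 20 motor coordinates.

    Accepts single points (ArticConfig or arrays) or row-stacked arrays;
    broadcasting follows numpy rules, e.g. (n, 20) vs (n, 20) gives (n,).
    """
    x = _as_rows(a, N_ARTIC)
    y = _as_rows(a2, N_ARTIC)
    d = np.sqrt(np.sum((x - y) ** 2, axis=-1))
    return float(d) if d.ndim == 0 else d


def sound_difference_vector(p, p2) -> np.ndarray:
    """The 11-component difference vector underlying the perceptual distance.

    Components: differences of the nine non-formant coordinates, plus the
    differences of (Z3 - Z1) and of (Z3 - Z2).  The formant combinations enter
    only through these two relative values, which makes the distance blind to
    a uniform translation of all three formants — the model's stand-in for
    speaker (vocal-tract-size) normalization.
    """
    x = _as_rows(p, N_SOUND)
    y = _as_rows(p2, N_SOUND)
    diff = x - y
    rel1 = (x[..., _I["Z3"]] - x[..., _I["Z1"]]) - (y[..., _I["Z3"]] - y[..., _I["Z1"]])
    rel2 = (x[..., _I["Z3"]] - x[..., _I["Z2"]]) - (y[..., _I["Z3"]] - y[..., _I["Z2"]])
    return np.concatenate(
        [diff[..., _NONFORMANT_IDX], rel1[..., None], rel2[..., None]], axis=-1
    )


def d_sounds(p, p2, weights: np.ndarray | None = None) -> np.ndarray | float:
    """Perceptual distance: weighted Euclidean norm of the 11-vector above.

    ``weights`` (length 11, default all ones) scales the components; the model
    leaves relative dimension weighting open, so it is exposed here.
    """
    v = sound_difference_vector(p, p2)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        if w.shape != (v.shape[-1],):
            raise ValidationError("weights must have length 11")
        v = v * np.sqrt(w)
    d = np.sqrt(np.sum(v**2, axis=-1))
    return float(d) if d.ndim == 0 else d
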