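"""Position-weight profiles F(i) over tetranucleotide start positions.

A profile assigns every start position i = 1..P (P = L-3 for fragment
length L) a weight 0 <= F(i) <= 1 describing how much a motif match at
that position contributes to the activity.  The built-in library holds
360 curves in two families over a shared parameter grid:

* S-shaped (logistic) ramps — weight concentrated toward one end;
* U-shaped (Gaussian) peaks and valleys — weight concentrated in, or
  depleted from, an interior region.

The exact functional forms and the 9 x 5 x 2 x 2 grid are this
package's parameterization; only the family counts (180 + 180), the
[0, 1] range and the "higher weight, larger contribution" convention are
fixed by the method.  Every profile is max-normalized so that
max_i F(i) = 1, which removes the scale ambiguity (any linear rescaling
is absorbed by the downstream regression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

CENTERS = tuple(round(0.1 * k, 1) for k in range(1, 10))  # 9 values
WIDTHS = (0.02, 0.05, 0.1, 0.2, 0.4)  # 5 values
FLOORS = (0.0, 0.25)  # 2 values
S_ORIENTATIONS = ("up", "down")
U_ORIENTATIONS = ("peak", "valley")


@dataclass(frozen=True)
class WeightProfile:
    """A deterministic per-position weight vector with its provenance."""

    family: str  # "U", "S" or "FLAT"
    center: float
    width: float
    orientation: str
    floor: float
    values: tuple[float, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.size == 0 or v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("profile weights must lie in [0, 1]")

    @property
    def n_positions(self) -> int:
        return len(self.values)

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=float)

    @property
    def name(self) -> str:
        if self.family == "FLAT":
            return "FLAT"
        return f"{self.family}:{self.orientation}:c={self.center}:w={self.width}:floor={self.floor}"


def relative_positions(L: int) -> np.ndarray:
    """Start positions mapped to [0, 1]: t_i = (i-1)/(P-1), P = L-3."""
    if L < 5:
        if L == 4:
            return np.array([0.5])
        raise ValueError(f"fragment length must be >= 5, got {L}")
    P = L - 3
    return np.arange(P) / (P - 1)


def _finalize(family: str, c: float, w: float, orientation: str, floor: float,
              raw: np.ndarray) -> WeightProfile:
    values = raw / raw.max()
    return WeightProfile(
        family=family, center=c, width=w, orientation=orientation, floor=floor,
        values=tuple(np.round(values, 12)),
    )


def _check_grid(c: float, w: float, floor: float) -> None:
    if c not in CENTERS:
        raise ValueError(f"center {c} not in grid {CENTERS}")
    if w not in WIDTHS:
        raise ValueError(f"width {w} not in grid {WIDTHS}")
    if floor not in FLOORS:
        raise ValueError(f"floor {floor} not in grid {FLOORS}")


def s_profile(c: float, w: float, orientation: str, floor: float, P: int) -> WeightProfile:
    """Logistic ramp: weight rises (``up``) or falls (``down``) across
    the fragment, switching around relative position ``c`` over a
    transition width ``w``."""
    _check_grid(c, w, floor)
    if orientation not in S_ORIENTATIONS:
        raise ValueError(f"S orientation must be in {S_ORIENTATIONS}")
    t = relative_positions(P + 3)
    sign = 1.0 if orientation == "up" else -1.0
    raw = floor + (1 - floor) / (1 + np.exp(-sign * (t - c) / w))
    return _finalize("S", c, w, orientation, floor, raw)


def u_profile(c: float, w: float, orientation: str, floor: float, P: int) -> WeightProfile:
    """Gaussian bump: weight concentrated at relative position ``c``
    (``peak``) or depleted there (``valley``), with scale ``w``."""
    _check_grid(c, w, floor)
    if orientation not in U_ORIENTATIONS:
        raise ValueError(f"U orientation must be in {U_ORIENTATIONS}")
    t = relative_positions(P + 3)
    bump = floor + (1 - floor) * np.exp(-(((t - c) / w) ** 2))
    raw = bump if orientation == "peak" else 1.0 - bump + floor
    return _finalize("U", c, w, orientation, floor, raw)


def flat_profile(P: int) -> WeightProfile:
    """F(i) = 1 everywhere: the feature degenerates to a motif count.
    Not part of the 360-curve library; used for diagnostics and tests."""
    return WeightProfile("FLAT", 0.5, 1.0, "flat", 1.0, tuple(np.ones(P)))


def builtin_profiles(L: int, include_flat: bool = False) -> list[WeightProfile]:
    """The deterministic library of 360 profiles for fragment length L.

    Ordering is (family S before U) x center x width x orientation x
    floor, so the library is bit-identical across runs.  With
    ``include_flat`` the FLAT diagnostic profile is prepended (index 0).
    """
    P = L - 3
    if P < 2:
        raise ValueError(f"fragment length must be >= 5, got {L}")
    out: list[WeightProfile] = []
    if include_flat:
        out.append(flat_profile(P))
    for maker, orientations in ((s_profile, S_ORIENTATIONS), (u_profile, U_ORIENTATIONS)):
        for c in CENTERS:
            for w in WIDTHS:
                for orientation in orientations:
                    for floor in FLOORS:
                        out.append(maker(c, w, orientation, floor, P))
    return out


def profiles_to_tsv(path, profiles: list[WeightProfile]) -> None:
    """Audit export: one row per profile with parameters and weights."""
    with open(path, "w", encoding="utf-8") as fh:
        P = profiles[0].n_positions
        cols = "\t".join(f"F{i}" for i in range(1, P + 1))
        fh.write(f"profile_id\tfamily\tc\tw\torientation\tfloor\t{cols}\n")
        for k, p in enumerate(profiles):
            weights = "\t".join(f"{v:.12g}" for v in p.values)
            fh.write(
                f"{k}\t{p.family}\t{p.center}\t{p.width}\t{p.orientation}\t{p.floor}\t{weights}\n"
            )
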