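"""Weighted degenerate-tetranucleotide features.

The feature of pattern ``z1 z2 z3 z4`` under weight profile F in a
fragment ``x_1 .. x_L`` is

    [z1z2z3z4]_F = sum_{i=1}^{L-3} 1[x_i x_{i+1} x_{i+2} x_{i+3} matches] * F(i)

i.e. every start position whose 4-base window matches the degenerate
pattern contributes its positional weight.  Overlapping matches all
count.  The value lies in [0, L-3].

Batch evaluation is vectorized: each fragment's windows are encoded as
base-index quadruples once, and pattern matching reduces to lookups in
the 15 x 4 IUPAC membership table, so that the full 360-profile x
50625-pattern space over a few dozen sequences is enumerable on one CPU.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import CODE_TABLE, DegenerateTetra, encode
from .profiles import WeightProfile
from .sequences import ActivityDataset


@dataclass(frozen=True)
class FeatureVariant:
    """One candidate feature: a degenerate tetranucleotide + a profile."""

    tetra: DegenerateTetra
    profile: WeightProfile

    @property
    def name(self) -> str:
        return f"[{self.tetra}]_{self.profile.name}"


@dataclass
class FeatureMatrix:
    """Feature values for a dataset: records x variants."""

    variants: list[FeatureVariant]
    values: np.ndarray
    dataset_label: str = ""

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.variants):
            raise ValueError("values/variants shape mismatch")


def window_codes(fragment: str) -> np.ndarray:
    """Base-index quadruples of all L-3 windows, shape (L-3, 4)."""
    enc = encode(fragment)
    if enc.size < 4:
        raise ValueError("fragment shorter than 4 bases")
    return np.lib.stride_tricks.sliding_window_view(enc, 4)


def match_positions(fragment: str, tetra: DegenerateTetra) -> np.ndarray:
    """Boolean vector over start positions: does each window match?"""
    w = window_codes(fragment)
    c = tetra.code_indices
    return (
        CODE_TABLE[c[0], w[:, 0]]
        & CODE_TABLE[c[1], w[:, 1]]
        & CODE_TABLE[c[2], w[:, 2]]
        & CODE_TABLE[c[3], w[:, 3]]
    )


def feature_value(fragment: str, variant: FeatureVariant) -> float:
    """The weighted abundance of the pattern in one fragment."""
    F = variant.profile.array
    if len(fragment) != F.size + 3:
        raise ValueError(
            f"fragment length {len(fragment)} incompatible with profile of {F.size} positions"
        )
    return float(match_positions(fragment, variant.tetra) @ F)


class _EncodedDataset:
    """Per-position window encodings shared across variants.

    ``membership[k]`` has shape (15, n, P): for window slot k, whether
    code c admits the base of record j's window at position i.
    """

    def __init__(self, ds: ActivityDataset):
        W = np.stack([window_codes(f) for f in ds.fragments])  # (n, P, 4)
        self.n, self.P, _ = W.shape
        self.membership = [CODE_TABLE[:, W[:, :, k]] for k in range(4)]

    def features(self, tetras: list[DegenerateTetra], F_stack: np.ndarray) -> np.ndarray:
        """Feature values, shape (len(tetras), n, n_profiles).

        ``F_stack`` is (P, n_profiles).  Patterns are processed in
        chunks to bound memory at ~(chunk x n x P) bytes.
        """
        idx = np.array([t.code_indices for t in tetras])  # (V, 4)
        V = idx.shape[0]
        out = np.empty((V, self.n, F_stack.shape[1]))
        chunk = max(1, int(2**22 // max(1, self.n * self.P)))
        m0, m1, m2, m3 = self.membership
        for s in range(0, V, chunk):
            e = min(V, s + chunk)
            mm = (
                m0[idx[s:e, 0]]
                & m1[idx[s:e, 1]]
                & m2[idx[s:e, 2]]
                & m3[idx[s:e, 3]]
            )  # (v, n, P) bool
            out[s:e] = mm.astype(float) @ F_stack
        return out


def feature_matrix(ds: ActivityDataset, variants: list[FeatureVariant]) -> FeatureMatrix:
    """Evaluate many variants over a dataset at once."""
    enc = _EncodedDataset(ds)
    values = np.empty((len(ds), len(variants)))
    # group variants sharing a profile so the weighted contraction batches
    by_profile: dict[WeightProfile, list[int]] = {}
    for k, v in enumerate(variants):
        if v.profile.n_positions != ds.fragment_length - 3:
            raise ValueError(f"variant {v.name}: profile length mismatch")
        by_profile.setdefault(v.profile, []).append(k)
    for profile, cols in by_profile.items():
        tetras = [variants[k].tetra for k in cols]
        feats = enc.features(tetras, profile.array[:, None])[:, :, 0]  # (v, n)
        values[:, cols] = feats.T
    return FeatureMatrix(variants=variants, values=values, dataset_label=ds.label)


def variant_grid(
    tetras: list[DegenerateTetra], profiles: list[WeightProfile]
) -> list[FeatureVariant]:
    """The Cartesian product variant space, profile-major within tetra."""
    return [FeatureVariant(t, p) for t in tetras for p in profiles]
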