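"""IUPAC degenerate RNA alphabet and degenerate tetranucleotide patterns.

The analysis alphabet is RNA: concrete bases ``{A, U, G, C}`` plus the
eleven IUPAC ambiguity codes, 15 single-letter codes in total (the gap
code is excluded).  A degenerate tetranucleotide is an ordered quadruple
of these codes; there are ``15**4 = 50625`` distinct patterns.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

#: concrete RNA bases in canonical order; index into this tuple is the
#: internal integer encoding of a base.
BASES: tuple[str, ...] = ("A", "U", "G", "C")

#: IUPAC code -> set of concrete RNA bases it stands for.
IUPAC_RNA: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "U": frozenset("U"),
    "G": frozenset("G"),
    "C": frozenset("C"),
    "W": frozenset("AU"),
    "S": frozenset("GC"),
    "R": frozenset("AG"),
    "Y": frozenset("CU"),
    "M": frozenset("AC"),
    "K": frozenset("GU"),
    "B": frozenset("CGU"),
    "D": frozenset("AGU"),
    "H": frozenset("ACU"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGU"),
}

#: the 15 codes in a fixed canonical order (concrete first, then by
#: increasing degeneracy, alphabetical within a degeneracy level).
CODES: tuple[str, ...] = ("A", "U", "G", "C", "W", "S", "R", "Y", "M", "K", "B", "D", "H", "V", "N")

_CODE_INDEX = {c: i for i, c in enumerate(CODES)}
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: boolean membership table, shape (15, 4): ``CODE_TABLE[c, b]`` is True
#: iff base ``BASES[b]`` belongs to code ``CODES[c]``.
CODE_TABLE: np.ndarray = np.array(
    [[BASES[b] in IUPAC_RNA[c] for b in range(4)] for c in CODES], dtype=bool
)


class AlphabetError(ValueError):
    """Raised for characters outside the accepted nucleotide alphabet."""


def normalize_sequence(text: str) -> tuple[str, list[int]]:
    """Normalize a nucleotide string to uppercase RNA.

    ``T``/``t`` are mapped to ``U`` (miRBase and most FASTA files use the
    DNA alphabet).  Case carries information in the source tables: the
    analysed fragment is typed in capitals while trimmed flanking bases
    are lowercase, so the case of each input position is returned as a
    mask alongside the normalized sequence.

    Parameters
    ----------
    text:
        Non-empty string over ``{A,C,G,T,U}`` in either case.

    Returns
    -------
    (sequence, lowercase_mask):
        ``sequence`` is the uppercase RNA string; ``lowercase_mask[i]``
        is 1 where the input character was lowercase.

    Raises
    ------
    AlphabetError
        If ``text`` is empty or contains any other character; the error
        message names the offending 1-based position.
    """
    if not text:
        raise AlphabetError("empty sequence")
    out = []
    mask = []
    for pos, ch in enumerate(text, start=1):
        up = ch.upper()
        if up == "T":
            up = "U"
        if up not in _BASE_INDEX:
            raise AlphabetError(f"invalid character {ch!r} at position {pos}")
        out.append(up)
        mask.append(1 if ch.islower() else 0)
    return "".join(out), mask


def encode(fragment: str) -> np.ndarray:
    """Encode a concrete RNA string as an int8 array of base indices."""
    try:
        return np.array([_BASE_INDEX[b] for b in fragment], dtype=np.int8)
    except KeyError as exc:
        raise AlphabetError(f"non-concrete base {exc.args[0]!r} in fragment") from None


@dataclass(frozen=True, order=True)
class DegenerateTetra:
    """An ordered quadruple of IUPAC codes, e.g. ``RHHK`` or ``WRHW``."""

    codes: str

    def __post_init__(self) -> None:
        if len(self.codes) != 4 or any(c not in IUPAC_RNA for c in self.codes):
            raise ValueError(f"need exactly 4 IUPAC codes, got {self.codes!r}")

    def __str__(self) -> str:
        return self.codes

    @property
    def code_indices(self) -> tuple[int, int, int, int]:
        c = self.codes
        return (_CODE_INDEX[c[0]], _CODE_INDEX[c[1]], _CODE_INDEX[c[2]], _CODE_INDEX[c[3]])

    @property
    def expansion_size(self) -> int:
        """Number of concrete tetranucleotides the pattern matches."""
        n = 1
        for c in self.codes:
            n *= len(IUPAC_RNA[c])
        return n


@lru_cache(maxsize=None)
def expand_degenerate(t: DegenerateTetra) -> frozenset[str]:
    """All concrete tetranucleotides matching ``t`` (Cartesian product)."""
    sets = [sorted(IUPAC_RNA[c]) for c in t.codes]
    return frozenset("".join(p) for p in itertools.product(*sets))


def matches(window: str, t: DegenerateTetra) -> bool:
    """True iff a concrete 4-base window matches the degenerate pattern."""
    if len(window) != 4:
        raise ValueError("window must be exactly 4 bases")
    return all(b in IUPAC_RNA[c] for b, c in zip(window, t.codes))


def all_tetras() -> list[DegenerateTetra]:
    """The full pattern space: all ``15**4`` degenerate tetranucleotides,
    in the canonical code order."""
    return [DegenerateTetra("".join(q)) for q in itertools.product(CODES, repeat=4)]


def random_tetra_space(
    k: int, seed: int, include: list[DegenerateTetra] | None = None
) -> list[DegenerateTetra]:
    """A reproducible random subset of the tetranucleotide space.

    Used to restrict the search space in simulations; ``include`` forces
    specific patterns (e.g. a planted one) into the sample.
    """
    rng = np.random.default_rng(seed)
    space = all_tetras()
    idx = rng.choice(len(space), size=min(k, len(space)), replace=False)
    chosen = {space[i] for i in idx}
    for t in include or []:
        chosen.add(t)
    return sorted(chosen)
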