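"""Sequence records, activity datasets, and plain-text I/O.

A dataset couples fixed-length mature miRNA fragments with one measured
activity per sequence (ln-abundance, ln-affinity, or any real value).
The convention of the source tables is kept: lowercase letters in an
input sequence mark trimmed flanking bases, and the uppercase run is the
analysed fragment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .alphabet import normalize_sequence


@dataclass
class SequenceRecord:
    """One mature miRNA: full normalized sequence plus its analysis window."""

    id: str
    raw: str
    fragment: str
    fragment_offset: int  # 1-based start of fragment within raw

    def __post_init__(self) -> None:
        start = self.fragment_offset - 1
        if self.raw[start : start + len(self.fragment)] != self.fragment:
            raise ValueError(
                f"{self.id}: fragment is not a substring of raw at offset {self.fragment_offset}"
            )


@dataclass(frozen=True)
class AffinityPair:
    """ln-affinities of one miRNA for Ago2 (x2) and Ago3 (x3).

    Sigma/Delta are the half-sum and half-difference reparameterization:
    sigma tracks overall Ago loading, delta > 0 indicates Ago2 preference.
    """

    x2: float
    x3: float

    @property
    def sigma(self) -> float:
        return (self.x2 + self.x3) / 2.0

    @property
    def delta(self) -> float:
        return (self.x2 - self.x3) / 2.0


def sigma_delta(x2: float, x3: float) -> tuple[float, float]:
    """Half-sum and half-difference of the two Ago ln-affinities."""
    return (x2 + x3) / 2.0, (x2 - x3) / 2.0


def sigma_delta_inverse(sigma: float, delta: float) -> tuple[float, float]:
    """Reconstruct (x2, x3) from (sigma, delta); exact inverse."""
    return sigma + delta, sigma - delta


@dataclass
class ActivityDataset:
    """Aligned (sequence fragment, activity) records of a common length."""

    records: list[SequenceRecord]
    activity: np.ndarray
    fragment_length: int
    label: str = ""
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if len(self.records) != len(self.activity):
            raise ValueError("records and activity lengths differ")
        if len(self.records) < 2:
            raise ValueError("need at least 2 records")
        if self.fragment_length < 4:
            raise ValueError("fragment length must be >= 4")
        for r in self.records:
            if len(r.fragment) != self.fragment_length:
                raise ValueError(
                    f"{r.id}: fragment length {len(r.fragment)} != declared {self.fragment_length}"
                )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def fragments(self) -> list[str]:
        return [r.fragment for r in self.records]

    def with_activity(self, activity: np.ndarray, label: str | None = None) -> "ActivityDataset":
        """A copy of the dataset with a replacement activity vector."""
        return ActivityDataset(
            records=list(self.records),
            activity=np.asarray(activity, dtype=float),
            fragment_length=self.fragment_length,
            label=self.label if label is None else label,
            annotations=dict(self.annotations),
        )


def extract_fragment(seq_id: str, raw_text: str, target_length: int) -> SequenceRecord:
    """Build a record whose fragment is the analysis window of ``raw_text``.

    Lowercase input positions mark trimmed flanks; when present, the
    fragment is the maximal uppercase run (which must have the target
    length exactly if its length differs a length error is raised unless
    it is at least ``target_length``, in which case its leading window is
    used).  All-uppercase input falls back to the leading window of
    ``target_length`` bases, with a warning.
    """
    raw, mask = normalize_sequence(raw_text)
    if len(raw) < target_length:
        raise ValueError(
            f"{seq_id}: sequence length {len(raw)} shorter than target {target_length}"
        )
    # locate the maximal uppercase (mask == 0) run
    best_start, best_len = 0, 0
    i = 0
    while i < len(mask):
        if mask[i] == 0:
            j = i
            while j < len(mask) and mask[j] == 0:
                j += 1
            if j - i > best_len:
                best_start, best_len = i, j - i
            i = j
        else:
            i += 1
    if any(mask):
        if best_len < target_length:
            raise ValueError(
                f"{seq_id}: uppercase run of {best_len} nt shorter than target {target_length}"
            )
        start = best_start
    else:
        if len(raw) > target_length:
            warnings.warn(
                f"{seq_id}: all-uppercase sequence longer than {target_length} nt; "
                "using the leading window",
                stacklevel=2,
            )
        start = 0
    fragment = raw[start : start + target_length]
    return SequenceRecord(id=seq_id, raw=raw, fragment=fragment, fragment_offset=start + 1)


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, sequence) pairs from a plain FASTA file, order preserved."""
    out = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq)))
    return out


def read_activity_tsv(path, fragment_length: int | None = None, label: str = "") -> ActivityDataset:
    """Load a tab-separated ``id<TAB>sequence<TAB>activity`` table.

    ``fragment_length`` defaults to the uppercase-run length of the first
    row.  Sequence case follows the trimming convention described above.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:3] != ["id", "sequence", "activity"]:
            raise ValueError(f"expected header id/sequence/activity, got {header[:3]}")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"line {lineno}: expected 3 columns")
            rows.append((lineno, parts[0], parts[1], parts[2]))
    if not rows:
        raise ValueError("empty activity table")
    ids = [r[1] for r in rows]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids in activity table")
    if fragment_length is None:
        raw0, mask0 = normalize_sequence(rows[0][2])
        upper = sum(1 for m in mask0 if m == 0)
        fragment_length = upper if upper else len(raw0)
    records, activity = [], []
    for lineno, rid, seq, act in rows:
        try:
            activity.append(float(act))
        except ValueError:
            raise ValueError(f"line {lineno} ({rid}): non-numeric activity {act!r}") from None
        records.append(extract_fragment(rid, seq, fragment_length))
    return ActivityDataset(
        records=records,
        activity=np.array(activity),
        fragment_length=fragment_length,
        label=label or str(path),
    )


def write_activity_tsv(path, ds: ActivityDataset) -> None:
    """Write a dataset back to ``id<TAB>sequence<TAB>activity`` (6 decimals)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tsequence\tactivity\n")
        for rec, act in zip(ds.records, ds.activity):
            fh.write(f"{rec.id}\t{rec.fragment}\t{act:.6f}\n")
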