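"""Packaged training datasets.

Two small tables ship with the package, transcribed column-for-column at
the printed 2-decimal precision:

* ``table1``: 17 Arabidopsis mature miRNA fragments (20 nt) with
  ln-abundance, plus two precomputed weighted-tetranucleotide feature
  columns, ``[WRHW]_F1`` (centre-weighted) and ``[DRYD]_F2``
  (3'-weighted).
* ``table2``: 12 human mature miRNA fragments (22 nt) with ln-affinities
  for Ago2 and Ago3, their half-difference Delta and half-sum Sigma, and
  feature columns ``[RHHK]_F3`` and ``[YRHB]_F4``.

The feature columns were produced with weight profiles that are not
published; they are treated here as data, not as values the feature
module reproduces.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .sequences import ActivityDataset, AffinityPair, extract_fragment


def _data_path(name: str):
    return resources.files("tetractivity.data").joinpath(name)


def _read(name: str) -> pd.DataFrame:
    with resources.as_file(_data_path(name)) as p:
        return pd.read_csv(p, sep="\t")


def load_table1() -> ActivityDataset:
    """Arabidopsis training set: 17 records, L=20, activity = ln[miRNA].

    Annotations carry the printed feature columns under ``wrhw_f1`` and
    ``dryd_f2`` (numpy arrays aligned with the records).
    """
    df = _read("table1.tsv")
    records = [extract_fragment(r.id, r.sequence, 20) for r in df.itertuples()]
    return ActivityDataset(
        records=records,
        activity=df["activity"].to_numpy(),
        fragment_length=20,
        label="arabidopsis-ln-abundance",
        annotations={
            "wrhw_f1": df["wrhw_f1"].to_numpy(),
            "dryd_f2": df["dryd_f2"].to_numpy(),
        },
    )


def load_table2(activity: str = "delta") -> ActivityDataset:
    """Human Ago-affinity training set: 12 records, L=22.

    ``activity`` selects which measured column is exposed as the dataset
    activity: ``"delta"`` (Ago2-vs-Ago3 preference, default), ``"sigma"``
    (overall loading), ``"x2"`` or ``"x3"``.  Annotations carry all four
    plus the printed ``rhhk_f3``/``yrhb_f4`` feature columns and
    per-record :class:`AffinityPair` objects.
    """
    df = _read("table2.tsv")
    if activity not in {"delta", "sigma", "x2", "x3"}:
        raise ValueError(f"unknown activity column {activity!r}")
    records = [extract_fragment(r.id, r.sequence, 22) for r in df.itertuples()]
    pairs = [AffinityPair(x2, x3) for x2, x3 in zip(df["x2"], df["x3"])]
    return ActivityDataset(
        records=records,
        activity=df[activity].to_numpy(),
        fragment_length=22,
        label=f"human-ago-affinity-{activity}",
        annotations={
            "x2": df["x2"].to_numpy(),
            "x3": df["x3"].to_numpy(),
            "delta": df["delta"].to_numpy(),
            "sigma": df["sigma"].to_numpy(),
            "rhhk_f3": df["rhhk_f3"].to_numpy(),
            "yrhb_f4": df["yrhb_f4"].to_numpy(),
            "pairs": pairs,
        },
    )
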