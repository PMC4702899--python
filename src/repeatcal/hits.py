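"""Hit records and tblout-like tabular IO.

A :class:`Hit` is one match of a family model to a target sequence, in the
style of an nhmmer tblout row: 1-based inclusive alignment envelope,
strand, bit score and E-value. Hit tables are plain TSV so that externally
produced hit lists can be dropped in alongside the internal scorer's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

__all__ = ["Hit", "read_hits_tsv", "write_hits_tsv", "hits_to_frame"]

_COLUMNS = ["target_id", "model_id", "ali_from", "ali_to", "strand", "score", "evalue"]


@dataclass(frozen=True)
class Hit:
    model_id: str
    target_id: str
    ali_from: int
    ali_to: int
    strand: str
    score: float
    evalue: float = math.nan

    def __post_init__(self) -> None:
        if self.ali_from > self.ali_to:
            raise ValueError("ali_from must be <= ali_to (strand-normalized)")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        if not math.isfinite(self.score):
            raise ValueError("score must be finite")

    @property
    def length(self) -> int:
        return self.ali_to - self.ali_from + 1


def hits_to_frame(hits: list[Hit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.target_id, h.model_id, h.ali_from, h.ali_to, h.strand, h.score, h.evalue)
         for h in hits],
        columns=_COLUMNS,
    )


def write_hits_tsv(hits: list[Hit], path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def read_hits_tsv(path) -> list[Hit]:
    df = pd.read_csv(path, sep="\t")
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"hit table missing columns: {sorted(missing)}")
    return [
        Hit(model_id=str(r.model_id), target_id=str(r.target_id),
            ali_from=int(r.ali_from), ali_to=int(r.ali_to), strand=str(r.strand),
            score=float(r.score), evalue=float(r.evalue))
        for r in df.itertuples()
    ]
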