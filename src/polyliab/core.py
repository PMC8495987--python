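"""Shared containers and small numeric helpers."""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

_STANDARDIZE_TOL = 1e-8


def standardize(values: np.ndarray) -> np.ndarray:
    """Center to mean 0 and scale to SD 1 (population SD, ddof=0)."""
    values = np.asarray(values, dtype=float)
    sd = values.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (values - values.mean()) / sd


@dataclass
class ScoreVector:
    """A named per-subject burden score (GP, PRS, WGRS, ...).

    Scores that enter downstream evaluation are standardized to mean 0,
    SD 1 over the scored subjects; ``raw`` retains the pre-standardization
    values when they are meaningful.
    """

    name: str
    subject_ids: np.ndarray
    values: np.ndarray
    standardized: bool = True
    provenance: str = ""
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.subject_ids = np.asarray(self.subject_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.subject_ids.shape[0] != self.values.shape[0]:
            raise ValueError("subject_ids and values length mismatch")
        if self.standardized:
            if abs(self.values.mean()) > _STANDARDIZE_TOL or abs(self.values.std() - 1.0) > 1e-6:
                raise ValueError("score marked standardized but mean/SD are not 0/1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"subject_id": self.subject_ids, "score": self.values})

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, index=pd.Index(self.subject_ids, name="subject_id"), name=self.name)

    @classmethod
    def from_raw(cls, name: str, subject_ids, raw_values, provenance: str = "") -> "ScoreVector":
        raw_values = np.asarray(raw_values, dtype=float)
        return cls(
            name=name,
            subject_ids=np.asarray(subject_ids),
            values=standardize(raw_values),
            standardized=True,
            provenance=provenance,
            raw=raw_values,
        )


def spawn_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic per-stage substream from one global seed.

    Uses CRC32 of the stage name so the stream is stable across processes
    (``hash`` is salted per interpreter).
    """
    ss = np.random.SeedSequence(seed, spawn_key=(zlib.crc32(stage.encode("utf-8")),))
    return np.random.default_rng(ss)
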