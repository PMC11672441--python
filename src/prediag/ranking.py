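"""Ranked diagnosis container shared by all inference engines."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["RankedDiagnosis", "TOP_K"]

TOP_K = 5


@dataclass(frozen=True)
class RankedDiagnosis:
    """Top-ranked (disease_id, score) pairs, descending score.

    At most :data:`TOP_K` entries; ties are broken by ascending disease_id so
    rankings are fully deterministic.
    """

    entries: tuple[tuple[int, float], ...]

    def __post_init__(self) -> None:
        scores = [sc for _, sc in self.entries]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("scores must be non-increasing")
        ids = [z for z, _ in self.entries]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate disease_id in ranking")

    @classmethod
    def from_scores(cls, disease_ids, scores, k: int = TOP_K) -> "RankedDiagnosis":
        ids = np.asarray(disease_ids, dtype=int)
        sc = np.asarray(scores, dtype=float)
        order = np.lexsort((ids, -sc))[:k]
        return cls(tuple((int(ids[i]), float(sc[i])) for i in order))

    @classmethod
    def empty(cls) -> "RankedDiagnosis":
        return cls(())

    @property
    def disease_ids(self) -> tuple[int, ...]:
        return tuple(z for z, _ in self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def to_dict(self, kb=None, ndigits: int = 6) -> dict:
        def label(z: int) -> str | None:
            if kb is None:
                return None
            rec = kb.disease_by_id.get(z)
            return rec.description if rec else None

        return {
            "results": [
                {"disease_id": z, "label": label(z), "score": round(s, ndigits)}
                for z, s in self.entries
            ]
        }
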