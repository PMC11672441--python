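"""Uniform engine plugin interface: every engine exposes
``infer(kb, query, config) -> RankedDiagnosis`` and a ``name``, so the
benchmark and the CLI can treat them interchangeably."""

from __future__ import annotations

from typing import Protocol, runtime_checkable

from .baselines import FHALWeights, PFCMParams, fhal_infer, fhal_train, pfcmr_infer
from .fuzzy import FuzzyConfig
from .knowledge_base import KnowledgeBase, Query
from .mnfl import mnfl_infer
from .ranking import RankedDiagnosis

__all__ = [
    "Engine",
    "MNFLEngine",
    "FHALEngine",
    "PFCMREngine",
    "get_engine",
    "ENGINE_NAMES",
]


@runtime_checkable
class Engine(Protocol):
    name: str

    def infer(
        self, kb: KnowledgeBase, query: Query, config: FuzzyConfig | None = None
    ) -> RankedDiagnosis: ...


class MNFLEngine:
    name = "mnfl"

    def infer(self, kb, query, config=None):
        return mnfl_infer(kb, query, config)


class FHALEngine:
    """FHAL with per-knowledge-base weight caching (training is deterministic)."""

    name = "fhal"

    def __init__(self, tau: float = 0.5, alpha: float = 0.5):
        self.tau = tau
        self.alpha = alpha
        self._cache: tuple[KnowledgeBase, FHALWeights] | None = None

    def weights_for(self, kb: KnowledgeBase):
        if self._cache is None or self._cache[0] is not kb:
            self._cache = (kb, fhal_train(kb, tau=self.tau, alpha=self.alpha))
        return self._cache[1]

    def infer(self, kb, query, config=None):
        return fhal_infer(kb, self.weights_for(kb), query, config)


class PFCMREngine:
    name = "pfcmr"

    def __init__(self, params: PFCMParams | None = None):
        self.params = params or PFCMParams()

    def infer(self, kb, query, config=None):
        return pfcmr_infer(kb, query, self.params, config)


_FACTORIES = {
    "mnfl": MNFLEngine,
    "fhal": FHALEngine,
    "pfcmr": PFCMREngine,
}

ENGINE_NAMES = tuple(_FACTORIES)


def get_engine(name: str) -> Engine:
    """Instantiate an engine by its registry name ('mnfl', 'fhal', 'pfcmr')."""
    try:
        return _FACTORIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown engine '{name}'; available: {', '.join(ENGINE_NAMES)}"
        ) from None
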