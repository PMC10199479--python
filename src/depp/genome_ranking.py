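"""Proteome-wide scoring and top-k candidate recovery.

A trained classifier is applied to every translated gene product of a phage
genome; proteins are sorted by descending depolymerase probability and
assigned 1-based ranks. Across a panel of genomes with annotated
depolymerases, top-k recovery summarizes how often the annotated enzyme
lands within the k highest-ranked candidates.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

from .errors import EmptyInputError, ValidationError
from .feature_extraction import GroupSchema, featurize_records
from .model import TrainedModel
from .sequence_io import ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RankedPrediction:
    """One protein's probability and rank within its proteome."""

    protein_id: str
    probability: float
    rank: int
    total: int


@dataclass
class RankingResult:
    """All ranked predictions of one proteome, plus any skipped records."""

    predictions: list[RankedPrediction]
    skipped: list[str]

    @property
    def total(self) -> int:
        return len(self.predictions)

    def rank_of(self, protein_id: str) -> int | None:
        for pred in self.predictions:
            if pred.protein_id == protein_id:
                return pred.rank
        return None


def rank_proteome(
    model: TrainedModel,
    proteome: Sequence[ProteinRecord],
    schema: GroupSchema | None = None,
) -> RankingResult:
    """Score and rank every protein of a proteome.

    Records that cannot be featurized are skipped with a warning and
    excluded from the ranking (and from ``total``). Sorting is by
    descending probability with ties broken by input (genome) order, so
    the output is deterministic and stable under equal scores.
    """
    scoreable: list[ProteinRecord] = []
    skipped: list[str] = []
    for rec in proteome:
        try:
            featurize_records([rec], schema)
            scoreable.append(rec)
        except Exception as exc:  # noqa: BLE001 - any featurization failure skips
            logger.warning("skipping record '%s': %s", rec.id, exc)
            skipped.append(rec.id)
    if not scoreable:
        raise EmptyInputError("no scoreable records in the proteome")
    features = featurize_records(scoreable, schema)
    probabilities = model.predict_proba(features)
    order = sorted(
        range(len(scoreable)), key=lambda i: -probabilities[i]
    )  # sorted() is stable: ties keep genome order
    total = len(scoreable)
    predictions = [
        RankedPrediction(
            protein_id=scoreable[i].id,
            probability=float(probabilities[i]),
            rank=rank,
            total=total,
        )
        for rank, i in enumerate(order, start=1)
    ]
    return RankingResult(predictions=predictions, skipped=skipped)


@dataclass(frozen=True)
class RecoveryStat:
    """Top-k recovery for one cutoff."""

    k: int
    count: int
    n_genomes: int
    fraction: float


def topk_recovery(
    ranks: Mapping[str, int | Iterable[int]],
    ks: Sequence[int],
) -> list[RecoveryStat]:
    """Fraction of genomes whose annotated depolymerase ranks within top k.

    ``ranks`` maps each genome to the observed rank of its annotated
    depolymerase; a genome with several annotated depolymerases contributes
    its best (minimum) rank. Returns one :class:`RecoveryStat` per cutoff
    in ``ks``; fractions are non-decreasing in k and reach 1.0 once k is at
    least the largest observed rank.
    """
    if not ranks:
        raise ValidationError("rank table is empty")
    best: dict[str, int] = {}
    for genome, value in ranks.items():
        candidates = [value] if isinstance(value, int) else [int(v) for v in value]
        if not candidates or min(candidates) < 1:
            raise ValidationError(
                f"genome '{genome}': ranks must be a non-empty set of integers >= 1"
            )
        best[genome] = min(candidates)
    n = len(best)
    stats = []
    for k in ks:
        if k < 1:
            raise ValidationError(f"cutoff k must be >= 1, got {k}")
        count = sum(1 for r in best.values() if r <= k)
        stats.append(RecoveryStat(k=int(k), count=count, n_genomes=n, fraction=count / n))
    return stats
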