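"""Labelled training tables and synthetic sequence generators.

The classifier is trained on a 1:1 balanced table of depolymerase positives
and non-depolymerase negatives. The negative-set generator emulates how such
negatives are constructed in practice — random proteins sampled across the
positive set's length distribution (150-1267 aa), so that sequence length
cannot act as a confounder. Because curated depolymerase sequences cannot be
redistributed here, a synthetic positive-like generator is also provided: it
draws sequences under a composition profile biased the way parallel
beta-solenoid tailspike enzymes are biased (enriched G/S/T/N/D, depleted
charged and sulphur residues). Both generators are seeded and fully
reproducible; see ``docs/methods.md`` for what they do and do not emulate.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Callable, Mapping, Sequence
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, ValidationError
from .feature_extraction import GroupSchema, featurize_records
from .sequence_io import STANDARD_AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

#: Length range of the curated positive set (shortest and longest
#: experimentally verified depolymerase), used as the default sampling range.
POSITIVE_LENGTH_RANGE = (150, 1267)

#: Per-sequence composition variability (Dirichlet concentration mass) used
#: by the bundled synthetic training recipe. Real proteins deviate strongly
#: from any average composition; this keeps the two synthetic classes from
#: being trivially separable on a single residue frequency.
DEFAULT_VARIABILITY = 60.0

LABEL_COLUMN = "label"


def _load_bundled_json(name: str) -> dict:
    with resources.files("depp").joinpath(f"data/{name}").open() as fh:
        return json.load(fh)


def load_composition(source: str | Path) -> dict[str, float]:
    """Load an amino-acid composition profile.

    ``source`` is either a bundled profile name (``uniform``, ``background``,
    ``depolymerase-like``) or a path to a JSON file mapping the 20 one-letter
    codes to probabilities (normalized on load).
    """
    if source == "uniform":
        return {aa: 1.0 / 20.0 for aa in STANDARD_AMINO_ACIDS}
    if source == "background":
        payload = _load_bundled_json("background_composition.json")
    elif source == "depolymerase-like":
        payload = _load_bundled_json("depolymerase_like_composition.json")
    else:
        with open(source) as fh:
            payload = json.load(fh)
    comp = {aa.upper(): float(p) for aa, p in payload.items()}
    if set(comp) != set(STANDARD_AMINO_ACIDS):
        raise ValidationError(
            "composition profile must cover exactly the 20 standard letters"
        )
    total = sum(comp.values())
    if total <= 0:
        raise ValidationError("composition probabilities must sum to > 0")
    return {aa: p / total for aa, p in comp.items()}


@dataclass
class FeatureTable:
    """An id-indexed feature matrix with optional class labels.

    ``features`` is a DataFrame whose columns are descriptor names in a fixed
    shared order; ``labels`` (1 = depolymerase, 0 = not) aligns with the row
    index when present. Tables produced by :func:`build_training_table` carry
    the canonical 424-column schema; the container itself only requires that
    all rows share one schema, so reduced toy tables can use the same
    machinery in tests.
    """

    features: pd.DataFrame
    labels: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.labels is not None:
            self.labels = pd.Series(
                np.asarray(self.labels, dtype=int),
                index=self.features.index,
                name=LABEL_COLUMN,
            )
            bad = set(self.labels.unique()) - {0, 1}
            if bad:
                raise ValidationError(f"labels must be 0/1, got {sorted(bad)}")

    @property
    def ids(self) -> list[str]:
        return [str(i) for i in self.features.index]

    @property
    def n(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(str(c) for c in self.features.columns)

    @property
    def is_labelled(self) -> bool:
        return self.labels is not None

    def to_frame(self) -> pd.DataFrame:
        """Features plus a terminal ``label`` column (when labelled)."""
        frame = self.features.copy()
        if self.labels is not None:
            frame[LABEL_COLUMN] = self.labels
        return frame

    def write(self, path: str | Path, delimiter: str = "\t") -> None:
        self.to_frame().to_csv(path, sep=delimiter, index=True)

    @classmethod
    def read(
        cls,
        path: str | Path,
        delimiter: str = "\t",
        schema: GroupSchema | None = None,
    ) -> "FeatureTable":
        """Load a training/prediction table from a delimited text file.

        Two layouts are accepted: pre-computed feature columns (with an
        optional ``label`` column), or a ``sequence`` column (plus optional
        ``label``) that is featurized on load — the import path for published
        supplementary training tables distributed as sequence+label lists.
        """
        frame = pd.read_csv(path, sep=delimiter, index_col=0)
        if frame.empty:
            raise EmptyInputError(f"{path}: table has no rows")
        cols_lower = {str(c).lower(): c for c in frame.columns}
        labels = None
        if "sequence" in cols_lower:
            records = [
                ProteinRecord(id=str(idx), sequence=str(seq).upper().replace("*", ""))
                for idx, seq in frame[cols_lower["sequence"]].items()
            ]
            features = featurize_records(records, schema)
        else:
            feature_cols = [c for c in frame.columns
                            if str(c).lower() != LABEL_COLUMN]
            features = frame[feature_cols].astype(float)
        if LABEL_COLUMN in cols_lower:
            labels = frame[cols_lower[LABEL_COLUMN]].astype(int).to_numpy()
        return cls(features=features, labels=labels)


def build_training_table(
    positives: Sequence[ProteinRecord],
    negatives: Sequence[ProteinRecord],
    schema: GroupSchema | None = None,
) -> FeatureTable:
    """Featurize positives and negatives into one labelled table.

    Row order is positives (label 1) then negatives (label 0). Class sizes
    may differ, but a warning is logged because the intended design is a 1:1
    balanced set.
    """
    if not positives or not negatives:
        raise EmptyInputError(
            "both a positive and a negative collection are required"
        )
    if len(positives) != len(negatives):
        logger.warning(
            "class imbalance: %d positives vs %d negatives "
            "(a 1:1 set is the intended design)",
            len(positives),
            len(negatives),
        )
    features = featurize_records(list(positives) + list(negatives), schema)
    labels = np.r_[np.ones(len(positives), int), np.zeros(len(negatives), int)]
    return FeatureTable(features=features, labels=labels)


def _sample_lengths(
    rng: np.random.Generator,
    n: int,
    lengths: Sequence[int] | tuple[int, int],
) -> np.ndarray:
    if isinstance(lengths, tuple):
        if len(lengths) != 2 or lengths[0] > lengths[1] or lengths[0] < 3:
            raise ValidationError(
                f"length range must be (min, max) with 3 <= min <= max, got {lengths}"
            )
        return rng.integers(int(lengths[0]), int(lengths[1]) + 1, size=n)
    arr = np.asarray(lengths, dtype=int)
    if arr.ndim != 1 or arr.size == 0 or arr.min() < 3:
        raise ValidationError(
            "lengths must be a (min, max) tuple or a non-empty list of lengths >= 3"
        )
    return rng.choice(arr, size=n, replace=True)


def _sample_records(
    n: int,
    seed: int,
    prefix: str,
    composition: Mapping[str, float],
    lengths: Sequence[int] | tuple[int, int],
    variability: float | None,
) -> list[ProteinRecord]:
    if n < 0:
        raise ValidationError(f"n must be >= 0, got {n}")
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD_AMINO_ACIDS))
    base = np.array([composition[aa] for aa in STANDARD_AMINO_ACIDS])
    base = base / base.sum()
    sizes = _sample_lengths(rng, n, lengths)
    records = []
    for i in range(n):
        if variability is not None:
            probs = rng.dirichlet(variability * base)
        else:
            probs = base
        seq = "".join(rng.choice(letters, size=int(sizes[i]), p=probs))
        records.append(ProteinRecord(id=f"{prefix}_{i + 1}", sequence=seq))
    return records


def generate_negative_set(
    n: int,
    seed: int,
    lengths: Sequence[int] | tuple[int, int] = POSITIVE_LENGTH_RANGE,
    composition: Mapping[str, float] | str | None = None,
    variability: float | None = None,
) -> list[ProteinRecord]:
    """Generate ``n`` random non-depolymerase protein sequences.

    Residues are drawn independently from ``composition`` (default: uniform
    over the 20 letters; pass ``"background"`` for a database-average
    profile). Lengths are drawn from ``lengths`` — either an inclusive
    (min, max) range or an empirical list to resample — defaulting to the
    positive set's 150-1267 aa range, so length carries no class signal.
    ``variability``, when set, draws a per-sequence composition from a
    Dirichlet centred on the profile (concentration mass ``variability``),
    emulating protein-to-protein composition spread. Fully reproducible
    given ``seed``; ids are ``synthneg_1..n``.
    """
    if composition is None:
        composition = load_composition("uniform")
    elif isinstance(composition, str):
        composition = load_composition(composition)
    return _sample_records(n, seed, "synthneg", composition, lengths, variability)


def generate_positive_like_set(
    n: int,
    seed: int,
    lengths: Sequence[int] | tuple[int, int] = POSITIVE_LENGTH_RANGE,
    composition: Mapping[str, float] | str | None = None,
    variability: float | None = DEFAULT_VARIABILITY,
) -> list[ProteinRecord]:
    """Generate ``n`` synthetic depolymerase-like sequences.

    Same sampling scheme as :func:`generate_negative_set` but under the
    bundled ``depolymerase-like`` composition profile: the beta-solenoid
    tailspike bias (G/S/T/N/D enriched; K/R/E/L/C/M depleted). These are
    composition-level surrogates only — they carry no folded domains or
    catalytic motifs — and are labelled synthetic wherever they appear.
    Ids are ``synthpos_1..n``.
    """
    if composition is None:
        composition = load_composition("depolymerase-like")
    elif isinstance(composition, str):
        composition = load_composition(composition)
    return _sample_records(n, seed, "synthpos", composition, lengths, variability)


def synthetic_training_table(
    n_pos: int = 50,
    n_neg: int = 50,
    seed: int = 0,
    schema: GroupSchema | None = None,
) -> FeatureTable:
    """The bundled synthetic study condition: a 1:1 balanced training table.

    50 positive-like + 50 negative sequences (lengths 150-1267 aa), both
    classes drawn with per-sequence Dirichlet composition variability
    (mass :data:`DEFAULT_VARIABILITY`), negatives under the database-average
    background profile. Deterministic given ``seed``.
    """
    positives = generate_positive_like_set(
        n_pos, seed=seed, variability=DEFAULT_VARIABILITY
    )
    negatives = generate_negative_set(
        n_neg,
        seed=seed + 1,
        composition="background",
        variability=DEFAULT_VARIABILITY,
    )
    return build_training_table(positives, negatives, schema)


def toy_feature_table(
    n_pos: int = 20,
    n_neg: int = 20,
    seed: int = 0,
    n_features: int = 24,
    shift: float = 10.0,
    shifted_feature: int = 0,
) -> FeatureTable:
    """A small noise table with one class-separating feature, for tests.

    Features are i.i.d. uniform noise; the positive rows are shifted by
    ``shift`` in column ``shifted_feature``. ``shift=0`` gives an
    unseparable null table. Column names are ``f000..``; labels are
    positives first.
    """
    rng = np.random.default_rng(seed)
    X = rng.random((n_pos + n_neg, n_features))
    X[:n_pos, shifted_feature] += shift
    names = [f"f{i:03d}" for i in range(n_features)]
    ids = [f"pos_{i + 1}" for i in range(n_pos)] + [
        f"neg_{i + 1}" for i in range(n_neg)
    ]
    frame = pd.DataFrame(X, index=pd.Index(ids, name="id"), columns=names)
    labels = np.r_[np.ones(n_pos, int), np.zeros(n_neg, int)]
    return FeatureTable(features=frame, labels=labels)


def homology_screen_hook(
    candidates: Sequence[ProteinRecord],
    positives: Sequence[ProteinRecord] | None = None,
    predicate: Callable[[ProteinRecord], bool] | None = None,
) -> list[ProteinRecord]:
    """Filter candidate negatives for homology against the positive set.

    Sequence-similarity screening requires an external search tool, so the
    default is the identity function with a logged notice. A user-supplied
    ``predicate`` (record -> keep?) plugs the result of such an external
    search back into the pipeline.
    """
    candidates = list(candidates)
    if predicate is None:
        logger.info(
            "homology screening requires an external similarity search; "
            "returning all %d candidates unfiltered",
            len(candidates),
        )
        return candidates
    return [rec for rec in candidates if predicate(rec)]
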