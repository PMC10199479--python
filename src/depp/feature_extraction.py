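"""The 424-descriptor physicochemical feature vector.

Every protein sequence is mapped to a fixed-order vector of 424 descriptors:

=========  ===  ==========================================================
block      n    content
=========  ===  ==========================================================
global     11   molecular weight (Da), aromaticity, instability index,
                isoelectric point, GRAVY, helix/turn/sheet fractions,
                molar extinction coefficients (reduced, oxidized),
                mean flexibility
residues   20   relative abundance of each amino acid (alphabetical)
length      1   sequence length in residues
dipeptide  49   grouped dipeptide frequencies over a 7-class reduced
                amino-acid alphabet, keys "11".."77"
tripeptide 343  grouped tripeptide frequencies, keys "111".."777"
=========  ===  ==========================================================

The 11 global parameters are computed with Biopython's ``ProteinAnalysis``
(Kyte-Doolittle hydropathy for GRAVY, Guruprasad weights for the instability
index, Bjellqvist pKa bisection for the isoelectric point, Vihinen window-9
profile for flexibility). The reduced alphabet partitions the 20 amino acids
into 7 physicochemical classes; k-mers are counted over class labels, which
shrinks the dipeptide space from 400 to 49 and the tripeptide space from
8000 to 343 keys while preserving chemistry-level sequence patterns.
"""

from __future__ import annotations

import itertools
import json
import logging
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import ValidationError
from .sequence_io import STANDARD_AMINO_ACIDS, ProteinRecord

logger = logging.getLogger(__name__)

_STANDARD_SET = frozenset(STANDARD_AMINO_ACIDS)

#: Number of physicochemical classes in the reduced alphabet.
N_GROUPS = 7

#: Default 20-letter -> 7-class partition. Classes: 1 hydrocarbon R group,
#: 2 aromatic uncharged, 3 sulphur-containing, 4 positively charged,
#: 5 negatively charged, 6 polar uncharged, 7 proline. Under this partition
#: the dipeptides "AE" and "LD" both reduce to the class string "15".
DEFAULT_GROUPS: dict[str, int] = {
    "G": 1, "A": 1, "V": 1, "L": 1, "I": 1,
    "F": 2, "W": 2, "Y": 2,
    "C": 3, "M": 3,
    "K": 4, "R": 4, "H": 4,
    "D": 5, "E": 5,
    "S": 6, "T": 6, "N": 6, "Q": 6,
    "P": 7,
}

DEFAULT_GROUP_NAMES: dict[int, str] = {
    1: "hydrocarbon-R",
    2: "aromatic-uncharged",
    3: "sulphur",
    4: "positive",
    5: "negative",
    6: "polar-uncharged",
    7: "proline",
}

#: Fixed names and order of the 11 directly calculated global parameters.
GLOBAL_FEATURE_NAMES: tuple[str, ...] = (
    "molecular_weight",
    "aromaticity",
    "instability_index",
    "isoelectric_point",
    "gravy",
    "helix_fraction",
    "turn_fraction",
    "sheet_fraction",
    "extinction_coefficient_reduced",
    "extinction_coefficient_oxidized",
    "flexibility_mean",
)

AA_FREQUENCY_NAMES: tuple[str, ...] = tuple(
    f"freq_{aa}" for aa in STANDARD_AMINO_ACIDS
)

#: Total descriptor count: 11 global + 20 residues + 1 length + 49 + 343.
N_FEATURES = 424


@dataclass(frozen=True)
class GroupSchema:
    """A total partition of the 20 standard amino acids into 7 classes.

    ``groups`` maps each one-letter code to a class index in 1..7; ``names``
    labels each class. The schema is data-driven (JSON-loadable) so an
    alternative partition can be swapped in without code changes.
    """

    groups: Mapping[str, int]
    names: Mapping[int, str]

    def __post_init__(self) -> None:
        letters = set(self.groups)
        if letters != _STANDARD_SET:
            missing = _STANDARD_SET - letters
            extra = letters - _STANDARD_SET
            raise ValidationError(
                f"group schema must cover exactly the 20 standard letters; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        indices = set(self.groups.values())
        if indices != set(range(1, N_GROUPS + 1)):
            raise ValidationError(
                f"group indices must be exactly 1..{N_GROUPS} with every "
                f"group non-empty; got {sorted(indices)}"
            )

    @classmethod
    def default(cls) -> "GroupSchema":
        return cls(groups=dict(DEFAULT_GROUPS), names=dict(DEFAULT_GROUP_NAMES))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroupSchema":
        """Load a flat ``{letter: index}`` map (optionally ``{"groups": ..., "names": ...}``)."""
        with open(path) as fh:
            payload = json.load(fh)
        if "groups" in payload:
            groups = {k.upper(): int(v) for k, v in payload["groups"].items()}
            names = {int(k): str(v) for k, v in payload.get("names", {}).items()}
        else:
            groups = {k.upper(): int(v) for k, v in payload.items()}
            names = {}
        if not names:
            names = {i: f"group-{i}" for i in sorted(set(groups.values()))}
        return cls(groups=groups, names=names)


def default_schema_path() -> Path:
    """Path of the bundled default group-schema JSON."""
    return Path(str(resources.files("depp").joinpath("data/group_schema.json")))


def assign_group(residue: str, schema: GroupSchema) -> int:
    """Class index (1..7) of a single residue under ``schema``."""
    try:
        return schema.groups[residue]
    except KeyError:
        raise ValidationError(
            f"residue '{residue}' is not one of the 20 standard amino acids"
        ) from None


def kmer_feature_names(k: int) -> tuple[str, ...]:
    """All 7**k grouped k-mer keys in lexicographic order ("11".."77", ...)."""
    digits = [str(i) for i in range(1, N_GROUPS + 1)]
    return tuple("".join(p) for p in itertools.product(digits, repeat=k))


def grouped_kmer_features(
    sequence: str, k: int, schema: GroupSchema | None = None
) -> dict[str, float]:
    """Grouped k-mer frequency profile of a sequence.

    A width-``k`` window slides over the sequence with step 1; each window is
    reduced to the concatenation of its residues' class indices. Counts are
    normalized by the number of windows, ``L - k + 1``, so values sum to 1.

    Returns a dict whose keys are all 7**k class strings in fixed
    lexicographic order (absent k-mers have frequency 0.0).
    """
    if schema is None:
        schema = GroupSchema.default()
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    n_windows = len(sequence) - k + 1
    if n_windows < 1:
        raise ValidationError(
            f"sequence of length {len(sequence)} is shorter than k={k}"
        )
    translated = [str(assign_group(res, schema)) for res in sequence]
    counts: Counter[str] = Counter(
        "".join(translated[i : i + k]) for i in range(n_windows)
    )
    return {
        key: counts.get(key, 0) / n_windows for key in kmer_feature_names(k)
    }


def global_features(sequence: str) -> dict[str, float]:
    """The 11 global parameters, 20 residue frequencies, and length.

    Global parameters come from Biopython's ``ProteinAnalysis``: average-mass
    molecular weight; aromaticity (freq F+W+Y); Guruprasad instability index;
    Bjellqvist isoelectric point; Kyte-Doolittle GRAVY; secondary-structure
    fractions (helix {V,I,Y,F,W,L}, turn {N,P,G,S}, sheet {E,M,A,L}); molar
    extinction coefficients (reduced 5500*nW + 1490*nY; oxidized adds
    125 per cystine pair, assuming maximal pairing); and the mean of the
    Vihinen window-9 flexibility profile. Sequences too short for a
    flexibility window get 0.0 there, with a logged warning.
    """
    bad = set(sequence) - _STANDARD_SET
    if bad:
        raise ValidationError(f"non-standard residue(s) {sorted(bad)}")
    analysis = ProteinAnalysis(sequence)
    helix, turn, sheet = analysis.secondary_structure_fraction()
    ext_reduced, ext_oxidized = analysis.molar_extinction_coefficient()
    flex_profile = analysis.flexibility()
    if flex_profile:
        flexibility = float(np.mean(flex_profile))
    else:
        logger.warning(
            "sequence shorter than the flexibility window; "
            "flexibility_mean set to 0.0"
        )
        flexibility = 0.0
    length = len(sequence)
    counts = Counter(sequence)
    features: dict[str, float] = {
        "molecular_weight": float(analysis.molecular_weight()),
        "aromaticity": float(analysis.aromaticity()),
        "instability_index": float(analysis.instability_index()),
        "isoelectric_point": float(analysis.isoelectric_point()),
        "gravy": float(analysis.gravy()),
        "helix_fraction": float(helix),
        "turn_fraction": float(turn),
        "sheet_fraction": float(sheet),
        "extinction_coefficient_reduced": float(ext_reduced),
        "extinction_coefficient_oxidized": float(ext_oxidized),
        "flexibility_mean": flexibility,
    }
    for aa in STANDARD_AMINO_ACIDS:
        features[f"freq_{aa}"] = counts.get(aa, 0) / length
    features["length"] = float(length)
    return features


def feature_names() -> tuple[str, ...]:
    """The fixed, ordered names of all 424 descriptors."""
    return (
        GLOBAL_FEATURE_NAMES
        + AA_FREQUENCY_NAMES
        + ("length",)
        + kmer_feature_names(2)
        + kmer_feature_names(3)
    )


@dataclass(frozen=True)
class FeatureVector:
    """An ordered 424-descriptor representation of one sequence."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        if len(self.names) != len(self.values):
            raise ValidationError("feature names and values differ in length")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def featurize(
    sequence: str | ProteinRecord, schema: GroupSchema | None = None
) -> FeatureVector:
    """Compute the full 424-descriptor vector for one sequence.

    Pure and deterministic: two calls on the same input give bit-identical
    vectors. Block order is global(11), residue frequencies(20), length(1),
    grouped dipeptides(49), grouped tripeptides(343).
    """
    if isinstance(sequence, ProteinRecord):
        sequence = sequence.sequence
    if schema is None:
        schema = GroupSchema.default()
    values = global_features(sequence)
    values.update(grouped_kmer_features(sequence, 2, schema))
    values.update(grouped_kmer_features(sequence, 3, schema))
    names = feature_names()
    return FeatureVector(
        names=names, values=np.array([values[n] for n in names], dtype=float)
    )


def featurize_records(
    records, schema: GroupSchema | None = None
):
    """Feature matrix for a collection of records.

    Returns a pandas DataFrame indexed by record id with the 424 named
    columns in canonical order.
    """
    import pandas as pd

    if schema is None:
        schema = GroupSchema.default()
    names = feature_names()
    rows = []
    ids = []
    for rec in records:
        try:
            rows.append(featurize(rec.sequence, schema).values)
        except ValidationError as exc:
            raise ValidationError(f"record '{rec.id}': {exc}") from exc
        ids.append(rec.id)
    data = np.vstack(rows) if rows else np.empty((0, len(names)))
    return pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=list(names))
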