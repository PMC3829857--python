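"""Core containers shared across the pipeline.

Expression data live in a genes × samples :class:`~pandas.DataFrame` of log2
intensities together with a sample-metadata table and a boolean
above-background flag matrix of the same shape.  Flags come from the upstream
platform's detection calls; the pipeline never recomputes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import numpy as np
import pandas as pd


class Condition(str, Enum):
    """Biopsy / sample condition labels used in paired and two-group designs."""

    PP = "PP"  # lesional (psoriasis plaque)
    PN = "PN"  # uninvolved skin from the same patient
    TREATED = "treated"
    CONTROL = "control"
    OTHER = "other"


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one microarray sample."""

    sample_id: str
    study_id: str
    patient_id: str
    condition: Condition

    def __post_init__(self) -> None:
        if not isinstance(self.condition, Condition):
            object.__setattr__(self, "condition", Condition(self.condition))


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass
class ExpressionMatrix:
    """Log2 expression values with sample metadata and detection flags.

    Parameters
    ----------
    values
        genes × samples DataFrame of log2 intensities. Row index = gene ids,
        column index = sample ids.
    samples
        Per-sample metadata indexed by sample id with columns
        ``study_id``, ``patient_id``, ``condition``.
    above_background
        Boolean DataFrame, same shape/labels as ``values``. Defaults to
        all-True when omitted.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    above_background: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {list(dups[:5])}")
        if self.values.columns.has_duplicates:
            raise FormatError("duplicate sample ids in expression matrix")
        missing = [s for s in self.values.columns if s not in self.samples.index]
        if missing:
            raise FormatError(f"samples without metadata: {missing}")
        self.samples = self.samples.loc[self.values.columns]
        if self.above_background is None:
            self.above_background = pd.DataFrame(
                True, index=self.values.index, columns=self.values.columns
            )
        if self.above_background.shape != self.values.shape:
            raise FormatError(
                "above_background shape "
                f"{self.above_background.shape} != values shape {self.values.shape}"
            )
        self.above_background = self.above_background.loc[
            self.values.index, self.values.columns
        ].astype(bool)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def paired_pp_pn(self) -> pd.DataFrame:
        """Return a patients table with one PP and one PN sample per patient.

        Raises ``FormatError`` if any PP sample lacks exactly one PN partner.
        """
        meta = self.samples
        pp = meta[meta["condition"] == Condition.PP.value]
        pn = meta[meta["condition"] == Condition.PN.value]
        rows = []
        for patient, grp in pp.groupby("patient_id"):
            if len(grp) != 1:
                raise FormatError(f"patient {patient!r} has {len(grp)} PP samples")
            partner = pn[pn["patient_id"] == patient]
            if len(partner) != 1:
                raise FormatError(
                    f"patient {patient!r} has {len(partner)} PN partners (need 1)"
                )
            rows.append(
                {
                    "patient_id": patient,
                    "study_id": grp["study_id"].iloc[0],
                    "pp_sample": grp.index[0],
                    "pn_sample": partner.index[0],
                }
            )
        return pd.DataFrame(rows).set_index("patient_id")

    def subset_genes(self, genes) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(
            values=self.values.loc[genes],
            samples=self.samples,
            above_background=self.above_background.loc[genes],
        )


@dataclass
class GeneSetCollection:
    """Named, ordered collection of gene sets (GMT carrier)."""

    name: str
    sets: dict[str, list[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, members in self.sets.items():
            if not members:
                raise FormatError(f"gene set {set_id!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"duplicate members in set {set_id!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())

    def __getitem__(self, set_id: str) -> list[str]:
        return self.sets[set_id]


# IUPAC degenerate DNA codes, letter -> set of concrete bases.
IUPAC_CODES: Mapping[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# base-set -> IUPAC letter
_SET_TO_IUPAC = {v: k for k, v in IUPAC_CODES.items()}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")

ALPHABET = "ACGT"


def iupac_complement(consensus: str) -> str:
    """Reverse-complement an IUPAC consensus string."""
    return consensus.translate(_COMPLEMENT)[::-1]


@dataclass
class MotifModel:
    """A DNA-binding motif: IUPAC consensus + 4×L position probability matrix.

    The PPM rows are ordered A, C, G, T.  The consensus may be supplied or
    derived from the PPM: per column, the IUPAC code covering every letter
    with probability ≥ 0.25.
    """

    motif_id: str
    ppm: np.ndarray
    consensus: str | None = None
    source: str = ""

    CONSENSUS_MIN_PROB = 0.25

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        if self.ppm.ndim != 2 or self.ppm.shape[0] != 4:
            raise FormatError(
                f"motif {self.motif_id!r}: PPM must be 4×L, got {self.ppm.shape}"
            )
        sums = self.ppm.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-3):
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise FormatError(
                f"motif {self.motif_id!r}: PPM column {bad} sums to {sums[bad]:.4f}"
            )
        if self.consensus is None:
            self.consensus = self.consensus_from_ppm(self.ppm)
        if len(self.consensus) != self.ppm.shape[1]:
            raise FormatError(
                f"motif {self.motif_id!r}: consensus length {len(self.consensus)} "
                f"!= PPM length {self.ppm.shape[1]}"
            )

    @property
    def length(self) -> int:
        return self.ppm.shape[1]

    @staticmethod
    def consensus_from_ppm(ppm: np.ndarray, min_prob: float = CONSENSUS_MIN_PROB) -> str:
        letters = []
        for col in np.asarray(ppm, float).T:
            bases = frozenset(
                ALPHABET[i] for i in range(4) if col[i] >= min_prob
            )
            if not bases:  # flat-ish column below threshold: treat as N
                bases = frozenset(ALPHABET)
            letters.append(_SET_TO_IUPAC[bases])
        return "".join(letters)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MotifModel):
            return NotImplemented
        return (
            self.motif_id == other.motif_id
            and self.consensus == other.consensus
            and self.ppm.shape == other.ppm.shape
            and np.allclose(self.ppm, other.ppm, atol=1e-9)
        )


@dataclass
class GeneModule:
    """A co-expression module: members, medoid profile, fold-change score.

    The label follows the ``GENE-N`` convention: the best-annotated member
    gene followed by the member count.
    """

    module_id: str
    members: list[str]
    label: str | None = None
    medoid_gene: str | None = None
    medoid: np.ndarray | None = None
    fc_score: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"module {self.module_id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"module {self.module_id!r} has duplicate members")
        if self.label is not None:
            suffix = self.label.rsplit("-", 1)[-1]
            if suffix.isdigit() and int(suffix) != len(self.members):
                raise ValueError(
                    f"label {self.label!r} count != member count {len(self.members)}"
                )

    @property
    def size(self) -> int:
        return len(self.members)
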