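"""Shared domain types and threshold configuration.

The vocabulary here mirrors how small-RNA annotation databases describe a
microRNA locus: a *hairpin* precursor folds into a stem-loop; the ~22-nt
*mature* products are excised from its 5' and 3' arms by Drosha and Dicer,
leaving the characteristic 2-nt 3' overhangs on the processing duplex; deep
sequencing *reads* stack on the arms and their pattern is the evidence for
(or against) genuine biogenesis.
"""

from __future__ import annotations

import dataclasses
import enum
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

_RNA_ALPHABET = frozenset("ACGU")


class Arm(enum.Enum):
    """Which part of the hairpin a sequence or read derives from."""

    FIVE_P = "5p"
    THREE_P = "3p"
    LOOP_SPANNING = "loop"
    UNASSIGNED = "unassigned"

    def opposite(self) -> "Arm":
        if self is Arm.FIVE_P:
            return Arm.THREE_P
        if self is Arm.THREE_P:
            return Arm.FIVE_P
        raise ValueError(f"{self} has no opposite arm")


class Provenance(enum.Enum):
    ANNOTATED = "annotated"
    INFERRED_STAR = "inferred_star"


class Verdict(enum.Enum):
    HIGH_CONFIDENCE = "HIGH_CONFIDENCE"
    INSUFFICIENT_EVIDENCE = "INSUFFICIENT_EVIDENCE"
    PATTERN_INCONSISTENT = "PATTERN_INCONSISTENT"
    # Read criteria pass but the fold does not. This is an extension beyond
    # the classical three-way call, kept separate so it is never conflated
    # with a read-pattern refutation.
    STRUCTURE_FAIL = "STRUCTURE_FAIL"
    # Applied only through an override file, never by the classifier itself.
    MANUAL = "MANUAL"


class MirhcError(Exception):
    """Base class for all package errors."""


class FormatError(MirhcError):
    """Malformed input file."""


class StructureError(MirhcError):
    """Invalid dot-bracket structure."""


class SpecError(MirhcError):
    """A synthetic locus specification that cannot be realized."""


def normalize_rna(seq: str, *, context: str = "sequence") -> str:
    """Uppercase and convert T to U; reject anything outside A/C/G/U."""
    norm = seq.upper().replace("T", "U")
    bad = set(norm) - _RNA_ALPHABET
    if bad:
        raise FormatError(
            f"illegal character(s) {sorted(bad)} in {context}: not an RNA/DNA base"
        )
    return norm


@dataclass(frozen=True)
class Thresholds:
    """The five criterion constants plus mapping parameters.

    Defaults are the published constants: at least 10 exactly-mapping reads
    per arm, a 0-4 nt 3' overhang on the mature duplex, at least 50% of an
    arm's reads sharing the modal 5' end, folding free energy strictly below
    -0.2 kcal/mol/nt, and at least 60% of mature bases paired. The energy
    criterion is a strict inequality; the others are inclusive.
    """

    min_reads_per_arm: int = 10
    overhang_min: int = 0
    overhang_max: int = 4
    min_modal5p_fraction: float = 0.50
    max_energy_per_nt: float = -0.2  # strict less-than
    min_mature_paired_fraction: float = 0.60
    read_len_min: int = 16
    read_len_max: int = 30
    mature_overlap_fraction: float = 0.5
    overhang_walk_limit: int = 5  # max unpaired nt bridged at a duplex end
    min_hairpin_len: int = 40

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "Thresholds":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown threshold key(s): {sorted(unknown)}")
        return cls(**data)


@dataclass(frozen=True)
class Hairpin:
    """A precursor stem-loop with optional secondary structure and MFE."""

    id: str
    sequence: str
    structure: Optional[str] = None
    mfe: Optional[float] = None  # kcal/mol
    species_prefix: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", normalize_rna(self.sequence, context=f"hairpin {self.id}"))
        if self.structure is not None:
            if len(self.structure) != len(self.sequence):
                raise StructureError(
                    f"hairpin {self.id}: structure length {len(self.structure)} "
                    f"!= sequence length {len(self.sequence)}"
                )
            depth = 0
            for ch in self.structure:
                if ch == "(":
                    depth += 1
                elif ch == ")":
                    depth -= 1
                    if depth < 0:
                        raise StructureError(f"hairpin {self.id}: unbalanced brackets")
                elif ch != ".":
                    raise StructureError(f"hairpin {self.id}: illegal structure character {ch!r}")
            if depth != 0:
                raise StructureError(f"hairpin {self.id}: unbalanced brackets")

    def validate_length(self, min_len: int = 40) -> None:
        if len(self.sequence) < min_len:
            raise FormatError(
                f"hairpin {self.id}: length {len(self.sequence)} below minimum {min_len}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatureLocus:
    """Coordinates of a mature product on its hairpin (0-based, half-open)."""

    id: str
    hairpin_id: str
    start: int
    end: int
    arm: Arm
    provenance: Provenance = Provenance.ANNOTATED

    def __post_init__(self):
        if not 0 <= self.start < self.end:
            raise ValueError(f"mature {self.id}: invalid interval [{self.start},{self.end})")
        if self.arm not in (Arm.FIVE_P, Arm.THREE_P):
            raise ValueError(f"mature {self.id}: arm must be 5p or 3p")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class AlignedRead:
    """A distinct read placed on a hairpin with zero mismatches."""

    sequence: str
    start: int
    count: int
    arm: Arm = Arm.UNASSIGNED
    multi_hit: bool = False

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("aligned read count must be >= 1")
        if self.start < 0:
            raise ValueError("aligned read start must be >= 0")

    @property
    def end(self) -> int:
        return self.start + len(self.sequence)


@dataclass
class ReadStack:
    """Per-arm collection of distinct aligned reads with summed counts."""

    hairpin_id: str
    reads: list  # list[AlignedRead]
    per_arm_total: dict = field(default_factory=dict)  # Arm -> int
    modal5p_fraction: dict = field(default_factory=dict)  # Arm -> float
    most_abundant: dict = field(default_factory=dict)  # Arm -> AlignedRead
    has_multi_hit: bool = False

    def total(self) -> int:
        return sum(r.count for r in self.reads)


@dataclass(frozen=True)
class DuplexGeometry:
    """3' overhangs at both ends of the mature:star duplex.

    Positive = 3' overhang (canonical Drosha/Dicer value is 2), zero = blunt,
    negative = recessed. ``None`` means no paired base was found near that
    duplex end within the walk limit.
    """

    overhang_5p_end: Optional[int]
    overhang_3p_end: Optional[int]
    derived_from: str = "ANNOTATED_PAIR"  # or MOST_ABUNDANT_READS

    @property
    def defined(self) -> bool:
        return self.overhang_5p_end is not None and self.overhang_3p_end is not None


@dataclass(frozen=True)
class CriteriaResult:
    """The five criterion booleans plus the raw metrics behind them."""

    c1_read_depth: bool
    c2_overhang: bool
    c3_five_prime_homogeneity: bool
    c4_energy: bool
    c5_mature_pairing: bool
    metrics: dict

    def all_pass(self) -> bool:
        return (
            self.c1_read_depth
            and self.c2_overhang
            and self.c3_five_prime_homogeneity
            and self.c4_energy
            and self.c5_mature_pairing
        )

    @classmethod
    def from_metrics(cls, metrics: dict, thresholds: Thresholds) -> "CriteriaResult":
        """Evaluate the five booleans as pure functions of the raw metrics.

        metrics keys used:
          reads_5p, reads_3p               summed exact-match counts per arm
          overhang_5p_end, overhang_3p_end duplex 3' overhangs (None if undefined)
          modal5p_fraction_5p/_3p          modal 5'-end fraction per arm (None if no reads)
          energy_per_nt                    MFE / hairpin length, kcal/mol/nt (None if no fold)
          mature_paired_fraction           paired fraction over mature base union
        """
        t = thresholds
        c1 = (
            metrics.get("reads_5p", 0) >= t.min_reads_per_arm
            and metrics.get("reads_3p", 0) >= t.min_reads_per_arm
        )
        o5, o3 = metrics.get("overhang_5p_end"), metrics.get("overhang_3p_end")
        c2 = (
            o5 is not None
            and o3 is not None
            and t.overhang_min <= o5 <= t.overhang_max
            and t.overhang_min <= o3 <= t.overhang_max
        )
        f5 = metrics.get("modal5p_fraction_5p")
        f3 = metrics.get("modal5p_fraction_3p")
        c3 = (
            f5 is not None
            and f3 is not None
            and f5 >= t.min_modal5p_fraction
            and f3 >= t.min_modal5p_fraction
        )
        e = metrics.get("energy_per_nt")
        c4 = e is not None and math.isfinite(e) and e < t.max_energy_per_nt
        pf = metrics.get("mature_paired_fraction")
        c5 = pf is not None and pf >= t.min_mature_paired_fraction
        return cls(c1, c2, c3, c4, c5, dict(metrics))


@dataclass
class ConfidenceCall:
    """Final verdict for one hairpin locus with per-criterion evidence."""

    hairpin_id: str
    verdict: Verdict
    criteria: CriteriaResult
    notes: list = field(default_factory=list)
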