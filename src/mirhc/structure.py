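"""Secondary-structure analysis of the hairpin precursor.

Parses dot-bracket strings into a pair table, locates the terminal loop
(hence the 5' and 3' arms), infers the star product from the canonical
Drosha/Dicer duplex geometry when only one mature is annotated, measures
the 3' overhangs of the mature duplex, the fraction of mature bases paired,
and the folding free energy per nucleotide. De novo folding is delegated to
ViennaRNA.
"""

from __future__ import annotations

import subprocess
from dataclasses import dataclass
from typing import Optional

from .core import (
    Arm,
    DuplexGeometry,
    Hairpin,
    MatureLocus,
    MirhcError,
    Provenance,
    StructureError,
)

UNPAIRED = -1


@dataclass(frozen=True)
class PairTable:
    """partner[i] = j if base i pairs with base j, else -1 (UNPAIRED)."""

    partner: tuple

    def __len__(self) -> int:
        return len(self.partner)

    def __getitem__(self, i: int) -> int:
        return self.partner[i]

    def paired(self, i: int) -> bool:
        return self.partner[i] != UNPAIRED


@dataclass(frozen=True)
class ArmPartition:
    """Terminal loop interval and the arm regions flanking it (0-based, half-open)."""

    loop_start: int
    loop_end: int
    length: int
    multiloop: bool = False

    @property
    def five_p_region(self):
        return (0, self.loop_start)

    @property
    def three_p_region(self):
        return (self.loop_end, self.length)


def pair_table(structure: str) -> PairTable:
    """Stack-match a dot-bracket string into a symmetric pair table."""
    partner = [UNPAIRED] * len(structure)
    stack = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise StructureError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            partner[j] = i
            partner[i] = j
        elif ch != ".":
            raise StructureError(f"illegal structure character {ch!r} at position {i}")
    if stack:
        raise StructureError(f"unmatched '(' at position {stack[-1]}")
    return PairTable(tuple(partner))


def _helix_run(pt: PairTable, i: int, j: int) -> int:
    """Length of the contiguous stacked-helix run closing hairpin loop (i, j)."""
    run = 1
    while i - 1 >= 0 and j + 1 < len(pt) and pt[i - 1] == j + 1:
        i, j = i - 1, j + 1
        run += 1
    return run


def find_loop(pt: PairTable) -> ArmPartition:
    """Locate the terminal loop and partition the hairpin into arms.

    A terminal (hairpin) loop is the unpaired interval enclosed by a pair
    with no pairs nested inside it. Simple stem-loops have exactly one; a
    multi-branched structure is flagged MULTILOOP and the branch closed by
    the longest stacked helix run is taken as the microRNA hairpin.
    """
    n = len(pt)
    terminal = []
    for i in range(n):
        j = pt[i]
        if j > i and all(not pt.paired(k) for k in range(i + 1, j)):
            terminal.append((i, j))
    if not terminal:
        raise StructureError("structure contains no base pair; cannot locate a loop")
    if len(terminal) == 1:
        i, j = terminal[0]
        return ArmPartition(loop_start=i + 1, loop_end=j, length=n, multiloop=False)
    # ties broken by 5'-most loop for determinism
    best = max(terminal, key=lambda ij: (_helix_run(pt, *ij), -ij[0]))
    return ArmPartition(loop_start=best[0] + 1, loop_end=best[1], length=n, multiloop=True)


def fold(sequence: str):
    """Predict the MFE structure of a sequence with ViennaRNA.

    Returns (dot-bracket structure, mfe in kcal/mol). Uses the Python
    bindings when importable, else shells out to RNAfold; either way the
    engine's default parameter set and temperature apply.
    """
    try:
        import RNA  # ViennaRNA bindings

        structure, mfe = RNA.fold(sequence)
        return structure, float(mfe)
    except ImportError:
        pass
    try:
        proc = subprocess.run(
            ["RNAfold", "--noPS"],
            input=f">q\n{sequence}\n",
            capture_output=True,
            text=True,
            check=True,
        )
    except (FileNotFoundError, subprocess.CalledProcessError) as exc:
        raise MirhcError(
            "no folding engine available (ViennaRNA bindings or RNAfold); "
            "supply precomputed dot-bracket structures instead"
        ) from exc
    lines = [ln for ln in proc.stdout.splitlines() if ln.strip()]
    struct_line = lines[-1]
    structure = struct_line.split()[0]
    mfe = float(struct_line[struct_line.rfind("(") + 1 : struct_line.rfind(")")])
    return structure, mfe


def folding_engine_id() -> str:
    """Identity and version of the folding engine, for the run log."""
    try:
        import RNA

        return f"ViennaRNA python bindings {RNA.__version__}"
    except ImportError:
        try:
            out = subprocess.run(["RNAfold", "--version"], capture_output=True, text=True)
            return out.stdout.strip() or "RNAfold (version unknown)"
        except FileNotFoundError:
            return "none"


def energy_per_nt(mfe: float, length: int) -> float:
    """Folding free energy normalized per nucleotide (kcal/mol/nt)."""
    if length <= 0:
        raise ValueError("length must be positive")
    return mfe / length


def _walk_3prime(pt: PairTable, pos: int, limit: int) -> Optional[int]:
    """Nearest paired base at/inside ``pos`` walking 3'-ward, within ``limit`` nt."""
    for step in range(limit + 1):
        p = pos + step
        if p >= len(pt):
            return None
        if pt.paired(p):
            return p
    return None


def _walk_5prime(pt: PairTable, pos: int, limit: int) -> Optional[int]:
    for step in range(limit + 1):
        p = pos - step
        if p < 0:
            return None
        if pt.paired(p):
            return p
    return None


def duplex_overhangs(
    m5: MatureLocus, m3: MatureLocus, pt: PairTable, walk_limit: int = 5
) -> DuplexGeometry:
    """3' overhangs at both ends of the 5p:3p product duplex.

    At the duplex end formed by the 5p product's 3' terminus: the overhang
    is how far that terminus extends past the partner of the 3p product's
    5'-most paired base (walking 3'-ward over unpaired ends, at most
    ``walk_limit`` nt). Symmetrically for the 3p product's 3' terminus.
    Positive = 3' overhang (canonically 2), 0 = blunt, negative = recessed;
    None when no paired base is reachable at that end.
    """
    if m5.arm is not Arm.FIVE_P or m3.arm is not Arm.THREE_P:
        raise ValueError("duplex_overhangs expects a (5p, 3p) mature pair")
    p = _walk_3prime(pt, m3.start, walk_limit)
    overhang_5p = (m5.end - 1) - pt[p] if p is not None else None
    q = _walk_3prime(pt, m5.start, walk_limit)
    overhang_3p = (m3.end - 1) - pt[q] if q is not None else None
    return DuplexGeometry(overhang_5p, overhang_3p)


def infer_star(mature: MatureLocus, pt: PairTable, hairpin: Hairpin) -> MatureLocus:
    """Construct the star product from the canonical processing geometry.

    Dicer and Drosha leave 2-nt 3' overhangs, so the star's 5' end is the
    partner of the base 2 nt inside the mature's 3' end, and its 3' end
    lies 2 nt past the partner of the mature's 5' end. Unpaired bases at
    the mature's ends are bridged by walking inward to the nearest paired
    base. Inference fails (StructureError) when no paired base exists
    within the mature.
    """
    inner_3p = _walk_5prime(pt, mature.end - 1 - 2, limit=len(pt))
    anchor_5p = _walk_3prime(pt, mature.start, limit=len(pt))
    if (
        inner_3p is None
        or anchor_5p is None
        or inner_3p < mature.start
        or anchor_5p >= mature.end
    ):
        raise StructureError(
            f"mature {mature.id}: no paired base inside the mature; star undefined"
        )
    star_start = pt[inner_3p]
    star_end = pt[anchor_5p] + 2 + 1  # 2 nt past the partner, half-open
    star_start = max(0, star_start)
    star_end = min(len(pt), star_end)
    if star_end - star_start < 2:
        raise StructureError(f"mature {mature.id}: inferred star collapses to nothing")
    return MatureLocus(
        id=f"{mature.id}*",
        hairpin_id=mature.hairpin_id,
        start=star_start,
        end=star_end,
        arm=mature.arm.opposite(),
        provenance=Provenance.INFERRED_STAR,
    )


def mature_paired_fraction(matures: list[MatureLocus], pt: PairTable) -> float:
    """Fraction of bases paired over the union of the mature intervals."""
    if not matures:
        raise ValueError("mature_paired_fraction requires at least one mature")
    positions = set()
    for m in matures:
        positions.update(range(m.start, min(m.end, len(pt))))
    if not positions:
        raise ValueError("mature intervals lie outside the structure")
    paired = sum(1 for i in positions if pt.paired(i))
    return paired / len(positions)
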