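"""Synthetic hairpin loci with exactly controlled read-stack properties.

Every criterion and verdict is testable without any sequencing download:
the generator builds a perfect-stem hairpin (3' arm is the reverse
complement of the 5' arm, joined by an unpairable poly-A loop), places the
mature products to realize requested duplex overhangs exactly, and emits
read stacks with chosen depth, modal 5'-end fraction and offset noise. The
ground-truth dot-bracket is constructed, not folded, so structure-dependent
behaviour is independent of any folding engine; the supplied MFE emulates
what a thermodynamic engine reports for such stems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .classify import LocusBundle
from .core import Arm, Hairpin, MatureLocus, Provenance, SpecError, Thresholds
from .mapping import build_stack, map_reads_exact
from .seqio import ReadRecord
from .structure import find_loop, pair_table

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

ARCHETYPES = ("SUPPORTED", "ONE_ARM_ONLY", "BAD_OVERHANG", "BAD_ENERGY")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class LocusSpec:
    """Parameters of one synthetic locus.

    Defaults describe a clean canonical microRNA: a 30-bp stem with an 8-nt
    loop, 22-nt matures cut with the canonical 2-nt 3' overhangs, 100 reads
    per arm of which 90% share the mature 5' end, the rest offset by up to
    2 nt, and a supplied folding energy of -0.35 kcal/mol/nt (a typical
    value for a well-paired precursor).
    """

    arm_len: int = 30
    loop_len: int = 8
    gc_fraction: float = 0.6
    mature_len: int = 22
    overhang_5p: int = 2
    overhang_3p: int = 2
    reads_5p: int = 100
    reads_3p: int = 100
    modal_fraction_5p: float = 0.9
    modal_fraction_3p: float = 0.9
    offset_noise: int = 2
    read_shift_3p: int = 0  # rigid shift of every 3p read (distorts the duplex)
    mfe_per_nt: float = -0.35
    mature5p_start: Optional[int] = None
    seed: int = 0

    def __post_init__(self):
        if self.loop_len < 3:
            raise SpecError("loop_len must be >= 3")
        if self.arm_len < 18:
            raise SpecError("arm_len must be >= 18")
        for f in (self.gc_fraction, self.modal_fraction_5p, self.modal_fraction_3p):
            if not 0.0 <= f <= 1.0:
                raise SpecError("fractions must lie in [0, 1]")


def _mature5p_start(spec: LocusSpec) -> int:
    if spec.mature5p_start is not None:
        return spec.mature5p_start
    # leave room for the 3p product's 3' extension, read offsets and shifts
    return max(2, spec.overhang_3p + spec.offset_noise + max(0, spec.read_shift_3p))


def make_hairpin(spec: LocusSpec):
    """Build a perfect-stem hairpin and its mature pair.

    Returns (Hairpin with ground-truth structure and supplied MFE,
    [5p MatureLocus, 3p MatureLocus]). Mature placement realizes the
    requested 3' overhangs exactly on the constructed structure.
    """
    rng = np.random.default_rng(spec.seed)
    n_gc = round(spec.gc_fraction * spec.arm_len)
    bases = ["G", "C"] * math.ceil(n_gc / 2) + ["A", "U"] * math.ceil((spec.arm_len - n_gc) / 2)
    arm5 = "".join(rng.permutation(np.array(list("".join(bases))[: spec.arm_len])))
    sequence = arm5 + "A" * spec.loop_len + revcomp(arm5)
    structure = "(" * spec.arm_len + "." * spec.loop_len + ")" * spec.arm_len
    L = len(sequence)

    a = _mature5p_start(spec)
    b = a + spec.mature_len
    m3_start = L - b + spec.overhang_5p
    m3_end = L - a + spec.overhang_3p
    if b > spec.arm_len:
        raise SpecError(
            f"5p mature [{a},{b}) does not fit on a {spec.arm_len}-nt arm"
        )
    if m3_start < spec.arm_len + spec.loop_len or m3_end > L or m3_start >= m3_end:
        raise SpecError(
            f"requested overhangs ({spec.overhang_5p},{spec.overhang_3p}) place the "
            f"3p product at [{m3_start},{m3_end}) outside the 3p arm"
        )
    hid = f"syn-mir-{spec.seed}"
    hairpin = Hairpin(
        id=hid,
        sequence=sequence,
        structure=structure,
        mfe=spec.mfe_per_nt * L,
    )
    matures = [
        MatureLocus(f"{hid}-5p", hid, a, b, Arm.FIVE_P, Provenance.ANNOTATED),
        MatureLocus(f"{hid}-3p", hid, m3_start, m3_end, Arm.THREE_P, Provenance.ANNOTATED),
    ]
    return hairpin, matures


def make_read_stack(spec: LocusSpec, hairpin: Hairpin, matures) -> list[ReadRecord]:
    """Emit collapsed reads per arm with controlled modal 5'-end fraction.

    ceil(modal_fraction x reads) reads start exactly at the mature 5' end;
    the remainder are offset uniformly over [-offset_noise, +offset_noise]
    excluding 0 (resampled if the offset read would leave the hairpin).
    All reads are exact substrings of the hairpin by construction.
    """
    rng = np.random.default_rng(spec.seed + 1)
    records: list[ReadRecord] = []
    plan = [
        (matures[0], spec.reads_5p, spec.modal_fraction_5p, 0, "5p"),
        (matures[1], spec.reads_3p, spec.modal_fraction_3p, spec.read_shift_3p, "3p"),
    ]
    L = len(hairpin)
    for mature, n_reads, modal_frac, shift, tag in plan:
        if n_reads <= 0:
            continue
        base = mature.start + shift
        rlen = len(mature)
        if base < 0 or base + rlen > L:
            raise SpecError(f"shifted {tag} reads fall outside the hairpin")
        n_modal = math.ceil(modal_frac * n_reads)
        starts = {base: n_modal}
        offsets = [
            o for o in range(-spec.offset_noise, spec.offset_noise + 1)
            if o != 0 and 0 <= base + o and base + o + rlen <= L
        ]
        n_rest = n_reads - n_modal
        if n_rest > 0 and not offsets:
            raise SpecError("offset_noise leaves no valid non-modal start")
        for o in rng.choice(offsets, size=n_rest) if n_rest else []:
            s = base + int(o)
            starts[s] = starts.get(s, 0) + 1
        for s in sorted(starts):
            records.append(
                ReadRecord(
                    id=f"{hairpin.id}_{tag}_s{s}_seed{spec.seed}",
                    sequence=hairpin.sequence[s : s + rlen],
                    count=starts[s],
                )
            )
    return records


def make_bundle(spec: LocusSpec, thresholds: Optional[Thresholds] = None) -> LocusBundle:
    """Generate hairpin, matures and aggregated read stack for one spec."""
    hairpin, matures = make_hairpin(spec)
    reads = make_read_stack(spec, hairpin, matures)
    pt = pair_table(hairpin.structure)
    partition = find_loop(pt)
    alignments = map_reads_exact(reads, hairpin, thresholds)
    stack = build_stack(alignments, matures, partition, hairpin.id, thresholds)
    return LocusBundle(
        hairpin=hairpin,
        matures=matures,
        stack=stack,
        partition=partition,
        structure_source="synthetic",
    )


def archetype_spec(archetype: str, seed: int = 0) -> LocusSpec:
    """The LocusSpec realizing one of the read-pattern archetypes."""
    base = LocusSpec(seed=seed, offset_noise=1)
    if archetype == "SUPPORTED":
        return base
    if archetype == "ONE_ARM_ONLY":
        return replace(base, reads_3p=0)
    if archetype == "BAD_OVERHANG":
        return replace(base, read_shift_3p=4, arm_len=32)
    if archetype == "BAD_ENERGY":
        return replace(base, mfe_per_nt=-0.1)
    raise ValueError(f"unknown archetype {archetype!r}; choose from {ARCHETYPES}")


def make_case(archetype: str, seed: int = 0, thresholds: Optional[Thresholds] = None) -> LocusBundle:
    """A full locus bundle realizing one of the read-pattern archetypes.

    SUPPORTED: deep homogeneous reads on both arms, canonical 2-nt
    overhangs -> HIGH_CONFIDENCE. ONE_ARM_ONLY: reads on the 5' arm only ->
    INSUFFICIENT_EVIDENCE. BAD_OVERHANG: deep reads on both arms but the 3p
    product shifted to a 6-nt overhang -> PATTERN_INCONSISTENT. BAD_ENERGY:
    supported read pattern on a weakly folding precursor -> STRUCTURE_FAIL.
    """
    return make_bundle(archetype_spec(archetype, seed), thresholds)


EXPECTED_VERDICT = {
    "SUPPORTED": "HIGH_CONFIDENCE",
    "ONE_ARM_ONLY": "INSUFFICIENT_EVIDENCE",
    "BAD_OVERHANG": "PATTERN_INCONSISTENT",
    "BAD_ENERGY": "STRUCTURE_FAIL",
}


def write_fixture_dir(outdir, n_per_archetype: int = 3, seed: int = 0) -> dict:
    """Emit a complete on-disk fixture: hairpin FASTA, mature linkage table,
    collapsed-read FASTA (suffix_xN dialect) split over two pseudo-datasets,
    dot-bracket structures with supplied energies, and the ground-truth
    verdict TSV. Returns the paths."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {
        "hairpins": os.path.join(outdir, "hairpins.fa"),
        "matures": os.path.join(outdir, "matures.fa"),
        "table": os.path.join(outdir, "mature_table.tsv"),
        "structures": os.path.join(outdir, "structures.db"),
        "reads": [os.path.join(outdir, f"reads_ds{i}.fa") for i in (1, 2)],
        "truth": os.path.join(outdir, "truth.tsv"),
    }
    hp_fh = open(paths["hairpins"], "w")
    mat_fh = open(paths["matures"], "w")
    tbl_fh = open(paths["table"], "w")
    db_fh = open(paths["structures"], "w")
    read_fhs = [open(p, "w") for p in paths["reads"]]
    truth_fh = open(paths["truth"], "w")
    truth_fh.write("locus_id\tarchetype\texpected_verdict\n")
    k = 0
    for archetype in ("SUPPORTED", "ONE_ARM_ONLY", "BAD_OVERHANG"):
        for _ in range(n_per_archetype):
            case_seed = seed * 1000 + k
            k += 1
            spec = archetype_spec(archetype, seed=case_seed)
            hp, matures = make_hairpin(spec)
            hp_fh.write(f">{hp.id} synthetic seed={case_seed}\n{hp.sequence}\n")
            db_fh.write(f">{hp.id}\n{hp.sequence}\n{hp.structure} ({hp.mfe:.2f})\n")
            for m in matures:
                mat_fh.write(f">{m.id} synthetic seed={case_seed}\n"
                             f"{hp.sequence[m.start:m.end]}\n")
                tbl_fh.write(f"{m.id}\t{hp.id}\t{m.start + 1}\t{m.end}\n")
            # split each distinct read's count across the two pseudo-datasets
            for rec in make_read_stack(spec, hp, matures):
                half = rec.count // 2
                if half:
                    read_fhs[0].write(f">{rec.id}_a_x{half}\n{rec.sequence}\n")
                if rec.count - half:
                    read_fhs[1].write(f">{rec.id}_b_x{rec.count - half}\n{rec.sequence}\n")
            truth_fh.write(f"{hp.id}\t{archetype}\t{EXPECTED_VERDICT[archetype]}\n")
    for fh in [hp_fh, mat_fh, tbl_fh, db_fh, truth_fh, *read_fhs]:
        fh.close()
    return paths
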