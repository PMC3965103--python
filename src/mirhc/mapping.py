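"""Exact mapping of reads onto hairpins and aggregation into read stacks.

Mapping is exact by definition: the read-depth criterion counts only reads
placed with zero mismatches, so alignment reduces to substring search over
the ~100-nt precursor. Only the sense strand is searched (small-RNA
protocols are stranded). Counts from multiple datasets are aggregated by
summation per distinct (sequence, start) placement.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Iterable, Optional

from .core import AlignedRead, Arm, Hairpin, MatureLocus, ReadStack, Thresholds
from .seqio import ReadRecord
from .structure import ArmPartition

logger = logging.getLogger(__name__)


def map_reads_exact(
    reads: Iterable[ReadRecord],
    hairpin: Hairpin,
    thresholds: Optional[Thresholds] = None,
    length_filter: bool = True,
) -> list[AlignedRead]:
    """Place every read at every exact-match offset on the hairpin.

    A read occurring at k sites on the hairpin yields k alignments, each
    carrying the full count and flagged multi_hit. Reads outside the
    [read_len_min, read_len_max] window are skipped (tallied in the log);
    reads with no exact match are dropped silently (non-mapping is normal).
    """
    t = thresholds or Thresholds()
    seq = hairpin.sequence
    alignments: list[AlignedRead] = []
    n_len_filtered = 0
    for read in reads:
        if length_filter and not (t.read_len_min <= len(read.sequence) <= t.read_len_max):
            n_len_filtered += 1
            continue
        starts = []
        pos = seq.find(read.sequence)
        while pos >= 0:
            starts.append(pos)
            pos = seq.find(read.sequence, pos + 1)
        multi = len(starts) > 1
        for s in starts:
            alignments.append(
                AlignedRead(sequence=read.sequence, start=s, count=read.count, multi_hit=multi)
            )
    if n_len_filtered:
        logger.info(
            "%s: %d read(s) outside length window [%d, %d] skipped",
            hairpin.id, n_len_filtered, t.read_len_min, t.read_len_max,
        )
    return alignments


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def assign_arm(
    aln: AlignedRead,
    matures: list[MatureLocus],
    partition: ArmPartition,
    thresholds: Optional[Thresholds] = None,
) -> Arm:
    """Assign an alignment to an arm by overlap with the mature loci.

    A read counts toward a mature (hence its arm) when it overlaps the
    mature interval by at least ``mature_overlap_fraction`` of the read
    length; this tolerates 3' trimming and tailing while excluding loop
    fragments. Reads covering the entire terminal loop are LOOP_SPANNING;
    anything else is UNASSIGNED.
    """
    if partition is None:
        raise ValueError("assign_arm requires an arm partition (run find_loop first)")
    t = thresholds or Thresholds()
    need = t.mature_overlap_fraction * len(aln.sequence)
    best_arm, best_ov = None, 0
    for m in matures:
        ov = _overlap(aln.start, aln.end, m.start, m.end)
        if ov >= need and (ov > best_ov or (ov == best_ov and best_arm is None)):
            best_arm, best_ov = m.arm, ov
    if best_arm is not None:
        return best_arm
    if aln.start <= partition.loop_start and aln.end >= partition.loop_end:
        return Arm.LOOP_SPANNING
    return Arm.UNASSIGNED


def build_stack(
    alignments: list[AlignedRead],
    matures: list[MatureLocus],
    partition: ArmPartition,
    hairpin_id: str = "",
    thresholds: Optional[Thresholds] = None,
) -> ReadStack:
    """Merge alignments into a per-arm read stack with summary statistics.

    Identical (sequence, start) placements are merged with summed counts.
    Per arm: the total count, the fraction of reads sharing the modal 5'
    start (the start position with the greatest summed count; ties broken
    by smaller start), and the most abundant distinct read (ties by smaller
    start, then lexicographically smaller sequence).
    """
    merged: dict = {}
    for aln in alignments:
        key = (aln.sequence, aln.start)
        if key in merged:
            prev = merged[key]
            merged[key] = AlignedRead(
                sequence=aln.sequence,
                start=aln.start,
                count=prev.count + aln.count,
                multi_hit=prev.multi_hit or aln.multi_hit,
            )
        else:
            merged[key] = aln
    reads = []
    for aln in sorted(merged.values(), key=lambda a: (a.start, a.sequence)):
        arm = assign_arm(aln, matures, partition, thresholds)
        reads.append(
            AlignedRead(
                sequence=aln.sequence,
                start=aln.start,
                count=aln.count,
                arm=arm,
                multi_hit=aln.multi_hit,
            )
        )
    per_arm_total: dict = defaultdict(int)
    start_counts: dict = defaultdict(lambda: defaultdict(int))
    for r in reads:
        per_arm_total[r.arm] += r.count
        start_counts[r.arm][r.start] += r.count
    modal5p_fraction = {}
    most_abundant = {}
    for arm, total in per_arm_total.items():
        if total <= 0:
            continue
        modal_start = min(
            start_counts[arm], key=lambda s: (-start_counts[arm][s], s)
        )
        modal5p_fraction[arm] = start_counts[arm][modal_start] / total
        most_abundant[arm] = min(
            (r for r in reads if r.arm == arm),
            key=lambda r: (-r.count, r.start, r.sequence),
        )
    return ReadStack(
        hairpin_id=hairpin_id,
        reads=reads,
        per_arm_total=dict(per_arm_total),
        modal5p_fraction=modal5p_fraction,
        most_abundant=most_abundant,
        has_multi_hit=any(r.multi_hit for r in reads),
    )


def aggregate_datasets(
    stacks: list[ReadStack],
    matures: list[MatureLocus],
    partition: ArmPartition,
    thresholds: Optional[Thresholds] = None,
) -> ReadStack:
    """Sum per-(sequence, start) counts across datasets and recompute stats.

    Order-invariant and conservative: the aggregated total equals the sum
    of the input totals.
    """
    if not stacks:
        raise ValueError("aggregate_datasets requires at least one stack")
    hid = stacks[0].hairpin_id
    for s in stacks[1:]:
        if s.hairpin_id != hid:
            raise ValueError(
                f"cannot aggregate stacks for different hairpins ({hid!r} vs {s.hairpin_id!r})"
            )
    all_alignments = [r for s in stacks for r in s.reads]
    return build_stack(all_alignments, matures, partition, hairpin_id=hid, thresholds=thresholds)
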