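"""Exact read mapping, arm assignment and stack aggregation."""

import random
from collections import defaultdict

import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from mirhc.core import AlignedRead, Arm, Hairpin, MatureLocus, Thresholds
from mirhc.mapping import aggregate_datasets, assign_arm, build_stack, map_reads_exact
from mirhc.seqio import ReadRecord
from mirhc.simulate import LocusSpec, make_bundle, make_hairpin, make_read_stack
from mirhc.structure import find_loop, pair_table


def _hp(seq):
    return Hairpin("h", seq)


def test_exact_mapping_single_and_multi_hit():
    aln = map_reads_exact([ReadRecord("r", "ACGU" * 5, 3)], _hp("AA" + "ACGU" * 5 + "UU" * 20))
    assert [(a.start, a.count, a.multi_hit) for a in aln] == [(2, 3, False)]
    # multi-hit: each site carries the full count, flagged
    aln = map_reads_exact(
        [ReadRecord("r", "AA", 5)], _hp("AAA" + "CG" * 20), length_filter=False
    )
    assert [(a.start, a.count, a.multi_hit) for a in aln] == [(0, 5, True), (1, 5, True)]


def test_length_filter_skips_out_of_window_reads():
    rng = random.Random(0)
    hp = _hp("".join(rng.choice("ACGU") for _ in range(80)))
    short = ReadRecord("s", hp.sequence[:4], 1)
    ok = ReadRecord("o", hp.sequence[10:30], 1)
    aln = map_reads_exact([short, ok], hp)
    assert [(a.sequence, a.start) for a in aln] == [(ok.sequence, 10)]


def test_exact_mapping_equals_brute_force_scan():
    """Alignments equal a naive O(n*m) scan over every offset."""
    rng = random.Random(123)
    hairpin = _hp("".join(rng.choice("ACGU") for _ in range(80)))
    reads = []
    for i in range(500):
        if rng.random() < 0.5:  # half are genuine substrings
            s = rng.randint(0, 60)
            ln = rng.randint(16, 20)
            reads.append(ReadRecord(f"r{i}", hairpin.sequence[s : s + ln], rng.randint(1, 9)))
        else:
            reads.append(ReadRecord(f"r{i}", "".join(rng.choice("ACGU") for _ in range(20)), 1))
    got = {(a.sequence, a.start, a.count) for a in map_reads_exact(reads, hairpin)}
    expected = set()
    for r in reads:
        for off in range(len(hairpin.sequence) - len(r.sequence) + 1):
            if hairpin.sequence[off : off + len(r.sequence)] == r.sequence:
                expected.add((r.sequence, off, r.count))
    assert got == expected


def _partitioned_locus(seed=1):
    hp, matures = make_hairpin(LocusSpec(seed=seed))
    partition = find_loop(pair_table(hp.structure))
    return hp, matures, partition


def test_assign_arm_mature_overlap_and_loop():
    hp, matures, part = _partitioned_locus()
    m5, m3 = matures
    exact = AlignedRead(hp.sequence[m5.start : m5.end], m5.start, 1)
    assert assign_arm(exact, matures, part) is Arm.FIVE_P
    exact3 = AlignedRead(hp.sequence[m3.start : m3.end], m3.start, 1)
    assert assign_arm(exact3, matures, part) is Arm.THREE_P
    loop_read = AlignedRead(
        hp.sequence[part.loop_start - 2 : part.loop_end + 2], part.loop_start - 2, 1
    )
    assert assign_arm(loop_read, matures, part) is Arm.LOOP_SPANNING


def test_assign_arm_matches_interval_arithmetic_oracle():
    hp, matures, part = _partitioned_locus(seed=2)
    t = Thresholds()
    rng = random.Random(9)
    for _ in range(300):
        ln = rng.randint(16, 26)
        start = rng.randint(0, len(hp.sequence) - ln)
        aln = AlignedRead(hp.sequence[start : start + ln], start, 1)
        # independent interval-overlap reimplementation
        expected = Arm.UNASSIGNED
        best = 0
        for m in matures:
            ov = max(0, min(start + ln, m.end) - max(start, m.start))
            if ov >= t.mature_overlap_fraction * ln and ov > best:
                expected, best = m.arm, ov
        if expected is Arm.UNASSIGNED and start <= part.loop_start and start + ln >= part.loop_end:
            expected = Arm.LOOP_SPANNING
        assert assign_arm(aln, matures, part, t) is expected


def test_build_stack_merges_and_computes_modal_fraction():
    hp, matures, part = _partitioned_locus()
    m5 = matures[0]
    seq = hp.sequence[m5.start : m5.end]
    seq_off = hp.sequence[m5.start + 1 : m5.end + 1]
    alns = [
        AlignedRead(seq, m5.start, 3),
        AlignedRead(seq, m5.start, 7),  # same (sequence, start): merged to 10
        AlignedRead(seq_off, m5.start + 1, 40),
    ]
    stack = build_stack(alns, matures, part, hp.id)
    merged = [r for r in stack.reads if r.start == m5.start]
    assert len(merged) == 1 and merged[0].count == 10
    # starts {m5.start: 10, m5.start+1: 40} -> modal fraction 0.8 at +1
    assert stack.per_arm_total[Arm.FIVE_P] == 50
    assert stack.modal5p_fraction[Arm.FIVE_P] == pytest.approx(0.8)
    assert stack.most_abundant[Arm.FIVE_P].start == m5.start + 1


def test_modal_fraction_equals_brute_force_over_random_stacks():
    hp, matures, part = _partitioned_locus(seed=4)
    m5 = matures[0]
    rng = random.Random(17)
    for trial in range(50):
        alns = []
        for _ in range(rng.randint(1, 30)):
            off = rng.randint(-2, 2)
            s = m5.start + off
            ln = len(m5)
            alns.append(AlignedRead(hp.sequence[s : s + ln], s, rng.randint(1, 20)))
        stack = build_stack(alns, matures, part, hp.id)
        per_start = defaultdict(int)
        total = 0
        for r in stack.reads:
            if r.arm is Arm.FIVE_P:
                per_start[r.start] += r.count
                total += r.count
        if total:
            assert stack.modal5p_fraction[Arm.FIVE_P] == pytest.approx(max(per_start.values()) / total)


def test_aggregate_identity_and_disjoint_union():
    bundle = make_bundle(LocusSpec(seed=3))
    hp, matures, part = bundle.hairpin, bundle.matures, bundle.partition
    one = aggregate_datasets([bundle.stack], matures, part)
    assert one.per_arm_total == bundle.stack.per_arm_total
    assert one.modal5p_fraction == bundle.stack.modal5p_fraction
    m5, m3 = matures
    s1 = build_stack([AlignedRead(hp.sequence[m5.start : m5.end], m5.start, 5)], matures, part, hp.id)
    s2 = build_stack([AlignedRead(hp.sequence[m3.start : m3.end], m3.start, 8)], matures, part, hp.id)
    agg = aggregate_datasets([s1, s2], matures, part)
    assert agg.per_arm_total == {Arm.FIVE_P: 5, Arm.THREE_P: 8}


def test_aggregate_rejects_mixed_hairpins():
    b1 = make_bundle(LocusSpec(seed=1))
    b2 = make_bundle(LocusSpec(seed=2))
    with pytest.raises(ValueError, match="different hairpins"):
        aggregate_datasets([b1.stack, b2.stack], b1.matures, b1.partition)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    counts=hst.lists(hst.lists(hst.integers(1, 50), min_size=1, max_size=8), min_size=1, max_size=5),
    perm_seed=hst.integers(0, 10**6),
)
def test_aggregation_conserves_counts_and_is_order_invariant(counts, perm_seed):
    """Totals equal the sum of inputs; dataset order never matters; the
    aggregate equals mapping all reads in one pass."""
    hp, matures, part = _partitioned_locus(seed=6)
    m5 = matures[0]
    rng = random.Random(perm_seed)
    stacks, all_alns = [], []
    for ds in counts:
        alns = []
        for c in ds:
            off = rng.randint(-2, 2)
            s = m5.start + off
            alns.append(AlignedRead(hp.sequence[s : s + len(m5)], s, c))
        stacks.append(build_stack(alns, matures, part, hp.id))
        all_alns.extend(alns)
    agg = aggregate_datasets(stacks, matures, part)
    assert agg.total() == sum(sum(ds) for ds in counts)
    shuffled = stacks[:]
    rng.shuffle(shuffled)
    agg2 = aggregate_datasets(shuffled, matures, part)
    assert agg2.per_arm_total == agg.per_arm_total
    assert agg2.modal5p_fraction == agg.modal5p_fraction
    direct = build_stack(all_alns, matures, part, hp.id)
    assert direct.per_arm_total == agg.per_arm_total
    assert [(r.sequence, r.start, r.count) for r in direct.reads] == [
        (r.sequence, r.start, r.count) for r in agg.reads
    ]


def test_adding_modal_reads_never_decreases_modal_fraction():
    hp, matures, part = _partitioned_locus(seed=8)
    m5 = matures[0]
    rng = random.Random(99)
    for _ in range(100):
        alns = [
            AlignedRead(
                hp.sequence[m5.start + off : m5.start + off + len(m5)],
                m5.start + off,
                rng.randint(1, 10),
            )
            for off in (rng.randint(-2, 2) for _ in range(rng.randint(1, 10)))
        ]
        stack = build_stack(alns, matures, part, hp.id)
        if Arm.FIVE_P not in stack.modal5p_fraction:
            continue
        before = stack.modal5p_fraction[Arm.FIVE_P]
        modal = max(
            {r.start for r in stack.reads if r.arm is Arm.FIVE_P},
            key=lambda s: sum(r.count for r in stack.reads if r.arm is Arm.FIVE_P and r.start == s),
        )
        boosted = alns + [
            AlignedRead(hp.sequence[modal : modal + len(m5)], modal, rng.randint(1, 20))
        ]
        after = build_stack(boosted, matures, part, hp.id).modal5p_fraction[Arm.FIVE_P]
        assert after >= before - 1e-12
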