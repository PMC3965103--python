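"""On-disk formats: FASTA/FASTQ reads, collapsed-count headers, hairpin and
mature FASTA, RNAfold-style dot-bracket files, and TSV/GFF3 reports.

FASTA and FASTQ parsing is delegated to Biopython; the dialect handling
(collapsed read counts, mature-to-hairpin linkage, dot-bracket energy
suffixes) is layered on top. Gzip compression is auto-detected by magic
bytes; header dialects are never auto-detected.
"""

from __future__ import annotations

import csv
import gzip
import re
from dataclasses import dataclass
from typing import Iterator, Optional

from Bio import SeqIO

from .core import (
    Arm,
    ConfidenceCall,
    CriteriaResult,
    FormatError,
    Hairpin,
    MatureLocus,
    Provenance,
    StructureError,
    Verdict,
    normalize_rna,
)

COLLAPSED_DIALECTS = ("suffix_xN", "count_field", "none")

# Fixed report schema; order matters for round-tripping.
REPORT_COLUMNS = [
    "locus_id",
    "verdict",
    "c1_read_depth",
    "c2_overhang",
    "c3_five_prime_homogeneity",
    "c4_energy",
    "c5_mature_pairing",
    "reads_5p",
    "reads_3p",
    "modal5p_fraction_5p",
    "modal5p_fraction_3p",
    "overhang_5p_end",
    "overhang_3p_end",
    "mfe",
    "energy_per_nt",
    "mature_paired_fraction",
    "structure_source",
    "multi_hit",
    "notes",
]


@dataclass(frozen=True)
class ReadRecord:
    """A read before mapping: id, sequence and collapsed count."""

    id: str
    sequence: str
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError(f"read {self.id}: count must be >= 1")
        if not self.sequence:
            raise ValueError(f"read {self.id}: empty sequence")


def _open_maybe_gzip(path, mode="rt"):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path, alphabet_policy: str = "strict"):
    """Parse FASTA into (id, description, sequence) triples in file order.

    Sequences are normalized (T->U, uppercase). ``alphabet_policy`` is
    'strict' (non-ACGU/T characters raise FormatError) or 'skip' (records
    with illegal characters are dropped).
    """
    out = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            raw = str(rec.seq)
            if not raw:
                raise FormatError(f"{path}: record {rec.id!r} has an empty sequence")
            try:
                seq = normalize_rna(raw, context=f"record {rec.id!r} in {path}")
            except FormatError:
                if alphabet_policy == "skip":
                    continue
                raise
            desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
            out.append((rec.id, desc, seq))
    return out


def parse_collapsed_header(header: str, dialect: str = "none"):
    """Extract (id, count) from a collapsed small-RNA FASTA header.

    Dialects: ``suffix_xN`` ("seq42_x117" -> count 117), ``count_field``
    ("seq42-117" -> count 117), ``none`` (count 1).
    """
    if dialect not in COLLAPSED_DIALECTS:
        raise ValueError(f"unknown collapsed-header dialect {dialect!r}")
    token = header.split()[0] if header.split() else header
    if dialect == "none":
        return token, 1
    if dialect == "suffix_xN":
        m = re.match(r"^(.*)_x(\S+)$", token)
        if not m:
            raise FormatError(f"header {token!r}: no _xN count suffix")
        ident, num = m.group(1), m.group(2)
    else:  # count_field
        ident, sep, num = token.rpartition("-")
        if not sep:
            raise FormatError(f"header {token!r}: no -N count field")
    if not num.isdigit() or int(num) < 1:
        raise FormatError(f"header {token!r}: count {num!r} is not a positive integer")
    return ident, int(num)


def read_reads(path, fmt: str = "fasta", dialect: str = "none") -> list[ReadRecord]:
    """Read a small-RNA read set (FASTA, collapsed FASTA, or FASTQ).

    FASTQ qualities are discarded: the confidence criteria use only read
    sequences, positions and counts.
    """
    records = []
    with _open_maybe_gzip(path) as fh:
        for rec in SeqIO.parse(fh, "fastq" if fmt == "fastq" else "fasta"):
            ident, count = parse_collapsed_header(rec.id, dialect)
            seq = normalize_rna(str(rec.seq), context=f"read {rec.id!r} in {path}")
            records.append(ReadRecord(ident, seq, count))
    return records


def read_dotbracket(path):
    """Parse RNAfold-style 3-line records: >id / sequence / structure (MFE).

    The energy suffix "( -12.30)" is optional; when absent the MFE is None.
    Returns (id, sequence, structure, mfe) tuples.
    """
    out = []
    with _open_maybe_gzip(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise FormatError(f"{path}:{i + 1}: expected FASTA-style header, got {lines[i]!r}")
        ident = lines[i][1:].split()[0]
        if i + 2 >= len(lines):
            raise FormatError(f"{path}:{i + 1}: truncated record {ident!r}")
        seq = normalize_rna(lines[i + 1].strip(), context=f"{ident} in {path}")
        struct_line = lines[i + 2].strip()
        m = re.match(r"^([.()]+)(?:\s*\(\s*(-?\d+(?:\.\d+)?)\s*\))?\s*$", struct_line)
        if not m:
            raise FormatError(f"{path}:{i + 3}: malformed structure line {struct_line!r}")
        structure, mfe_str = m.group(1), m.group(2)
        mfe = float(mfe_str) if mfe_str is not None else None
        if len(structure) != len(seq):
            raise StructureError(
                f"{path}: {ident}: structure length {len(structure)} != sequence length {len(seq)}"
            )
        depth = 0
        for ch in structure:
            depth += 1 if ch == "(" else (-1 if ch == ")" else 0)
            if depth < 0:
                raise StructureError(f"{path}: {ident}: unbalanced brackets")
        if depth != 0:
            raise StructureError(f"{path}: {ident}: unbalanced brackets")
        out.append((ident, seq, structure, mfe))
        i += 3
    return out


def read_hairpins(path, min_len: int = 40) -> list[Hairpin]:
    """Read hairpin precursors from miRBase-dialect FASTA.

    The species prefix is taken from the id when it looks like a miRBase
    name (e.g. "dme-mir-100" -> "dme"); descriptions are kept verbatim.
    """
    hairpins = []
    for ident, desc, seq in read_fasta(path):
        prefix = ident.split("-", 1)[0] if "-" in ident else None
        hp = Hairpin(id=ident, sequence=seq, species_prefix=prefix)
        hp.validate_length(min_len)
        hairpins.append(hp)
    return hairpins


def link_matures(
    mature_seqs,
    hairpins: list[Hairpin],
    table: Optional[dict] = None,
) -> dict[str, list[MatureLocus]]:
    """Place mature sequences on their parent hairpins.

    ``mature_seqs`` is (id, description, sequence) triples. Linkage is via
    ``table`` (mature_id -> hairpin_id, optionally with coordinates) when
    given, else by exact substring match of the mature in each hairpin; an
    ambiguous match (several hairpins, or several sites in one hairpin)
    without explicit coordinates is an error.

    Arm labels are provisional here (midpoint vs hairpin midpoint); the
    structure-derived partition refines them downstream.
    """
    by_id = {h.id: h for h in hairpins}
    loci: dict[str, list[MatureLocus]] = {h.id: [] for h in hairpins}
    for mid, _desc, mseq in mature_seqs:
        if table is not None and mid in table:
            entry = table[mid]
            hid = entry["hairpin_id"]
            if hid not in by_id:
                raise FormatError(f"mature {mid}: unknown hairpin {hid!r}")
            hp = by_id[hid]
            if "start" in entry and entry["start"] is not None:
                start, end = int(entry["start"]), int(entry["end"])
            else:
                start = hp.sequence.find(mseq)
                if start < 0:
                    raise FormatError(f"mature {mid}: sequence not found in hairpin {hid}")
                if hp.sequence.find(mseq, start + 1) >= 0:
                    raise FormatError(
                        f"mature {mid}: multiple sites in hairpin {hid}; supply coordinates"
                    )
                end = start + len(mseq)
        else:
            hits = []
            for hp in hairpins:
                pos = hp.sequence.find(mseq)
                while pos >= 0:
                    hits.append((hp.id, pos))
                    pos = hp.sequence.find(mseq, pos + 1)
            if not hits:
                raise FormatError(f"mature {mid}: sequence not found in any hairpin")
            if len(hits) > 1:
                raise FormatError(
                    f"mature {mid}: ambiguous placement ({len(hits)} sites); "
                    "supply a linkage table with coordinates"
                )
            hid, start = hits[0]
            end = start + len(mseq)
        hp = by_id[hid]
        mid_point = (start + end) / 2
        arm = Arm.FIVE_P if mid_point < len(hp) / 2 else Arm.THREE_P
        loci[hid].append(
            MatureLocus(id=mid, hairpin_id=hid, start=start, end=end, arm=arm,
                        provenance=Provenance.ANNOTATED)
        )
    return loci


def read_mature_table(path) -> dict:
    """Read a mature->hairpin linkage TSV: mature_id, hairpin_id[, start, end].

    Coordinates, when present, are 1-based inclusive on disk and converted
    to 0-based half-open.
    """
    table = {}
    with _open_maybe_gzip(path) as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), 1):
            if not row or row[0].startswith("#"):
                continue
            if len(row) < 2:
                raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
            entry = {"hairpin_id": row[1], "start": None, "end": None}
            if len(row) >= 4 and row[2] and row[3]:
                entry["start"] = int(row[2]) - 1
                entry["end"] = int(row[3])
            table[row[0]] = entry
    return table


def _fmt(value):
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        return f"{value:.6f}"
    return str(value)


def write_report(calls: list[ConfidenceCall], path, format: str = "tsv") -> None:
    """Write the per-locus classification report (TSV or GFF3).

    TSV carries the verdict, the five criterion booleans and every raw
    metric; GFF3 rows are one hairpin locus each with 1-based inclusive
    coordinates and a ``high_confidence`` attribute.
    """
    if format not in ("tsv", "gff3"):
        raise ValueError(f"unknown report format {format!r}")
    with open(path, "w", newline="") as fh:
        if format == "tsv":
            fh.write("\t".join(REPORT_COLUMNS) + "\n")
            for call in calls:
                m = call.criteria.metrics
                row = [
                    call.hairpin_id,
                    call.verdict.value,
                    _fmt(call.criteria.c1_read_depth),
                    _fmt(call.criteria.c2_overhang),
                    _fmt(call.criteria.c3_five_prime_homogeneity),
                    _fmt(call.criteria.c4_energy),
                    _fmt(call.criteria.c5_mature_pairing),
                    _fmt(m.get("reads_5p", 0)),
                    _fmt(m.get("reads_3p", 0)),
                    _fmt(m.get("modal5p_fraction_5p")),
                    _fmt(m.get("modal5p_fraction_3p")),
                    _fmt(m.get("overhang_5p_end")),
                    _fmt(m.get("overhang_3p_end")),
                    _fmt(m.get("mfe")),
                    _fmt(m.get("energy_per_nt")),
                    _fmt(m.get("mature_paired_fraction")),
                    _fmt(m.get("structure_source", "given")),
                    _fmt(m.get("multi_hit", False)),
                    ";".join(call.notes) if call.notes else "",
                ]
                fh.write("\t".join(row) + "\n")
        else:
            fh.write("##gff-version 3\n")
            for call in calls:
                m = call.criteria.metrics
                length = m.get("length", 0)
                hc = call.verdict in (Verdict.HIGH_CONFIDENCE,) or (
                    call.verdict is Verdict.MANUAL and m.get("manual_high_confidence", False)
                )
                attrs = (
                    f"ID={call.hairpin_id};verdict={call.verdict.value};"
                    f"high_confidence={'true' if hc else 'false'}"
                )
                fh.write(
                    "\t".join(
                        [
                            call.hairpin_id,
                            "mirhc",
                            "miRNA_primary_transcript",
                            "1",
                            str(length if length else 1),
                            ".",
                            "+",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )


def _parse_opt(text, cast):
    return None if text == "NA" else cast(text)


def read_report(path) -> list[ConfidenceCall]:
    """Parse a TSV report back into ConfidenceCalls (round-trip of write_report)."""
    calls = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames != REPORT_COLUMNS:
            raise FormatError(f"{path}: unexpected report columns {reader.fieldnames}")
        for row in reader:
            metrics = {
                "reads_5p": int(row["reads_5p"]),
                "reads_3p": int(row["reads_3p"]),
                "modal5p_fraction_5p": _parse_opt(row["modal5p_fraction_5p"], float),
                "modal5p_fraction_3p": _parse_opt(row["modal5p_fraction_3p"], float),
                "overhang_5p_end": _parse_opt(row["overhang_5p_end"], int),
                "overhang_3p_end": _parse_opt(row["overhang_3p_end"], int),
                "mfe": _parse_opt(row["mfe"], float),
                "energy_per_nt": _parse_opt(row["energy_per_nt"], float),
                "mature_paired_fraction": _parse_opt(row["mature_paired_fraction"], float),
                "structure_source": row["structure_source"],
                "multi_hit": row["multi_hit"] == "true",
            }
            criteria = CriteriaResult(
                c1_read_depth=row["c1_read_depth"] == "true",
                c2_overhang=row["c2_overhang"] == "true",
                c3_five_prime_homogeneity=row["c3_five_prime_homogeneity"] == "true",
                c4_energy=row["c4_energy"] == "true",
                c5_mature_pairing=row["c5_mature_pairing"] == "true",
                metrics=metrics,
            )
            notes = row["notes"].split(";") if row["notes"] else []
            calls.append(
                ConfidenceCall(
                    hairpin_id=row["locus_id"],
                    verdict=Verdict(row["verdict"]),
                    criteria=criteria,
                    notes=notes,
                )
            )
    return calls
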