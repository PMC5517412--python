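"""Read demultiplexing and tag collapsing ("fastqcoll") with grooming.

A *tag* is a unique, fixed-length sequence obtained by collapsing the
identical trimmed reads of one sample, carrying its read count.
Staggered (variable-length) inline barcodes are removed by exact-prefix
matching, and all trimmed reads are truncated to a common length
``read_length - max(barcode length)`` so tags are Hamming-comparable
without alignment.  *Grooming* merges likely-erroneous singleton tags
into nearby high-count template tags.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .simulate import BarcodeManifest

__all__ = ["Tag", "TagTable", "demultiplex", "collapse", "groom",
           "write_tag_tables", "read_tag_tables"]


@dataclass
class Tag:
    sequence: str
    count: int
    sample_id: str


@dataclass
class TagTable:
    """Per-sample collapsed tag counts plus read accounting.

    ``tables[sample_id]`` maps tag sequence -> count.  ``reads_in`` is
    the number of FASTQ reads seen, ``reads_kept`` the number assigned to
    a sample and passing the quality filter; ``unassigned`` and
    ``low_quality`` account for the rest.
    """

    tables: dict[str, dict[str, int]]
    tag_length: int
    reads_in: int = 0
    reads_kept: int = 0
    unassigned: int = 0
    low_quality: int = 0
    groomed_singletons: int = 0

    def total_count(self, sample_id: str | None = None) -> int:
        if sample_id is not None:
            return sum(self.tables[sample_id].values())
        return sum(sum(t.values()) for t in self.tables.values())

    def n_tags(self, sample_id: str | None = None) -> int:
        if sample_id is not None:
            return len(self.tables[sample_id])
        return sum(len(t) for t in self.tables.values())


def demultiplex(
    fastq: str | Path,
    manifest: BarcodeManifest,
    barcode_max_mismatch: int = 0,
    min_mean_quality: float = 20.0,
    read_length: int | None = None,
) -> tuple[dict[str, list[str]], dict[str, int]]:
    """Assign reads to samples by their inline barcode and trim them.

    The default ``barcode_max_mismatch=0`` is the stringent criterion:
    a read is assigned iff its prefix equals a manifest barcode exactly
    (barcodes are prefix-free, so the match is unique).  With a positive
    mismatch budget, a read is assigned to the unique sample whose
    barcode is closest within the budget; ties stay unassigned.  Reads
    whose mean Phred quality falls below ``min_mean_quality`` are
    discarded.  Trimmed reads are truncated to the common tag length.

    Returns ``(per_sample_reads, accounting)`` where accounting has keys
    ``reads_in``, ``assigned``, ``unassigned``, ``low_quality``,
    ``tag_length``.
    """
    by_length: dict[int, dict[str, str]] = {}
    for sid, bc in manifest.barcodes.items():
        by_length.setdefault(len(bc), {})[bc] = sid
    lengths = sorted(by_length)
    max_len = lengths[-1]

    per_sample: dict[str, list[str]] = {sid: [] for sid in manifest.barcodes}
    reads_in = assigned = unassigned = low_quality = 0
    tag_length = None
    for _title, seq, qual in FastqGeneralIterator(str(fastq)):
        reads_in += 1
        if tag_length is None:
            if read_length is None:
                read_length = len(seq)
            tag_length = read_length - max_len
        q = np.frombuffer(qual.encode(), dtype=np.uint8)
        if float(q.mean()) - 33.0 < min_mean_quality:
            low_quality += 1
            continue
        sid = None
        for length in lengths:
            sid = by_length[length].get(seq[:length])
            if sid is not None:
                bc_len = length
                break
        if sid is None and barcode_max_mismatch > 0:
            best: list[tuple[int, int, str]] = []
            for length in lengths:
                prefix = seq[:length]
                for bc, s in by_length[length].items():
                    d = sum(a != b for a, b in zip(prefix, bc))
                    if d <= barcode_max_mismatch:
                        best.append((d, length, s))
            if best:
                best.sort()
                if len(best) == 1 or best[0][0] < best[1][0]:
                    _, bc_len, sid = best[0]
        if sid is None:
            unassigned += 1
            continue
        assigned += 1
        per_sample[sid].append(seq[bc_len:bc_len + tag_length])
    accounting = {
        "reads_in": reads_in, "assigned": assigned,
        "unassigned": unassigned, "low_quality": low_quality,
        "tag_length": tag_length if tag_length is not None else 0,
    }
    return per_sample, accounting


def collapse(per_sample: dict[str, list[str]],
             accounting: dict[str, int] | None = None) -> TagTable:
    """Collapse identical trimmed reads into counted tags, per sample."""
    tables = {sid: dict(sorted(Counter(reads).items()))
              for sid, reads in per_sample.items()}
    lengths = {len(s) for t in tables.values() for s in t}
    if len(lengths) > 1:
        raise ValueError("reads must share a common trimmed length")
    acc = accounting or {}
    return TagTable(
        tables=tables,
        tag_length=next(iter(lengths), acc.get("tag_length", 0)),
        reads_in=acc.get("reads_in", 0),
        reads_kept=acc.get("assigned", 0),
        unassigned=acc.get("unassigned", 0),
        low_quality=acc.get("low_quality", 0),
    )


def _encode(seqs: list[str]) -> np.ndarray:
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1)


def groom(table: TagTable, max_edit: int = 1,
          min_template_count: int = 2) -> TagTable:
    """Merge singleton tags into nearby high-count template tags.

    Each count-1 tag within Hamming distance ``max_edit`` of a template
    (a tag whose *pre-grooming* count is >= ``min_template_count``) is
    absorbed into the best template: highest count first, ties broken by
    lexicographically smallest sequence.  Singletons are processed in
    lexicographic order against the fixed pre-grooming template set, so
    no correction can cascade.  The operation conserves total count mass
    and is idempotent.
    """
    new_tables: dict[str, dict[str, int]] = {}
    groomed = 0
    for sid, tags in table.tables.items():
        templates = {s: c for s, c in tags.items() if c >= min_template_count}
        singles = sorted(s for s, c in tags.items() if c == 1)
        merged = dict(tags)
        if templates and singles:
            tseqs = sorted(templates)
            T = _encode(tseqs)
            S = _encode(singles)
            # blockwise Hamming distances singleton x template
            for s_i, s in enumerate(singles):
                d = (T != S[s_i][None, :]).sum(axis=1)
                ok = np.nonzero(d <= max_edit)[0]
                if ok.size == 0:
                    continue
                best = min(ok, key=lambda j: (-templates[tseqs[j]], tseqs[j]))
                merged[tseqs[best]] += 1
                del merged[s]
                groomed += 1
        new_tables[sid] = dict(sorted(merged.items()))
    out = TagTable(
        tables=new_tables, tag_length=table.tag_length,
        reads_in=table.reads_in, reads_kept=table.reads_kept,
        unassigned=table.unassigned, low_quality=table.low_quality,
        groomed_singletons=table.groomed_singletons + groomed,
    )
    return out


def write_tag_tables(table: TagTable, out_dir: str | Path) -> None:
    """One TSV per sample (sequence, count) — the "fastqcoll" analog."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for sid, tags in table.tables.items():
        with open(out_dir / f"{sid}.tags.tsv", "w") as fh:
            fh.write("sequence\tcount\n")
            for seq, count in sorted(tags.items()):
                fh.write(f"{seq}\t{count}\n")


def read_tag_tables(in_dir: str | Path) -> TagTable:
    in_dir = Path(in_dir)
    tables: dict[str, dict[str, int]] = {}
    length = 0
    for path in sorted(in_dir.glob("*.tags.tsv")):
        sid = path.name.removesuffix(".tags.tsv")
        tags: dict[str, int] = {}
        with open(path) as fh:
            next(fh)
            for line in fh:
                seq, count = line.split()
                tags[seq] = int(count)
                length = len(seq)
        tables[sid] = tags
    return TagTable(tables=tables, tag_length=length)
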