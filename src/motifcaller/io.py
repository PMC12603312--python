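"""File formats: FASTA/FASTQ, the raw-signal container, and the TSV tables.

Raw-signal reads live in a gzipped JSON-lines container (one header record
with schema version, then one record per read holding float32 samples and
metadata) — human-inspectable and dependency-free.  Sequence data use
standard FASTA/FASTQ (Phred+33) through Biopython.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .design import InformationBlock, MotifLibrary, OligoDesign
from .search import SearchResult
from .simulate import BasecalledRead, SignalRead

__all__ = [
    "write_fasta", "read_fasta", "write_fastq", "read_fastq",
    "write_library", "read_library", "write_blocks", "read_blocks",
    "write_signal_reads", "read_signal_reads",
    "write_truth_tsv", "read_truth_tsv",
    "write_calls_tsv", "read_calls_tsv",
    "write_labels_tsv", "read_labels_tsv",
]

SIGNAL_SCHEMA_VERSION = 1


# -- FASTA / FASTQ ---------------------------------------------------------

def write_fasta(path: str | Path, records: dict[str, str]) -> None:
    SeqIO.write(
        (SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()),
        str(path), "fasta",
    )


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}


def write_fastq(path: str | Path, reads: Iterable[BasecalledRead]) -> None:
    def _records():
        for r in reads:
            rec = SeqRecord(Seq(r.seq), id=r.read_id, description=f"block={r.block_id} orientation={r.orientation}")
            rec.letter_annotations["phred_quality"] = [int(q) for q in r.quals]
            yield rec

    SeqIO.write(_records(), str(path), "fastq")


def read_fastq(path: str | Path) -> list[BasecalledRead]:
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        meta = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        out.append(
            BasecalledRead(
                read_id=rec.id,
                seq=str(rec.seq),
                quals=np.array(rec.letter_annotations["phred_quality"], dtype=np.int64),
                orientation=meta.get("orientation", "unknown"),
                block_id=meta.get("block", ""),
            )
        )
    return out


# -- motif libraries and blocks -------------------------------------------

def write_library(path: str | Path, library: MotifLibrary) -> None:
    """FASTA with motif ids verbatim, spacers as spacer_pos<i>, addresses addr_<id>."""
    records = dict(library.motifs)
    records.update({f"spacer_pos{i}": s for i, s in library.spacers.items()})
    records.update({f"addr_{a}": s for a, s in library.address_motifs.items()})
    write_fasta(path, records)


def read_library(path: str | Path, min_hamming: int = 0) -> MotifLibrary:
    motifs, spacers, address = {}, {}, {}
    for rid, seq in read_fasta(path).items():
        if rid.startswith("spacer_pos"):
            spacers[int(rid[len("spacer_pos"):])] = seq
        elif rid.startswith("addr_"):
            address[rid[len("addr_"):]] = seq
        else:
            motifs[rid] = seq
    return MotifLibrary(motifs=motifs, spacers=spacers, address_motifs=address, min_hamming=min_hamming)


def write_blocks(path: str | Path, blocks: list[InformationBlock]) -> None:
    with open(path, "w") as fh:
        fh.write("block_id\taddress_id\tslot_index\tmotif_ids\n")
        for b in blocks:
            for s, ids in enumerate(b.payload_sets):
                fh.write(f"{b.block_id}\t{b.address_id}\t{s}\t{','.join(sorted(ids))}\n")


def read_blocks(path: str | Path) -> list[InformationBlock]:
    rows: dict[str, dict] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("block_id"):
            raise ValueError(f"{path}: missing blocks header")
        for line in fh:
            bid, aid, s, ids = line.rstrip("\n").split("\t")
            entry = rows.setdefault(bid, {"address_id": aid, "slots": {}})
            entry["slots"][int(s)] = frozenset(ids.split(","))
    return [
        InformationBlock(
            block_id=bid,
            address_id=e["address_id"],
            payload_sets=[e["slots"][i] for i in sorted(e["slots"])],
        )
        for bid, e in sorted(rows.items())
    ]


# -- raw-signal container --------------------------------------------------

def write_signal_reads(path: str | Path, reads: Iterable[SignalRead]) -> None:
    with gzip.open(path, "wt") as fh:
        fh.write(json.dumps({"schema_version": SIGNAL_SCHEMA_VERSION}) + "\n")
        for r in reads:
            fh.write(
                json.dumps(
                    {
                        "read_id": r.read_id,
                        "block_id": r.block_id,
                        "orientation": r.orientation,
                        "samples": np.asarray(r.samples, dtype=np.float32).tolist(),
                        "truth": list(r.truth),
                    }
                )
                + "\n"
            )


def read_signal_reads(path: str | Path) -> Iterator[SignalRead]:
    """Stream reads one record at a time; raises on schema mismatch."""
    with gzip.open(path, "rt") as fh:
        header = json.loads(fh.readline())
        version = header.get("schema_version")
        if version != SIGNAL_SCHEMA_VERSION:
            raise ValueError(f"unsupported signal store schema {version!r}")
        for lineno, line in enumerate(fh, start=2):
            try:
                rec = json.loads(line)
                yield SignalRead(
                    read_id=rec["read_id"],
                    samples=np.array(rec["samples"], dtype=np.float32),
                    orientation=rec["orientation"],
                    block_id=rec["block_id"],
                    truth=list(rec["truth"]),
                )
            except (json.JSONDecodeError, KeyError) as exc:
                raise ValueError(f"{path}: bad signal record at line {lineno}: {exc}") from exc


# -- TSV tables ------------------------------------------------------------

def write_truth_tsv(path: str | Path, reads: Iterable[SignalRead], design: OligoDesign) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tblock_id\torientation\tslot_index\tmotif_id\n")
        for r in reads:
            for s, m in enumerate(r.truth):
                fh.write(f"{r.read_id}\t{r.block_id}\t{r.orientation}\t{s}\t{m}\n")


def read_truth_tsv(path: str | Path) -> dict[str, list[str]]:
    out: dict[str, dict[int, str]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, _bid, _ori, s, m = line.rstrip("\n").split("\t")
            out.setdefault(rid, {})[int(s)] = m
    return {rid: [slots[i] for i in sorted(slots)] for rid, slots in out.items()}


def write_calls_tsv(path: str | Path, results: Iterable[SearchResult]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tmethod\tstrand\tslot_index\tmotif_id\tscore\n")
        for r in results:
            for s, (call, score) in enumerate(zip(r.slot_calls, r.slot_scores)):
                call_s = call if call is not None else "."
                score_s = f"{score:.3f}" if score is not None else "."
                fh.write(f"{r.read_id}\t{r.method}\t{r.strand}\t{s}\t{call_s}\t{score_s}\n")


def read_calls_tsv(path: str | Path) -> dict[str, list[str | None]]:
    out: dict[str, dict[int, str | None]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, _m, _st, s, call, _sc = line.rstrip("\n").split("\t")
            out.setdefault(rid, {})[int(s)] = None if call == "." else call
    return {rid: [slots[i] for i in sorted(slots)] for rid, slots in out.items()}


def write_labels_tsv(path: str | Path, labels: list[tuple[SignalRead, list[str]]]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttokens\n")
        for read, tokens in labels:
            fh.write(f"{read.read_id}\t{','.join(tokens)}\n")


def read_labels_tsv(path: str | Path) -> dict[str, list[str]]:
    out = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            rid, toks = line.rstrip("\n").split("\t")
            out[rid] = toks.split(",") if toks else []
    return out
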