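"""Read preprocessing: barcode demultiplexing, primer filtering, primer trimming.

Mirrors the standard single-end amplicon intake: reads (read 1 only; the
~150 bp forward read) are demultiplexed by exact match of a fixed-length
barcode (9 nt by default, no mismatches allowed), then any read whose
observed primer region differs at one or more positions from the expected
gene-specific primer is discarded, and surviving reads have barcode and
primer removed.  Primer comparison is IUPAC-aware, so degenerate positions
in e.g. 515F/799R never count as mismatches.  Quality strings pass through
untouched; quality filtering belongs to the downstream ASV pipeline.

The barcode sits on a PCR primer, and instruments deliver it either as a
separate index read (then it appears in the FASTQ header) or as the first
cycles of read 1.  Both dialects are supported through ``barcode_location``
("header" or "inline"); neither is guessed.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "IUPAC_SETS",
    "BarcodeTable",
    "PrimerSet",
    "DemuxReport",
    "FastqParseError",
    "iupac_match",
    "parse_fastq",
    "write_fastq",
    "demultiplex",
    "resolve_shared_barcode",
]

IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"), "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("GC"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: (read id, sequence, quality string)
FastqRecord = tuple[str, str, str]


class FastqParseError(ValueError):
    pass


def iupac_match(primer: str, observed: str) -> bool:
    """True iff *observed* matches *primer* at every position (IUPAC-aware).

    The primer may contain degeneracy codes; the observed read bases are
    taken literally (an observed ``N`` matches only a primer ``N``).
    Length mismatch is a mismatch.
    """
    if len(primer) != len(observed):
        return False
    for p, o in zip(primer.upper(), observed.upper()):
        allowed = IUPAC_SETS.get(p)
        if allowed is None:
            raise ValueError(f"invalid IUPAC code {p!r} in primer")
        if o not in allowed:
            return False
    return True


@dataclass(frozen=True)
class BarcodeTable:
    """Fixed-length barcode sequence -> sample id (default length 9 nt)."""

    barcodes: Mapping[str, str]

    def __post_init__(self) -> None:
        lengths = {len(b) for b in self.barcodes}
        if len(lengths) > 1:
            raise ValueError(f"barcodes differ in length: {sorted(lengths)}")
        for b in self.barcodes:
            if set(b.upper()) - set("ACGT"):
                raise ValueError(f"barcode {b!r} contains non-ACGT characters")
        object.__setattr__(self, "barcodes", dict(self.barcodes))

    @property
    def length(self) -> int:
        return len(next(iter(self.barcodes))) if self.barcodes else 0

    def sample_for(self, barcode: str) -> str | None:
        return self.barcodes.get(barcode)


@dataclass(frozen=True)
class PrimerSet:
    """Gene-specific primer pair with the amplicon class it amplifies."""

    name: str
    forward: str
    reverse: str
    amplicon_class: str

    def __post_init__(self) -> None:
        for seq in (self.forward, self.reverse):
            if not seq:
                raise ValueError(f"primer set {self.name!r} has an empty primer")
            bad = set(seq.upper()) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"primer set {self.name!r}: invalid bases {sorted(bad)}")


@dataclass
class DemuxReport:
    """Bookkeeping for a demultiplexing run; every read lands somewhere."""

    assigned: dict[str, int] = field(default_factory=dict)
    discarded: dict[str, int] = field(default_factory=dict)
    total: int = 0

    def check(self) -> None:
        balance = sum(self.assigned.values()) + sum(self.discarded.values())
        if balance != self.total:
            raise AssertionError(
                f"partition violated: {balance} accounted vs {self.total} input reads"
            )


def parse_fastq(source) -> Iterator[FastqRecord]:
    """Yield (id, seq, qual) from a path, handle, or iterable of records."""
    if isinstance(source, (str, Path)):
        path = Path(source)
        opener = gzip.open if path.suffix == ".gz" else open
        with opener(path, "rt") as fh:
            yield from _iter_handle(fh)
    elif hasattr(source, "read"):
        yield from _iter_handle(source)
    else:  # already an iterable of records
        yield from source


def _iter_handle(fh) -> Iterator[FastqRecord]:
    it = FastqGeneralIterator(fh)
    index = 0
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise FastqParseError(f"malformed FASTQ near record {index}: {exc}") from exc
        yield rec
        index += 1


def write_fastq(records: Iterable[FastqRecord], path: str | Path) -> None:
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def _header_barcode(read_id: str, length: int) -> str:
    # Illumina convention: the index sequence is the final colon-separated
    # field of the header, e.g. "...:1:N:0:ACGTACGTA".
    token = read_id.rsplit(":", 1)[-1].split("+")[0]
    return token[:length]


def demultiplex(
    reads,
    barcodes: BarcodeTable,
    primers: Iterable[PrimerSet],
    barcode_location: str = "header",
) -> tuple[dict[str, list[FastqRecord]], DemuxReport]:
    """Assign reads to samples by exact barcode, filter and trim primers.

    Parameters
    ----------
    reads
        FASTQ path, open handle, or iterable of (id, seq, qual) records.
    barcodes
        Exact-match barcode table; one mismatch anywhere means the read is
        discarded as ``unknown_barcode``.
    primers
        Candidate primer sets.  A surviving read must match one forward
        primer IUPAC-exactly at its 5' end; otherwise it is discarded as
        ``primer_mismatch``.  Matching reads are returned with barcode
        (if inline) and primer removed.
    barcode_location
        ``"header"`` (index read recorded in the FASTQ header) or
        ``"inline"`` (first cycles of read 1).

    Returns
    -------
    (per-sample record lists, DemuxReport) with the partition identity
    ``sum(assigned) + sum(discarded) == total`` enforced.
    """
    if barcode_location not in {"header", "inline"}:
        raise ValueError("barcode_location must be 'header' or 'inline'")
    primers = list(primers)
    blen = barcodes.length
    if blen == 0:
        raise ValueError("empty barcode table")
    out: dict[str, list[FastqRecord]] = {s: [] for s in barcodes.barcodes.values()}
    report = DemuxReport(
        assigned={s: 0 for s in out},
        discarded={"unknown_barcode": 0, "primer_mismatch": 0},
    )
    for rid, seq, qual in parse_fastq(reads):
        report.total += 1
        if barcode_location == "inline":
            bc, body, bqual = seq[:blen], seq[blen:], qual[blen:]
        else:
            bc, body, bqual = _header_barcode(rid, blen), seq, qual
        sample = barcodes.sample_for(bc)
        if sample is None:
            report.discarded["unknown_barcode"] += 1
            continue
        trimmed = None
        for ps in primers:
            plen = len(ps.forward)
            if len(body) >= plen and iupac_match(ps.forward, body[:plen]):
                trimmed = (rid, body[plen:], bqual[plen:])
                break
        if trimmed is None:
            report.discarded["primer_mismatch"] += 1
            continue
        out[sample].append(trimmed)
        report.assigned[sample] += 1
    report.check()
    return out, report


def resolve_shared_barcode(
    reads,
    primer_a: PrimerSet,
    primer_b: PrimerSet,
) -> tuple[list[FastqRecord], list[FastqRecord], dict[str, int]]:
    """Split one barcode-sharing pool into two samples by primer identity.

    Two samples may deliberately share a barcode when they were amplified
    with distinct primer pairs; their reads are separated afterwards by
    matching the expected forward primer at the read start.  Reads matching
    neither primer are discarded (``neither``); reads matching both are
    ambiguous and discarded separately (``ambiguous``).  Matched reads keep
    their primers (trimming is demultiplex's job when given both sets).
    """
    a_reads: list[FastqRecord] = []
    b_reads: list[FastqRecord] = []
    dropped = {"neither": 0, "ambiguous": 0}
    for rec in parse_fastq(reads):
        _, seq, _ = rec
        hit_a = len(seq) >= len(primer_a.forward) and iupac_match(
            primer_a.forward, seq[: len(primer_a.forward)])
        hit_b = len(seq) >= len(primer_b.forward) and iupac_match(
            primer_b.forward, seq[: len(primer_b.forward)])
        if hit_a and hit_b:
            dropped["ambiguous"] += 1
        elif hit_a:
            a_reads.append(rec)
        elif hit_b:
            b_reads.append(rec)
        else:
            dropped["neither"] += 1
    return a_reads, b_reads, dropped
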