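"""QC-gated methylation-index calling from bisulfite read sets.

One sample is sequenced as up to four overlapping Sanger reactions (forward
and reverse primer, each in duplicate).  In place of chromatogram peak
heights, per-read base calls are piled up at every CpG and control position;
the evidence at a site is summarized by the cytosine fraction
``c_fraction = C / (C + T)``.

Calling proceeds in two gates:

1. **Conversion QC** — every one of the non-CpG control cytosines must read
   as converted (``c_fraction`` below the detection threshold, with adequate
   coverage) before any index is reported.  A sample with a single
   unconverted control yields no index.
2. **Index** — a CpG site is called methylated when its ``c_fraction``
   reaches the detection threshold (default 0.10, the approximate
   sensitivity of Sanger sequencing; ties at the threshold call methylated).
   The methylation index is the count of methylated sites, 0–17 on the
   default template, and is additionally reported in binary / tertile /
   quintile codings.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .amplicon import SiteMap, reverse_complement

__all__ = [
    "Read",
    "ReadSet",
    "SiteEvidence",
    "CallerConfig",
    "MethylationCall",
    "QCError",
    "pile_up",
    "qc_controls",
    "call_index",
    "call_sample",
    "categorize",
    "write_reads",
    "read_reads",
    "write_calls",
]

BINARY_LABELS = ("unmethylated", "methylated")
TERTILE_LABELS = ("unmethylated", "1-6", "7-12", "13-17")
QUINTILE_LABELS = ("unmethylated", "1-3", "4-6", "7-9", "10-13", "14-17")


class QCError(RuntimeError):
    """Raised when an index is requested for a QC-failed sample."""


@dataclass(frozen=True)
class Read:
    read_id: str
    orientation: str  # "forward" | "reverse"
    replicate: int  # 1 | 2
    sequence: str  # template-length; reverse reads stored reverse-complemented

    def __post_init__(self) -> None:
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    def oriented(self) -> str:
        """Sequence normalized to template (top-strand) orientation."""
        if self.orientation == "reverse":
            return reverse_complement(self.sequence)
        return self.sequence


@dataclass(frozen=True)
class ReadSet:
    sample_id: str
    reads: tuple[Read, ...]

    def __post_init__(self) -> None:
        if not 1 <= len(self.reads) <= 4:
            raise ValueError("a read set holds 1-4 reads")


@dataclass(frozen=True)
class SiteEvidence:
    """Base-call census at one template position across covering reads."""

    position: int
    kind: str  # "cpg" | "control"
    counts: dict[str, int]  # over A/C/G/T/N

    @property
    def coverage(self) -> int:
        """Informative coverage: reads calling C or T at this position."""
        return self.counts.get("C", 0) + self.counts.get("T", 0)

    @property
    def c_fraction(self) -> Optional[float]:
        cov = self.coverage
        if cov == 0:
            return None
        return self.counts.get("C", 0) / cov


@dataclass(frozen=True)
class CallerConfig:
    detection_threshold: float = 0.10
    min_site_coverage: int = 2

    def __post_init__(self) -> None:
        if not 0.0 < self.detection_threshold < 1.0:
            raise ValueError("detection_threshold must lie in (0, 1)")
        if self.min_site_coverage < 1:
            raise ValueError("min_site_coverage must be >= 1")


@dataclass(frozen=True)
class MethylationCall:
    sample_id: str
    qc_pass: bool
    failed_controls: tuple[int, ...] = ()
    low_coverage_cpgs: tuple[int, ...] = ()
    per_cpg_methylated: tuple[bool, ...] = ()
    index: Optional[int] = None
    binary: Optional[str] = None
    tertile: Optional[str] = None
    quintile: Optional[str] = None

    @property
    def site_string(self) -> str:
        """Compact per-site rendering: M methylated, U unmethylated, . no call."""
        if not self.qc_pass:
            return "." * max(len(self.per_cpg_methylated), 1)
        return "".join("M" if m else "U" for m in self.per_cpg_methylated)


def pile_up(readset: ReadSet, site_map: SiteMap) -> list[SiteEvidence]:
    """Tally base calls at every CpG and control position.

    Reads are normalized to template orientation first; 'N' calls are kept in
    the census but never contribute to ``c_fraction``.
    """
    seqs = [r.oriented() for r in readset.reads]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"reads have inconsistent lengths {sorted(lengths)}")
    (length,) = lengths
    positions = [(p, "cpg") for p in site_map.cpg_positions] + [
        (p, "control") for p in site_map.control_positions
    ]
    evidence = []
    for pos, kind in sorted(positions):
        if pos >= length:
            raise ValueError(f"site position {pos} beyond read length {length}")
        counts = Counter(s[pos] for s in seqs)
        evidence.append(SiteEvidence(pos, kind, dict(counts)))
    return evidence


def qc_controls(
    evidence: Iterable[SiteEvidence],
    site_map: SiteMap,
    config: CallerConfig = CallerConfig(),
) -> tuple[bool, tuple[int, ...]]:
    """Conversion-control gate.

    Passes iff every control position has informative coverage of at least
    ``min_site_coverage`` and a defined ``c_fraction`` strictly below the
    detection threshold.  Failure is a value, not an error.
    """
    by_pos = {e.position: e for e in evidence}
    missing = [p for p in site_map.control_positions if p not in by_pos]
    if missing:
        raise ValueError(f"evidence missing control positions {missing}")
    failed = []
    for pos in site_map.control_positions:
        e = by_pos[pos]
        frac = e.c_fraction
        if frac is None or e.coverage < config.min_site_coverage:
            failed.append(pos)
        elif frac >= config.detection_threshold:
            failed.append(pos)
    return (not failed, tuple(failed))


def call_index(
    evidence: Iterable[SiteEvidence],
    site_map: SiteMap,
    config: CallerConfig = CallerConfig(),
    sample_id: str = "sample",
) -> MethylationCall:
    """Score the methylation index of a conversion-QC-passing sample.

    Raises :class:`QCError` if the control gate fails — callers that want a
    failure value should use :func:`call_sample`.  A CpG site with
    informative coverage below ``min_site_coverage`` also fails the sample
    (read dropout leaves the index undefined).
    """
    evidence = list(evidence)
    qc_pass, failed = qc_controls(evidence, site_map, config)
    if not qc_pass:
        raise QCError(f"sample {sample_id!r} failed conversion QC at {failed}")
    by_pos = {e.position: e for e in evidence}
    missing = [p for p in site_map.cpg_positions if p not in by_pos]
    if missing:
        raise ValueError(f"evidence missing CpG positions {missing}")
    low_cov = tuple(
        p
        for p in site_map.cpg_positions
        if by_pos[p].coverage < config.min_site_coverage
    )
    if low_cov:
        return MethylationCall(
            sample_id=sample_id, qc_pass=False, low_coverage_cpgs=low_cov
        )
    calls = tuple(
        by_pos[p].c_fraction >= config.detection_threshold
        for p in site_map.cpg_positions
    )
    index = int(sum(calls))
    binary, tertile, quintile = categorize(index)
    return MethylationCall(
        sample_id=sample_id,
        qc_pass=True,
        per_cpg_methylated=calls,
        index=index,
        binary=binary,
        tertile=tertile,
        quintile=quintile,
    )


def call_sample(
    readset: ReadSet,
    site_map: SiteMap,
    config: CallerConfig = CallerConfig(),
) -> MethylationCall:
    """Full pile-up → QC → index chain; QC failure returns an index-less call."""
    evidence = pile_up(readset, site_map)
    qc_pass, failed = qc_controls(evidence, site_map, config)
    if not qc_pass:
        return MethylationCall(
            sample_id=readset.sample_id, qc_pass=False, failed_controls=failed
        )
    return call_index(evidence, site_map, config, sample_id=readset.sample_id)


def categorize(index: int) -> tuple[str, str, str]:
    """Map an index 0-17 to its binary / tertile / quintile labels.

    An index of 0 is 'unmethylated' in every coding.  Tertile bins are 1-6,
    7-12, 13-17; quintile bins are 1-3, 4-6, 7-9, 10-13, 14-17 (note the
    deliberate boundary asymmetry: 13 is in tertile 13-17 but quintile
    10-13).
    """
    if not isinstance(index, (int,)) or isinstance(index, bool):
        raise TypeError("index must be an integer")
    if not 0 <= index <= 17:
        raise ValueError(f"index {index} outside [0, 17]")
    if index == 0:
        return ("unmethylated", "unmethylated", "unmethylated")
    if index <= 6:
        tertile = "1-6"
    elif index <= 12:
        tertile = "7-12"
    else:
        tertile = "13-17"
    if index <= 3:
        quintile = "1-3"
    elif index <= 6:
        quintile = "4-6"
    elif index <= 9:
        quintile = "7-9"
    elif index <= 13:
        quintile = "10-13"
    else:
        quintile = "14-17"
    return ("methylated", tertile, quintile)


# ---------------------------------------------------------------------------
# FASTA / CSV interfaces
# ---------------------------------------------------------------------------

_ORIENT_CODE = {"forward": "F", "reverse": "R"}
_CODE_ORIENT = {v: k for k, v in _ORIENT_CODE.items()}


def write_reads(readsets: Iterable[ReadSet], path: str | Path) -> None:
    """Write read sets as FASTA; IDs encode ``sample|orientation|replicate``."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = []
    for rs in readsets:
        for r in rs.reads:
            rid = f"{rs.sample_id}|{_ORIENT_CODE[r.orientation]}|{r.replicate}"
            records.append(SeqRecord(Seq(r.sequence), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_reads(path: str | Path) -> list[ReadSet]:
    """Parse a reads FASTA written by :func:`write_reads`."""
    from Bio import SeqIO

    grouped: dict[str, list[Read]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        try:
            sample_id, code, rep = record.id.rsplit("|", 2)
        except ValueError as exc:
            raise ValueError(
                f"read id {record.id!r} is not 'sample|orientation|replicate'"
            ) from exc
        grouped.setdefault(sample_id, []).append(
            Read(
                read_id=record.id,
                orientation=_CODE_ORIENT[code],
                replicate=int(rep),
                sequence=str(record.seq).upper(),
            )
        )
    return [ReadSet(sid, tuple(reads)) for sid, reads in grouped.items()]


def write_calls(calls: Iterable[MethylationCall], path: str | Path) -> None:
    """Write calls as CSV: sample, QC, index, codings, per-site M/U string."""
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle)
        writer.writerow(
            ["sample_id", "qc_pass", "index", "binary", "tertile", "quintile", "sites"]
        )
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.qc_pass,
                    "" if c.index is None else c.index,
                    c.binary or "",
                    c.tertile or "",
                    c.quintile or "",
                    c.site_string,
                ]
            )
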