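"""Bisulfite amplicon model: site maps, in-silico conversion, primer location.

The assay targets a short PCR amplicon of the *MGMT* promoter amplified from
bisulfite-treated DNA.  On the top strand, bisulfite treatment converts every
unmethylated cytosine to uracil (read as thymine after PCR) while methylated
CpG cytosines stay cytosine.  Cytosines outside a CpG context are essentially
never methylated, so every non-CpG cytosine of the template must read as T in
a successful conversion — they act as built-in conversion controls.

This module models exactly that chemistry on the top (sense) strand:

* :class:`AmpliconTemplate` — the pre-conversion reference sequence with its
  primers and optional genomic coordinates;
* :func:`build_site_map` — classify every template cytosine as CpG
  (methylatable, scored) or non-CpG (conversion control);
* :func:`bisulfite_convert` — convert one molecule given a binary per-CpG
  methylation allele;
* :func:`locate_amplicon` — find the primer-delimited amplicon span in a
  (converted-space) reference.

The packaged :data:`DEFAULT_TEMPLATE` is a synthetic 191 bp sequence built to
match the assay's printed structure — 17 CpG sites and 31 non-CpG cytosine
controls between/around the published primer pair — not the real GRCh38
promoter sequence.  Its nominal genomic coordinates are carried as metadata
only.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

__all__ = [
    "AmpliconTemplate",
    "SiteMap",
    "MethylationPattern",
    "MalformedSequenceError",
    "AmpliconNotFoundError",
    "AmbiguousPrimerError",
    "build_site_map",
    "bisulfite_convert",
    "locate_amplicon",
    "synthesize_template",
    "reverse_complement",
    "write_template",
    "read_template",
    "DEFAULT_FWD_PRIMER",
    "DEFAULT_REV_PRIMER",
    "DEFAULT_GENOMIC_COORDS",
    "DEFAULT_TEMPLATE",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: Published primer pair, written in bisulfite-converted space.
DEFAULT_FWD_PRIMER = "ATTATTTTTGTGATAGGAAAAGGTA"
DEFAULT_REV_PRIMER = "AAACAATCTACGCATCCT"

#: Nominal coordinates of the assayed promoter amplicon (1-based inclusive).
#: Metadata only — the packaged template sequence is synthetic.
DEFAULT_GENOMIC_COORDS = ("chr10", 129_466_812, 129_467_002, "GRCh38")


class MalformedSequenceError(ValueError):
    """Sequence contains a character outside A/C/G/T."""


class AmpliconNotFoundError(LookupError):
    """No primer-delimited amplicon span exists in the reference."""


class AmbiguousPrimerError(LookupError):
    """More than one primer-delimited amplicon span exists in the reference."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _check_sequence(seq: str) -> None:
    bad = set(seq) - _BASES
    if not seq or bad:
        raise MalformedSequenceError(
            f"sequence must be non-empty A/C/G/T; offending characters: {sorted(bad)}"
        )


@dataclass(frozen=True)
class SiteMap:
    """Positions (0-based) of CpG cytosines and non-CpG control cytosines."""

    cpg_positions: tuple[int, ...]
    control_positions: tuple[int, ...]

    @property
    def n_cpg(self) -> int:
        return len(self.cpg_positions)

    @property
    def n_controls(self) -> int:
        return len(self.control_positions)


@dataclass(frozen=True)
class MethylationPattern:
    """Ground-truth per-CpG methylated-allele fractions, one per CpG site."""

    fractions: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(not (0.0 <= f <= 1.0) for f in self.fractions):
            raise ValueError("allele fractions must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.fractions)


@dataclass(frozen=True)
class AmpliconTemplate:
    """Pre-conversion amplicon reference sequence.

    ``fwd_primer``/``rev_primer`` are given in bisulfite-converted space (as
    synthesized oligos are).  When both primers are present the template is
    validated to be exactly one primer-delimited amplicon.  ``genomic_coords``
    is ``(chrom, start, end, assembly)``, 1-based inclusive, metadata only.
    """

    name: str
    sequence: str
    fwd_primer: Optional[str] = None
    rev_primer: Optional[str] = None
    genomic_coords: Optional[tuple[str, int, int, str]] = None

    def __post_init__(self) -> None:
        _check_sequence(self.sequence)
        if self.fwd_primer and self.rev_primer:
            span = locate_amplicon(self.sequence, self.fwd_primer, self.rev_primer)
            if span != (0, len(self.sequence)):
                raise ValueError(
                    f"primers delimit {span}, not the full template "
                    f"(0, {len(self.sequence)})"
                )

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def site_map(self) -> SiteMap:
        return build_site_map(self)


def build_site_map(template: AmpliconTemplate | str) -> SiteMap:
    """Classify each template cytosine as CpG (followed by G) or control.

    Detection is dinucleotide-based on the pre-conversion sequence; a C at
    the final position has no following base and is therefore a control.
    """
    seq = template.sequence if isinstance(template, AmpliconTemplate) else template
    _check_sequence(seq)
    cpg, controls = [], []
    for i, base in enumerate(seq):
        if base != "C":
            continue
        if i + 1 < len(seq) and seq[i + 1] == "G":
            cpg.append(i)
        else:
            controls.append(i)
    return SiteMap(tuple(cpg), tuple(controls))


def bisulfite_convert(
    template: AmpliconTemplate | str,
    allele: Sequence[bool],
    site_map: Optional[SiteMap] = None,
) -> str:
    """Convert one molecule of the top strand given a realized per-CpG allele.

    Every control cytosine becomes T; a CpG cytosine stays C iff its allele
    entry is methylated (truthy).  A/G/T positions are untouched, so the
    output has the template's length.
    """
    seq = template.sequence if isinstance(template, AmpliconTemplate) else template
    if site_map is None:
        site_map = build_site_map(seq)
    if len(allele) != site_map.n_cpg:
        raise ValueError(
            f"allele has {len(allele)} entries for {site_map.n_cpg} CpG sites"
        )
    out = list(seq)
    for pos in site_map.control_positions:
        out[pos] = "T"
    for pos, methylated in zip(site_map.cpg_positions, allele):
        if not methylated:
            out[pos] = "T"
    return "".join(out)


def _match_positions(reference: str, probe: str, cpg: frozenset[int]) -> list[int]:
    """Start offsets where ``probe`` (converted space) matches the reference.

    The reference is compared in fully-converted space: C outside CpG reads
    as T; a CpG cytosine is ambiguous (matches C or T).
    """
    hits = []
    n, m = len(reference), len(probe)
    for i in range(n - m + 1):
        ok = True
        for o in range(m):
            p = i + o
            r, c = reference[p], probe[o]
            if p in cpg:
                if c not in ("C", "T"):
                    ok = False
                    break
            else:
                r_conv = "T" if r == "C" else r
                if r_conv != c:
                    ok = False
                    break
        if ok:
            hits.append(i)
    return hits


def locate_amplicon(
    reference: str, fwd_primer: str, rev_primer: str
) -> tuple[int, int]:
    """Locate the primer-delimited amplicon in a pre-conversion reference.

    Returns the 0-based half-open span ``(start, end)`` whose 5' end matches
    ``fwd_primer`` and whose 3' end matches the reverse complement of
    ``rev_primer``, both taken in bisulfite-converted space with CpG
    positions ambiguous (C or T).  Raises :class:`AmpliconNotFoundError` if
    no span exists and :class:`AmbiguousPrimerError` if several do.
    """
    _check_sequence(reference)
    cpg = frozenset(build_site_map(reference).cpg_positions)
    rc_rev = reverse_complement(rev_primer)
    fwd_hits = _match_positions(reference, fwd_primer, cpg)
    rev_hits = _match_positions(reference, rc_rev, cpg)
    spans = [
        (i, j + len(rc_rev))
        for i in fwd_hits
        for j in rev_hits
        if j >= i + len(fwd_primer)
    ]
    if not spans:
        raise AmpliconNotFoundError("no primer-delimited amplicon found")
    if len(spans) > 1:
        raise AmbiguousPrimerError(f"{len(spans)} candidate amplicon spans found")
    return spans[0]


def synthesize_template(
    n_cpg: int = 17,
    n_controls: int = 31,
    length: int = 191,
    fwd_primer: str = DEFAULT_FWD_PRIMER,
    rev_primer: str = DEFAULT_REV_PRIMER,
    name: str = "synthetic_amplicon",
    seed: Optional[int] = None,
) -> AmpliconTemplate:
    """Construct a synthetic amplicon template with a prescribed site census.

    The template starts with the forward primer verbatim (it must be C-free
    in converted space) and ends with the reverse complement of the reverse
    primer.  CpG dinucleotides inside that 3' footprint count toward
    ``n_cpg``; the remaining CpGs (as ``CG``) and all controls (as ``CA``/
    ``CT``) are interleaved with A/T filler in the interior so that no
    accidental CpG or control arises at token junctions.  With the default
    ``seed=None`` the token order is a deterministic even spread; a seed
    shuffles it.
    """
    import random

    rc_rev = reverse_complement(rev_primer)
    if set(fwd_primer) - _BASES or set(rev_primer) - _BASES:
        raise MalformedSequenceError("primers must be A/C/G/T")
    if "C" in fwd_primer:
        raise ValueError("forward primer must be C-free in converted space")
    tail_map = build_site_map(rc_rev) if "C" in rc_rev else SiteMap((), ())
    if tail_map.n_controls:
        raise ValueError(
            "reverse-primer footprint would contain control cytosines, which "
            "could never read as C in converted space"
        )
    inner_cpg = n_cpg - tail_map.n_cpg
    interior_len = length - len(fwd_primer) - len(rc_rev)
    n_filler = interior_len - 2 * inner_cpg - 2 * n_controls
    if inner_cpg < 0 or n_filler < 0:
        raise ValueError("requested site census does not fit in the length")

    tokens = (
        ["CG"] * inner_cpg
        + ["CT"] * ((n_controls + 1) // 2)
        + ["CA"] * (n_controls // 2)
        + ["A"] * ((n_filler + 1) // 2)
        + ["T"] * (n_filler // 2)
    )
    if seed is None:
        # deterministic even spread: round-robin interleave by token class
        classes = [
            ["CG"] * inner_cpg,
            ["CT"] * ((n_controls + 1) // 2) + ["CA"] * (n_controls // 2),
            ["A", "T"] * (n_filler // 2) + ["A"] * (n_filler % 2),
        ]
        tokens = []
        while any(classes):
            for cls in classes:
                if cls:
                    tokens.append(cls.pop())
    else:
        random.Random(seed).shuffle(tokens)

    sequence = fwd_primer + "".join(tokens) + rc_rev
    template = AmpliconTemplate(
        name=name,
        sequence=sequence,
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
    )
    site_map = template.site_map
    if (site_map.n_cpg, site_map.n_controls) != (n_cpg, n_controls):
        raise AssertionError(
            f"constructed {site_map.n_cpg} CpG / {site_map.n_controls} controls, "
            f"wanted {n_cpg}/{n_controls}"
        )
    return template


def _default_template() -> AmpliconTemplate:
    t = synthesize_template(name="MGMT_promoter_amplicon_synthetic")
    return AmpliconTemplate(
        name=t.name,
        sequence=t.sequence,
        fwd_primer=t.fwd_primer,
        rev_primer=t.rev_primer,
        genomic_coords=DEFAULT_GENOMIC_COORDS,
    )


#: Packaged default template: synthetic 191 bp sequence, 17 CpG, 31 controls.
DEFAULT_TEMPLATE = _default_template()


def write_template(
    template: AmpliconTemplate,
    fasta_path: str | Path,
    sidecar_path: Optional[str | Path] = None,
) -> None:
    """Write the template as single-record FASTA plus a JSON site-map sidecar."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    fasta_path = Path(fasta_path)
    record = SeqRecord(Seq(template.sequence), id=template.name, description="")
    SeqIO.write([record], str(fasta_path), "fasta")
    if sidecar_path is None:
        sidecar_path = fasta_path.with_suffix(".json")
    sm = template.site_map
    payload = {
        "name": template.name,
        "cpg_positions": list(sm.cpg_positions),
        "control_positions": list(sm.control_positions),
        "fwd_primer": template.fwd_primer,
        "rev_primer": template.rev_primer,
        "genomic_coords": list(template.genomic_coords)
        if template.genomic_coords
        else None,
    }
    Path(sidecar_path).write_text(json.dumps(payload, indent=2) + "\n")


def read_template(
    fasta_path: str | Path, sidecar_path: Optional[str | Path] = None
) -> AmpliconTemplate:
    """Load a template FASTA; if a sidecar exists, verify its site map."""
    from Bio import SeqIO

    fasta_path = Path(fasta_path)
    record = next(SeqIO.parse(str(fasta_path), "fasta"))
    if sidecar_path is None:
        candidate = fasta_path.with_suffix(".json")
        sidecar_path = candidate if candidate.exists() else None
    meta: dict = {}
    if sidecar_path is not None:
        meta = json.loads(Path(sidecar_path).read_text())
    template = AmpliconTemplate(
        name=meta.get("name", record.id),
        sequence=str(record.seq).upper(),
        fwd_primer=meta.get("fwd_primer"),
        rev_primer=meta.get("rev_primer"),
        genomic_coords=tuple(meta["genomic_coords"])
        if meta.get("genomic_coords")
        else None,
    )
    if meta:
        sm = template.site_map
        if list(sm.cpg_positions) != meta.get("cpg_positions", list(sm.cpg_positions)):
            raise ValueError("sidecar CpG positions disagree with the sequence")
        if list(sm.control_positions) != meta.get(
            "control_positions", list(sm.control_positions)
        ):
            raise ValueError("sidecar control positions disagree with the sequence")
    return template
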